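import numpy as np
import pytest

from aegiscan.genotype_io import CallMatrix, Marker, Sample
from aegiscan.synthetic_data import (IntrogressionBlock, SimulationConfig,
                                     SpeciesSpec, simulate_species_panel,
                                     simulate_introgression_lines)


def make_matrix(calls, chromosome="1A", spacing=1_000_000, species=None,
                roles=None):
    """Small CallMatrix from a 2-D list: rows = markers, cols = samples."""
    calls = np.asarray(calls, dtype=np.int8)
    n_m, n_s = calls.shape
    markers = [Marker(marker_id=f"M{i:03d}", chromosome=chromosome,
                      position_bp=i * spacing, allele_a="A", allele_b="G")
               for i in range(n_m)]
    species = species or [f"sp{j}" for j in range(n_s)]
    roles = roles or ["relative"] * n_s
    samples = [Sample(sample_id=f"S{j:02d}", species=species[j],
                      role=roles[j]) for j in range(n_s)]
    return CallMatrix(markers=markers, samples=samples, calls=calls)


@pytest.fixture
def toy_matrix():
    # 4 markers × 4 samples with one no-call apiece
    return make_matrix([
        [0, 0, 2, 1],
        [1, 0, 1, 1],
        [2, 2, 0, 1],
        [-1, 2, 1, 1],
    ])


@pytest.fixture(scope="session")
def panel_sim():
    """Mixed-ploidy species panel with mild noise (seeded)."""
    cfg = SimulationConfig(seed=11, n_markers=400)
    return simulate_species_panel(cfg)


@pytest.fixture(scope="session")
def clean_diploid_panel():
    """Four diploid species, five accessions each, noise-free."""
    cfg = SimulationConfig(
        seed=7, n_markers=300, nocall_rate=0.0, call_error_rate=0.0,
        unmapped_fraction=0.0,
        species=tuple(SpeciesSpec(name, formula, 5) for name, formula in
                      [("Aegilops tauschii", "DD"),
                       ("Aegilops speltoides", "SS"),
                       ("Aegilops umbellulata", "UU"),
                       ("Aegilops comosa", "MM")]))
    return simulate_species_panel(cfg)


@pytest.fixture(scope="session")
def introgression_sim():
    """Noise-free hexaploid lines: one donor block each, plus a null line."""
    blocks = (
        IntrogressionBlock("L_block1", "Aegilops sharonensis", "1B",
                           100_000_000, 400_000_000),
        IntrogressionBlock("L_block2", "Aegilops sharonensis", "1A",
                           50_000_000, 250_000_000),
    )
    cfg = SimulationConfig(
        seed=5, n_markers=900, chromosomes=("1A", "1B", "1D"),
        nocall_rate=0.0, call_error_rate=0.0, blocks=blocks,
        test_line_ids=("L_block1", "L_block2", "L_null"))
    return simulate_introgression_lines(cfg)
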