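"""Ground-truthed simulation of polyploid SNP-array genotyping.

Two generators share a probe-response model for biallelic array probes on
allopolyploid genomes:

* :func:`simulate_species_panel` — a mixed-ploidy panel of wild-relative
  species.  Per species and subgenome, each marker gets a B-allele frequency;
  accession genotypes are drawn under Hardy–Weinberg within subgenomes; the
  probe model turns each accession's subgenome alleles into a B-allele
  hybridization fraction; and cohort-relative cluster calling converts
  fractions into 0/1/2 calls, exactly as an intensity-clustering caller does
  when polyploid cohorts are screened together.

* :func:`simulate_introgression_lines` — hexaploid wheat lines (AABBDD)
  carrying donor chromatin blocks at known coordinates, plus the donor
  accessions and wheat backgrounds needed to detect them.  Inside a declared
  block the line's homoeologous wheat subgenome carries the donor parent's
  allele pair; the :class:`TruthTrack` records per-marker origin.

Probe behaviour follows the array's two hybridization classes: a
*co-dominant* probe reads a single subgenome, so heterozygotes separate from
both homozygotes; a *dominant* (cross-genome) probe reads several
homoeologous subgenomes at once, so cluster positions depend on the whole
cohort.  The canonical cohort — DDMMUU accessions ABAAAA and BBAAAA screened
with a DD accession AB under a dominant D/M/U probe — yields hybridization
fractions 1/6, 2/6 and 1/2, called 0, 1 and 2 by ascending rank.

Noise (call errors, then no-calls) is injected after calling.  All draws
come from one seeded generator consumed in a fixed order (probes →
frequencies → genotypes → noise), so a fixed seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import CallMatrix, Marker, Sample, NOCALL, UNMAPPED

__all__ = [
    "SubgenomeGenotype", "ProbeSpec", "SpeciesSpec", "IntrogressionBlock",
    "SimulationConfig", "TruthTrack", "PanelTruth",
    "parse_genome_formula", "b_allele_fraction", "cluster_call_cohort",
    "simulate_species_panel", "simulate_introgression_lines",
]


def parse_genome_formula(formula: str) -> tuple[str, ...]:
    """Split a genome formula into its subgenome letters, one per diploid set.

    ``"DDMMUU" -> ("D", "M", "U")``; ``"DDMMMM" -> ("D", "M", "M")``.
    """
    if not formula or len(formula) % 2:
        raise ValueError(f"bad genome formula {formula!r}")
    letters = []
    for i in range(0, len(formula), 2):
        if formula[i] != formula[i + 1]:
            raise ValueError(
                f"bad genome formula {formula!r}: subgenome letters come in "
                "pairs")
        letters.append(formula[i])
    return tuple(letters)


@dataclass(frozen=True)
class SubgenomeGenotype:
    """Per-subgenome allele pairs of one (possibly polyploid) accession.

    ``pairs`` is aligned with the subgenome sets of ``genome_formula``:
    a DDMMUU accession with compact genotype ``ABAAAA`` has pairs
    ``(("A","B"), ("A","A"), ("A","A"))``.
    """

    genome_formula: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        subg = parse_genome_formula(self.genome_formula)
        if len(self.pairs) != len(subg):
            raise ValueError(
                f"{len(self.pairs)} allele pairs for formula "
                f"{self.genome_formula!r} ({len(subg)} subgenomes)")
        for pair in self.pairs:
            if len(pair) != 2 or any(a not in "AB" for a in pair):
                raise ValueError(f"bad allele pair {pair!r}")

    @property
    def subgenomes(self) -> tuple[str, ...]:
        return parse_genome_formula(self.genome_formula)

    @property
    def ploidy(self) -> int:
        return 2 * len(self.pairs)

    @classmethod
    def from_compact(cls, genome_formula: str, compact: str
                     ) -> "SubgenomeGenotype":
        """Build from a compact allele string, e.g. ``("DDMMUU", "ABAAAA")``."""
        subg = parse_genome_formula(genome_formula)
        if len(compact) != 2 * len(subg):
            raise ValueError(
                f"compact genotype {compact!r} has {len(compact)} alleles; "
                f"formula {genome_formula!r} needs {2 * len(subg)}")
        pairs = tuple((compact[2 * i], compact[2 * i + 1])
                      for i in range(len(subg)))
        return cls(genome_formula=genome_formula, pairs=pairs)

    def compact(self) -> str:
        return "".join(a for pair in self.pairs for a in pair)


@dataclass(frozen=True)
class ProbeSpec:
    """Hybridization behaviour of one array probe."""

    marker_id: str
    hybridizing_subgenomes: frozenset[str]
    mode: str  # co_dominant_specific | dominant_cross_genome

    def __post_init__(self) -> None:
        n = len(self.hybridizing_subgenomes)
        if n == 0:
            raise ValueError(f"probe {self.marker_id}: empty subgenome set")
        if self.mode == "co_dominant_specific" and n != 1:
            raise ValueError(
                f"probe {self.marker_id}: co-dominant probes read exactly one "
                f"subgenome, got {n}")
        if self.mode == "dominant_cross_genome" and n < 2:
            raise ValueError(
                f"probe {self.marker_id}: dominant probes read ≥2 subgenomes")
        if self.mode not in ("co_dominant_specific", "dominant_cross_genome"):
            raise ValueError(f"probe {self.marker_id}: bad mode {self.mode!r}")


def b_allele_fraction(genotype: SubgenomeGenotype, probe: ProbeSpec) -> float:
    """B-allele fraction a probe reads from an accession.

    Only subgenome copies the probe hybridizes to contribute:
    (# B alleles among hybridizing copies) / (2 × # hybridizing copies).
    A dominant D/M/U probe on a DDMMUU accession ABAAAA reads 1/6; the same
    probe on a diploid DD accession AB reads 1/2 (only the D copy is
    present).  Raises if no hybridizing subgenome occurs in the accession.
    """
    pairs = [pair for letter, pair in zip(genotype.subgenomes, genotype.pairs)
             if letter in probe.hybridizing_subgenomes]
    if not pairs:
        raise ValueError(
            f"probe {probe.marker_id} targets "
            f"{sorted(probe.hybridizing_subgenomes)} but accession genome is "
            f"{genotype.genome_formula}")
    n_b = sum(a == "B" for pair in pairs for a in pair)
    return n_b / (2 * len(pairs))


def cluster_call_cohort(fractions: Sequence[float | None],
                        resolution: float = 1 / 24,
                        ) -> tuple[np.ndarray, bool]:
    """Cohort-relative cluster calling at one locus.

    Distinct hybridization-fraction values (after snapping to ``resolution``)
    are ranked ascending and mapped to calls 0, 1, 2.  Samples whose fraction
    is None (probe does not hybridize) are NOCALL.  Loci with more than three
    distinct clusters behave like off-target variants: every call is set to
    NOCALL and the locus is flagged.

    Returns ``(calls, otv_flagged)``.
    """
    if len(fractions) == 0:
        raise ValueError("empty cohort")
    keys = [None if f is None else round(f / resolution) for f in fractions]
    levels = sorted({k for k in keys if k is not None})
    calls = np.full(len(fractions), NOCALL, dtype=np.int8)
    if len(levels) > 3:
        return calls, True
    rank = {k: i for i, k in enumerate(levels)}
    for j, k in enumerate(keys):
        if k is not None:
            calls[j] = rank[k]
    return calls, False


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """One species in a simulated panel.

    ``prob_polymorphic`` is the chance a (marker, subgenome) is segregating
    within the species; when it is not, the subgenome is fixed for A or B
    with equal probability (fixed differences between species are what the
    array was selected for).  Segregating B-allele frequencies are drawn
    from Beta(*maf_beta*).
    """

    name: str
    genome_formula: str
    n_accessions: int
    prob_polymorphic: float = 0.4
    maf_beta: tuple[float, float] = (0.8, 0.8)

    def __post_init__(self) -> None:
        parse_genome_formula(self.genome_formula)
        if self.n_accessions < 0:
            raise ValueError(f"{self.name}: negative accession count")


@dataclass(frozen=True)
class IntrogressionBlock:
    """A donor chromatin block carried by one test line (0-based half-open)."""

    line_id: str
    donor_species: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0 or self.start_bp >= self.end_bp:
            raise ValueError(
                f"block {self.chromosome}:{self.start_bp}-{self.end_bp}: "
                "need 0 <= start < end")


def _default_species() -> tuple[SpeciesSpec, ...]:
    # a cross-section of the genus: three ploidy levels, distinct genomes,
    # accession counts as genotyped on the array
    return (
        SpeciesSpec("Aegilops mutica", "TT", 12),
        SpeciesSpec("Aegilops comosa", "MM", 14),
        SpeciesSpec("Aegilops tauschii", "DD", 22),
        SpeciesSpec("Aegilops umbellulata", "UU", 15),
        SpeciesSpec("Aegilops juvenalis", "DDMMUU", 5),
    )


@dataclass
class SimulationConfig:
    """Knobs for both generators; a fixed seed gives bit-identical output."""

    seed: int = 0
    n_markers: int = 2000
    species: tuple[SpeciesSpec, ...] = field(default_factory=_default_species)
    fraction_co_dominant: float = 0.7
    nocall_rate: float = 0.05
    call_error_rate: float = 0.01
    cluster_resolution: float = 1 / 24
    chromosomes: tuple[str, ...] = ("1A", "1B", "1D", "2A", "2B", "2D",
                                    "3A", "3B", "3D")
    chromosome_length_bp: int = 600_000_000
    unmapped_fraction: float = 0.02
    # introgression-specific
    n_background_lines: int = 2
    n_donor_accessions: int = 2
    donor_divergence: float = 0.9
    donor_het_rate: float = 0.05
    blocks: tuple[IntrogressionBlock, ...] = ()
    test_line_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("nocall_rate", "call_error_rate", "unmapped_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name}={v} outside [0, 1)")
        if not (0 <= self.fraction_co_dominant <= 1):
            raise ValueError("fraction_co_dominant outside [0, 1]")
        if not (0 <= self.donor_divergence <= 1):
            raise ValueError("donor_divergence outside [0, 1]")
        if self.n_markers < 1:
            raise ValueError("n_markers must be positive")
        self.species = tuple(
            s if isinstance(s, SpeciesSpec) else SpeciesSpec(**s)
            for s in self.species)
        self.blocks = tuple(
            b if isinstance(b, IntrogressionBlock) else IntrogressionBlock(**b)
            for b in self.blocks)
        self.chromosomes = tuple(self.chromosomes)
        self.test_line_ids = tuple(self.test_line_ids)

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["species"] = [asdict(s) for s in self.species]
        data["blocks"] = [asdict(b) for b in self.blocks]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data["species"] = tuple(SpeciesSpec(**{**s, "maf_beta": tuple(
            s.get("maf_beta", (0.8, 0.8)))}) for s in data.get("species", []))
        data["blocks"] = tuple(IntrogressionBlock(**b)
                               for b in data.get("blocks", []))
        return cls(**data)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class PanelTruth:
    """Ground truth behind a simulated species panel."""

    genotypes: dict[str, list[SubgenomeGenotype]]  # sample -> per-marker truth
    frequencies: dict[str, np.ndarray]  # species -> (n_subgenomes, n_markers)
    probes: list[ProbeSpec]
    otv_flagged: np.ndarray  # per-marker off-target-variant flag


@dataclass
class TruthTrack:
    """Per-marker origin labels for simulated introgression lines."""

    origin: pd.DataFrame  # index marker_id, columns line ids
    blocks: tuple[IntrogressionBlock, ...]

    def donor_markers(self, line_id: str) -> list[str]:
        col = self.origin[line_id]
        return list(col.index[col == "donor"])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.origin.to_csv(path, sep="\t", index_label="marker_id")
        return path

    def blocks_bed(self, path: str | Path) -> Path:
        path = Path(path)
        rows = sorted(self.blocks,
                      key=lambda b: (b.line_id, b.chromosome, b.start_bp))
        with open(path, "w") as fh:
            for b in rows:
                fh.write(f"{b.chromosome}\t{b.start_bp}\t{b.end_bp}\t"
                         f"{b.line_id}\t{b.donor_species}\n")
        return path


# ---------------------------------------------------------------------------
# marker scaffolding shared by both generators
# ---------------------------------------------------------------------------

def _draw_markers(cfg: SimulationConfig, rng: np.random.Generator,
                  allow_unmapped: bool) -> list[Marker]:
    n = cfg.n_markers
    n_unmapped = int(round(cfg.unmapped_fraction * n)) if allow_unmapped else 0
    n_mapped = n - n_unmapped
    chroms = cfg.chromosomes
    per = np.full(len(chroms), n_mapped // len(chroms))
    per[: n_mapped % len(chroms)] += 1
    nucs = np.array(list("ACGT"))
    markers: list[Marker] = []
    k = 0

    def alleles() -> tuple[str, str]:
        a, b = rng.choice(4, size=2, replace=False)
        return str(nucs[a]), str(nucs[b])

    for chrom, cnt in zip(chroms, per):
        pos = np.sort(rng.integers(0, cfg.chromosome_length_bp, size=cnt))
        # nudge collisions apart to keep positions strictly increasing
        for i in range(1, cnt):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        for p in pos:
            a, b = alleles()
            markers.append(Marker(marker_id=f"AX-{k:06d}", chromosome=chrom,
                                  position_bp=int(p), allele_a=a,
                                  allele_b=b))
            k += 1
    for _ in range(n_unmapped):
        a, b = alleles()
        markers.append(Marker(marker_id=f"AX-{k:06d}", chromosome=UNMAPPED,
                              position_bp=None, allele_a=a, allele_b=b))
        k += 1
    return markers


def _apply_noise(calls: np.ndarray, cfg: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Inject call errors, then no-calls (in this documented order)."""
    calls = calls.copy()
    called = calls != NOCALL
    if cfg.call_error_rate > 0:
        err = called & (rng.random(calls.shape) < cfg.call_error_rate)
        # replace with one of the two other valid codes
        shift = rng.integers(1, 3, size=calls.shape)
        calls[err] = (calls[err] + shift[err]) % 3
    if cfg.nocall_rate > 0:
        drop = rng.random(calls.shape) < cfg.nocall_rate
        calls[drop] = NOCALL
    return calls


def _sample_id(species: str, i: int) -> str:
    return species.replace(" ", "_").replace(".", "") + f"_{i + 1:02d}"


# ---------------------------------------------------------------------------
# species panel generator
# ---------------------------------------------------------------------------

def simulate_species_panel(config: SimulationConfig
                           ) -> tuple[CallMatrix, PanelTruth]:
    """Simulate a mixed-ploidy relative-species panel on the array.

    Draw order under one seeded generator: marker placement → probe classes →
    per-species subgenome B-allele frequencies → accession genotypes →
    cohort cluster calling (deterministic) → noise.
    """
    for sp in config.species:
        if sp.n_accessions == 0:
            raise ValueError(f"species {sp.name} has zero accessions")
    if not config.species:
        raise ValueError("no species configured")
    rng = np.random.default_rng(config.seed)

    markers = _draw_markers(config, rng, allow_unmapped=True)
    universe = sorted({letter for sp in config.species
                       for letter in parse_genome_formula(sp.genome_formula)})

    # probe classes
    probes: list[ProbeSpec] = []
    for m in markers:
        if len(universe) >= 2 and rng.random() >= config.fraction_co_dominant:
            size = int(rng.integers(2, len(universe) + 1))
            letters = rng.choice(universe, size=size, replace=False)
            probes.append(ProbeSpec(m.marker_id, frozenset(letters.tolist()),
                                    "dominant_cross_genome"))
        else:
            letter = universe[int(rng.integers(len(universe)))]
            probes.append(ProbeSpec(m.marker_id, frozenset({letter}),
                                    "co_dominant_specific"))

    # per-species, per-subgenome allele frequencies
    n = config.n_markers
    freqs: dict[str, np.ndarray] = {}
    for sp in config.species:
        subg = parse_genome_formula(sp.genome_formula)
        a, b = sp.maf_beta
        f = np.where(rng.random((len(subg), n)) < sp.prob_polymorphic,
                     rng.beta(a, b, size=(len(subg), n)),
                     rng.integers(0, 2, size=(len(subg), n)).astype(float))
        freqs[sp.name] = f

    # accession genotypes
    samples: list[Sample] = []
    genotypes: dict[str, list[SubgenomeGenotype]] = {}
    for sp in config.species:
        subg = parse_genome_formula(sp.genome_formula)
        f = freqs[sp.name]
        for i in range(sp.n_accessions):
            sid = _sample_id(sp.name, i)
            draws = rng.random((2, len(subg), n)) < f[None, :, :]
            per_marker = []
            for j in range(n):
                pairs = tuple(("B" if draws[0, g, j] else "A",
                               "B" if draws[1, g, j] else "A")
                              for g in range(len(subg)))
                per_marker.append(SubgenomeGenotype(sp.genome_formula, pairs))
            genotypes[sid] = per_marker
            samples.append(Sample(sample_id=sid, species=sp.name,
                                  genome_formula=sp.genome_formula,
                                  ploidy=2 * len(subg), role="relative"))

    # cohort cluster calling, locus by locus.  Probes derive from wheat genic
    # sequence, so accessions lacking every target subgenome still hybridize
    # through their homoeologous copies: a co-dominant probe then reads the
    # accession's first subgenome, a dominant probe all of them.
    calls = np.empty((n, len(samples)), dtype=np.int8)
    otv = np.zeros(n, dtype=bool)
    for j, probe in enumerate(probes):
        fractions: list[float | None] = []
        for s in samples:
            geno = genotypes[s.sample_id][j]
            present = set(geno.subgenomes) & probe.hybridizing_subgenomes
            if present:
                fractions.append(b_allele_fraction(geno, probe))
            elif probe.mode == "co_dominant_specific":
                pair = geno.pairs[0]
                fractions.append(sum(a == "B" for a in pair) / 2)
            else:
                n_b = sum(a == "B" for p in geno.pairs for a in p)
                fractions.append(n_b / geno.ploidy)
        calls[j], otv[j] = cluster_call_cohort(
            fractions, resolution=config.cluster_resolution)

    calls = _apply_noise(calls, config, rng)
    matrix = CallMatrix(markers=markers, samples=samples, calls=calls)
    truth = PanelTruth(genotypes=genotypes, frequencies=freqs,
                       probes=probes, otv_flagged=otv)
    return matrix, truth


# ---------------------------------------------------------------------------
# introgression line generator
# ---------------------------------------------------------------------------

_WHEAT_FORMULA = "AABBDD"


def simulate_introgression_lines(config: SimulationConfig
                                 ) -> tuple[CallMatrix, TruthTrack]:
    """Simulate hexaploid test lines carrying donor introgression blocks.

    The cohort contains wheat background cultivars, donor accessions of every
    species named in ``config.blocks``, and the test lines.  At each mapped
    marker the probe reads one wheat subgenome (the chromosome's letter) for
    wheat-background material and the donor's own (homoeologous) genome for
    donor accessions; calls are allele-pair dosages (AA→0, AB→1, BB→2), the
    straightforward co-dominant case.  Inside a declared block the test
    line's interrogated pair is replaced by the donor parent's pair before
    calling; noise is injected afterwards.
    """
    rng = np.random.default_rng(config.seed)
    markers = _draw_markers(config, rng, allow_unmapped=False)
    n = config.n_markers

    donor_species = []
    for b in config.blocks:
        if b.donor_species not in donor_species:
            donor_species.append(b.donor_species)
        if b.chromosome not in config.chromosomes:
            raise ValueError(
                f"block for {b.line_id} on unknown chromosome "
                f"{b.chromosome!r}")
    line_ids = list(config.test_line_ids) or sorted(
        {b.line_id for b in config.blocks})
    for b in config.blocks:
        if b.line_id not in line_ids:
            raise ValueError(f"block names unknown test line {b.line_id!r}")
    by_line: dict[str, list[IntrogressionBlock]] = {l: [] for l in line_ids}
    for b in config.blocks:
        for other in by_line[b.line_id]:
            if (other.chromosome == b.chromosome
                    and b.start_bp < other.end_bp
                    and other.start_bp < b.end_bp):
                raise ValueError(
                    f"overlapping blocks on {b.chromosome} for line "
                    f"{b.line_id}")
        by_line[b.line_id].append(b)

    # wheat cultivar dosage at the interrogated subgenome: fixed A or B
    wheat_dosage = rng.integers(0, 2, size=n) * 2  # 0 (AA) or 2 (BB)

    # donor parent dosages: diverged from wheat at ~donor_divergence of loci,
    # with a small residual heterozygosity (selfing wild species)
    donor_dosage: dict[str, np.ndarray] = {}
    for spname in donor_species:
        flip = rng.random(n) < config.donor_divergence
        dos = np.where(flip, 2 - wheat_dosage, wheat_dosage)
        het = rng.random(n) < config.donor_het_rate
        dos = np.where(het, 1, dos)
        donor_dosage[spname] = dos.astype(np.int8)

    samples: list[Sample] = []
    cols: list[np.ndarray] = []

    for i in range(config.n_background_lines):
        samples.append(Sample(sample_id=f"wheat_bg_{i + 1:02d}",
                              species="Triticum aestivum",
                              genome_formula=_WHEAT_FORMULA, ploidy=6,
                              role="wheat_background"))
        cols.append(wheat_dosage.astype(np.int8))

    donor_parent: dict[str, str] = {}
    for spname in donor_species:
        for i in range(config.n_donor_accessions):
            sid = _sample_id(spname, i)
            samples.append(Sample(sample_id=sid, species=spname,
                                  ploidy=2, role="relative"))
            if i == 0:
                donor_parent[spname] = sid
                cols.append(donor_dosage[spname].copy())
            else:
                # sibling accession: mostly the parent's alleles
                dos = donor_dosage[spname].copy()
                differ = rng.random(n) < 0.05
                dos[differ] = rng.integers(0, 3, size=int(differ.sum()))
                cols.append(dos)

    chrom_arr = np.array([m.chromosome for m in markers])
    pos_arr = np.array([m.position_bp for m in markers])
    origin = pd.DataFrame("background",
                          index=[m.marker_id for m in markers],
                          columns=line_ids)
    for line in line_ids:
        dos = wheat_dosage.astype(np.int8).copy()
        for b in by_line[line]:
            inside = ((chrom_arr == b.chromosome) & (pos_arr >= b.start_bp)
                      & (pos_arr < b.end_bp))
            dos[inside] = donor_dosage[b.donor_species][inside]
            origin.loc[inside, line] = "donor"
        samples.append(Sample(sample_id=line, species="Triticum aestivum",
                              genome_formula=_WHEAT_FORMULA, ploidy=6,
                              role="test_line"))
        cols.append(dos)

    calls = _apply_noise(np.column_stack(cols), config, rng)
    matrix = CallMatrix(markers=markers, samples=samples, calls=calls)
    return matrix, TruthTrack(origin=origin, blocks=tuple(config.blocks))
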