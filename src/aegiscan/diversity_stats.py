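"""Polymorphism counts, Nei's standard genetic distance and Fst.

Genotype calls are treated as B-allele dosages (0, 1, 2); no-calls are
excluded from every denominator.  Population allele frequencies therefore
come from called alleles only, with no imputation: a locus is usable for a
between-population statistic only if every population involved has at least
one called allele there.

Nei's standard genetic distance between populations with per-locus B-allele
frequencies x and y, averaged over usable loci::

    Jx  = mean(x^2 + (1-x)^2)        within-population identity
    Jxy = mean(x*y + (1-x)*(1-y))    between-population identity
    D   = -ln( Jxy / sqrt(Jx * Jy) )

Fst defaults to the Hudson estimator as a ratio of per-locus averages
(numerator (x-y)^2 - x(1-x)/(n_x-1) - y(1-y)/(n_y-1); denominator
x(1-y) + y(1-x)), with Nei's Gst available as an alternative; negative
multi-locus estimates are clamped to 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import (CallMatrix, SpeciesSummaryTable, NOCALL)

__all__ = [
    "AlleleFrequencySet", "PairwiseMatrix",
    "allele_frequencies", "count_polymorphic_within",
    "count_polymorphic_vs_reference", "subsample_polymorphism",
    "r_squared", "nei_standard_distance", "fst",
    "species_summary_percentages", "pairwise_species_matrices",
]


@dataclass
class AlleleFrequencySet:
    """Per-marker B-allele frequencies of one population.

    ``n_called_alleles`` counts called allele copies per marker (2 × called
    genotypes); markers with zero called alleles are unusable and carry
    frequency NaN.
    """

    marker_ids: list[str]
    freq_b: np.ndarray
    n_called_alleles: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.freq_b = np.asarray(self.freq_b, dtype=float)
        self.n_called_alleles = np.asarray(self.n_called_alleles, dtype=int)
        if not (len(self.marker_ids) == self.freq_b.size
                == self.n_called_alleles.size):
            raise ValueError("marker/frequency/count lengths disagree")
        ok = self.usable
        if np.any((self.freq_b[ok] < 0) | (self.freq_b[ok] > 1)):
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def usable(self) -> np.ndarray:
        return self.n_called_alleles > 0


def allele_frequencies(matrix: CallMatrix,
                       sample_ids: list[str] | None = None,
                       label: str = "") -> AlleleFrequencySet:
    """B-allele frequencies over a sample subset (default: all samples)."""
    sub = matrix if sample_ids is None else matrix.subset_samples(sample_ids)
    calls = sub.calls
    called = calls != NOCALL
    n_alleles = 2 * called.sum(axis=1)
    dosage = np.where(called, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, dosage / np.maximum(n_alleles, 1),
                        np.nan)
    return AlleleFrequencySet(marker_ids=sub.marker_ids, freq_b=freq,
                              n_called_alleles=n_alleles, label=label)


# ---------------------------------------------------------------------------
# polymorphism counting
# ---------------------------------------------------------------------------

def count_polymorphic_within(matrix: CallMatrix, species: str) -> int:
    """Markers with ≥2 distinct called genotypes among a species' accessions."""
    idx = matrix.species_columns(species)  # raises on unknown species
    if idx.size < 2:
        raise ValueError(
            f"species {species!r} has {idx.size} accession(s); polymorphism "
            "within a species needs at least 2")
    calls = matrix.calls[:, idx]
    return int(_polymorphic_mask(calls).sum())


def _polymorphic_mask(calls: np.ndarray) -> np.ndarray:
    called = calls != NOCALL
    lo = np.where(called, calls, 3).min(axis=1)
    hi = np.where(called, calls, -2).max(axis=1)
    return (called.sum(axis=1) >= 2) & (hi > lo) & (lo != 3)


def count_polymorphic_vs_reference(matrix: CallMatrix, species: str,
                                   reference_samples: list[str]) -> int:
    """Markers where any called genotype in the species differs from any
    called genotype in the reference group (e.g. the wheat samples)."""
    if not reference_samples:
        raise ValueError("empty reference group")
    sp_idx = matrix.species_columns(species)
    ref_idx = np.array([matrix.sample_index(s) for s in reference_samples])
    a, b = matrix.calls[:, sp_idx], matrix.calls[:, ref_idx]
    count = 0
    for i in range(matrix.n_markers):
        va = set(int(c) for c in a[i] if c != NOCALL)
        vb = set(int(c) for c in b[i] if c != NOCALL)
        if not va or not vb:
            continue  # a side with no calls cannot show a difference
        if va != vb or len(va) > 1:
            count += 1
    return count


def subsample_polymorphism(matrix: CallMatrix, species: str, k: int,
                           n_rep: int, seed: int) -> list[int]:
    """Within-species polymorphism counts over random accession subsets.

    Draws ``n_rep`` subsets of ``k`` accessions without replacement and
    returns :func:`count_polymorphic_within` for each; deterministic under
    ``seed``.
    """
    idx = matrix.species_columns(species)
    if k > idx.size:
        raise ValueError(
            f"k={k} exceeds the {idx.size} accessions of {species!r}")
    if k < 2:
        raise ValueError("subsets need k >= 2 accessions")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_rep):
        pick = rng.choice(idx, size=k, replace=False)
        counts.append(int(_polymorphic_mask(matrix.calls[:, pick]).sum()))
    return counts


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y)[0] ** 2)


# ---------------------------------------------------------------------------
# Nei's standard genetic distance and Fst
# ---------------------------------------------------------------------------

def _joint_usable(p: AlleleFrequencySet, q: AlleleFrequencySet) -> np.ndarray:
    if p.marker_ids != q.marker_ids:
        raise ValueError("frequency sets are on different marker panels")
    both = p.usable & q.usable
    if not both.any():
        raise ValueError("no jointly usable loci")
    return both

def nei_standard_distance(p: AlleleFrequencySet,
                          q: AlleleFrequencySet) -> float:
    """Nei's standard genetic distance D over jointly usable loci.

    Returns ``inf`` when the between-population identity Jxy is zero
    (populations fixed for opposite alleles at every usable locus).
    """
    both = _joint_usable(p, q)
    x, y = p.freq_b[both], q.freq_b[both]
    jx = float(np.mean(x ** 2 + (1 - x) ** 2))
    jy = float(np.mean(y ** 2 + (1 - y) ** 2))
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    if jxy == 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def fst(p: AlleleFrequencySet, q: AlleleFrequencySet,
        estimator: str = "hudson") -> float:
    """Multi-locus Fst between two populations, clamped to [0, 1].

    ``hudson`` (default) is the ratio-of-averages Hudson estimator with
    sample-size correction; ``nei_gst`` is Nei's Gst from mean expected
    heterozygosities.  Loci need ≥2 called alleles per population for the
    Hudson correction terms.
    """
    both = _joint_usable(p, q)
    if estimator == "hudson":
        both = both & (p.n_called_alleles >= 2) & (q.n_called_alleles >= 2)
        if not both.any():
            raise ValueError("no loci with >= 2 called alleles in both "
                             "populations")
        x, y = p.freq_b[both], q.freq_b[both]
        nx = p.n_called_alleles[both].astype(float)
        ny = q.n_called_alleles[both].astype(float)
        num = ((x - y) ** 2
               - x * (1 - x) / (nx - 1)
               - y * (1 - y) / (ny - 1))
        den = x * (1 - y) + y * (1 - x)
        total_den = float(den.sum())
        if total_den == 0:
            return 0.0
        est = float(num.sum() / total_den)
    elif estimator == "nei_gst":
        x, y = p.freq_b[both], q.freq_b[both]
        hs = float(np.mean((2 * x * (1 - x) + 2 * y * (1 - y)) / 2))
        m = (x + y) / 2
        ht = float(np.mean(2 * m * (1 - m)))
        if ht == 0:
            return 0.0
        est = (ht - hs) / ht
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    return float(min(1.0, max(0.0, est)))


@dataclass
class PairwiseMatrix:
    """Species × species matrix of a pairwise statistic (zero diagonal)."""

    labels: list[str]
    values: np.ndarray
    statistic: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


def pairwise_species_matrices(matrix: CallMatrix,
                              species: list[str] | None = None,
                              estimator: str = "hudson",
                              ) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Nei D and Fst between every species pair of a panel.

    Returns ``(nei_d, fst)`` matrices in the printed two-statistic layout's
    ordering (labels alphabetical unless given).
    """
    if species is None:
        species = sorted({s.species for s in matrix.samples})
    freq = {sp: allele_frequencies(
        matrix, [s.sample_id for s in matrix.samples if s.species == sp],
        label=sp) for sp in species}
    n = len(species)
    dmat = np.zeros((n, n))
    fmat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = nei_standard_distance(freq[species[i]], freq[species[j]])
        f = fst(freq[species[i]], freq[species[j]], estimator=estimator)
        dmat[i, j] = dmat[j, i] = d
        fmat[i, j] = fmat[j, i] = f
    return (PairwiseMatrix(species, dmat, "nei_d"),
            PairwiseMatrix(species, fmat, f"fst_{estimator}"))


# ---------------------------------------------------------------------------
# printed-summary percentages
# ---------------------------------------------------------------------------

def species_summary_percentages(table: SpeciesSummaryTable) -> pd.DataFrame:
    """Per-species polymorphism percentages of the array total (1 d.p.).

    Adds two summary rows: ``<mean>`` (column means of the percentages) and
    ``<collection>`` (the collection-wide polymorphic fraction).
    """
    t = table.table
    total = table.total_array_snps
    pct = pd.DataFrame({
        "species": t["species"],
        "pct_within": (100 * t["n_poly_within"] / total).round(1),
        "pct_vs_wheat": (100 * t["n_poly_vs_wheat"] / total).round(1),
    })
    mean_row = pd.DataFrame({
        "species": ["<mean>"],
        "pct_within": [round(float(np.mean(100 * t["n_poly_within"] / total)),
                             1)],
        "pct_vs_wheat": [round(float(np.mean(100 * t["n_poly_vs_wheat"]
                                             / total)), 1)],
    })
    coll = round(100 * table.collection_polymorphic / total, 1)
    coll_row = pd.DataFrame({"species": ["<collection>"],
                             "pct_within": [coll],
                             "pct_vs_wheat": [np.nan]})
    return pd.concat([pct, mean_row, coll_row], ignore_index=True)
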