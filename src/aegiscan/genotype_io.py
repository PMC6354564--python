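"""Core data model and on-disk formats for genotype call matrices.

The central container is :class:`CallMatrix`: a markers × samples grid of
biallelic genotype calls (0 = AA, 1 = AB, 2 = BB, -1 = no-call) together with
marker metadata (chromosome, physical position, alleles) and sample metadata
(species, genome formula, ploidy, role).  Two text dialects are supported:

``matrix_tsv``
    A tab-separated grid of integer (or AA/AB/BB/NoCall letter) calls with a
    header of sample ids and ``marker_id`` as first column, accompanied by
    ``<base>.markers.tsv`` and ``<base>.samples.tsv`` sidecar tables.

``hapmap``
    The standard 11-fixed-column haplotype-map exchange format with one
    single-letter IUPAC genotype column per sample (heterozygotes as
    ambiguity codes, missing as ``N``).

Coordinates are 0-based half-open internally and in BED output; hapmap
positions are 1-based and converted at the read/write boundary.  Markers
without a genomic placement live on the sentinel chromosome ``"unmapped"``
(written to hapmap as chromosome ``0``, position ``0``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM_A",
    "HET",
    "HOM_B",
    "NOCALL",
    "UNMAPPED",
    "TOTAL_ARRAY_SNPS",
    "COLLECTION_POLYMORPHIC_SNPS",
    "Marker",
    "Sample",
    "CallMatrix",
    "SpeciesSummaryTable",
    "IntrogressionSegment",
    "read_call_matrix",
    "write_call_matrix",
    "load_table1_fixture",
    "write_bed",
]

HOM_A = 0
HET = 1
HOM_B = 2
NOCALL = -1

#: sentinel chromosome for markers without a genomic placement
UNMAPPED = "unmapped"

#: number of SNP probes on the wheat-relative genotyping array
TOTAL_ARRAY_SNPS = 36_711
#: probes polymorphic across the full relative-species collection
COLLECTION_POLYMORPHIC_SNPS = 34_602

_LETTER_TOKENS = {"AA": HOM_A, "AB": HET, "BA": HET, "BB": HOM_B,
                  "NOCALL": NOCALL, "NC": NOCALL, "---": NOCALL}
_INT_TOKENS = {"0": HOM_A, "1": HET, "2": HOM_B, "-1": NOCALL}

# IUPAC ambiguity codes for unordered nucleotide pairs
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_IUPAC_REV = {v: k for k, v in _IUPAC.items()}

_HAPMAP_COLS = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


class GenotypeIOError(ValueError):
    """Malformed genotype file or inconsistent matrix construction."""


@dataclass(frozen=True)
class Marker:
    """One biallelic array probe / SNP with its genomic placement."""

    marker_id: str
    chromosome: str = UNMAPPED
    position_bp: int | None = None
    allele_a: str = "A"
    allele_b: str = "B"
    probe_class_label: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise GenotypeIOError(
                f"marker {self.marker_id}: alleles must differ "
                f"({self.allele_a!r})")
        mapped = self.chromosome != UNMAPPED
        if mapped and self.position_bp is None:
            raise GenotypeIOError(
                f"marker {self.marker_id}: mapped marker needs a position")
        if not mapped and self.position_bp is not None:
            raise GenotypeIOError(
                f"marker {self.marker_id}: unmapped marker cannot carry a "
                "position")
        if self.position_bp is not None and self.position_bp < 0:
            raise GenotypeIOError(
                f"marker {self.marker_id}: negative position")

    @property
    def mapped(self) -> bool:
        return self.chromosome != UNMAPPED


@dataclass(frozen=True)
class Sample:
    """One genotyped accession or line."""

    sample_id: str
    species: str
    section: str | None = None
    genome_formula: str = ""
    ploidy: int = 2
    role: str = "relative"  # relative | wheat_background | test_line

    def __post_init__(self) -> None:
        if not self.species:
            raise GenotypeIOError(f"sample {self.sample_id}: empty species")
        if self.role not in ("relative", "wheat_background", "test_line"):
            raise GenotypeIOError(
                f"sample {self.sample_id}: unknown role {self.role!r}")
        if self.role == "relative" and self.genome_formula:
            if self.ploidy != len(self.genome_formula):
                raise GenotypeIOError(
                    f"sample {self.sample_id}: ploidy {self.ploidy} does not "
                    f"match genome formula {self.genome_formula!r}")


@dataclass
class CallMatrix:
    """Markers × samples grid of genotype calls with metadata.

    ``calls`` is an int8 array of shape (n_markers, n_samples) over
    {0, 1, 2, -1}.
    """

    markers: list[Marker]
    samples: list[Sample]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise GenotypeIOError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers × {len(self.samples)} samples")
        bad = ~np.isin(self.calls, (HOM_A, HET, HOM_B, NOCALL))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeIOError(
                f"invalid call value {self.calls[i, j]} at marker "
                f"{self.markers[i].marker_id}, sample "
                f"{self.samples[j].sample_id}")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise GenotypeIOError(
                f"duplicate marker ids: {dup[dup > 1].index.tolist()[:5]}")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def species_columns(self, species: str) -> np.ndarray:
        idx = np.array([j for j, s in enumerate(self.samples)
                        if s.species == species], dtype=int)
        if idx.size == 0:
            raise KeyError(f"no samples of species {species!r}")
        return idx

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls, in [0, 1]."""
        return (self.calls != NOCALL).mean(axis=1)

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "CallMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return CallMatrix(markers=list(self.markers),
                          samples=[self.samples[j] for j in idx],
                          calls=self.calls[:, idx].copy())

    def subset_markers(self, keep: np.ndarray) -> "CallMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CallMatrix(markers=[self.markers[i] for i in keep],
                          samples=list(self.samples),
                          calls=self.calls[keep, :].copy())

    def filter_by_call_rate(self, min_call_rate: float = 0.8) -> "CallMatrix":
        """Quality screen: keep markers called in ≥ ``min_call_rate`` of
        samples (the array's standard 80% threshold)."""
        return self.subset_markers(self.call_rate() >= min_call_rate)

    def mapped_only(self) -> "CallMatrix":
        return self.subset_markers(
            np.array([m.mapped for m in self.markers]))

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chromosome": [m.chromosome for m in self.markers],
            "position_bp": [-1 if m.position_bp is None else m.position_bp
                            for m in self.markers],
        })


@dataclass(frozen=True)
class IntrogressionSegment:
    """A run of flagged windows: putative donor chromatin in a test line.

    Coordinates are 0-based half-open on the wheat assembly.
    """

    line_id: str
    donor_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_windows: int
    mean_match_percent: float

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"segment {self.chromosome}:{self.start_bp}-{self.end_bp}: "
                "start must precede end")
        if self.n_windows < 1:
            raise ValueError("segment must contain at least one window")


# ---------------------------------------------------------------------------
# species summary (printed Table 1)
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSummaryTable:
    """Per-species accession and polymorphism counts for the array panel."""

    table: pd.DataFrame
    total_array_snps: int = TOTAL_ARRAY_SNPS
    collection_polymorphic: int = COLLECTION_POLYMORPHIC_SNPS

    def __post_init__(self) -> None:
        required = {"species", "section", "genome", "ploidy", "n_accessions",
                    "n_poly_within", "n_poly_vs_wheat"}
        missing = required - set(self.table.columns)
        if missing:
            raise GenotypeIOError(f"summary table missing columns {missing}")
        for col in ("n_poly_within", "n_poly_vs_wheat"):
            if (self.table[col] > self.total_array_snps).any():
                raise GenotypeIOError(
                    f"{col} exceeds the array total {self.total_array_snps}")

    def row(self, species: str) -> pd.Series:
        hit = self.table[self.table["species"] == species]
        if hit.empty:
            raise KeyError(f"species {species!r} not in summary table")
        return hit.iloc[0]


def load_table1_fixture() -> SpeciesSummaryTable:
    """Load the packaged per-species summary of the wheat-relative array.

    One row per *Aegilops* species: number of accessions genotyped, markers
    polymorphic within the species, and markers polymorphic versus the bread
    wheat samples, out of 36,711 probes on the array.
    """
    ref = importlib.resources.files("aegiscan") / "data" / "species_summary.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"ploidy": str})
    return SpeciesSummaryTable(table=df)


# ---------------------------------------------------------------------------
# call token handling
# ---------------------------------------------------------------------------

def _parse_token(tok: str, marker_id: str, sample_id: str) -> int:
    t = tok.strip()
    if t in _INT_TOKENS:
        return _INT_TOKENS[t]
    if t.upper() in _LETTER_TOKENS:
        return _LETTER_TOKENS[t.upper()]
    raise GenotypeIOError(
        f"unknown call token {tok!r} at marker {marker_id!r}, "
        f"sample {sample_id!r}")


# ---------------------------------------------------------------------------
# matrix_tsv dialect
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix == ".tsv" else path
    return (Path(f"{base}.markers.tsv"), Path(f"{base}.samples.tsv"))


def _read_matrix_tsv(path: Path) -> CallMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeIOError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "marker_id":
            raise GenotypeIOError(
                f"{path}: malformed header, first column must be "
                f"'marker_id', got {cols[0]!r}")
        sample_ids = cols[1:]
        if not sample_ids:
            raise GenotypeIOError(f"{path}: header lists no samples")
        marker_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise GenotypeIOError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(cols)})")
            marker_ids.append(fields[0])
            rows.append([_parse_token(tok, fields[0], sid)
                         for tok, sid in zip(fields[1:], sample_ids)])
    if not marker_ids:
        raise GenotypeIOError(f"{path}: no marker rows")

    mpath, spath = _sidecar_paths(path)
    markers = _read_marker_sidecar(mpath, marker_ids)
    samples = _read_sample_sidecar(spath, sample_ids)
    return CallMatrix(markers=markers, samples=samples,
                      calls=np.array(rows, dtype=np.int8))


def _read_marker_sidecar(path: Path, marker_ids: list[str]) -> list[Marker]:
    if not path.exists():
        return [Marker(marker_id=mid) for mid in marker_ids]
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    byid = df.set_index("marker_id")
    markers = []
    for mid in marker_ids:
        if mid not in byid.index:
            raise GenotypeIOError(f"{path}: no metadata row for {mid!r}")
        r = byid.loc[mid]
        chrom = str(r["chromosome"])
        pos = None if chrom == UNMAPPED else int(r["position_bp"])
        markers.append(Marker(
            marker_id=mid, chromosome=chrom, position_bp=pos,
            allele_a=str(r.get("allele_a", "A")),
            allele_b=str(r.get("allele_b", "B"))))
    return markers


def _read_sample_sidecar(path: Path, sample_ids: list[str]) -> list[Sample]:
    if not path.exists():
        return [Sample(sample_id=sid, species="unknown") for sid in sample_ids]
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype=str).set_index("sample_id")
    samples = []
    for sid in sample_ids:
        if sid not in df.index:
            raise GenotypeIOError(f"{path}: no metadata row for {sid!r}")
        r = df.loc[sid]
        samples.append(Sample(
            sample_id=sid, species=str(r["species"]),
            section=(str(r["section"]) or None) if "section" in r else None,
            genome_formula=str(r.get("genome_formula", "")),
            ploidy=int(r.get("ploidy", 2) or 2),
            role=str(r.get("role") or "relative")))
    return samples


def _write_matrix_tsv(matrix: CallMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["marker_id", *matrix.sample_ids]) + "\n")
        for i, m in enumerate(matrix.markers):
            fh.write(m.marker_id + "\t"
                     + "\t".join(str(int(c)) for c in matrix.calls[i])
                     + "\n")
    mpath, spath = _sidecar_paths(path)
    pd.DataFrame({
        "marker_id": matrix.marker_ids,
        "chromosome": [m.chromosome for m in matrix.markers],
        "position_bp": ["" if m.position_bp is None else m.position_bp
                        for m in matrix.markers],
        "allele_a": [m.allele_a for m in matrix.markers],
        "allele_b": [m.allele_b for m in matrix.markers],
    }).to_csv(mpath, sep="\t", index=False)
    pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "species": [s.species for s in matrix.samples],
        "section": [s.section or "" for s in matrix.samples],
        "genome_formula": [s.genome_formula for s in matrix.samples],
        "ploidy": [s.ploidy for s in matrix.samples],
        "role": [s.role for s in matrix.samples],
    }).to_csv(spath, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hapmap dialect
# ---------------------------------------------------------------------------

def _hapmap_code(call: int, a: str, b: str) -> str:
    if call == NOCALL:
        return "N"
    if call == HOM_A:
        return a
    if call == HOM_B:
        return b
    # non-nucleotide allele symbols (e.g. abstract A/B) fall back to "H"
    return _IUPAC.get(frozenset((a, b)), "H")


def _read_hapmap(path: Path) -> CallMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeIOError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[: len(_HAPMAP_COLS)] != _HAPMAP_COLS:
            raise GenotypeIOError(
                f"{path}: malformed hapmap header (expected the 11 standard "
                "columns first)")
        sample_ids = cols[len(_HAPMAP_COLS):]
        if not sample_ids:
            raise GenotypeIOError(f"{path}: hapmap lists no samples")
        markers: list[Marker] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise GenotypeIOError(f"{path}:{lineno}: ragged row")
            mid, alleles, chrom, pos = fields[0], fields[1], fields[2], fields[3]
            if mid in seen:
                raise GenotypeIOError(f"{path}:{lineno}: duplicate marker "
                                      f"id {mid!r}")
            seen.add(mid)
            try:
                a, b = alleles.split("/")
            except ValueError:
                raise GenotypeIOError(
                    f"{path}:{lineno}: bad alleles field {alleles!r}") from None
            if chrom == "0":
                marker = Marker(marker_id=mid, chromosome=UNMAPPED,
                                position_bp=None, allele_a=a, allele_b=b)
            else:
                # hapmap is 1-based; internal coordinates are 0-based
                marker = Marker(marker_id=mid, chromosome=chrom,
                                position_bp=int(pos) - 1,
                                allele_a=a, allele_b=b)
            markers.append(marker)
            row = []
            for tok, sid in zip(fields[len(_HAPMAP_COLS):], sample_ids):
                t = tok.strip().upper()
                if t in ("N", "NN", "--"):
                    row.append(NOCALL)
                elif t == a or t == a + a:
                    row.append(HOM_A)
                elif t == b or t == b + b:
                    row.append(HOM_B)
                elif t == "H" or (t in _IUPAC_REV
                                  and _IUPAC_REV[t] == frozenset((a, b))):
                    row.append(HET)
                elif len(t) == 2 and set(t) == {a, b}:
                    row.append(HET)
                else:
                    raise GenotypeIOError(
                        f"unknown call token {tok!r} at marker {mid!r}, "
                        f"sample {sid!r}")
            rows.append(row)
    if not markers:
        raise GenotypeIOError(f"{path}: no marker rows")
    samples = [Sample(sample_id=sid, species="unknown") for sid in sample_ids]
    return CallMatrix(markers=markers, samples=samples,
                      calls=np.array(rows, dtype=np.int8))


def _write_hapmap(matrix: CallMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_COLS + matrix.sample_ids) + "\n")
        for i, m in enumerate(matrix.markers):
            chrom = "0" if not m.mapped else m.chromosome
            pos = 0 if not m.mapped else m.position_bp + 1
            fixed = [m.marker_id, f"{m.allele_a}/{m.allele_b}", chrom,
                     str(pos), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            codes = [_hapmap_code(int(c), m.allele_a, m.allele_b)
                     for c in matrix.calls[i]]
            fh.write("\t".join(fixed + codes) + "\n")


# ---------------------------------------------------------------------------
# public read/write
# ---------------------------------------------------------------------------

_DIALECTS = ("matrix_tsv", "hapmap")


def read_call_matrix(path: str | Path, dialect: str = "matrix_tsv") -> CallMatrix:
    """Read a genotype call matrix from ``path`` in the given dialect."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise GenotypeIOError(f"unknown dialect {dialect!r}; "
                              f"expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "matrix_tsv":
        return _read_matrix_tsv(path)
    return _read_hapmap(path)


def write_call_matrix(matrix: CallMatrix, path: str | Path,
                      dialect: str = "matrix_tsv") -> Path:
    """Write ``matrix`` to ``path``; the matrix_tsv dialect also writes
    ``<base>.markers.tsv`` / ``<base>.samples.tsv`` sidecars."""
    if dialect not in _DIALECTS:
        raise GenotypeIOError(f"unknown dialect {dialect!r}; "
                              f"expected one of {_DIALECTS}")
    if matrix.n_samples == 0:
        raise GenotypeIOError("refusing to write a 0-sample matrix")
    if matrix.n_markers == 0:
        raise GenotypeIOError("refusing to write a 0-marker matrix")
    path = Path(path)
    if dialect == "matrix_tsv":
        _write_matrix_tsv(matrix, path)
    else:
        _write_hapmap(matrix, path)
    return path


def write_bed(segments: Iterable[IntrogressionSegment],
              path: str | Path) -> Path:
    """Write introgression segments as BED3+ (0-based half-open).

    Extra columns: line id, donor id, mean window match percent.  Segments
    must arrive sorted by (chromosome, start); overlapping segments on the
    same chromosome for the same line are rejected (merge upstream).
    """
    segments = list(segments)
    key = [(s.line_id, s.chromosome, s.start_bp) for s in segments]
    if key != sorted(key):
        raise GenotypeIOError(
            "segments must be sorted by (line, chromosome, start)")
    prev: dict[tuple[str, str], int] = {}
    for s in segments:
        k = (s.line_id, s.chromosome)
        if k in prev and s.start_bp < prev[k]:
            raise GenotypeIOError(
                f"overlapping segments for line {s.line_id} on "
                f"{s.chromosome}; merge before writing")
        prev[k] = s.end_bp
    path = Path(path)
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chromosome}\t{s.start_bp}\t{s.end_bp}\t"
                     f"{s.line_id}\t{s.donor_id}\t"
                     f"{s.mean_match_percent:.1f}\n")
    return path
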