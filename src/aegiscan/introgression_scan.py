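"""Windowed percentage-match detection of alien chromatin in wheat lines.

A hexaploid test line is compared with a candidate donor accession over
windows of consecutive mapped markers (default 10 per window, advanced
non-overlapping).  Within a window, the match percentage is computed over
*usable* markers — those called in both samples::

    match% = 100 × #(line call == donor call) / #usable

A window is flagged when its match percentage reaches the threshold
(default 40%, inclusive: "40% or higher"), a deliberately permissive cut
calibrated on known introgressions such as the 1B/1RS translocation, which
absorbs heterozygous and homoeologous-cluster ambiguity.  Windows with too
few usable markers (fewer than ``min_usable_fraction × window_size``) are
UNDEFINED and never flagged.  Maximal runs of flagged windows become
:class:`~aegiscan.genotype_io.IntrogressionSegment` calls, optionally
bridging an UNDEFINED window flanked by flagged ones.

Trailing partial windows at chromosome ends are scored over their actual
marker count provided they meet the usable-marker minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import CallMatrix, IntrogressionSegment, Marker, NOCALL

__all__ = ["ScanParams", "WindowScore", "window_match", "call_segments",
           "scan_population", "select_tracking_markers", "PopulationScan"]


@dataclass(frozen=True)
class ScanParams:
    window_size: int = 10
    match_threshold: float = 40.0  # percent, inclusive
    window_step: int | None = None  # default: non-overlapping
    min_usable_fraction: float = 0.5
    bridge_undefined: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 < self.match_threshold <= 100):
            raise ValueError("match_threshold must lie in (0, 100]")
        step = self.step
        if not (1 <= step <= self.window_size):
            raise ValueError("window_step must lie in [1, window_size]")
        if not (0 <= self.min_usable_fraction <= 1):
            raise ValueError("min_usable_fraction must lie in [0, 1]")

    @property
    def step(self) -> int:
        return self.window_size if self.window_step is None else \
            self.window_step

    @property
    def min_usable(self) -> int:
        """Smallest usable-marker count for a window to be defined."""
        return max(1, math.ceil(self.min_usable_fraction * self.window_size))


@dataclass(frozen=True)
class WindowScore:
    """Match statistic for one window of markers on one chromosome."""

    chromosome: str
    ordinal: int
    first_marker: str
    last_marker: str
    start_bp: int
    end_bp: int  # half-open: position of last marker + 1
    n_markers: int
    n_usable: int
    match_percent: float  # NaN when UNDEFINED
    flagged: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.match_percent)


def _check_mapped_sorted(markers: list[Marker]) -> None:
    last: dict[str, int] = {}
    seen_order: list[str] = []
    for m in markers:
        if not m.mapped:
            raise ValueError(
                f"unmapped marker {m.marker_id} in scan input; filter with "
                "mapped_only() first")
        if m.chromosome not in last:
            seen_order.append(m.chromosome)
        elif seen_order[-1] != m.chromosome:
            raise ValueError("markers are not grouped by chromosome")
        if m.chromosome in last and m.position_bp < last[m.chromosome]:
            raise ValueError(
                f"markers not position-sorted on {m.chromosome}")
        last[m.chromosome] = m.position_bp


def window_match(line: np.ndarray, donor: np.ndarray,
                 markers: list[Marker],
                 params: ScanParams = ScanParams()) -> list[WindowScore]:
    """Per-window percentage match between one test line and one donor.

    ``line`` and ``donor`` are call vectors indexed on ``markers``, which
    must be mapped and sorted by (chromosome, position).
    """
    line = np.asarray(line)
    donor = np.asarray(donor)
    if not (len(line) == len(donor) == len(markers)):
        raise ValueError("line, donor and markers must be equally indexed")
    _check_mapped_sorted(markers)

    usable = (line != NOCALL) & (donor != NOCALL)
    match = usable & (line == donor)
    chroms = np.array([m.chromosome for m in markers])

    scores: list[WindowScore] = []
    for chrom in dict.fromkeys(chroms):  # preserve input order
        idx = np.flatnonzero(chroms == chrom)
        ordinal = 0
        for start in range(0, idx.size, params.step):
            win = idx[start: start + params.window_size]
            n_use = int(usable[win].sum())
            if n_use >= params.min_usable:
                pct = 100.0 * float(match[win].sum()) / n_use
            else:
                pct = float("nan")
            flagged = (not math.isnan(pct)
                       and pct >= params.match_threshold)
            first, last = markers[win[0]], markers[win[-1]]
            scores.append(WindowScore(
                chromosome=chrom, ordinal=ordinal,
                first_marker=first.marker_id, last_marker=last.marker_id,
                start_bp=first.position_bp, end_bp=last.position_bp + 1,
                n_markers=int(win.size), n_usable=n_use,
                match_percent=pct, flagged=flagged))
            ordinal += 1
            if start + params.window_size >= idx.size:
                break
    return scores


def call_segments(scores: list[WindowScore], line_id: str, donor_id: str,
                  params: ScanParams = ScanParams()
                  ) -> list[IntrogressionSegment]:
    """Merge maximal runs of flagged windows into introgression segments.

    With ``params.bridge_undefined`` on, a single UNDEFINED window whose
    neighbours on the same chromosome are both flagged does not break a
    run.  Segment coordinates span the first flagged marker's position to
    the last flagged marker's position (half-open).
    """
    segments: list[IntrogressionSegment] = []
    by_chrom: dict[str, list[WindowScore]] = {}
    for s in scores:
        by_chrom.setdefault(s.chromosome, []).append(s)

    for chrom, ws in by_chrom.items():
        run: list[WindowScore] = []
        pending_gap = False  # an UNDEFINED window awaiting a flagged right

        def close() -> None:
            nonlocal run, pending_gap
            if run:
                segments.append(IntrogressionSegment(
                    line_id=line_id, donor_id=donor_id, chromosome=chrom,
                    start_bp=run[0].start_bp, end_bp=run[-1].end_bp,
                    n_windows=len(run),
                    mean_match_percent=float(
                        np.mean([w.match_percent for w in run]))))
            run, pending_gap = [], False

        for w in ws:
            if w.flagged:
                run.append(w)
                pending_gap = False
            elif (params.bridge_undefined and not w.defined and run
                  and not pending_gap):
                pending_gap = True  # bridge iff the next window is flagged
            else:
                close()
        close()
    segments.sort(key=lambda s: (s.line_id, s.chromosome, s.start_bp))
    return segments


@dataclass
class PopulationScan:
    """All window scores and segments for a (lines × donors) comparison."""

    scores: dict[tuple[str, str], list[WindowScore]]
    segments: dict[tuple[str, str], list[IntrogressionSegment]]
    params: ScanParams

    def grid(self, donor_id: str) -> pd.DataFrame:
        """Lines × windows match-percent grid against one donor
        (the per-window heat-strip layout used to report scans)."""
        rows = {}
        cols: list[str] | None = None
        for (line, donor), ws in self.scores.items():
            if donor != donor_id:
                continue
            if cols is None:
                cols = [f"{w.chromosome}:{w.ordinal}" for w in ws]
            rows[line] = [w.match_percent for w in ws]
        if cols is None:
            raise KeyError(f"donor {donor_id!r} not in scan")
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def summary(self) -> pd.DataFrame:
        rows = []
        for (line, donor), segs in self.segments.items():
            rows.append({
                "line_id": line, "donor_id": donor,
                "n_segments": len(segs),
                "introgressed_bp": sum(s.end_bp - s.start_bp for s in segs),
            })
        return pd.DataFrame(rows)


def scan_population(lines: CallMatrix, donors: CallMatrix,
                    params: ScanParams = ScanParams()) -> PopulationScan:
    """Window-match every test line against every donor accession.

    Both matrices must be on the same mapped, sorted marker panel.
    """
    if lines.n_samples == 0 or donors.n_samples == 0:
        raise ValueError("empty line or donor set")
    if lines.marker_ids != donors.marker_ids:
        a, b = set(lines.marker_ids), set(donors.marker_ids)
        raise ValueError(
            "line and donor matrices are on different marker panels; "
            f"e.g. only-in-lines={sorted(a - b)[:3]}, "
            f"only-in-donors={sorted(b - a)[:3]}")
    scores: dict[tuple[str, str], list[WindowScore]] = {}
    segments: dict[tuple[str, str], list[IntrogressionSegment]] = {}
    for li, line in enumerate(lines.samples):
        for dj, donor in enumerate(donors.samples):
            ws = window_match(lines.calls[:, li], donors.calls[:, dj],
                              lines.markers, params)
            key = (line.sample_id, donor.sample_id)
            scores[key] = ws
            segments[key] = call_segments(ws, line.sample_id,
                                          donor.sample_id, params)
    return PopulationScan(scores=scores, segments=segments, params=params)


def select_tracking_markers(donor_calls: np.ndarray,
                            background_calls: np.ndarray,
                            markers: list[Marker]
                            ) -> tuple[list[Marker], pd.DataFrame]:
    """Diagnostic marker panel for one donor × background cross.

    Keeps markers where both profiles are called and differ — the loci able
    to distinguish donor chromatin from the wheat background.  Returns the
    panel (input order preserved) and per-chromosome counts.
    """
    donor_calls = np.asarray(donor_calls)
    background_calls = np.asarray(background_calls)
    if not (len(donor_calls) == len(background_calls) == len(markers)):
        raise ValueError("profiles and markers must be equally indexed")
    keep = ((donor_calls != NOCALL) & (background_calls != NOCALL)
            & (donor_calls != background_calls))
    panel = [m for m, k in zip(markers, keep) if k]
    counts = pd.Series([m.chromosome for m in panel],
                       dtype="object").value_counts().rename_axis(
        "chromosome").reset_index(name="n_markers")
    return panel, counts
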