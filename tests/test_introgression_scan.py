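import math

import numpy as np
import pytest

from aegiscan.genotype_io import Marker, NOCALL
from aegiscan.introgression_scan import (ScanParams, call_segments,
                                         scan_population,
                                         select_tracking_markers,
                                         window_match)
from aegiscan.synthetic_data import (IntrogressionBlock, SimulationConfig,
                                     simulate_introgression_lines)


def markers_on(chrom, n, spacing=1_000_000, start=0):
    return [Marker(f"{chrom}_{i:03d}", chrom, start + i * spacing, "A", "G")
            for i in range(n)]


def match_oracle(line, donor, window):
    """Naive per-window match percentages on a single chromosome."""
    out = []
    for s in range(0, len(line), window):
        w_line, w_donor = line[s:s + window], donor[s:s + window]
        usable = [(a, b) for a, b in zip(w_line, w_donor)
                  if a != NOCALL and b != NOCALL]
        if len(usable) < math.ceil(0.5 * window):
            out.append(float("nan"))
        else:
            out.append(100 * sum(a == b for a, b in usable) / len(usable))
    return out


class TestWindowMatch:
    def test_identical_profiles_all_hundred(self):
        line = np.tile([0, 1, 2], 10)
        ws = window_match(line, line.copy(), markers_on("1A", 30))
        assert [w.match_percent for w in ws] == [100.0] * 3
        assert all(w.flagged for w in ws)

    def test_forty_percent_boundary_is_flagged(self):
        # 4 matches out of 10 usable -> exactly 40% -> flagged (">= 40")
        donor = np.zeros(10, dtype=int)
        line = np.array([0, 0, 0, 0, 2, 2, 2, 2, 2, 2])
        ws = window_match(line, donor, markers_on("2B", 10))
        assert ws[0].match_percent == pytest.approx(40.0)
        assert ws[0].flagged

    def test_insufficient_usable_markers_undefined(self):
        donor = np.zeros(10, dtype=int)
        line = np.full(10, NOCALL)
        line[:3] = 0  # 3 usable < 5 = 0.5 × window
        ws = window_match(line, donor, markers_on("2B", 10))
        assert not ws[0].defined and not ws[0].flagged
        assert ws[0].n_usable == 3

    def test_nocall_pairs_leave_denominator(self):
        donor = np.array([0, 0, 0, 0, 0, -1, -1, -1, 0, 0])
        line = np.array([0, 0, 0, 2, 2, 0, 0, 0, -1, 2])
        ws = window_match(line, donor, markers_on("3D", 10))
        # usable: idx 0-4 and 9 -> 6 usable, 3 match
        assert ws[0].n_usable == 6
        assert ws[0].match_percent == pytest.approx(50.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        line = rng.integers(-1, 3, size=95)
        donor = rng.integers(-1, 3, size=95)
        ws = window_match(line, donor, markers_on("5A", 95))
        expect = match_oracle(list(line), list(donor), 10)
        got = [w.match_percent for w in ws]
        assert len(got) == len(expect) == 10
        for g, e in zip(got, expect):
            assert (math.isnan(g) and math.isnan(e)) or g == pytest.approx(
                e, abs=1e-12)

    def test_symmetric_in_line_and_donor(self):
        rng = np.random.default_rng(23)
        a = rng.integers(-1, 3, size=40)
        b = rng.integers(-1, 3, size=40)
        mk = markers_on("1B", 40)
        fwd = [w.match_percent for w in window_match(a, b, mk)]
        rev = [w.match_percent for w in window_match(b, a, mk)]
        assert fwd == pytest.approx(rev, nan_ok=True)

    def test_trailing_partial_window_scored(self):
        # 17 markers: second window has 7 markers >= 5 usable minimum
        line = np.zeros(17, dtype=int)
        ws = window_match(line, line.copy(), markers_on("1A", 17))
        assert len(ws) == 2
        assert ws[1].n_markers == 7 and ws[1].defined

    def test_unmapped_markers_rejected(self):
        mk = markers_on("1A", 9) + [Marker("u", "unmapped", None, "A", "G")]
        with pytest.raises(ValueError, match="unmapped"):
            window_match(np.zeros(10), np.zeros(10), mk)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(31)
        line = rng.integers(0, 3, size=200)
        donor = rng.integers(0, 3, size=200)
        mk = markers_on("2A", 200)
        flagged = []
        for thr in (20, 40, 60, 80):
            ws = window_match(line, donor, mk,
                              ScanParams(match_threshold=thr))
            flagged.append(sum(w.flagged for w in ws))
        assert flagged == sorted(flagged, reverse=True)


class TestCallSegments:
    def mkscores(self, pattern, chrom="1A"):
        """Pattern letters: F flagged, u unflagged, N undefined."""
        line = {"F": (80.0, True), "u": (10.0, False),
                "N": (float("nan"), False)}
        mk = markers_on(chrom, 10 * len(pattern))
        scores = window_match(np.zeros(10 * len(pattern)),
                              np.zeros(10 * len(pattern)), mk)
        out = []
        for w, ch in zip(scores, pattern):
            pct, fl = line[ch]
            out.append(type(w)(chromosome=w.chromosome, ordinal=w.ordinal,
                               first_marker=w.first_marker,
                               last_marker=w.last_marker,
                               start_bp=w.start_bp, end_bp=w.end_bp,
                               n_markers=w.n_markers,
                               n_usable=0 if ch == "N" else 10,
                               match_percent=pct, flagged=fl))
        return out

    def test_no_flagged_windows_no_segments(self):
        assert call_segments(self.mkscores("uuuu"), "L", "D") == []

    def test_contiguous_run_becomes_one_segment(self):
        segs = call_segments(self.mkscores("uuuFFFFFuu"), "L", "D")
        assert len(segs) == 1
        assert segs[0].n_windows == 5
        assert segs[0].mean_match_percent == pytest.approx(80.0)
        # spans windows 3..7: markers 30..79
        assert segs[0].start_bp == 30 * 1_000_000
        assert segs[0].end_bp == 79 * 1_000_000 + 1

    def test_undefined_bridging_modes(self):
        pattern = "FFNFF"
        merged = call_segments(self.mkscores(pattern), "L", "D",
                               ScanParams(bridge_undefined=True))
        split = call_segments(self.mkscores(pattern), "L", "D",
                              ScanParams(bridge_undefined=False))
        assert len(merged) == 1 and merged[0].n_windows == 4
        assert len(split) == 2

    def test_two_undefined_windows_break_runs(self):
        segs = call_segments(self.mkscores("FFNNFF"), "L", "D",
                             ScanParams(bridge_undefined=True))
        assert len(segs) == 2

    def test_chromosomes_kept_separate(self):
        scores = self.mkscores("FF", "1A") + self.mkscores("FF", "1B")
        segs = call_segments(scores, "L", "D")
        assert [s.chromosome for s in segs] == ["1A", "1B"]


class TestScanPopulation:
    def test_single_pair_equals_window_match(self, introgression_sim):
        m, _ = introgression_sim
        lines = m.subset_samples(["L_block1"])
        donor_id = [s.sample_id for s in m.samples
                    if s.role == "relative"][0]
        donors = m.subset_samples([donor_id])
        res = scan_population(lines, donors)
        direct = window_match(lines.calls[:, 0], donors.calls[:, 0],
                              lines.markers)
        assert res.scores[("L_block1", donor_id)] == direct

    def test_true_blocks_recovered_noise_free(self, introgression_sim):
        m, truth = introgression_sim
        donor_id = [s.sample_id for s in m.samples
                    if s.role == "relative"][0]
        res = scan_population(
            m.subset_samples(["L_block1", "L_block2"]),
            m.subset_samples([donor_id]))
        for blk in truth.blocks:
            segs = res.segments[(blk.line_id, donor_id)]
            hits = [s for s in segs if s.chromosome == blk.chromosome
                    and s.start_bp < blk.end_bp and blk.start_bp < s.end_bp]
            assert hits, f"block on {blk.chromosome} not recovered"

    def test_null_line_false_positive_rate_low(self, introgression_sim):
        m, _ = introgression_sim
        donor_id = [s.sample_id for s in m.samples
                    if s.role == "relative"][0]
        res = scan_population(m.subset_samples(["L_null"]),
                              m.subset_samples([donor_id]))
        ws = res.scores[("L_null", donor_id)]
        rate = sum(w.flagged for w in ws) / len(ws)
        assert rate < 0.05

    def test_recall_degrades_monotonically_with_error_rate(self):
        blocks = tuple(
            IntrogressionBlock(f"L{i}", "donor sp", "1A",
                               i * 60_000_000, (i + 1) * 60_000_000)
            for i in range(5))
        recalls = []
        for err in (0.0, 0.05, 0.1, 0.2):
            cfg = SimulationConfig(seed=13, n_markers=600,
                                   chromosomes=("1A",), nocall_rate=0.0,
                                   call_error_rate=err, blocks=blocks)
            m, truth = simulate_introgression_lines(cfg)
            donor_id = [s.sample_id for s in m.samples
                        if s.role == "relative"][0]
            res = scan_population(
                m.subset_samples(sorted({b.line_id for b in blocks})),
                m.subset_samples([donor_id]))
            hit = 0
            for blk in truth.blocks:
                segs = res.segments[(blk.line_id, donor_id)]
                if any(s.start_bp < blk.end_bp and blk.start_bp < s.end_bp
                       for s in segs if s.chromosome == blk.chromosome):
                    hit += 1
            recalls.append(hit / len(blocks))
        assert recalls[0] == 1.0
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_grid_and_summary_shapes(self, introgression_sim):
        m, _ = introgression_sim
        donor_id = [s.sample_id for s in m.samples
                    if s.role == "relative"][0]
        lines = m.subset_samples(["L_block1", "L_null"])
        res = scan_population(lines, m.subset_samples([donor_id]))
        grid = res.grid(donor_id)
        assert list(grid.index) == ["L_block1", "L_null"]
        summary = res.summary()
        assert set(summary.columns) == {"line_id", "donor_id", "n_segments",
                                        "introgressed_bp"}

    def test_disjoint_marker_panels_rejected(self, introgression_sim):
        m, _ = introgression_sim
        donor_id = [s.sample_id for s in m.samples
                    if s.role == "relative"][0]
        lines = m.subset_samples(["L_null"])
        donors = m.subset_samples([donor_id]).subset_markers(
            np.arange(m.n_markers - 1))
        with pytest.raises(ValueError, match="different marker panels"):
            scan_population(lines, donors)


class TestTrackingMarkers:
    def test_identical_profiles_empty_panel(self):
        mk = markers_on("1A", 5)
        panel, counts = select_tracking_markers(
            np.zeros(5), np.zeros(5), mk)
        assert panel == [] and counts.empty

    def test_differing_subset_selected_in_order(self):
        rng = np.random.default_rng(3)
        donor = rng.integers(0, 3, 200)
        bg = donor.copy()
        flip = rng.choice(200, size=50, replace=False)
        bg[flip] = (bg[flip] + 1) % 3
        mk = markers_on("6B", 200)
        panel, counts = select_tracking_markers(donor, bg, mk)
        assert len(panel) == 50
        ids = [m.marker_id for m in panel]
        assert ids == [m.marker_id for m in mk if m.marker_id in set(ids)]
        assert counts["n_markers"].sum() == 50

    def test_nocalls_excluded(self):
        donor = np.array([0, -1, 2, 1])
        bg = np.array([2, 2, -1, 0])
        panel, _ = select_tracking_markers(donor, bg, markers_on("1A", 4))
        assert [m.marker_id for m in panel] == ["1A_000", "1A_003"]
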