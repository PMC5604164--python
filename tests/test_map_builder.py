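import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thyromap as tm
from thyromap.map_builder import SegmentRecord


def exact_upper_tail(x, k, M, m):
    """P(X >= x), X ~ Hypergeom(M, m, k), with exact rational arithmetic."""
    total = Fraction(0)
    for i in range(x, min(k, m) + 1):
        total += Fraction(math.comb(m, i) * math.comb(M - m, k - i),
                          math.comb(M, k))
    return float(total)


class TestSegmentGenome:
    def test_windows_cover_gene_and_assignment_by_start(self):
        ann = {"G": tm.GeneLocus("G", "chr1", 600_000, 610_000)}
        segs = tm.segment_genome(ann)
        assert [(s.start, s.end) for s in segs] == [
            (1, 500_000), (250_001, 750_000), (500_001, 1_000_000)]
        assert [s.members for s in segs] == [[], ["G"], ["G"]]

    def test_gene_at_start_134100000_lies_in_8q24_window(self):
        ann = {"TG": tm.GeneLocus("TG", "chr8", 134_100_000, 134_148_000)}
        segs = tm.segment_genome(ann)
        containing = [s for s in segs if "TG" in s.members]
        assert (("chr8", 134_000_001, 134_500_000)
                in [(s.chromosome, s.start, s.end) for s in containing])

    def test_single_gene_mode_windows(self):
        ann = {"G": tm.GeneLocus("G", "chr1", 20_000, 21_000)}
        segs = tm.segment_genome(ann, window_bp=12_500, shift_bp=6_250)
        assert all(s.end - s.start + 1 == 12_500 for s in segs)
        assert sum("G" in s.members for s in segs) == 2

    def test_interior_locus_belongs_to_exactly_two_windows(self, small_annotation):
        segs = tm.segment_genome(small_annotation)
        counts = {}
        for s in segs:
            for sym in s.members:
                counts[sym] = counts.get(sym, 0) + 1
        for sym, locus in small_annotation.items():
            expected = 1 if locus.start <= 250_000 else 2
            assert counts[sym] == expected, sym

    def test_empty_annotation_is_error(self):
        with pytest.raises(ValueError):
            tm.segment_genome({})

    def test_window_must_be_multiple_of_shift(self):
        ann = {"G": tm.GeneLocus("G", "chr1", 1, 10)}
        with pytest.raises(ValueError):
            tm.segment_genome(ann, window_bp=500_000, shift_bp=300_000)


class TestSegmentValues:
    def test_mean_of_members(self):
        seg = SegmentRecord("chr1", 1, 500_000, members=["A", "B"])
        tm.compute_segment_values({"A": 100.0, "B": 300.0}, [seg])
        assert seg.value == 200.0 and seg.n_genes == 2

    def test_single_member(self):
        seg = SegmentRecord("chr1", 1, 500_000, members=["TG"])
        tm.compute_segment_values({"TG": 8662.34}, [seg])
        assert seg.value == 8662.34

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(1)
        vals = {f"G{i}": float(v) for i, v in enumerate(rng.lognormal(4, 1, 50))}
        seg = SegmentRecord("chr1", 1, 500_000, members=list(vals))
        tm.compute_segment_values(vals, [seg])
        assert seg.value == pytest.approx(sum(vals.values()) / 50, rel=1e-12)

    def test_empty_segment_carries_no_value(self):
        seg = SegmentRecord("chr1", 1, 500_000, members=[])
        tm.compute_segment_values({"A": 1.0}, [seg])
        assert seg.value is None and seg.n_genes == 0


class TestExtremeFlags:
    def test_exact_tails_on_1_to_200(self):
        values = {f"G{i}": float(i) for i in range(1, 201)}
        flags = tm.flag_extreme_loci(values)
        high = {s for s, f in flags.items() if f == "high"}
        low = {s for s, f in flags.items() if f == "low"}
        assert high == {f"G{i}" for i in range(196, 201)}
        assert low == {f"G{i}" for i in range(1, 6)}

    def test_identical_values_flag_nothing(self):
        flags = tm.flag_extreme_loci({f"G{i}": 7.0 for i in range(100)})
        assert set(flags.values()) == {"none"}

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(5)
        values = {f"G{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 400))}
        flags = tm.flag_extreme_loci(values)
        vals = np.array(list(values.values()))
        lo, hi = np.quantile(vals, [0.025, 0.975])
        for s, v in values.items():
            expected = "high" if v >= hi else ("low" if v <= lo else "none")
            assert flags[s] == expected


class TestEnrichment:
    def test_zero_observed_gives_p_one(self):
        assert tm.segment_enrichment_test(0, 4, 200, 5) == 1.0

    def test_small_instance_matches_exact_summation(self):
        p = tm.segment_enrichment_test(2, 4, 200, 5)
        assert p == pytest.approx(exact_upper_tail(2, 4, 200, 5), rel=1e-10)
        assert p == pytest.approx(0.00296, abs=2e-5)

    def test_whole_genome_segment(self):
        # drawing every locus surely captures all m extremes
        assert tm.segment_enrichment_test(3, 100, 100, 5) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.segment_enrichment_test(5, 4, 100, 10)
        with pytest.raises(ValueError):
            tm.segment_enrichment_test(1, 4, 100, 200)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_exact_tail_on_random_instances(self, data):
        M = data.draw(st.integers(5, 80))
        m = data.draw(st.integers(0, M))
        k = data.draw(st.integers(1, M))
        x = data.draw(st.integers(0, min(k, m)))
        assert tm.segment_enrichment_test(x, k, M, m) == pytest.approx(
            exact_upper_tail(x, k, M, m), rel=1e-9, abs=1e-12)

    @given(st.data())
    @settings(max_examples=20, deadline=None)
    def test_pmf_sums_to_one(self, data):
        M = data.draw(st.integers(2, 40))
        m = data.draw(st.integers(0, M))
        k = data.draw(st.integers(1, M))
        # P(X >= 0) over the full support is exactly 1
        assert exact_upper_tail(0, k, M, m) == pytest.approx(1.0, rel=1e-12)


def _segments_with_p(ps, extremes):
    segs = []
    for i, (p, nx) in enumerate(zip(ps, extremes)):
        s = SegmentRecord("chr1", i * 250_000 + 1, i * 250_000 + 500_000)
        s.n_genes = 5
        s.p_value = p
        s.n_extreme_high = nx
        segs.append(s)
    return segs


class TestCalling:
    def test_bh_arithmetic_and_min_extreme_gate(self):
        # 10 segments: one strong p among nine at 0.5 -> q1 = 0.01
        values = {f"G{i}": float(i) for i in range(200)}
        flags = {s: "none" for s in values}
        # mark 5 high-extreme genes, all inside segment 0
        for i in range(5):
            flags[f"G{i}"] = "high"
        segs = []
        for j in range(10):
            s = SegmentRecord("chr1", j * 250_000 + 1, j * 250_000 + 500_000,
                              members=[f"G{5 * j + i}" for i in range(5)])
            segs.append(s)
        tm.compute_segment_values(values, segs)
        tm.call_segments(segs, flags, values)
        assert segs[0].call == "over"
        assert all(s.call == "none" for s in segs[1:])
        assert all(s.q_value >= s.p_value for s in segs)

    def test_significant_q_but_two_extremes_not_called(self):
        values = {f"G{i}": float(i) for i in range(100)}
        flags = {s: "none" for s in values}
        flags["G0"] = flags["G1"] = "high"
        seg = SegmentRecord("chr1", 1, 500_000, members=["G0", "G1"])
        tm.compute_segment_values(values, [seg])
        tm.call_segments([seg], flags, values, min_extreme=3)
        assert seg.call == "none"

    def test_single_gene_mode_prevails_rule(self):
        # a lone dominant extreme gene keeps its call; a window where two
        # extreme genes split the expression evenly loses it (neither
        # prevails over the other)
        values = {f"G{i}": float(i) for i in range(1, 201)}
        values["BIG"] = 1000.0
        values["E3"] = 300.0
        values["E1"] = 900.0
        values["E2"] = 900.0
        flags = tm.flag_extreme_loci(values)
        assert all(flags[s] == "high" for s in ("BIG", "E1", "E2", "E3"))
        dominant = SegmentRecord("chr1", 1, 12_500, members=["BIG", "E3"])
        split = SegmentRecord("chr2", 1, 12_500, members=["E1", "E2"])
        segs = [dominant, split]
        tm.compute_segment_values(values, segs)
        tm.call_segments(segs, flags, values, min_extreme=1)
        assert dominant.call == "over"      # 1000 / 1300 of the window
        assert split.call == "none"         # 900 / 1800 each: no gene prevails
        assert split.q_value < 0.05         # demotion came from the rule, not q

    def test_planted_cluster_called_end_to_end(self, planted_study,
                                               planted_maps, small_annotation):
        stats_a, stats_b = planted_maps
        records, _ = tm.differential_map(stats_a, stats_b)
        ratios = {r.symbol: r.ratio for r in records}
        segs, _ = tm.build_segment_map(small_annotation, ratios)
        chrom, start, end, _ = planted_study.truth.spiked_segments[0]
        overlapping = [s for s in segs
                       if s.chromosome == chrom and s.start <= end and s.end >= start]
        assert any(s.call == "over" for s in overlapping)
        # no underexpression was planted anywhere
        assert all(s.call != "under" for s in segs)


class TestDifferential:
    def test_ratio_of_pool_values(self, planted_maps):
        records, _ = tm.differential_map(*planted_maps)
        for r in records[:50]:
            assert r.ratio == pytest.approx(r.value_a / r.value_b, rel=1e-12)
            assert r.ratio > 0

    def test_swapping_pools_inverts_every_ratio(self, planted_maps):
        stats_a, stats_b = planted_maps
        fwd, _ = tm.differential_map(stats_a, stats_b)
        rev, _ = tm.differential_map(stats_b, stats_a)
        rev_by_symbol = {r.symbol: r for r in rev}
        for r in fwd:
            assert r.ratio * rev_by_symbol[r.symbol].ratio == pytest.approx(1.0, rel=1e-12)

    def test_equal_values_give_ratio_one(self):
        from thyromap.normalization import LocusStats
        a = [LocusStats("G", 5.0, 0.0, 2, 2)]
        records, _ = tm.differential_map(a, a)
        assert records[0].ratio == 1.0

    def test_locus_missing_in_one_pool_excluded_and_reported(self):
        from thyromap.normalization import LocusStats
        a = [LocusStats("G1", 5.0, 0.0, 2, 2), LocusStats("G2", 1.0, 0.0, 2, 2)]
        b = [LocusStats("G1", 2.0, 0.0, 2, 2)]
        records, excluded = tm.differential_map(a, b)
        assert [r.symbol for r in records] == ["G1"]
        assert excluded == ["G2"]


class TestDataPointFilter:
    def _setup(self, dp_b):
        from thyromap.map_builder import DifferentialRecord
        rec = DifferentialRecord("G0", 100.0, 1.0, 100.0, 10, dp_b, 5.0, 5.0)
        seg = SegmentRecord("chr1", 1, 500_000, members=["G0"], call="over")
        seg.n_genes = 1
        flags = {"G0": "high"}
        return seg, {"G0": rec}, flags

    def test_low_coverage_extreme_gene_demotes_segment(self):
        seg, diff, flags = self._setup(dp_b=3)
        tm.filter_called_segments([seg], diff, flags)
        assert seg.call == "none"

    def test_well_supported_segment_unchanged(self):
        seg, diff, flags = self._setup(dp_b=7)
        tm.filter_called_segments([seg], diff, flags)
        assert seg.call == "over"

    def test_planted_artifact_removed_true_cluster_kept(self, small_annotation):
        """Of two called planted clusters, the one whose genes rest on too
        few data points in pool B is demoted; the well-supported one stays."""
        from dataclasses import replace
        cfg = tm.TruthConfig(n_spiked_clusters=2, cluster_size=5, cluster_fold=20.0)
        study = tm.generate_study(small_annotation, cfg,
                                  n_samples_a=10, n_samples_b=10, seed=77)
        sa, _ = tm.build_reference_map(study.samples_a, study.probe_map,
                                       small_annotation)
        sb, _ = tm.build_reference_map(study.samples_b, study.probe_map,
                                       small_annotation)
        records, _ = tm.differential_map(sa, sb)
        # make the second cluster an artifact: pool-B support drops below 5
        c2_chrom, c2_start, c2_end, _ = study.truth.spiked_segments[1]
        def in_cluster2(sym):
            loc = small_annotation[sym]
            return loc.chromosome == c2_chrom and c2_start <= loc.start <= c2_end
        records = [replace(r, data_points_b=3) if in_cluster2(r.symbol) else r
                   for r in records]
        ratios = {r.symbol: r.ratio for r in records}
        segs, flags = tm.build_segment_map(small_annotation, ratios)
        diff = {r.symbol: r for r in records}
        called_before = {(s.chromosome, s.start) for s in segs if s.call == "over"}
        tm.filter_called_segments(segs, diff, flags)
        c1_chrom, c1_start, c1_end, _ = study.truth.spiked_segments[0]
        true_hit = any(s.call == "over" and s.chromosome == c1_chrom
                       and s.start <= c1_end and s.end >= c1_start for s in segs)
        artifact_still_called = any(
            s.call == "over" and s.chromosome == c2_chrom
            and s.start <= c2_end and s.end >= c2_start for s in segs)
        # both clusters were called before the data-point filter
        assert any(c == c2_chrom for c, _ in called_before)
        assert true_hit
        assert not artifact_still_called
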