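"""Peak calling, cross-study arbitration, context classification, rank test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import chip_arbiter as ca
from chip_arbiter.io import ValidationError

from conftest import (make_annotation, make_ztrack, oracle_binomial_upper_tail,
                      oracle_call_targets, oracle_genic_fraction)


def _target(peak, z, name, seq="chr"):
    return ca.TargetRegion(seq, peak, z, peak - 25, peak + 25, name=name)


class TestCallTargets:
    def test_single_region_peak_is_max(self):
        z = make_ztrack([0, 4, 5, 4, 0], spacing=100, start=100)
        targets = ca.call_targets(z, threshold=3, merge_distance=300)
        assert len(targets) == 1
        t = targets[0]
        assert t.peak_z == 5.0
        assert t.peak_position == int(z.track.midpoints[2])
        assert t.region_start == z.track.starts[1] and t.region_end == z.track.ends[3]

    def test_all_below_threshold_empty(self):
        z = make_ztrack([1.0, 2.0, 2.9])
        assert ca.call_targets(z, threshold=3) == []

    def test_distant_probes_split_regions(self):
        z = make_ztrack([4, 0, 0, 0, 4], spacing=300)
        targets = ca.call_targets(z, threshold=3, merge_distance=500)
        assert len(targets) == 2

    def test_tie_goes_to_leftmost_probe(self):
        z = make_ztrack([4.0, 4.0])
        targets = ca.call_targets(z, threshold=3, merge_distance=500)
        assert len(targets) == 1
        assert targets[0].peak_position == int(z.track.midpoints[0])

    def test_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = rng.integers(1, 51)
            spacing = int(rng.integers(50, 400))
            zv = np.round(rng.normal(1.0, 2.0, n), 1)  # rounding forces ties
            z = make_ztrack(zv, spacing=spacing)
            thr = float(rng.uniform(0.5, 4.0))
            merge = int(rng.integers(0, 800))
            got = [(t.peak_position, t.peak_z, t.region_start, t.region_end)
                   for t in ca.call_targets(z, threshold=thr, merge_distance=merge)]
            assert got == oracle_call_targets(z.track, zv, thr, merge)


class TestNearestProbe:
    def test_exact_midpoint(self):
        z = make_ztrack([1.0, 2.0, 3.0], spacing=100)  # mids 25, 125, 225
        idx, val, dist = ca.nearest_probe(z, 125)
        assert (idx, val, dist) == (1, 2.0, 0)

    def test_equidistant_tie_leftmost(self):
        z = make_ztrack([1.0, 2.0], spacing=100)  # mids 25, 125
        idx, _, dist = ca.nearest_probe(z, 75)
        assert idx == 0 and dist == 50

    def test_beyond_last_probe(self):
        z = make_ztrack([1.0, 2.0], spacing=100)
        idx, val, _ = ca.nearest_probe(z, 10_000)
        assert idx == 1 and val == 2.0


class TestCompareStudies:
    def test_match_within_tolerance(self):
        comp = ca.compare_studies([_target(1000, 5, "a1")], [_target(1100, 4, "b1")],
                                  tolerance=500)
        assert len(comp.matched) == 1
        _, b, dist = comp.matched[0]
        assert b.name == "b1" and dist == 100
        assert comp.disputed == []

    def test_empty_b_all_disputed(self):
        a = [_target(1000, 5, "a1"), _target(9000, 4, "a2")]
        comp = ca.compare_studies(a, [], tolerance=500)
        assert comp.disputed_names == {"a1", "a2"}

    def test_excluded_counted_nowhere_else(self):
        a = [_target(1000, 5, "a1"), _target(9000, 4, "rep_region")]
        comp = ca.compare_studies(a, [], tolerance=500, exclude=("rep_region",))
        assert comp.disputed_names == {"a1"}
        assert [t.name for t in comp.excluded] == ["rep_region"]

    def test_duplicate_names_rejected(self):
        a = [_target(1000, 5, "x"), _target(2000, 4, "x")]
        with pytest.raises(ValidationError, match="duplicate"):
            ca.compare_studies(a, [], tolerance=500)

    @given(st.data())
    def test_partition_property(self, data):
        """matched + disputed + excluded partition study A, distances <= tolerance."""
        peaks_a = data.draw(st.lists(st.integers(100, 100_000), min_size=1, max_size=15,
                                     unique=True))
        peaks_b = data.draw(st.lists(st.integers(100, 100_000), max_size=10, unique=True))
        tol = data.draw(st.integers(1, 5_000))
        a = [_target(p, 4.0, f"a{i}") for i, p in enumerate(sorted(peaks_a))]
        b = [_target(p, 4.0, f"b{i}") for i, p in enumerate(sorted(peaks_b))]
        excl = tuple(t.name for t in a[::3])
        comp = ca.compare_studies(a, b, tolerance=tol, exclude=excl)
        names = ([t.name for t, _, _ in comp.matched] + [t.name for t in comp.disputed]
                 + [t.name for t in comp.excluded])
        assert sorted(names) == sorted(t.name for t in a)
        assert all(d <= tol for _, _, d in comp.matched)
        for t, bm, d in comp.matched:
            assert d == min(abs(t.peak_position - x.peak_position) for x in b)


class TestClassifyPosition:
    def test_inside_gene_is_genic(self):
        ann = make_annotation([(100, 500, "+")], 1000)
        assert ca.classify_position(ann, 150) == "genic"

    def test_convergent_gap(self):
        ann = make_annotation([(0, 100, "+"), (200, 300, "-")], 400)
        assert ca.classify_position(ann, 150) == "intergenic_convergent"

    def test_tandem_gap_is_plain_intergenic(self):
        ann = make_annotation([(0, 100, "+"), (200, 300, "+")], 400)
        assert ca.classify_position(ann, 150) == "intergenic"

    def test_sequence_end_gap_is_intergenic(self):
        ann = make_annotation([(100, 200, "-")], 400)
        assert ca.classify_position(ann, 50) == "intergenic"
        assert ca.classify_position(ann, 300) == "intergenic"

    def test_out_of_range_rejected(self):
        ann = make_annotation([(100, 200, "+")], 400)
        with pytest.raises(ValidationError):
            ca.classify_position(ann, 400)


class TestGenicFraction:
    def test_overlapping_union(self):
        ann = make_annotation([(0, 400, "+"), (200, 600, "-")], 1000)
        assert ca.genic_fraction(ann) == pytest.approx(0.6)

    def test_no_genes(self):
        ann = make_annotation([], 1000)
        assert ca.genic_fraction(ann) == 0.0

    def test_full_cover(self):
        ann = make_annotation([(0, 1000, "+")], 1000)
        assert ca.genic_fraction(ann) == 1.0

    def test_matches_per_base_counting(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            L = int(rng.integers(500, 10_000))
            n = int(rng.integers(0, 12))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, L + 1))
                ivs.append((s, e))
            ann = make_annotation([(s, e, "+") for s, e in ivs], L)
            assert ca.genic_fraction(ann) == pytest.approx(
                oracle_genic_fraction(ivs, L), rel=1e-12)


class TestPositionalEnrichmentTest:
    def test_whole_distribution(self):
        assert ca.positional_enrichment_test(0, 10, 0.12).p_value == 1.0

    def test_small_enumeration(self):
        # P(X >= 2), X ~ Bin(3, 0.5): (3 + 1)/8
        assert ca.positional_enrichment_test(2, 3, 0.5).p_value == pytest.approx(0.5)

    def test_paper_scale_configuration_matches_exact_summation(self):
        """15 intergenic of 46 at p0=0.12: exact one-sided upper tail."""
        res = ca.positional_enrichment_test(15, 46, 0.12)
        oracle = float(oracle_binomial_upper_tail(15, 46, 0.12))
        assert res.p_value == pytest.approx(oracle, rel=1e-12)
        assert res.expected == pytest.approx(5.52)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ca.positional_enrichment_test(5, 3, 0.5)
        with pytest.raises(ValueError):
            ca.positional_enrichment_test(1, 3, 1.0)


class TestRankAnalysis:
    def _targets(self, zs):
        return [_target(100 * (i + 1), z, f"t{i}") for i, z in enumerate(zs)]

    def test_bottom_slice_counts_disputed(self):
        targets = self._targets([1, 2, 3, 4])
        count, k = ca.rank_analysis(targets, {"t0", "t1"}, 2)
        assert (count, k) == (2, 2)

    def test_empty_disputed(self):
        targets = self._targets([1, 2, 3])
        assert ca.rank_analysis(targets, set(), 2) == (0, 2)

    def test_all_disputed(self):
        targets = self._targets([1, 2, 3])
        assert ca.rank_analysis(targets, {"t0", "t1", "t2"}, 3) == (3, 3)

    def test_unknown_name_warns_and_ignores(self, caplog):
        targets = self._targets([1, 2])
        with caplog.at_level("WARNING"):
            count, _ = ca.rank_analysis(targets, {"t0", "ghost"}, 2)
        assert count == 1
        assert any("ghost" in r.message for r in caplog.records)
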