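"""Fragment filtering, pileup, normalization chain and peak calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenmap import (CoverageTrack, FragmentFilterSpec, call_peaks,
                    compute_occupancy, compute_threshold, filter_fragments,
                    mask_regions, normalize_to_centromeres, smooth,
                    subtract_background)
from cenmap.genome import intervals

from conftest import brute_force_pileup, brute_force_runs


def frags(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def track(values, stage="normalized"):
    return CoverageTrack(data={"c": np.asarray(values, dtype=float)},
                         stage=stage)


class TestFilterFragments:
    def test_insert_bounds_inclusive(self):
        raw = frags([("c", 0, 0 + n, 60) for n in (30, 50, 149, 240, 241,
                                                   500)])
        kept = filter_fragments(raw, FragmentFilterSpec())
        assert sorted(kept["end"] - kept["start"]) == [50, 149, 240]

    def test_low_mapping_score_dropped(self):
        raw = frags([("c", 0, 150, 10)])
        assert filter_fragments(raw).empty

    def test_score_bound_inclusive(self):
        raw = frags([("c", 0, 150, 30)])
        assert len(filter_fragments(raw)) == 1

    def test_empty_input(self):
        assert filter_fragments(frags([])).empty

    def test_improper_pairs_dropped_when_required(self):
        raw = frags([("c", 0, 150, 60), ("c", 0, 150, 60)])
        raw["proper_pair"] = [True, False]
        assert len(filter_fragments(raw)) == 1

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FragmentFilterSpec(min_insert=100, max_insert=50)


class TestOccupancy:
    def test_single_fragment(self):
        cov = compute_occupancy(frags([("c", 10, 15, 60)]), {"c": 20})
        expected = np.zeros(20)
        expected[10:15] = 1
        assert np.array_equal(cov.data["c"], expected)

    def test_overlapping_fragments(self):
        cov = compute_occupancy(frags([("c", 0, 10, 60), ("c", 5, 15, 60)]),
                                {"c": 20})
        assert (cov.data["c"][5:10] == 2).all()

    def test_total_equals_fragment_bases(self):
        f = frags([("c", 0, 10, 60), ("c", 5, 15, 60), ("c", 18, 20, 60)])
        cov = compute_occupancy(f, {"c": 20})
        assert cov.total() == float((f["end"] - f["start"]).sum())

    def test_out_of_bounds_fragment_named(self):
        with pytest.raises(ValueError, match="fragment 0"):
            compute_occupancy(frags([("c", 10, 30, 60)]), {"c": 20})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 48), st.integers(1, 30)),
                    max_size=20))
    def test_matches_brute_force_oracle(self, spans):
        f = frags([("c", s, min(50, s + w), 60) for s, w in spans])
        cov = compute_occupancy(f, {"c": 50})
        assert np.array_equal(cov.data["c"],
                              brute_force_pileup(f, {"c": 50})["c"])


class TestSubtractBackground:
    def test_identical_tracks_cancel(self):
        chip = track([4, 2, 7], stage="raw")
        assert subtract_background(chip, track([4, 2, 7], "raw")
                                   ).data["c"].sum() == 0

    def test_elementwise_with_clamping(self):
        out = subtract_background(track([5, 3], "raw"), track([2, 6], "raw"))
        assert list(out.data["c"]) == [3, 0]

    def test_depth_scaling_invariance(self):
        chip = track([5, 3, 0, 8], "raw")
        inp = np.array([2.0, 6.0, 1.0, 1.0])
        a = subtract_background(chip, track(inp, "raw"))
        b = subtract_background(chip, track(2 * inp, "raw"))
        assert np.allclose(a.data["c"], b.data["c"])

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            subtract_background(track([1, 2], "raw"), track([0, 0], "raw"))


CEN = intervals([("c", 0, 2)])


class TestNormalize:
    def test_identity_when_already_at_reference(self):
        t = normalize_to_centromeres(track([100.0, 100.0, 5.0]), CEN,
                                     reference_level=100.0)
        assert np.allclose(t.data["c"], [100, 100, 5])

    def test_scaling_arithmetic(self):
        t = normalize_to_centromeres(track([10.0, 10.0, 3.0]), CEN,
                                     reference_level=100.0)
        assert np.allclose(t.data["c"], [100, 100, 30])
        assert t.norm_factor == pytest.approx(10.0)

    def test_idempotent(self):
        t1 = normalize_to_centromeres(track([7.0, 3.0, 2.0]), CEN, 100.0)
        t2 = normalize_to_centromeres(t1, CEN, 100.0)
        assert np.allclose(t1.data["c"], t2.data["c"])

    def test_zero_centromeric_coverage_rejected(self):
        with pytest.raises(ValueError, match="[Zz]ero centromeric"):
            normalize_to_centromeres(track([0.0, 0.0, 9.0]), CEN, 100.0)


class TestSmooth:
    def test_window_one_is_identity(self):
        t = track([1.0, 5.0, 2.0])
        assert np.array_equal(smooth(t, 1).data["c"], t.data["c"])

    def test_impulse_spreads_evenly(self):
        t = track([0.0, 0.0, 3.0, 0.0, 0.0])
        assert np.allclose(smooth(t, 3).data["c"], [0, 1, 1, 1, 0])

    def test_mass_conserved_away_from_edges(self):
        rng = np.random.default_rng(0)
        vals = rng.random(100)
        sm = smooth(track(vals), 5).data["c"]
        assert sm[2:-2].sum() == pytest.approx(
            np.convolve(vals, np.ones(5) / 5, mode="valid").sum())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(track([1.0]), 4)


class TestMask:
    def test_empty_mask_is_identity(self):
        t = track([1.0, 2.0, 3.0])
        out = mask_regions(t, intervals([]))
        assert np.array_equal(out.data["c"], t.data["c"])

    def test_full_mask_zeroes_track(self):
        out = mask_regions(track([1.0, 2.0]), intervals([("c", 0, 2)]))
        assert out.data["c"].sum() == 0

    def test_mask_exact_bases(self):
        t = track(np.arange(10, dtype=float) + 1)
        out = mask_regions(t, intervals([("c", 5, 8)]))
        assert list(out.data["c"][5:8]) == [0, 0, 0]
        assert out.data["c"][4] == 5 and out.data["c"][8] == 9


class TestThreshold:
    def test_constant_centromere(self):
        t = track([7.0, 7.0, 1.0])
        assert compute_threshold(t, CEN) == 7.0

    def test_min_of_per_centromere_means(self):
        t = track([10.0, 10.0, 7.0, 7.0])
        cen = intervals([("c", 0, 2), ("c", 2, 4)])
        assert compute_threshold(t, cen) == 7.0

    def test_no_centromeres_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(track([1.0]), intervals([]))


class TestCallPeaks:
    def test_all_zero_no_peaks(self):
        assert len(call_peaks(track([0.0] * 8), 4)) == 0

    def test_worked_example(self):
        peaks = call_peaks(track([0, 5, 5, 0, 9, 9, 9, 0]), 4)
        rows = peaks.df[["start", "end", "center", "score"]].values.tolist()
        assert rows == [[1, 3, 1, 5.0], [4, 7, 5, 9.0]]

    def test_strictly_above(self):
        assert len(call_peaks(track([4.0, 4.0]), 4)) == 0

    def test_merge_gap(self):
        peaks = call_peaks(track([9, 0, 9, 0, 0, 9]), 4, merge_gap=1)
        assert [(r.start, r.end) for r in peaks.df.itertuples()] == [(0, 3),
                                                                     (5, 6)]

    def test_min_width(self):
        peaks = call_peaks(track([9, 0, 9, 9]), 4, min_width=2)
        assert [(r.start, r.end) for r in peaks.df.itertuples()] == [(2, 4)]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=40),
           st.integers(0, 4))
    def test_matches_brute_force_runs(self, values, threshold):
        peaks = call_peaks(track([float(v) for v in values]), threshold)
        got = [(r.start, r.end) for r in peaks.df.itertuples()]
        assert got == brute_force_runs(values, threshold)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=1, max_size=50),
           st.integers(0, 6))
    def test_threshold_monotonicity(self, values, threshold):
        """Raising the threshold never increases total peak width, and every
        higher-threshold peak nests inside a lower-threshold peak. (Peak
        *count* is not monotone: a bimodal run splits at its saddle.)"""
        t = track([float(v) for v in values])
        lo, hi = call_peaks(t, threshold), call_peaks(t, threshold + 1)
        width = lambda p: int((p.df["end"] - p.df["start"]).sum())
        assert width(hi) <= width(lo)
        for r in hi.df.itertuples():
            assert ((lo.df["start"] <= r.start)
                    & (lo.df["end"] >= r.end)).sum() == 1

    def test_mask_then_call_equals_call_then_drop(self):
        """When no peak straddles a mask edge, masking before calling equals
        calling first and discarding mask-overlapping peaks."""
        vals = [0, 9, 9, 0, 8, 8, 0, 7, 0]
        mask = intervals([("c", 4, 6)])
        t = track([float(v) for v in vals])
        a = call_peaks(mask_regions(t, mask), 4).df
        b = call_peaks(t, 4).df
        b = b[~((b["start"] < 6) & (b["end"] > 4))].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
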