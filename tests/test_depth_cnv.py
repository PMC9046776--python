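"""Read-depth CNV engine: binning, normalisation, segmentation, refinement.

Brute-force oracles (explicit window enumeration, maximal-run scanning)
are kept deliberately independent of the vectorised implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from matesv import GenomeMap, depth_cnv
from matesv.depth_cnv import CnvCall, CopyRatioProfile, WindowScheme

from conftest import make_pair_frame


def brute_force_windows_containing(pos, width, step, chrom_len):
    """All window starts (1-based, step grid) whose window contains pos."""
    out = []
    s = 1
    while s <= chrom_len:
        e = min(s + width - 1, chrom_len)
        if e - s + 1 >= width / 2 and s <= pos <= e:
            out.append(s)
        s += step
    return out


def brute_force_runs(ratio, lo_ok, min_run, merge_gap):
    """Independent maximal-run scan used as the segmentation oracle."""
    flags = [bool(lo_ok(r)) if np.isfinite(r) else False for r in ratio]
    runs, i = [], 0
    idx = [k for k, f in enumerate(flags) if f]
    if not idx:
        return []
    start = prev = idx[0]
    for k in idx[1:]:
        if k - prev - 1 <= merge_gap:
            prev = k
        else:
            runs.append((start, prev))
            start = prev = k
    runs.append((start, prev))
    return [(a, b) for a, b in runs if sum(flags[a:b + 1]) >= min_run]


@pytest.fixture(scope="module")
def small_genome():
    return GenomeMap(chromosomes=(("chr1", 1_000_000),))


def flat_profile(ratios, scheme=None, chrom="chr1", width=5_000):
    scheme = scheme or WindowScheme("fixed", width)
    starts = np.arange(len(ratios)) * scheme.step + 1
    table = pd.DataFrame({
        "chrom": chrom, "start": starts,
        "end": starts + scheme.width_bp - 1,
        "raw_count": 100, "gc": 0.45, "ratio": ratios})
    return CopyRatioProfile(scheme=scheme, table=table)


class TestWindows:
    def test_fixed_tiling_and_partial_window_drop(self):
        scheme = WindowScheme("fixed", 5_000)
        genome = GenomeMap(chromosomes=(("chr1", 12_400),))
        win = scheme.windows(genome)
        # final 2,400-bp remnant < width/2 is dropped
        assert win[["start", "end"]].values.tolist() == [[1, 5000], [5001, 10000]]

    def test_sliding_starts_on_step_grid(self):
        scheme = WindowScheme("sliding", 50_000, 5_000)
        starts = scheme.starts(200_000)
        assert starts[0] == 1 and starts[1] == 5_001
        assert all(np.diff(starts) == 5_000)


class TestBinCounts:
    def test_fixed_scheme_example(self, toy_genome):
        pairs = make_pair_frame([("p1", "chr1", 2_500, "+", "chr1", 7_500, "-")])
        counts = depth_cnv.bin_counts(pairs, WindowScheme("fixed", 5_000),
                                      toy_genome)
        assert counts.iloc[0].raw_count == 1 and counts.iloc[1].raw_count == 1
        assert counts.raw_count.sum() == 2   # end-count conserved

    @pytest.mark.parametrize("pos,expected_n", [(2_500, 1), (52_500, 10)])
    def test_sliding_scheme_matches_enumeration(self, toy_genome, pos,
                                                expected_n):
        pairs = make_pair_frame([("p1", "chr1", pos, "+", "chr2", 100, "-")])
        scheme = WindowScheme("sliding", 50_000, 5_000)
        counts = depth_cnv.bin_counts(pairs, scheme, toy_genome)
        oracle = brute_force_windows_containing(pos, 50_000, 5_000, 30_000_000)
        assert len(oracle) == expected_n
        hit = counts[(counts.chrom == "chr1") & (counts.raw_count > 0)]
        assert sorted(hit.start) == oracle

    def test_empty_stream_all_zero(self, toy_genome):
        counts = depth_cnv.bin_counts(make_pair_frame([]),
                                      WindowScheme("fixed", 5_000), toy_genome)
        assert counts.raw_count.sum() == 0

    def test_duplicates_excluded(self, toy_genome):
        pairs = make_pair_frame([("p1", "chr1", 2_500, "+", "chr1", 7_500, "-")])
        pairs.loc[0, "duplicate"] = True
        counts = depth_cnv.bin_counts(pairs, WindowScheme("fixed", 5_000),
                                      toy_genome)
        assert counts.raw_count.sum() == 0

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(1, 199_000), min_size=1, max_size=30))
    def test_sliding_counts_equal_enumeration_property(self, positions):
        genome = GenomeMap(chromosomes=(("chr1", 200_000),))
        scheme = WindowScheme("sliding", 50_000, 5_000)
        pairs = make_pair_frame([
            (f"p{i}", "chr1", p, "+", "chr1", min(p + 5_000, 200_000), "-")
            for i, p in enumerate(positions)])
        counts = depth_cnv.bin_counts(pairs, scheme, genome)
        ends = [p for p in positions] + \
               [min(p + 5_000, 200_000) for p in positions]
        for _, row in counts.iterrows():
            expected = sum(1 for e in ends
                           if row.start in brute_force_windows_containing(
                               e, 50_000, 5_000, 200_000))
            assert row.raw_count == expected


class TestNormalize:
    def test_uniform_fixed_point(self, small_genome):
        scheme = WindowScheme("fixed", 5_000)
        counts = scheme.windows(small_genome).assign(raw_count=100)
        gc = counts[["chrom", "start"]].assign(gc=0.45)
        prof = depth_cnv.normalize(counts, scheme, gc_track=gc,
                                   genome=small_genome)
        assert np.allclose(prof.table.ratio, 1.0)

    def test_doubled_region_reaches_two(self, small_genome):
        rng = np.random.default_rng(11)
        scheme = WindowScheme("fixed", 5_000)
        counts = scheme.windows(small_genome)
        lam = np.full(len(counts), 200.0)
        lam[50:100] *= 2          # one arm doubled
        counts["raw_count"] = rng.poisson(lam)
        prof = depth_cnv.normalize(counts, scheme, genome=small_genome)
        arm = prof.table.ratio[50:100]
        se = 2.0 / np.sqrt(400 * 50)
        assert abs(arm.mean() - 2.0) < 3 * se + 0.02

    def test_small_gc_stratum_falls_back_to_global(self, small_genome):
        scheme = WindowScheme("fixed", 5_000)
        counts = scheme.windows(small_genome).assign(raw_count=100)
        gc = counts[["chrom", "start"]].assign(gc=0.45)
        gc.loc[0, "gc"] = 0.30            # singleton stratum, count 100
        counts.loc[0, "raw_count"] = 50   # would be ratio 1.0 if self-normalised
        prof = depth_cnv.normalize(counts, scheme, gc_track=gc,
                                   genome=small_genome)
        assert prof.table.ratio.iloc[0] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self, small_genome):
        scheme = WindowScheme("fixed", 5_000)
        counts = scheme.windows(small_genome).assign(raw_count=0)
        with pytest.raises(ValueError, match="insufficient coverage"):
            depth_cnv.normalize(counts, scheme, genome=small_genome)

    def test_panel_zero_window_masked(self, small_genome):
        scheme = WindowScheme("fixed", 5_000)
        counts = scheme.windows(small_genome).assign(raw_count=100)
        panel = counts[["chrom", "start", "end"]].assign(median_count=100.0)
        panel.loc[3, "median_count"] = 0.0
        prof = depth_cnv.normalize(counts, scheme, panel=panel,
                                   genome=small_genome)
        assert np.isnan(prof.table.ratio.iloc[3])
        assert np.allclose(prof.table.ratio.drop(index=3), 1.0)


class TestSegment:
    def test_flat_profile_no_calls(self):
        prof = flat_profile(np.ones(100),
                            WindowScheme("sliding", 50_000, 5_000))
        assert depth_cnv.segment(prof) == []

    def test_merge_across_single_noisy_window(self):
        ratio = np.ones(30)
        ratio[5:10] = 1.5
        ratio[10] = 1.1          # one sub-threshold window
        ratio[11:16] = 1.5
        prof = flat_profile(ratio, WindowScheme("sliding", 50_000, 5_000))
        calls = depth_cnv.segment(prof)
        assert len(calls) == 1 and calls[0].type == "gain"
        assert calls[0].n_windows == 10

    def test_two_window_gap_not_merged(self):
        ratio = np.ones(30)
        ratio[5:10] = 1.5
        ratio[12:17] = 1.5
        prof = flat_profile(ratio, WindowScheme("sliding", 50_000, 5_000))
        assert len(depth_cnv.segment(prof)) == 2

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from([0.4, 0.7, 1.0, 1.3, 1.6]),
                    min_size=1, max_size=200),
           st.integers(1, 4))
    def test_matches_brute_force_enumeration(self, ratios, min_run):
        ratio = np.array(ratios)
        prof = flat_profile(ratio, WindowScheme("sliding", 50_000, 5_000))
        calls = depth_cnv.segment(prof, min_run=min_run)
        got = {(c.type, c.start, c.end) for c in calls}
        expected = set()
        starts = prof.table.start.to_numpy()
        ends = prof.table.end.to_numpy()
        for ctype, ok in (("gain", lambda r: r >= 1.25),
                          ("loss", lambda r: r <= 0.75)):
            for a, b in brute_force_runs(ratio, ok, min_run, 1):
                expected.add((ctype, int(starts[a]), int(ends[b])))
        assert got == expected


class TestRefineBoundaries:
    def test_clean_step_returns_exact_edge(self):
        ratio = np.concatenate([np.ones(40), np.full(40, 0.5), np.ones(40)])
        prof5 = flat_profile(ratio)
        # coarse call deliberately 15 kb off on both sides
        call = CnvCall("chr1", 40 * 5_000 + 1 - 15_000, 80 * 5_000 + 15_000,
                       "loss", 0.5, 8)
        refined = depth_cnv.refine_boundaries(call, prof5)
        assert refined.refined
        assert refined.start == 40 * 5_000 + 1
        assert refined.end == 80 * 5_000

    def test_flat_profile_ties_break_to_coarse_boundary(self):
        prof5 = flat_profile(np.ones(100))
        call = CnvCall("chr1", 150_001, 350_000, "loss", 0.5, 10)
        refined = depth_cnv.refine_boundaries(call, prof5)
        assert (refined.start, refined.end) == (150_001, 350_000)

    def test_fully_masked_flank_flags_call(self):
        ratio = np.full(100, np.nan)
        prof5 = flat_profile(ratio)
        call = CnvCall("chr1", 150_001, 350_000, "loss", 0.5, 10)
        refined = depth_cnv.refine_boundaries(call, prof5)
        assert not refined.refined and "unrefined" in refined.notes


class TestHomdel:
    def test_single_low_window_not_reported(self):
        prof = flat_profile(np.array([1.0, 0.05, 1.0]))
        assert depth_cnv.call_homdel(prof) == []

    def test_two_windows_reported_spanning_10kb(self):
        prof = flat_profile(np.array([1.0, 0.0, 0.08, 1.0]))
        (call,) = depth_cnv.call_homdel(prof)
        assert (call.start, call.end) == (5_001, 15_000)
        assert call.end - call.start + 1 == 10_000
        assert call.type == "homdel" and call.mean_ratio <= 0.1

    def test_whole_chromosome_run(self):
        prof = flat_profile(np.full(50, 0.05))
        (call,) = depth_cnv.call_homdel(prof)
        assert call.n_windows == 50


class TestMonotonicity:
    def test_mean_ratio_nondecreasing_in_copy_number(self):
        """Higher implanted copy number never lowers the region's mean
        ratio (paired seeds, same fragment randomness)."""
        from matesv import synthetic_data as sd
        genome = GenomeMap(chromosomes=(("chr1", 8_000_000),))
        means = []
        for zygosity in (None, "het", "hom"):   # copy number 2, 3, 4
            events = () if zygosity is None else (
                sd.SimEvent("dup", "chr1", 3_000_000, 3_400_000,
                            zygosity=zygosity),)
            cfg = sd.SimConfig(genome=(("chr1", 8_000_000),), events=events,
                               seed=77)
            res = sd.simulate(cfg, pairs_only=True)
            scheme = WindowScheme("fixed", 5_000)
            counts = depth_cnv.bin_counts(res.pairs, scheme, genome)
            prof = depth_cnv.normalize(counts, scheme, genome=genome)
            view = prof.table[(prof.table.start >= 3_000_001)
                              & (prof.table.end <= 3_400_000)]
            means.append(view.ratio.mean())
        assert means[0] < means[1] < means[2]
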