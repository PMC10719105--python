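"""Summit extension, SPM, reproducibility rule, union merge and the ZIB filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ccre_atlas import peak_filter as pf


def _peaks(intervals, chrom="chr1", spm=None):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    if spm is not None:
        df["spm"] = spm
    return df


class TestExtendSummits:
    def test_width_501(self):
        out = pf.extend_summits(pd.DataFrame({"chrom": ["chr1"], "summit": [1000]}))
        assert out.loc[0, "start"] == 750 and out.loc[0, "end"] == 1251
        assert not out.loc[0, "clipped"]

    def test_clipped_at_contig_start(self):
        out = pf.extend_summits(pd.DataFrame({"chrom": ["chr1"], "summit": [100]}))
        assert out.loc[0, "start"] == 0 and out.loc[0, "end"] == 351
        assert out.loc[0, "clipped"]

    def test_random_unclipped_widths(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"chrom": "chr1", "summit": rng.integers(250, 10**6, 100)})
        out = pf.extend_summits(df)
        assert ((out["end"] - out["start"]) == 501).all()

    def test_summit_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            pf.extend_summits(pd.DataFrame({"chrom": ["chr1"], "summit": [-5]}))
        with pytest.raises(ValueError):
            pf.extend_summits(
                pd.DataFrame({"chrom": ["chr1"], "summit": [2000]}),
                contig_sizes={"chr1": 1500},
            )


class TestSpm:
    def test_equal_scores(self):
        peaks = pd.DataFrame({"score": np.full(40, 3.0)})
        out = pf.spm_transform(peaks)
        assert np.allclose(out["spm"], 1e6 / 40)

    def test_hand_computed_example(self):
        # total score 2e6; a peak scoring 10 gets spm 10/(2e6/1e6) = 5
        scores = np.concatenate([[10.0], np.full(1000, (2e6 - 10) / 1000)])
        out = pf.spm_transform(pd.DataFrame({"score": scores}))
        assert out.loc[0, "spm"] == pytest.approx(5.0, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1, max_size=50)
    )
    def test_sums_to_one_million(self, scores):
        out = pf.spm_transform(pd.DataFrame({"score": scores}))
        assert out["spm"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pf.spm_transform(pd.DataFrame({"score": [0.0, 0.0]}))

    def test_cutoff_inclusive(self):
        peaks = pd.DataFrame({"spm": np.arange(1.0, 11.0)})
        kept = pf.spm_filter(peaks, min_spm=5.0)
        assert kept["spm"].min() == 5.0


def _brute_max_overlap(pooled, others):
    """All-pairs oracle: max overlap fraction of each pooled peak."""
    frac = np.zeros(len(pooled))
    for i, (c, s, e) in enumerate(zip(pooled["chrom"], pooled["start"], pooled["end"])):
        best = 0
        for c2, s2, e2 in zip(others["chrom"], others["start"], others["end"]):
            if c2 != c:
                continue
            best = max(best, max(0, min(e, e2) - max(s, s2)))
        frac[i] = best / (e - s)
    return frac


class TestReproduciblePeaks:
    def test_exact_half_overlap_retained(self):
        pooled = _peaks([(0, 500)])
        rep = _peaks([(250, 750)])
        out = pf.reproducible_peaks(pooled, rep, rep, None, None)
        assert len(out) == 1

    def test_just_below_half_fails_replicates(self):
        pooled = _peaks([(0, 500)])
        rep1 = _peaks([(250, 750)])
        rep2 = _peaks([(251, 751)])  # overlap 249/500
        out = pf.reproducible_peaks(pooled, rep1, rep2, rep1, rep1)
        # rescued only through the pseudoreplicate branch
        assert len(out) == 1
        out2 = pf.reproducible_peaks(pooled, rep1, rep2, rep2, rep2)
        assert len(out2) == 0

    def test_empty_sets_retain_nothing(self):
        pooled = _peaks([(0, 500), (1000, 1500)])
        empty = _peaks([])
        out = pf.reproducible_peaks(pooled, empty, empty, empty, empty)
        assert len(out) == 0

    def test_absent_sets_auto_pass(self):
        pooled = _peaks([(0, 500)])
        out = pf.reproducible_peaks(pooled, None, None, None, None)
        assert len(out) == 1 and out.loc[0, "auto_pass"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)

        def random_set(n):
            starts = rng.integers(0, 5000, n)
            return _peaks(
                list(zip(starts, starts + rng.integers(50, 600, n))),
                chrom=rng.choice(["chr1", "chr2"], n),
            )

        pooled = random_set(300)
        sets = [random_set(200) for _ in range(4)]
        out = pf.reproducible_peaks(pooled, *sets)
        f = [_brute_max_overlap(pooled, s) for s in sets]
        expected = ((f[0] >= 0.5) & (f[1] >= 0.5)) | ((f[2] >= 0.5) & (f[3] >= 0.5))
        assert set(out["start"]) == set(pooled["start"][expected])


class TestMergeUnion:
    def test_identical_peak_in_two_clusters(self):
        p = _peaks([(100, 601)], spm=[7.0]).assign(summit=350)
        cat = pf.merge_union({"c1": p, "c2": p})
        assert len(cat) == 1
        assert cat.loc[0, "source_clusters"] == "c1,c2"

    def test_highest_spm_anchors(self):
        a = _peaks([(100, 601)], spm=[8.0]).assign(summit=350)
        b = _peaks([(400, 901)], spm=[3.0]).assign(summit=650)
        cat = pf.merge_union({"c1": a, "c2": b})
        assert len(cat) == 1
        assert cat.loc[0, "summit"] == 350

    def test_disjoint_peaks_all_kept(self):
        a = _peaks([(0, 501), (1000, 1501)], spm=[5, 6]).assign(summit=[250, 1250])
        b = _peaks([(3000, 3501)], spm=[2]).assign(summit=[3250])
        cat = pf.merge_union({"c1": a, "c2": b})
        assert len(cat) == 3

    def test_matches_greedy_oracle(self):
        rng = np.random.default_rng(2)
        clusters = {}
        for c in range(3):
            summits = rng.integers(250, 20_000, 60)
            clusters[c] = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": summits - 250,
                    "end": summits + 251,
                    "summit": summits,
                    "spm": rng.uniform(1, 100, 60),
                }
            )
        cat = pf.merge_union(clusters)

        # oracle: repeatedly take the global max-SPM peak, drop overlaps
        remaining = pd.concat(clusters.values(), ignore_index=True)
        kept = []
        while len(remaining):
            top = remaining.loc[remaining["spm"].idxmax()]
            kept.append((top["start"], top["end"]))
            keep_mask = ~(
                (remaining["start"] < top["end"]) & (remaining["end"] > top["start"])
            )
            remaining = remaining[keep_mask]
        assert sorted(kept) == sorted(zip(cat["start"], cat["end"]))
        # union is non-overlapping
        s = cat.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


class TestBlacklistFilter:
    def test_inside_removed_and_empty_identity(self):
        peaks = _peaks([(100, 601)])
        bl = _peaks([(200, 300)])
        assert len(pf.blacklist_filter(peaks, bl)) == 0
        assert len(pf.blacklist_filter(peaks, _peaks([]))) == 1

    def test_single_bp_overlap_removed(self):
        peaks = _peaks([(100, 601)])
        assert len(pf.blacklist_filter(peaks, _peaks([(600, 700)]))) == 0
        assert len(pf.blacklist_filter(peaks, _peaks([(601, 700)]))) == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 10_000, 400)
        peaks = _peaks(list(zip(starts, starts + 501)), chrom=rng.choice(["chr1", "chr2"], 400))
        bs = rng.integers(0, 10_000, 50)
        bl = _peaks(list(zip(bs, bs + rng.integers(10, 500, 50))), chrom=rng.choice(["chr1", "chr2"], 50))
        out = pf.blacklist_filter(peaks, bl)
        keep = []
        for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"]):
            hit = any(
                c == c2 and s < e2 and e > s2
                for c2, s2, e2 in zip(bl["chrom"], bl["start"], bl["end"])
            )
            keep.append(not hit)
        assert len(out) == sum(keep)


class TestZib:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        true = pf.ZibParams(0.6, 0.8, 20.0)
        fit = pf.fit_zib(true.rvs(30_000, rng))
        assert fit.pi0 == pytest.approx(0.6, rel=0.05)
        assert fit.alpha == pytest.approx(0.8, rel=0.05)
        assert fit.beta == pytest.approx(20.0, rel=0.05)

    def test_all_zero_degenerates(self):
        fit = pf.fit_zib(np.zeros(500))
        assert fit.pi0 == 1.0 and fit.degenerate

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_zib(np.array([0.2, 1.5] * 100))

    def test_tail_probabilities(self):
        null = pf.ZibParams(0.6, 0.8, 20.0)
        assert null.sf(0.0) == 1.0
        assert null.sf(1.0) == pytest.approx(0.0, abs=1e-12)
        # whole nonzero mass: just above zero the tail is 1 - pi0
        assert null.sf(1e-12) == pytest.approx(0.4, rel=1e-6)

    def test_filter_monotone_in_fdr(self):
        rng = np.random.default_rng(5)
        null = pf.ZibParams(0.5, 1.0, 10.0)
        table = pd.DataFrame(null.rvs(3000, rng).reshape(300, 10))
        table.iloc[:20] = 0.9  # clearly accessible rows
        strict, _ = pf.zib_filter(table, null, fdr=0.001)
        loose, _ = pf.zib_filter(table, null, fdr=0.05)
        assert set(strict.index) <= set(loose.index)
        assert set(range(20)) <= set(strict.index)

    def test_pvalues_uniform_under_null(self):
        # the mixed tail probability is a valid p-value: P(p <= t) == t
        rng = np.random.default_rng(6)
        null = pf.ZibParams(0.6, 0.8, 20.0)
        p = null.sf(null.rvs(20_000, rng))
        for t in (0.01, 0.05, 0.2):
            assert np.mean(p <= t) == pytest.approx(t, abs=0.01)
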