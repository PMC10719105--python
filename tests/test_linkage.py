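"""Pair enumeration, co-accessibility scoring/null, PCC linking, empirical FDR."""

import numpy as np
import pandas as pd
import pytest

from ccre_atlas import linkage as lk


def _peaks(summits, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "summit": summits})


def _tss(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestEnumeratePairs:
    def test_window_excludes_distant_peaks(self):
        pairs = lk.enumerate_pairs(_peaks([0, 600_000]), _tss([10]))
        assert len(pairs) == 0
        pairs = lk.enumerate_pairs(_peaks([0, 499_999]), _tss([10]))
        assert len(pairs) == 1

    def test_proximal_margin(self):
        peaks = _peaks([10_500, 11_500])  # TSS at 10_000
        pairs = lk.enumerate_pairs(peaks, _tss([10_000]))
        assert pairs.loc[0, "class"] == "distal-proximal"
        # +500 is proximal, +1500 is distal

    def test_single_peak_empty(self):
        assert len(lk.enumerate_pairs(_peaks([100]), _tss([10]))) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n = 300
        peaks = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], n),
                "summit": rng.integers(0, 2_000_000, n),
            }
        )
        tss = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], 30), "pos": rng.integers(0, 2_000_000, 30)}
        )
        pairs = lk.enumerate_pairs(peaks, tss)
        got = {tuple(sorted((a, b))) for a, b in zip(pairs["a"], pairs["b"])}

        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if peaks["chrom"].iat[i] != peaks["chrom"].iat[j]:
                    continue
                if abs(int(peaks["summit"].iat[i]) - int(peaks["summit"].iat[j])) <= 500_000:
                    expected.add(tuple(sorted((i, j))))
        assert got == expected

        # pair classes agree with a direct per-member distance check
        def is_prox(idx):
            chrom = peaks["chrom"].iat[idx]
            d = np.abs(
                tss[tss["chrom"] == chrom]["pos"].to_numpy() - peaks["summit"].iat[idx]
            )
            return len(d) > 0 and d.min() <= 1000

        for _, row in pairs.iterrows():
            pa, pb = is_prox(row["a"]), is_prox(row["b"])
            expected_cls = (
                "proximal-proximal" if pa and pb
                else "distal-distal" if not pa and not pb
                else "distal-proximal"
            )
            assert row["class"] == expected_cls
        assert (pairs["distance"] <= 500_000).all()


class TestScoreCoaccessibility:
    def test_duplicated_column_scores_one(self):
        rng = np.random.default_rng(1)
        X = (rng.random((200, 3)) < 0.3).astype(int)
        X[:, 2] = X[:, 0]
        meta = lk.make_metacells(X, np.zeros(200, dtype=int), 10, rng)
        scores, valid = lk.score_coaccessibility(meta, pd.DataFrame({"a": [0], "b": [2]}))
        assert valid[0] and scores[0] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        X = (rng.random((5000, 40)) < 0.3).astype(int)
        meta = lk.make_metacells(X, np.zeros(5000, dtype=int), 10, rng)
        pairs = pd.DataFrame({"a": np.arange(20), "b": np.arange(20, 40)})
        scores, _ = lk.score_coaccessibility(meta, pairs)
        assert np.abs(scores).max() < 0.2
        assert np.abs(scores).mean() < 0.06

    def test_deterministic_under_seed(self):
        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        X = (np.random.default_rng(4).random((100, 5)) < 0.5).astype(int)
        sub = np.repeat([0, 1], 50)
        m1 = lk.make_metacells(X, sub, 5, rng1)
        m2 = lk.make_metacells(X, sub, 5, rng2)
        assert np.array_equal(m1, m2)

    def test_zero_variance_excluded(self):
        meta = np.ones((10, 2))
        scores, valid = lk.score_coaccessibility(meta, pd.DataFrame({"a": [0], "b": [1]}))
        assert not valid[0] and np.isnan(scores[0])


class TestCalibrateNull:
    def test_score_at_mu_has_half_p(self):
        null = lk.NullFit(mu=0.2, sigma=0.1)
        assert null.pvalue(0.2) == pytest.approx(0.5)

    def test_null_scores_rarely_retained(self):
        rng = np.random.default_rng(5)
        shuffled = rng.normal(0, 0.1, 5000)
        real = rng.normal(0, 0.1, 5000)
        retained, _, _ = lk.calibrate_coaccess_null(real, shuffled, fdr=0.001)
        assert retained.mean() <= 0.002

    def test_retained_sets_monotone_in_fdr(self):
        rng = np.random.default_rng(6)
        shuffled = rng.normal(0, 0.1, 1000)
        real = np.concatenate([rng.normal(0, 0.1, 900), rng.normal(0.5, 0.1, 100)])
        strict, _, _ = lk.calibrate_coaccess_null(real, shuffled, fdr=0.001)
        loose, _, _ = lk.calibrate_coaccess_null(real, shuffled, fdr=0.01)
        assert set(np.nonzero(strict)[0]) <= set(np.nonzero(loose)[0])
        assert strict.sum() > 50  # the planted tail is found

    def test_too_few_shuffled_rejected(self):
        with pytest.raises(ValueError):
            lk.calibrate_coaccess_null(np.zeros(10), np.zeros(50))


class TestLinkEnhancerGene:
    def test_perfect_coupling_gives_unit_pcc(self):
        idx = [f"s{i}" for i in range(5)]
        acc = pd.DataFrame({"p1": [1.0, 2, 3, 4, 5]}, index=idx)
        expr = pd.DataFrame({"g1": [2.0, 4, 6, 8, 10]}, index=idx)
        links = pd.DataFrame({"peak": ["p1"], "gene": ["g1"]})
        out = lk.link_enhancer_gene(acc, expr, links, normalize=False)
        assert out.loc[0, "pcc"] == pytest.approx(1.0)

    def test_permuted_labels_centre_at_zero(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(40)]
        acc = pd.DataFrame(rng.random((40, 50)), index=idx, columns=[f"p{i}" for i in range(50)])
        expr = pd.DataFrame(
            acc.to_numpy()[rng.permutation(40)], index=idx, columns=[f"g{i}" for i in range(50)]
        )
        links = pd.DataFrame({"peak": [f"p{i}" for i in range(50)], "gene": [f"g{i}" for i in range(50)]})
        out = lk.link_enhancer_gene(acc, expr, links, normalize=False)
        assert abs(out["pcc"].mean()) < 0.1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(20)]
        acc = pd.DataFrame(rng.random((20, 5)), index=idx, columns=list("abcde"))
        expr = pd.DataFrame(rng.random((20, 3)), index=idx, columns=list("xyz"))
        links = pd.DataFrame({"peak": ["a", "c"], "gene": ["x", "z"]})
        out = lk.link_enhancer_gene(acc, expr, links, normalize=False)
        for k, (p, g) in enumerate([("a", "x"), ("c", "z")]):
            expected = np.corrcoef(acc[p], expr[g])[0, 1]
            assert out.loc[k, "pcc"] == pytest.approx(expected, abs=1e-12)

    def test_needs_three_subclasses(self):
        acc = pd.DataFrame({"p": [1.0, 2]}, index=["a", "b"])
        expr = pd.DataFrame({"g": [1.0, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            lk.link_enhancer_gene(acc, expr, pd.DataFrame({"peak": ["p"], "gene": ["g"]}))


class TestEmpiricalFdr:
    def test_identical_distributions_find_no_threshold(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 0.2, 2000)
        pos_t, neg_t, cls = lk.empirical_fdr(scores, scores.copy(), fdr=0.01)
        assert pos_t is None and neg_t is None
        assert (cls == 0).all()

    def test_fdr_curve_monotone_on_separated_input(self):
        # real stochastically larger than shuffled: FDR+ is non-increasing in t
        real = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3])
        shuffled = np.array([-0.2, 0.0, 0.2, 0.4])
        shuffled_sorted = np.sort(shuffled)
        real_sorted = np.sort(real)
        scale = len(real) / len(shuffled)
        fdrs = []
        for t in real_sorted:
            n_real = len(real_sorted) - np.searchsorted(real_sorted, t)
            n_shuf = len(shuffled_sorted) - np.searchsorted(shuffled_sorted, t)
            fdrs.append(n_shuf * scale / n_real)
        assert all(a >= b for a, b in zip(fdrs, fdrs[1:]))

    def test_classification_respects_thresholds(self):
        real = np.array([-0.9, -0.5, 0.0, 0.5, 0.9])
        shuffled = np.zeros(1000)
        pos_t, neg_t, cls = lk.empirical_fdr(real, shuffled, fdr=0.01)
        assert cls.tolist() == [-1, -1, 0, 1, 1]

    def test_empty_real_rejected(self):
        with pytest.raises(ValueError):
            lk.empirical_fdr(np.array([]), np.zeros(10))
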