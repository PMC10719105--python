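"""TE overlap, mixture classification, DCA, enrichment and orthology rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.mixture import GaussianMixture

from ccre_atlas import te_conservation as te


def _bed(intervals, chrom="chr1"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    return df


class TestTeFraction:
    def test_extremes(self):
        peaks = _bed([(0, 501), (1000, 1501)])
        assert te.te_fraction({"s": peaks}, _bed([]))["s"] == 0.0
        assert te.te_fraction({"s": peaks}, _bed([(0, 2000)]))["s"] == 1.0

    def test_half_overlap_and_oracle(self):
        peaks = _bed([(0, 501), (1000, 1501), (2000, 2501), (3000, 3501)])
        tes = _bed([(400, 450), (2100, 2200)])
        assert te.te_fraction({"s": peaks}, tes)["s"] == 0.5

        rng = np.random.default_rng(0)
        starts = rng.integers(0, 50_000, 500)
        peaks = _bed(list(zip(starts, starts + 501)))
        ts = rng.integers(0, 50_000, 100)
        tes = _bed(list(zip(ts, ts + rng.integers(50, 1000, 100))))
        got = te.overlaps_any(peaks, tes)
        for k in range(500):
            s, e = peaks["start"].iat[k], peaks["end"].iat[k]
            hit = any(s < e2 and e > s2 for s2, e2 in zip(tes["start"], tes["end"]))
            assert got[k] == hit

    def test_empty_peak_set_undefined(self):
        out = te.te_fraction({"s": _bed([])}, _bed([(0, 10)]))
        assert np.isnan(out["s"])


class TestHighTeMixture:
    def _draws(self, n=250, mus=(0.18, 0.30), sd=0.02, frac_high=0.3, seed=1):
        rng = np.random.default_rng(seed)
        is_high = rng.random(n) < frac_high
        x = rng.normal(np.where(is_high, mus[1], mus[0]), sd)
        return x, is_high

    def test_recovery_well_separated(self):
        x, is_high = self._draws()
        fit = te.fit_highte_mixture(x)
        assert abs(fit.means[0] - 0.18) <= 0.01
        assert abs(fit.means[1] - 0.30) <= 0.01
        assert (fit.is_high == is_high).mean() >= 0.95

    def test_loglik_nondecreasing(self):
        x, _ = self._draws(seed=2)
        fit = te.fit_highte_mixture(x)
        assert np.all(np.diff(fit.loglik) >= -1e-9)

    def test_single_component_collapses_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.2, 1e-6, 100)
        fit = te.fit_highte_mixture(x)
        assert fit.collapsed

    def test_agrees_with_sklearn_mixture(self):
        x, _ = self._draws(seed=4)
        fit = te.fit_highte_mixture(x)
        gm = GaussianMixture(2, random_state=0, n_init=5).fit(x.reshape(-1, 1))
        sk_means = np.sort(gm.means_.ravel())
        assert np.allclose(np.sort(fit.means), sk_means, atol=0.005)

    def test_posteriors_valid(self):
        x, _ = self._draws(seed=5)
        fit = te.fit_highte_mixture(x)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert ((fit.posterior_upper >= 0) & (fit.posterior_upper <= 1)).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            te.fit_highte_mixture(np.ones(5))


class TestDcaWilcoxon:
    def test_exact_small_sample_p(self):
        # A={1,2}, B={3,4}: the most extreme of the 6 equally likely rank
        # splits, two-sided p = 2/6 = 1/3
        acc = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=list("abcd"))
        out = te.dca_wilcoxon(acc, ["a", "b"], ["c", "d"])
        assert out["pvalue"].iloc[0] == pytest.approx(1 / 3)

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        acc = pd.DataFrame(rng.normal(size=(300, 20)), columns=[f"s{i}" for i in range(20)])
        out = te.dca_wilcoxon(acc, [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)])
        assert (out["qvalue"] < 0.05).mean() <= 0.01

    def test_power_against_location_shift(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(200, 20))
        b = rng.normal(1.0, 1, size=(200, 20))  # one s.d. shift
        acc = pd.DataFrame(np.hstack([a, b]), columns=[f"s{i}" for i in range(40)])
        out = te.dca_wilcoxon(acc, [f"s{i}" for i in range(20)], [f"s{i}" for i in range(20, 40)])
        assert (out["qvalue"] < 0.05).mean() > 0.5

    def test_constant_rows_p_one(self):
        acc = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], columns=list("abcd"))
        out = te.dca_wilcoxon(acc, ["a", "b"], ["c", "d"])
        assert out["pvalue"].iloc[0] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            te.dca_wilcoxon(pd.DataFrame({"a": [1.0]}), [], ["a"])


class TestFamilyEnrichment:
    def test_equal_proportions_or_one(self):
        fg = pd.Series({"L1": 10, "L2": 30})
        bg = pd.Series({"L1": 100, "L2": 300})
        out = te.family_enrichment(fg, bg).set_index("family")
        assert out.loc["L1", "odds_ratio"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # table [[8, 2], [1, 5]]: two-sided Fisher p by exhaustive tail sum
        fg = pd.Series({"L1": 8, "other": 2})
        bg = pd.Series({"L1": 1, "other": 5})
        out = te.family_enrichment(fg, bg).set_index("family")
        # enumerate all tables with the same margins
        M, n, N = 16, 9, 10  # total, L1 margin, fg margin
        probs = {k: stats.hypergeom.pmf(k, M, n, N) for k in range(max(0, N + n - M), min(n, N) + 1)}
        p_obs = probs[8]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert out.loc["L1", "pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_direction_matches_log_odds(self):
        fg = pd.Series({"L1": 50, "SINE": 5, "LTR": 20})
        bg = pd.Series({"L1": 20, "SINE": 40, "LTR": 20})
        out = te.family_enrichment(fg, bg)
        for _, row in out.iterrows():
            fg_prop = fg.get(row["family"], 0) / fg.sum()
            bg_prop = bg.get(row["family"], 0) / bg.sum()
            if fg_prop > bg_prop:
                assert row["odds_ratio"] > 1
            elif fg_prop < bg_prop:
                assert row["odds_ratio"] < 1

    def test_zero_margin_table(self):
        fg = pd.Series({"L1": 0, "L2": 10})
        bg = pd.Series({"L1": 0, "L2": 20})
        out = te.family_enrichment(fg, bg).set_index("family")
        assert out.loc["L1", "pvalue"] == 1.0
        assert np.isnan(out.loc["L1", "odds_ratio"])


class TestIntervalPermutation:
    def test_self_overlap_minimal_p(self):
        q = _bed([(100, 200), (500, 600)])
        obs, null, p = te.interval_permutation_test(q, q, {"chr1": 100_000}, n=99, seed=0)
        assert obs == 2
        assert p == pytest.approx(1 / 100)

    def test_empty_reference(self):
        q = _bed([(100, 200)])
        obs, null, p = te.interval_permutation_test(q, _bed([]), {"chr1": 10_000}, n=19, seed=0)
        assert obs == 0 and p == 1.0

    def test_null_mean_matches_analytic_expectation(self):
        # one query of length L on one contig; reference one interval of
        # length R: P(overlap) = (L + R - 1) / (G - L + 1)
        L, R, Gsize = 100, 400, 100_000
        q = _bed([(0, L)])
        ref = _bed([(50_000, 50_000 + R)])
        n = 3000
        _, null, _ = te.interval_permutation_test(q, ref, {"chr1": Gsize}, n=n, seed=1)
        p_hit = (L + R - 1) / (Gsize - L + 1)
        se = np.sqrt(p_hit * (1 - p_hit) / n)
        assert abs(null.mean() - p_hit) <= 3 * se

    def test_pvalues_never_zero(self):
        q = _bed([(10, 20)])
        ref = _bed([(10, 20)])
        _, _, p = te.interval_permutation_test(q, ref, {"chr1": 1000}, n=50, seed=2)
        assert p > 0

    def test_query_longer_than_contig_rejected(self):
        with pytest.raises(ValueError):
            te.interval_permutation_test(
                _bed([(0, 2000)]), _bed([]), {"chr1": 1000}, n=5
            )


class TestOrthology:
    def test_class_rules(self):
        records = pd.DataFrame(
            {
                "mapped_fraction": [0.8, 0.8, 0.4, 0.5],
                "accessible_in_target": [True, False, True, True],
            }
        )
        out = te.classify_orthology(records)
        assert out["class"].tolist() == [
            "CA-conserved",
            "CA-divergent",
            "mouse-specific",
            "mouse-specific",  # boundary: strictly more than 50%
        ]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            te.classify_orthology(
                pd.DataFrame({"mapped_fraction": [1.2], "accessible_in_target": [True]})
            )


class TestSignalCorrelation:
    def test_perfect_anticorrelation(self):
        acc = pd.DataFrame([[1.0, 2, 3, 4]], columns=list("abcd"))
        mcg = -acc + 10
        rna = acc * 0 + 1
        out = te.te_signal_correlation(acc, mcg, rna)
        assert out["pcc_mcg"].iloc[0] == pytest.approx(-1.0)
        assert np.isnan(out["pcc_rna"].iloc[0])  # constant RNA excluded

    def test_independent_signals_near_zero(self):
        rng = np.random.default_rng(8)
        cols = [f"s{i}" for i in range(50)]
        acc = pd.DataFrame(rng.normal(size=(100, 50)), columns=cols)
        mcg = pd.DataFrame(rng.normal(size=(100, 50)), columns=cols)
        rna = pd.DataFrame(rng.normal(size=(100, 50)), columns=cols)
        out = te.te_signal_correlation(acc, mcg, rna)
        assert abs(out["pcc_mcg"].mean()) < 0.05

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(9)
        cols = list("abcde")
        acc = pd.DataFrame(rng.normal(size=(10, 5)), columns=cols)
        mcg = pd.DataFrame(rng.normal(size=(10, 5)), columns=cols)
        rna = pd.DataFrame(rng.normal(size=(10, 5)), columns=cols)
        out = te.te_signal_correlation(acc, mcg, rna)
        for i in range(10):
            assert out["pcc_mcg"].iloc[i] == pytest.approx(
                np.corrcoef(acc.iloc[i], mcg.iloc[i])[0, 1], abs=1e-12
            )

    def test_requires_three_subclasses(self):
        acc = pd.DataFrame([[1.0, 2]], columns=["a", "b"])
        with pytest.raises(ValueError):
            te.te_signal_correlation(acc, acc, acc)
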