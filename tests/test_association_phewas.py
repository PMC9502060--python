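import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dapes.association_phewas import (assoc_score, compute_dimorphism,
                                      elevated_indicator, elevated_pes,
                                      inverse_rank_normal, liability_r2,
                                      nested_prs_test, phewas,
                                      residualize_pes,
                                      split_train_validation)
from dapes.pes_scoring import ScoreVector


def sv(values):
    return ScoreVector.from_raw([f"S{i}" for i in range(len(values))],
                                np.asarray(values, float))


def liability_r2_reference(r2, K, P):
    """Independent closed-form implementation for cross-checking."""
    from math import exp, pi, sqrt

    t = sps.norm.ppf(1 - K)
    z = exp(-t * t / 2) / sqrt(2 * pi)
    return r2 * (K * (1 - K) / z ** 2) * (K * (1 - K) / (P * (1 - P)))


class TestLiabilityConversion:
    def test_matches_reference_on_grid(self):
        Ks = [0.007, 0.01, 0.05, 0.1, 0.25, 0.5]
        Ps = [0.1, 1 / 3, 0.5]
        r2s = [0.001, 0.01, 0.05, 0.1, 0.3, 0.6]
        for K in Ks:
            for P in Ps:
                for r2 in r2s:
                    ref = min(liability_r2_reference(r2, K, P), 1.0)
                    assert liability_r2(r2, K, P) == \
                        pytest.approx(ref, abs=1e-10)

    def test_equal_prevalence_factor(self):
        # K = P = 0.5: factor reduces to 0.25 / phi(0)^2 ~ 1.5708
        assert liability_r2(1e-6, 0.5, 0.5) / 1e-6 == \
            pytest.approx(np.pi / 2, abs=1e-6)

    def test_zero_maps_to_zero_and_monotone(self):
        assert liability_r2(0.0, 0.01, 0.3) == 0.0
        vals = [liability_r2(r, 0.01, 0.3) for r in np.linspace(0, 0.2, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            liability_r2(0.1, 0.0, 0.5)


class TestAssocScore:
    def _cohort(self, n, beta, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        logit = -0.5 + beta * x
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        return sv(x), y.astype(float)

    def test_null_p_uniform(self):
        pvals = []
        for seed in range(300):
            s, y = self._cohort(150, 0.0, seed)
            pvals.append(assoc_score(s, y, None, prevalence=0.1).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_recovers_effect_direction_and_r2(self):
        s, y = self._cohort(4000, 0.4, 1)
        res = assoc_score(s, y, None, prevalence=0.05)
        assert res.beta_per_sd == pytest.approx(0.4, abs=0.1)
        assert res.p < 1e-10
        assert 0 < res.r2_liability < 1
        assert res.n_cases + res.n_controls == 4000

    def test_p_consistent_with_beta_se(self):
        s, y = self._cohort(800, 0.3, 2)
        res = assoc_score(s, y, None, prevalence=0.1)
        assert res.p == pytest.approx(
            2 * sps.norm.sf(abs(res.beta_per_sd / res.se)), abs=1e-6)

    def test_separation_flagged_and_finite(self):
        x = np.r_[np.ones(20), -np.ones(20)]
        y = (x > 0).astype(float)
        res = assoc_score(sv(x + 1e-6 * np.arange(40)), y, None, 0.1)
        assert res.separation_flag and np.isfinite(res.beta_per_sd)


class TestNestedPrsTest:
    def test_collinear_scores_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        with pytest.raises(ValueError):
            nested_prs_test(sv(x), sv(x + 1e-9 * rng.standard_normal(200)),
                            rng.binomial(1, 0.5, 200).astype(float), None)

    def test_redundant_pes_adds_nothing(self):
        rng = np.random.default_rng(4)
        prs = rng.standard_normal(2000)
        pes = prs + 0.4 * rng.standard_normal(2000)  # r ~ 0.93
        y = rng.binomial(1, 1 / (1 + np.exp(-prs))).astype(float)
        out = nested_prs_test(sv(pes), sv(prs), y, None)
        assert out["deviance_diff"] >= 0
        assert out["p"] > 0.05

    def test_independent_signal_detected(self):
        rng = np.random.default_rng(5)
        prs = rng.standard_normal(3000)
        pes = rng.standard_normal(3000)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.5 * prs + 0.4 * pes))))
        out = nested_prs_test(sv(pes), sv(prs), y.astype(float), None)
        assert out["p"] < 1e-6


class TestElevatedPes:
    def test_single_score_prevalence_ten_percent(self):
        x = np.arange(1000, dtype=float)
        ind = elevated_indicator([sv(x)])
        assert ind.mean() == pytest.approx(0.1, abs=0.001)

    def test_independent_scores_union_prevalence(self):
        rng = np.random.default_rng(6)
        k, n = 4, 20000
        scores = [sv(rng.standard_normal(n)) for _ in range(k)]
        ind = elevated_indicator(scores)
        expect = 1 - 0.9 ** k
        ci = 1.96 * np.sqrt(expect * (1 - expect) / n)
        assert abs(ind.mean() - expect) < ci + 0.01

    def test_degenerate_ties_documented_policy(self):
        # all-equal scores: ScoreVector refuses the degenerate SD upstream
        with pytest.raises(ValueError):
            sv(np.ones(50))
        # ties exactly at the threshold count as elevated
        x = np.r_[np.zeros(90), np.ones(10)]
        ind = elevated_indicator([sv(x)])
        assert ind.sum() == 10

    def test_low_prs_stratum_reported(self):
        rng = np.random.default_rng(7)
        n = 3000
        pes = rng.standard_normal(n)
        prs = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * prs + 0.8 * pes))))
        out = elevated_pes([sv(pes)], y.astype(float), sv(prs))
        assert out["low_prs"]["n"] == 300
        assert out["low_prs"]["p_one_sided"] < 0.05  # strong planted effect
        assert 0 <= out["indicator_prevalence"] <= 1

    def test_constant_indicator_stratum_is_na(self):
        rng = np.random.default_rng(8)
        prs = np.arange(100, dtype=float)
        pes = prs.copy() * 0.9 + rng.normal(0, 10, 100)  # elevated only at top
        y = rng.binomial(1, 0.3, 100).astype(float)
        out = elevated_pes([sv(pes)], y, sv(prs))
        assert "reason" in out["low_prs"] or \
            np.isfinite(out["low_prs"]["p"])


class TestResidualizePes:
    def test_orthogonal_prs_leaves_score(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        prs = rng.standard_normal(2000)
        res = residualize_pes(sv(x), sv(prs))
        assert np.corrcoef(res.scaled, sv(x).scaled)[0, 1] > 0.999

    def test_residual_uncorrelated_with_prs(self):
        rng = np.random.default_rng(10)
        prs = rng.standard_normal(1500)
        x = 0.7 * prs + rng.standard_normal(1500)
        res = residualize_pes(sv(x), sv(prs))
        assert abs(np.corrcoef(res.scaled, sv(prs).scaled)[0, 1]) < 1e-10

    def test_score_equal_prs_degenerate(self):
        x = np.random.default_rng(11).standard_normal(500)
        with pytest.raises(ValueError):
            residualize_pes(sv(x), sv(x.copy()))

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100)
        prs = rng.standard_normal(100)
        covs = pd.DataFrame({"a": np.ones(100), "b": np.ones(100)})
        with pytest.raises(ValueError):
            residualize_pes(sv(x), sv(prs), covs)


class TestDimorphism:
    def test_equal_effects_null(self):
        d = compute_dimorphism("t", 0.3, 0.1, 0.3, 0.1)
        assert d.z_diff == 0.0 and d.p_diff == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        d = compute_dimorphism("t", 0.3, 0.1, 0.0, 0.1)
        assert d.z_diff == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-10)
        assert d.p_diff == pytest.approx(0.0339, abs=2e-4)

    def test_sex_swap_antisymmetry(self):
        a = compute_dimorphism("t", 0.3, 0.1, 0.1, 0.2)
        b = compute_dimorphism("t", 0.1, 0.2, 0.3, 0.1)
        assert b.z_diff == pytest.approx(-a.z_diff)
        assert b.p_diff == pytest.approx(a.p_diff)

    def test_z_diff_invariant(self):
        d = compute_dimorphism("t", 0.5, 0.12, -0.2, 0.07)
        expect = (0.5 - -0.2) / np.sqrt(0.12 ** 2 + 0.07 ** 2)
        assert d.z_diff == pytest.approx(expect, abs=1e-10)


class TestPhewas:
    def _setup(self, n=2500, seed=13):
        rng = np.random.default_rng(seed)
        s1 = rng.standard_normal(n)
        s2 = rng.standard_normal(n)
        traits = pd.DataFrame({
            "lipid": 1.0 + np.exp(0.5 * s1 + rng.standard_normal(n)),
            "null_trait": rng.standard_normal(n),
            "binary_trait": rng.binomial(1, 0.3, n).astype(float),
            "constant": np.ones(n),
        })
        return {"net1": sv(s1), "net2": sv(s2)}, traits, rng

    def test_planted_trait_flagged_others_not(self):
        scores, traits, rng = self._setup()
        out = phewas(scores, traits)
        primary = out[out["analysis"] == "primary"].set_index(
            ["score", "trait"])
        assert primary.loc[("net1", "lipid"), "fdr_flag"]
        assert not primary.loc[("net2", "null_trait"), "fdr_flag"]
        assert "constant" not in out["trait"].values

    def test_bonferroni_threshold_recomputed_from_pairs(self):
        scores, traits, _ = self._setup(n=400)
        out = phewas(scores, traits)
        n_pairs = (out["analysis"] == "primary").sum()
        assert out["bonf_threshold"].iloc[0] == pytest.approx(0.05 / n_pairs)

    def test_sensitivity_and_stratified_analyses_present(self):
        scores, traits, rng = self._setup(n=800)
        n = 800
        out = phewas(scores, traits, prs=sv(rng.standard_normal(n)),
                     statin=rng.binomial(1, 0.2, n),
                     sex=rng.binomial(1, 0.5, n), sensitivity=True)
        kinds = set(out["analysis"])
        assert {"primary", "prs_adjusted", "ln_outcome", "int_outcome",
                "statin_adjusted", "sex_stratified", "dimorphism"} <= kinds

    def test_ln_transform_preserves_sign(self):
        """Log-transforming a positive log-normal-like outcome keeps the
        direction of a planted effect."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(600)
            y = np.exp(0.3 * x + rng.standard_normal(600))
            out = phewas({"s": sv(x)}, pd.DataFrame({"t": y}),
                         sensitivity=True)
            est = out.set_index("analysis")["estimate"]
            hits += np.sign(est["primary"]) == np.sign(est["ln_outcome"])
        assert hits >= 19

    def test_inverse_rank_normal_is_standard_normal(self):
        x = np.random.default_rng(14).exponential(2.0, 5000)
        z = inverse_rank_normal(x)
        assert abs(z.mean()) < 0.01
        assert sps.kstest(z, "norm").pvalue > 0.01


class TestSplitTrainValidation:
    def test_deterministic_disjoint_and_ratio(self):
        rng = np.random.default_rng(15)
        labels = rng.binomial(1, 0.25, 3000)
        tr1, va1 = split_train_validation(labels, seed=7)
        tr2, va2 = split_train_validation(labels, seed=7)
        assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)
        assert not set(tr1) & set(va1)
        for idx, frac in ((tr1, 0.7), (va1, 0.3)):
            cases = labels[idx].sum()
            controls = len(idx) - cases
            assert controls == 2 * cases
        assert labels[tr1].sum() == pytest.approx(0.7 * labels.sum(), abs=1)

    def test_insufficient_controls_rejected(self):
        labels = np.r_[np.ones(100), np.zeros(50)]
        with pytest.raises(ValueError):
            split_train_validation(labels, seed=0)
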