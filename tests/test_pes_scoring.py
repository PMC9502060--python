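import itertools

import numpy as np
import pandas as pd
import pytest

from dapes.io_formats import CohortTable, LDReference
from dapes.pes_scoring import (ScoreModel, ScoreVector, build_ct_model,
                               build_lasso_model, clump, coordinate_descent,
                               default_lambda_grid, lasso_objective, score)
from dapes.synthetic_data import LDBlockSpec, simulate_genotypes

from conftest import make_sumstats


def toy_cohort(dosages, effect="A", other="G"):
    dosages = np.asarray(dosages, float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": effect, "other_allele": other})
    return CohortTable([f"S{i}" for i in range(len(dosages))], dosages,
                       variants)


@pytest.fixture(scope="module")
def ld():
    spec = LDBlockSpec(4, [2, 2], within_block_rho=0.8, spacing_bp=2000)
    return LDReference(simulate_genotypes(spec, 4000, seed=3))


class TestClump:
    def test_correlated_pair_keeps_most_significant(self, ld):
        ss = make_sumstats([0.5, 0.2, 0.0, 0.0], pos=[1, 2001, 4001, 6001])
        kept = clump(ss, ld, window_kb=10, r2_max=0.1)
        assert "rs1" in kept and "rs2" not in kept

    def test_low_r2_keeps_both(self, ld):
        # rs1/rs3 are in different LD blocks: realized r2 ~ 0
        ss = make_sumstats([0.5, 0.0, 0.2, 0.0], pos=[1, 2001, 4001, 6001])
        kept = clump(ss, ld, window_kb=10, r2_max=0.1)
        assert {"rs1", "rs3"} <= set(kept)

    def test_tie_broken_by_position(self, ld):
        ss = make_sumstats([0.3, 0.3, 0.0, 0.0], pos=[1, 2001, 4001, 6001])
        kept = clump(ss, ld, window_kb=10, r2_max=0.1)
        assert kept[0] == "rs1"  # equal p: lower position wins

    def test_retained_pairwise_r2_bounded(self, ld):
        ss = make_sumstats([0.5, 0.4, 0.3, 0.2], pos=[1, 2001, 4001, 6001])
        kept = clump(ss, ld, window_kb=10, r2_max=0.1)
        for a, b in itertools.combinations(kept, 2):
            assert ld.r2(a, b) <= 0.1 + 1e-12


class TestBuildCtModel:
    def test_threshold_one_keeps_all_clumped(self):
        ss = make_sumstats([0.5, 0.2], pvals=[0.9, 0.99])
        m = build_ct_model(ss, ["rs1", "rs2"], 1.0, "m")
        assert m.n_variants == 2

    def test_threshold_filters(self):
        ss = make_sumstats([0.5, 0.2], pvals=[0.001, 0.01])
        m = build_ct_model(ss, ["rs1", "rs2"], 0.005, "m")
        assert m.variants["variant_id"].tolist() == ["rs1"]

    def test_empty_model_names_threshold(self):
        ss = make_sumstats([0.5], pvals=[0.9])
        with pytest.raises(ValueError, match="0.005"):
            build_ct_model(ss, ["rs1"], 0.005, "m")


class TestScore:
    def test_hand_arithmetic(self):
        cohort = toy_cohort([[2.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        model = ScoreModel("m", pd.DataFrame({
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": "A",
            "coefficient": [0.1, -0.2, 0.05]}), "ct")
        raw = score(model, cohort).raw
        assert raw[0] == pytest.approx(0.0)  # 0.2 - 0.2 + 0

    def test_matches_brute_force_oracle_exactly(self):
        """Dyadic-rational coefficients and integer dosages make every sum
        exact in float64, so the dot-product oracle must agree bitwise."""
        rng = np.random.default_rng(1)
        cohort = toy_cohort(rng.integers(0, 3, (15, 8)))
        coef = rng.integers(-512, 513, 8) / 256.0
        model = ScoreModel("m", pd.DataFrame({
            "variant_id": [f"rs{i + 1}" for i in range(8)],
            "effect_allele": "A", "coefficient": coef}), "ct")
        raw = score(model, cohort).raw
        expected = [sum(c * g for c, g in zip(coef, row))
                    for row in cohort.dosages]
        assert np.array_equal(raw, expected)

    def test_scaling_affine_invariance(self):
        rng = np.random.default_rng(2)
        cohort = toy_cohort(rng.integers(0, 3, (30, 4)))
        base = pd.DataFrame({"variant_id": [f"rs{i + 1}" for i in range(4)],
                             "effect_allele": "A",
                             "coefficient": rng.standard_normal(4)})
        s1 = score(ScoreModel("m", base, "ct"), cohort)
        doubled = base.assign(coefficient=2 * base["coefficient"])
        s2 = score(ScoreModel("m", doubled, "ct"), cohort)
        assert np.allclose(s2.raw, 2 * s1.raw)
        assert np.allclose(s2.scaled, s1.scaled, atol=1e-10)
        assert abs(s1.scaled.mean()) < 1e-10
        assert s1.scaled.std() == pytest.approx(1.0, abs=1e-10)

    def test_allele_flip_harmonized(self):
        cohort = toy_cohort([[2.0], [0.0], [1.0]])
        flipped = ScoreModel("m", pd.DataFrame({
            "variant_id": ["rs1"], "effect_allele": ["G"],
            "coefficient": [0.5]}), "ct")
        raw = score(flipped, cohort).raw
        assert np.allclose(raw, 0.5 * (2 - cohort.dosages[:, 0]))

    def test_too_many_missing_variants(self):
        cohort = toy_cohort([[1.0], [0.0]])
        model = ScoreModel("m", pd.DataFrame({
            "variant_id": ["rs1", "gone1", "gone2"],
            "effect_allele": "A", "coefficient": [0.1, 0.2, 0.3]}), "ct")
        with pytest.raises(ValueError):
            score(model, cohort)

    def test_duplicate_model_variants_rejected(self):
        with pytest.raises(ValueError):
            ScoreModel("m", pd.DataFrame({
                "variant_id": ["rs1", "rs1"], "effect_allele": "A",
                "coefficient": [0.1, 0.2]}), "ct")


def lattice_search(R, r, s, lam, width, center, points=9):
    """Brute-force objective minimization over a dense beta lattice."""
    grids = [np.linspace(c - width, c + width, points) for c in center]
    best_obj, best_beta = np.inf, None
    for beta in itertools.product(*grids):
        beta = np.array(beta)
        obj = lasso_objective(beta, R, r, s, lam)
        if obj < best_obj:
            best_obj, best_beta = obj, beta
    return best_obj, best_beta


class TestCoordinateDescent:
    def test_s_one_closed_form(self):
        rng = np.random.default_rng(4)
        r = rng.standard_normal(6) * 0.1
        R = np.eye(6)
        lam = 0.05
        beta, conv = coordinate_descent(R, r, s=1.0, lam=lam)
        closed = np.sign(r) * np.maximum(np.abs(r) - lam, 0)
        assert conv and np.max(np.abs(beta - closed)) < 1e-10

    def test_large_lambda_zeroes_model(self):
        rng = np.random.default_rng(5)
        r = rng.standard_normal(5) * 0.1
        beta, _ = coordinate_descent(np.eye(5), r, s=1.0,
                                     lam=np.abs(r).max())
        assert np.all(beta == 0)

    def test_objective_matches_lattice_oracle(self):
        """5-variant problem: solver objective within 1e-8 of a refined
        lattice search minimum."""
        rng = np.random.default_rng(6)
        A = rng.standard_normal((40, 5))
        R = np.corrcoef(A.T)
        r = rng.standard_normal(5) * 0.2
        s, lam = 0.5, 0.01
        beta, conv = coordinate_descent(R, r, s, lam, tol=1e-12,
                                        max_sweeps=2000)
        assert conv
        obj = lasso_objective(beta, R, r, s, lam)
        center, width = np.zeros(5), 1.0
        for _ in range(12):  # multiresolution lattice refinement
            lat_obj, center = lattice_search(R, r, s, lam, width, center)
            width /= 3.0
        assert obj <= lat_obj + 1e-12
        assert lat_obj - obj < 1e-8

    def test_objective_monotone_over_sweeps(self):
        """Each sweep of coordinate descent cannot increase the objective."""
        rng = np.random.default_rng(7)
        A = rng.standard_normal((30, 8))
        R = np.corrcoef(A.T)
        r = rng.standard_normal(8) * 0.3
        objs = []
        beta = np.zeros(8)
        for _ in range(25):
            beta, _ = coordinate_descent(R, r, 0.2, 0.02, beta0=beta,
                                         max_sweeps=1, tol=0)
            objs.append(lasso_objective(beta, R, r, 0.2, 0.02))
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))


class TestBuildLassoModel:
    def test_selects_nonzero_model_and_reports_params(self):
        spec = LDBlockSpec(12, [4, 4, 4], within_block_rho=0.3)
        cohort = simulate_genotypes(spec, 1200, seed=8)
        rng = np.random.default_rng(9)
        true = np.zeros(12)
        true[[0, 5]] = 0.4
        liability = cohort.dosages @ true + rng.standard_normal(1200)
        y = (liability > np.quantile(liability, 0.5)).astype(float)
        from dapes.synthetic_data import emit_gwas_sumstats

        ss = emit_gwas_sumstats(cohort, y)
        ld = LDReference(cohort)
        model, grid = build_lasso_model(ss, ld, cohort, y, "m")
        assert model.method == "lasso"
        assert model.params["n_nonzero"] == model.n_variants > 0
        assert {"s", "lambda"} <= set(model.params)
        assert set(grid.columns) == {"s", "lambda", "n_nonzero", "abs_corr"}

    def test_lambda_grid_default_spans_max_r(self):
        r = np.array([0.1, -0.5, 0.2])
        grid = default_lambda_grid(r)
        assert len(grid) == 20
        assert grid[0] == pytest.approx(1e-4) and \
            grid[-1] == pytest.approx(0.5)
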