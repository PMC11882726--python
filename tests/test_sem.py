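"""DWLS estimation: oracles, identities, indices, genetic regression."""

import numpy as np
import pytest

from factorgwas.ldsc import CovarianceStack, vech_indices
from factorgwas.models import endorsed_model, endorsed_model_literal, model_zoo
from factorgwas.sem import (
    CompiledModel,
    ModelError,
    classify_fit,
    compare_models,
    delta_chi2,
    fit,
    fit_many,
    genetic_multiple_regression,
    independence_model,
)


def exact_stack(spec, theta=None, v_scale=1e-6, seed=0):
    """Stack whose S is exactly the model-implied matrix at a chosen theta."""
    cm = CompiledModel(spec)
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = cm.default_start(np.eye(cm.t) * 0.2)
        theta = theta + 0.01 * rng.standard_normal(cm.k)
    lam, psi, th, _, _ = cm.build(theta)
    S = lam @ psi @ lam.T + th
    p = cm.t * (cm.t + 1) // 2
    V = np.eye(p) * v_scale
    return CovarianceStack(list(spec.indicators), S, V, 0), theta, cm


class TestExactModelOracle:
    def test_endorsed_recovery_to_machine_precision(self):
        spec = endorsed_model()
        stack, theta_true, cm = exact_stack(spec)
        res = fit(stack, spec)
        assert res.converged
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        for key, true in zip(cm.params, theta_true):
            assert abs(abs(res.estimates[key]) - abs(true)) < 1e-6

    def test_chi2_vanishes_for_exact_stack_regardless_of_v(self):
        spec = model_zoo()["common_factor"]
        for v_scale in (1e-4, 1e-6, 1e-8):
            stack, _, _ = exact_stack(spec, v_scale=v_scale)
            res = fit(stack, spec, compute_indices=False)
            assert res.chi2 < 1e-6

    def test_literal_under_identified_spec_raises(self):
        spec = endorsed_model()
        stack, _, _ = exact_stack(spec)
        with pytest.raises(ModelError, match="singular information"):
            fit(stack, endorsed_model_literal(), compute_indices=False)


class TestSaturation:
    def test_saturated_model_zero_residuals(self):
        from test_models import saturated_spec
        spec = endorsed_model()
        stack, _, _ = exact_stack(spec)
        res = fit(stack, saturated_spec())
        assert res.df == 0
        assert res.chi2 == 0.0
        assert res.srmr == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.sigma_yy, res.S_obs, atol=1e-8)


class TestIdentities:
    def test_aic_and_df_identities_on_synthetic_stack(self, demo_stack_small):
        fits = fit_many(demo_stack_small, model_zoo())
        for name, f in fits.items():
            spec = model_zoo()[name]
            assert f.aic - f.chi2 == pytest.approx(2 * spec.n_free())
            assert f.df + f.k == 45

    def test_permutation_invariance(self, demo_stack_small):
        spec = endorsed_model()
        base = fit(demo_stack_small, spec)
        perm = np.random.default_rng(3).permutation(9)
        labels = [demo_stack_small.labels[i] for i in perm]
        order = vech_indices(9)
        pos = {}
        for p, (i, j) in enumerate(order):
            pos[(i, j)] = p
            pos[(j, i)] = p
        rows = [pos[(perm[i], perm[j])] for i, j in order]
        stack_p = CovarianceStack(
            labels, demo_stack_small.S[np.ix_(perm, perm)],
            demo_stack_small.V[np.ix_(rows, rows)], demo_stack_small.n_blocks)
        res = fit(stack_p, spec.reorder(labels))
        assert res.chi2 == pytest.approx(base.chi2, rel=1e-6)
        assert res.aic == pytest.approx(base.aic, rel=1e-6)
        for key, est in base.estimates.items():
            assert res.estimates[key] == pytest.approx(est, abs=1e-6)

    def test_loading_recovery_within_sandwich_ses(self, demo_stack_small,
                                                  demo_config_small):
        spec = endorsed_model()
        res = fit(demo_stack_small, spec)
        lam_true = demo_config_small.loadings
        fmap = {f: i for i, f in enumerate(demo_config_small.factor_labels)}
        imap = {t.label: i for i, t in enumerate(demo_config_small.traits)}
        assert res.converged
        for (kind, key), est in res.estimates.items():
            if kind != "loading":
                continue
            ind, fac = key
            true = lam_true[imap[ind], fmap[fac]]
            z = (abs(est) - abs(true)) / res.se[(kind, key)]
            assert abs(z) < 3.5

    def test_heywood_case_flagged_not_constrained(self):
        spec = model_zoo()["common_factor"]
        lam = 0.5 * np.ones((9, 1))
        resid = np.full(9, 0.1)
        resid[0] = -0.03  # inadmissible generating residual
        S = lam @ lam.T + np.diag(resid)
        stack = CovarianceStack(list(spec.indicators), S, np.eye(45) * 1e-6, 0)
        res = fit(stack, spec, compute_indices=False)
        assert "UKB_Trails" in res.heywood


class TestIndices:
    @pytest.mark.parametrize("cfi,srmr,label", [
        (0.96, 0.04, "good"),
        (0.9859904, 0.09571648, "acceptable"),
        (0.89, 0.03, "poor"),
        (0.92, 0.12, "poor"),
        (0.97, 0.07, "acceptable"),
    ])
    def test_classification_thresholds(self, cfi, srmr, label):
        assert classify_fit(cfi, srmr) == label

    def test_cfi_bounds_and_p_value(self, demo_stack_small):
        from scipy.stats import chi2 as chi2_dist
        res = fit(demo_stack_small, endorsed_model())
        if res.chi2 <= res.df:
            assert res.cfi == 1.0
        assert 0.0 <= res.cfi <= 1.0
        assert res.p_value == pytest.approx(chi2_dist.sf(res.chi2, res.df))

    def test_compare_models_tie_and_best(self, demo_stack_small):
        f = fit(demo_stack_small, endorsed_model())
        table = compare_models({"a": f, "b": f})
        assert (table["dAIC"] == 0).all()
        assert table["best"].sum() == 1

    def test_delta_chi2_df_between_common_and_three_factor(self, demo_stack_small):
        fits = fit_many(demo_stack_small, model_zoo())
        _, d_df, _ = delta_chi2(fits["common_factor"], fits["three_factor"])
        assert d_df == 4


class TestGeneticRegression:
    def _stack(self, S, v=1e-5):
        t = len(S)
        p = t * (t + 1) // 2
        return CovarianceStack([f"t{i}" for i in range(t)], np.asarray(S, float),
                               np.eye(p) * v, 0)

    def test_orthogonal_predictors_give_marginal_coefficients(self):
        S = np.array([[1.0, 0.0, 0.3],
                      [0.0, 1.0, -0.2],
                      [0.3, -0.2, 1.0]])
        out = genetic_multiple_regression(self._stack(S), "t2", ["t0", "t1"])
        assert out["t0"][0] == pytest.approx(0.3)
        assert out["t1"][0] == pytest.approx(-0.2)

    def test_outcome_as_own_predictor(self):
        S = np.array([[1.0, 0.4, 0.4],
                      [0.4, 1.0, 0.5],
                      [0.4, 0.5, 1.0]])
        out = genetic_multiple_regression(self._stack(S), "t2", ["t2", "t0"])
        assert out["t2"][0] == pytest.approx(1.0)
        assert out["t0"][0] == pytest.approx(0.0, abs=1e-10)

    def test_recovery_of_generating_partials(self):
        # outcome built with partial coefficients (0.4, -0.2) on correlated
        # genetic predictors; estimate from a simulated panel's stack
        from factorgwas import ldsc as L
        from factorgwas import simulate as sim
        b = np.array([0.4, -0.2])
        Spp = np.array([[1.0, 0.3], [0.3, 1.0]]) * 0.3  # predictor gencov
        spo = Spp @ b
        s_oo = float(b @ Spp @ b) + 0.1
        S = np.zeros((3, 3))
        S[:2, :2] = Spp
        S[:2, 2] = S[2, :2] = spo
        S[2, 2] = s_oo
        vals, vecs = np.linalg.eigh(S)
        lam = vecs * np.sqrt(np.maximum(vals, 0))
        cfg = sim.GeneratorConfig(
            m_snps=20_000,
            traits=[sim.TraitSpec("t0", 60_000), sim.TraitSpec("t1", 60_000),
                    sim.TraitSpec("t2", 60_000)],
            loadings=lam, factor_h2=np.ones(3), specific_h2=np.zeros(3), seed=21)
        panel, ld = sim.simulate_panel(cfg)
        stack = L.build_covariance_stack(panel, ld, 20_000, n_blocks=100)
        out = genetic_multiple_regression(stack, "t2", ["t0", "t1"])
        for name, true in zip(["t0", "t1"], b):
            est, se = out[name]
            assert abs(est - true) < 2.5 * se

    def test_singular_predictors_rejected(self):
        S = np.ones((3, 3))
        with pytest.raises(ModelError, match="singular"):
            genetic_multiple_regression(self._stack(S), "t2", ["t0", "t1"])

    def test_unknown_trait_rejected(self):
        S = np.eye(2)
        with pytest.raises(ModelError):
            genetic_multiple_regression(self._stack(S), "zz", ["t0"])


def test_independence_model_is_baseline():
    spec = independence_model(["a", "b", "c"])
    assert spec.factors == []
    assert spec.n_free() == 3
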