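"""LD-score regression estimators, jackknife covariance, screening."""

import numpy as np
import pandas as pd
import pytest

from factorgwas import ldsc as L
from factorgwas import simulate as sim
from factorgwas.ldsc import CovarianceStack, vech, vech_indices, unvech
from factorgwas.simulate import GeneratorConfig, TraitSpec
from factorgwas.sumstats import SumStatsTable
from factorgwas.table2 import table2_fixture


def _single_trait(h2, n, m, seed):
    cfg = GeneratorConfig(
        m_snps=m, traits=[TraitSpec("t", n)],
        loadings=np.array([[np.sqrt(h2)]]), factor_h2=np.array([1.0]),
        specific_h2=np.zeros(1), seed=seed,
    )
    tables, ld = sim.simulate_sumstats(cfg)
    return tables[0], ld


class TestVech:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        a = a + a.T
        assert np.allclose(unvech(vech(a), 5), a)

    def test_column_major_lower_triangle_order(self):
        assert vech_indices(3) == [(0, 0), (1, 0), (2, 0), (1, 1), (2, 1), (2, 2)]


class TestH2:
    def test_flat_regression_gives_zero_h2_unit_intercept(self):
        m = 2_000
        ld = sim.simulate_ld_scores(m, ("uniform", {"low": 1, "high": 20}), seed=0)
        df = pd.DataFrame({
            "SNP": ld["SNP"], "CHR": "1", "BP": np.arange(m) + 1,
            "A1": "A", "A2": "G", "Z": 1.0, "N": 10_000.0, "P": 0.3,
        })
        est = L.estimate_h2(SumStatsTable("t", df), ld, m, n_blocks=50)
        assert est.h2 == pytest.approx(0.0, abs=1e-10)
        assert est.intercept == pytest.approx(1.0, abs=1e-10)

    def test_parameter_recovery(self):
        table, ld = _single_trait(0.25, 80_000, 20_000, seed=5)
        est = L.estimate_h2(table, ld, 20_000, n_blocks=100)
        assert abs(est.h2 - 0.25) < 2 * est.se

    def test_jackknife_se_tracks_empirical_sd(self):
        ests = [L.estimate_h2(*_single_trait(0.25, 80_000, 4_000, seed=100 + r),
                              m=4_000, n_blocks=50) for r in range(50)]
        h2s = np.array([e.h2 for e in ests])
        ses = np.array([e.se for e in ests])
        ratio = np.median(ses) / h2s.std(ddof=1)
        assert 1 / 1.5 < ratio < 1.5

    def test_too_few_snps_is_input_error(self):
        table, ld = _single_trait(0.2, 10_000, 100, seed=0)
        with pytest.raises(L.LdscInputError):
            L.estimate_h2(table, ld, 100, n_blocks=200)


class TestGencov:
    def test_self_covariance_equals_h2(self):
        table, ld = _single_trait(0.25, 80_000, 5_000, seed=2)
        copy = table.copy()
        copy.trait = "t2"
        est = L.estimate_gencov(table, copy, ld, 5_000, n_blocks=50)
        h2 = L.estimate_h2(table, ld, 5_000, n_blocks=50)
        assert est.cov == pytest.approx(h2.h2, rel=1e-9)

    def test_independent_traits_near_zero(self):
        cfg = GeneratorConfig(
            m_snps=20_000,
            traits=[TraitSpec("a", 60_000), TraitSpec("b", 60_000)],
            loadings=np.array([[0.5, 0.0], [0.0, 0.5]]),
            factor_h2=np.ones(2), specific_h2=np.zeros(2), seed=9,
        )
        tables, ld = sim.simulate_sumstats(cfg)
        est = L.estimate_gencov(tables[0], tables[1], ld, 20_000, n_blocks=100)
        assert abs(est.cov) < 2 * est.se

    def test_overlap_absorbed_by_intercept(self):
        # rho_g = 0.7 with complete sample overlap: slope recovers the
        # genetic covariance while the intercept picks up the overlap term
        h = np.sqrt(0.3)
        cfg = GeneratorConfig(
            m_snps=20_000,
            traits=[TraitSpec("a", 60_000), TraitSpec("b", 60_000)],
            loadings=np.array([[h * np.sqrt(0.7), h * np.sqrt(0.3), 0.0],
                               [h * np.sqrt(0.7), 0.0, h * np.sqrt(0.3)]]),
            factor_h2=np.ones(3), specific_h2=np.zeros(2),
            overlap=np.array([[1.0, 1.0], [1.0, 1.0]]), overlap_rho=0.6, seed=11,
        )
        true_cov = 0.7 * 0.3
        tables, ld = sim.simulate_sumstats(cfg)
        est = L.estimate_gencov(tables[0], tables[1], ld, 20_000, n_blocks=100)
        assert abs(est.cov - true_cov) < 2 * est.se
        assert est.intercept > 0.3  # generating cross-intercept is 0.6


class TestStack:
    def test_diag_v_matches_pairwise_squared_ses(self, demo_stack_small,
                                                 demo_panel_small, demo_config_small):
        stack = demo_stack_small
        t = stack.n_traits
        se_mat = stack.se_matrix()
        assert np.all(np.diag(stack.V) > 0)
        assert se_mat.shape == (t, t)
        assert len(np.diag(stack.V)) == t * (t + 1) // 2

    def test_duplicated_trait_gives_identical_entries(self):
        table, ld = _single_trait(0.25, 80_000, 5_000, seed=3)
        copy = table.copy()
        copy.trait = "t2"
        from factorgwas.sumstats import merge_cohorts
        panel = merge_cohorts([table, copy])
        stack = L.build_covariance_stack(panel, ld, 5_000, n_blocks=50)
        assert np.allclose(stack.S, stack.S[0, 0])

    def test_recovery_against_generating_matrix(self, demo_stack_small,
                                                demo_config_small):
        S_true = demo_config_small.genetic_covariance()
        z = (demo_stack_small.S - S_true) / demo_stack_small.se_matrix()
        assert np.abs(z[np.tril_indices(9)]).max() < 3.5

    def test_serialization_round_trip(self, demo_stack_small, tmp_path):
        path = tmp_path / "stack.json"
        demo_stack_small.to_json(path)
        back = CovarianceStack.from_json(path)
        assert back.labels == demo_stack_small.labels
        assert np.allclose(back.S, demo_stack_small.S)
        assert np.allclose(back.V, demo_stack_small.V)

    def test_scale_equivariance_under_trait_negation(self, demo_panel_small,
                                                     demo_config_small):
        panel, ld = demo_panel_small
        flipped = type(panel)(panel.snps, list(panel.traits), panel.Z.copy(),
                              panel.N)
        flipped.Z[:, 0] = -flipped.Z[:, 0]
        a = L.build_covariance_stack(panel, ld, demo_config_small.m_snps, 50)
        b = L.build_covariance_stack(flipped, ld, demo_config_small.m_snps, 50)
        sign = np.ones((9, 9))
        sign[0, :] = -1
        sign[:, 0] = -1
        sign[0, 0] = 1
        assert np.allclose(b.S, sign * a.S)
        ra, rb = L.standardize(a).S, L.standardize(b).S
        assert np.allclose(np.abs(ra), np.abs(rb))

    def test_jackknife_consistency_across_block_counts(self, demo_panel_small,
                                                       demo_config_small):
        panel, ld = demo_panel_small
        m = demo_config_small.m_snps
        v100 = L.build_covariance_stack(panel, ld, m, 100).V
        v200 = L.build_covariance_stack(panel, ld, m, 200).V
        d100, d200 = np.diag(v100), np.diag(v200)
        ratio = d100 / d200
        assert np.all((ratio > 0.5) & (ratio < 2.0))


class TestStandardize:
    def _toy(self):
        S = np.array([[0.1141, 0.1471], [0.1471, 0.3765]])
        V = np.diag([1e-4, 2e-4, 4e-4])
        return CovarianceStack(["a", "b"], S, V, 10)

    def test_correlation_arithmetic(self):
        std = L.standardize(self._toy())
        assert std.S[0, 1] == pytest.approx(0.7097, abs=5e-4)

    def test_unit_diagonal_and_idempotence(self):
        std = L.standardize(self._toy())
        assert np.all(np.diag(std.S) == 1.0)
        again = L.standardize(std)
        assert np.allclose(again.S, std.S)
        assert np.allclose(again.V, std.V, atol=1e-12)

    def test_nonpositive_diagonal_names_trait(self):
        S = np.array([[0.0, 0.1], [0.1, 0.3]])
        stack = CovarianceStack(["bad", "ok"], S, np.eye(3), 10)
        with pytest.raises(L.NumericalError, match="bad"):
            L.standardize(stack)


class TestScreen:
    def test_nonsignificant_h2_excluded(self):
        rep = L.screen(np.array([0.05, 0.3]), np.array([0.20, 0.05]),
                       np.eye(2), ["weak", "strong"], h2_z_threshold=1.96)
        assert rep.retained == ["strong"]
        assert rep.excluded[0][0] == "weak"

    def test_table2_collinearity_flags_nih_g6(self):
        fx = table2_fixture()
        rep = L.screen(fx.h2, np.diag(fx.se), fx.r_g, fx.labels,
                       h2_z_threshold=1.645, collinearity_r=0.90)
        reasons = dict(rep.excluded)
        assert "NIH_G6" in reasons
        assert "multicollinear" in reasons["NIH_G6"]
        assert "UKB_Trails" in rep.retained
        assert "UKB_SDST" in rep.retained

    def test_clean_panel_fully_retained(self):
        rep = L.screen(np.array([0.2, 0.3, 0.25]), np.array([0.02, 0.03, 0.02]),
                       np.eye(3) * 0.2 + 0.8 * np.eye(3), ["a", "b", "c"])
        assert rep.retained == ["a", "b", "c"]
        assert rep.excluded == []
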