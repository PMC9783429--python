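import math

import numpy as np
import pytest

from sacontrast.datamodel import ObservationTable
from sacontrast.design import ModelSpec, build_dual_design, build_single_design
from sacontrast.inference import (
    InestimableError,
    fit_sequential_anova,
    phi,
    sa_test_dual,
    sa_test_single,
)
from sacontrast.simulate import SimulationConfig, analysis_model, estimate_fpr

from conftest import make_experiment, sequential_ss_oracle


class TestSequentialAnova:
    def test_one_way_two_groups_closed_form(self):
        # two groups of size n: group SS = n (ybar1 - ybar2)^2 / 2
        rng = np.random.default_rng(1)
        n = 7
        y = np.concatenate([rng.normal(1.0, 1, n), rng.normal(3.0, 1, n)])
        g = np.r_[np.ones(n), -np.ones(n)]  # sum-to-zero coding
        from sacontrast.design import DesignMatrix
        X = np.column_stack([np.ones(2 * n), g])
        design = DesignMatrix(X, ["intercept", "group"],
                              {"intercept": slice(0, 1), "group": slice(1, 2)},
                              np.arange(2 * n))
        table, _ = fit_sequential_anova(design, y)
        df_g, ss_g, _ = table.term("group")
        expected = n * (y[:n].mean() - y[n:].mean()) ** 2 / 2
        assert df_g == 1
        assert ss_g == pytest.approx(expected, rel=1e-12)

    def test_pythagorean_identity_and_df_sum(self, study_experiment):
        table, spec, _ = study_experiment
        design = build_dual_design(table, spec)
        anova, _ = fit_sequential_anova(design, table.df["response"].to_numpy())
        frame = anova.to_frame()
        assert frame["sum_sq"].sum() == pytest.approx(anova.total_ss, rel=1e-10)
        assert frame["df"].sum() == anova.n - 1

    def test_ss_invariant_to_main_effect_order_when_balanced(self):
        table, spec, cfg = make_experiment(pops_per_env=(2, 2, 2),
                                           units_per_pop_phase=2, seed=13)
        y = table.df["response"].to_numpy()
        d1 = build_dual_design(table, spec)
        from sacontrast.design import Term
        swapped = ModelSpec(spec.trait_spec,
                            (Term.TEST_ENV, Term.POPULATION) + spec.terms[2:])
        d2 = build_dual_design(table, swapped)
        a1, _ = fit_sequential_anova(d1, y)
        a2, _ = fit_sequential_anova(d2, y)
        for name in ("population", "test_env", "sa_genetic", "interaction"):
            assert a1.term(name)[1] == pytest.approx(a2.term(name)[1], rel=1e-9)

    def test_matches_nested_rss_oracle(self, tiny_experiment):
        table, spec, _ = tiny_experiment
        y = table.df["response"].to_numpy()
        design = build_dual_design(table, spec)
        anova, _ = fit_sequential_anova(design, y)
        ss, df, rss = sequential_ss_oracle(design.block_list(), y)
        for name, df_k, ss_k, _ in anova.rows:
            assert ss_k == pytest.approx(ss[name], rel=1e-8, abs=1e-10), name
            assert df_k == df[name], name
        assert anova.residual[1] == pytest.approx(rss, rel=1e-8)


class TestPhi:
    @pytest.mark.parametrize("constrained,free,expected",
                             [(10.0, 10.0, 0.0), (10.0, 0.0, 1.0), (4.0, 4.2, -0.05)])
    def test_direct_substitution(self, constrained, free, expected):
        assert phi(constrained, free) == pytest.approx(expected)

    def test_zero_constrained_ms_flagged(self):
        with pytest.raises(ZeroDivisionError):
            phi(0.0, 0.0)

    def test_phi_matches_two_independent_fits(self, tiny_experiment):
        # recompute phi from scratch: constrained and free brute-force fits
        table, spec, _ = tiny_experiment
        y = table.df["response"].to_numpy()
        result = sa_test_dual(table, spec)
        from sacontrast.design import Term
        free = build_dual_design(table, spec)
        ss_f, df_f, _ = sequential_ss_oracle(free.block_list(), y)
        constrained_spec = ModelSpec(
            spec.trait_spec, tuple(t for t in spec.terms if t is not Term.SA_GENETIC))
        con = build_dual_design(table, constrained_spec)
        ss_c, df_c, _ = sequential_ss_oracle(con.block_list(), y)
        expected = phi(ss_c["interaction"] / df_c["interaction"],
                       ss_f["interaction"] / df_f["interaction"])
        assert result.genetic.phi == pytest.approx(expected, rel=1e-8)


class TestDualTest:
    def test_noise_free_recovery_and_phi_one(self):
        table, spec, _ = make_experiment(
            pops_per_env=(3, 3, 3), sd_pop=0, sd_test_env=0, sd_interaction=0,
            sd_unit=0, sd_res=0, sa_genetic_true=1.0, seed=1)
        res = sa_test_dual(table, spec)
        assert res.genetic.sa.estimate == pytest.approx(1.0, abs=1e-10)
        assert res.plastic.sa.estimate == pytest.approx(0.0, abs=1e-10)
        assert res.genetic.phi == pytest.approx(1.0, abs=1e-9)
        assert res.genetic.degenerate and math.isnan(res.genetic.F)

    def test_pure_main_effects_give_zero_sa(self):
        table, spec, _ = make_experiment(
            pops_per_env=(3, 3, 3), sd_pop=0.8, sd_test_env=0.5, sd_interaction=0,
            sd_unit=0, sd_res=0, seed=2)
        res = sa_test_dual(table, spec)
        assert res.genetic.sa.estimate == pytest.approx(0.0, abs=1e-9)
        assert res.plastic.sa.estimate == pytest.approx(0.0, abs=1e-9)

    def test_both_effects_recovered_jointly(self):
        table, spec, _ = make_experiment(
            pops_per_env=(3, 3, 3), sd_pop=0.4, sd_test_env=0.2, sd_interaction=0,
            sd_unit=0, sd_res=0, sa_genetic_true=0.5, sa_plastic_true=-0.3, seed=3)
        res = sa_test_dual(table, spec)
        assert res.genetic.sa.estimate == pytest.approx(0.5, abs=1e-9)
        assert res.plastic.sa.estimate == pytest.approx(-0.3, abs=1e-9)

    def test_f_statistics_match_nested_rss_oracle(self, tiny_experiment):
        table, spec, _ = tiny_experiment
        y = table.df["response"].to_numpy()
        res = sa_test_dual(table, spec)
        design = build_dual_design(table, spec)
        ss, df, _ = sequential_ss_oracle(design.block_list(), y)
        F_g = (ss["sa_genetic"] / df["sa_genetic"]) / (ss["interaction"] / df["interaction"])
        F_p = (ss["sa_plastic"] / df["sa_plastic"]) / (
            ss["delta_interaction"] / df["delta_interaction"])
        assert res.genetic.F == pytest.approx(F_g, rel=1e-8)
        assert res.plastic.F == pytest.approx(F_p, rel=1e-8)

    def test_missing_phase_is_an_error(self, tiny_experiment):
        table, spec, _ = tiny_experiment
        common = ObservationTable.from_frame(table.df[table.df["phase"] == "common"])
        with pytest.raises(ValueError):
            sa_test_dual(common, spec)

    def test_serialization_schema(self, tiny_experiment):
        table, spec, _ = tiny_experiment
        d = sa_test_dual(table, spec).to_dict()
        for block in ("genetic", "plastic"):
            assert {"estimate", "se", "F", "df_num", "df_den", "p", "phi"} <= d[block].keys()
        assert d["genetic"]["df_num"] == 1 and d["plastic"]["df_num"] == 1


class TestSingleTest:
    def test_noise_free_injected_bonus(self):
        table, _, cfg = make_experiment(
            pops_per_env=(3, 3, 3), sd_pop=0.2, sd_test_env=0.1, sd_interaction=0,
            sd_unit=0, sd_res=0, sa_genetic_true=0.7, seed=4)
        spec = ModelSpec.single(analysis_model(cfg).trait_spec)
        res = sa_test_single(table, spec, "common")
        assert res.sa.estimate == pytest.approx(0.7, abs=1e-9)
        assert res.degenerate  # zero interaction-remainder MS: F undefined

    def test_two_environments_raise_inestimable(self):
        table, _, cfg = make_experiment(n_envs=2, pops_per_env=(3, 3), seed=4)
        spec = ModelSpec.single(analysis_model(cfg).trait_spec)
        with pytest.raises(InestimableError):
            sa_test_single(table, spec, "common")

    def test_matches_oracle_f(self, tiny_experiment):
        table, _, cfg = tiny_experiment
        spec = ModelSpec.single(analysis_model(cfg).trait_spec)
        res = sa_test_single(table, spec, "common")
        sub = ObservationTable.from_frame(
            table.df[table.df["phase"] == "common"].reset_index(drop=True))
        design = build_single_design(sub, spec, "common")
        y = table.df.loc[table.df["phase"] == "common", "response"].to_numpy()
        ss, df, _ = sequential_ss_oracle(design.block_list(), y)
        F = (ss["sa"] / df["sa"]) / (ss["interaction"] / df["interaction"])
        assert res.F == pytest.approx(F, rel=1e-8)


class TestCalibration:
    def test_mean_estimate_recovers_injected_effect(self):
        """Across 200 replicates the mean genetic estimate matches the truth."""
        from sacontrast.simulate import estimate_power
        cfg = SimulationConfig(seed=21, family="normal", sa_genetic_true=0.3)
        res = estimate_power([cfg], 200, 0.05)[0]
        sem = res.sd_sa_genetic / math.sqrt(res.n_reps)
        assert abs(res.mean_sa_genetic - 0.3) < 2 * sem + 1e-12

    def test_null_rejection_not_anticonservative(self):
        """Quick null check: both tests reject at most ~alpha."""
        res = estimate_fpr(SimulationConfig(seed=33, family="normal"), 300, 0.05)
        for rate, se in ((res.reject_rate_genetic, res.mc_se_genetic),
                         (res.reject_rate_plastic, res.mc_se_plastic)):
            assert rate <= 0.05 + 2 * max(se, math.sqrt(0.05 * 0.95 / res.n_reps))
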