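import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sacontrast.datamodel import ObservationTable, TraitSpec, Transform, UnitAdjustment
from sacontrast.design import ModelSpec
from sacontrast.descriptives import (
    cross_generation_correlation,
    effect_means,
    original_vs_alternative,
    preference_performance_correlation,
    weighted_pearson,
)
from sacontrast.simulate import SimulationConfig, analysis_model, generate_dataset
from sacontrast.datamodel import transform_response

from conftest import make_experiment


def _identity_spec():
    return ModelSpec.dual(TraitSpec("fecundity", Transform.IDENTITY, UnitAdjustment.NONE))


def _manual_table(values, pops=("p1", "p2", "p3"), envs=("a", "b")):
    """Tiny two-env table with explicit response values per (pop, env, phase)."""
    rows = []
    i = 0
    for pop in pops:
        origin = envs[0] if pop != pops[-1] else envs[1]
        for phase in ("field", "common"):
            for env in envs:
                rows.append({"population": pop, "origin": origin, "test": env,
                             "phase": phase, "unit": f"{pop}-{phase}-{i}", "eggs": 1,
                             "value": values[i]})
                i += 1
    df = pd.DataFrame(rows)
    table = ObservationTable.from_frame(df)
    return transform_response(table, _identity_spec().trait_spec)


class TestWeightedPearson:
    def test_equal_weights_reduce_to_ordinary_pearson(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        ours = weighted_pearson(x, y, np.ones(40)).rho
        assert ours == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_three_point_weighted_example(self):
        # frozen value from the direct weighted-moment formula
        w = weighted_pearson(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]),
                             np.array([1.0, 1, 2]))
        assert w.rho == pytest.approx(0.9864400504156211, abs=1e-12)
        assert w.n_eff == pytest.approx(16 / 6)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.weightstats import DescrStatsW
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = 0.7 * x + rng.normal(size=25)
        w = rng.integers(1, 9, size=25).astype(float)
        ref = DescrStatsW(np.column_stack([x, y]), weights=w).corrcoef[0, 1]
        assert weighted_pearson(x, y, w).rho == pytest.approx(ref, abs=1e-10)

    def test_perfect_line_and_ci_ordering(self):
        x = np.arange(10.0)
        w = np.ones(10)
        res = weighted_pearson(x, 2 * x + 1, w)
        assert res.rho == pytest.approx(1.0)
        res2 = weighted_pearson(x, 2 * x + np.sin(x), w)
        assert res2.ci_low <= res2.rho <= res2.ci_high

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson(np.arange(3.0), np.arange(3.0), np.array([1.0, -1, 1]))

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            weighted_pearson(np.ones(4), np.arange(4.0), np.ones(4))

    @given(a=st.floats(0.1, 5), b=st.floats(-5, 5), c=st.floats(0.1, 7))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariance_under_affine_maps_and_weight_scaling(self, a, b, c):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 0.3 * x + rng.normal(size=20)
        w = rng.uniform(0.5, 3, size=20)
        base = weighted_pearson(x, y, w).rho
        assert weighted_pearson(a * x + b, a * y - b, c * w).rho == pytest.approx(base, abs=1e-9)


class TestEffectMeans:
    def test_no_nuisance_effects_equals_raw_cell_means(self):
        table, spec, _ = make_experiment(pops_per_env=(3, 3, 3), units_per_pop_phase=4,
                                         sd_pop=0, sd_test_env=0, sd_unit=0,
                                         sd_interaction=0, sd_res=0.2, seed=6)
        cells = effect_means(table, spec).cells
        df = table.df
        # residualization is a no-op up to the grand mean: compare to raw means
        for (test, origin), cell in cells.items():
            sub = df[(df["test"] == test) & (df["origin"] == origin)
                     & (df["phase"] == "common")]
            raw = (sub["response"] - df["response"].mean()).mean()
            assert cell.genetic_mean == pytest.approx(raw, abs=0.1)

    def test_projection_oracle_on_tiny_table(self):
        values = list(range(12))
        table = _manual_table(np.array(values, float))
        spec = _identity_spec()
        cells = effect_means(table, spec).cells
        # independent two-step oracle: residualize by explicit lstsq, then average
        df = table.df
        pops = pd.get_dummies(df["population"], dtype=float).to_numpy()
        envs = pd.get_dummies(df["test"], dtype=float).to_numpy()
        X = np.column_stack([np.ones(len(df)), pops[:, :-1], envs[:, :-1]])
        beta, *_ = np.linalg.lstsq(X, df["response"].to_numpy(), rcond=None)
        resid = df["response"].to_numpy() - X @ beta
        for (test, origin), cell in cells.items():
            mask = (df["test"] == test) & (df["origin"] == origin)
            common = resid[(mask & (df["phase"] == "common")).to_numpy()]
            fieldr = resid[(mask & (df["phase"] == "field")).to_numpy()]
            assert cell.genetic_mean == pytest.approx(common.mean(), abs=1e-9)
            assert cell.plastic_mean == pytest.approx(fieldr.mean() - common.mean(), abs=1e-9)

    def test_identical_phases_have_zero_plastic_means(self):
        table, spec, _ = make_experiment(pops_per_env=(2, 2, 2), units_per_pop_phase=2, seed=6)
        df = table.df.copy()
        common = df[df["phase"] == "common"].copy()
        mirrored = common.copy()
        mirrored["phase"] = "field"
        mirrored["unit"] = mirrored["unit"] + "-f"
        both = ObservationTable.from_frame(pd.concat([mirrored, common], ignore_index=True))
        both.df["response"] = np.r_[common["response"].to_numpy(), common["response"].to_numpy()]
        cells = effect_means(both, spec).cells
        for cell in cells.values():
            assert cell.plastic_mean == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance(self):
        table, spec, _ = make_experiment(pops_per_env=(2, 2, 2), units_per_pop_phase=2, seed=6)
        shifted = ObservationTable.from_frame(table.df)
        shifted.df["response"] = table.df["response"] + 100.0
        a = effect_means(table, spec).to_frame()
        b = effect_means(shifted, spec).to_frame()
        assert np.allclose(a["genetic_mean"], b["genetic_mean"], atol=1e-8)
        assert np.allclose(a["plastic_mean"], b["plastic_mean"], atol=1e-8)


class TestOriginalVsAlternative:
    def test_hand_computed_means(self):
        values = np.array([2.0, 1.0, 2.0, 1.5] * 3)  # field a,b then common a,b per pop
        table = _manual_table(values, pops=("p1", "p2", "p3"))
        out = original_vs_alternative(table, "common")
        p1 = out[out["population"] == "p1"]
        assert p1["mean_original"].item() == pytest.approx(2.0)
        assert p1["mean_alternative"].item() == pytest.approx(1.5)

    def test_identical_values_sit_on_identity_line(self):
        table = _manual_table(np.full(12, 3.0))
        out = original_vs_alternative(table, "field")
        assert np.allclose(out["mean_original"], out["mean_alternative"])

    def test_injected_bonus_pushes_points_below_identity(self):
        table, _, _ = make_experiment(seed=19, sa_genetic_true=0.6)
        out = original_vs_alternative(table, "common")
        below = (out["mean_alternative"] < out["mean_original"]).mean()
        assert below > 0.5


class TestCrossGenerationCorrelation:
    def test_identical_phases_give_rho_one(self):
        table, spec, _ = make_experiment(pops_per_env=(4, 4, 4), units_per_pop_phase=2, seed=6)
        df = table.df
        common = df[df["phase"] == "common"].copy()
        mirrored = common.copy()
        mirrored["phase"] = "field"
        mirrored["unit"] = mirrored["unit"] + "-f"
        both = ObservationTable.from_frame(pd.concat([mirrored, common], ignore_index=True))
        both.df["response"] = np.r_[common["response"].to_numpy(), common["response"].to_numpy()]
        for cor in cross_generation_correlation(both, spec).values():
            assert cor.rho == pytest.approx(1.0)

    def test_shared_quality_signal_gives_positive_rho(self):
        table, spec, _ = make_experiment(sd_pop=1.0, sd_res=0.2, sd_unit=0.1, seed=23)
        for cor in cross_generation_correlation(table, spec).values():
            assert cor.rho > 0.5

    def test_independent_phases_ci_covers_zero(self):
        """With no shared signal, the 95% CI contains 0 in >= 90% of runs."""
        cover = 0
        reps = 120
        for r in range(reps):
            cfg = SimulationConfig(pops_per_env=(12, 12, 12), units_per_pop_phase=2,
                                   sd_pop=0.0, sd_test_env=0.0, sd_interaction=0.0,
                                   sd_unit=0.0, sd_res=1.0, seed=50_000 + r)
            spec = analysis_model(cfg)
            table = transform_response(generate_dataset(cfg), spec.trait_spec)
            cors = cross_generation_correlation(table, spec)
            cor = cors["cherry"]
            if cor.ci_low is not None and cor.ci_low <= 0.0 <= cor.ci_high:
                cover += 1
        assert cover / reps >= 0.90


class TestPreferencePerformanceCorrelation:
    def _pair(self, seed, shared_bonus):
        pref_cfg = SimulationConfig(seed=seed, family="normal",
                                    sa_genetic_true=shared_bonus)
        perf_cfg = SimulationConfig(seed=seed + 1, family="normal",
                                    sa_genetic_true=shared_bonus)
        pref_spec, perf_spec = analysis_model(pref_cfg), analysis_model(perf_cfg)
        pref = transform_response(generate_dataset(pref_cfg), pref_spec.trait_spec)
        perf = transform_response(generate_dataset(perf_cfg), perf_spec.trait_spec)
        return pref, perf, pref_spec, perf_spec

    def test_affine_function_of_cell_means_gives_rho_one(self):
        pref, _, pref_spec, perf_spec = self._pair(31, 0.0)
        perf = ObservationTable.from_frame(pref.df)
        perf.df["response"] = 2.0 * pref.df["response"] + 1.0
        cor = preference_performance_correlation(pref, perf, pref_spec, perf_spec, "common")
        assert cor.rho == pytest.approx(1.0, abs=1e-9)

    def test_shared_sympatric_bonus_gives_positive_rho(self):
        pref, perf, pref_spec, perf_spec = self._pair(37, 0.8)
        cor = preference_performance_correlation(pref, perf, pref_spec, perf_spec, "common")
        assert cor.rho > 0.0

    def test_disjoint_population_warns(self):
        pref, perf, pref_spec, perf_spec = self._pair(41, 0.0)
        drop = perf.df["population"].iloc[0]
        perf2 = ObservationTable.from_frame(perf.df[perf.df["population"] != drop])
        with pytest.warns(UserWarning, match="one table only"):
            preference_performance_correlation(pref, perf2, pref_spec, perf_spec, "common")
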