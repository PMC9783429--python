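"""Residualized genetic/plastic effect means and weighted correlations.

These are the descriptive companions to the SA tests: per-cell genetic and
plastic effect means after removing nuisance variation, per-population
original-vs-alternative trait means, and weighted Pearson correlations
(between phases, and between preference and performance) with Fisher-z
confidence intervals using an effective sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ObservationTable, Phase, UnitAdjustment
from .design import ModelSpec, _Builder, _egg_density, _factor, _sum_contrasts, _unit_block

__all__ = [
    "EffectCell",
    "EffectCellTable",
    "WeightedCorrelation",
    "effect_means",
    "original_vs_alternative",
    "weighted_pearson",
    "cross_generation_correlation",
    "preference_performance_correlation",
]


@dataclass
class EffectCell:
    genetic_mean: float
    genetic_ci: tuple[float, float] | None
    plastic_mean: float
    plastic_ci: tuple[float, float] | None
    n_common: int
    n_field: int


@dataclass
class EffectCellTable:
    """(test_env, origin_env) -> genetic and plastic effect means."""

    cells: dict[tuple[str, str], EffectCell]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (test, origin), c in sorted(self.cells.items()):
            rows.append({
                "test": test, "origin": origin,
                "genetic_mean": c.genetic_mean,
                "genetic_ci_low": c.genetic_ci[0] if c.genetic_ci else np.nan,
                "genetic_ci_high": c.genetic_ci[1] if c.genetic_ci else np.nan,
                "plastic_mean": c.plastic_mean,
                "plastic_ci_low": c.plastic_ci[0] if c.plastic_ci else np.nan,
                "plastic_ci_high": c.plastic_ci[1] if c.plastic_ci else np.nan,
                "n_common": c.n_common, "n_field": c.n_field,
            })
        return pd.DataFrame(rows)


@dataclass
class WeightedCorrelation:
    rho: float
    ci_low: float | None
    ci_high: float | None
    n_eff: float
    weights_used: str

    def to_dict(self) -> dict:
        return {"rho": self.rho, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_eff": self.n_eff, "weights_used": self.weights_used}


# -- nuisance residualization -----------------------------------------------


def _nuisance_residuals(table: ObservationTable, spec: ModelSpec) -> np.ndarray:
    """Residuals of the nuisance-only model (no SA, no interaction terms).

    Fits intercept + population + test environment + the trait's unit
    adjustment (arena contrasts or log egg density) by least squares and
    returns the residuals, which carry the genetic/plastic and interaction
    structure plus noise.
    """
    df = table.df
    if "response" not in df.columns:
        raise ValueError("table has no 'response' column; run transform_response first")
    n = len(df)
    b = _Builder(n)
    b.add("intercept", np.ones((n, 1)), ["intercept"])
    pop_codes, pop_levels = _factor(df["population"])
    env_codes, env_levels = _factor(df["test"])
    b.add("population", _sum_contrasts(pop_codes, len(pop_levels)),
          [f"population[{p}]" for p in pop_levels[:-1]])
    b.add("test_env", _sum_contrasts(env_codes, len(env_levels)),
          [f"test[{e}]" for e in env_levels[:-1]])
    adj = spec.trait_spec.unit_adjustment
    if adj is UnitAdjustment.ARENA_BLOCK:
        X, labels, _ = _unit_block(df)
        b.add("unit_block", X, labels)
    elif adj is UnitAdjustment.LOG_EGG_DENSITY:
        b.add("egg_density", _egg_density(df, spec.trait_spec.log_offset), ["log_egg_density"])
    y = df["response"].to_numpy(float)
    return y - b.basis @ (b.basis.T @ y)


def effect_means(table: ObservationTable, spec: ModelSpec) -> EffectCellTable:
    """Per-cell genetic and plastic effect means after nuisance removal.

    The genetic mean of a (test environment, origin environment) cell is
    the mean common-phase residual; the plastic mean is the mean field
    residual minus the mean common residual.  Genetic CIs use the
    common-phase residual spread.  The plastic CI treats the excess of the
    field-phase variance over the common-phase variance as the variance
    attributable to plasticity; when the common-phase variance is larger
    the CI cannot be constructed and is reported as absent.
    """
    if {Phase(p) for p in table.df["phase"].unique()} != {Phase.FIELD, Phase.COMMON}:
        raise ValueError("effect means require records from both phases")
    resid = _nuisance_residuals(table, spec)
    df = table.df.assign(_resid=resid)
    cells: dict[tuple[str, str], EffectCell] = {}
    for (test, origin), sub in df.groupby(["test", "origin"]):
        common = sub.loc[sub["phase"] == Phase.COMMON.value, "_resid"].to_numpy()
        fieldr = sub.loc[sub["phase"] == Phase.FIELD.value, "_resid"].to_numpy()
        if common.size == 0 or fieldr.size == 0:
            warnings.warn(f"cell (test={test}, origin={origin}) lacks one phase; skipped",
                          stacklevel=2)
            continue
        g_mean = float(common.mean())
        g_ci = None
        if common.size > 1:
            half = 1.96 * common.std(ddof=1) / math.sqrt(common.size)
            g_ci = (g_mean - half, g_mean + half)
        p_mean = float(fieldr.mean() - common.mean())
        p_ci = None
        if common.size > 1 and fieldr.size > 1:
            excess = fieldr.var(ddof=1) - common.var(ddof=1)
            if excess > 0:
                half = 1.96 * math.sqrt(excess / fieldr.size)
                p_ci = (p_mean - half, p_mean + half)
        cells[(test, origin)] = EffectCell(g_mean, g_ci, p_mean, p_ci,
                                           int(common.size), int(fieldr.size))
    return EffectCellTable(cells)


# -- original vs alternative ------------------------------------------------


def original_vs_alternative(table: ObservationTable, phase: Phase | str) -> pd.DataFrame:
    """Per-population trait means on the original vs each alternative medium.

    One row per population x alternative environment: the mean transformed
    trait on the sympatric (original) environment, the mean on that
    allopatric environment, standard errors of both means, and the record
    counts.  In a three-environment system each population contributes two
    rows sharing one original-fruit mean.  Points below the identity line
    (alternative < original) are the visual signature of local adaptation.
    """
    phase = Phase(phase)
    df = table.df[table.df["phase"] == phase.value]
    if df.empty:
        raise ValueError(f"phase {phase.value!r} not present in table")
    if "response" not in df.columns:
        raise ValueError("table has no 'response' column; run transform_response first")
    rows = []
    for pop, sub in df.groupby("population"):
        origin = sub["origin"].iloc[0]
        home = sub[sub["test"] == origin]["response"]
        if home.empty:
            warnings.warn(f"population {pop!r} lacks sympatric assays; excluded",
                          stacklevel=2)
            continue
        m0 = float(home.mean())
        se0 = float(home.std(ddof=1) / math.sqrt(len(home))) if len(home) > 1 else float("nan")
        for env, away in sub[sub["test"] != origin].groupby("test"):
            vals = away["response"]
            rows.append({
                "population": pop, "origin": origin, "alternative": env,
                "mean_original": m0, "se_original": se0,
                "mean_alternative": float(vals.mean()),
                "se_alternative": float(vals.std(ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1 else float("nan"),
                "n_vials": int(len(sub)),
            })
    return pd.DataFrame(rows)


# -- weighted correlation ---------------------------------------------------


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                     weights_used: str = "user") -> WeightedCorrelation:
    """Weighted Pearson correlation with a Fisher-z confidence interval.

    rho is the weighted covariance over the product of weighted standard
    deviations (weighted means throughout).  The 95% CI uses the Fisher z
    transform with effective sample size n_eff = (sum w)^2 / sum(w^2); with
    n_eff <= 3 the interval cannot be formed and is reported absent.  With
    equal weights this reduces exactly to the ordinary Pearson coefficient.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (x.size == y.size == w.size):
        raise ValueError("x, y and w must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    W = w.sum()
    if W <= 0:
        raise ValueError("weights sum to zero")
    mx = (w * x).sum() / W
    my = (w * y).sum() / W
    cov = (w * (x - mx) * (y - my)).sum() / W
    vx = (w * (x - mx) ** 2).sum() / W
    vy = (w * (y - my) ** 2).sum() / W
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance; correlation undefined")
    rho = float(cov / math.sqrt(vx * vy))
    rho = min(1.0, max(-1.0, rho))
    n_eff = float(W * W / (w * w).sum())
    lo = hi = None
    if n_eff > 3 and abs(rho) < 1:
        z = math.atanh(rho)
        se = 1.0 / math.sqrt(n_eff - 3)
        lo = math.tanh(z - 1.96 * se)
        hi = math.tanh(z + 1.96 * se)
    return WeightedCorrelation(rho, lo, hi, n_eff, weights_used)


def cross_generation_correlation(table: ObservationTable, spec: ModelSpec
                                 ) -> dict[str, WeightedCorrelation]:
    """Correlation of per-population means between phases, per test env.

    For each test environment, the field-phase and common-phase mean
    responses per population are correlated with the population's total
    record count in that environment as weight.  A high correlation means
    population quality persists through common-environment rearing.
    """
    df = table.df
    if {Phase(p) for p in df["phase"].unique()} != {Phase.FIELD, Phase.COMMON}:
        raise ValueError("cross-generation correlation requires both phases")
    if "response" not in df.columns:
        raise ValueError("table has no 'response' column; run transform_response first")
    out: dict[str, WeightedCorrelation] = {}
    for env, sub in df.groupby("test"):
        piv = sub.pivot_table(index="population", columns="phase",
                              values="response", aggfunc="mean")
        counts = sub.groupby("population").size()
        piv = piv.dropna()
        if len(piv) < 3 or Phase.FIELD.value not in piv or Phase.COMMON.value not in piv:
            continue
        w = counts.reindex(piv.index).to_numpy(float)
        out[env] = weighted_pearson(
            piv[Phase.FIELD.value].to_numpy(), piv[Phase.COMMON.value].to_numpy(),
            w, weights_used="records per population")
    return out


def preference_performance_correlation(pref: ObservationTable, perf: ObservationTable,
                                       pref_spec: ModelSpec, perf_spec: ModelSpec,
                                       phase: Phase | str) -> WeightedCorrelation:
    """Weighted correlation between residualized preference and performance.

    Both tables are residualized against their nuisance models (population,
    test environment, unit adjustment), averaged per (population, test
    environment) within the chosen phase, joined on the shared pairs, and
    correlated with the combined record count as weight.  Populations
    present in only one table are dropped with a warning.
    """
    phase = Phase(phase)

    def _cell_means(table: ObservationTable, spec: ModelSpec) -> pd.DataFrame:
        resid = _nuisance_residuals(table, spec)
        df = table.df.assign(_resid=resid)
        df = df[df["phase"] == phase.value]
        g = df.groupby(["population", "test"])
        return pd.DataFrame({"mean": g["_resid"].mean(), "n": g.size()})

    a = _cell_means(pref, pref_spec)
    b = _cell_means(perf, perf_spec)
    only = set(a.index.get_level_values(0)).symmetric_difference(
        b.index.get_level_values(0))
    if only:
        warnings.warn(f"population(s) present in one table only, dropped: {sorted(only)}",
                      stacklevel=2)
    joined = a.join(b, how="inner", lsuffix="_pref", rsuffix="_perf").dropna()
    return weighted_pearson(
        joined["mean_pref"].to_numpy(), joined["mean_perf"].to_numpy(),
        (joined["n_pref"] + joined["n_perf"]).to_numpy(float),
        weights_used="combined records per population x environment")
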