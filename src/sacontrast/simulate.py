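"""Synthetic reciprocal common-environment experiments and calibration studies.

The generator emulates the study layout: J host environments (default
three, labeled cherry / strawberry / blackberry), populations sampled from
each origin (default 9/3/13, the study's unbalanced sampling; a balanced
variant uses equal counts), two assay phases (field-derived and
common-environment flies), a fixed number of rearing units per population
and phase, and one observation per unit in each test environment.

On the link scale (identity, log or logit) each observation is

    eta = mu + pop_i + env_j + gxe_jk + I_field * (d_pop_i + d_env_j + d_gxe_jk)
          + sa_genetic * S_jk + I_field * sa_plastic * S_jk + unit + eps

where ``S_jk`` is the sympatric indicator.  All random effects are
zero-mean normal draws with the configured SDs.  The genotype x
environment matrices (shared ``gxe`` and field-specific ``d_gxe``) are
double-centered *and have their sympatric-contrast component removed*, so
the injected ``sa_genetic_true`` / ``sa_plastic_true`` are the only
sympatric signals in the data: with both set to zero the data are a true
null for the SA tests, while still carrying non-sympatric genotype x
environment structure in the F-test denominators.

The link value maps to data as the response itself (normal family), a
Poisson egg count with log link (count traits), or a binomial number of
emerging adults out of a fixed egg count with logit link (survival).
Every dataset is a pure function of its config, including the seed.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ObservationTable,
    Phase,
    Trait,
    TraitSpec,
    Transform,
    UnitAdjustment,
)
from .design import ModelSpec
from .inference import compile_dual_model

__all__ = [
    "Family",
    "SimulationConfig",
    "PowerResult",
    "generate_dataset",
    "analysis_model",
    "scale_design",
    "estimate_fpr",
    "estimate_power",
    "power_report",
]

_DEFAULT_ENVS = ("cherry", "strawberry", "blackberry")


class Family(str, enum.Enum):
    NORMAL = "normal"
    POISSON = "poisson"
    BINOMIAL = "binomial"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of a synthetic experiment.

    Defaults mirror the study: 3 environments, 9/3/13 populations per
    origin, 8 rearing units per population and phase, one observation per
    unit and test environment (25 x 2 x 24 = 1200 records), and link-scale
    variance components with population quality the dominant source
    (sd_pop > sd_test_env > sd_interaction).  ``mu = 3.0`` on the log scale
    corresponds to roughly 20 eggs per assay.  ``design_multiplier``
    scales the number of units (the X1/X2/X10/X100 design series).
    """

    n_envs: int = 3
    pops_per_env: tuple[int, ...] = (9, 3, 13)
    units_per_pop_phase: int = 8
    obs_per_unit_env: int = 1
    family: Family = Family.NORMAL
    mu: float = 3.0
    sd_pop: float = 0.5
    sd_test_env: float = 0.3
    sd_interaction: float = 0.1
    sd_unit: float = 0.3
    sd_res: float = 0.5
    sa_genetic_true: float = 0.0
    sa_plastic_true: float = 0.0
    trials_binomial: int = 30
    design_multiplier: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "pops_per_env", tuple(int(p) for p in self.pops_per_env))
        if len(self.pops_per_env) != self.n_envs:
            raise ConfigError("pops_per_env must have one entry per environment")
        for name in ("sd_pop", "sd_test_env", "sd_interaction", "sd_unit", "sd_res"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.design_multiplier < 1:
            raise ConfigError("design_multiplier must be >= 1")
        if self.family is Family.BINOMIAL and self.trials_binomial < 1:
            raise ConfigError("binomial family requires trials_binomial >= 1")

    @classmethod
    def balanced_study(cls, **kw) -> "SimulationConfig":
        """Study-like layout with equal populations per origin."""
        kw.setdefault("pops_per_env", (9, 9, 9))
        return cls(**kw)

    # -- structured text round-trip ----------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["family"] = self.family.value
        d["pops_per_env"] = list(self.pops_per_env)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["pops_per_env"] = tuple(d["pops_per_env"])
        return cls(**d)

    def summary(self) -> dict:
        d = asdict(self)
        d["family"] = self.family.value
        d["pops_per_env"] = list(self.pops_per_env)
        return d


def scale_design(config: SimulationConfig, factor: int) -> SimulationConfig:
    """Scale the design by replicating rearing units (X2, X10, X100 ...)."""
    if factor < 1:
        raise ValueError("scale factor must be >= 1")
    return replace(config,
                   units_per_pop_phase=config.units_per_pop_phase * factor,
                   design_multiplier=config.design_multiplier * factor)


def analysis_model(config: SimulationConfig) -> ModelSpec:
    """The dual-generation model a synthetic dataset is analysed with.

    Normal responses are already on the analysis scale (identity transform,
    arena-style unit block); Poisson egg counts are analysed as a choice
    trait (log counts, unit block); binomial survival as performance
    (arcsine-sqrt, log-egg-density covariate).
    """
    if config.family is Family.NORMAL:
        ts = TraitSpec(Trait.PREFERENCE, Transform.IDENTITY, UnitAdjustment.ARENA_BLOCK)
    elif config.family is Family.POISSON:
        ts = TraitSpec.for_trait(Trait.PREFERENCE)
    else:
        ts = TraitSpec.for_trait(Trait.PERFORMANCE)
    return ModelSpec.dual(ts)


# -- layout and draws -------------------------------------------------------


@dataclass
class _Layout:
    """Record-level index arrays for a config (row order is canonical)."""

    env_labels: list[str]
    pop_labels: list[str]
    pop_origin_code: np.ndarray  # per population
    pop_idx: np.ndarray  # per record
    env_idx: np.ndarray
    origin_idx: np.ndarray
    field: np.ndarray  # 1.0 for FIELD rows
    unit_idx: np.ndarray  # global unit code per record
    unit_labels: list[str]
    n: int


def _layout(config: SimulationConfig) -> _Layout:
    J = config.n_envs
    if J == 3:
        envs = list(_DEFAULT_ENVS)
    else:
        envs = [f"env{j + 1}" for j in range(J)]
    pop_labels, pop_origin = [], []
    for k, n_k in enumerate(config.pops_per_env):
        for i in range(n_k):
            pop_labels.append(f"{envs[k]}-p{i + 1}")
            pop_origin.append(k)
    n_pop = len(pop_labels)
    units = config.units_per_pop_phase
    reps = config.obs_per_unit_env
    rows_pop, rows_env, rows_origin, rows_field, rows_unit = [], [], [], [], []
    unit_labels: list[str] = []
    for p in range(n_pop):
        for phase_code, phase in enumerate((Phase.FIELD, Phase.COMMON)):
            for u in range(units):
                unit_id = f"{pop_labels[p]}-{phase.value[0]}{u + 1}"
                unit_code = len(unit_labels)
                unit_labels.append(unit_id)
                for j in range(J):
                    for _ in range(reps):
                        rows_pop.append(p)
                        rows_env.append(j)
                        rows_origin.append(pop_origin[p])
                        rows_field.append(1.0 if phase is Phase.FIELD else 0.0)
                        rows_unit.append(unit_code)
    return _Layout(
        env_labels=envs,
        pop_labels=pop_labels,
        pop_origin_code=np.array(pop_origin),
        pop_idx=np.array(rows_pop),
        env_idx=np.array(rows_env),
        origin_idx=np.array(rows_origin),
        field=np.array(rows_field),
        unit_idx=np.array(rows_unit),
        unit_labels=unit_labels,
        n=len(rows_pop),
    )


def _centered(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    x = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    return x - x.mean() if n else x


def _sa_centered_indicator(J: int, col_weights: np.ndarray) -> np.ndarray:
    """Sympatric indicator residualized against main effects, cell-weighted.

    The metric weights each (test j, origin k) cell by its record count,
    which is proportional to the number of populations from origin k; this
    is the metric in which the fitted model residualizes its SA contrast.
    """
    w = np.broadcast_to(np.asarray(col_weights, float)[None, :], (J, J)).ravel()
    s = np.eye(J).ravel()
    cells = np.arange(J * J)
    D = np.column_stack([np.ones(J * J),
                         *(1.0 * (cells // J == j) for j in range(J)),
                         *(1.0 * (cells % J == k) for k in range(J))])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(D * sw[:, None], s * sw, rcond=None)
    return (s - D @ beta).reshape(J, J)


def _sa_free_interaction(rng: np.random.Generator, J: int, sd: float,
                         col_weights: np.ndarray) -> np.ndarray:
    """Double-centered J x J interaction matrix with zero sympatric contrast.

    The sympatric component is removed in the record-count-weighted cell
    metric -- the metric the fitted model itself uses -- so the injected SA
    parameters are the only sympatric signal the model can see and a
    zero-SA configuration is an exact null for the SA coefficients.
    """
    G = rng.normal(0.0, sd, (J, J)) if sd > 0 else np.zeros((J, J))
    G = G - G.mean(axis=0, keepdims=True) - G.mean(axis=1, keepdims=True) + G.mean()
    S = _sa_centered_indicator(J, col_weights)
    w = np.broadcast_to(np.asarray(col_weights, float)[None, :], (J, J))
    denom = float((w * S * S).sum())
    if denom > 0:
        G = G - ((w * G * S).sum() / denom) * S
    return G


def _draw_response(config: SimulationConfig, lay: _Layout, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Link-scale draws mapped through the family; returns (value, eggs, adults)."""
    J = config.n_envs
    n_pop = len(lay.pop_labels)
    weights = np.asarray(config.pops_per_env, float)
    pop_eff = _centered(rng, n_pop, config.sd_pop)
    env_eff = _centered(rng, J, config.sd_test_env)
    gxe = _sa_free_interaction(rng, J, config.sd_interaction, weights)
    d_pop = _centered(rng, n_pop, config.sd_pop)
    d_env = _centered(rng, J, config.sd_test_env)
    d_gxe = _sa_free_interaction(rng, J, config.sd_interaction, weights)
    unit_eff = rng.normal(0.0, config.sd_unit, len(lay.unit_labels)) \
        if config.sd_unit > 0 else np.zeros(len(lay.unit_labels))
    eps = rng.normal(0.0, config.sd_res, lay.n) if config.sd_res > 0 else np.zeros(lay.n)

    s = (lay.env_idx == lay.origin_idx).astype(float)
    eta = (config.mu
           + pop_eff[lay.pop_idx]
           + env_eff[lay.env_idx]
           + gxe[lay.env_idx, lay.origin_idx]
           + config.sa_genetic_true * s
           + lay.field * (d_pop[lay.pop_idx]
                          + d_env[lay.env_idx]
                          + d_gxe[lay.env_idx, lay.origin_idx]
                          + config.sa_plastic_true * s)
           + unit_eff[lay.unit_idx]
           + eps)

    if config.family is Family.NORMAL:
        return eta, None, None
    if config.family is Family.POISSON:
        eggs = rng.poisson(np.exp(eta))
        return eta, eggs, None
    p = 1.0 / (1.0 + np.exp(-eta))
    eggs = np.full(lay.n, config.trials_binomial)
    adults = rng.binomial(eggs, p)
    return eta, eggs, adults


def generate_dataset(config: SimulationConfig) -> ObservationTable:
    """Draw one synthetic experiment; deterministic given the config.

    Normal responses are stored in the ``value`` column (analysed with the
    identity transform); Poisson draws fill ``eggs``; binomial draws fill
    ``eggs`` (the fixed trial count) and ``adults``.
    """
    lay = _layout(config)
    rng = np.random.default_rng(config.seed)
    eta, eggs, adults = _draw_response(config, lay, rng)
    phase = np.where(lay.field > 0, Phase.FIELD.value, Phase.COMMON.value)
    df = pd.DataFrame({
        "population": np.array(lay.pop_labels)[lay.pop_idx],
        "origin": np.array(lay.env_labels)[lay.origin_idx],
        "test": np.array(lay.env_labels)[lay.env_idx],
        "phase": phase,
        "unit": np.array(lay.unit_labels)[lay.unit_idx],
        "eggs": eggs if eggs is not None else np.zeros(lay.n, dtype=int),
    })
    if adults is not None:
        df["adults"] = adults
    if config.family is Family.NORMAL:
        df["value"] = eta
    table = ObservationTable.from_frame(df, normalize=False)
    table.meta["config"] = config.summary()
    return table


def _response_only(config: SimulationConfig, lay: _Layout, seed: int) -> np.ndarray:
    """Transformed analysis response for one replicate, without a DataFrame.

    Follows exactly the draw order of :func:`generate_dataset` plus the
    transform of the analysis model, so `transform(generate(seed))` and
    this function agree bitwise (asserted in the tests).
    """
    rng = np.random.default_rng(seed)
    eta, eggs, adults = _draw_response(config, lay, rng)
    if config.family is Family.NORMAL:
        return eta
    if config.family is Family.POISSON:
        return np.log(eggs + 1.0)
    p = np.minimum(adults / eggs, 1.0)
    return np.arcsin(np.sqrt(p))


# -- calibration and power studies ------------------------------------------


@dataclass
class PowerResult:
    """Rejection-rate summary for one simulated condition."""

    condition: dict
    alpha: float
    n_reps: int
    n_excluded: int
    reject_rate_genetic: float
    reject_rate_plastic: float
    mc_se_genetic: float
    mc_se_plastic: float
    mean_sa_genetic: float
    sd_sa_genetic: float
    mean_sa_plastic: float
    sd_sa_plastic: float

    def to_dict(self) -> dict:
        return asdict(self)


def _substream_seed(master_seed: int, index: int) -> int:
    """Independent, reproducible per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _mc_se(rate: float, n: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / n)) if n else float("nan")


def _run_condition(config: SimulationConfig, n_reps: int, alpha: float) -> PowerResult:
    """Generate -> transform -> dual SA test, n_reps times.

    The design depends only on the layout, so the model is compiled once
    per condition and each replicate supplies only a fresh response vector;
    the compiled path reproduces :func:`sa_test_dual` exactly.
    """
    lay = _layout(config)
    template = generate_dataset(replace(config, seed=_substream_seed(config.seed, 0)))
    spec = analysis_model(config)
    from .datamodel import transform_response  # local import to avoid cycle confusion
    compiled = compile_dual_model(transform_response(template, spec.trait_spec), spec)

    rej_g = rej_p = 0
    excluded = 0
    est_g, est_p = [], []
    for r in range(n_reps):
        y = _response_only(config, lay, _substream_seed(config.seed, r))
        st = compiled.stats(y)
        if not st["ok"]:
            excluded += 1
            continue
        rej_g += st["p_genetic"] < alpha
        rej_p += st["p_plastic"] < alpha
        est_g.append(st["sa_genetic"])
        est_p.append(st["sa_plastic"])
    used = n_reps - excluded
    rate_g = rej_g / used if used else float("nan")
    rate_p = rej_p / used if used else float("nan")
    return PowerResult(
        condition=config.summary(), alpha=alpha, n_reps=used, n_excluded=excluded,
        reject_rate_genetic=rate_g, reject_rate_plastic=rate_p,
        mc_se_genetic=_mc_se(rate_g, used), mc_se_plastic=_mc_se(rate_p, used),
        mean_sa_genetic=float(np.mean(est_g)) if est_g else float("nan"),
        sd_sa_genetic=float(np.std(est_g, ddof=1)) if len(est_g) > 1 else float("nan"),
        mean_sa_plastic=float(np.mean(est_p)) if est_p else float("nan"),
        sd_sa_plastic=float(np.std(est_p, ddof=1)) if len(est_p) > 1 else float("nan"),
    )


def estimate_fpr(null_config: SimulationConfig, n_reps: int, alpha: float = 0.05
                 ) -> PowerResult:
    """Empirical false-positive rates of the genetic and plastic F tests.

    Requires a true null config (both injected SA effects zero).  Each
    replicate uses an independent substream of the config's seed.
    """
    if null_config.sa_genetic_true != 0.0 or null_config.sa_plastic_true != 0.0:
        raise ConfigError("false-positive-rate study requires both SA effects = 0")
    return _run_condition(null_config, n_reps, alpha)


def estimate_power(config_grid: list[SimulationConfig], n_reps: int,
                   alpha: float = 0.05) -> list[PowerResult]:
    """Rejection rates across a grid of effect sizes and/or design scales."""
    return [_run_condition(cfg, n_reps, alpha) for cfg in config_grid]


def power_report(results: list[PowerResult]) -> pd.DataFrame:
    """One row per condition with the key knobs and both rejection rates."""
    rows = []
    for r in results:
        c = r.condition
        rows.append({
            "family": c["family"],
            "pops_per_env": "/".join(str(p) for p in c["pops_per_env"]),
            "design_multiplier": c["design_multiplier"],
            "sa_genetic_true": c["sa_genetic_true"],
            "sa_plastic_true": c["sa_plastic_true"],
            "n_reps": r.n_reps,
            "n_excluded": r.n_excluded,
            "power_genetic": r.reject_rate_genetic,
            "power_plastic": r.reject_rate_plastic,
            "mc_se_genetic": r.mc_se_genetic,
            "mc_se_plastic": r.mc_se_plastic,
            "mean_sa_genetic": r.mean_sa_genetic,
            "mean_sa_plastic": r.mean_sa_plastic,
        })
    return pd.DataFrame(rows)
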