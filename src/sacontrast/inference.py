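"""Sequential ANOVA, SA effect estimates, F tests and variance fractions.

The SA (sympatric-allopatric) tests ask whether populations do better in
the environment they came from than in alternative environments, after
removing population quality, test-environment quality and nuisance unit
variation.  Each SA term is a single contrast carved out of the test x
origin interaction space; its F statistic compares the SA mean square to
the mean square of the interaction directions that remain:

    F = MS(SA) / MS(interaction remainder),   df = (1, (J-1)(K-1) - 1)

for J test and K origin environments.  The denominator is the interaction
remainder, not the model residual: variation due to habitat and population
quality is excluded by construction, and genuine but non-sympatric
genotype x environment structure sits in the denominator, which makes the
test conservative rather than anticonservative when such structure exists.

The fraction of the interaction mean square removed by estimating the SA
term is

    phi = (MS_constrained - MS_free) / MS_constrained

where the constrained mean square comes from a fit with the SA column
omitted (interaction block carrying the full (J-1)(K-1) df) and the free
mean square is the interaction-remainder MS.  phi may be negative because
the two mean squares use different degrees of freedom.

Sums of squares are sequential (Type I) in the model's term order: each
block's SS is the drop in residual SS when the block enters after all the
blocks before it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ObservationTable, Phase, transform_response
from .design import (
    DesignMatrix,
    ModelSpec,
    Term,
    _orthonormalize,
    _residualize,
    build_dual_design,
    build_single_design,
)

__all__ = [
    "AnovaTable",
    "SAEstimate",
    "SATestResult",
    "DualSAResult",
    "fit_sequential_anova",
    "sa_test_single",
    "sa_test_dual",
    "phi",
    "CompiledDualModel",
    "compile_dual_model",
]

#: a denominator MS below this fraction of the total MS is treated as zero
#: (noise-free data); the F statistic is then reported as undefined
_DEGENERATE_REL = 1e-12


class InestimableError(ValueError):
    """The requested test has no denominator degrees of freedom."""


@dataclass
class AnovaTable:
    """Sequential (Type I) ANOVA table."""

    rows: list[tuple[str, int, float, float]]  # (term, df, SS, MS)
    residual: tuple[int, float, float]  # (df, SS, MS)
    total_ss: float  # intercept-corrected
    n: int

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"term": t, "df": df, "sum_sq": ss, "mean_sq": ms}
            for t, df, ss, ms in self.rows
        ]
        df_r, ss_r, ms_r = self.residual
        recs.append({"term": "residual", "df": df_r, "sum_sq": ss_r, "mean_sq": ms_r})
        return pd.DataFrame(recs)

    def term(self, name: str) -> tuple[int, float, float]:
        for t, df, ss, ms in self.rows:
            if t == name:
                return df, ss, ms
        raise KeyError(name)

    @property
    def residual_ms(self) -> float:
        return self.residual[2]


@dataclass
class SAEstimate:
    """Sympatric-minus-allopatric contrast on the trait scale."""

    estimate: float
    se: float


@dataclass
class SATestResult:
    sa: SAEstimate
    F: float
    df_num: int
    df_den: int
    p: float
    phi: float | None
    degenerate: bool = False  # noise-free denominator; F/p undefined

    def to_dict(self) -> dict:
        def _num(x):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            return float(x)

        return {
            "estimate": _num(self.sa.estimate),
            "se": _num(self.sa.se),
            "F": _num(self.F),
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": _num(self.p),
            "phi": _num(self.phi),
            "degenerate": self.degenerate,
        }


@dataclass
class DualSAResult:
    """Joint result of the genetic and plastic SA tests."""

    genetic: SATestResult
    plastic: SATestResult
    anova: AnovaTable
    fit_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genetic": self.genetic.to_dict(),
            "plastic": self.plastic.to_dict(),
            "anova": self.anova.to_frame().to_dict(orient="records"),
            "fit_meta": self.fit_meta,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# -- core sequential fit ----------------------------------------------------


@dataclass
class _SeqFit:
    names: list[str]
    dfs: list[int]
    sss: list[float]
    basis: np.ndarray  # accumulated orthonormal basis (all blocks)
    slices: dict[str, slice]
    y_ss: float
    n: int

    def ss(self, name: str) -> float:
        return self.sss[self.names.index(name)]

    def df(self, name: str) -> int:
        return self.dfs[self.names.index(name)]

    def residual_ss(self) -> float:
        return max(self.y_ss - sum(self.sss), 0.0)

    def residual_df(self) -> int:
        return self.n - sum(self.dfs)


def _sequential(blocks: Sequence[tuple[str, np.ndarray]], y: np.ndarray) -> _SeqFit:
    n = y.size
    basis = np.empty((n, 0))
    names, dfs, sss = [], [], []
    slices: dict[str, slice] = {}
    cursor = 0
    for name, X in blocks:
        if X.ndim == 1:
            X = X[:, None]
        q = _orthonormalize(_residualize(X, basis))
        proj = q.T @ y if q.shape[1] else np.empty(0)
        names.append(name)
        dfs.append(q.shape[1])
        sss.append(float(proj @ proj))
        slices[name] = slice(cursor, cursor + q.shape[1])
        cursor += q.shape[1]
        if q.shape[1]:
            basis = np.hstack([basis, q])
    return _SeqFit(names, dfs, sss, basis, slices, float(y @ y), n)


def fit_sequential_anova(design: DesignMatrix, response: np.ndarray
                         ) -> tuple[AnovaTable, pd.Series]:
    """Least-squares fit with sequential (Type I) sums of squares.

    Each term's SS is the reduction in residual SS when its block enters
    after all preceding blocks; MS = SS / df, with df the rank the block
    adds.  Rank-deficient blocks have their df reduced (recorded in the
    design's ``meta['dropped']``).  Coefficients are the minimum-norm
    least-squares solution over the full labeled design.
    """
    y = np.asarray(response, float)
    if y.size != design.matrix.shape[0]:
        raise ValueError("response length does not match design rows")
    fit = _sequential(design.block_list(), y)
    rows = []
    for name, df_, ss in zip(fit.names, fit.dfs, fit.sss):
        if name == "intercept":
            continue
        rows.append((name, df_, ss, ss / df_ if df_ else 0.0))
    res_df, res_ss = fit.residual_df(), fit.residual_ss()
    try:
        icpt = fit.ss("intercept")
    except ValueError:  # pragma: no cover - intercept always present
        icpt = 0.0
    total = fit.y_ss - icpt
    table = AnovaTable(rows, (res_df, res_ss, res_ss / res_df if res_df else 0.0), total, fit.n)
    coef, *_ = np.linalg.lstsq(design.matrix, y, rcond=None)
    return table, pd.Series(coef, index=design.columns, name="coef")


def phi(ms_constrained: float, ms_free: float) -> float:
    """Fraction of the constrained interaction MS removed by the SA term.

    ``ms_constrained`` is the interaction mean square from the model with
    the SA term constrained to zero (SA column omitted, the interaction
    block carrying its full degrees of freedom); ``ms_free`` is the
    interaction-remainder mean square once the SA term is estimated.  The
    value may be negative because the two mean squares divide by different
    degrees of freedom.
    """
    if ms_constrained < 0 or ms_free < 0:
        raise ValueError("mean squares must be non-negative")
    if ms_constrained == 0:
        raise ZeroDivisionError("constrained interaction MS is zero; phi undefined")
    return (ms_constrained - ms_free) / ms_constrained


# -- joint coefficient fit (estimates and SEs) ------------------------------


def _group_demean(x: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if x.ndim == 1:
        means = np.bincount(codes, weights=x, minlength=n_groups) / counts
        return x - means[codes]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        means = np.bincount(codes, weights=x[:, j], minlength=n_groups) / counts
        out[:, j] = x[:, j] - means[codes]
    return out


def _joint_sa_fit(design: DesignMatrix, y: np.ndarray, sa_names: list[str]
                  ) -> tuple[dict[str, float], dict[str, float], float]:
    """Coefficients of the raw SA indicators in the full joint fit.

    The raw sympatric indicator (and, for the dual model, the field-phase
    indicator times it) replaces the residualized SA columns, so the fitted
    coefficients are exactly the sympatric-minus-allopatric contrasts of
    the generative parameterization.  A fixed unit block is absorbed by
    within-unit demeaning (Frisch-Waugh); the remaining dense columns are
    solved directly.  Returns ({name: coefficient}, {name: unitless
    variance factor [(X'X)^-1]_ss}, condition number of the dense matrix).
    """
    raw = {
        "sa_genetic": design.meta.get("sa_genetic_raw"),
        "sa_plastic": design.meta.get("sa_plastic_raw"),
        "sa": design.meta.get("sa_genetic_raw"),
    }
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for name, sl in design.blocks.items():
        if name == "unit_block":
            continue
        if name in sa_names:
            cols.append(raw[name][:, None])
            labels.append(name)
        else:
            X = design.matrix[:, sl]
            cols.append(X)
            labels.extend(design.columns[sl.start:sl.stop])
    X = np.hstack(cols)
    if "unit_block" in design.blocks:
        codes = design.meta["unit_codes"]
        n_groups = int(codes.max()) + 1
        X = _group_demean(X, codes, n_groups)
        y = _group_demean(y, codes, n_groups)
    norms = np.linalg.norm(X, axis=0)
    keep = norms > 1e-9 * max(np.sqrt(X.shape[0]), float(norms.max()))
    for name in sa_names:  # SA columns must survive absorption
        keep[labels.index(name)] = norms[labels.index(name)] > 0
    Xk = X[:, keep]
    kept_labels = [l for l, k in zip(labels, keep) if k]
    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    xtx_inv = np.linalg.pinv(Xk.T @ Xk)
    cond = float(np.linalg.cond(Xk)) if Xk.size else float("nan")
    est = {name: float(coef[kept_labels.index(name)]) for name in sa_names}
    vfac = {name: float(xtx_inv[kept_labels.index(name), kept_labels.index(name)])
            for name in sa_names}
    return est, vfac, cond


# -- the SA tests -----------------------------------------------------------


def _ensure_response(table: ObservationTable, spec: ModelSpec) -> ObservationTable:
    if "response" in table.df.columns:
        return table
    return transform_response(table, spec.trait_spec)


def _sa_component(fit: _SeqFit, sa_name: str, den_name: str, total_ms: float,
                  estimate: float, vfac: float) -> SATestResult:
    df_num = fit.df(sa_name)
    df_den = fit.df(den_name)
    if df_den == 0:
        raise InestimableError(
            f"no denominator degrees of freedom for {sa_name}: with J = K = 2 the "
            "interaction is fully consumed by the SA contrast; use more environments "
            "or the dual-generation test"
        )
    ms_num = fit.ss(sa_name) / df_num if df_num else 0.0
    ms_den = fit.ss(den_name) / df_den
    degenerate = ms_den <= _DEGENERATE_REL * max(total_ms, 0.0)
    if degenerate:
        F = float("nan")
        p = float("nan")
    else:
        F = ms_num / ms_den
        p = float(stats.f.sf(F, df_num, df_den))
    se = math.sqrt(max(ms_den, 0.0) * max(vfac, 0.0)) if not degenerate else 0.0
    return SATestResult(SAEstimate(estimate, se), F, df_num, df_den, p, None, degenerate)


def _constrained_interaction_ms(table: ObservationTable, spec: ModelSpec,
                                drop: Term, den_term: str, y: np.ndarray,
                                phase: Phase | None = None) -> float | None:
    """Interaction MS from an independent fit with one SA term omitted.

    Blocks after the interaction term in question cannot change its
    sequential SS, so the trailing unit/egg-density terms are not refit.
    """
    keep: list[Term] = []
    for t in spec.terms:
        if t is drop or t in (Term.UNIT_BLOCK, Term.EGG_DENSITY):
            continue
        keep.append(t)
    reduced = ModelSpec(spec.trait_spec, tuple(keep))
    if phase is None:
        d = build_dual_design(table, reduced)
    else:
        d = build_single_design(table, reduced, phase)
    fit = _sequential(d.block_list(), y)
    df_den = fit.df(den_term)
    if df_den == 0:
        return None
    return fit.ss(den_term) / df_den


def _safe_phi(ms_constrained: float | None, ms_free: float) -> float | None:
    if ms_constrained is None or ms_constrained == 0.0:
        return None
    return phi(ms_constrained, ms_free)


def sa_test_dual(table: ObservationTable, spec: ModelSpec | None = None) -> DualSAResult:
    """Dual-generation test for local adaptation and adaptive plasticity.

    Fits the sequential ANOVA across both assay phases and reports, for the
    genetic SA term (shared by both phases) and the plastic SA term (field
    phase only): the sympatric-minus-allopatric estimate with its standard
    error, the F statistic against the corresponding interaction-remainder
    mean square with df (1, (J-1)(K-1)-1), the upper-tail p-value, and the
    variance fraction phi.  A significant positive genetic term supports
    local adaptation; a significant positive plastic term supports adaptive
    phenotypic plasticity.

    If the table lacks a ``response`` column it is transformed first using
    the model's trait specification.
    """
    if spec is None:
        raise ValueError("a ModelSpec is required (e.g. ModelSpec.dual('preference'))")
    if {Phase(p) for p in table.df["phase"].unique()} != {Phase.FIELD, Phase.COMMON}:
        raise ValueError("dual test requires records from both phases")
    table = _ensure_response(table, spec)
    design = build_dual_design(table, spec)
    y = table.df["response"].to_numpy(float)
    fit = _sequential(design.block_list(), y)
    total_ms = (fit.y_ss - fit.ss("intercept")) / max(fit.n - 1, 1)

    est, vfac, cond = _joint_sa_fit(design, y, ["sa_genetic", "sa_plastic"])
    genetic = _sa_component(fit, "sa_genetic", "interaction", total_ms,
                            est["sa_genetic"], vfac["sa_genetic"])
    plastic = _sa_component(fit, "sa_plastic", "delta_interaction", total_ms,
                            est["sa_plastic"], vfac["sa_plastic"])
    ms_free_g = fit.ss("interaction") / fit.df("interaction")
    ms_free_p = fit.ss("delta_interaction") / fit.df("delta_interaction")
    genetic.phi = _safe_phi(
        _constrained_interaction_ms(table, spec, Term.SA_GENETIC, "interaction", y),
        ms_free_g)
    plastic.phi = _safe_phi(
        _constrained_interaction_ms(table, spec, Term.SA_PLASTIC, "delta_interaction", y),
        ms_free_p)

    anova, _ = _anova_from_seq(fit)
    meta = {
        "trait": spec.trait_spec.trait.value,
        "transform": spec.trait_spec.transform.value,
        "n_records": fit.n,
        "condition_number": cond,
        "dropped_columns": design.meta.get("dropped", []),
        "n_capped": int(table.df.get("capped", pd.Series(dtype=bool)).sum()),
    }
    return DualSAResult(genetic, plastic, anova, meta)


def sa_test_single(table: ObservationTable, spec: ModelSpec | None = None,
                   phase: Phase | str = Phase.COMMON) -> SATestResult:
    """Single-generation SA test within one assay phase.

    F = MS(SA) / MS(interaction remainder) with df (1, (J-1)(K-1)-1); a
    positive estimate indicates a pattern of local adaptation, a negative
    one local maladaptation.
    """
    if spec is None:
        raise ValueError("a ModelSpec is required (e.g. ModelSpec.single('preference'))")
    phase = Phase(phase)
    table = _ensure_response(table, spec)
    sub = table.subset_phase(phase)
    if sub.n_records == 0:
        raise ValueError(f"phase {phase.value!r} not present in table")
    design = build_single_design(sub, spec, phase)
    y = sub.df["response"].to_numpy(float)
    fit = _sequential(design.block_list(), y)
    total_ms = (fit.y_ss - fit.ss("intercept")) / max(fit.n - 1, 1)
    est, vfac, _ = _joint_sa_fit(design, y, ["sa"])
    result = _sa_component(fit, "sa", "interaction", total_ms, est["sa"], vfac["sa"])
    ms_free = fit.ss("interaction") / fit.df("interaction")
    result.phi = _safe_phi(
        _constrained_interaction_ms(sub, spec, Term.SA, "interaction", y, phase=phase),
        ms_free)
    return result


def _anova_from_seq(fit: _SeqFit) -> tuple[AnovaTable, float]:
    rows = []
    for name, df_, ss in zip(fit.names, fit.dfs, fit.sss):
        if name == "intercept":
            continue
        rows.append((name, df_, ss, ss / df_ if df_ else 0.0))
    res_df, res_ss = fit.residual_df(), fit.residual_ss()
    total = fit.y_ss - fit.ss("intercept")
    table = AnovaTable(rows, (res_df, res_ss, res_ss / res_df if res_df else 0.0),
                       total, fit.n)
    return table, total


# -- compiled model for simulation loops ------------------------------------


@dataclass
class CompiledDualModel:
    """Dual-model projections precomputed for a fixed experimental layout.

    Simulation studies refit the same design thousands of times with fresh
    responses.  The design matrix depends only on the layout, so the
    orthonormal block basis (through the field-phase interaction block) and
    the joint-fit factorization are computed once; each replicate then
    costs two matrix-vector products.  Produces numbers identical to
    :func:`sa_test_dual` (asserted in the test suite).
    """

    Q: np.ndarray
    slices: dict[str, slice]
    dfs: dict[str, int]
    unit_codes: np.ndarray | None
    n_groups: int
    Qj: np.ndarray
    Rj: np.ndarray
    idx_g: int
    idx_p: int
    vfac_g: float
    vfac_p: float

    def stats(self, y: np.ndarray) -> dict:
        c = self.Q.T @ y
        out = {}
        for name in ("sa_genetic", "interaction", "sa_plastic", "delta_interaction"):
            sl = self.slices[name]
            out[f"ss_{name}"] = float(c[sl] @ c[sl])
        ms_den_g = out["ss_interaction"] / self.dfs["interaction"]
        ms_den_p = out["ss_delta_interaction"] / self.dfs["delta_interaction"]
        ydm = y
        if self.unit_codes is not None:
            ydm = _group_demean(y, self.unit_codes, self.n_groups)
        coef = np.linalg.solve(self.Rj, self.Qj.T @ ydm)
        ok = ms_den_g > 0 and ms_den_p > 0
        F_g = out["ss_sa_genetic"] / ms_den_g if ok else float("nan")
        F_p = out["ss_sa_plastic"] / ms_den_p if ok else float("nan")
        return {
            "ok": ok,
            "F_genetic": F_g,
            "p_genetic": float(stats.f.sf(F_g, 1, self.dfs["interaction"])) if ok else float("nan"),
            "F_plastic": F_p,
            "p_plastic": float(stats.f.sf(F_p, 1, self.dfs["delta_interaction"])) if ok else float("nan"),
            "sa_genetic": float(coef[self.idx_g]),
            "sa_plastic": float(coef[self.idx_p]),
        }


def compile_dual_model(table: ObservationTable, spec: ModelSpec) -> CompiledDualModel:
    """Precompute the dual-model projections for a fixed layout.

    The trailing unit/egg-density block never alters the sequential SS of
    the SA and interaction terms (it enters last), so the cached basis
    stops at the field-phase interaction block; the unit block is never
    materialized as dense contrasts but absorbed exactly in the joint fit
    by within-unit demeaning.
    """
    has_units = Term.UNIT_BLOCK in spec.terms
    if has_units:
        reduced = ModelSpec(spec.trait_spec,
                            tuple(t for t in spec.terms if t is not Term.UNIT_BLOCK))
    else:
        reduced = spec
    design = build_dual_design(table, reduced)
    if has_units:
        codes = pd.factorize(table.df["unit"], sort=True)[0]
        design.meta["unit_codes"] = codes
        design.blocks["unit_block"] = slice(design.matrix.shape[1], design.matrix.shape[1])
    blocks = [(n, X) for n, X in design.block_list() if n not in ("unit_block",)]
    y0 = np.zeros(design.matrix.shape[0])
    fit = _sequential(blocks, y0)
    for name in ("sa_genetic", "interaction", "sa_plastic", "delta_interaction"):
        if fit.df(name) == 0:
            raise InestimableError(f"term {name!r} has zero degrees of freedom")

    raw = {"sa_genetic": design.meta["sa_genetic_raw"],
           "sa_plastic": design.meta["sa_plastic_raw"]}
    cols, labels = [], []
    for name, sl in design.blocks.items():
        if name == "unit_block":
            continue
        if name in raw:
            cols.append(raw[name][:, None])
            labels.append(name)
        else:
            cols.append(design.matrix[:, sl])
            labels.extend(design.columns[sl.start:sl.stop])
    X = np.hstack(cols)
    unit_codes = design.meta.get("unit_codes")
    n_groups = 0
    if "unit_block" in design.blocks and unit_codes is not None:
        n_groups = int(unit_codes.max()) + 1
        X = _group_demean(X, unit_codes, n_groups)
    else:
        unit_codes = None
    norms = np.linalg.norm(X, axis=0)
    keep = norms > 1e-9 * max(np.sqrt(X.shape[0]), float(norms.max()))
    Xk = X[:, keep]
    kept = [l for l, k in zip(labels, keep) if k]
    Qj, Rj = np.linalg.qr(Xk)
    xtx_inv = np.linalg.pinv(Xk.T @ Xk)
    idx_g, idx_p = kept.index("sa_genetic"), kept.index("sa_plastic")
    return CompiledDualModel(
        Q=fit.basis, slices=fit.slices,
        dfs={n: fit.df(n) for n in fit.names},
        unit_codes=unit_codes, n_groups=n_groups,
        Qj=Qj, Rj=Rj, idx_g=idx_g, idx_p=idx_p,
        vfac_g=float(xtx_inv[idx_g, idx_g]), vfac_p=float(xtx_inv[idx_p, idx_p]),
    )
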