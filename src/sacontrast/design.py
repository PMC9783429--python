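"""Design matrices for the single- and dual-generation sympatric-allopatric models.

The dual-generation model partitions a trait measured in two assay phases
(field-derived vs. common-environment flies) into:

* population quality (shared across phases),
* test-environment quality,
* a single *genetic* sympatric-allopatric (SA) contrast shared by both
  phases -- the signature of local adaptation,
* the remaining test x origin interaction,
* field-phase deviations of population, test-environment and interaction
  effects (non-adaptive plasticity),
* a single *plastic* SA contrast confined to the field phase -- the
  signature of adaptive phenotypic plasticity,
* a rearing-unit adjustment (fixed arena contrasts for choice assays, or a
  log egg-density covariate for survival).

All categorical blocks use sum-to-zero contrasts, so the SA terms are
symmetric sympatric-minus-allopatric mean contrasts and main effects read
as quality deviations.  Each SA column is the sympatric indicator
residualized against every preceding block, which confines it to the
interaction space: its sum of squares cannot be contaminated by population
or habitat quality.  The interaction blocks that follow an SA column carry
the remaining (J-1)(K-1) - 1 degrees of freedom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    ObservationTable,
    Phase,
    ReciprocalityError,
    Trait,
    TraitSpec,
    UnitAdjustment,
)

__all__ = [
    "Term",
    "ModelSpec",
    "DesignMatrix",
    "sympatric_indicator",
    "build_dual_design",
    "build_single_design",
]

#: columns whose singular values fall below this (relative) threshold after
#: residualization are dropped from a block and recorded in ``meta``
RANK_TOL = 1e-10


class Term(str, enum.Enum):
    POPULATION = "population"
    TEST_ENV = "test_env"
    SA_GENETIC = "sa_genetic"
    INTERACTION = "interaction"
    DELTA_POPULATION = "delta_population"
    DELTA_TEST_ENV = "delta_test_env"
    SA_PLASTIC = "sa_plastic"
    DELTA_INTERACTION = "delta_interaction"
    SA = "sa"
    UNIT_BLOCK = "unit_block"
    EGG_DENSITY = "egg_density"


_DUAL_ORDER = (
    Term.POPULATION,
    Term.TEST_ENV,
    Term.SA_GENETIC,
    Term.INTERACTION,
    Term.DELTA_POPULATION,
    Term.DELTA_TEST_ENV,
    Term.SA_PLASTIC,
    Term.DELTA_INTERACTION,
)

_SINGLE_ORDER = (Term.POPULATION, Term.TEST_ENV, Term.SA, Term.INTERACTION)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered fixed-effect term list with sum-to-zero contrasts."""

    trait_spec: TraitSpec
    terms: tuple[Term, ...]
    contrast_convention: str = "sum_to_zero"

    def __post_init__(self) -> None:
        terms = tuple(Term(t) for t in self.terms)
        object.__setattr__(self, "terms", terms)
        if self.contrast_convention != "sum_to_zero":
            raise ValueError("only sum-to-zero contrasts are supported")

        def _before(a: Term, b: Term) -> None:
            if a in terms and b in terms and terms.index(a) > terms.index(b):
                raise ValueError(f"{a.value} must precede {b.value}")

        _before(Term.SA_GENETIC, Term.INTERACTION)
        _before(Term.SA_PLASTIC, Term.DELTA_INTERACTION)
        _before(Term.SA, Term.INTERACTION)

    @staticmethod
    def _tail(trait_spec: TraitSpec) -> tuple[Term, ...]:
        adj = trait_spec.unit_adjustment
        if adj is UnitAdjustment.ARENA_BLOCK:
            return (Term.UNIT_BLOCK,)
        if adj is UnitAdjustment.LOG_EGG_DENSITY:
            return (Term.EGG_DENSITY,)
        return ()

    @classmethod
    def dual(cls, trait_spec: TraitSpec | Trait | str) -> "ModelSpec":
        """The dual-generation model for a trait (both assay phases)."""
        if not isinstance(trait_spec, TraitSpec):
            trait_spec = TraitSpec.for_trait(trait_spec)
        return cls(trait_spec, _DUAL_ORDER + cls._tail(trait_spec))

    @classmethod
    def single(cls, trait_spec: TraitSpec | Trait | str) -> "ModelSpec":
        """The single-generation SA model (one assay phase)."""
        if not isinstance(trait_spec, TraitSpec):
            trait_spec = TraitSpec.for_trait(trait_spec)
        return cls(trait_spec, _SINGLE_ORDER + cls._tail(trait_spec))


@dataclass
class DesignMatrix:
    """A labeled numeric design matrix with ordered term blocks.

    ``blocks`` maps term name -> column slice; the blocks partition the
    columns and appear in model order, starting with ``intercept``.
    ``row_alignment`` gives the source-record index of each row.  ``meta``
    carries the raw (un-residualized) SA indicator columns, the unit group
    codes used for fixed-block absorption, and a list of any columns
    dropped as numerically degenerate.
    """

    matrix: np.ndarray
    columns: list[str]
    blocks: dict[str, slice]
    row_alignment: np.ndarray
    meta: dict = field(default_factory=dict)

    def block(self, name: str) -> np.ndarray:
        return self.matrix[:, self.blocks[name]]

    def block_list(self) -> list[tuple[str, np.ndarray]]:
        return [(name, self.matrix[:, sl]) for name, sl in self.blocks.items()]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)


def sympatric_indicator(test_env: str, origin_env: str, env_set: set[str] | None = None) -> int:
    """1 if the test environment is the population's origin, else 0."""
    if env_set is not None:
        unknown = {test_env, origin_env} - set(env_set)
        if unknown:
            raise ValueError(f"unknown environment label(s): {sorted(unknown)}")
    return int(test_env == origin_env)


# -- contrast helpers -------------------------------------------------------


def _sum_contrasts(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero contrast columns for an integer-coded factor.

    Level ``i < n_levels - 1`` maps to column ``i`` carrying +1; the last
    level carries -1 in every column.
    """
    out = np.zeros((codes.size, max(n_levels - 1, 0)))
    for i in range(n_levels - 1):
        out[codes == i, i] = 1.0
    out[codes == n_levels - 1, :] = -1.0
    return out


def _residualize(X: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project the columns of X off an orthonormal basis (twice, for stability)."""
    if basis.shape[1] == 0:
        return X.copy()
    X = X - basis @ (basis.T @ X)
    X -= basis @ (basis.T @ X)
    return X


def _orthonormalize(X: np.ndarray, tol: float = RANK_TOL) -> np.ndarray:
    """Orthonormal basis of the column space of X, rank-truncated at tol."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    ref = max(float(np.abs(X).max()) * np.sqrt(X.shape[0]), 1.0)
    return U[:, s > tol * ref]


class _Builder:
    """Accumulates labeled blocks plus an orthonormal basis of their span."""

    def __init__(self, n_rows: int):
        self.n = n_rows
        self.parts: list[np.ndarray] = []
        self.columns: list[str] = []
        self.blocks: dict[str, slice] = {}
        self.basis = np.empty((n_rows, 0))
        self.dropped: list[str] = []
        self._cursor = 0

    def add(self, name: str, X: np.ndarray, labels: list[str]) -> None:
        if X.ndim == 1:
            X = X[:, None]
        self.parts.append(X)
        self.columns.extend(labels)
        self.blocks[name] = slice(self._cursor, self._cursor + X.shape[1])
        self._cursor += X.shape[1]
        resid = _residualize(X, self.basis)
        q = _orthonormalize(resid)
        if q.shape[1] < X.shape[1]:
            self.dropped.append(f"{name}: {X.shape[1] - q.shape[1]} column(s) degenerate")
        if q.shape[1]:
            self.basis = np.hstack([self.basis, q])

    def residualized(self, x: np.ndarray) -> np.ndarray:
        """x with the span of all blocks added so far projected out."""
        return _residualize(x[:, None] if x.ndim == 1 else x, self.basis)

    def remainder_basis(self, X: np.ndarray) -> np.ndarray:
        """Orthonormal basis of X's columns net of everything added so far."""
        return _orthonormalize(_residualize(X, self.basis))

    def finish(self, row_alignment: np.ndarray, meta: dict) -> DesignMatrix:
        matrix = np.hstack(self.parts) if self.parts else np.empty((self.n, 0))
        meta = dict(meta)
        meta["dropped"] = self.dropped
        return DesignMatrix(matrix, self.columns, self.blocks, row_alignment, meta)


def _require_response_ready(table: ObservationTable) -> pd.DataFrame:
    return table.df


def _factor(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(values.unique())
    lookup = {v: i for i, v in enumerate(levels)}
    return values.map(lookup).to_numpy(), levels


def _interaction_columns(env_codes: np.ndarray, origin_codes: np.ndarray,
                         n_env: int, n_origin: int) -> tuple[np.ndarray, list[str]]:
    """Row-wise Kronecker product of test-env and origin sum contrasts."""
    A = _sum_contrasts(env_codes, n_env)
    B = _sum_contrasts(origin_codes, n_origin)
    cols = []
    labels = []
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            cols.append(A[:, i] * B[:, j])
            labels.append(f"test[{i}]:origin[{j}]")
    if not cols:
        return np.empty((env_codes.size, 0)), []
    return np.column_stack(cols), labels


def _unit_block(df: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fixed rearing-unit contrasts, sum-coded within (population, phase).

    Centering within the population x phase group keeps between-unit mean
    differences attributable to the population inside the population block,
    so population quality stays identifiable.  Returns the columns, their
    labels, and integer unit-group codes (for fixed-block absorption).
    """
    group = df["population"].astype(str) + "\x00" + df["phase"].astype(str)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    unit_codes, unit_levels = _factor(df["unit"])
    n = len(df)
    for g in sorted(group.unique()):
        mask = (group == g).to_numpy()
        units = sorted(df.loc[mask, "unit"].unique())
        if len(units) < 2:
            continue
        lookup = {u: i for i, u in enumerate(units)}
        codes_g = df.loc[mask, "unit"].map(lookup).to_numpy()
        C = _sum_contrasts(codes_g, len(units))
        for i in range(C.shape[1]):
            col = np.zeros(n)
            col[mask] = C[:, i]
            cols.append(col)
            labels.append(f"unit[{units[i]}]")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, labels, unit_codes


def _egg_density(df: pd.DataFrame, offset: float) -> np.ndarray:
    x = np.log(df["eggs"].to_numpy(float) + offset)
    return x - x.mean()


def _check_reciprocal(df: pd.DataFrame) -> None:
    # every population must be assayed on at least one non-origin environment
    envs_per_pop = df.groupby("population")["test"].agg(set)
    origin = df.groupby("population")["origin"].first()
    only_home = [p for p in envs_per_pop.index if envs_per_pop[p] <= {origin[p]}]
    if only_home:
        raise ReciprocalityError(
            f"population(s) tested only on their own environment: {only_home}"
        )
    if not set(df["origin"]) <= set(df["test"]):
        raise ReciprocalityError("origin environments are not a subset of test environments")


def build_dual_design(table: ObservationTable, spec: ModelSpec) -> DesignMatrix:
    """Design matrix of the dual-generation SA model.

    Requires both assay phases.  Emits one column block per term in model
    order.  ``sa_genetic`` is the sympatric indicator residualized against
    the population and test-environment blocks; ``sa_plastic`` is the
    field-phase indicator times the sympatric indicator, residualized
    against all preceding blocks.  Each interaction block is an orthonormal
    basis of the remaining interaction space, carrying (J-1)(K-1) - 1
    degrees of freedom after its SA column.
    """
    df = _require_response_ready(table)
    phases = set(df["phase"])
    if phases != {Phase.FIELD.value, Phase.COMMON.value}:
        raise ValueError("dual model requires records from both phases")
    _check_reciprocal(df)
    return _build(df, spec, dual=True)


def build_single_design(table: ObservationTable, spec: ModelSpec,
                        phase: Phase | str) -> DesignMatrix:
    """Design matrix of the single-generation SA model for one phase."""
    phase = Phase(phase)
    df = table.df[table.df["phase"] == phase.value].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"phase {phase.value!r} not present in table")
    _check_reciprocal(df)
    return _build(df, spec, dual=False)


def _build(df: pd.DataFrame, spec: ModelSpec, *, dual: bool) -> DesignMatrix:
    n = len(df)
    pop_codes, pop_levels = _factor(df["population"])
    env_codes, env_levels = _factor(df["test"])
    # reciprocality: origin levels are indexed on the test-environment scale
    origin_codes = df["origin"].map({v: i for i, v in enumerate(env_levels)}).to_numpy()
    n_env = len(env_levels)

    s_raw = (df["test"] == df["origin"]).to_numpy(float)
    field_ind = (df["phase"] == Phase.FIELD.value).to_numpy(float)

    b = _Builder(n)
    b.add("intercept", np.ones((n, 1)), ["intercept"])

    meta: dict = {
        "env_levels": env_levels,
        "population_levels": pop_levels,
        "n_env": n_env,
        "sa_genetic_raw": s_raw,
        "field_indicator": field_ind,
    }

    inter_X, inter_labels = _interaction_columns(env_codes, origin_codes, n_env, n_env)

    for term in spec.terms:
        if term is Term.POPULATION:
            b.add("population", _sum_contrasts(pop_codes, len(pop_levels)),
                  [f"population[{p}]" for p in pop_levels[:-1]])
        elif term is Term.TEST_ENV:
            b.add("test_env", _sum_contrasts(env_codes, n_env),
                  [f"test[{e}]" for e in env_levels[:-1]])
        elif term in (Term.SA_GENETIC, Term.SA):
            z = b.residualized(s_raw)
            b.add(term.value, z, [term.value])
        elif term is Term.INTERACTION:
            basis = b.remainder_basis(inter_X)
            b.add("interaction", basis,
                  [f"interaction[{i}]" for i in range(basis.shape[1])])
        elif term is Term.DELTA_POPULATION:
            # field-phase deviations; the leading I column is the overall
            # field-vs-common shift implied by the unconstrained delta effects
            X = np.column_stack([field_ind,
                                 field_ind[:, None] * _sum_contrasts(pop_codes, len(pop_levels))])
            b.add("delta_population", X,
                  ["field"] + [f"field:population[{p}]" for p in pop_levels[:-1]])
        elif term is Term.DELTA_TEST_ENV:
            X = field_ind[:, None] * _sum_contrasts(env_codes, n_env)
            b.add("delta_test_env", X, [f"field:test[{e}]" for e in env_levels[:-1]])
        elif term is Term.SA_PLASTIC:
            meta["sa_plastic_raw"] = field_ind * s_raw
            z = b.residualized(field_ind * s_raw)
            b.add("sa_plastic", z, ["sa_plastic"])
        elif term is Term.DELTA_INTERACTION:
            basis = b.remainder_basis(field_ind[:, None] * inter_X)
            b.add("delta_interaction", basis,
                  [f"field:interaction[{i}]" for i in range(basis.shape[1])])
        elif term is Term.UNIT_BLOCK:
            X, labels, unit_codes = _unit_block(df)
            meta["unit_codes"] = unit_codes
            b.add("unit_block", X, labels)
        elif term is Term.EGG_DENSITY:
            b.add("egg_density", _egg_density(df, spec.trait_spec.log_offset),
                  ["log_egg_density"])
        else:  # pragma: no cover - exhaustive
            raise ValueError(f"unhandled term {term}")

    return b.finish(np.arange(n), meta)
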