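"""Long-format data model for reciprocal common-environment trait assays.

The universal input is one record per rearing unit x test environment: a
population (with its environment of origin), the environment it was assayed
in, the experimental phase (field-derived flies vs. flies reared for two
generations in a common laboratory environment), the rearing-unit label
(choice arena or no-choice vial), the number of eggs laid and -- for
offspring performance -- the number of emerging adults.

Three traits are supported:

``preference``
    eggs laid per medium in a multi-medium choice arena; analysed as
    log(eggs + offset) with a fixed arena block.
``fecundity``
    eggs laid in a single-medium no-choice vial; analysed as
    log(eggs + offset) with no unit adjustment.
``performance``
    egg-to-adult survival; analysed as arcsin(sqrt(adults/eggs)) with the
    log initial egg count as a density covariate, survival capped at one.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Trait",
    "Transform",
    "UnitAdjustment",
    "TraitSpec",
    "ObservationTable",
    "DesignSummary",
    "SchemaError",
    "ConsistencyError",
    "ReciprocalityError",
    "read_observations",
    "write_observations",
    "transform_response",
    "summarize_design",
]

SCHEMA_VERSION = "1"

#: canonical column names of the delimited-text dialect
COLUMNS = ("population", "origin", "test", "phase", "unit", "eggs", "adults", "value")


class SchemaError(ValueError):
    """A required column is missing or a field has the wrong type/shape."""


class ConsistencyError(ValueError):
    """Records contradict each other (e.g. one population, two origins)."""


class ReciprocalityError(ValueError):
    """An origin environment is never used as a test environment."""


class Phase(str, enum.Enum):
    """Assay phase: field-derived flies vs. common-environment flies.

    ``FIELD`` covers assays on adults that emerged from field-collected
    fruit (generations G0 for preference/fecundity, G1 for performance);
    ``COMMON`` covers assays after two generations of common laboratory
    rearing (G2 / G3).  Phenotypic differences persisting into the COMMON
    phase are attributed to genetic effects.
    """

    FIELD = "field"
    COMMON = "common"


_PHASE_ALIASES = {
    "field": Phase.FIELD, "g0": Phase.FIELD, "g1": Phase.FIELD,
    "common": Phase.COMMON, "g2": Phase.COMMON, "g3": Phase.COMMON,
}


class Trait(str, enum.Enum):
    PREFERENCE = "preference"
    FECUNDITY = "fecundity"
    PERFORMANCE = "performance"


class Transform(str, enum.Enum):
    """Response transformation applied before model fitting.

    ``IDENTITY`` is used for synthetic continuous traits that are generated
    directly on the analysis scale (normal-family simulations).
    """

    LOG_COUNT = "log_count"
    ARCSINE_SQRT = "arcsine_sqrt_proportion"
    IDENTITY = "identity"


class UnitAdjustment(str, enum.Enum):
    ARENA_BLOCK = "arena_block"
    LOG_EGG_DENSITY = "log_egg_density"
    NONE = "none"


@dataclass(frozen=True)
class TraitSpec:
    """How a trait is transformed and unit-adjusted before analysis.

    Parameters
    ----------
    trait
        Which trait the table holds.
    transform
        Response transformation.  Count traits use ``log(eggs + log_offset)``;
        performance uses the angular transform ``arcsin(sqrt(p))`` of the
        egg-to-adult proportion.
    unit_adjustment
        ``ARENA_BLOCK`` adds fixed arena contrasts (preference),
        ``LOG_EGG_DENSITY`` replaces them with the log initial egg count
        (performance), ``NONE`` drops both (fecundity).
    survival_cap
        Cap the survival proportion at one when more adults than eggs were
        counted (miscounted low-egg vials); capped records are flagged, not
        dropped.
    log_offset
        Offset added inside the log for count responses so that zero counts
        remain finite.
    """

    trait: Trait
    transform: Transform
    unit_adjustment: UnitAdjustment
    survival_cap: bool = True
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        trait = Trait(self.trait)
        transform = Transform(self.transform)
        adj = UnitAdjustment(self.unit_adjustment)
        object.__setattr__(self, "trait", trait)
        object.__setattr__(self, "transform", transform)
        object.__setattr__(self, "unit_adjustment", adj)
        if transform is Transform.IDENTITY:
            return  # synthetic continuous traits may pair with any adjustment
        if trait is Trait.PERFORMANCE:
            if transform is not Transform.ARCSINE_SQRT or adj is not UnitAdjustment.LOG_EGG_DENSITY:
                raise SchemaError(
                    "performance requires the arcsine-sqrt transform and the "
                    "log-egg-density unit adjustment"
                )
        else:
            if transform is not Transform.LOG_COUNT:
                raise SchemaError(f"{trait.value} requires the log-count transform")
            expected = (
                UnitAdjustment.ARENA_BLOCK if trait is Trait.PREFERENCE else UnitAdjustment.NONE
            )
            if adj is not expected:
                raise SchemaError(
                    f"{trait.value} requires unit_adjustment={expected.value!r}"
                )

    @classmethod
    def for_trait(cls, trait: Trait | str) -> "TraitSpec":
        """Return the conventional specification for a trait."""
        trait = Trait(trait)
        if trait is Trait.PREFERENCE:
            return cls(trait, Transform.LOG_COUNT, UnitAdjustment.ARENA_BLOCK)
        if trait is Trait.FECUNDITY:
            return cls(trait, Transform.LOG_COUNT, UnitAdjustment.NONE)
        return cls(trait, Transform.ARCSINE_SQRT, UnitAdjustment.LOG_EGG_DENSITY)


def _normalize_label(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


@dataclass
class ObservationTable:
    """Validated long-format table of trait observations.

    Wraps a :class:`pandas.DataFrame` with columns ``population``,
    ``origin``, ``test``, ``phase``, ``unit``, ``eggs`` and optionally
    ``adults`` (performance), ``value`` (identity-transform synthetic
    traits), ``response``/``capped`` (added by :func:`transform_response`).

    Invariants enforced on construction: counts are non-negative; each
    population has exactly one origin environment; every origin environment
    also occurs as a test environment (reciprocality); each unit belongs to
    exactly one (population, phase) pair.
    """

    df: pd.DataFrame
    schema_version: str = SCHEMA_VERSION
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, normalize: bool = True) -> "ObservationTable":
        df = df.copy()
        missing = [c for c in ("population", "origin", "test", "phase", "unit", "eggs") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if normalize:
            for col in ("population", "origin", "test", "unit"):
                df[col] = _normalize_label(df[col])
            phase_raw = _normalize_label(df["phase"])
            bad = sorted(set(phase_raw) - set(_PHASE_ALIASES))
            if bad:
                raise SchemaError(f"unrecognized phase label(s): {bad}")
            df["phase"] = phase_raw.map(lambda p: _PHASE_ALIASES[p].value)
        table = cls(df.reset_index(drop=True))
        table.validate()
        return table

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        eggs = pd.to_numeric(df["eggs"], errors="raise")
        if (eggs < 0).any():
            raise ValueError("negative egg count")
        if not np.allclose(eggs, np.round(eggs)):
            raise SchemaError("eggs must be integer counts")
        df["eggs"] = eggs.astype(int)
        if "adults" in df.columns:
            adults = pd.to_numeric(df["adults"], errors="raise")
            present = adults.notna()
            if (adults[present] < 0).any():
                raise ValueError("negative adult count")
            df["adults"] = adults.astype("Float64")
        origins = df.groupby("population")["origin"].nunique()
        multi = origins[origins > 1]
        if len(multi):
            raise ConsistencyError(
                f"population(s) with more than one origin environment: {list(multi.index)}"
            )
        if not set(df["origin"]) <= set(df["test"]):
            missing = sorted(set(df["origin"]) - set(df["test"]))
            raise ReciprocalityError(
                f"origin environment(s) never used as test environment: {missing}"
            )
        owners = df.groupby("unit")[["population", "phase"]].nunique()
        shared = owners[(owners > 1).any(axis=1)]
        if len(shared):
            raise ConsistencyError(
                f"unit(s) appearing under more than one (population, phase): {list(shared.index)}"
            )

    # -- convenience --------------------------------------------------------

    @property
    def env_set(self) -> set[str]:
        return set(self.df["test"]) | set(self.df["origin"])

    @property
    def n_records(self) -> int:
        return len(self.df)

    def phases(self) -> set[Phase]:
        return {Phase(p) for p in self.df["phase"].unique()}

    def subset_phase(self, phase: Phase | str) -> "ObservationTable":
        phase = Phase(phase)
        out = ObservationTable(self.df[self.df["phase"] == phase.value].reset_index(drop=True),
                               self.schema_version, dict(self.meta))
        return out

    def origin_of(self) -> dict[str, str]:
        """Mapping population -> origin environment."""
        return dict(self.df.groupby("population")["origin"].first())

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)

    def equals(self, other: "ObservationTable") -> bool:
        """Field-level equality of records (ignoring metadata)."""
        cols = [c for c in COLUMNS if c in self.df.columns]
        if [c for c in COLUMNS if c in other.df.columns] != cols:
            return False
        return self.df[cols].equals(other.df[cols])


def read_observations(path: str | Path, column_map: dict[str, str] | None = None,
                      sep: str | None = None) -> ObservationTable:
    """Read a delimited text file of trait observations.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.  The delimiter is inferred from
        the extension unless ``sep`` is given.
    column_map
        Optional mapping from file column names to the canonical field
        names (``population``, ``origin``, ``test``, ``phase``, ``unit``,
        ``eggs``, ``adults``, ``value``).

    Row order is preserved; environment labels are case-folded and trimmed.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return ObservationTable.from_frame(df)


def write_observations(table: ObservationTable, path: str | Path, sep: str | None = None) -> None:
    """Write a table in the same dialect that :func:`read_observations` reads."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = [c for c in (*COLUMNS, "response", "capped") if c in table.df.columns]
    table.df.to_csv(path, sep=sep, index=False, columns=cols)


def transform_response(table: ObservationTable, spec: TraitSpec) -> ObservationTable:
    """Attach the transformed analysis response to a table.

    Count traits get ``response = log(eggs + offset)``.  Performance gets
    ``response = arcsin(sqrt(p))`` with ``p = adults / eggs`` capped at one
    (flagged in the ``capped`` column); vials with zero eggs have an
    undefined proportion and are excluded with a warning.  Identity leaves
    the ``value`` column untouched.

    Returns a new :class:`ObservationTable`; the input is not modified.
    """
    df = table.df.copy()
    has_adults = "adults" in df.columns and df["adults"].notna().any()
    if spec.trait is not Trait.PERFORMANCE and has_adults and spec.transform is not Transform.IDENTITY:
        raise SchemaError(f"adult counts present but trait is {spec.trait.value!r}")
    capped = np.zeros(len(df), dtype=bool)
    if spec.transform is Transform.LOG_COUNT:
        if spec.log_offset <= 0:
            raise ValueError("log offset must be positive")
        response = np.log(df["eggs"].to_numpy(float) + spec.log_offset)
    elif spec.transform is Transform.ARCSINE_SQRT:
        if not has_adults:
            raise SchemaError("performance requires an 'adults' column")
        eggs = df["eggs"].to_numpy(float)
        adults = df["adults"].to_numpy(float)
        if np.isnan(adults).any():
            raise SchemaError("performance records with missing adult counts")
        zero = eggs == 0
        if zero.any():
            warnings.warn(
                f"excluding {int(zero.sum())} performance record(s) with zero eggs "
                "(undefined survival proportion)",
                stacklevel=2,
            )
            df = df[~zero].reset_index(drop=True)
            eggs, adults = eggs[~zero], adults[~zero]
        p = adults / eggs
        capped = p > 1.0
        if capped.any() and not spec.survival_cap:
            raise ValueError("adults > eggs but survival_cap is disabled")
        p = np.minimum(p, 1.0)
        response = np.arcsin(np.sqrt(p))
    else:  # identity
        if "value" not in df.columns:
            raise SchemaError("identity transform requires a 'value' column")
        response = df["value"].to_numpy(float)
    df["response"] = response
    df["capped"] = capped
    meta = dict(table.meta)
    meta["trait_spec"] = {
        "trait": spec.trait.value,
        "transform": spec.transform.value,
        "unit_adjustment": spec.unit_adjustment.value,
        "survival_cap": spec.survival_cap,
        "log_offset": spec.log_offset,
    }
    out = ObservationTable(df, table.schema_version, meta)
    return out


@dataclass
class DesignSummary:
    """Cell counts and balance diagnostics for an observation table."""

    cell_counts: pd.DataFrame  # population x test x phase -> n
    balanced: bool
    units_per_population_phase: pd.Series
    populations_per_origin: dict[str, int]

    def origin_population_counts(self) -> list[int]:
        return sorted(self.populations_per_origin.values())


def summarize_design(table: ObservationTable) -> DesignSummary:
    """Per-cell counts, a balance flag and the population layout.

    The balance flag is true iff every population x test-environment x phase
    cell holds the same number of records (a cell emptied or thinned flips
    it).  Unequal numbers of populations per origin (the study's 9/3/13
    sampling) do not by themselves unbalance the cells.
    """
    df = table.df
    pops = df[["population", "phase"]].drop_duplicates()
    envs = sorted(set(df["test"]))
    full = (
        pops.merge(pd.DataFrame({"test": envs}), how="cross")
        .set_index(["population", "test", "phase"])
    )
    counts = df.groupby(["population", "test", "phase"]).size()
    counts = counts.reindex(full.index, fill_value=0).rename("n")
    balanced = counts.nunique() == 1
    units = df.groupby(["population", "phase"])["unit"].nunique()
    per_origin = df.groupby("origin")["population"].nunique().to_dict()
    return DesignSummary(counts.reset_index(), bool(balanced), units, per_origin)
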