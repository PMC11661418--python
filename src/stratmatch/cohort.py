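"""Cohort data model, CSV I/O, simple imputation, and balance diagnostics.

A :class:`Cohort` is the package's central container: a raw covariate table
``X`` (mixed continuous / binary / categorical columns described by a list of
:class:`CovariateSchema`), a binary treatment vector ``a``, a nonnegative
time-to-event/censoring vector ``t`` and a binary event indicator ``y``.
Rows are a *multiset*: matched or oversampled cohorts may repeat patients,
and ``ids`` preserve provenance back to the original subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_KINDS = ("continuous", "binary", "categorical")


class SchemaError(ValueError):
    """A covariate schema is inconsistent with itself or with the data."""


class CohortValidationError(ValueError):
    """Cohort-level contract violated (non-binary treatment, negative times...)."""


@dataclass(frozen=True)
class CovariateSchema:
    """Description of one covariate column.

    Parameters
    ----------
    name:
        Column name in the covariate table.
    kind:
        One of ``continuous``, ``binary``, ``categorical``.
    categories:
        Ordered category labels; required (with >= 2 entries) for
        categorical covariates. The first category is the reference level
        dropped during one-hot encoding.
    """

    name: str
    kind: str
    categories: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise SchemaError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise SchemaError(
                    f"categorical covariate {self.name!r} needs >= 2 categories"
                )
        object.__setattr__(
            self,
            "categories",
            tuple(self.categories) if self.categories is not None else None,
        )


def validate_schema(schema: Sequence[CovariateSchema]) -> None:
    names = [c.name for c in schema]
    if len(set(names)) != len(names):
        raise SchemaError("covariate names must be unique")


@dataclass
class Cohort:
    """Patient-level survival cohort (row multiset).

    ``a`` and ``y`` are 0/1 integer vectors, ``t`` nonnegative times in
    ``time_unit`` (months by default). ``ids`` trace every row back to an
    original patient, so duplicated rows remain attributable.
    """

    ids: np.ndarray
    X: pd.DataFrame
    a: np.ndarray
    t: np.ndarray
    y: np.ndarray
    schema: Sequence[CovariateSchema]
    time_unit: str = "months"
    imputation_mask: Optional[pd.DataFrame] = None

    def __post_init__(self):
        validate_schema(self.schema)
        self.ids = np.asarray(self.ids)
        self.a = np.asarray(self.a)
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y)
        n = len(self.ids)
        if not (len(self.X) == len(self.a) == len(self.t) == len(self.y) == n):
            raise CohortValidationError("ids, X, a, t, y must have equal length")
        for vec, nm in ((self.a, "treatment"), (self.y, "event")):
            vals = pd.Series(vec).dropna().unique()
            if not set(vals) <= {0, 1}:
                raise CohortValidationError(f"{nm} vector must be binary 0/1, got {sorted(vals)}")
        if np.isnan(self.a.astype(float)).any() or np.isnan(self.t).any() or np.isnan(
            self.y.astype(float)
        ).any():
            raise CohortValidationError("a, t, y must have no missing values")
        if (self.t < 0).any():
            raise CohortValidationError("times must be nonnegative")
        self.a = self.a.astype(int)
        self.y = self.y.astype(int)
        missing_cols = [c.name for c in self.schema if c.name not in self.X.columns]
        if missing_cols:
            raise SchemaError(f"covariates missing from table: {missing_cols}")
        self.X = self.X[[c.name for c in self.schema]].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.ids)

    def take(self, indices) -> "Cohort":
        """Row-multiset selection; duplicate indices duplicate rows."""
        idx = np.asarray(indices, dtype=int)
        return Cohort(
            ids=self.ids[idx],
            X=self.X.iloc[idx].reset_index(drop=True),
            a=self.a[idx],
            t=self.t[idx],
            y=self.y[idx],
            schema=self.schema,
            time_unit=self.time_unit,
        )


@dataclass
class EncodedCohort:
    """Numeric design matrix: one-hot categoricals, reference level dropped."""

    Z: pd.DataFrame
    schema: Sequence[CovariateSchema]

    @property
    def column_names(self) -> list:
        return list(self.Z.columns)

    @property
    def K(self) -> int:
        return self.Z.shape[1]


def encode(cohort_or_X, schema: Sequence[CovariateSchema] = None) -> EncodedCohort:
    """Deterministically encode raw covariates into a numeric design matrix.

    Continuous and binary columns pass through as floats; each categorical
    column with L levels becomes L-1 indicator columns ``name=level`` in
    schema category order, the first category being the dropped reference.
    """
    if isinstance(cohort_or_X, Cohort):
        X, schema = cohort_or_X.X, cohort_or_X.schema
    else:
        X = cohort_or_X
        if schema is None:
            raise SchemaError("schema required when encoding a bare table")
    cols = {}
    for cov in schema:
        col = X[cov.name]
        if cov.kind in ("continuous", "binary"):
            vals = pd.to_numeric(col, errors="coerce").astype(float)
            if not np.isfinite(vals.to_numpy()).all():
                raise CohortValidationError(
                    f"column {cov.name!r} has missing/non-numeric values; impute first"
                )
            cols[cov.name] = vals.to_numpy()
        else:
            known = set(cov.categories)
            bad = set(col.dropna().unique()) - known
            if bad:
                raise SchemaError(f"column {cov.name!r} has unknown categories {bad}")
            if col.isna().any():
                raise CohortValidationError(
                    f"column {cov.name!r} has missing values; impute first"
                )
            for level in cov.categories[1:]:
                cols[f"{cov.name}={level}"] = (col == level).astype(float).to_numpy()
    Z = pd.DataFrame(cols)
    return EncodedCohort(Z=Z, schema=tuple(schema))


def read_cohort(
    path,
    schema: Sequence[CovariateSchema],
    columns: Mapping[str, str],
    time_unit: str = "months",
) -> Cohort:
    """Load a cohort from CSV, dropping rows with missing a/t/y.

    ``columns`` maps roles to CSV column names and must contain
    ``treatment``, ``time`` and ``event``; an optional ``id`` role names a
    patient-identifier column (row numbers are used otherwise). Covariate
    missingness is preserved for :func:`impute_missing`; rows missing
    treatment, time or event are excluded with a logged count, since those
    fields are not imputable.
    """
    validate_schema(schema)
    df = pd.read_csv(path)
    for role in ("treatment", "time", "event"):
        if role not in columns:
            raise SchemaError(f"column map must provide {role!r}")
        if columns[role] not in df.columns:
            raise SchemaError(f"CSV has no column {columns[role]!r} (role {role})")
    for cov in schema:
        if cov.name not in df.columns:
            raise SchemaError(f"CSV has no covariate column {cov.name!r}")
    core = df[[columns["treatment"], columns["time"], columns["event"]]]
    keep = core.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing treatment/time/event", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    ids = (
        df[columns["id"]].to_numpy()
        if "id" in columns
        else np.arange(len(df))
    )
    return Cohort(
        ids=ids,
        X=df[[c.name for c in schema]],
        a=df[columns["treatment"]].to_numpy(),
        t=df[columns["time"]].to_numpy(dtype=float),
        y=df[columns["event"]].to_numpy(),
        schema=tuple(schema),
        time_unit=time_unit,
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV (inverse of :func:`read_cohort` on complete data)."""
    df = cohort.X.copy()
    df.insert(0, "id", cohort.ids)
    df["treatment"] = cohort.a
    df["time"] = cohort.t
    df["event"] = cohort.y
    df.to_csv(path, index=False)


def impute_missing(cohort: Cohort) -> Cohort:
    """Single imputation: column median (continuous) / mode (binary, categorical).

    Idempotent; the returned cohort carries an ``imputation_mask`` marking
    filled cells. A column that is entirely missing cannot be imputed and
    raises.
    """
    X = cohort.X.copy()
    mask = X.isna()
    if not mask.any().any():
        return cohort
    for cov in cohort.schema:
        col = X[cov.name]
        if not col.isna().any():
            continue
        if col.isna().all():
            raise CohortValidationError(f"covariate {cov.name!r} is entirely missing")
        if cov.kind == "continuous":
            fill = pd.to_numeric(col, errors="coerce").median()
        else:
            # mode; ties broken by first-sorted value for determinism
            fill = col.mode().iloc[0]
        X[cov.name] = col.fillna(fill)
        logger.info("imputed %d values in %r with %r", int(mask[cov.name].sum()), cov.name, fill)
    out = replace(cohort, X=X)
    out.imputation_mask = mask
    return out


def split_by_treatment(cohort: Cohort) -> tuple:
    """Partition into (untreated, treated) sub-cohorts, order preserved."""
    untreated = cohort.take(np.flatnonzero(cohort.a == 0))
    treated = cohort.take(np.flatnonzero(cohort.a == 1))
    return untreated, treated


def standardized_mean_differences(
    group_a: EncodedCohort, group_b: EncodedCohort
) -> pd.Series:
    """Per-column SMD: (mean_A - mean_B) / pooled SD.

    The pooled SD is sqrt((sd_A^2 + sd_B^2) / 2) with sample SDs. A
    degenerate column (pooled SD zero) gets SMD 0 when the means agree and
    +/- inf otherwise.
    """
    if group_a.column_names != group_b.column_names:
        raise SchemaError("encoded schemas differ between groups")
    A, B = group_a.Z.to_numpy(), group_b.Z.to_numpy()
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    sd_a = A.std(axis=0, ddof=1) if len(A) > 1 else np.zeros(A.shape[1])
    sd_b = B.std(axis=0, ddof=1) if len(B) > 1 else np.zeros(B.shape[1])
    pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = diff / pooled
    smd[(pooled == 0) & (diff == 0)] = 0.0
    smd[(pooled == 0) & (diff != 0)] = np.inf * np.sign(diff[(pooled == 0) & (diff != 0)])
    return pd.Series(smd, index=group_a.column_names, name="smd")
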