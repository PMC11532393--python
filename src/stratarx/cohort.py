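"""Patient-cohort data model, CSV I/O and horizon-based outcome labels.

A cohort is a thin, validated wrapper around a :class:`pandas.DataFrame` with
canonical columns::

    id | <covariates...> | treatment | event | [follow_up] | excluded_from_training

``treatment`` and ``event`` are strict ``{0, 1}`` integers; covariates are
declared either ``continuous`` or ``categorical``.  No imputation is ever
performed: records with missing covariate values fail validation instead of
being silently filled, because downstream matching distances and model fits
would be contaminated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import CohortValidationError, IntegrityError, SchemaError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, CATEGORICAL)

#: canonical internal column names
ID, TREATMENT, EVENT, FOLLOW_UP = "id", "treatment", "event", "follow_up"
EXCLUDED = "excluded_from_training"


@dataclass(frozen=True)
class ColumnMap:
    """Maps raw file columns onto the canonical cohort schema.

    Parameters
    ----------
    id, treatment, event:
        Names of the id / binary-treatment / binary-event columns in the file.
    follow_up:
        Optional name of a non-negative follow-up time column (months).
    covariates:
        Mapping of covariate column name -> kind (``continuous`` or
        ``categorical``).
    """

    id: str
    treatment: str
    event: str
    covariates: dict = field(default_factory=dict)
    follow_up: str | None = None

    def __post_init__(self):
        for name, kind in self.covariates.items():
            if kind not in _KINDS:
                raise SchemaError(
                    f"covariate {name!r} has unknown kind {kind!r}; "
                    f"expected one of {_KINDS}"
                )

    @classmethod
    def from_file(cls, path) -> "ColumnMap":
        """Load a column map from a YAML or JSON config file."""
        text = open(path).read()
        payload = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls(
            id=payload["id"],
            treatment=payload["treatment"],
            event=payload["event"],
            covariates=dict(payload.get("covariates", {})),
            follow_up=payload.get("follow_up"),
        )


class Cohort:
    """Validated patient-level dataset.

    Parameters
    ----------
    data:
        Frame already in canonical column layout (see module docstring).
    covariates:
        Mapping covariate name -> kind.
    """

    def __init__(self, data: pd.DataFrame, covariates: dict):
        for name, kind in covariates.items():
            if kind not in _KINDS:
                raise SchemaError(f"unknown covariate kind {kind!r} for {name!r}")
        required = [ID] + list(covariates) + [TREATMENT, EVENT]
        for col in required:
            if col not in data.columns:
                raise SchemaError(f"missing required column {col!r}")
        data = data.copy()
        if EXCLUDED not in data.columns:
            data[EXCLUDED] = False
        data[EXCLUDED] = data[EXCLUDED].astype(bool)

        if data[ID].duplicated().any():
            dupes = data.loc[data[ID].duplicated(), ID].tolist()
            raise IntegrityError(f"duplicate patient ids: {dupes[:5]}")
        for col in (TREATMENT, EVENT):
            _check_binary(data, col)
            data[col] = data[col].astype(int)
        if FOLLOW_UP in data.columns and data[FOLLOW_UP].notna().any():
            bad = data[FOLLOW_UP].dropna() < 0
            if bad.any():
                raise CohortValidationError("negative follow_up values present")
        for name, kind in covariates.items():
            if kind == CONTINUOUS:
                try:
                    data[name] = pd.to_numeric(data[name])
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"continuous covariate {name!r} is not numeric"
                    ) from exc
        self.data = data.reset_index(drop=True)
        self.covariates = dict(covariates)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data[ID]

    @property
    def treatment(self) -> np.ndarray:
        return self.data[TREATMENT].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data[EVENT].to_numpy()

    @property
    def follow_up(self) -> np.ndarray | None:
        if FOLLOW_UP not in self.data.columns:
            return None
        return self.data[FOLLOW_UP].to_numpy()

    @property
    def X(self) -> pd.DataFrame:
        """Covariate frame, in declaration order."""
        return self.data[list(self.covariates)]

    @property
    def excluded(self) -> np.ndarray:
        """Excluded-from-training flags (censored before the horizon)."""
        return self.data[EXCLUDED].to_numpy()

    @property
    def training_mask(self) -> np.ndarray:
        return ~self.excluded

    def continuous_names(self) -> list:
        return [c for c, k in self.covariates.items() if k == CONTINUOUS]

    def categorical_names(self) -> list:
        return [c for c, k in self.covariates.items() if k == CATEGORICAL]

    def subset(self, mask) -> "Cohort":
        """Row-subset by boolean mask or positional index, preserving order."""
        return Cohort(self.data.loc[np.asarray(mask)].reset_index(drop=True),
                      self.covariates)

    def equals(self, other: "Cohort") -> bool:
        if self.covariates != other.covariates or self.n != other.n:
            return False
        cols = sorted(set(self.data.columns) & set(other.data.columns))
        return self.data[cols].equals(other.data[cols])

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"Cohort(n={self.n}, covariates={list(self.covariates)}, "
                f"treated={int(self.treatment.sum())})")


def _check_binary(data: pd.DataFrame, col: str) -> None:
    vals = pd.to_numeric(data[col], errors="coerce")
    ok = vals.isin([0, 1])
    if not ok.all():
        row = int(np.flatnonzero(~ok.to_numpy())[0])
        raise CohortValidationError(
            f"non-binary value {data[col].iloc[row]!r} in column {col!r} at row {row}"
        )
    data[col] = vals


def read_cohort(path, schema: ColumnMap) -> Cohort:
    """Read and validate a delimited cohort file.

    Row order is preserved and nothing is imputed.  Raises
    :class:`SchemaError` for a missing mapped column,
    :class:`CohortValidationError` for a non-binary treatment/event value and
    :class:`IntegrityError` for a duplicate id.
    """
    raw = pd.read_csv(path)
    rename = {schema.id: ID, schema.treatment: TREATMENT, schema.event: EVENT}
    if schema.follow_up is not None:
        rename[schema.follow_up] = FOLLOW_UP
    for col in list(rename) + list(schema.covariates):
        if col not in raw.columns:
            raise SchemaError(f"mapped column {col!r} not found in {path}")
    data = raw.rename(columns=rename)
    return Cohort(data, schema.covariates)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort in canonical column order (CSV, lossless round-trip)."""
    cols = [ID] + list(cohort.covariates) + [TREATMENT, EVENT]
    if FOLLOW_UP in cohort.data.columns:
        cols.append(FOLLOW_UP)
    cols.append(EXCLUDED)
    cohort.data[cols].to_csv(path, index=False)


def canonical_map(covariates: dict, follow_up: bool = False) -> ColumnMap:
    """Column map for files written by :func:`write_cohort`."""
    return ColumnMap(id=ID, treatment=TREATMENT, event=EVENT,
                     covariates=dict(covariates),
                     follow_up=FOLLOW_UP if follow_up else None)


def derive_horizon_label(cohort: Cohort, horizon: float) -> Cohort:
    """Realize the binary fixed-horizon outcome from time-to-event columns.

    * event observed at or before ``horizon``  -> label 1
    * event-free with follow-up >= ``horizon`` -> label 0
    * event after the horizon                  -> label 0 (event-free at horizon)
    * censored (event-free) before the horizon -> label 0 but flagged
      excluded-from-training; the record is retained so a fitted policy can
      still be applied to it (prediction needs only covariates).
    """
    fu = cohort.follow_up
    if fu is None or np.isnan(fu.astype(float)).any():
        raise CohortValidationError("derive_horizon_label requires follow_up for all records")
    fu = fu.astype(float)
    event = cohort.event
    data = cohort.data.copy()
    new_event = ((event == 1) & (fu <= horizon)).astype(int)
    censored = (event == 0) & (fu < horizon)
    data[EVENT] = new_event
    data[EXCLUDED] = censored
    return Cohort(data, cohort.covariates)


@dataclass
class CohortReport:
    """Diagnostics from :func:`validate_cohort`."""

    n: int
    arm_sizes: dict            # {0: n_untreated, 1: n_treated}
    event_prevalence: dict     # per arm
    missing_by_column: dict    # column -> count of missing values
    missing_ids: list          # ids of rows with any missing covariate
    ok: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "arm_sizes": {str(k): v for k, v in self.arm_sizes.items()},
            "event_prevalence": {str(k): v for k, v in self.event_prevalence.items()},
            "missing_by_column": self.missing_by_column,
            "missing_ids": self.missing_ids,
            "ok": self.ok,
        }


def validate_cohort(cohort: Cohort) -> CohortReport:
    """Report per-column missingness, arm sizes and per-arm event prevalence.

    ``ok`` is False when any declared covariate has a missing value (those
    records would silently poison matching and model fits downstream).
    """
    if cohort.n == 0:
        raise CohortValidationError("empty cohort")
    t = cohort.treatment
    y = cohort.event
    arm_sizes = {0: int((t == 0).sum()), 1: int((t == 1).sum())}
    prevalence = {}
    for arm in (0, 1):
        m = t == arm
        prevalence[arm] = float(y[m].mean()) if m.any() else float("nan")
    X = cohort.X
    missing = {c: int(X[c].isna().sum()) for c in X.columns if X[c].isna().any()}
    bad_rows = X.isna().any(axis=1)
    missing_ids = cohort.ids[bad_rows].tolist()
    return CohortReport(
        n=cohort.n,
        arm_sizes=arm_sizes,
        event_prevalence=prevalence,
        missing_by_column=missing,
        missing_ids=missing_ids,
        ok=not missing,
    )
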