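"""Participant tables: loading, validation and stratification.

A :class:`CohortTable` is the single input to every downstream stage: a
participants x variables numeric matrix in schema column order plus a
binary stratification flag (1 = condition present, 0 = absent).

Validation is strict by default — the pipeline assumes complete data, so
missing cells are a hard error unless the caller explicitly opts into
listwise deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import VariableSchema, default_schema

#: below this many rows per stratum, network estimation is unstable
MIN_STABLE_STRATUM = 20


class CohortValidationError(ValueError):
    """Raised when a participant table violates the input contract."""


@dataclass(frozen=True)
class CohortTable:
    """Validated participants x variables matrix with a stratum flag."""

    values: np.ndarray  # (n, len(schema)) float64
    stratum: np.ndarray  # (n,) int, 1 = FA+, 0 = FA-
    schema: VariableSchema

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.stratum, dtype=int)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "stratum", s)
        if v.ndim != 2 or v.shape[1] != len(self.schema):
            raise CohortValidationError(
                f"values must be (n, {len(self.schema)}), got {v.shape}"
            )
        if s.shape != (v.shape[0],):
            raise CohortValidationError("stratum length must equal row count")
        if not np.isfinite(v).all():
            bad = np.argwhere(~np.isfinite(v))[0]
            raise CohortValidationError(
                f"non-finite value at row {bad[0]}, column {self.schema.names[bad[1]]}"
            )
        if not np.isin(s, (0, 1)).all():
            raise CohortValidationError("stratum flag must be 0/1")
        for j, e in enumerate(self.schema):
            if e.mtype == "binary" and not np.isin(v[:, j], (0.0, 1.0)).all():
                rows = np.where(~np.isin(v[:, j], (0.0, 1.0)))[0]
                raise CohortValidationError(
                    f"binary column {e.name!r} has value outside {{0,1}} "
                    f"at row {rows[0]}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self, stratum_column: str = "FA") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schema.names)
        df[stratum_column] = self.stratum
        return df

    def to_csv(self, path: str | Path, stratum_column: str = "FA") -> None:
        self.to_frame(stratum_column).to_csv(path, index=False)


def load_cohort(
    path: str | Path,
    schema: VariableSchema | None = None,
    stratum_column: str = "FA",
    allow_listwise_deletion: bool = False,
) -> CohortTable:
    """Read and validate a participant CSV.

    The header must contain every schema variable name plus
    ``stratum_column``; extra columns are ignored. Column order in the
    result follows the schema, not the file. Missing cells are a hard
    error unless ``allow_listwise_deletion`` drops the affected rows.
    """
    schema = schema or default_schema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)

    missing = [c for c in [*schema.names, stratum_column] if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {', '.join(missing)}")

    df = df[[*schema.names, stratum_column]]
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise CohortValidationError(
                    f"non-numeric cell in column {col!r} at row {int(bad.idxmax())}"
                )
            df[col] = coerced

    if df.isna().any().any():
        if allow_listwise_deletion:
            df = df.dropna(axis=0).reset_index(drop=True)
        else:
            row = int(df.isna().any(axis=1).idxmax())
            raise CohortValidationError(
                f"missing value at row {row}; pass allow_listwise_deletion=True "
                "to drop incomplete rows"
            )

    return CohortTable(
        values=df[schema.names].to_numpy(dtype=float),
        stratum=df[stratum_column].to_numpy(dtype=int),
        schema=schema,
    )


def split_by_stratum(cohort: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition a cohort into its (positive, negative) strata.

    A non-empty stratum with fewer than ``MIN_STABLE_STRATUM`` rows emits a
    warning; an empty stratum is an error (no network can be estimated).
    """
    out = []
    for flag, name in ((1, "positive"), (0, "negative")):
        mask = cohort.stratum == flag
        k = int(mask.sum())
        if k == 0:
            raise CohortValidationError(f"{name} stratum is empty")
        if k < MIN_STABLE_STRATUM:
            warnings.warn(
                f"{name} stratum has only {k} rows; "
                "network estimation is unstable below "
                f"{MIN_STABLE_STRATUM}",
                stacklevel=2,
            )
        out.append(
            CohortTable(cohort.values[mask], cohort.stratum[mask], cohort.schema)
        )
    return out[0], out[1]
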