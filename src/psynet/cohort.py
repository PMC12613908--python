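"""Reading, validating and filtering participant-level cohort tables.

A cohort table is a pandas DataFrame with one row per participant:
an id column, demographics (age, marital status, education, sexual
orientation), the 58 raw scale items, and the two sexual-behavior codes
(condom use 1-4, partner count 1-5). Files are UTF-8 CSV with a header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import DEFAULT_SCALE_MAP, ScaleMap

#: Strings interpreted as missing responses (configurable per read).
DEFAULT_MISSING = ("", "NA")


class ConfigurationError(ValueError):
    """A column map / configuration problem (e.g. missing column)."""


class NoCompleteCasesError(ValueError):
    """Listwise deletion removed every participant."""


@dataclass
class Cohort:
    """A validated cohort: the data plus per-cell out-of-range flags."""

    data: pd.DataFrame
    flags: pd.DataFrame
    scale_map: ScaleMap = field(default_factory=lambda: DEFAULT_SCALE_MAP)

    @property
    def n(self) -> int:
        return len(self.data)

    def n_flagged(self) -> int:
        return int(self.flags.to_numpy().sum())


@dataclass
class DeletionReport:
    removed_ids: list
    per_variable_missing: dict[str, int]

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def _validate_ranges(data: pd.DataFrame, scale_map: ScaleMap) -> pd.DataFrame:
    """Boolean frame marking cells outside their declared integer range."""
    flags = pd.DataFrame(False, index=data.index, columns=data.columns)
    ranges: dict[str, tuple[int, int]] = {}
    for scale in scale_map.scales.values():
        for col in scale.items:
            ranges[col] = scale.item_range
    ranges[scale_map.condom_column] = (1, 4)
    ranges[scale_map.partner_column] = (1, 5)
    for col, (lo, hi) in ranges.items():
        vals = data[col]
        ok = vals.isna() | ((vals >= lo) & (vals <= hi) & (vals == np.floor(vals)))
        flags[col] = ~ok
    # eligibility: aged 15 or older
    age = data[scale_map.age_column]
    flags[scale_map.age_column] = ~(age.isna() | (age >= 15))
    return flags


def read_cohort(
    path,
    scale_map: ScaleMap | None = None,
    missing_values: tuple[str, ...] = DEFAULT_MISSING,
) -> Cohort:
    """Read a cohort CSV, check columns and flag out-of-range cells.

    Raises
    ------
    ConfigurationError
        If a column named by the scale map is absent (the error names it).
    ValueError
        If a cell cannot be parsed as a number; the message carries the
        row index and column.
    """
    scale_map = scale_map or DEFAULT_SCALE_MAP
    df = pd.read_csv(
        path, na_values=list(missing_values), keep_default_na=False, dtype=str
    )
    required = (
        [scale_map.id_column, scale_map.age_column]
        + list(scale_map.demographic_columns)
        + scale_map.item_columns()
        + scale_map.behavior_columns()
    )
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} missing from {path}")
    numeric_cols = (
        [scale_map.age_column]
        + scale_map.item_columns()
        + scale_map.behavior_columns()
    )
    for col in numeric_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0]
            raise ValueError(
                f"unparseable value {bad.iloc[0]!r} at row {row}, column {col!r}"
            ) from None
    flags = _validate_ranges(df, scale_map)
    return Cohort(df, flags, scale_map)


def write_cohort(cohort: Cohort, path, missing_token: str = "") -> None:
    """Write a cohort back to CSV; round-trips all values exactly."""
    df = cohort.data.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            as_int = df[col].dropna()
            if len(as_int) and (as_int == np.floor(as_int)).all():
                df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False, na_rep=missing_token)


def apply_listwise_deletion(
    cohort: Cohort, required: list[str] | None = None
) -> tuple[Cohort, DeletionReport]:
    """Drop participants missing any required ('key') variable.

    Default key variables are all 58 items, both behavior codes, and age.
    Returns the filtered cohort and a report of removed ids and
    per-variable missingness counts.
    """
    sm = cohort.scale_map
    required = list(required) if required is not None else sm.key_columns()
    for col in required:
        if col not in cohort.data.columns:
            raise ConfigurationError(f"required column {col!r} not in cohort")
    sub = cohort.data[required]
    missing_mask = sub.isna()
    drop = missing_mask.any(axis=1)
    per_var = {c: int(missing_mask[c].sum()) for c in required if missing_mask[c].any()}
    removed = cohort.data.loc[drop, sm.id_column].tolist()
    kept = cohort.data.loc[~drop].reset_index(drop=True)
    if kept.empty:
        raise NoCompleteCasesError(
            "no complete cases remain after listwise deletion"
        )
    flags = cohort.flags.loc[~drop].reset_index(drop=True)
    return Cohort(kept, flags, sm), DeletionReport(removed, per_var)
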