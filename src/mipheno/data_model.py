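"""Tabular data contract shared by all pipeline stages.

An :class:`AssayTable` holds one row per individual sample, one or more
categorical grouping-factor columns (assay plate, planting group, ...) and
one or more quantitative attribute columns (metabolite responses, reporter
readouts, ...).  A :class:`GroupingSpec` says which grouping factor governs
which attributes, e.g. an ``LC_ID`` column for LC-derived attributes and an
``HPLC_ID`` column for HPLC-derived ones.  All downstream stages (QC,
normalization, scoring) operate attribute-by-attribute under this contract.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayTable",
    "GroupingSpec",
    "MissingPolicy",
    "ValidationError",
    "read_table",
    "write_table",
    "select_grouping_factor",
]

#: string tokens recognised as missing on read (case-insensitive), covering
#: R exports ("NA"), numpy/pandas reprs and empty spreadsheet cells.
MISSING_TOKENS = ("", "na", "nan", "n/a", "null")


class ValidationError(ValueError):
    """Input data violates the tabular contract."""


class MissingPolicy(enum.Enum):
    """How missing attribute values travel through a stage.

    ``propagate``: missing cells stay missing in outputs.
    ``drop_per_attribute``: rows missing a value are excluded from that
    attribute's computation (other attributes unaffected).
    """

    PROPAGATE = "propagate"
    DROP_PER_ATTRIBUTE = "drop_per_attribute"


@dataclass(frozen=True)
class GroupingSpec:
    """Maps each grouping-factor column to the attribute columns it governs.

    Every attribute must be governed by exactly one factor.
    """

    factors: Mapping[str, tuple[str, ...]]

    def __init__(self, factors: Mapping[str, Sequence[str]]):
        cleaned = {str(f): tuple(attrs) for f, attrs in factors.items()}
        seen: dict[str, str] = {}
        for factor, attrs in cleaned.items():
            for a in attrs:
                if a in seen:
                    raise ValidationError(
                        f"attribute {a!r} governed by both {seen[a]!r} and {factor!r}"
                    )
                seen[a] = factor
        if not seen:
            raise ValidationError("GroupingSpec governs zero attributes")
        object.__setattr__(self, "factors", cleaned)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for attrs in self.factors.values() for a in attrs)

    def factor_of(self, attribute: str) -> str:
        for factor, attrs in self.factors.items():
            if attribute in attrs:
                return factor
        raise KeyError(attribute)

    @classmethod
    def single(cls, factor: str, attributes: Sequence[str]) -> "GroupingSpec":
        """Convenience constructor: one factor governing all attributes."""
        return cls({factor: tuple(attributes)})


@dataclass
class AssayTable:
    """Sample-by-attribute table: the in-memory currency of the pipeline.

    Parameters
    ----------
    data
        One row per sample.  Must contain ``sample_id``, every factor and
        every attribute column.  Attribute columns are coerced to float;
        missing values are NaN.
    sample_id
        Name of the unique sample-identifier column.
    factor_columns
        Categorical grouping-factor columns.
    attribute_columns
        Quantitative response columns.
    """

    data: pd.DataFrame
    sample_id: str = "sample_id"
    factor_columns: tuple[str, ...] = ()
    attribute_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.factor_columns = tuple(self.factor_columns)
        self.attribute_columns = tuple(self.attribute_columns)
        missing_cols = [
            c
            for c in (self.sample_id, *self.factor_columns, *self.attribute_columns)
            if c not in self.data.columns
        ]
        if missing_cols:
            raise ValidationError(f"columns absent from table: {missing_cols}")
        if not self.factor_columns:
            raise ValidationError("at least one grouping factor is required")
        if not self.attribute_columns:
            raise ValidationError("at least one attribute column is required")
        ids = self.data[self.sample_id]
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample_id values: {dup}")
        # coerce attributes to numeric; non-numeric entries become NaN
        coerced = self.data.copy()
        n_bad = 0
        for col in self.attribute_columns:
            as_num = pd.to_numeric(coerced[col], errors="coerce")
            n_bad += int((as_num.isna() & coerced[col].notna()
                          & ~coerced[col].astype(str).str.strip().str.lower()
                          .isin(MISSING_TOKENS)).sum())
            coerced[col] = as_num.astype(float)
        if n_bad:
            warnings.warn(
                f"{n_bad} non-numeric attribute entrie(s) coerced to missing",
                stacklevel=3,
            )
        self.data = coerced.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def copy(self) -> "AssayTable":
        return AssayTable(
            self.data.copy(),
            sample_id=self.sample_id,
            factor_columns=self.factor_columns,
            attribute_columns=self.attribute_columns,
        )

    def values(self, attribute: str) -> pd.Series:
        if attribute not in self.attribute_columns:
            raise KeyError(attribute)
        return self.data[attribute]

    def groups(self, factor: str) -> pd.core.groupby.generic.DataFrameGroupBy:
        if factor not in self.factor_columns:
            raise KeyError(factor)
        return self.data.groupby(factor, sort=True, observed=True)


def read_table(
    path: str | Path,
    *,
    sample_id: str = "sample_id",
    factor_columns: Sequence[str],
    attribute_columns: Sequence[str] | None = None,
    delimiter: str = ",",
) -> AssayTable:
    """Read a delimited sample-by-attribute file into an :class:`AssayTable`.

    The file must have a header row.  Cells equal (case-insensitively) to
    one of ``MISSING_TOKENS`` are read as missing.  When
    ``attribute_columns`` is None, every column other than the sample id and
    the factors is treated as an attribute.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        na_values=[t for t in MISSING_TOKENS if t],
        keep_default_na=True,
        dtype={sample_id: str},
    )
    if attribute_columns is None:
        attribute_columns = [
            c for c in df.columns if c != sample_id and c not in set(factor_columns)
        ]
    return AssayTable(
        df,
        sample_id=sample_id,
        factor_columns=tuple(factor_columns),
        attribute_columns=tuple(attribute_columns),
    )


def write_table(
    table: AssayTable | pd.DataFrame, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a table to delimited text.

    Round-trip contract: ``read_table(write_table(t))`` reproduces the
    values to full stored precision; missing cells are written as "NA".
    """
    df = table.data if isinstance(table, AssayTable) else table
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")


def _group_median_iqr(
    table: AssayTable, factor: str, attributes: Iterable[str]
) -> pd.DataFrame:
    grouped = table.data.groupby(factor, sort=True, observed=True)
    rows = []
    for attr in attributes:
        med = grouped[attr].median()
        q1, q3 = med.quantile(0.25), med.quantile(0.75)
        rows.append(
            {
                "factor": factor,
                "attribute": attr,
                "n_groups": med.notna().sum(),
                "iqr_of_group_medians": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)


def select_grouping_factor(
    table: AssayTable,
    candidates: Sequence[str],
    attributes: Sequence[str] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Pick the grouping factor carrying the most batch-level variation.

    For each candidate factor the interquartile range of per-group medians
    is computed per attribute; candidates are summarised by the median of
    those per-attribute IQRs (robust to a single high-variance attribute)
    and the factor with the largest summary wins.  Normalizing on the
    factor with the widest group-median spread removes the most technical
    error.

    Returns the winning factor name and the full diagnostic table with one
    row per (factor, attribute).
    """
    if not candidates:
        raise ValidationError("no candidate factors supplied")
    attributes = tuple(attributes or table.attribute_columns)
    diagnostics = []
    summaries: dict[str, float] = {}
    for factor in candidates:
        n_groups = table.data[factor].nunique(dropna=True)
        if n_groups < 2:
            warnings.warn(f"factor {factor!r} has a single group; excluded")
            continue
        diag = _group_median_iqr(table, factor, attributes)
        diagnostics.append(diag)
        summaries[factor] = float(diag["iqr_of_group_medians"].median())
    if not summaries:
        raise ValidationError("all candidate factors excluded (need >= 2 groups)")
    best = max(summaries, key=lambda f: summaries[f])
    return best, pd.concat(diagnostics, ignore_index=True)
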