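"""Group-level quality control for post-hoc screening data.

When the order of data generation is unknown, groups whose median response
deviates grossly from the global median are the most likely carriers of
assay- or process-specific error (instrument malfunction, mishandled
batches, abnormal growth conditions).  ``qc_filter`` removes such
(group x attribute) blocks: the deviation of each group median from the
global median is measured in MAD units and blocks beyond a cutoff
(default 3 MAD) are set to missing.  Attributes are treated as independent,
so a group failing QC for one attribute keeps its data for every other
attribute.

Drift (group medians trending with run order) is deliberately left to
visual inspection; ``qc_overview_plotdata`` provides the per-group
box-and-whisker statistics for that purpose.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from mipheno.data_model import AssayTable, GroupingSpec

__all__ = ["qc_filter", "qc_overview_plotdata", "scaled_mad"]

#: normal-consistency constant: MAD * 1.4826 estimates sigma for Gaussians.
MAD_SCALE = 1.4826


def scaled_mad(values: np.ndarray | pd.Series, scale: float = MAD_SCALE) -> float:
    """Median absolute deviation about the median, times ``scale``.

    NaNs are ignored. Returns NaN for an empty input.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    return float(np.median(np.abs(v - np.median(v))) * scale)


def qc_filter(
    table: AssayTable,
    spec: GroupingSpec,
    cutoff: float = 3.0,
    *,
    mad_basis: Literal["group-medians", "observations"] = "group-medians",
    mad_scale: float = MAD_SCALE,
    min_group_size: int = 1,
) -> tuple[AssayTable, pd.DataFrame]:
    """Remove (group x attribute) blocks with aberrant group medians.

    For each attribute, under its governing factor: every group's median is
    compared to the global median; groups with ``|group median - global
    median| / MAD > cutoff`` have all their values for that attribute set
    to missing.  Values for other attributes of the same group are kept.

    Parameters
    ----------
    cutoff
        Threshold in MAD units (default 3; a permissive choice suited to
        post-hoc analysis where run order is unknown).
    mad_basis
        ``"group-medians"`` (default) measures the MAD over the group
        medians themselves — the cutoff targets group-level process error —
        while ``"observations"`` uses the MAD of all observations.
    mad_scale
        Consistency constant applied to the MAD (1.4826 for the Gaussian
        convention; pass 1.0 for the raw MAD).
    min_group_size
        Groups smaller than this are flagged in the report; they are still
        judged (QC applies to groups of any size by default).

    Returns
    -------
    (filtered table, report)
        The report has one row per (factor, group, attribute) with the
        group median, global median, MAD, deviation in MAD units, flags
        and the removal decision.  Surviving values are bitwise identical
        to the input.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = table.copy()
    records: list[dict] = []
    for factor, attributes in spec.factors.items():
        grouped = table.data.groupby(factor, sort=True, observed=True)
        sizes = grouped.size()
        for attr in attributes:
            col = table.data[attr]
            global_median = float(col.median())
            group_medians = grouped[attr].median()
            if mad_basis == "group-medians":
                mad = scaled_mad(group_medians, mad_scale)
            elif mad_basis == "observations":
                mad = scaled_mad(col, mad_scale)
            else:
                raise ValueError(f"unknown mad_basis {mad_basis!r}")
            if not np.isfinite(mad):
                deviations = pd.Series(np.nan, index=group_medians.index)
                removable = pd.Series(False, index=group_medians.index)
            elif mad == 0.0:
                # degenerate scale: a majority of groups sit exactly on the
                # global median.  Groups on the median deviate by 0; any
                # group off it is infinitely many MADs away.
                warnings.warn(
                    f"MAD is zero for attribute {attr!r}; groups off the "
                    "global median are treated as infinitely deviant"
                )
                diff = group_medians - global_median
                deviations = diff.apply(
                    lambda d: 0.0 if d == 0 else np.copysign(np.inf, d)
                )
                removable = deviations.abs() > cutoff
            else:
                deviations = (group_medians - global_median) / mad
                removable = deviations.abs() > cutoff
            for group_id, gmed in group_medians.items():
                removed = bool(removable.loc[group_id]) and np.isfinite(gmed)
                records.append(
                    {
                        "factor": factor,
                        "group": group_id,
                        "attribute": attr,
                        "group_median": gmed,
                        "global_median": global_median,
                        "mad": mad,
                        "deviation_mads": float(deviations.loc[group_id])
                        if np.isfinite(gmed)
                        else np.nan,
                        "group_size": int(sizes.loc[group_id]),
                        "small_group": bool(sizes.loc[group_id] < min_group_size),
                        "removed": removed,
                    }
                )
                if removed:
                    mask = out.data[factor] == group_id
                    out.data.loc[mask, attr] = np.nan
    report = pd.DataFrame.from_records(records)
    report.attrs["cutoff"] = cutoff
    report.attrs["mad_basis"] = mad_basis
    report.attrs["mad_scale"] = mad_scale
    return out, report


def qc_overview_plotdata(table: AssayTable, spec: GroupingSpec) -> pd.DataFrame:
    """Five-number summaries per (group, attribute) for drift inspection.

    Returns one row per group per attribute with the median, quartiles and
    Tukey whiskers (most extreme points within 1.5 IQR of the box), ordered
    by group id — the numbers a box-and-whisker plot of group drift would
    show.  Rendering is left to the caller.
    """
    rows = []
    for factor, attributes in spec.factors.items():
        grouped = table.data.groupby(factor, sort=True, observed=True)
        for attr in attributes:
            for group_id, sub in grouped:
                v = sub[attr].dropna().to_numpy(dtype=float)
                if v.size == 0:
                    continue
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                iqr = q3 - q1
                in_whisker = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
                rows.append(
                    {
                        "factor": factor,
                        "group": group_id,
                        "attribute": attr,
                        "n": int(v.size),
                        "whisker_low": float(in_whisker.min()),
                        "q1": float(q1),
                        "median": float(med),
                        "q3": float(q3),
                        "whisker_high": float(in_whisker.max()),
                    }
                )
    return pd.DataFrame(rows)
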