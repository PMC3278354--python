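"""Cross-batch median normalization.

A reduction of invariant-set normalization to a single quantile: per
attribute, a scaling factor brings every group's median to the global
median, under the assumptions that (i) samples from the same background
respond alike over time, (ii) differences between a group's distribution
and the global one are technical, and (iii) most samples in any group are
wild type.  Only the median is matched — no per-group variance adjustment —
which tolerates the unequal, modest group sizes typical of post-hoc data.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd

from mipheno.data_model import AssayTable, GroupingSpec

__all__ = ["normalize"]


def normalize(
    table: AssayTable,
    spec: GroupingSpec,
    *,
    mode: Literal["multiplicative", "additive"] = "multiplicative",
    min_group_size: int = 10,
) -> tuple[AssayTable, pd.DataFrame]:
    """Scale every group's median to the global median, per attribute.

    Multiplicative mode (default, suited to positive responses such as
    metabolite abundances) multiplies each group's values by
    ``global_median / group_median``; additive mode adds
    ``global_median - group_median`` instead.  The global median is
    computed once from the input (normally the post-QC table) and frozen;
    groups are scaled to that constant in a single pass.

    Groups with fewer than ``min_group_size`` non-missing values are still
    normalized but flagged — small groups give noisy medians, and the
    default of 10 reflects the guidance that a normalization group should
    contain as many individuals as possible (n > 10).  Missing values stay
    missing.

    Returns the normalized table and a factor table with one row per
    (factor, group, attribute): scaling factor, pre-scaling group median,
    global median, group size and the small-group flag.

    Raises
    ------
    ValueError
        In multiplicative mode when a group median is <= 0 — the scaling
        factor would flip or explode signs; use additive mode or inspect
        the data.
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown mode {mode!r}")
    out = table.copy()
    records: list[dict] = []
    for factor, attributes in spec.factors.items():
        grouped = table.data.groupby(factor, sort=True, observed=True)
        for attr in attributes:
            global_median = float(table.data[attr].median())
            group_medians = grouped[attr].median()
            counts = grouped[attr].count()
            for group_id, gmed in group_medians.items():
                n = int(counts.loc[group_id])
                if n == 0 or not np.isfinite(gmed):
                    records.append(
                        {
                            "factor": factor,
                            "group": group_id,
                            "attribute": attr,
                            "factor_applied": np.nan,
                            "group_median": np.nan,
                            "global_median": global_median,
                            "group_size": n,
                            "small_group": n < min_group_size,
                            "skipped": True,
                        }
                    )
                    continue
                if mode == "multiplicative":
                    if gmed <= 0:
                        raise ValueError(
                            f"group {group_id!r} has non-positive median "
                            f"({gmed:g}) for attribute {attr!r}; "
                            "multiplicative scaling is undefined — use "
                            "additive mode or inspect the data"
                        )
                    scale = global_median / gmed
                else:
                    scale = global_median - gmed
                small = n < min_group_size
                if small:
                    warnings.warn(
                        f"group {group_id!r} has only {n} values for "
                        f"{attr!r} (< {min_group_size}); its median is noisy"
                    )
                mask = out.data[factor] == group_id
                if mode == "multiplicative":
                    out.data.loc[mask, attr] = out.data.loc[mask, attr] * scale
                else:
                    out.data.loc[mask, attr] = out.data.loc[mask, attr] + scale
                records.append(
                    {
                        "factor": factor,
                        "group": group_id,
                        "attribute": attr,
                        "factor_applied": float(scale),
                        "group_median": float(gmed),
                        "global_median": global_median,
                        "group_size": n,
                        "small_group": small,
                        "skipped": False,
                    }
                )
    factors = pd.DataFrame.from_records(records)
    factors.attrs["mode"] = mode
    factors.attrs["min_group_size"] = min_group_size
    return out, factors
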