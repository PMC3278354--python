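"""Empirical-CDF hit detection and the group-based robust z comparator.

After QC and normalization all samples share one distribution per
attribute, so the pooled data (or a user-supplied null sample) serve as an
empirical null.  Each observation is placed on that null's CDF and assigned
an empirical p-value — the probability of seeing a value at least as
extreme in the relevant tail — plus a direction label (Low/High).  Hit
thresholds are capacity-driven: pick the cutoff that yields a follow-up
list of the size the downstream assay can absorb, or one that recovers
known gold-standard hits.

``zscore_method`` implements the group-based comparator commonly used for
plate screens: a robust z-score from the group median and MAD, computed on
raw data within each processing group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mipheno.data_model import AssayTable, GroupingSpec
from mipheno.qc import MAD_SCALE

__all__ = [
    "EmpiricalNull",
    "build_null",
    "empirical_pvalue",
    "call_hits",
    "score_table",
    "zscore_method",
]


@dataclass(frozen=True)
class EmpiricalNull:
    """Sorted reference sample defining the per-attribute null CDF."""

    values: np.ndarray  # sorted, finite
    attribute: str = ""

    @property
    def n(self) -> int:
        return int(self.values.size)


def build_null(values, attribute: str = "") -> EmpiricalNull:
    """Build an empirical null from a reference sample.

    ``values`` is typically the post-QC, normalized, pooled data for one
    attribute, but any user-supplied sample (e.g. draws from a known WT
    distribution) works.  Missing and non-finite entries are dropped; at
    least two finite values are required.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(
            f"need >= 2 finite values to build a null, got {v.size}"
        )
    return EmpiricalNull(values=np.sort(v), attribute=attribute)


def empirical_pvalue(null: EmpiricalNull, x) -> pd.DataFrame:
    """Place observations on the null CDF and assign empirical p-values.

    Uses the midrank plotting position

        F(x) = (#{v < x} + 0.5 * #{v = x} + 0.5) / (n + 1),

    which keeps F strictly inside (0, 1) — no observation gets p = 0 —
    and treats ties symmetrically.  The p-value is the smaller tail,
    ``p = min(F, 1 - F)``, with direction "Low" when F < 0.5, "High" when
    F > 0.5 and "WT" at an exact tie.

    Accepts a scalar or an array; returns a DataFrame with columns
    ``cdf``, ``p``, ``direction``.  Non-finite queries yield missing
    outputs with direction "NA".
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    finite = np.isfinite(xs)
    below = np.searchsorted(null.values, xs, side="left")
    upto = np.searchsorted(null.values, xs, side="right")
    n = null.n
    cdf = (below + 0.5 * (upto - below) + 0.5) / (n + 1)
    cdf = np.where(finite, cdf, np.nan)
    p = np.minimum(cdf, 1.0 - cdf)
    direction = np.where(
        ~finite, "NA", np.where(cdf < 0.5, "Low", np.where(cdf > 0.5, "High", "WT"))
    )
    return pd.DataFrame({"cdf": cdf, "p": p, "direction": direction})


def call_hits(scores: pd.DataFrame, cutoff: float = 0.1) -> pd.DataFrame:
    """Flag hits at an empirical p-value threshold.

    ``scores`` must carry a ``p`` column (as produced by
    :func:`empirical_pvalue` or :func:`score_table`).  The cutoff must lie
    in (0, 0.5] — 0.5 is the centre of the null, beyond which "more
    extreme" has no meaning.  Adds/overwrites a boolean ``hit`` column.
    """
    if not 0 < cutoff <= 0.5:
        raise ValueError(f"cutoff must be in (0, 0.5], got {cutoff}")
    out = scores.copy()
    out["hit"] = out["p"] <= cutoff
    out.loc[out["p"].isna(), "hit"] = False
    out.attrs["cutoff"] = cutoff
    return out


def score_table(
    table: AssayTable,
    attributes=None,
    nulls: dict[str, EmpiricalNull] | None = None,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Empirical p-values for every (sample, attribute) of a table.

    When ``nulls`` is not given, the null for each attribute is built from
    the pooled values of that attribute in ``table`` itself — the standard
    choice after QC and normalization.  Returns a long table with columns
    sample id, attribute, cdf, p, direction, hit.
    """
    attributes = tuple(attributes or table.attribute_columns)
    frames = []
    for attr in attributes:
        col = table.data[attr].to_numpy(dtype=float)
        null = (nulls or {}).get(attr) or build_null(col, attribute=attr)
        res = empirical_pvalue(null, col)
        res.insert(0, "attribute", attr)
        res.insert(0, table.sample_id, table.data[table.sample_id].to_numpy())
        frames.append(res)
    out = call_hits(pd.concat(frames, ignore_index=True), cutoff)
    return out


def zscore_method(
    table: AssayTable,
    spec: GroupingSpec,
    cutoff: float = 2.5,
    *,
    mad_scale: float = MAD_SCALE,
) -> pd.DataFrame:
    """Group-based robust z-scores: ``z = (x - group median) / scaled MAD``.

    Computed on the raw (non-normalized) table within each group of the
    governing factor, so group-level batch offsets cancel by construction.
    Groups whose MAD is zero get missing z (division guard, with a flag in
    the output); each group needs at least two non-missing values.

    Returns a long table with sample id, attribute, group, z, direction
    (sign of z) and the hit flag at ``|z| >= cutoff``.
    """
    frames = []
    for factor, attributes in spec.factors.items():
        grouped = table.data.groupby(factor, sort=True, observed=True)
        for attr in attributes:
            med = grouped[attr].transform("median")
            mad = grouped[attr].transform(
                lambda s: np.nanmedian(np.abs(s - np.nanmedian(s)))
                if s.notna().sum() >= 2
                else np.nan
            ) * mad_scale
            x = table.data[attr]
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (x - med) / mad.where(mad > 0)
            frames.append(
                pd.DataFrame(
                    {
                        table.sample_id: table.data[table.sample_id],
                        "attribute": attr,
                        "factor": factor,
                        "group": table.data[factor],
                        "z": z.astype(float),
                        "zero_mad": (mad == 0).fillna(False).astype(bool),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["direction"] = np.where(
        out["z"].isna(), "NA", np.where(out["z"] < 0, "Low", np.where(out["z"] > 0, "High", "WT"))
    )
    out["hit"] = out["z"].abs() >= cutoff
    out.loc[out["z"].isna(), "hit"] = False
    out.attrs["cutoff"] = cutoff
    out.attrs["mad_scale"] = mad_scale
    return out
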