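"""Per-line and per-locus consensus calls for multi-allele screens.

Reverse-genetic screens sample several independent insertion lines
(alleles) per locus, and each line may be assayed several times.  Scores
are therefore summarised in two steps: replicate samples of a line are
averaged into one phenotypic score per (line, attribute), and a locus is
called a putative mutant for an attribute/direction only when at least
``min_lines`` lines show the phenotype at the cutoff AND those lines are a
majority (> 50%) of the lines sampled for that locus — independent alleles
agreeing is far stronger evidence than a single outlier line.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["average_by_line", "call_loci"]

#: columns of the line map: sample -> (locus, line, dataset).  ``dataset``
#: distinguishes measurement scales (e.g. mol% vs nmol/gFW) or tissues.
LINE_MAP_COLUMNS = ("sample_id", "locus", "line", "dataset")


def _score_kind(scores: pd.DataFrame) -> str:
    if "cdf" in scores.columns:
        return "pvalue"
    if "z" in scores.columns:
        return "zscore"
    raise ValueError("scores must carry a 'cdf' (empirical p) or 'z' column")


def average_by_line(
    scores: pd.DataFrame, line_map: pd.DataFrame, *, sample_id: str = "sample_id"
) -> pd.DataFrame:
    """Average replicate samples into one score per (locus, line, attribute).

    ``scores`` is a long table from :func:`mipheno.hits.score_table`
    (columns ``cdf``/``p``/``direction``) or
    :func:`mipheno.hits.zscore_method` (column ``z``).  ``line_map`` maps
    every scored sample to its locus, insertion line and dataset id; an
    optional boolean ``exclude`` column drops samples (e.g. those
    genotyped wild-type or heterozygous) before averaging.

    Empirical p-values are averaged on the signed tail scale ``cdf - 0.5``
    and mapped back, so replicates on opposite tails cancel instead of
    both counting as extreme; z-scores are averaged directly (their sign
    already carries direction).
    """
    missing = [c for c in LINE_MAP_COLUMNS if c not in line_map.columns and c != "sample_id"]
    if missing:
        raise ValueError(f"line map lacks columns: {missing}")
    kind = _score_kind(scores)
    lm = line_map.copy()
    if "exclude" in lm.columns:
        dropped = lm.loc[lm["exclude"].astype(bool), sample_id]
        lm = lm[~lm["exclude"].astype(bool)]
        if len(dropped):
            warnings.warn(f"{len(dropped)} genotype-excluded sample(s) dropped")
    unmapped = set(scores[sample_id]) - set(lm[sample_id]) - set(
        line_map[sample_id]
    )
    if unmapped:
        raise ValueError(f"samples absent from line map: {sorted(unmapped)[:10]}")
    merged = scores.merge(lm[[sample_id, "locus", "line", "dataset"]], on=sample_id)
    keys = ["locus", "line", "dataset", "attribute"]
    if kind == "pvalue":
        merged["_signed"] = merged["cdf"] - 0.5
        agg = merged.groupby(keys, as_index=False).agg(
            signed_mean=("_signed", "mean"), n_replicates=("_signed", "count")
        )
        # exact cancellations land within float error of zero; snap them so
        # the direction reads WT rather than an arbitrary tail
        agg.loc[agg["signed_mean"].abs() < 1e-12, "signed_mean"] = 0.0
        agg["cdf"] = agg["signed_mean"] + 0.5
        agg["p"] = 0.5 - agg["signed_mean"].abs()
        agg["direction"] = np.where(
            agg["signed_mean"] < 0, "Low", np.where(agg["signed_mean"] > 0, "High", "WT")
        )
        return agg.drop(columns="signed_mean")
    agg = merged.groupby(keys, as_index=False).agg(
        z=("z", "mean"), n_replicates=("z", "count")
    )
    agg["direction"] = np.where(
        agg["z"] < 0, "Low", np.where(agg["z"] > 0, "High", "WT")
    )
    return agg


def call_loci(
    line_scores: pd.DataFrame, cutoff: float, *, min_lines: int = 2
) -> pd.DataFrame:
    """Apply the multi-allele agreement rules to per-line scores.

    A line *shows* a phenotype for an attribute when its averaged score is
    beyond the cutoff (p <= cutoff for empirical p-values, |z| >= cutoff
    for z-scores) with a definite direction.  Lines showing in any dataset
    count once (union across measurement scales).  A locus is flagged
    putative for (attribute, direction) when

        lines_showing >= min_lines  and  lines_showing / lines_sampled > 0.5,

    where ``lines_sampled`` counts the distinct lines of the locus scored
    for that attribute.  Lines split between High and Low therefore defeat
    each other: each direction is tallied separately and neither reaches a
    majority.
    """
    if min_lines < 2:
        raise ValueError("min_lines must be >= 2 (single-line calls are not consensus)")
    kind = "pvalue" if "p" in line_scores.columns and "cdf" in line_scores.columns else "zscore"
    df = line_scores.copy()
    if kind == "pvalue":
        if not 0 < cutoff <= 0.5:
            raise ValueError(f"p-value cutoff must be in (0, 0.5], got {cutoff}")
        df["shows"] = (df["p"] <= cutoff) & (df["direction"] != "WT")
    else:
        if cutoff <= 0:
            raise ValueError("z cutoff must be positive")
        df["shows"] = (df["z"].abs() >= cutoff) & (df["direction"] != "WT")

    sampled = (
        df.groupby(["locus", "attribute"])["line"].nunique().rename("lines_sampled")
    )
    showing = (
        df[df["shows"]]
        .groupby(["locus", "attribute", "direction"])["line"]
        .nunique()
        .rename("lines_showing")
    )
    calls = showing.reset_index().merge(
        sampled.reset_index(), on=["locus", "attribute"], how="left"
    )
    if calls.empty:
        return pd.DataFrame(
            columns=[
                "locus", "attribute", "direction",
                "lines_showing", "lines_sampled", "putative",
            ]
        )
    calls["putative"] = (calls["lines_showing"] >= min_lines) & (
        calls["lines_showing"] / calls["lines_sampled"] > 0.5
    )
    return calls.sort_values(["locus", "attribute", "direction"]).reset_index(
        drop=True
    )
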