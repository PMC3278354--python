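"""Small deterministic fixtures with oracle-computed expectations.

Each fixture is generated, never stored, so the generating parameters stay
auditable; alongside the data table(s) a sidecar table records the
expected downstream behaviour with a provenance note saying how each
expectation was derived (hand arithmetic or a named oracle).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mipheno.data_model import AssayTable, write_table
from mipheno.qc import scaled_mad

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("qc_outlier_block", "norm_two_groups", "consensus_two_scale")


def _qc_outlier_block(seed: int) -> dict[str, pd.DataFrame]:
    """5 groups x 20 samples x 2 attributes; group g5 shifted on attr1 only.

    The shift is +10 global (scaled) MADs of the unshifted attr1 values,
    far beyond any sensible QC cutoff, so exactly the (g5, attr1) block
    should be removed at cutoff 3 while (g5, attr2) survives.
    """
    rng = np.random.default_rng(seed)
    n_groups, n_per = 5, 20
    groups = np.repeat([f"g{i + 1}" for i in range(n_groups)], n_per)
    attr1 = rng.normal(100.0, 5.0, size=n_groups * n_per)
    attr2 = rng.normal(50.0, 2.0, size=n_groups * n_per)
    shift = 10.0 * scaled_mad(attr1)
    attr1 = attr1 + np.where(groups == "g5", shift, 0.0)
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n_groups * n_per)],
            "plate": groups,
            "attr1": attr1,
            "attr2": attr2,
        }
    )
    sidecar = pd.DataFrame(
        [
            {
                "expectation": "qc removes exactly (g5, attr1) at cutoff 3",
                "value": shift,
                "provenance": "hand arithmetic: shift = 10 x scaled MAD of "
                "unshifted attr1 >> 3 MAD of group medians",
            },
            {
                "expectation": "(g5, attr2) retained",
                "value": 0.0,
                "provenance": "hand arithmetic: attr2 is unshifted",
            },
        ]
    )
    return {"table": table, "expected": sidecar}


def _norm_two_groups(seed: int) -> dict[str, pd.DataFrame]:
    """Two groups {1,2,3} and {10,20,30}; pooled median 6.5 by hand."""
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "plate": ["a"] * 3 + ["b"] * 3,
            "attr1": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
        }
    )
    sidecar = pd.DataFrame(
        [
            {
                "expectation": "global median",
                "value": 6.5,
                "provenance": "hand arithmetic: median of {1,2,3,10,20,30}",
            },
            {
                "expectation": "post-normalization median of every group",
                "value": 6.5,
                "provenance": "normalization contract: group medians scale "
                "to the global median",
            },
        ]
    )
    return {"table": table, "expected": sidecar}


def _consensus_two_scale(seed: int) -> dict[str, pd.DataFrame]:
    """Line-level scores over two measurement scales plus the truth table.

    Loci: L1 — both lines Low (called); L2 — 2 of 5 lines show (minority,
    not called); L3 — one line High, one Low (direction conflict, not
    called).  Expectations follow directly from the >= 2 line and > 50%
    rules.
    """
    rows = []

    def add(locus, line, dataset, cdf):
        rows.append(
            {
                "locus": locus,
                "line": line,
                "dataset": dataset,
                "attribute": "attr1",
                "cdf": cdf,
                "p": min(cdf, 1 - cdf),
                "direction": "Low" if cdf < 0.5 else ("High" if cdf > 0.5 else "WT"),
                "n_replicates": 1,
            }
        )

    for ds in ("mol_pct", "per_weight"):
        add("L1", "L1-a", ds, 0.02)
        add("L1", "L1-b", ds, 0.05)
        for i, cdf in enumerate([0.03, 0.04, 0.5, 0.6, 0.45]):
            add("L2", f"L2-{i}", ds, cdf)
        add("L3", "L3-a", ds, 0.02)
        add("L3", "L3-b", ds, 0.97)
    line_scores = pd.DataFrame(rows)
    sidecar = pd.DataFrame(
        [
            {
                "expectation": "L1 putative Low (2/2 lines at p <= 0.1)",
                "value": 1,
                "provenance": "hand application of >=2-line and >50% rules",
            },
            {
                "expectation": "L2 not called (2/5 lines = 40% <= 50%)",
                "value": 0,
                "provenance": "hand application of majority rule",
            },
            {
                "expectation": "L3 not called (directions disagree)",
                "value": 0,
                "provenance": "hand application of direction-agreement rule",
            },
        ]
    )
    return {"line_scores": line_scores, "expected": sidecar}


_BUILDERS = {
    "qc_outlier_block": _qc_outlier_block,
    "norm_two_groups": _norm_two_groups,
    "consensus_two_scale": _consensus_two_scale,
}


def make_fixture(
    name: str, seed: int = 0, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Build a named fixture; optionally write its tables to ``out_dir``.

    Deterministic per (name, seed).  Returns the frames keyed by role
    (``table``/``line_scores`` plus an ``expected`` sidecar); when
    ``out_dir`` is given each frame is also written as
    ``<name>.<role>.csv``.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_BUILDERS)}"
        ) from None
    frames = builder(seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for role, df in frames.items():
            write_table(df, out_dir / f"{name}.{role}.csv")
    return frames
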