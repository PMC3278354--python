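"""Synthetic screening data with ground truth.

Emulates a first-pass phenotypic screen: each individual's 'metabolite'
response is drawn from one of three Gaussian populations — low abundance,
wild type (WT) and high abundance — with mutant means two WT standard
deviations from the WT mean (the common screening cutoff for a hit).
Dispersion is either equal across populations (equal SD) or proportional to
the mean (equal RSD).  Individuals are then nested in a hierarchy mirroring
a plant-growth pipeline: flats (trays) of up to 32 plants, three flats per
assay group, two assay groups per planting group.  Batch effects enter as
one uniform offset per planting group followed by one per assay group, with
the assay amplitude exceeding the planting amplitude.

Ground-truth class labels are assigned from the pre-noise value — low if
it falls more than two WT standard deviations below the WT mean, high if
above — so a WT-population draw that happens to land beyond the boundary
counts as a mutant, exactly as a screener reading the value would class it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from mipheno.data_model import AssayTable

__all__ = ["SyntheticConfig", "simulate_dataset", "truth_binary"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic screen.

    Attributes
    ----------
    wt_mean
        Mean of the WT population (abstract units; scale only).
    dispersion_mode
        ``"equal_rsd"``: each population k has sigma_k = rsd * mu_k;
        ``"equal_sd"``: every population has sigma = sd.
    sd, rsd
        Dispersion parameters for the two modes (defaults 5 and 15%).
    p_low, p_wt, p_high
        Sampling probabilities of the three populations; must sum to 1.
    flat_size, flats_per_assay, assays_per_planting, n_planting_groups
        Hierarchy sizes: 32 plants per flat, 3 flats per assay group, 2
        assay groups grown concurrently per planting group.
    planting_amp, assay_amp
        Half-widths of the uniform batch offsets, as fractions of
        ``wt_mean``; the assay effect must exceed the planting effect.
    seed
        Master seed; per-stage substreams are spawned from it so the same
        seed always reproduces the same table.
    """

    wt_mean: float = 100.0
    dispersion_mode: Literal["equal_sd", "equal_rsd"] = "equal_rsd"
    sd: float = 5.0
    rsd: float = 0.15
    p_low: float = 0.035
    p_wt: float = 0.93
    p_high: float = 0.035
    flat_size: int = 32
    flats_per_assay: int = 3
    assays_per_planting: int = 2
    n_planting_groups: int = 4
    planting_amp: float = 0.05
    assay_amp: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_low, self.p_wt, self.p_high)
        if any(p < 0 for p in probs):
            raise ValueError("sampling probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"p_low + p_wt + p_high must equal 1, got {sum(probs)}")
        if not self.assay_amp >= self.planting_amp >= 0:
            raise ValueError("require assay_amp >= planting_amp >= 0")
        if self.dispersion_mode == "equal_rsd" and self.wt_mean <= 0:
            raise ValueError("equal_rsd needs a positive wt_mean")
        if self.dispersion_mode not in ("equal_sd", "equal_rsd"):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")

    @property
    def sigma_wt(self) -> float:
        if self.dispersion_mode == "equal_sd":
            return self.sd
        return self.rsd * self.wt_mean

    @property
    def population_means(self) -> tuple[float, float, float]:
        """(low, wt, high) means: mutants sit 2 WT standard deviations out."""
        s = self.sigma_wt
        return (self.wt_mean - 2 * s, self.wt_mean, self.wt_mean + 2 * s)

    @property
    def population_sigmas(self) -> tuple[float, float, float]:
        if self.dispersion_mode == "equal_sd":
            return (self.sd, self.sd, self.sd)
        lo, wt, hi = self.population_means
        return (self.rsd * lo, self.rsd * wt, self.rsd * hi)

    @property
    def n_samples(self) -> int:
        return (
            self.flat_size
            * self.flats_per_assay
            * self.assays_per_planting
            * self.n_planting_groups
        )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def simulate_dataset(config: SyntheticConfig) -> tuple[AssayTable, pd.DataFrame]:
    """Draw one synthetic screen.

    Steps: (1) draw each individual's population with (p_low, p_wt,
    p_high) and its value from that population's Gaussian; (2) label each
    individual from the pre-noise value by the two-WT-SD rule; (3) assign
    flat/assay/planting ids by position in the hierarchy; (4) add one
    uniform offset per planting group on [-planting_amp * wt_mean,
    +planting_amp * wt_mean], then one per assay group with assay_amp.

    Returns an :class:`AssayTable` with grouping columns ``flat``,
    ``assay_group`` and ``planting_group`` and a single attribute
    ``response``, plus a truth frame with the class label, pre-noise value
    and the realized offsets (bookkeeping for calibration checks).
    """
    master = np.random.SeedSequence(config.seed)
    rng_class, rng_value, rng_noise = (
        np.random.default_rng(s) for s in master.spawn(3)
    )
    n = config.n_samples
    means = np.array(config.population_means)
    sigmas = np.array(config.population_sigmas)

    pop = rng_class.choice(3, size=n, p=[config.p_low, config.p_wt, config.p_high])
    values = rng_value.normal(means[pop], sigmas[pop])

    lo_bound = config.wt_mean - 2 * config.sigma_wt
    hi_bound = config.wt_mean + 2 * config.sigma_wt
    label = np.where(values < lo_bound, "low", np.where(values > hi_bound, "high", "wt"))

    idx = np.arange(n)
    flat = idx // config.flat_size
    assay = flat // config.flats_per_assay
    planting = assay // config.assays_per_planting
    n_assay = config.n_planting_groups * config.assays_per_planting

    planting_off = rng_noise.uniform(
        -config.planting_amp * config.wt_mean,
        config.planting_amp * config.wt_mean,
        size=config.n_planting_groups,
    )
    assay_off = rng_noise.uniform(
        -config.assay_amp * config.wt_mean,
        config.assay_amp * config.wt_mean,
        size=n_assay,
    )
    observed = values + planting_off[planting] + assay_off[assay]

    sample_id = np.array([f"S{i:05d}" for i in idx])
    table = AssayTable(
        pd.DataFrame(
            {
                "sample_id": sample_id,
                "flat": [f"F{i:03d}" for i in flat],
                "assay_group": [f"A{i:03d}" for i in assay],
                "planting_group": [f"P{i:02d}" for i in planting],
                "response": observed,
            }
        ),
        sample_id="sample_id",
        factor_columns=("flat", "assay_group", "planting_group"),
        attribute_columns=("response",),
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "population": np.array(["low", "wt", "high"])[pop],
            "label": label,
            "pre_noise_value": values,
            "planting_offset": planting_off[planting],
            "assay_offset": assay_off[assay],
        }
    )
    return table, truth


def truth_binary(truth: pd.DataFrame) -> pd.Series:
    """Collapse class labels to a mutant indicator: low/high -> 1, wt -> 0."""
    return (truth["label"] != "wt").astype(int)
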