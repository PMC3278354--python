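# Methods

This note documents the statistical model behind `mipheno`, the defaults
and why they were chosen, what the synthetic benchmark does and does not
emulate, and the numerical conventions the implementation commits to.

## Data model and assumptions

Input is a sample-by-attribute table: one row per individual, one or more
categorical grouping factors (plate, assay batch, planting group) and one
or more quantitative attributes. Three assumptions drive everything:

1. samples of the same background respond alike over time, so as a group
   grows its response distribution approaches the population's;
2. differences between a group's distribution and the global one are
   therefore technical, not biological;
3. any single perturbation (gene knockout, compound) changes only a few
   attributes, so most values in any group — and most values of any
   attribute — are wild type (WT).

Assumption 3 is load-bearing: every group is normalized to the cohort, so
a group genuinely enriched for non-WT responses (> ~50% mutant for an
attribute) will have its real signal partially normalized away. That
hazard is the user's responsibility to avoid when choosing groupings; the
package does not correct for it.

Attributes are treated as independent throughout, even when they are
biochemically coupled (e.g. branch-chain amino acids): QC removals,
scaling factors and p-values for one attribute never affect another.

## Quality control

For each attribute under its governing factor, the deviation of each group
median from the global median is expressed in MAD units and groups beyond
a cutoff have that attribute (only) set to missing.

* **Cutoff** — default 3 MAD: permissive on purpose, since in post-hoc
  analysis the run order is usually unknown and aggressive removal costs
  data. Exposed as `cutoff`.
* **MAD basis** — default is the MAD *of the group medians*, since the
  cutoff judges group-level process error; the MAD of all observations is
  available via `mad_basis="observations"` (it is systematically larger,
  hence more permissive).
* **MAD constant** — 1.4826 (normal-consistent scaled MAD), matching the
  convention of the common statistical environments; set `mad_scale=1`
  for the raw MAD.
* **Zero MAD** — if a majority of group medians coincide with the global
  median the MAD is 0. Groups exactly on the median then deviate by 0 and
  are kept; any group off it is infinitely many MADs away and is removed.
  This keeps the two degenerate cases consistent: all-identical medians
  remove nothing, a lone aberrant group among identical ones is removed.
* **Drift** is deliberately not auto-detected: steadily trending group
  medians or protocol switches need human judgment, so the package only
  computes the per-group five-number summaries (`qc_overview_plotdata`)
  that a box-and-whisker inspection needs.

## Normalization

Per attribute, every group's values are multiplied by
`global_median / group_median` (default) or shifted by
`global_median − group_median` (`mode="additive"`). The global median is
computed once from the post-QC table and frozen, so the result is a
single deterministic pass; after it, every group's median equals that
constant to 1e-9 relative tolerance (asserted in tests).

Multiplicative scaling is the default because screening responses are
typically positive concentrations and a scale factor preserves
proportional structure; it refuses non-positive group medians (the factor
would flip signs) and points the user to additive mode. Groups smaller
than `min_group_size` (default 10 — group medians from fewer individuals
are too noisy to anchor a normalization) are still normalized but flagged
and warned about, leaving the filtering decision to the caller.

Only the median is matched — no variance adjustment, unlike quantile
normalization. This is a deliberate trade: post-hoc group sizes are small
and unequal (12–96 in the motivating screen), too thin to estimate more
than one quantile reliably.

## Empirical p-values

The pooled post-QC, normalized values of an attribute (or a user-supplied
sample) form the empirical null. An observation is placed at

    F̂(x) = (#{v < x} + 0.5·#{v = x} + 0.5) / (n + 1)

— the midrank plotting position. The +0.5/(n+1) construction keeps F̂
strictly inside (0, 1), so no observation receives p = 0 (an honest
statement about what n samples can resolve), and ties are split
symmetrically. The reported p-value is the smaller tail,
`p = min(F̂, 1 − F̂)`, with a Low/High direction label; no two-sided
doubling and no multiple-testing correction are applied, because hit
thresholds in first-pass screens are capacity decisions, not error-rate
guarantees. Default cutoff 0.1; z-score cutoffs 2.5 (strict) and 1.3
(permissive) are the comparator's conventional operating points.

Note the p-value resolution is 1/(n+1): with a 768-sample null the
smallest attainable p is ≈ 6.5e-4 and cutoffs below ~1.3e-3 can call at
most one observation per tail. Pool as much data as the assumptions allow
before scoring.

The group z comparator is `z = (x − median_g)/(1.4826·MAD_g)` on raw
data, with a division guard: a zero-MAD group yields missing z (flagged)
rather than infinities.

## Synthetic benchmark

`simulate_dataset` emulates a first-pass screen in which ground truth is
knowable:

* three Gaussian populations — low, WT, high — with mutant means two WT
  standard deviations from the WT mean (the conventional screening cutoff
  for a hit); dispersion either equal across populations (`equal_sd`,
  default SD 5) or proportional to the mean (`equal_rsd`, default 15%);
* each individual's population drawn with probabilities
  `(p_low, p_wt, p_high)`; the benchmark crosses WT frequency 0.93
  (sparse mutants) with 0.40 (mutant-heavy);
* truth labels assigned from the **pre-noise value** by the ±2σ_wt rule,
  so a WT-population draw landing beyond the boundary counts as a mutant
  — the label a screener reading the true value would assign;
* a hierarchy mirroring a plant pipeline: flats of 32, three flats per
  assay group (96), two assay groups per planting group (192); one
  uniform batch offset per planting group (default half-width 5% of the
  WT mean) then one per assay group (25%), the assay effect dominating.

Defaults the study design leaves open, fixed here once:

* **WT mean 33.3 in the benchmark** (`BenchmarkConfig.base`), so that the
  equal-SD setting (σ = 5) and the equal-RSD setting (σ_wt = 0.15·33.3 ≈ 5)
  describe populations of the same width and differ only in how mutant
  dispersion scales with the mean. `SyntheticConfig` itself defaults to
  an abstract mean of 100.
* **Offset amplitudes 0.05/0.25** of the WT mean: large enough that
  batch structure dominates raw values, small enough that group medians
  stay well-positive for multiplicative scaling.
* **Benchmark size** 4 planting groups × 192 = 768 samples per dataset,
  25 replicate datasets per setting: desk-scale (the whole study runs in
  seconds) yet enough for pooled-AUC standard errors of ~0.002.
* Seeding: a master `SeedSequence` spawns per-stage substreams (class
  draws, values, offsets), so the same seed reproduces the same table
  exactly and stages can be varied independently.

Three routes are scored against the binary truth (low/high → mutant):
the full pipeline (`mipheno`), the identical CDF scoring on raw data
(`raw`, isolating the value of pre-processing), and the within-assay-group
robust z (`zscore`). AUC uses the rank (Mann–Whitney) formulation with
midrank ties. Accuracy, FNDR = FN/(FN+TN), the miss rate FN/(FN+TP) and
FPR are swept over per-tail cutoffs
{0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.15, 0.2, 0.25}; for the
z route, |z| is mapped through the standard-normal tail so all methods
share the cutoff axis. Paired method differences (per setting × replicate
× cutoff) are tested with the two-sided Wilcoxon signed-rank test, zeros
dropped.

**Pooled vs per-setting AUC.** The summary reports both. Within a single
setting the z-score is an excellent ranker here — the injected offsets
are constant within exactly the groups it conditions on, so they cancel
in `x − median_g`, and with 96 samples per group its median/MAD estimates
are precise. Pooled across settings the picture reverses: |z| scales
shrink wherever mutants inflate the group MAD (the p_wt = 0.40 settings),
so z-scores from different settings are not comparable, while empirical
p-values remain on one probability scale. The pooled AUC is therefore the
number that reflects the method's purpose (cross-dataset comparison), and
it is what `scripts/acceptance.py` reports.

**What the generator does not emulate** — and hence what passing the
benchmark does not establish about real screens: missing data, drift and
protocol switches within a factor level, multiplicative batch effects,
non-Gaussian/tailed response distributions, correlated attributes, groups
enriched for mutants, and unequal group sizes. The QC and normalization
stages handle several of these in real data, but the benchmark does not
stress them.

## Consensus calls for multi-allele screens

Replicate samples of an insertion line are averaged into one score per
(line, attribute). Empirical p-values are averaged on the signed tail
scale `F̂ − 0.5` and mapped back, so replicates on opposite tails cancel
to WT instead of both counting as extreme; z-scores average directly
(means within 1e-12 of zero are snapped to zero so exact cancellations
read as WT). A locus is a putative mutant for (attribute, direction) when
at least `min_lines` (default 2 — a single line is never consensus) show
the phenotype at the cutoff *and* those lines are a strict majority of
the lines sampled for that locus. Lines showing in any dataset (e.g.
mol% or per-fresh-weight scales) count once, by union. Opposite-direction
lines are tallied separately, so High-vs-Low splits defeat each other —
directional agreement is part of "same phenotype".

## Numerical conventions and degenerate inputs

* Missing markers on read: empty cell, `NA`, `NaN`, `N/A`, `null`
  (case-insensitive); non-numeric attribute cells coerce to missing with
  a counted warning. Written output uses `NA`.
* Grouping-factor selection summarises each candidate by the median over
  attributes of the IQR of its group medians (robust to one noisy
  attribute) and needs ≥ 2 groups per candidate.
* Ratio metrics with empty denominators (e.g. FNDR when everything is
  called) are reported as 0 rather than NaN, and the convention is noted
  in the output schema. FNDR = FN/(FN+TN) is *not* monotone in the
  threshold (its denominator moves with its numerator); the miss rate is,
  and both are emitted.
* AUC requires both classes present and drops samples with missing
  scores; single-class input is an error, not a default value.
* Exit codes of the CLI: 0 success, 2 validation error (bad columns,
  duplicate ids, invalid cutoffs), 1 I/O or runtime error.

## Known limitations

* Scaling to a contaminated global median: with very high mutant
  frequency (> 50% per group for an attribute) normalization absorbs real
  signal; the benchmark's p_wt = 0.40 settings already show the pooled
  empirical null flattening mutant p-values.
* The empirical null includes the mutants themselves; p-values are tail
  probabilities of the observed mixture, not of a clean WT distribution.
  Supplying an external WT null (`build_null` accepts any sample)
  sharpens them.
* Within-group variance differences between batches are not corrected —
  only the median is matched.
* The QC stage judges whole groups; a single aberrant sample inside an
  otherwise healthy group is the hit detector's job, not QC's.
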