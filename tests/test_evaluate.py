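import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mipheno.evaluate import (
    BenchmarkConfig,
    compare_methods,
    roc_auc,
    run_benchmark,
    threshold_metrics,
)
from mipheno.simulate import SyntheticConfig


def pairwise_auc_oracle(scores, truth):
    """AUC as explicit concordance counting over all (mutant, WT) pairs."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_chance(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_four_sample_hand_case(self):
        # pairs: (0.9,0.8)+, (0.9,0.1)+, (0.4,0.8)-, (0.4,0.1)+ -> 3/4
        assert roc_auc([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(10, 500))
            scores = rng.integers(0, 20, n).astype(float)  # force ties
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                continue
            assert roc_auc(scores, truth) == pytest.approx(
                pairwise_auc_oracle(scores, truth)
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.normal(size=300)
        truth = rng.integers(0, 2, 300)
        assert roc_auc(scores, truth) == pytest.approx(roc_auc_score(truth, scores))


def confusion_oracle(p, truth, cut):
    tp = fp = tn = fn = 0
    for pi, ti in zip(p, truth):
        called = pi <= cut
        if called and ti == 1:
            tp += 1
        elif called and ti == 0:
            fp += 1
        elif not called and ti == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestThresholdMetrics:
    def test_all_called_all_mutant(self):
        out = threshold_metrics([0.01, 0.02], [1, 1], thresholds=(0.1,))
        assert out["accuracy"].iloc[0] == 1.0
        assert out["fndr"].iloc[0] == 0.0  # no negatives called: convention

    def test_none_called(self):
        m, n = 3, 10
        p = [0.4] * n
        truth = [1] * m + [0] * (n - m)
        out = threshold_metrics(p, truth, thresholds=(0.1,))
        assert out["fndr"].iloc[0] == pytest.approx(m / n)
        assert out["accuracy"].iloc[0] == pytest.approx((n - m) / n)

    def test_matches_confusion_oracle(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 0.5, 200)
        truth = rng.integers(0, 2, 200)
        out = threshold_metrics(p, truth)
        for _, row in out.iterrows():
            tp, fp, tn, fn = confusion_oracle(p, truth, row["threshold"])
            assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (tp, fp, tn, fn)
            assert row["accuracy"] == pytest.approx((tp + tn) / 200)
            assert row["fndr"] == pytest.approx(fn / (fn + tn) if fn + tn else 0.0)

    def test_miss_rate_and_fpr_monotone_in_threshold(self):
        # loosening the cutoff can only convert FN->TP and TN->FP, so the
        # miss rate FN/(FN+TP) falls and the FPR rises; the ratio
        # FN/(FN+TN) has a moving denominator and is not monotone
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 0.5, 500)
        truth = rng.integers(0, 2, 500)
        out = threshold_metrics(p, truth, thresholds=np.linspace(0.01, 0.5, 25))
        assert (np.diff(out["miss_rate"]) <= 1e-12).all()
        assert (np.diff(out["fpr"]) >= -1e-12).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_metrics([0.1], [1], thresholds=())


def signed_rank_null_oracle(diffs):
    """Exhaustive two-sided signed-rank p-value over all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        np.sum([r for r, s in zip(ranks, signs) if s])
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    mean_w = n * (n + 1) / 4
    return np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)


class TestCompareMethods:
    def test_uniform_improvement_significant(self):
        rng = np.random.default_rng(15)
        b = rng.uniform(0.5, 0.9, 20)
        a = b + 0.05
        _, p = compare_methods(a, b)
        assert p < 0.01

    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning):
            _, p = compare_methods(np.ones(10), np.ones(10))
        assert p == 1.0

    def test_eight_pair_exhaustive_enumeration(self):
        # |differences| all distinct so the exact null has no rank ties
        a = np.array([0.80, 0.75, 0.90, 0.60, 0.85, 0.70, 0.95, 0.65])
        b = np.array([0.78, 0.771, 0.845, 0.552, 0.799, 0.723, 0.898, 0.601])
        _, p = compare_methods(a, b)
        assert p == pytest.approx(signed_rank_null_oracle(a - b))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            compare_methods([1, 2], [2, 3])


@pytest.fixture(scope="module")
def small_benchmark():
    cfg = BenchmarkConfig(
        base=SyntheticConfig(wt_mean=33.3, n_planting_groups=2),
        replicates=2,
        seed=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, run_benchmark(cfg)


class TestRunBenchmark:
    def test_shape_and_methods(self, small_benchmark):
        _, res = small_benchmark
        assert set(res.auc["method"]) == {"mipheno", "raw", "zscore"}
        assert res.auc.shape[0] == 4 * 2 * 3  # settings x replicates x methods
        assert res.metrics.shape[0] == 4 * 2 * 3 * 10

    def test_reproducible_from_seed(self, small_benchmark):
        cfg, res = small_benchmark
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = run_benchmark(cfg)
        pd.testing.assert_frame_equal(res.auc, again.auc)

    def test_batch_noise_hurts_raw_more_than_mipheno(self, small_benchmark):
        _, res = small_benchmark
        assert res.pooled_auc("raw") < res.pooled_auc("mipheno")

    def test_summary_mentions_all_methods(self, small_benchmark):
        _, res = small_benchmark
        text = res.summary()
        for m in ("mipheno", "raw", "zscore"):
            assert m in text


def test_no_batch_noise_makes_mipheno_equal_raw():
    """With zero offsets, normalization factors are ~1 and the mipheno and
    raw routes score identically up to QC no-ops."""
    from mipheno.data_model import GroupingSpec
    from mipheno.hits import score_table
    from mipheno.normalize import normalize
    from mipheno.qc import qc_filter
    from mipheno.simulate import simulate_dataset

    cfg = SyntheticConfig(seed=31, planting_amp=0.0, assay_amp=0.0)
    table, _ = simulate_dataset(cfg)
    spec = GroupingSpec.single("assay_group", ("response",))
    filtered, report = qc_filter(table, spec, cutoff=3.0)
    normed, factors = normalize(filtered, spec, min_group_size=1)
    # factors deviate from 1 only by group-median sampling noise (~sigma/mu/sqrt(n))
    assert factors["factor_applied"].to_numpy() == pytest.approx(1.0, abs=0.06)
    p_mip = score_table(normed)["p"].to_numpy()
    p_raw = score_table(table)["p"].to_numpy()
    keep = np.isfinite(p_mip)
    assert np.corrcoef(p_mip[keep], p_raw[keep])[0, 1] > 0.95
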