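import numpy as np
import pandas as pd
import pytest

from mipheno.data_model import AssayTable, GroupingSpec
from mipheno.fixtures import make_fixture
from mipheno.qc import qc_filter, qc_overview_plotdata, scaled_mad


def _single_value_groups(values):
    """One sample per group, so group medians equal the values."""
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(values))],
            "plate": [f"g{i}" for i in range(len(values))],
            "a": values,
        }
    )
    return AssayTable(df, factor_columns=("plate",), attribute_columns=("a",)), (
        GroupingSpec.single("plate", ("a",))
    )


def test_single_outlier_group_removed_at_cutoff_3():
    # group medians {10,10,10,10,100}: median of medians 10, MAD 0, so the
    # 100-group is infinitely deviant and the rest deviate by exactly 0.
    t, spec = _single_value_groups([10.0, 10.0, 10.0, 10.0, 100.0])
    with pytest.warns(UserWarning, match="MAD is zero"):
        out, report = qc_filter(t, spec, cutoff=3)
    removed = report[report["removed"]]
    assert list(removed["group"]) == ["g4"]
    assert out.data["a"].isna().tolist() == [False] * 4 + [True]


def test_group_on_global_median_retained():
    t, spec = _single_value_groups([10.0, 13.0, 9.0, 7.0, 11.0])
    out, report = qc_filter(t, spec, cutoff=3)
    on_median = report[report["group"] == "g0"]
    assert float(on_median["deviation_mads"].iloc[0]) == 0.0
    assert not bool(on_median["removed"].iloc[0])


def test_all_identical_group_medians_remove_nothing():
    t, spec = _single_value_groups([7.0, 7.0, 7.0, 7.0])
    with pytest.warns(UserWarning, match="MAD is zero"):
        _, report = qc_filter(t, spec, cutoff=3)
    assert not report["removed"].any()


def test_only_deviating_attribute_removed_other_attributes_kept():
    """A group failing QC for one metabolite keeps its other responses,
    mirroring the attribute-independence contract."""
    rng = np.random.default_rng(3)
    n_groups, n_per = 6, 10
    plates = np.repeat([f"h{i}" for i in range(n_groups)], n_per)
    ala = rng.normal(100, 3, n_groups * n_per)
    pro = rng.normal(40, 2, n_groups * n_per)
    ala[plates == "h0"] += 200.0  # gross shift of alanine on plate h0 only
    t = AssayTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(plates))],
                "plate": plates,
                "alanine": ala,
                "proline": pro,
            }
        ),
        factor_columns=("plate",),
        attribute_columns=("alanine", "proline"),
    )
    spec = GroupingSpec.single("plate", ("alanine", "proline"))
    out, report = qc_filter(t, spec, cutoff=3)
    removed = report[report["removed"]]
    assert set(zip(removed["group"], removed["attribute"])) == {("h0", "alanine")}
    mask = out.data["plate"] == "h0"
    assert out.data.loc[mask, "alanine"].isna().all()
    assert out.data.loc[mask, "proline"].notna().all()


def test_survivors_bitwise_identical(toy_table, toy_spec):
    out, _ = qc_filter(toy_table, toy_spec, cutoff=3)
    for col in toy_table.attribute_columns:
        a, b = toy_table.data[col], out.data[col]
        kept = b.notna()
        assert (a[kept].to_numpy() == b[kept].to_numpy()).all()


def test_second_pass_removes_nothing_new():
    frames = make_fixture("qc_outlier_block", seed=0)
    t = AssayTable(
        frames["table"],
        factor_columns=("plate",),
        attribute_columns=("attr1", "attr2"),
    )
    spec = GroupingSpec.single("plate", ("attr1", "attr2"))
    once, rep1 = qc_filter(t, spec, cutoff=3)
    twice, rep2 = qc_filter(once, spec, cutoff=3)
    assert rep1["removed"].sum() == 1
    assert not rep2["removed"].any()
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_attribute_independence_under_column_drop():
    frames = make_fixture("qc_outlier_block", seed=0)
    full = AssayTable(
        frames["table"], factor_columns=("plate",),
        attribute_columns=("attr1", "attr2"),
    )
    only1 = AssayTable(
        frames["table"].drop(columns="attr2"),
        factor_columns=("plate",), attribute_columns=("attr1",),
    )
    _, rep_full = qc_filter(full, GroupingSpec.single("plate", ("attr1", "attr2")), 3)
    _, rep_only = qc_filter(only1, GroupingSpec.single("plate", ("attr1",)), 3)
    f = rep_full[rep_full["attribute"] == "attr1"].set_index("group")["removed"]
    o = rep_only.set_index("group")["removed"]
    pd.testing.assert_series_equal(f, o)


def test_cutoff_must_be_positive(toy_table, toy_spec):
    with pytest.raises(ValueError):
        qc_filter(toy_table, toy_spec, cutoff=0)


def test_scaled_mad_gaussian_consistency():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 2.0, 20000)
    assert abs(scaled_mad(x) - 2.0) < 0.05


class TestOverviewPlotData:
    def test_five_number_summary(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(5)],
                "plate": ["g"] * 5,
                "a": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        t = AssayTable(df, factor_columns=("plate",), attribute_columns=("a",))
        out = qc_overview_plotdata(t, GroupingSpec.single("plate", ("a",)))
        row = out.iloc[0]
        assert row["median"] == 3 and row["q1"] == 2 and row["q3"] == 4

    def test_constant_group_degenerate(self):
        df = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "plate": ["g"] * 3, "a": [7.0] * 3}
        )
        t = AssayTable(df, factor_columns=("plate",), attribute_columns=("a",))
        row = qc_overview_plotdata(t, GroupingSpec.single("plate", ("a",))).iloc[0]
        assert {row[k] for k in ("whisker_low", "q1", "median", "q3", "whisker_high")} == {7.0}

    def test_drifting_groups_show_monotone_medians(self):
        rng = np.random.default_rng(9)
        rows = []
        for g in range(8):
            for i in range(25):
                rows.append(
                    {
                        "sample_id": f"s{g}_{i}",
                        "plate": f"g{g}",
                        "a": rng.normal(100 + 5 * g, 1.0),
                    }
                )
        t = AssayTable(
            pd.DataFrame(rows), factor_columns=("plate",), attribute_columns=("a",)
        )
        out = qc_overview_plotdata(t, GroupingSpec.single("plate", ("a",)))
        med = out.sort_values("group")["median"].to_numpy()
        assert (np.diff(med) > 0).all()
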