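"""Cohort records, I/O and descriptive/comparative statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sstats

from bridgeflow import (
    BVRecord,
    CohortValidationError,
    Group,
    InputError,
    StatsError,
    anova_oneway,
    pooled_mean,
    read_cohort,
    summarize,
    summary_table,
    write_cohort,
)
from bridgeflow.synthetic import default_config, generate_cohort


def _records():
    return [
        BVRecord("a1", Group.anterior, 2.0, 93.0),
        BVRecord("a2", Group.anterior, 1.4, 120.0),
        BVRecord("p1", Group.posterior, 3.1, 43.0),
    ]


def test_csv_roundtrip_is_identity(tmp_path):
    path = tmp_path / "cohort.csv"
    records = _records()
    write_cohort(records, path)
    back = read_cohort(path)
    assert back == records


@pytest.mark.parametrize(
    "row, exc, match",
    [
        ("x,anterior,2.0,185", CohortValidationError, "row 2"),
        ("x,anterior,-1.0,90", CohortValidationError, "row 2"),
        ("x,middle,2.0,90", InputError, "group"),
        ("x,anterior,abc,90", InputError, "non-numeric"),
    ],
)
def test_invalid_rows_are_rejected_naming_the_row(tmp_path, row, exc, match):
    path = tmp_path / "bad.csv"
    path.write_text("id,group,diameter_mm,entry_angle_deg\n" + row + "\n")
    with pytest.raises(exc, match=match):
        read_cohort(path)


def test_duplicate_ids_are_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "id,group,diameter_mm,entry_angle_deg\nv1,anterior,2,90\nv1,posterior,3,45\n"
    )
    with pytest.raises(InputError, match="duplicate"):
        read_cohort(path)


def test_default_cohort_emulates_the_anatomical_table(tmp_path):
    """137 veins: 62 anterior + 75 posterior, written and read back intact."""
    records = generate_cohort(default_config(seed=0))
    assert len(records) == 137
    assert sum(r.group is Group.anterior for r in records) == 62
    assert sum(r.group is Group.posterior for r in records) == 75
    path = tmp_path / "table1.csv"
    write_cohort(records, path)
    assert read_cohort(path) == records


def test_summarize_single_and_hand_case():
    one = summarize([BVRecord("v", Group.anterior, 2.0, 90.0)], "diameter", "anterior")
    assert (one.mean, one.sd, one.min, one.max, one.n) == (2.0, 0.0, 2.0, 2.0, 1)
    recs = [BVRecord(f"v{i}", Group.anterior, d, 90.0) for i, d in enumerate([1.0, 2.0, 3.0])]
    s = summarize(recs, "diameter", "anterior")
    assert (s.mean, s.sd, s.min, s.max) == (2.0, 1.0, 1.0, 3.0)


def test_summarize_total_combines_groups():
    records = _records()
    total = summarize(records, "diameter", "total")
    ant = summarize(records, "diameter", "anterior")
    post = summarize(records, "diameter", "posterior")
    assert total.n == ant.n + post.n
    assert total.min == min(ant.min, post.min)
    assert total.max == max(ant.max, post.max)
    assert total.mean == pytest.approx(
        pooled_mean([ant.mean, post.mean], [ant.n, post.n])
    )


def test_summarize_empty_selection_raises():
    with pytest.raises(StatsError):
        summarize([BVRecord("v", Group.anterior, 2.0, 90.0)], "diameter", "posterior")


def test_summary_table_rounds_to_printed_precision():
    table = summary_table(generate_cohort(default_config(seed=3)))
    ant_d = table[(table.group == "anterior") & (table.variable == "diameter")].iloc[0]
    assert ant_d["n"] == 62
    assert float(ant_d["mean"]) == round(float(ant_d["mean"]), 1)
    ant_a = table[(table.group == "anterior") & (table.variable == "entry_angle")].iloc[0]
    assert float(ant_a["mean"]) == int(ant_a["mean"])


def test_pooled_mean_reproduces_the_total_angle_row():
    # anterior 93 deg (n=62), posterior 43 deg (n=75) -> printed total 66 deg
    total = pooled_mean([93.0, 43.0], [62, 75])
    assert total == pytest.approx(65.63, abs=0.005)
    assert round(total) == 66


def test_pooled_mean_identity_and_hand_case():
    assert pooled_mean([5.0, 5.0], [10, 10]) == 5.0
    assert pooled_mean([1.0, 3.0], [1, 3]) == 2.5
    assert pooled_mean([4.0], [7]) == 4.0
    with pytest.raises(InputError):
        pooled_mean([1.0, 2.0], [1])


def test_anova_identical_groups_gives_f_zero():
    f, p = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_two_groups_equals_squared_t():
    a = [1.2, 1.9, 2.8, 3.1]
    b = [2.5, 3.6, 4.0, 4.9, 5.5]
    f, p_f = anova_oneway([a, b])
    t, p_t = sstats.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t * t, rel=1e-12)
    assert p_f == pytest.approx(p_t, rel=1e-12)


def test_anova_matches_textbook_ss_decomposition():
    groups = [[1.0, 2.0], [5.0, 6.0], [9.0, 10.0]]
    flat = [v for g in groups for v in g]
    grand = np.mean(flat)
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - np.mean(g)) ** 2 for v in g) for g in groups)
    k, n = len(groups), len(flat)
    f_ref = (ssb / (k - 1)) / (ssw / (n - k))
    p_ref = sstats.f.sf(f_ref, k - 1, n - k)
    f, p = anova_oneway(groups)
    assert f == pytest.approx(f_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-12)


def test_anova_invariances():
    groups = [[1.0, 2.0, 4.0], [2.5, 3.5, 5.0], [0.5, 1.5, 2.0]]
    f0, p0 = anova_oneway(groups)
    f1, p1 = anova_oneway(groups[::-1])  # relabeling
    f2, p2 = anova_oneway([[v + 7.3 for v in g] for g in groups])  # shift
    assert (f1, p1) == pytest.approx((f0, p0), rel=1e-10)
    assert (f2, p2) == pytest.approx((f0, p0), rel=1e-10)


def test_anova_degenerate_inputs_raise():
    with pytest.raises(StatsError):
        anova_oneway([[1.0, 2.0]])
    with pytest.raises(StatsError):
        anova_oneway([[1.0], [2.0, 3.0]])
    with pytest.raises(StatsError):
        anova_oneway([[2.0, 2.0], [3.0, 3.0]])
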