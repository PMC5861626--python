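"""Sweep orchestration, demarcation detection and the findings tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgeflow import (
    BVRecord,
    Group,
    InputError,
    MinWSS,
    RunConfig,
    StableValue,
    WallLabel,
    classify_angle_groups,
    compare_anterior_posterior,
    demarcation_threshold,
    morphology_cuts,
    predilection_extent,
    ratio_percent,
)
from bridgeflow.sweep import (
    ModelResult,
    SweepResult,
    analyze_model,
    findings,
    load_sweep,
    save_sweep,
    stratified_subset,
)
from bridgeflow.synthetic import default_config, generate_cohort
from helpers import make_result





def test_demarcation_on_the_constructed_minima_set():
    th = demarcation_threshold([0.005, 0.008, 0.010, 0.3, 0.4])
    assert th.found
    assert th.pair == (0.010, 0.3)
    assert th.wss_demarcation == pytest.approx(math.sqrt(0.010 * 0.3), rel=1e-12)
    assert th.wss_demarcation == pytest.approx(0.0548, abs=5e-5)


def test_flat_minima_have_no_demarcation():
    th = demarcation_threshold([1.0, 1.0, 1.0])
    assert not th.found
    assert th.wss_demarcation is None


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=1e-6, max_value=1e6))
def test_demarcation_is_scale_equivariant(c):
    base = [0.005, 0.008, 0.010, 0.3, 0.4]
    th1 = demarcation_threshold(base)
    th2 = demarcation_threshold([c * v for v in base])
    assert th2.wss_demarcation == pytest.approx(c * th1.wss_demarcation, rel=1e-9)


def test_demarcation_input_guards():
    with pytest.raises(InputError):
        demarcation_threshold([0.1, 0.2])
    with pytest.raises(InputError):
        demarcation_threshold([0.0, 0.1, 0.2])


@pytest.mark.parametrize(
    "num, den, expected", [(0.005, 0.008, 63.0), (0.4, 0.4, 100.0), (0.2, 0.4, 50.0)]
)
def test_ratio_percent_rounds_half_up(num, den, expected):
    assert ratio_percent(num, den) == expected


def test_ratio_percent_rejects_nonpositive_denominator():
    with pytest.raises(InputError):
        ratio_percent(1.0, 0.0)


def test_predilection_extent():
    assert predilection_extent([2.9, 13.5, 0.3]) == pytest.approx(27.0)
    assert predilection_extent([0.0, 0.0]) == 0.0
    assert predilection_extent([1.0, 2.0, 3.0]) == 6.0


def test_morphology_cuts_recover_the_harmful_pattern():
    """Synthetic sweep obeying the reported rules: depressed minima only for
    d > 1.2 mm with SSD affected below 105 deg and BVU below 65 deg."""
    results = []
    rid = 0
    for d in (0.8, 1.2, 2.0, 3.0, 4.0):
        for a in (43.0, 90.0, 130.0):
            ssd = 0.008 if (d > 1.2 and a < 105.0) else 0.3
            bvu = 0.005 if (d > 1.2 and a < 65.0) else 0.4
            results.append(make_result(f"m{rid}", "anterior", d, a, ssd, bvu))
            rid += 1
    cuts = morphology_cuts(results, threshold=0.017)
    assert cuts.diameter_cut == 1.2
    assert cuts.angle_cut_ssd == 130.0  # smallest sampled angle always above
    assert cuts.angle_cut_bvu == 90.0


def test_angle_group_table_counts_and_floor():
    results = [
        make_result("a", "anterior", 0.9, 43.0, 0.3, 0.3),  # excluded: small vein
        make_result("b", "anterior", 2.0, 43.0, 0.008, 0.005),
        make_result("c", "anterior", 2.0, 65.0, 0.009, 0.006),  # boundary -> low bin
        make_result("d", "anterior", 2.0, 66.0, 0.010, 0.2),
        make_result("e", "anterior", 2.0, 105.0, 0.011, 0.21),  # boundary -> mid bin
        make_result("f", "anterior", 2.0, 140.0, 0.33, 0.7),
    ]
    table = classify_angle_groups(results).table
    n = {g: int(table[(table.group == g) & (table.wall == "SSD")
                      & (table.metric == "min_value")].iloc[0]["n"])
         for g in ("(10,65]", "(65,105]", "(105,170]")}
    assert n == {"(10,65]": 2, "(65,105]": 2, "(105,170]": 1}
    # invariant to input ordering
    table2 = classify_angle_groups(results[::-1]).table
    assert table.sort_values(list(table.columns)).reset_index(drop=True).equals(
        table2.sort_values(list(table.columns)).reset_index(drop=True)
    )


def test_single_occupied_bin_is_degenerate_but_reported():
    results = [make_result(f"m{i}", "anterior", 2.0, 90.0, 0.01 + i * 1e-4, 0.2)
               for i in range(4)]
    gt = classify_angle_groups(results)
    mid = gt.table[(gt.table.group == "(65,105]") & (gt.table.metric == "min_value")]
    assert set(mid["n"]) == {4}
    empty = gt.table[(gt.table.group == "(10,65]")]
    assert set(empty["n"]) == {0}
    assert gt.anova == {}  # fewer than two populated bins


def test_group_comparison_flags_constructed_separation():
    rng = np.random.default_rng(0)
    results = []
    for i in range(10):
        v = 0.4 + 0.02 * rng.standard_normal()
        results.append(make_result(f"a{i}", "anterior", 2.0, 100.0, v, v))
    for i in range(10):
        v = 0.2 + 0.01 * rng.standard_normal()
        results.append(make_result(f"p{i}", "posterior", 3.0, 45.0, v, v, ssd_pos=9.0))
    gt = compare_anterior_posterior(results)
    t = gt.table
    mean = lambda g, w: float(t[(t.group == g) & (t.wall == w)
                                & (t.metric == "min_value")].iloc[0]["mean"])
    assert mean("posterior", "BVU") < mean("anterior", "BVU")
    f, p = gt.anova[("BVU", "min_value")]
    assert p < 0.01
    assert {"anterior", "posterior", "total"} <= set(t.group)


def test_group_comparison_requires_both_groups():
    results = [make_result("a", "anterior", 2.0, 90.0, 0.1, 0.1)]
    with pytest.raises(InputError):
        compare_anterior_posterior(results)


def test_identical_groups_are_not_significant():
    rng = np.random.default_rng(1)
    results = []
    for grp in ("anterior", "posterior"):
        for i in range(8):
            v = 0.3 + 0.02 * rng.standard_normal()
            results.append(make_result(f"{grp}{i}", grp, 2.0, 90.0, v, v))
    # same generating distribution: F should be small, p large
    _, p = compare_anterior_posterior(results).anova[("SSD", "min_value")]
    assert p > 0.05


def test_stratified_subset_is_deterministic_and_small():
    cohort = generate_cohort(default_config(seed=4))
    sub = stratified_subset(cohort)
    assert len(sub) <= 12
    assert sub == stratified_subset(list(reversed(cohort)))
    assert len({r.id for r in sub}) == len(sub)


def test_sweep_results_serialize_roundtrip(tmp_path):
    results = [make_result("a", "anterior", 2.0, 90.0, 0.1, 0.2),
               make_result("b", "posterior", 3.0, 45.0, 0.01, 0.02)]
    results[0].stable["SSU"] = None
    results[0].minima["SSU"] = None
    results[0].notes["SSU"] = "window empty"
    sweep = SweepResult(results, [("c", "geometry error")])
    path = tmp_path / "sweep.json"
    save_sweep(sweep, path)
    back = load_sweep(path)
    assert back.results == results
    assert back.failures == [("c", "geometry error")]


def test_findings_summarize_a_constructed_sweep():
    results = []
    for i, (d, a, ssd, bvu, bpos) in enumerate([
        (0.9, 120.0, 0.31, 0.42, 0.5),
        (1.0, 100.0, 0.35, 0.40, 0.2),
        (2.0, 43.0, 0.008, 0.005, 13.5),
        (3.0, 50.0, 0.007, 0.004, 2.9),
        (4.0, 60.0, 0.009, 0.006, 1.0),
    ]):
        grp = "posterior" if a < 65 else "anterior"
        results.append(make_result(f"m{i}", grp, d, a, ssd, bvu, bvu_pos=bpos))
    doc = findings(SweepResult(results, []))
    assert doc["n_models"] == 5
    assert doc["demarcation_pa"] is not None
    assert 0.004 < doc["demarcation_pa"] < 0.31
    assert doc["diameter_cut_mm"] == 1.0
    assert doc["predilection_extent_mm"] == pytest.approx(27.0)
    # in the shallow-angle harmful group, BVU minima sit below SSD minima
    assert doc["bvu_ssd_ratio_percent"] == ratio_percent(
        np.mean([0.005, 0.004, 0.006]), np.mean([0.008, 0.007, 0.009])
    )


def test_per_model_pipeline_is_deterministic():
    cfg = RunConfig.desk_scale()
    cfg = cfg.model_copy(update={
        "geometry": cfg.geometry.model_copy(update={"l_up": 8.0, "l_down": 10.0,
                                                    "l_bv": 5.0}),
        "solver": cfg.solver.model_copy(update={"max_iterations": 6000,
                                                "avg_steps": 2000}),
        "analysis": cfg.analysis.model_copy(update={"inlet_exclusion_widths": 0.0,
                                                    "entrance_exclusion_spans": 0.5}),
    })
    rec = BVRecord("tiny", Group.anterior, 2.0, 135.0)
    r1 = analyze_model(rec, cfg)
    r2 = analyze_model(rec, cfg)
    assert r1 == r2
    assert set(r1.minima) == {w.value for w in WallLabel}
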