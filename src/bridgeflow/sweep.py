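"""Per-vein model sweep and the thrombosis-morphology findings.

Runs the geometry -> flow -> WSS pipeline for each bridging-vein record and
reproduces the study's analysis surface: the demarcation threshold separating
sharply depressed WSS minima from the rest, the angle-group and
anterior/posterior comparison tables, the vein/sinus minimum ratio and the
predilection extent.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import BVRecord, Group, anova_oneway
from .config import RunConfig
from .errors import AnalysisError, BridgeflowError, InputError, StatsError
from .geometry import WallLabel, build_geometry, rasterize
from .lbm import solve_steady
from .wss import MinWSS, StableValue, min_wss, stable_value, wall_shear_profile

__all__ = [
    "ModelResult",
    "SweepResult",
    "ThresholdResult",
    "GroupTable",
    "reference_subset",
    "stratified_subset",
    "run_sweep",
    "analyze_model",
    "demarcation_threshold",
    "morphology_cuts",
    "classify_angle_groups",
    "compare_anterior_posterior",
    "ratio_percent",
    "predilection_extent",
    "findings",
    "save_sweep",
    "load_sweep",
]

ANGLE_BIN_NAMES = ("(10,65]", "(65,105]", "(105,170]")


@dataclass
class ModelResult:
    """Per-wall stable values and minima for one vein model."""

    record_id: str
    group: str
    d_bv: float
    alpha: float
    converged: bool
    stable: dict[str, StableValue | None] = field(default_factory=dict)
    minima: dict[str, MinWSS | None] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def min_value(self, wall: str) -> float | None:
        m = self.minima.get(wall)
        return None if m is None else m.value

    def min_position(self, wall: str) -> float | None:
        m = self.minima.get(wall)
        return None if m is None else m.position


@dataclass
class SweepResult:
    results: list[ModelResult]
    failures: list[tuple[str, str]]  # (record_id, reason)


@dataclass(frozen=True)
class ThresholdResult:
    """Demarcation threshold and the morphology cuts derived from it."""

    found: bool
    wss_demarcation: float | None = None
    pair: tuple[float, float] | None = None
    diameter_cut: float | None = None
    angle_cut_ssd: float | None = None
    angle_cut_bvu: float | None = None


@dataclass
class GroupTable:
    """Summary table (one row per group x wall x metric) with ANOVA p-values."""

    table: pd.DataFrame
    anova: dict[tuple[str, str], tuple[float, float]]  # (wall, metric) -> (F, p)


def reference_subset() -> list[BVRecord]:
    """Stratified 12-model grid: d_bv in {1, 2, 3, 4.5} mm x alpha in {43, 90, 135} deg.

    Groups are assigned by angle (shallow angles are characteristic of
    posterior veins), which only matters for the group-comparison table.
    """
    records = []
    for d in (1.0, 2.0, 3.0, 4.5):
        for a in (43.0, 90.0, 135.0):
            grp = Group.posterior if a < 65 else Group.anterior
            records.append(BVRecord(f"ref_d{d:g}_a{a:g}", grp, d, a))
    return records


def stratified_subset(
    records: Sequence[BVRecord],
    diameter_edges: Sequence[float] = (0.0, 1.5, 2.5, 3.5, 10.0),
    angle_edges: Sequence[float] = (0.0, 65.0, 105.0, 180.0),
) -> list[BVRecord]:
    """One representative per occupied (diameter bin x angle bin) cell.

    The representative is the record closest to its cell centroid, so a full
    cohort reduces to a deterministic desk-scale subset.
    """
    chosen: dict[tuple[int, int], BVRecord] = {}
    best: dict[tuple[int, int], float] = {}
    for r in records:
        i = int(np.searchsorted(diameter_edges, r.diameter_mm) - 1)
        j = int(np.searchsorted(angle_edges, r.entry_angle_deg) - 1)
        cell = [r2 for r2 in records
                if diameter_edges[i] < r2.diameter_mm <= diameter_edges[i + 1]
                and angle_edges[j] < r2.entry_angle_deg <= angle_edges[j + 1]]
        cd = float(np.mean([c.diameter_mm for c in cell]))
        ca = float(np.mean([c.entry_angle_deg for c in cell]))
        dist = ((r.diameter_mm - cd) / max(cd, 1e-9)) ** 2 + (
            (r.entry_angle_deg - ca) / max(ca, 1e-9)
        ) ** 2
        if (i, j) not in best or dist < best[(i, j)]:
            best[(i, j)] = dist
            chosen[(i, j)] = r
    return [chosen[k] for k in sorted(chosen)]


def analyze_model(record: BVRecord, config: RunConfig) -> ModelResult:
    """Geometry -> steady flow -> per-wall WSS statistics for one vein."""
    geo = build_geometry(
        config.geometry.d_ss, record.diameter_mm, record.entry_angle_deg,
        config.geometry.lengths,
    )
    mask = rasterize(geo, config.geometry.spacing_for(record.diameter_mm))
    fld = solve_steady(mask, config.boundary.to_conditions(),
                       config.fluid.to_properties(), config.solver.to_config())
    result = ModelResult(
        record_id=record.id, group=record.group.value,
        d_bv=record.diameter_mm, alpha=record.entry_angle_deg,
        converged=fld.converged,
    )
    for label in geo.walls:
        profile = wall_shear_profile(fld, geo.walls[label])
        try:
            result.minima[label.value] = min_wss(profile)
        except AnalysisError as exc:
            result.minima[label.value] = None
            result.notes[label.value] = str(exc)
        try:
            result.stable[label.value] = stable_value(
                profile, geo,
                inlet_widths=config.analysis.inlet_exclusion_widths,
                entrance_spans=config.analysis.entrance_exclusion_spans,
            )
        except AnalysisError as exc:
            result.stable[label.value] = None
            result.notes.setdefault(label.value, str(exc))
    return result


def run_sweep(
    records: Sequence[BVRecord],
    config: RunConfig | None = None,
    progress: bool = True,
) -> SweepResult:
    """Run the pipeline for every record; failures are collected, not dropped.

    Deterministic under a fixed config. Raises only if *every* model fails.
    """
    config = config or RunConfig.desk_scale()
    results: list[ModelResult] = []
    failures: list[tuple[str, str]] = []
    for k, rec in enumerate(records):
        try:
            res = analyze_model(rec, config)
            results.append(res)
            if progress:
                print(
                    f"[{k + 1}/{len(records)}] {rec.id}: d={rec.diameter_mm:g} mm, "
                    f"alpha={rec.entry_angle_deg:g} deg, converged={res.converged}",
                    file=sys.stderr,
                )
        except BridgeflowError as exc:
            failures.append((rec.id, str(exc)))
            if progress:
                print(f"[{k + 1}/{len(records)}] {rec.id}: FAILED ({exc})", file=sys.stderr)
    if records and not results:
        raise BridgeflowError(f"all {len(records)} models failed; first: {failures[0][1]}")
    return SweepResult(results, failures)


def demarcation_threshold(minima: Sequence[float], min_ratio: float = 2.0) -> ThresholdResult:
    """Demarcation in a set of per-model WSS minima.

    Sorts ascending, finds the adjacent pair with the largest ratio and
    places the demarcation at the pair's geometric mean. If the maximal
    ratio is below ``min_ratio`` there is no clear demarcation and the
    result says so explicitly (``found=False``) rather than inventing one.
    Scale-equivariant: scaling all minima by c scales the demarcation by c.
    """
    vals = np.sort(np.asarray([v for v in minima if v is not None], dtype=float))
    if vals.size < 3:
        raise InputError("need at least three minima")
    if np.any(vals <= 0):
        raise InputError("minima must be positive")
    ratios = vals[1:] / vals[:-1]
    k = int(np.argmax(ratios))
    if ratios[k] < min_ratio:
        return ThresholdResult(found=False)
    lo, hi = float(vals[k]), float(vals[k + 1])
    return ThresholdResult(found=True, wss_demarcation=float(math.sqrt(lo * hi)), pair=(lo, hi))


def morphology_cuts(
    results: Sequence[ModelResult],
    threshold: float,
    walls: tuple[str, str] = ("SSD", "BVU"),
) -> ThresholdResult:
    """Diameter/angle cuts below/above which minima stay above ``threshold``.

    * ``diameter_cut``: largest diameter d such that every model with
      ``d_bv <= d`` keeps both walls' minima above the threshold.
    * ``angle_cut_*``: per wall, the smallest angle a such that every model
      with ``alpha >= a`` (diameter above the cut) stays above the threshold.
    """
    ok = [r for r in results if all(r.min_value(w) is not None for w in walls)]

    def above(r: ModelResult, wall_set) -> bool:
        return all(r.min_value(w) > threshold for w in wall_set)

    diameter_cut = None
    for d in sorted({r.d_bv for r in ok}):
        if all(above(r, walls) for r in ok if r.d_bv <= d):
            diameter_cut = d
        else:
            break
    floor = diameter_cut if diameter_cut is not None else 0.0
    cuts = {}
    for w in walls:
        cut = None
        for a in sorted({r.alpha for r in ok}, reverse=True):
            if all(above(r, (w,)) for r in ok if r.alpha >= a and r.d_bv > floor):
                cut = a
            else:
                break
        cuts[w] = cut
    return ThresholdResult(
        found=True, wss_demarcation=threshold, diameter_cut=diameter_cut,
        angle_cut_ssd=cuts.get("SSD"), angle_cut_bvu=cuts.get("BVU"),
    )


def _summary_rows(
    grouped: dict[str, list[ModelResult]],
    walls: tuple[str, ...] = ("SSD", "BVU"),
) -> tuple[pd.DataFrame, dict]:
    rows = []
    anova: dict[tuple[str, str], tuple[float, float]] = {}
    for wall in walls:
        for metric, getter in (("min_value", ModelResult.min_value),
                               ("position", ModelResult.min_position)):
            per_group = {}
            for name, members in grouped.items():
                vals = np.array([getter(r, wall) for r in members
                                 if getter(r, wall) is not None], dtype=float)
                per_group[name] = vals
                row = {"group": name, "wall": wall, "metric": metric, "n": int(vals.size)}
                if vals.size:
                    row.update(
                        mean=float(vals.mean()),
                        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        min=float(vals.min()), max=float(vals.max()),
                    )
                rows.append(row)
            usable = [v for v in per_group.values() if v.size >= 2]
            if len(usable) >= 2:
                try:
                    anova[(wall, metric)] = anova_oneway(usable)
                except StatsError:
                    pass
    cols = ["group", "wall", "metric", "n", "mean", "sd", "min", "max"]
    return pd.DataFrame(rows, columns=cols), anova


def classify_angle_groups(
    results: Sequence[ModelResult],
    diameter_floor: float = 1.2,
    cutpoints: tuple[float, float] = (65.0, 105.0),
) -> GroupTable:
    """Angle-bin table of SSD/BVU minima, excluding small-caliber veins.

    Veins with ``d_bv <= diameter_floor`` are excluded (they do not depress
    the WSS); the rest fall into half-open bins (lo, hi] at the cutpoints.
    """
    lo_cut, hi_cut = cutpoints
    if not lo_cut < hi_cut:
        raise InputError("cutpoints must be ordered")
    included = [r for r in results if r.d_bv > diameter_floor and r.converged]
    grouped: dict[str, list[ModelResult]] = {name: [] for name in ANGLE_BIN_NAMES}
    for r in included:
        if r.alpha <= lo_cut:
            grouped[ANGLE_BIN_NAMES[0]].append(r)
        elif r.alpha <= hi_cut:
            grouped[ANGLE_BIN_NAMES[1]].append(r)
        else:
            grouped[ANGLE_BIN_NAMES[2]].append(r)
    table, anova = _summary_rows(grouped)
    return GroupTable(table, anova)


def compare_anterior_posterior(results: Sequence[ModelResult]) -> GroupTable:
    """Anterior vs posterior table of SSD/BVU minima, with a recomputed total."""
    grouped = {
        "anterior": [r for r in results if r.group == "anterior" and r.converged],
        "posterior": [r for r in results if r.group == "posterior" and r.converged],
    }
    if not grouped["anterior"] or not grouped["posterior"]:
        raise InputError("both anterior and posterior groups must be non-empty")
    table, anova = _summary_rows(grouped)
    total, _ = _summary_rows({"total": grouped["anterior"] + grouped["posterior"]})
    return GroupTable(pd.concat([table, total], ignore_index=True), anova)


def ratio_percent(numerator: float, denominator: float) -> float:
    """100*numerator/denominator, rounded half-up to an integer percent."""
    if denominator <= 0:
        raise InputError("denominator must be positive")
    return float(math.floor(100.0 * numerator / denominator + 0.5))


def predilection_extent(positions: Sequence[float]) -> float:
    """Predilection extent: twice the farthest minimum position (mm)."""
    pos = [p for p in positions if p is not None]
    if not pos:
        raise InputError("need at least one position")
    return 2.0 * float(max(pos))


def findings(sweep: SweepResult, analysis=None) -> dict:
    """Headline findings of a sweep: demarcation, cuts, ratio, extent."""
    results = [r for r in sweep.results if r.converged]
    out: dict = {"n_models": len(results), "n_failures": len(sweep.failures)}
    for wall in ("SSD", "BVU"):
        vals = [r.min_value(wall) for r in results if r.min_value(wall)]
        if len(vals) >= 3:
            try:
                th = demarcation_threshold(vals)
                out[f"demarcation_{wall.lower()}"] = th.wss_demarcation if th.found else None
            except InputError:
                out[f"demarcation_{wall.lower()}"] = None
    pooled = [r.min_value(w) for r in results for w in ("SSD", "BVU") if r.min_value(w)]
    th = demarcation_threshold(pooled) if len(pooled) >= 3 else ThresholdResult(False)
    out["demarcation_pa"] = th.wss_demarcation if th.found else None
    if th.found:
        cuts = morphology_cuts(results, th.wss_demarcation)
        out["diameter_cut_mm"] = cuts.diameter_cut
        out["angle_cut_ssd_deg"] = cuts.angle_cut_ssd
        out["angle_cut_bvu_deg"] = cuts.angle_cut_bvu
    shallow = [r for r in results if r.alpha <= 65 and r.d_bv > 1.2]
    ssd = [r.min_value("SSD") for r in shallow if r.min_value("SSD")]
    bvu = [r.min_value("BVU") for r in shallow if r.min_value("BVU")]
    if ssd and bvu:
        out["bvu_ssd_ratio_percent"] = ratio_percent(
            float(np.mean(bvu)), float(np.mean(ssd))
        )
    positions = [r.min_position("BVU") for r in results if r.min_position("BVU") is not None]
    if positions:
        out["predilection_extent_mm"] = predilection_extent(positions)
    return out


# --- persistence -------------------------------------------------------------

def save_sweep(sweep: SweepResult, path: str | Path) -> None:
    """Serialize a sweep to JSON (plain dataclass dump)."""
    doc = {
        "results": [
            {
                **{k: v for k, v in asdict(r).items() if k not in ("stable", "minima")},
                "stable": {k: (asdict(v) if v else None) for k, v in r.stable.items()},
                "minima": {k: (asdict(v) if v else None) for k, v in r.minima.items()},
            }
            for r in sweep.results
        ],
        "failures": sweep.failures,
    }
    Path(path).write_text(json.dumps(doc, indent=1, default=str) + "\n")


def load_sweep(path: str | Path) -> SweepResult:
    doc = json.loads(Path(path).read_text())
    results = []
    for r in doc["results"]:
        results.append(
            ModelResult(
                record_id=r["record_id"], group=r["group"], d_bv=r["d_bv"],
                alpha=r["alpha"], converged=r["converged"],
                stable={k: (StableValue(WallLabel(v["wall"]), v["value"],
                                        tuple(v["extent"])) if v else None)
                        for k, v in r["stable"].items()},
                minima={k: (MinWSS(WallLabel(v["wall"]), v["value"], v["position"],
                                   v.get("uncertainty", 0.0))
                            if v else None)
                        for k, v in r["minima"].items()},
                notes=r.get("notes", {}),
            )
        )
    failures = [tuple(f) for f in doc.get("failures", [])]
    return SweepResult(results, failures)
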