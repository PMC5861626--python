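"""Anatomical bridging-vein cohort: records, CSV I/O and descriptive statistics.

A cohort is a list of :class:`BVRecord`, one per measured bridging vein (BV)
entering the superior sagittal sinus (SSS). Each record carries the two
morphological parameters that drive the hemodynamic model: the vein diameter
(mm) and the entry angle (degrees) between the vein and the sinus axis at the
dural entrance. Veins are grouped by where they enter the sinus (anterior or
posterior segment).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import CohortValidationError, InputError, StatsError

__all__ = [
    "Group",
    "Variable",
    "BVRecord",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "summarize",
    "summary_table",
    "pooled_mean",
    "anova_oneway",
]

COHORT_HEADER = ["id", "group", "diameter_mm", "entry_angle_deg"]


class Group(str, Enum):
    """Longitudinal position of the dural entrance along the sinus."""

    anterior = "anterior"
    posterior = "posterior"


class Variable(str, Enum):
    diameter = "diameter"
    entry_angle = "entry_angle"


@dataclass(frozen=True)
class BVRecord:
    """One measured bridging vein.

    Invariants: ``diameter_mm > 0`` and ``0 < entry_angle_deg < 180``.
    """

    id: str
    group: Group
    diameter_mm: float
    entry_angle_deg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        if not self.diameter_mm > 0:
            raise CohortValidationError(
                f"record {self.id!r}: diameter must be positive, got {self.diameter_mm}"
            )
        if not 0 < self.entry_angle_deg < 180:
            raise CohortValidationError(
                f"record {self.id!r}: entry angle must lie in (0, 180) degrees, "
                f"got {self.entry_angle_deg}"
            )

    def value(self, variable: Variable | str) -> float:
        variable = Variable(variable)
        return self.diameter_mm if variable is Variable.diameter else self.entry_angle_deg


@dataclass(frozen=True)
class CohortSummary:
    """mean ± sd (min–max) style summary of one variable in one group."""

    group: str  # "anterior", "posterior" or "total"
    variable: Variable
    n: int
    mean: float
    sd: float
    min: float
    max: float


def read_cohort(path: str | Path) -> list[BVRecord]:
    """Read a cohort CSV (header ``id,group,diameter_mm,entry_angle_deg``).

    Raises :class:`InputError` on structural problems (missing columns,
    duplicate ids, unknown group) and :class:`CohortValidationError`, naming
    the row, when a value violates a record invariant.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    records: list[BVRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != COHORT_HEADER:
            raise InputError(
                f"cohort CSV must have header {','.join(COHORT_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            rid = (row["id"] or "").strip()
            if not rid:
                raise InputError(f"row {lineno}: missing id")
            if rid in seen:
                raise InputError(f"row {lineno}: duplicate id {rid!r}")
            seen.add(rid)
            try:
                group = Group(row["group"].strip())
            except ValueError:
                raise InputError(
                    f"row {lineno}: group must be 'anterior' or 'posterior', "
                    f"got {row['group']!r}"
                ) from None
            try:
                diameter = float(row["diameter_mm"])
                angle = float(row["entry_angle_deg"])
            except (TypeError, ValueError):
                raise InputError(f"row {lineno}: non-numeric diameter or angle") from None
            try:
                records.append(BVRecord(rid, group, diameter, angle))
            except CohortValidationError as exc:
                raise CohortValidationError(f"row {lineno}: {exc}") from None
    return records


def write_cohort(records: Iterable[BVRecord], path: str | Path) -> None:
    """Write records as the canonical cohort CSV (deterministic formatting)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_HEADER)
        for rec in records:
            # repr gives the shortest exact decimal, so read(write(x)) == x
            writer.writerow(
                [rec.id, rec.group.value, repr(rec.diameter_mm), repr(rec.entry_angle_deg)]
            )


def _select(records: Sequence[BVRecord], group: Group | str | None) -> list[BVRecord]:
    if group is None or group == "total":
        return list(records)
    group = Group(group)
    return [r for r in records if r.group is group]


def summarize(
    records: Sequence[BVRecord],
    variable: Variable | str,
    group: Group | str | None = "total",
) -> CohortSummary:
    """n, mean, sample SD (n−1), min and max of one variable in one group."""
    variable = Variable(variable)
    chosen = _select(records, group)
    if not chosen:
        raise StatsError(f"no records in group {group!r}")
    values = np.array([r.value(variable) for r in chosen], dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return CohortSummary(
        group="total" if group in (None, "total") else Group(group).value,
        variable=variable,
        n=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        min=float(values.min()),
        max=float(values.max()),
    )


def summary_table(records: Sequence[BVRecord]):
    """Cohort summary as a DataFrame mirroring the anatomical table layout.

    Means/SDs are rounded to 1 decimal for diameters (mm) and to integer
    degrees for angles, the printed precision of the source table.
    """
    import pandas as pd

    rows = []
    for grp in ["anterior", "posterior", "total"]:
        for var in Variable:
            try:
                s = summarize(records, var, grp)
            except StatsError:
                continue
            nd = 1 if var is Variable.diameter else 0
            rows.append(
                {
                    "group": grp,
                    "variable": var.value,
                    "n": s.n,
                    "mean": round(s.mean, nd) if nd else int(round(s.mean)),
                    "sd": round(s.sd, nd) if nd else int(round(s.sd)),
                    "min": s.min,
                    "max": s.max,
                }
            )
    return pd.DataFrame(rows, columns=["group", "variable", "n", "mean", "sd", "min", "max"])


def pooled_mean(group_means: Sequence[float], group_sizes: Sequence[int]) -> float:
    """Size-weighted average of group means."""
    if len(group_means) != len(group_sizes):
        raise InputError("group_means and group_sizes must have equal length")
    if not group_means:
        raise InputError("need at least one group")
    sizes = np.asarray(group_sizes, dtype=float)
    if np.any(sizes < 1):
        raise InputError("group sizes must be >= 1")
    means = np.asarray(group_means, dtype=float)
    return float(np.sum(means * sizes) / np.sum(sizes))


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classic (equal-variance) one-way ANOVA.

    Returns ``(F, p)`` with p from the F distribution on (k−1, N−k) degrees
    of freedom. Requires at least two groups of at least two values and a
    nonzero pooled within-group variance.
    """
    if len(groups) < 2:
        raise StatsError("one-way ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("each group needs at least two values")
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if ssw == 0.0:
        raise StatsError("zero within-group variance in every group")
    f, p = _sstats.f_oneway(*arrays)
    return float(f), float(p)
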