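"""Wall shear stress extraction and profile analysis.

The pointwise wall shear stress is the magnitude of the tangential viscous
traction, tau = mu * |du_t/dn|, evaluated at wall sample points by a
one-sided second-order finite difference into the fluid: with the no-slip
value u_t = 0 on the wall and bilinear velocity samples at 0.5 h and 1.5 h
along the inward normal, the derivative of the interpolating parabola at the
wall is (9 u1 - u2) / (3 h). This is exact for parabolic (plane-Poiseuille)
profiles.

Profile statistics follow the source study's reading of the junction flow:

* the *stable value* is the plateau WSS level a wall settles to away from
  its vessel's inlet and from the junction — estimated as the median of tau
  after excluding a developing-flow zone near the inlet and a junction zone
  near the dural entrance;
* the *minimum* is the global minimum of tau over the profile (junction
  region included — the deficits of interest live there), with its position
  reported as the unsigned arc-length distance to the dural entrance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, InputError
from .geometry import JunctionGeometry, WallLabel, WallPolyline
from .lbm import FlowField

__all__ = [
    "WSSProfile",
    "StableValue",
    "MinWSS",
    "wall_shear_profile",
    "average_wss",
    "stable_value",
    "min_wss",
    "extent_below",
]

END_TRIM_SPACINGS = 2.0  # profile exclusion near inlet/outlet faces


@dataclass
class WSSProfile:
    """WSS vs arc length for one wall.

    ``s`` ascends; ``tau >= 0``; ``exclusions`` are (s_lo, s_hi) intervals
    (open-face neighbourhoods) omitted from minimum statistics.
    """

    wall: WallLabel
    s: np.ndarray  # mm
    tau: np.ndarray  # Pa
    exclusions: list[tuple[float, float]] = field(default_factory=list)
    spacing: float = 0.0  # sample spacing, mm

    def included(self) -> np.ndarray:
        keep = np.ones(self.s.shape, dtype=bool)
        for lo, hi in self.exclusions:
            keep &= ~((self.s >= lo) & (self.s <= hi))
        return keep

    def position(self) -> np.ndarray:
        """Unsigned distance to the dural-entrance anchor."""
        return np.abs(self.s)


@dataclass(frozen=True)
class StableValue:
    wall: WallLabel
    value: float  # Pa
    extent: tuple[float, float]  # s-window the plateau was estimated over


@dataclass(frozen=True)
class MinWSS:
    """Discrete profile minimum with its sampling uncertainty.

    Where the tangential traction changes sign (separation / reattachment),
    the continuum minimum of |tau| is exactly zero between two samples; the
    sampled minimum then reflects the local slope times the sample offset.
    ``uncertainty`` is the largest neighbour-sample gap at the minimum — a
    bound on that discretization error. Minima differing by less than their
    combined uncertainties are indistinguishable.
    """

    wall: WallLabel
    value: float  # Pa
    position: float  # mm, |s| at the minimum
    uncertainty: float = 0.0  # Pa


def wall_shear_profile(field_: FlowField, wall: WallPolyline) -> WSSProfile:
    """Extract tau(s) along ``wall`` from a solved flow field."""
    mask = field_.mask
    h = mask.spacing
    if wall.length < 2 * h:
        raise InputError(f"wall {wall.label.value} shorter than two grid spacings")
    s = wall.sample(h)
    pts = wall.point_at(s)
    nhat = np.asarray(wall.normal)
    that = np.asarray(wall.tangent)
    u1 = field_.sample_velocity(pts + 0.5 * h * nhat) @ that
    u2 = field_.sample_velocity(pts + 1.5 * h * nhat) @ that
    h_m = h * 1e-3
    tau = field_.fluid.viscosity * np.abs(9.0 * u1 - u2) / (3.0 * h_m)

    exclusions: list[tuple[float, float]] = []
    trim = END_TRIM_SPACINGS * h
    if "start" in wall.open_ends:
        exclusions.append((wall.s0, wall.s0 + trim))
    if "end" in wall.open_ends:
        exclusions.append((wall.s1 - trim, wall.s1))
    order = np.argsort(s)
    return WSSProfile(wall.label, s[order], tau[order], exclusions, spacing=h)


def average_wss(profile: WSSProfile, interval: tuple[float, float]) -> float:
    """Length-weighted mean of tau over ``interval`` (trapezoidal)."""
    lo, hi = min(interval), max(interval)
    s, tau = profile.s, profile.tau
    lo = max(lo, float(s[0]))
    hi = min(hi, float(s[-1]))
    if not lo < hi:
        raise InputError("interval does not overlap the profile")
    grid = np.unique(np.concatenate([[lo, hi], s[(s > lo) & (s < hi)]]))
    vals = np.interp(grid, s, tau)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def stable_value(
    profile: WSSProfile,
    geometry: JunctionGeometry,
    inlet_widths: float = 5.0,
    entrance_spans: float = 3.0,
) -> StableValue:
    """Plateau WSS of a wall: median of tau over the surviving window.

    Excluded: (a) within ``inlet_widths`` local channel widths of the wall's
    own vessel inlet, and (b) within ``entrance_spans`` BV-mouth spans of the
    dural entrance. Raises :class:`AnalysisError` naming the violated
    exclusion when nothing survives.
    """
    wall = geometry.walls[profile.wall]
    keep = profile.included()
    if wall.inlet_end is not None and inlet_widths > 0:
        d = inlet_widths * wall.channel_width
        if wall.inlet_end == "start":
            keep &= profile.s >= wall.s0 + d
        else:
            keep &= profile.s <= wall.s1 - d
        if not keep.any():
            raise AnalysisError(
                f"{profile.wall.value}: inlet exclusion ({inlet_widths} widths = {d:.3g} mm) "
                f"leaves no plateau window"
            )
    if geometry.has_bv and entrance_spans > 0:
        d = entrance_spans * geometry.mouth_span
        keep &= profile.position() >= d
        if not keep.any():
            raise AnalysisError(
                f"{profile.wall.value}: junction exclusion ({entrance_spans} mouth spans "
                f"= {d:.3g} mm) leaves no plateau window"
            )
    if not keep.any():
        raise AnalysisError(f"{profile.wall.value}: no points left for the plateau")
    s_in = profile.s[keep]
    return StableValue(
        wall=profile.wall,
        value=float(np.median(profile.tau[keep])),
        extent=(float(s_in.min()), float(s_in.max())),
    )


def min_wss(profile: WSSProfile) -> MinWSS:
    """Global minimum of tau over included points; ties break toward the entrance."""
    keep = profile.included()
    if not keep.any():
        raise AnalysisError(f"{profile.wall.value}: all points excluded")
    s = profile.s[keep]
    tau = profile.tau[keep]
    pos = np.abs(s)
    # lexicographic: smallest tau, then smallest |s|
    order = np.lexsort((pos, tau))
    k = order[0]
    gaps = [abs(tau[j] - tau[k]) for j in (k - 1, k + 1) if 0 <= j < tau.size]
    return MinWSS(wall=profile.wall, value=float(tau[k]), position=float(pos[k]),
                  uncertainty=float(max(gaps)) if gaps else 0.0)


def extent_below(profile: WSSProfile, threshold: float) -> float:
    """Length (mm) of the maximal contiguous sub-threshold run containing the minimum."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    keep = profile.included()
    if not keep.any():
        return 0.0
    s = profile.s[keep]
    tau = profile.tau[keep]
    k = int(np.argmin(tau))
    if tau[k] >= threshold:
        return 0.0
    lo = k
    while lo > 0 and tau[lo - 1] < threshold:
        lo -= 1
    hi = k
    while hi < tau.size - 1 and tau[hi + 1] < threshold:
        hi += 1
    return float(s[hi] - s[lo])
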