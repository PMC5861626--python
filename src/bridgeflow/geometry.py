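"""Parametric bridging-vein / sinus junction geometry and rasterization.

The junction symmetry plane is modelled in 2-D. The superior sagittal sinus
(SSS) is a straight channel of width ``d_ss`` along the x axis, flowing in
+x, occupying ``y in [-d_ss, 0]``. The bridging vein (BV) is a straight
channel of width ``d_bv`` whose centerline meets the upper sinus wall at the
*dural entrance*, the origin of all coordinates. The entry angle ``alpha``
is measured between the BV inflow direction and the *upstream* (-x) sinus
direction: ``alpha < 90`` means the vein discharges against the sinus
stream, the configuration characteristic of posterior bridging veins and
the one that produces the deep junction WSS deficits; ``alpha > 90``
discharges with the stream.

Six wall segments tile the solid boundary (inlet/outlet faces excepted):

========  ==========================================================
SSU       upper sinus wall upstream of the entrance
SSD       upper sinus wall downstream of the entrance
SSO_U     opposite (lower) sinus wall, upstream of the entrance foot
SSO_D     opposite (lower) sinus wall, downstream of the entrance foot
BVU       BV wall meeting the upstream junction corner (shared with SSU)
BVD       BV wall meeting the downstream junction corner (shared with SSD)
========  ==========================================================

Arc-length coordinates: walls anchor ``s = 0`` at their junction-proximal
point (the corner for SSU/SSD/BVU/BVD; the foot of the perpendicular from
the entrance for SSO_U/SSO_D). On sinus walls ``s`` equals the signed x
coordinate (negative upstream); on BV walls ``s >= 0`` grows from the corner
toward the BV inlet. Reported minimum positions are ``|s|``, the distance to
the dural entrance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InputError, ResolutionError

__all__ = [
    "WallLabel",
    "WallPolyline",
    "JunctionGeometry",
    "GridMask",
    "SOLID",
    "FLUID",
    "INLET_SSS",
    "INLET_BV",
    "OUTLET",
    "build_geometry",
    "build_channel",
    "rasterize",
    "wall_arclength",
]

# GridMask cell classes
SOLID, FLUID, INLET_SSS, INLET_BV, OUTLET = 0, 1, 2, 3, 4


class WallLabel(str, Enum):
    SSU = "SSU"
    SSD = "SSD"
    SSO_U = "SSO_U"
    SSO_D = "SSO_D"
    BVU = "BVU"
    BVD = "BVD"


@dataclass(frozen=True)
class WallPolyline:
    """A straight wall segment with its arc-length convention.

    ``p0``/``p1`` are the endpoints (mm) ordered by increasing ``s``;
    ``normal`` is the inward (into-fluid) unit normal; ``open_ends`` marks
    which ends sit on an open (inlet/outlet) face; ``inlet_end`` the end, if
    any, on the owning vessel's *inlet*; ``channel_width`` the owning
    vessel's width (mm).
    """

    label: WallLabel
    p0: tuple[float, float]
    p1: tuple[float, float]
    s0: float
    s1: float
    normal: tuple[float, float]
    open_ends: tuple[str, ...] = ()
    inlet_end: str | None = None
    channel_width: float = 0.0

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def tangent(self) -> tuple[float, float]:
        L = self.length
        return ((self.p1[0] - self.p0[0]) / L, (self.p1[1] - self.p0[1]) / L)

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Points (N, 2) at arc-length coordinates ``s``."""
        t = (np.asarray(s, dtype=float) - self.s0) / (self.s1 - self.s0)
        p0 = np.asarray(self.p0)
        p1 = np.asarray(self.p1)
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]

    def sample(self, spacing: float) -> np.ndarray:
        """Uniform interior s-samples at roughly ``spacing`` (mm)."""
        n = max(int(math.floor(self.length / spacing)), 1)
        return self.s0 + (np.arange(n) + 0.5) * (self.s1 - self.s0) / n


@dataclass(frozen=True)
class JunctionGeometry:
    """Analytic description of the BV–SSS confluence (or a plain channel)."""

    d_ss: float
    d_bv: float  # 0 for a plain channel
    alpha: float  # degrees; undefined (0) for a plain channel
    l_up: float
    l_down: float
    l_bv: float
    walls: dict[WallLabel, WallPolyline]
    entrance: tuple[float, float] = (0.0, 0.0)

    @property
    def has_bv(self) -> bool:
        return self.d_bv > 0

    @property
    def mouth_span(self) -> float:
        """Extent of the BV mouth on the sinus wall, d_bv / sin(alpha)."""
        if not self.has_bv:
            return 0.0
        return self.d_bv / math.sin(math.radians(self.alpha))

    @property
    def corner_offset(self) -> float:
        """|x| of each junction corner: half the mouth span."""
        return self.mouth_span / 2.0

    @property
    def bv_axis(self) -> tuple[float, float]:
        """Unit vector from the entrance toward the BV inlet."""
        a = math.radians(self.alpha)
        return (math.cos(a), math.sin(a))

    @property
    def bv_flow_dir(self) -> tuple[float, float]:
        ax, ay = self.bv_axis
        return (-ax, -ay)

    def fluid_area(self) -> float:
        """Analytic area of the fluid polygon (mm^2)."""
        area = self.d_ss * (self.l_up + self.l_down)
        if self.has_bv:
            # BV strip above y=0: parallelogram mouth..inlet plus the mouth
            # triangle pair cancels: area = d_bv * l_bv exactly.
            area += self.d_bv * self.l_bv
        return area


def build_geometry(
    d_ss: float,
    d_bv: float,
    alpha: float,
    lengths: tuple[float, float, float] = (30.0, 60.0, 20.0),
) -> JunctionGeometry:
    """Build the parametric junction.

    ``lengths`` is ``(l_up, l_down, l_bv)``: sinus length upstream/downstream
    of the entrance and BV length along its centerline. Raises
    :class:`GeometryError` naming the violated constraint when the parameter
    combination is infeasible.
    """
    l_up, l_down, l_bv = lengths
    if min(d_ss, d_bv, l_up, l_down, l_bv) <= 0:
        raise GeometryError("all widths and lengths must be positive")
    if not 0.0 < alpha < 180.0:
        raise GeometryError(f"entry angle must lie in (0, 180) degrees, got {alpha}")
    a = math.radians(alpha)
    sin_a, cos_a = math.sin(a), math.cos(a)
    x_c = d_bv / (2.0 * sin_a)  # corner offset
    if x_c >= min(l_up, l_down):
        raise GeometryError(
            f"BV mouth (half-span {x_c:.3g} mm) exceeds the sinus length on one side"
        )
    half_shift = (d_bv / 2.0) * (cos_a / sin_a)  # corner shift along the BV wall
    len_bvu = l_bv + half_shift
    len_bvd = l_bv - half_shift
    if min(len_bvu, len_bvd) <= 0:
        raise GeometryError(
            "BV too short for this entry angle: a BV wall would have nonpositive length"
        )

    axis = (cos_a, sin_a)  # entrance -> BV inlet (alpha from the upstream direction)
    n_hat = (-sin_a, cos_a)  # transverse, toward the upstream-corner wall
    corner_d = (x_c, 0.0)
    corner_u = (-x_c, 0.0)
    end_bvu = (l_bv * axis[0] + (d_bv / 2.0) * n_hat[0], l_bv * axis[1] + (d_bv / 2.0) * n_hat[1])
    end_bvd = (l_bv * axis[0] - (d_bv / 2.0) * n_hat[0], l_bv * axis[1] - (d_bv / 2.0) * n_hat[1])
    bv_x_reach = max(abs(end_bvu[0]), abs(end_bvd[0]))
    if (max(end_bvu[0], end_bvd[0]) >= l_down) or (min(end_bvu[0], end_bvd[0]) <= -l_up):
        raise GeometryError(
            f"BV inlet (|x| up to {bv_x_reach:.3g} mm) overhangs a sinus end face"
        )

    walls = {
        WallLabel.SSU: WallPolyline(
            WallLabel.SSU, (-l_up, 0.0), corner_u, -l_up, -x_c, (0.0, -1.0),
            open_ends=("start",), inlet_end="start", channel_width=d_ss,
        ),
        WallLabel.SSD: WallPolyline(
            WallLabel.SSD, corner_d, (l_down, 0.0), x_c, l_down, (0.0, -1.0),
            open_ends=("end",), inlet_end=None, channel_width=d_ss,
        ),
        WallLabel.SSO_U: WallPolyline(
            WallLabel.SSO_U, (-l_up, -d_ss), (0.0, -d_ss), -l_up, 0.0, (0.0, 1.0),
            open_ends=("start",), inlet_end="start", channel_width=d_ss,
        ),
        WallLabel.SSO_D: WallPolyline(
            WallLabel.SSO_D, (0.0, -d_ss), (l_down, -d_ss), 0.0, l_down, (0.0, 1.0),
            open_ends=("end",), inlet_end=None, channel_width=d_ss,
        ),
        WallLabel.BVU: WallPolyline(
            WallLabel.BVU, corner_u, end_bvu, 0.0, len_bvu, (-n_hat[0], -n_hat[1]),
            open_ends=("end",), inlet_end="end", channel_width=d_bv,
        ),
        WallLabel.BVD: WallPolyline(
            WallLabel.BVD, corner_d, end_bvd, 0.0, len_bvd, n_hat,
            open_ends=("end",), inlet_end="end", channel_width=d_bv,
        ),
    }
    return JunctionGeometry(d_ss, d_bv, alpha, l_up, l_down, l_bv, walls)


def build_channel(width: float, length: float) -> JunctionGeometry:
    """A plain straight channel (validation geometry, no BV).

    Spans ``x in [0, length]``, ``y in [-width, 0]``; inlet at x=0, outlet at
    x=length. Walls reuse the SSD (top) / SSO_D (bottom) labels with ``s``
    measured from the inlet face.
    """
    if min(width, length) <= 0:
        raise GeometryError("width and length must be positive")
    walls = {
        WallLabel.SSD: WallPolyline(
            WallLabel.SSD, (0.0, 0.0), (length, 0.0), 0.0, length, (0.0, -1.0),
            open_ends=("start", "end"), inlet_end="start", channel_width=width,
        ),
        WallLabel.SSO_D: WallPolyline(
            WallLabel.SSO_D, (0.0, -width), (length, -width), 0.0, length, (0.0, 1.0),
            open_ends=("start", "end"), inlet_end="start", channel_width=width,
        ),
    }
    return JunctionGeometry(width, 0.0, 0.0, 0.0, length, 0.0, walls)


def wall_arclength(geometry: JunctionGeometry, label: WallLabel | str) -> WallPolyline:
    """The labeled wall with its arc-length coordinate (anchored per module docs)."""
    label = WallLabel(label)
    if label not in geometry.walls:
        raise InputError(f"wall {label.value} not present in this geometry")
    return geometry.walls[label]


@dataclass
class GridMask:
    """Uniform-grid classification of the junction domain.

    ``classes`` holds SOLID/FLUID/INLET_SSS/INLET_BV/OUTLET per cell;
    ``wall_labels`` the WallLabel index (or -1) on solid cells bordering
    fluid. ``origin`` is the lower-left corner of cell (0, 0) in mm; cell
    centers sit at ``origin + (i + 1/2) * spacing``.
    """

    spacing: float
    origin: tuple[float, float]
    classes: np.ndarray  # (ny, nx) int8
    wall_labels: np.ndarray  # (ny, nx) int8, -1 where not a wall cell
    d_ss: float
    d_bv: float
    sss_direction: int = 1  # +1: SSS flows in +x (inlet on the left face)
    bv_flow_dir: tuple[float, float] = (0.0, -1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.classes.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return np.meshgrid(x, y)

    def fluid_like(self) -> np.ndarray:
        return self.classes != SOLID

    def fluid_area(self) -> float:
        return float(np.count_nonzero(self.fluid_like())) * self.spacing**2

    def mirror_x(self) -> "GridMask":
        """The x-mirrored mask (used by the solver symmetry checks)."""
        ny, nx = self.classes.shape
        x0, y0 = self.origin
        return GridMask(
            spacing=self.spacing,
            origin=(-(x0 + nx * self.spacing), y0),
            classes=self.classes[:, ::-1].copy(),
            wall_labels=self.wall_labels[:, ::-1].copy(),
            d_ss=self.d_ss,
            d_bv=self.d_bv,
            sss_direction=-self.sss_direction,
            bv_flow_dir=(-self.bv_flow_dir[0], self.bv_flow_dir[1]),
        )


def _point_segment_distance(px, py, a, b):
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / L2, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def rasterize(geometry: JunctionGeometry, spacing: float) -> GridMask:
    """Classify a uniform grid over the junction.

    Requires at least 8 cells across the narrowest channel
    (``spacing <= d_bv / 8``, and ``<= d_ss / 8``), else
    :class:`ResolutionError`.
    """
    narrow = geometry.d_bv if geometry.has_bv else geometry.d_ss
    if spacing > narrow / 8.0 + 1e-12 or spacing > geometry.d_ss / 8.0 + 1e-12:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse: need >= 8 cells across the "
            f"narrowest channel ({narrow} mm)"
        )
    h = spacing
    if geometry.has_bv:
        x_lo, x_hi = -geometry.l_up, geometry.l_down
        bvu = geometry.walls[WallLabel.BVU]
        bvd = geometry.walls[WallLabel.BVD]
        y_top = max(bvu.p1[1], bvd.p1[1])
    else:
        x_lo, x_hi = 0.0, geometry.l_down
        y_top = 0.0
    y_lo = -geometry.d_ss
    nx = int(math.ceil((x_hi - x_lo) / h - 1e-9))
    ny = int(math.ceil((y_top - y_lo) / h - 1e-9)) if y_top > y_lo else 1
    # one-cell solid pad all around
    nx_t, ny_t = nx + 2, ny + 2
    origin = (x_lo - h, y_lo - h)
    X, Y = np.meshgrid(
        origin[0] + (np.arange(nx_t) + 0.5) * h,
        origin[1] + (np.arange(ny_t) + 0.5) * h,
    )

    in_sss = (X > x_lo) & (X < x_hi) & (Y > y_lo) & (Y < 0.0)
    fluid = in_sss
    bv_inlet = np.zeros_like(fluid)
    if geometry.has_bv:
        ax, ay = geometry.bv_axis
        nhx, nhy = -ay, ax  # transverse unit vector across the vein
        t_ax = X * ax + Y * ay
        t_n = X * nhx + Y * nhy
        in_bv = (Y >= 0.0) & (np.abs(t_n) < geometry.d_bv / 2.0) & (t_ax < geometry.l_bv)
        fluid = fluid | in_bv
        bv_inlet = in_bv & (t_ax >= geometry.l_bv - h)

    classes = np.where(fluid, FLUID, SOLID).astype(np.int8)
    # open faces: first/last interior column of the sinus
    col_in, col_out = 1, nx_t - 2
    sss_level = Y < 0.0
    classes[:, col_in][fluid[:, col_in] & sss_level[:, col_in]] = INLET_SSS
    classes[:, col_out][fluid[:, col_out] & sss_level[:, col_out]] = OUTLET
    classes[bv_inlet & (classes != SOLID)] = INLET_BV

    # connectivity of the fluid region (4-connected)
    lab, ncomp = ndimage.label(classes != SOLID, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if ncomp != 1:
        raise GeometryError(f"fluid region is not 4-connected ({ncomp} components)")

    # wall cells: solid cells 4-adjacent to fluid, labeled by nearest wall segment
    fl = classes != SOLID
    nb = np.zeros_like(fl)
    nb[1:, :] |= fl[:-1, :]
    nb[:-1, :] |= fl[1:, :]
    nb[:, 1:] |= fl[:, :-1]
    nb[:, :-1] |= fl[:, 1:]
    wall_cells = (~fl) & nb
    wall_labels = np.full(classes.shape, -1, dtype=np.int8)
    wy, wx = np.nonzero(wall_cells)
    if wy.size:
        px, py = X[wy, wx], Y[wy, wx]
        labels = list(geometry.walls)
        dists = np.stack(
            [
                _point_segment_distance(px, py, geometry.walls[lbl].p0, geometry.walls[lbl].p1)
                for lbl in labels
            ]
        )
        wall_labels[wy, wx] = np.argmin(dists, axis=0).astype(np.int8)

    return GridMask(
        spacing=h,
        origin=origin,
        classes=classes,
        wall_labels=wall_labels,
        d_ss=geometry.d_ss,
        d_bv=geometry.d_bv,
        sss_direction=1,
        bv_flow_dir=geometry.bv_flow_dir if geometry.has_bv else (0.0, -1.0),
    )
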