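"""Junction geometry construction, wall labeling and rasterization."""

import math

import numpy as np
import pytest

from bridgeflow import (
    GeometryError,
    ResolutionError,
    WallLabel,
    build_channel,
    build_geometry,
    rasterize,
    wall_arclength,
)
from bridgeflow.geometry import FLUID, INLET_BV, INLET_SSS, OUTLET, SOLID

FULL = (30.0, 60.0, 20.0)  # default full-scale lengths


def test_perpendicular_entry_is_mirror_symmetric():
    geo = build_geometry(8.0, 2.0, 90.0, FULL)
    bvu = geo.walls[WallLabel.BVU]
    bvd = geo.walls[WallLabel.BVD]
    assert bvu.p0 == pytest.approx((-1.0, 0.0))
    assert bvd.p0 == pytest.approx((1.0, 0.0))
    assert abs(bvu.p0[0]) == pytest.approx(abs(bvd.p0[0]))
    assert bvu.length == pytest.approx(bvd.length)


@pytest.mark.parametrize(
    "d_bv, alpha, span",
    [(2.0, 90.0, 2.0), (2.0, 43.0, 2.0 / math.sin(math.radians(43.0)))],
)
def test_mouth_span_closed_form(d_bv, alpha, span):
    geo = build_geometry(8.0, d_bv, alpha, FULL)
    assert geo.mouth_span == pytest.approx(span)
    if alpha == 43.0:
        assert geo.mouth_span == pytest.approx(2.933, abs=5e-4)


@pytest.mark.parametrize("d_bv", [0.6, 2.6, 5.8])
@pytest.mark.parametrize("alpha", [10.0, 66.0, 90.0, 170.0])
def test_cohort_extremes_build_at_default_lengths(d_bv, alpha):
    geo = build_geometry(8.0, d_bv, alpha, FULL)
    assert set(geo.walls) == set(WallLabel)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(d_ss=8.0, d_bv=2.0, alpha=0.0),
        dict(d_ss=8.0, d_bv=2.0, alpha=180.0),
        dict(d_ss=8.0, d_bv=-1.0, alpha=90.0),
        dict(d_ss=8.0, d_bv=5.8, alpha=4.0),  # mouth wider than the sinus run
    ],
)
def test_infeasible_parameters_raise(kwargs):
    with pytest.raises(GeometryError):
        build_geometry(kwargs["d_ss"], kwargs["d_bv"], kwargs["alpha"], FULL)


def test_supplementary_angles_are_reflections():
    """geometry(alpha) and geometry(180 - alpha) mirror through the entrance
    transverse line, with the two vein walls exchanging roles."""
    a, b = build_geometry(8.0, 2.0, 43.0, (20.0, 20.0, 10.0)), None
    b = build_geometry(8.0, 2.0, 137.0, (20.0, 20.0, 10.0))
    for la, lb in [(WallLabel.BVU, WallLabel.BVD), (WallLabel.BVD, WallLabel.BVU)]:
        wa, wb = a.walls[la], b.walls[lb]
        assert wa.p0[0] == pytest.approx(-wb.p0[0])
        assert wa.p1[0] == pytest.approx(-wb.p1[0])
        assert wa.p1[1] == pytest.approx(wb.p1[1])
        assert wa.length == pytest.approx(wb.length)


def test_wall_arclength_anchors_and_additivity():
    geo = build_geometry(8.0, 2.0, 43.0, FULL)
    x_c = geo.corner_offset
    ssd = wall_arclength(geo, "SSD")
    ssu = wall_arclength(geo, "SSU")
    bvu = wall_arclength(geo, "BVU")
    # SSD runs from the downstream corner to the outlet end
    assert ssd.length == pytest.approx(60.0 - x_c)
    assert ssd.s0 == pytest.approx(x_c)
    # BVU anchors s = 0 at its shared (upstream) corner
    assert bvu.s0 == 0.0
    assert tuple(bvu.point_at(np.array([0.0]))[0]) == pytest.approx((-x_c, 0.0))
    # upper-wall extent: SSU + SSD + mouth span = l_up + l_down
    assert ssu.length + ssd.length + geo.mouth_span == pytest.approx(90.0)
    # s increases away from the junction on both sinus walls
    assert ssu.s0 < ssu.s1 <= 0.0
    assert 0.0 <= ssd.s0 < ssd.s1


def test_channel_rasterization_recovers_the_analytic_area():
    geo = build_channel(8.0, 40.0)
    mask = rasterize(geo, 0.4)
    exact = geo.fluid_area()
    perimeter = 2 * (8.0 + 40.0)
    assert abs(mask.fluid_area() - exact) <= 2 * 0.4 * perimeter


def test_junction_area_error_shrinks_under_refinement():
    geo = build_geometry(8.0, 2.0, 43.0, (10.0, 14.0, 8.0))
    exact = geo.fluid_area()
    errors = [abs(rasterize(geo, h).fluid_area() - exact) for h in (0.25, 0.125, 0.0625)]
    assert errors[0] >= errors[1] >= errors[2]
    perimeter = 2 * (8.0 + 24.0) + 2 * 8.0 + geo.mouth_span
    assert errors[0] <= 2 * 0.25 * perimeter


def test_too_coarse_spacing_is_rejected():
    geo = build_geometry(8.0, 2.0, 90.0, FULL)
    with pytest.raises(ResolutionError):
        rasterize(geo, 0.3)  # fewer than 8 cells across the 2 mm vein


def test_perpendicular_mask_is_mirror_symmetric_up_to_one_cell():
    geo = build_geometry(8.0, 2.0, 90.0, (10.0, 10.0, 6.0))
    mask = rasterize(geo, 0.25)
    fluid = mask.classes != SOLID
    diff = fluid ^ fluid[:, ::-1]
    # disagreement confined to at most a one-cell seam per row
    assert diff.sum(axis=1).max() <= 2


def test_mask_classification_covers_the_boundary():
    geo = build_geometry(8.0, 2.0, 43.0, (10.0, 14.0, 8.0))
    mask = rasterize(geo, 0.2)
    cls = mask.classes
    fl = cls != SOLID
    assert {INLET_SSS, INLET_BV, OUTLET, FLUID} <= set(np.unique(cls))
    # every solid cell 4-adjacent to fluid carries exactly one wall label
    nb = np.zeros_like(fl)
    nb[1:, :] |= fl[:-1, :]
    nb[:-1, :] |= fl[1:, :]
    nb[:, 1:] |= fl[:, :-1]
    nb[:, :-1] |= fl[:, 1:]
    boundary = (~fl) & nb
    assert (mask.wall_labels[boundary] >= 0).all()
    assert (mask.wall_labels[~boundary] == -1).all()
    # all six walls appear in the labeling
    assert set(np.unique(mask.wall_labels[boundary])) == set(range(6))


def test_mirror_mask_roundtrip():
    geo = build_geometry(8.0, 2.0, 43.0, (10.0, 14.0, 8.0))
    mask = rasterize(geo, 0.25)
    twice = mask.mirror_x().mirror_x()
    assert np.array_equal(twice.classes, mask.classes)
    assert twice.origin == pytest.approx(mask.origin)
    assert twice.sss_direction == mask.sss_direction
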