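"""Legacy-VTK (ASCII structured points) export of masks and flow fields.

Cell-centered data are written as POINT_DATA on a grid of cell centers,
which every VTK reader renders directly. A JSON sidecar carries the run
parameters and wall anchor coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import GridMask, JunctionGeometry
from .lbm import FlowField

__all__ = ["write_structured_points", "save_mask", "save_flow_field"]


def write_structured_points(
    path,
    spacing_mm: float,
    origin_mm: tuple[float, float],
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    title: str = "bridgeflow field",
) -> None:
    scalars = scalars or {}
    vectors = vectors or {}
    arrays = list(scalars.values()) + [v[0] for v in vectors.values()]
    if not arrays:
        raise ValueError("nothing to write")
    ny, nx = arrays[0].shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {origin_mm[0] + spacing_mm / 2:.9g} {origin_mm[1] + spacing_mm / 2:.9g} 0",
        f"SPACING {spacing_mm:.9g} {spacing_mm:.9g} {spacing_mm:.9g}",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in scalars.items():
        is_int = np.issubdtype(arr.dtype, np.integer)
        lines.append(f"SCALARS {name} {'int' if is_int else 'float'} 1")
        lines.append("LOOKUP_TABLE default")
        fmt = "%d" if is_int else "%.7g"
        lines.extend(" ".join(fmt % v for v in row) for row in arr)
    for name, (vx, vy) in vectors.items():
        lines.append(f"VECTORS {name} float")
        flat = np.stack([vx.ravel(), vy.ravel(), np.zeros(vx.size)], axis=1)
        lines.extend(f"{a:.7g} {b:.7g} {c:.7g}" for a, b, c in flat)
    Path(path).write_text("\n".join(lines) + "\n")


def _sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(payload, indent=1) + "\n")


def save_mask(mask: GridMask, path, geometry: JunctionGeometry | None = None) -> None:
    path = Path(path)
    write_structured_points(
        path, mask.spacing, mask.origin,
        scalars={
            "cell_class": mask.classes.astype(np.int32),
            "wall_label": mask.wall_labels.astype(np.int32),
        },
        title="bridgeflow grid mask",
    )
    payload = {
        "spacing_mm": mask.spacing,
        "origin_mm": list(mask.origin),
        "d_ss_mm": mask.d_ss,
        "d_bv_mm": mask.d_bv,
        "cell_classes": {"solid": 0, "fluid": 1, "inlet_sss": 2, "inlet_bv": 3, "outlet": 4},
    }
    if geometry is not None:
        payload["entry_angle_deg"] = geometry.alpha
        payload["angle_convention"] = "measured against the upstream sinus direction"
        payload["walls"] = {
            lbl.value: {"p0": list(w.p0), "p1": list(w.p1), "s0": w.s0, "s1": w.s1}
            for lbl, w in geometry.walls.items()
        }
        payload["dural_entrance_mm"] = list(geometry.entrance)
    _sidecar(path, payload)


def save_flow_field(field: FlowField, path) -> None:
    path = Path(path)
    write_structured_points(
        path, field.mask.spacing, field.mask.origin,
        scalars={"pressure_pa": field.pressure},
        vectors={"velocity_m_per_s": (field.ux, field.uy)},
        title="bridgeflow steady flow field",
    )
    _sidecar(path, {
        "converged": field.converged,
        "residual_history": field.residual_history[-20:],
        "units": {"velocity": "m/s", "pressure": "Pa gauge", "spacing": "mm"},
        "metadata": field.metadata,
        "fluid": {"density_kg_m3": field.fluid.density, "viscosity_pa_s": field.fluid.viscosity},
        "boundary": {
            "u_ss_inlet_m_s": field.bc.u_ss_inlet,
            "u_bv_inlet_m_s": field.bc.u_bv_inlet,
            "outlet_gauge_pa": field.bc.outlet_gauge_pressure,
            "ambient_pa": field.bc.ambient_pressure,
            "inlet_profile": field.bc.inlet_profile,
        },
    })
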