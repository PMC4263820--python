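"""Field-snapshot export/import in the legacy VTK ASCII format.

A compact writer/reader for unstructured grids of 9-node biquadratic quads
(VTK cell type 28), carrying nodal displacement and pressure, Gauss-point-
averaged total stress per cell, region ids, and fibre directions.  The files
are plain text, deterministic for a fixed state, and re-readable by
:func:`read_snapshot` for round-trip checks and post-processing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["export_fields", "read_snapshot"]

# local tensor-product order -> VTK biquadratic quad order
_VTK_ORDER = np.array([0, 2, 8, 6, 1, 5, 7, 3, 4])
_FMT = "%.12g"


def _fmt_rows(arr: np.ndarray) -> str:
    arr = np.atleast_2d(arr)
    return "\n".join(" ".join(_FMT % v for v in row) for row in arr)


def export_fields(state, model, path) -> Path:
    """Write one converged state to ``path`` as a legacy VTK snapshot.

    Point data: displacement (3-vector, z=0), pressure (0 on nodes without a
    pressure DOF is written as the bilinear interpolant is not available --
    midside nodes carry NaN-free 0.0 and are flagged by `has_pressure`).
    Cell data: region id, in-plane fibre direction, cell-averaged total
    stress components (sxx, syy, sxy, szz).
    """
    mesh = model.mesh
    ops = model.ops
    n = mesh.n_nodes
    u = state.u.reshape(-1, 2)
    p_full = np.zeros(n)
    has_p = np.zeros(n)
    p_full[mesh.pressure_nodes] = state.p
    has_p[mesh.pressure_nodes] = 1.0

    s, szz = ops.effective_stress_at_gauss(state.u, model.lam, model.mu,
                                           model.fibre_dir, model.E_f)
    pg = ops.pressures_at_gauss(state.p)
    cell_stress = np.column_stack([
        (s[..., 0] - pg).mean(axis=1),
        (s[..., 1] - pg).mean(axis=1),
        s[..., 2].mean(axis=1),
        (szz - pg).mean(axis=1),
    ])

    elems = mesh.elements[:, _VTK_ORDER]
    ne = len(elems)
    lines = [
        "# vtk DataFile Version 3.0",
        f"poroknee snapshot t={state.t:.12g}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
        _fmt_rows(np.column_stack([mesh.nodes, np.zeros(n)])),
        f"CELLS {ne} {ne * 10}",
        "\n".join("9 " + " ".join(str(i) for i in row) for row in elems),
        f"CELL_TYPES {ne}",
        "\n".join(["28"] * ne),
        f"POINT_DATA {n}",
        "VECTORS displacement double",
        _fmt_rows(np.column_stack([u, np.zeros(n)])),
        "SCALARS pressure double 1",
        "LOOKUP_TABLE default",
        _fmt_rows(p_full[:, None]),
        "SCALARS has_pressure double 1",
        "LOOKUP_TABLE default",
        _fmt_rows(has_p[:, None]),
        f"CELL_DATA {ne}",
        "SCALARS region_id double 1",
        "LOOKUP_TABLE default",
        _fmt_rows(mesh.region_id[:, None].astype(float)),
        "VECTORS fibre_direction double",
        _fmt_rows(np.column_stack([mesh.fibre_dir, np.zeros(ne)])),
        "SCALARS total_stress_xx_yy_xy_zz double 4",
        "LOOKUP_TABLE default",
        _fmt_rows(cell_stress),
        "",
    ]
    path = Path(path)
    path.write_text("\n".join(lines))
    return path


def read_snapshot(path) -> dict:
    """Read a snapshot written by :func:`export_fields`."""
    tokens = Path(path).read_text().split("\n")
    out: dict = {}
    i = 0

    def grab(count, width):
        nonlocal i
        vals = []
        while len(vals) < count * width:
            vals.extend(float(v) for v in tokens[i].split())
            i += 1
        return np.array(vals).reshape(count, width)

    while i < len(tokens):
        line = tokens[i]
        parts = line.split()
        if line.startswith("POINTS"):
            npts = int(parts[1])
            i += 1
            out["points"] = grab(npts, 3)[:, :2]
            continue
        if line.startswith("CELLS"):
            ne = int(parts[1])
            i += 1
            conn = grab(ne, 10)[:, 1:].astype(int)
            inv = np.empty_like(_VTK_ORDER)
            inv[_VTK_ORDER] = np.arange(9)
            out["elements"] = conn[:, inv]
            continue
        if line.startswith("VECTORS"):
            name = parts[1]
            i += 1
            count = len(out["points"]) if "cells_started" not in out else len(out["elements"])
            out[name] = grab(count, 3)[:, :2]
            continue
        if line.startswith("SCALARS"):
            name, width = parts[1], int(parts[3])
            i += 2   # skip LOOKUP_TABLE
            count = len(out["points"]) if "cells_started" not in out else len(out["elements"])
            data = grab(count, width)
            out[name] = data[:, 0] if width == 1 else data
            continue
        if line.startswith("CELL_DATA"):
            out["cells_started"] = True
        i += 1
    out.pop("cells_started", None)
    return out
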