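"""Synthetic geometry: verification fixtures and the 2-D coronal joint.

The joint generator produces an idealized coronal-plane cross-section of a
tibiofemoral joint: two circular-arc femoral condyle cartilage layers bonded
to a single rigid femur, a flat tibial cartilage layer bonded to the (rigid,
fixed) tibia, and -- in the intact variant -- two wedge-shaped menisci seated
between condyle and tibial surfaces.  All inter-tissue interaction is by
biphasic contact; no regions share nodes.

The wedge top edge conforms to the condyle arc at a small clearance, so the
reference configuration is contact-free but immediately engages under load.
The meniscectomy variant simply omits the wedges; every other node
coordinate is identical, i.e. joint alignment is unchanged by meniscectomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import RegionMesh, grid_node_id, merge_blocks, structured_block

__all__ = [
    "JointGeometryParams",
    "GeometryError",
    "make_confined_column",
    "make_unconfined_strip",
    "make_coronal_joint",
    "fibre_field",
]


class GeometryError(ValueError):
    """Raised when requested joint proportions cannot be realized."""


@dataclass
class JointGeometryParams:
    """Free parameters of the synthetic coronal joint (mm).

    These are modelling choices of this package, not measured anatomy; they
    are sized to adult-knee proportions (condyle radius ~25 mm, cartilage
    ~2 mm, meniscus wedge ~3 mm tall at the rim).
    """

    condyle_radius: float = 25.0
    condyle_spacing: float = 44.0            # centre-to-centre distance
    condyle_half_angle_deg: float = 35.0     # angular half-span of each cartilage arc
    femoral_cartilage_thickness: float = 2.0
    tibial_cartilage_thickness: float = 2.0
    tibial_width: float = 70.0
    meniscus_inner_height: float = 0.5       # wedge tip height
    meniscus_outer_height: float = 3.6       # wedge rim height
    meniscus_width: float | None = None      # horizontal span; None -> from heights
    meniscus_clearance: float = 0.005        # wedge-top gap below the condyle arc
    meniscus_seat_clearance: float = 0.005   # wedge-bottom lift off the tibial
                                             # surface; keeps the reference
                                             # state strictly contact-free
    meniscus_tip_relief: float = 0.08        # extra top clearance at the wedge tip
                                             # and rim (parabolic profile), so
                                             # contact engages at the wedge body
                                             # and the thin free edge and the
                                             # anchored rim corner are unloaded
    initial_gap: float = 0.13                # condyle apex height above tibial surface
    out_of_plane_depth: float = 240.0        # plane-strain depth for force scaling
    mesh_size: float = 1.0
    variant: str = "intact"                  # "intact" | "meniscectomy"

    def __post_init__(self) -> None:
        for name in ("condyle_radius", "condyle_spacing", "femoral_cartilage_thickness",
                     "tibial_cartilage_thickness", "tibial_width", "meniscus_inner_height",
                     "meniscus_outer_height", "out_of_plane_depth", "mesh_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.meniscus_outer_height <= self.meniscus_inner_height:
            raise ValueError("meniscus_outer_height must exceed meniscus_inner_height "
                             "(the wedge tapers inward)")
        if self.initial_gap < 0 or self.meniscus_clearance < 0 \
                or self.meniscus_tip_relief < 0:
            raise ValueError("gaps must be >= 0")
        if self.variant not in ("intact", "meniscectomy"):
            raise ValueError(f"variant must be 'intact' or 'meniscectomy', "
                             f"got {self.variant!r}")


def _n_div(length: float, size: float, minimum: int = 1) -> int:
    return max(minimum, int(math.ceil(length / size - 1e-9)))


def make_confined_column(height: float, n_elements: int,
                         width: float | None = None) -> RegionMesh:
    """1-element-wide confined-compression column (Terzaghi fixture).

    Lateral edges are rollers (u_x = 0) and sealed; the bottom is fixed and
    impermeable; the top edge is loaded by the applied traction and
    free-draining.
    """
    if height <= 0:
        raise ValueError("height must be > 0")
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    w = width if width is not None else height / n_elements

    nodes, elems = structured_block(lambda u, v: (w * u, height * v), 1, n_elements)
    gx = 3
    top = np.array([grid_node_id(1, i, 2 * n_elements) for i in range(gx)])
    bottom = np.array([grid_node_id(1, i, 0) for i in range(gx)])
    all_ids = np.arange(len(nodes))
    block = {
        "nodes": nodes, "elements": elems, "region": "column",
        "fibre_dir": np.tile([1.0, 0.0], (len(elems), 1)),
        "tags": {
            "fixed_base": bottom,
            "roller_x": all_ids,
            "peripheral_draining": top,
        },
        "edges": {"loaded_top": np.array([[top[0], top[1], top[2]]])},
    }
    mesh = merge_blocks([block])
    mesh.meta = {"kind": "confined_column", "height": height, "width": w}
    return mesh


def make_unconfined_strip(width: float, height: float, n: int) -> RegionMesh:
    """Plane-strain strip between frictionless impermeable rigid platens.

    ``n`` elements across the width; vertical resolution keeps elements
    near-square.  Lateral edges are free-draining and traction-free; the
    platen edges carry prescribed vertical displacement with free sliding.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    ny = _n_div(height, width / n)
    nodes, elems = structured_block(
        lambda u, v: (width * (u - 0.5), height * v), n, ny)
    gx = 2 * n + 1
    top = np.array([grid_node_id(n, i, 2 * ny) for i in range(gx)])
    bottom = np.array([grid_node_id(n, i, 0) for i in range(gx)])
    left = np.array([grid_node_id(n, 0, j) for j in range(2 * ny + 1)])
    right = np.array([grid_node_id(n, gx - 1, j) for j in range(2 * ny + 1)])
    block = {
        "nodes": nodes, "elements": elems, "region": "strip",
        "fibre_dir": np.tile([1.0, 0.0], (len(elems), 1)),
        "tags": {
            "platen_top": top,
            "platen_bottom": bottom,
            "pin_x": np.array([grid_node_id(n, n, 0)]),   # centre of bottom edge
            "peripheral_draining": np.concatenate([left, right]),
        },
    }
    mesh = merge_blocks([block])
    mesh.meta = {"kind": "unconfined_strip", "width": width, "height": height}
    return mesh


# -- coronal joint ----------------------------------------------------------


def _arc_height(d: np.ndarray, R: float, gap: float):
    """Height of the condyle articular arc above the tibial surface at
    lateral distance d from the apex."""
    return gap + R - np.sqrt(R * R - d * d)


def _wedge_span(p: JointGeometryParams) -> tuple[float, float]:
    """Horizontal span [d_in, d_out] of the meniscus wedge, measured from the
    condyle apex, located on the articular arc from the wedge end heights."""
    R, gap = p.condyle_radius, p.initial_gap

    def locate(h: float, what: str, c: float) -> float:
        s = R + gap - h - c
        if h + c <= gap:
            raise GeometryError(
                f"meniscus {what} height {h} mm (+clearance) does not clear the "
                f"initial condyle-tibia gap {gap} mm: the wedge tip would sit "
                f"below the condyle apex")
        if s <= 0 or s > R:
            raise GeometryError(
                f"meniscus {what} height {h} mm does not intersect the condyle "
                f"arc (radius {R} mm, gap {gap} mm)")
        return math.sqrt(R * R - s * s)

    c_end = p.meniscus_clearance + p.meniscus_tip_relief
    d_in = locate(p.meniscus_inner_height, "inner", c_end)
    if p.meniscus_width is not None:
        d_out = d_in + p.meniscus_width
    else:
        d_out = locate(p.meniscus_outer_height, "outer", c_end)
    max_d = R * math.sin(math.radians(p.condyle_half_angle_deg))
    if d_out >= max_d:
        raise GeometryError(
            f"meniscus rim at d={d_out:.2f} mm lies beyond the condyle cartilage "
            f"arc (max {max_d:.2f} mm); reduce meniscus_outer_height/width or "
            f"increase condyle_half_angle_deg")
    if d_out <= d_in:
        raise GeometryError("meniscus wedge has non-positive width")
    return d_in, d_out


def _condyle_block(p: JointGeometryParams, side: str) -> dict:
    R, t = p.condyle_radius, p.femoral_cartilage_thickness
    xc = 0.5 * p.condyle_spacing * (1 if side == "med" else -1)
    yc = p.initial_gap + R
    th = math.radians(p.condyle_half_angle_deg)
    arc_len = 2 * th * R
    nx = _n_div(arc_len, p.mesh_size)
    ny = _n_div(t, p.mesh_size, minimum=2)

    def mapping(u, v):
        theta = (2 * u - 1) * th          # from -th to +th, measured off vertical-down
        r = R - v * t
        return xc + r * np.sin(theta), yc - r * np.cos(theta)

    nodes, elems = structured_block(mapping, nx, ny)
    gx, gy = 2 * nx + 1, 2 * ny + 1
    articular = np.array([grid_node_id(nx, i, 0) for i in range(gx)])
    bone = np.array([grid_node_id(nx, i, gy - 1) for i in range(gx)])
    ends = np.array([grid_node_id(nx, i, j) for i in (0, gx - 1) for j in range(gy)])
    # element fibre directions: tangent to the articular surface
    th_el = (2 * ((np.arange(nx) + 0.5) / nx) - 1) * th
    fib_one = np.column_stack([np.cos(th_el), np.sin(th_el)])
    fibre = np.tile(fib_one, (ny, 1))
    return {
        "nodes": nodes, "elements": elems, "region": f"femoral_{side}",
        "fibre_dir": fibre,
        "tags": {
            "rigid_femur_interface": bone,
            "peripheral_draining": ends,
        },
        "surfaces": {f"femoral_{side}_articular": articular},
    }


def _tibial_block(p: JointGeometryParams) -> dict:
    W, t = p.tibial_width, p.tibial_cartilage_thickness
    nx = _n_div(W, p.mesh_size)
    ny = _n_div(t, p.mesh_size, minimum=2)
    nodes, elems = structured_block(
        lambda u, v: (W * (u - 0.5), t * (v - 1.0)), nx, ny)
    gx, gy = 2 * nx + 1, 2 * ny + 1
    top = np.array([grid_node_id(nx, i, gy - 1) for i in range(gx)])
    bottom = np.array([grid_node_id(nx, i, 0) for i in range(gx)])
    sides = np.array([grid_node_id(nx, i, j) for i in (0, gx - 1) for j in range(gy)])
    return {
        "nodes": nodes, "elements": elems, "region": "tibial",
        "fibre_dir": np.tile([1.0, 0.0], (len(elems), 1)),
        "tags": {
            "fixed_base": bottom,
            "peripheral_draining": sides,
        },
        "surfaces": {"tibial_top": top},
    }


def _meniscus_block(p: JointGeometryParams, side: str,
                    d_in: float, d_out: float) -> dict:
    R, gap, c = p.condyle_radius, p.initial_gap, p.meniscus_clearance
    xc = 0.5 * p.condyle_spacing * (1 if side == "med" else -1)
    sgn = 1 if side == "med" else -1
    nx = _n_div(d_out - d_in, p.mesh_size)
    h_out = float(_arc_height(np.array([d_out]), R, gap)[0]) - c
    ny = _n_div(0.5 * h_out, p.mesh_size, minimum=2)

    relief = p.meniscus_tip_relief
    seat = p.meniscus_seat_clearance

    d_mid = 0.5 * (d_in + d_out)
    half = 0.5 * (d_out - d_in)

    def mapping(u, v):
        # parameterize so x increases with u on both sides (positive Jacobian)
        d = d_in + u * (d_out - d_in) if sgn > 0 else d_out - u * (d_out - d_in)
        # top conforms to the condyle arc at a clearance that is smallest at
        # the wedge body and widens parabolically toward both the thin free
        # edge and the anchored rim, so contact engages centrally and spreads
        cd = c + relief * ((d - d_mid) / half) ** 2
        top = _arc_height(d, R, gap) - cd
        return xc + sgn * d, seat + v * (top - seat)

    nodes, elems = structured_block(mapping, nx, ny)
    gx, gy = 2 * nx + 1, 2 * ny + 1
    top = np.array([grid_node_id(nx, i, gy - 1) for i in range(gx)])
    bottom = np.array([grid_node_id(nx, i, 0) for i in range(gx)])
    tip_col = 0 if sgn > 0 else gx - 1
    rim_col = gx - 1 if sgn > 0 else 0
    tip = np.array([grid_node_id(nx, tip_col, j) for j in range(gy)])
    rim = np.array([grid_node_id(nx, rim_col, j) for j in range(gy)])
    # horn/capsule tether acts near plateau level: anchor the lower half of
    # the rim so its top corner can still follow the articulating surfaces
    anchor = rim[: (gy + 1) // 2 + 1]
    return {
        "nodes": nodes, "elements": elems, "region": f"meniscus_{side}",
        "fibre_dir": np.tile([1.0, 0.0], (len(elems), 1)),
        "tags": {
            # only the peripheral rim is tethered by the horn/circumferential
            # system; the thin inner edge is free, as in the real meniscus
            "horn_anchor": anchor,
            "peripheral_draining": np.unique(np.concatenate([tip, rim])),
        },
        "surfaces": {
            f"meniscus_{side}_top": top,
            f"meniscus_{side}_bottom": bottom,
        },
    }


def make_coronal_joint(params: JointGeometryParams) -> RegionMesh:
    """Generate the 2-D coronal joint mesh (intact or double meniscectomy).

    The medial compartment is at x > 0 (the load offset side); the lateral at
    x < 0.  Geometry is deterministic: regenerating with equal params yields
    bit-identical meshes.
    """
    p = params
    d_in, d_out = _wedge_span(p)
    xc = 0.5 * p.condyle_spacing
    if xc + d_out >= 0.5 * p.tibial_width:
        raise GeometryError("tibial_width too small to support the meniscus rims")

    blocks = [
        _tibial_block(p),
        _condyle_block(p, "med"),
        _condyle_block(p, "lat"),
    ]
    if p.variant == "intact":
        blocks.append(_meniscus_block(p, "med", d_in, d_out))
        blocks.append(_meniscus_block(p, "lat", d_in, d_out))
    mesh = merge_blocks(blocks)

    # tibial-top nodes beyond the outermost possible contact never engage:
    # tag them free-draining statically
    tib_top = mesh.surfaces["tibial_top"]
    x = mesh.nodes[tib_top, 0]
    margin = 1.0
    outside = tib_top[(np.abs(np.abs(x) - xc) > d_out + margin)]
    mesh.tags["peripheral_draining"] = np.unique(
        np.concatenate([mesh.tag("peripheral_draining"), outside]))

    mesh.meta = {
        "kind": "coronal_joint",
        "variant": p.variant,
        "condyle_centre_x": xc,
        "condyle_radius": p.condyle_radius,
        "condyle_centre_y": p.initial_gap + p.condyle_radius,
        "initial_gap": p.initial_gap,
        "d_in": d_in,
        "d_out": d_out,
        "out_of_plane_depth": p.out_of_plane_depth,
        "joint_centre": (0.0, 0.0),
        "fibre_label_by_region": {
            "femoral_med": "tangent", "femoral_lat": "tangent",
            "tibial": "tangent",
            "meniscus_med": "radial", "meniscus_lat": "radial",
        },
        "params": p,
    }
    return mesh


def fibre_field(mesh: RegionMesh) -> RegionMesh:
    """(Re)assign per-element fibre directions from region labels.

    Cartilage fibres run tangent to the nearest articular surface (flat for
    the tibia, circumferentially around the condyle arcs); meniscus fibres
    run radially (medio-lateral) in plane.  The circumferential (out-of-
    plane) meniscal family is represented by the horn-anchor hoop springs,
    not by an in-plane fibre tensor.  Returns the mesh, modified in place.
    """
    centroids = mesh.nodes[mesh.elements].mean(axis=1)
    for rid, name in enumerate(mesh.region_names):
        sel = mesh.region_id == rid
        if not np.any(sel):
            continue
        if name.startswith("femoral"):
            xc = mesh.meta["condyle_centre_x"] * (1 if name.endswith("med") else -1)
            yc = mesh.meta["condyle_centre_y"]
            radial = centroids[sel] - np.array([xc, yc])
            radial /= np.linalg.norm(radial, axis=1, keepdims=True)
            mesh.fibre_dir[sel] = np.column_stack([-radial[:, 1], radial[:, 0]])
        else:
            mesh.fibre_dir[sel] = [1.0, 0.0]
    # normalize orientation sign (fibres are direction-less)
    flip = mesh.fibre_dir[:, 0] < 0
    mesh.fibre_dir[flip] *= -1.0
    mesh.validate()
    return mesh
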