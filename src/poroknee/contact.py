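"""Penalty contact between biphasic surfaces with switching drainage.

Discretization is node-to-segment: the nodes of the *secondary* surface
(always a cartilage surface) are projected onto the *primary* surface
polyline.  Normal traction follows the penalty rule

    t_n = penalty_factor * max(gap, 0)         [MPa],

with ``gap`` the penetration depth (positive when overlapping).  The fluid
boundary condition on every contact face follows the patch: where contact
is active the interstitial fluid cannot escape, so the pressure field is
tied across the interface (penalty on the pressure jump); everywhere else
the face is free-draining (p = 0).  The active/sealed partition is
recomputed every Newton iteration, so the drainage boundary moves with the
contact patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactPair",
    "PairState",
    "project_and_gap",
    "penalty_traction",
    "auto_penalty",
    "update_drainage",
]


def _polyline_normals(coords: np.ndarray, orient: str) -> np.ndarray:
    """Unit outward normals of polyline segments.

    ``orient`` states on which side of the walking direction the body
    exterior lies: "right" gives n = (t_y, -t_x), "left" the opposite.  This
    is robust for thin bodies where a point-in-body heuristic would fail.
    """
    seg = coords[1:] - coords[:-1]
    L = np.linalg.norm(seg, axis=1)
    if np.any(L <= 0):
        raise ValueError("degenerate zero-length surface segment")
    t = seg / L[:, None]
    if orient == "right":
        return np.column_stack([t[:, 1], -t[:, 0]])
    if orient == "left":
        return np.column_stack([-t[:, 1], t[:, 0]])
    raise ValueError(f"orient must be 'left' or 'right', got {orient!r}")


def project_and_gap(points: np.ndarray, surf_coords: np.ndarray,
                    orient: str = "right"
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closest-point projection of points onto a surface polyline.

    Returns ``(gap, normal, seg_index, seg_param, interior)`` where ``gap``
    is penetration-positive, ``normal`` is the outward primary normal at the
    projection, and ``interior`` is False for points whose projection falls
    beyond the polyline ends (such points cannot carry traction).
    """
    P = np.atleast_2d(np.asarray(points, float))
    Q = np.asarray(surf_coords, float)
    if len(Q) < 2:
        raise ValueError("surface must have at least one segment")
    normals = _polyline_normals(Q, orient)
    # vertex-averaged normals, interpolated along each segment: the normal
    # field is then continuous in the sliding coordinate, which keeps the
    # penalty force continuous when a node crosses a polyline kink
    vnorm = np.zeros_like(Q)
    vnorm[:-1] += normals
    vnorm[1:] += normals
    vnorm /= np.linalg.norm(vnorm, axis=1, keepdims=True)
    A, B = Q[:-1], Q[1:]
    AB = B - A                                        # (m,2)
    L2 = np.einsum("ij,ij->i", AB, AB)
    # t-parameter of each point on each segment: (n,m)
    t_raw = np.einsum("nmj,mj->nm", P[:, None, :] - A[None, :, :], AB) / L2
    t = np.clip(t_raw, 0.0, 1.0)
    C = A[None, :, :] + t[..., None] * AB[None, :, :]
    d2 = np.einsum("nmj,nmj->nm", P[:, None, :] - C, P[:, None, :] - C)
    seg = np.argmin(d2, axis=1)
    idx = np.arange(len(P))
    tsel = t[idx, seg]
    Csel = C[idx, seg]
    nsel = (1.0 - tsel)[:, None] * vnorm[seg] + tsel[:, None] * vnorm[seg + 1]
    nsel /= np.linalg.norm(nsel, axis=1, keepdims=True)
    gap = -np.einsum("ij,ij->i", P - Csel, nsel)      # positive when penetrating
    interior = ~(((seg == 0) & (t_raw[idx, seg] < 0.0))
                 | ((seg == len(AB) - 1) & (t_raw[idx, seg] > 1.0)))
    return gap, nsel, seg, tsel, interior


def penalty_traction(gap, penalty_factor: float):
    """Normal contact traction t_n = penalty_factor * max(gap, 0), MPa."""
    if penalty_factor <= 0:
        raise ValueError("penalty_factor must be > 0")
    return penalty_factor * np.maximum(np.asarray(gap, float), 0.0)


def regularized_traction(gap, penalty_factor: float, band: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """C1 penalty law: quadratic blend over ``0 < gap < band``, linear beyond.

    Returns (traction, stiffness dT/dgap).  The blend removes the slope
    discontinuity of the plain penalty rule at gap = 0, which otherwise makes
    Newton chatter when many nodes of a conforming (flat-on-flat) interface
    hover at the contact boundary simultaneously.  ``band`` is a small
    fraction of typical working penetrations, so tractions differ from the
    plain rule by at most penalty_factor*band/2.
    """
    g = np.asarray(gap, float)
    if band <= 0:
        return penalty_factor * np.maximum(g, 0.0), \
            np.where(g > 0, penalty_factor, 0.0)
    t = np.where(g <= 0, 0.0,
                 np.where(g < band,
                          penalty_factor * g * g / (2.0 * band),
                          penalty_factor * (g - 0.5 * band)))
    dt = np.where(g <= 0, 0.0,
                  np.where(g < band, penalty_factor * g / band, penalty_factor))
    return t, dt


def auto_penalty(H_A_primary: float, H_A_secondary: float,
                 char_length: float, scale: float = 100.0) -> float:
    """Deterministic initial penalty factor, N/mm^3.

    factor = scale * min(adjacent aggregate moduli) / characteristic element
    length.  The aggregate modulus sets the stress scale of the contacting
    layers; dividing by the surface element length keeps nodal penetration a
    small fraction of layer thickness.
    """
    if char_length <= 0:
        raise ValueError("characteristic length must be > 0")
    if H_A_primary <= 0 or H_A_secondary <= 0:
        raise ValueError("aggregate moduli must be > 0")
    return scale * min(H_A_primary, H_A_secondary) / char_length


def _tributary_lengths(coords: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(coords[1:] - coords[:-1], axis=1)
    ell = np.zeros(len(coords))
    ell[:-1] += 0.5 * seg
    ell[1:] += 0.5 * seg
    return ell


@dataclass
class PairState:
    """Per-iteration contact status of one pair (secondary-node arrays)."""
    gap: np.ndarray
    normal: np.ndarray
    seg: np.ndarray
    t: np.ndarray
    active: np.ndarray           # penetrating and interior (carries traction)
    traction: np.ndarray         # MPa
    stiffness: np.ndarray = None  # dT/dgap, MPa/mm
    sealed: np.ndarray = None    # pressure-continuity status (with hysteresis)


@dataclass
class ContactPair:
    """One primary/secondary surface pairing.

    ``primary``/``secondary`` are ordered node-id polylines into the global
    mesh; the secondary is always a cartilage surface.  ``orient`` states on
    which side of the primary walking direction its body exterior (and hence
    the secondary body) lies.
    """
    name: str
    kind: str                    # femoral-meniscus | meniscus-tibial | femoral-tibial
    compartment: str             # medial | lateral
    primary: np.ndarray
    secondary: np.ndarray
    orient: str
    penalty_factor: float
    reg_band: float = 2e-4       # mm; C1 blend width of the penalty law
    state: PairState | None = field(default=None, repr=False)
    ell_ref: np.ndarray = field(default=None, repr=False)
    _sealed_prev: np.ndarray = field(default=None, repr=False)
    _frozen_geom: tuple | None = field(default=None, repr=False)

    def freeze_geometry(self) -> None:
        """Pin projections, normals and switching sets at the current state.

        While frozen, the gap is evaluated with the pinned segment/parameter/
        normal data, which makes the contact residual an exactly linear (up
        to the C1 penalty blend) function of displacement -- the same model
        the assembled tangent describes.  Used to finish Newton steps whose
        geometric contact nonlinearity otherwise causes slow creep of the
        iterates; the frozen-geometry error is quadratic in the within-step
        sliding distance.
        """
        if self.state is None:
            raise RuntimeError("cannot freeze before the first update")
        st = self.state
        self._frozen_geom = (st.seg.copy(), st.t.copy(), st.normal.copy(),
                             st.active.copy(), st.sealed.copy())

    def thaw(self) -> None:
        self._frozen_geom = None

    def __post_init__(self) -> None:
        self.primary = np.asarray(self.primary, int)
        self.secondary = np.asarray(self.secondary, int)
        if self.penalty_factor <= 0:
            raise ValueError("penalty_factor must be > 0")

    def tributary_lengths(self, ref_nodes: np.ndarray) -> np.ndarray:
        if self.ell_ref is None:
            self.ell_ref = _tributary_lengths(ref_nodes[self.secondary])
        return self.ell_ref

    def update(self, coords: np.ndarray) -> PairState:
        """Recompute gaps/tractions from current (deformed) coordinates.

        The sealing (pressure-continuity) status switches with hysteresis: a
        point seals only once its penetration exceeds the regularization
        band and unseals only on true separation, so points hovering at the
        patch edge do not toggle the drainage boundary every iterate.
        """
        if self._frozen_geom is not None:
            seg, t, n, active, sealed = self._frozen_geom
            P = coords[self.secondary]
            A = coords[self.primary[seg]]
            B = coords[self.primary[seg + 1]]
            C = (1.0 - t)[:, None] * A + t[:, None] * B
            gap = -np.einsum("ij,ij->i", P - C, n)
            traction, stiff = regularized_traction(gap, self.penalty_factor,
                                                   self.reg_band)
            traction = np.where(active, traction, 0.0)
            stiff = np.where(active, stiff, 0.0)
            self.state = PairState(gap=gap, normal=n, seg=seg, t=t,
                                   active=active, traction=traction,
                                   stiffness=stiff, sealed=sealed)
            return self.state
        gap, n, seg, t, interior = project_and_gap(
            coords[self.secondary], coords[self.primary], self.orient)
        active = (gap > 0.0) & interior
        traction, stiff = regularized_traction(gap, self.penalty_factor,
                                               self.reg_band)
        traction = np.where(active, traction, 0.0)
        stiff = np.where(active, stiff, 0.0)
        prev = self._sealed_prev
        if prev is None or len(prev) != len(gap):
            prev = np.zeros(len(gap), dtype=bool)
        sealed = np.where(prev, gap > 0.0, gap > self.reg_band) & interior
        self._sealed_prev = sealed
        self.state = PairState(gap=gap, normal=n, seg=seg, t=t,
                               active=active, traction=traction,
                               stiffness=stiff, sealed=sealed)
        return self.state

    # -- metrics ------------------------------------------------------------

    def contact_length(self, ref_nodes: np.ndarray) -> float:
        if self.state is None:
            return 0.0
        return float(self.tributary_lengths(ref_nodes)[self.state.active].sum())

    def transmitted_force(self, ref_nodes: np.ndarray) -> np.ndarray:
        """Integrated contact force vector (per unit depth, N/mm) acting on
        the secondary surface."""
        if self.state is None or not np.any(self.state.active):
            return np.zeros(2)
        st = self.state
        ell = self.tributary_lengths(ref_nodes)
        f = (st.traction * ell)[:, None] * st.normal
        return f[st.active].sum(axis=0)


def update_drainage(pairs: list[ContactPair], mesh, pressure_nodes: np.ndarray,
                    coords: np.ndarray, enabled: bool = True
                    ) -> tuple[np.ndarray, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Moving-boundary drainage conditions for the current contact state.

    Returns ``(drained_nodes, seal_ties)``: pressure-node ids to clamp at
    p = 0 (faces outside the contact patch) and, for each active secondary
    pressure node, a tie ``(node, primary_pressure_nodes, weights)``
    enforcing pressure continuity across the interface.

    With ``enabled=False`` every contact-face node drains freely regardless
    of contact status (the regression switch for demonstrating that the
    moving drainage boundary matters).
    """
    pset = set(pressure_nodes.tolist())
    drained: list[int] = []
    ties: list[tuple[int, np.ndarray, np.ndarray]] = []
    for pair in pairs:
        st = pair.state
        sec_p_mask = np.isin(pair.secondary, pressure_nodes)
        prim_p = pair.primary[np.isin(pair.primary, pressure_nodes)]
        prim_p_coords = coords[prim_p]
        if st is None or not enabled or not np.any(st.sealed):
            drained.extend(int(n) for n in pair.secondary[sec_p_mask])
            drained.extend(int(n) for n in prim_p)
            continue
        # secondary side
        for i, node in enumerate(pair.secondary):
            if node not in pset:
                continue
            if not st.sealed[i]:
                drained.append(int(node))
                continue
            gap, n, seg, t, interior = project_and_gap(
                coords[node][None, :], prim_p_coords, pair.orient)
            s, w = int(seg[0]), float(t[0])
            ties.append((int(node), prim_p[s:s + 2],
                         np.array([1.0 - w, w])))
        # primary side: corner nodes outside the sealed footprint drain
        act_sec = coords[pair.secondary[st.sealed]]
        gap, n, seg, t, interior = project_and_gap(
            act_sec, prim_p_coords, pair.orient)
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(prim_p_coords, axis=0), axis=1))])
        s_act = arc[seg] + t * (arc[seg + 1] - arc[seg])
        lo, hi = s_act.min(), s_act.max()
        spacing = np.diff(arc).mean()
        inside_fp = (arc >= lo - 0.6 * spacing) & (arc <= hi + 0.6 * spacing)
        drained.extend(int(nid) for nid, ok in zip(prim_p, inside_fp) if not ok)
    return np.unique(np.array(drained, dtype=int)), ties
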