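"""Mixed displacement-pressure finite-element engine.

Solves the coupled biphasic equations on a :class:`~poroknee.mesh.RegionMesh`:
solid momentum balance ``div(sigma_eff - p I) = 0`` and fluid continuity
``d(tr eps)/dt = div(k grad p)``, discretized with Q9/Q4 elements and
backward-Euler time integration.  Nonlinearities (tension-only fibrils,
penalty contact with a moving drainage boundary) are handled by Newton
iteration with the contact/fibril switching sets recomputed each iterate.

Kinematics are small-strain; the contact search runs on the deformed
configuration.  A warning is logged whenever any Gauss-point strain exceeds
15 %, the regime where the small-strain assumption degrades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .contact import ContactPair, regularized_traction, update_drainage
from .elements import FEOperators
from .materials import TissueMaterial

logger = logging.getLogger("poroknee")

__all__ = ["LoadSchedule", "SolverSettings", "RigidBody", "BiphasicModel",
           "StepState", "ramp_hold", "time_march"]


@dataclass
class LoadSchedule:
    """Ramp-hold vertical creep load on the rigid femur.

    total_force : N (applied downward)
    ramp_duration, hold_duration : s
    medial_offset : mm, load reference point medial (+x) of the joint centre
    """
    total_force: float = 800.0
    ramp_duration: float = 1.0
    hold_duration: float = 1200.0
    medial_offset: float = 5.0
    clamp: bool = False

    @property
    def end_time(self) -> float:
        return self.ramp_duration + self.hold_duration

    @property
    def equivalent_moment(self) -> float:
        """Adduction moment about the joint centre equivalent to the offset
        load, N m."""
        return self.total_force * self.medial_offset / 1000.0

    def force(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        if t <= self.ramp_duration:
            return self.total_force * t / self.ramp_duration
        if t <= self.end_time or self.clamp:
            return self.total_force
        raise ValueError(f"t={t} beyond schedule end {self.end_time} "
                         f"(set clamp=True to extend the hold)")


def ramp_hold(schedule: LoadSchedule, t: float) -> float:
    """Force value of a ramp-hold schedule at time t (N)."""
    return schedule.force(t)


@dataclass
class SolverSettings:
    dt_initial: float = 0.05
    dt_max: float = 50.0
    newton_tol_rel: float = 1e-6
    newton_max_iter: int = 25
    dt_growth: float = 1.7
    max_retries: int = 12
    newton_clip: float = 0.5        # max |du| per Newton update, mm
    freeze_iters: int = 12          # freeze switching sets after this iterate
    must_points: tuple = ()

    def __post_init__(self) -> None:
        if self.dt_initial <= 0:
            raise ValueError("dt_initial must be > 0")


@dataclass
class RigidBody:
    """Rigid femur: interface nodes coupled to vertical translation U and
    in-plane (varus-valgus analogue) rotation theta about ``ref_point``.
    Horizontal translation is fixed.  Small grounding springs keep the body
    well-posed before contact engages; their reactions are negligible
    against the applied load and are reported separately."""
    nodes: np.ndarray
    ref_point: np.ndarray
    grounding_translation: float = 0.01      # N/mm per mm depth
    grounding_rotation: float = 1.0          # N mm/rad per mm depth


@dataclass
class StepState:
    """Converged solution snapshot at one output time."""
    t: float
    u: np.ndarray                    # (2*Nn,)
    p: np.ndarray                    # (Np,) on mesh.pressure_nodes
    rigid: tuple | None              # (U, theta)
    pair_states: dict                # pair name -> dict of status arrays
    applied_force: float             # per unit depth, N/mm
    newton_iters: int = 0


class BiphasicModel:
    """Assembled biphasic problem: mesh + materials + constraints + contact."""

    def __init__(self, mesh, materials: dict[str, TissueMaterial],
                 fibre_labels: dict[str, str] | None = None) -> None:
        mesh.validate()
        self.mesh = mesh
        self.materials = materials
        self.ops = FEOperators(mesh)
        ne = len(mesh.elements)
        self.lam = np.zeros(ne)
        self.mu = np.zeros(ne)
        self.k = np.zeros(ne)
        self.E_f = np.zeros(ne)
        fibre_labels = fibre_labels or mesh.meta.get("fibre_label_by_region", {})
        for rid, name in enumerate(mesh.region_names):
            mat = materials[name]
            sel = mesh.region_id == rid
            lam, mu = mat.lame
            self.lam[sel], self.mu[sel], self.k[sel] = lam, mu, mat.permeability
            label = fibre_labels.get(name, "tangent")
            self.E_f[sel] = mat.fibril_moduli.get(label, 0.0)
        self.fibre_dir = mesh.fibre_dir

        # constant operators
        self.K = self.ops.stiffness_matrix(self.lam, self.mu)
        self.Bc = self.ops.coupling_matrix()
        self.H = self.ops.permeability_matrix(self.k)

        self.fixed_dofs: list[int] = []
        self.prescribed: list[tuple[int, object]] = []
        self.springs: list[tuple[int, float]] = []
        self.load_vectors: list[tuple[np.ndarray, object]] = []
        self.rigid: RigidBody | None = None
        self.rigid_load = None        # callable t -> (F_y, M_z) per unit depth
        self.pairs: list[ContactPair] = []
        self.drainage_switch = True
        self.seal_scale = 1e3
        self.penetration_warn_limit: float | None = None   # mm; warn if exceeded
        pn = mesh.pressure_nodes
        drain = np.intersect1d(mesh.tag("peripheral_draining"), pn)
        self.static_drained = drain
        self._pdof = {int(n): 2 * self.ops.n_nodes + i for i, n in enumerate(pn)}
        self._T = None

    # -- constraint builders ------------------------------------------------

    def fix_nodes(self, nodes, components=(0, 1)) -> None:
        for n in np.atleast_1d(nodes):
            for c in components:
                self.fixed_dofs.append(2 * int(n) + c)

    def prescribe_nodes(self, nodes, component: int, func) -> None:
        for n in np.atleast_1d(nodes):
            self.prescribed.append((2 * int(n) + component, func))

    def add_spring(self, node: int, component: int, stiffness: float) -> None:
        self.springs.append((2 * int(node) + component, float(stiffness)))

    def add_edge_traction(self, edge_nodes: np.ndarray, direction, scale_func) -> None:
        """Uniform traction on quadratic edges: consistent nodal loads
        weighted (1/6, 2/3, 1/6) per edge, scaled by ``scale_func(t)`` (MPa)."""
        direction = np.asarray(direction, float)
        base = np.zeros(self.ops.ndof)
        for edge in np.atleast_2d(edge_nodes):
            L = np.linalg.norm(self.mesh.nodes[edge[2]] - self.mesh.nodes[edge[0]])
            for nid, w in zip(edge, (1 / 6, 2 / 3, 1 / 6)):
                base[2 * nid:2 * nid + 2] += w * L * direction
        self.load_vectors.append((base, scale_func))

    def set_rigid_body(self, body: RigidBody, load_func=None) -> None:
        self.rigid = body
        self.rigid_load = load_func
        self._T = None

    # -- reduction (rigid-body master-slave elimination) --------------------

    def _build_transform(self) -> None:
        ndof = self.ops.ndof
        if self.rigid is None:
            self._T = sp.identity(ndof, format="csr")
            self._full2red = np.arange(ndof)
            self.nred = ndof
            self.dof_U = self.dof_th = None
            return
        slaves = np.concatenate([2 * self.rigid.nodes, 2 * self.rigid.nodes + 1])
        keep = np.setdiff1d(np.arange(ndof), slaves)
        nred = len(keep) + 2
        self.dof_U, self.dof_th = nred - 2, nred - 1
        full2red = -np.ones(ndof, dtype=int)
        full2red[keep] = np.arange(len(keep))
        rows, cols, vals = list(keep), list(range(len(keep))), [1.0] * len(keep)
        xr, yr = self.rigid.ref_point
        for n in self.rigid.nodes:
            x, y = self.mesh.nodes[n]
            rows += [2 * n, 2 * n + 1]
            cols += [self.dof_th, self.dof_U]
            vals += [-(y - yr), 1.0]
            rows.append(2 * n + 1)
            cols.append(self.dof_th)
            vals.append(x - xr)
        self._T = sp.csr_matrix((vals, (rows, cols)), shape=(ndof, nred))
        self._full2red = full2red
        self.nred = nred

    @property
    def T(self) -> sp.csr_matrix:
        if self._T is None:
            self._build_transform()
        return self._T

    def red_index(self, full_dof: int) -> int:
        i = self._full2red[full_dof]
        if i < 0:
            raise ValueError(f"DOF {full_dof} is slaved to the rigid body")
        return int(i)

    def full_vector(self, x_red: np.ndarray) -> np.ndarray:
        return self.T @ x_red

    # -- assembly -----------------------------------------------------------

    def external_load(self, t: float) -> np.ndarray:
        f = np.zeros(self.ops.ndof)
        for base, scale in self.load_vectors:
            f += base * scale(t)
        return f

    def _contact_terms(self, coords: np.ndarray):
        rows, cols, vals = [], [], []
        f = np.zeros(self.ops.ndof)
        for pair in self.pairs:
            st = pair.state
            if st is None or not np.any(st.active):
                continue
            ell = pair.tributary_lengths(self.mesh.nodes)
            for i in np.where(st.active)[0]:
                nids = [int(pair.secondary[i]),
                        int(pair.primary[st.seg[i]]),
                        int(pair.primary[st.seg[i] + 1])]
                s = np.array([-1.0, 1.0 - st.t[i], st.t[i]])
                n = st.normal[i]
                fmag = st.traction[i] * ell[i]
                kmag = st.stiffness[i] * ell[i]
                for a in range(3):
                    f[2 * nids[a]:2 * nids[a] + 2] += s[a] * fmag * n
                    for b in range(3):
                        blk = s[a] * s[b] * kmag * np.outer(n, n)
                        for ca in range(2):
                            for cb in range(2):
                                rows.append(2 * nids[a] + ca)
                                cols.append(2 * nids[b] + cb)
                                vals.append(blk[ca, cb])
        Kc = sp.csr_matrix((vals, (rows, cols)),
                           shape=(self.ops.ndof, self.ops.ndof))
        return f, Kc

    def _seal_matrix(self, ties) -> sp.csr_matrix:
        ndof = self.ops.ndof
        if not ties:
            return sp.csr_matrix((ndof, ndof))
        c = self.seal_scale * float(np.mean(self.k))
        rows, cols, vals = [], [], []
        for node, prim, w in ties:
            dofs = [self._pdof[int(node)]] + [self._pdof[int(m)] for m in prim]
            s = np.concatenate([[1.0], -w])
            for a in range(len(dofs)):
                for b in range(len(dofs)):
                    rows.append(dofs[a])
                    cols.append(dofs[b])
                    vals.append(c * s[a] * s[b])
        return sp.csr_matrix((vals, (rows, cols)), shape=(ndof, ndof))

    def internal_force(self, full: np.ndarray) -> np.ndarray:
        """Internal nodal force vector at a given full state (contact
        statuses are refreshed from the deformed coordinates).  The reaction
        at a constrained DOF is ``internal_force - external_load`` there."""
        nu2 = 2 * self.ops.n_nodes
        coords = self.mesh.nodes + full[:nu2].reshape(-1, 2)
        for pair in self.pairs:
            pair.update(coords)
        f_c, _ = self._contact_terms(coords)
        f_fib, _, _ = self.ops.fibril_force_tangent(full[:nu2], self.fibre_dir, self.E_f)
        f_sp, _ = self._spring_terms(full)
        return self.K @ full - self.Bc.T @ full + f_fib + f_c + f_sp

    def _spring_terms(self, full: np.ndarray):
        ndof = self.ops.ndof
        f = np.zeros(ndof)
        rows, cols, vals = [], [], []
        for dof, k in self.springs:
            f[dof] += k * full[dof]
            rows.append(dof)
            cols.append(dof)
            vals.append(k)
        return f, sp.csr_matrix((vals, (rows, cols)), shape=(ndof, ndof))


class _StepAssembler:
    """Residual/tangent assembly for one backward-Euler step."""

    def __init__(self, model: BiphasicModel, full_n: np.ndarray,
                 t: float, dt: float) -> None:
        self.model = model
        self.full_n = full_n
        self.t = t
        self.dt = dt
        self.nu2 = 2 * model.ops.n_nodes
        self.f_ext = model.external_load(t)
        self.mom_ref = max(np.abs(self.f_ext).max(), 1e-8)
        if model.rigid_load is not None:
            Fy, _ = model.rigid_load(t)
            self.mom_ref = max(self.mom_ref, abs(Fy), 1e-8)
        self.frozen = False
        self.frozen_fib = None
        self.frozen_drainage = None
        self._last_fib_mask = None
        self.is_p = np.zeros(model.nred, dtype=bool)
        self.is_p[model._full2red[self.nu2:]] = True

    def freeze(self) -> None:
        """Pin contact geometry and switching sets: the step becomes a
        smooth, nearly linear problem that Newton finishes in a few
        iterations.  See :meth:`ContactPair.freeze_geometry`."""
        for pair in self.model.pairs:
            pair.freeze_geometry()
        self.frozen = True
        self.frozen_fib = self._last_fib_mask.copy() \
            if self._last_fib_mask is not None else None

    def thaw(self) -> None:
        for pair in self.model.pairs:
            pair.thaw()
        self.frozen = False
        self.frozen_drainage = None

    def __call__(self, x: np.ndarray, need_A: bool):
        """Assemble residual (and tangent) at reduced state x.

        Returns dict with R, A (or None), dir_rows, free, sig, drained,
        ties, cont_ref, and scalar residual measures ru/rp/rd.
        """
        model, dt, t = self.model, self.dt, self.t
        full = model.full_vector(x)
        coords = model.mesh.nodes + full[:self.nu2].reshape(-1, 2)
        for pair in model.pairs:
            pair.update(coords)
        if self.frozen and self.frozen_drainage is not None:
            drained, ties = self.frozen_drainage
        else:
            drained, ties = update_drainage(
                model.pairs, model.mesh, model.mesh.pressure_nodes, coords,
                enabled=model.drainage_switch)
            if self.frozen:
                self.frozen_drainage = (drained, ties)
        sig = (tuple(tuple(p.state.active.tolist()) for p in model.pairs),
               tuple(drained.tolist()))

        f_c, Kc = model._contact_terms(coords)
        f_fib, Kfib, fib_mask = model.ops.fibril_force_tangent(
            full[:self.nu2], model.fibre_dir, model.E_f,
            forced_active=self.frozen_fib)
        self._last_fib_mask = fib_mask
        f_sp, Ksp = model._spring_terms(full)
        Cs = model._seal_matrix(ties)
        HC = model.H + Cs

        R = (model.K @ full - model.Bc.T @ full
             - model.Bc @ (full - self.full_n) - dt * (HC @ full)
             + f_fib + f_c + f_sp - self.f_ext)
        R = model.T.T @ R
        A = None
        if need_A:
            A = (model.K + Kfib + Kc + Ksp
                 - model.Bc.T - model.Bc - dt * HC)
            A = (model.T.T @ A @ model.T).tolil()

        if model.rigid is not None:
            gt = model.rigid.grounding_translation
            gr = model.rigid.grounding_rotation
            R[model.dof_U] += gt * x[model.dof_U]
            R[model.dof_th] += gr * x[model.dof_th]
            if need_A:
                A[model.dof_U, model.dof_U] += gt
                A[model.dof_th, model.dof_th] += gr
            if model.rigid_load is not None:
                Fy, Mz = model.rigid_load(t)
                R[model.dof_U] -= Fy
                R[model.dof_th] -= Mz

        dir_rows, dir_vals = [], []
        for dof in model.fixed_dofs:
            dir_rows.append(model.red_index(dof))
            dir_vals.append(0.0)
        for dof, func in model.prescribed:
            dir_rows.append(model.red_index(dof))
            dir_vals.append(func(t))
        pz = np.union1d(model.static_drained, drained)
        for node in pz:
            dir_rows.append(model.red_index(model._pdof[int(node)]))
            dir_vals.append(0.0)
        dir_rows = np.asarray(dir_rows, int)
        for r, v in zip(dir_rows, dir_vals):
            if need_A:
                A.rows[r] = [r]
                A.data[r] = [1.0]
            R[r] = x[r] - v

        free = np.setdiff1d(np.arange(model.nred), dir_rows)
        fu = free[~self.is_p[free]]
        fp = free[self.is_p[free]]
        cont_ref = max(np.abs(model.Bc @ (full - self.full_n)).max(),
                       dt * np.abs(HC @ full).max(), 1e-12)
        rd = np.abs(np.asarray(R)[dir_rows]).max(initial=0.0) if len(dir_rows) else 0.0
        merit = np.linalg.norm(R[fu]) / self.mom_ref + np.linalg.norm(R[fp]) / cont_ref
        if len(dir_rows):
            merit += np.linalg.norm(np.asarray(R)[dir_rows])
        return {
            "R": R, "A": A, "dir_rows": dir_rows, "sig": sig,
            "drained": drained, "ties": ties, "cont_ref": cont_ref,
            "ru": np.abs(R[fu]).max(initial=0.0),
            "rp": np.abs(R[fp]).max(initial=0.0),
            "rd": rd,
            "merit": float(merit),
        }


def _newton_step(model: BiphasicModel, x_red: np.ndarray, full_n: np.ndarray,
                 t: float, dt: float, settings: SolverSettings):
    """One backward-Euler step solved by damped Newton iteration.

    The contact search is geometrically nonlinear beyond the assembled
    tangent (frozen projections/normals), so the update is globalized by a
    backtracking line search on a scaled residual norm, with a hard cap on
    the displacement increment to prevent fall-through of open contacts.
    Returns (x_red, n_iters, drained, ties) or raises on divergence.
    """
    asm = _StepAssembler(model, full_n, t, dt)
    x = x_red.copy()
    prev_sig = None
    try:
        return _newton_loop(model, asm, x, t, dt, settings)
    finally:
        asm.thaw()


def _newton_loop(model, asm, x, t, dt, settings):
    prev_sig = None
    for it in range(settings.newton_max_iter):
        out = asm(x, need_A=True)
        ok = (out["ru"] <= settings.newton_tol_rel * asm.mom_ref
              and out["rp"] <= settings.newton_tol_rel * out["cont_ref"]
              and out["rd"] <= 1e-10)
        if logger.isEnabledFor(logging.DEBUG):
            nact = sum(int(p.state.active.sum()) for p in model.pairs
                       if p.state is not None)
            logger.debug("  it=%d ru=%.3e/%.1e rp=%.3e/%.1e act=%d ok=%s",
                         it, out["ru"], settings.newton_tol_rel * asm.mom_ref,
                         out["rp"], settings.newton_tol_rel * out["cont_ref"],
                         nact, ok)
        if ok and it > 0 and (out["sig"] == prev_sig or asm.frozen):
            return x, it, out["drained"], out["ties"]
        prev_sig = out["sig"]
        if not asm.frozen and it + 1 >= settings.freeze_iters:
            asm.freeze()

        dx = spla.spsolve(out["A"].tocsc(), -out["R"])
        if not np.all(np.isfinite(dx)):
            raise RuntimeError(
                "linear solve produced non-finite values; the system is "
                "singular (insufficient displacement or pressure constraints)")
        du_max = np.abs(dx[~asm.is_p]).max(initial=0.0)
        if du_max > settings.newton_clip:
            dx *= settings.newton_clip / du_max
        # backtracking line search on the scaled residual norm
        alpha = 1.0
        accepted = None
        for _ in range(5):
            trial = x + alpha * dx
            m = asm(trial, need_A=False)["merit"]
            if m <= (1.0 - 0.25 * alpha) * out["merit"]:
                accepted = trial
                break
            alpha *= 0.5
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("    alpha=%.4g merit %.3e -> %.3e", alpha,
                         out["merit"], m)
        x = accepted if accepted is not None else x + alpha * dx
    raise RuntimeError(f"Newton did not converge in {settings.newton_max_iter} "
                       f"iterations at t={t:.4g}, dt={dt:.4g}")


def _snapshot(model: BiphasicModel, x_red: np.ndarray, t: float,
              applied: float, iters: int) -> StepState:
    full = model.full_vector(x_red)
    nu2 = 2 * model.ops.n_nodes
    pair_states = {}
    for pair in model.pairs:
        st = pair.state
        ell = pair.tributary_lengths(model.mesh.nodes)
        pair_states[pair.name] = {
            "kind": pair.kind,
            "compartment": pair.compartment,
            "secondary": pair.secondary.copy(),
            "active": st.active.copy() if st is not None else np.zeros(len(pair.secondary), bool),
            "gap": st.gap.copy() if st is not None else np.zeros(len(pair.secondary)),
            "traction": st.traction.copy() if st is not None else np.zeros(len(pair.secondary)),
            "normal": st.normal.copy() if st is not None else np.zeros((len(pair.secondary), 2)),
            "ell": ell.copy(),
        }
    rigid = None
    if model.rigid is not None:
        rigid = (float(x_red[model.dof_U]), float(x_red[model.dof_th]))
    return StepState(t=t, u=full[:nu2].copy(), p=full[nu2:].copy(),
                     rigid=rigid, pair_states=pair_states,
                     applied_force=applied, newton_iters=iters)


def time_march(model: BiphasicModel, schedule: LoadSchedule | None,
               settings: SolverSettings, output_times,
               applied_force_func=None) -> tuple[list[StepState], list[dict]]:
    """March the model through the load schedule.

    ``output_times`` (strictly increasing, > 0) are hit exactly; a state
    snapshot is stored at each.  Time-step size adapts: it grows by
    ``dt_growth`` after each accepted step, shrinks by halving on Newton
    failure.  Returns (states, log).
    """
    output_times = np.asarray(sorted(output_times), float)
    if np.any(output_times <= 0):
        raise ValueError("output times must be > 0")
    must = np.unique(np.concatenate([output_times,
                                     np.asarray(settings.must_points, float)])) \
        if settings.must_points else output_times

    if applied_force_func is None:
        if schedule is None:
            applied_force_func = lambda t: 0.0
        else:
            applied_force_func = schedule.force

    _ = model.T          # build the rigid-body reduction before sizing vectors
    x = np.zeros(model.nred)
    full_n = model.full_vector(x)
    t = 0.0
    dt = settings.dt_initial
    states: list[StepState] = []
    log: list[dict] = []
    out_iter = iter(output_times)
    next_out = next(out_iter)
    must_iter = iter(must)
    next_must = next(must_iter)

    while True:
        dt_try = min(dt, next_must - t)
        retries = 0
        while True:
            try:
                x_new, iters, drained, ties = _newton_step(
                    model, x, full_n, t + dt_try, dt_try, settings)
                break
            except RuntimeError as err:
                retries += 1
                if retries > settings.max_retries:
                    logger.error("time march failed at t=%.4g: %s", t, err)
                    raise
                dt_try *= 0.5
                logger.info("Newton retry at t=%.4g with dt=%.4g", t, dt_try)
        t = t + dt_try
        x = x_new
        full_n = model.full_vector(x)
        log.append({"t": t, "dt": dt_try, "iters": iters})
        logger.info("accepted step t=%.4g dt=%.4g iters=%d", t, dt_try, iters)
        _check_strains(model, full_n, t)
        if model.penetration_warn_limit is not None and model.pairs:
            g = max((float(p.state.gap[p.state.active].max())
                     for p in model.pairs
                     if p.state is not None and np.any(p.state.active)),
                    default=0.0)
            if g > model.penetration_warn_limit:
                logger.warning("max contact penetration %.4f mm exceeds %.4f "
                               "mm at t=%.4g; consider a larger penalty "
                               "factor", g, model.penetration_warn_limit, t)
        if np.isclose(t, next_must, rtol=0, atol=1e-9 * max(1.0, next_must)):
            if np.isclose(t, next_out, rtol=0, atol=1e-9 * max(1.0, next_out)):
                states.append(_snapshot(model, x, t, applied_force_func(t), iters))
                next_out = next(out_iter, None)
            next_must = next(must_iter, None)
            if next_must is None:
                break
        dt = min(dt_try * settings.dt_growth, settings.dt_max)
    return states, log


def _check_strains(model: BiphasicModel, full: np.ndarray, t: float) -> None:
    eps = model.ops.strains(full[:2 * model.ops.n_nodes])
    m = np.abs(eps).max()
    if m > 0.15:
        logger.warning("max strain %.3f exceeds 15%% at t=%.4g; small-strain "
                       "kinematics degrade in this regime", m, t)
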