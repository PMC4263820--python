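"""Creep analysis of the synthetic coronal joint.

Builds the intact / meniscectomy joint models, runs the ramp-hold body-weight
protocol, and reduces the solution states to the study's output metrics:
femoral vertical displacement, contact areas per interface and compartment,
interface and compartment load partition, peak compressive stress (magnitude
of the third principal total stress), and fluid pressure / fluid support
ratio at named probe points on the tibial articular surface.

Forces are computed per unit out-of-plane depth in the plane-strain model
and reported in N after scaling by the configured depth, so the 800 N
protocol maps onto the 2-D cross-section consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactPair, auto_penalty
from .fem import BiphasicModel, LoadSchedule, RigidBody, SolverSettings, StepState, time_march
from .geometry import JointGeometryParams, make_coronal_joint
from .materials import TissueMaterial, material_preset

__all__ = [
    "CreepTimeSeries", "build_joint_model", "joint_output_times", "run_creep",
    "contact_metrics", "interface_load_partition", "fluid_support_ratio",
    "peak_compressive_stress", "compare_cases", "percent_increase",
    "compartment_shares",
]

TRACTION_THRESHOLD = 1e-4   # MPa; below this a probe is "out of contact"


def percent_increase(initial: float, final: float) -> float:
    """Percent change from initial to final, e.g. 0.95 -> 1.65 gives 73.7."""
    if initial == 0:
        raise ValueError("initial value must be nonzero")
    return 100.0 * (final - initial) / initial


def default_materials() -> dict[str, TissueMaterial]:
    return {name: material_preset(name)
            for name in ("femoral_cartilage", "tibial_cartilage", "meniscus")}


def _region_materials(mesh, materials: dict[str, TissueMaterial]
                      ) -> dict[str, TissueMaterial]:
    out = {}
    for name in mesh.region_names:
        if name.startswith("femoral"):
            out[name] = materials["femoral_cartilage"]
        elif name == "tibial":
            out[name] = materials["tibial_cartilage"]
        elif name.startswith("meniscus"):
            out[name] = materials["meniscus"]
        else:
            raise KeyError(f"no material mapping for region {name!r}")
    return out


def build_joint_model(mesh, materials: dict[str, TissueMaterial] | None = None,
                      schedule: LoadSchedule | None = None,
                      penalty_scale: float = 100.0,
                      seal_scale: float = 1e3,
                      drainage_switch: bool = True,
                      horn_attachment: str = "fixed",
                      horn_effective_length: float = 35.0) -> BiphasicModel:
    """Assemble the joint contact model from a coronal-joint mesh."""
    materials = materials or default_materials()
    schedule = schedule or LoadSchedule()
    meta = mesh.meta
    depth = meta["out_of_plane_depth"]
    xc, d_in, d_out = meta["condyle_centre_x"], meta["d_in"], meta["d_out"]
    yc = meta["condyle_centre_y"]
    intact = meta["variant"] == "intact"

    model = BiphasicModel(mesh, _region_materials(mesh, materials))
    model.seal_scale = seal_scale
    model.drainage_switch = drainage_switch
    params = meta.get("params")
    if params is not None:
        model.penetration_warn_limit = 0.01 * min(
            params.femoral_cartilage_thickness, params.tibial_cartilage_thickness)
    model.fix_nodes(mesh.tag("fixed_base"))

    body = RigidBody(nodes=mesh.tag("rigid_femur_interface"),
                     ref_point=np.asarray(meta["joint_centre"], float))
    offset = schedule.medial_offset

    def rigid_load(t):
        f2d = schedule.force(t) / depth
        return (-f2d, -offset * f2d)

    model.set_rigid_body(body, rigid_load)

    mats = {"femoral": materials["femoral_cartilage"],
            "tibial": materials["tibial_cartilage"],
            "meniscus": materials["meniscus"]}
    HA = {k: m.aggregate_modulus for k, m in mats.items()}

    tib_top = mesh.surfaces["tibial_top"]
    tx = mesh.nodes[tib_top, 0]
    char = np.diff(np.sort(tx)).mean()

    pairs: list[ContactPair] = []
    for side, sgn in (("med", 1.0), ("lat", -1.0)):
        comp = "medial" if side == "med" else "lateral"
        fem_surf = mesh.surfaces[f"femoral_{side}_articular"]
        d = sgn * (tx - sgn * xc)        # outward distance from the apex
        if intact:
            direct = tib_top[(d <= d_in) & (d >= -d_out)]
        else:
            direct = tib_top[np.abs(d) <= d_out]
        pairs.append(ContactPair(
            name=f"femoral-tibial-{side}", kind="femoral-tibial", compartment=comp,
            primary=fem_surf, secondary=direct, orient="right",
            penalty_factor=auto_penalty(HA["femoral"], HA["tibial"], char,
                                        penalty_scale)))
        if intact:
            men_top = mesh.surfaces[f"meniscus_{side}_top"]
            men_bot = mesh.surfaces[f"meniscus_{side}_bottom"]
            fx = mesh.nodes[fem_surf, 0]
            fd = sgn * (fx - sgn * xc)
            fem_sec = fem_surf[(fd >= d_in - 0.5) & (fd <= d_out + 0.5)]
            pairs.append(ContactPair(
                name=f"femoral-meniscus-{side}", kind="femoral-meniscus",
                compartment=comp, primary=men_top, secondary=fem_sec,
                orient="left",
                penalty_factor=auto_penalty(HA["femoral"], HA["meniscus"], char,
                                            penalty_scale)))
            men_sec = tib_top[(d > d_in) & (d <= d_out + 0.5)]
            pairs.append(ContactPair(
                name=f"meniscus-tibial-{side}", kind="meniscus-tibial",
                compartment=comp, primary=men_bot, secondary=men_sec,
                orient="right",
                penalty_factor=auto_penalty(HA["meniscus"], HA["tibial"], char,
                                            penalty_scale)))
    model.pairs = pairs

    if intact:
        # Horn attachment at the meniscal rim.  "fixed" clamps the rim nodes
        # in the transverse (horizontal) direction, the 2-D analogue of horns
        # rigidly anchored in the transverse plane; vertical motion stays
        # free.  "spring" instead tethers the rim with the hoop-stiffness of
        # the circumferential fibre bundle, E_circ * A_wedge / L_eff, divided
        # by the out-of-plane depth because model forces are per unit depth.
        anchors = mesh.tag("horn_anchor")
        if horn_attachment == "fixed":
            model.fix_nodes(anchors, components=(0,))
        elif horn_attachment == "spring":
            E_circ = materials["meniscus"].fibril_moduli.get("circumferential", 0.0)
            for side, sgn in (("med", 1.0), ("lat", -1.0)):
                rid = mesh.region_names.index(f"meniscus_{side}")
                area = model.ops.detJw[mesh.region_id == rid].sum()
                side_anchors = anchors[np.sign(mesh.nodes[anchors, 0]) == sgn]
                k_tot = E_circ * area / (horn_effective_length * depth)
                for n in side_anchors:
                    model.add_spring(int(n), 0, k_tot / len(side_anchors))
        else:
            raise ValueError(f"horn_attachment must be 'fixed' or 'spring', "
                             f"got {horn_attachment!r}")
    return model


def joint_output_times(schedule: LoadSchedule, n_hold: int = 20,
                       first_offset: float = 0.3) -> np.ndarray:
    """Output grid: end of ramp plus log-spaced hold times ending at the end
    of the hold."""
    t0 = schedule.ramp_duration
    hold = np.geomspace(first_offset, schedule.hold_duration, n_hold)
    return np.concatenate([[t0], t0 + hold])


# -- metrics ----------------------------------------------------------------


def _pair_vertical_force(ps: dict, depth: float) -> float:
    """Vertical force transmitted to the femur through one pair, N."""
    act = ps["active"]
    if not np.any(act):
        return 0.0
    fy = (ps["traction"] * ps["ell"] * ps["normal"][:, 1])[act].sum()
    if ps["kind"] == "femoral-tibial":
        # secondary surface is tibial: the femur sees the reaction
        fy = -fy
    elif ps["kind"] == "meniscus-tibial":
        fy = -fy
    return float(fy * depth)


def interface_load_partition(state: StepState, depth: float) -> dict:
    """Vertical load split by interface type and compartment, N.

    meniscus_path sums the femoral-meniscus pairs (the load entering the
    menisci from the femur); direct sums the femoral-tibial pairs.
    Compartment forces are femur-side sums, so medial + lateral equals the
    applied load when the femur is in equilibrium.
    """
    out = {"meniscus_path": 0.0, "direct": 0.0, "medial": 0.0, "lateral": 0.0,
           "meniscus_tibial": 0.0}
    for ps in state.pair_states.values():
        f = _pair_vertical_force(ps, depth)
        if ps["kind"] == "femoral-meniscus":
            out["meniscus_path"] += f
        elif ps["kind"] == "femoral-tibial":
            out["direct"] += f
        else:
            out["meniscus_tibial"] += f
            continue
        out[ps["compartment"]] += f
    out["total"] = out["meniscus_path"] + out["direct"]
    return out


def contact_metrics(state: StepState, depth: float) -> dict:
    """Contact areas (mm^2 = active length x depth) per pair and compartment.

    Compartment and total areas count the tibial-surface coverage (the
    femoral-tibial plus meniscus-tibial interfaces), so overlapping femoral-
    and tibial-side measures of the same patch are not double counted.
    """
    out = {"pairs": {}, "medial": 0.0, "lateral": 0.0, "total": 0.0}
    for name, ps in state.pair_states.items():
        area = float(ps["ell"][ps["active"]].sum() * depth)
        out["pairs"][name] = area
        if ps["kind"] in ("femoral-tibial", "meniscus-tibial"):
            out[ps["compartment"]] += area
    out["total"] = out["medial"] + out["lateral"]
    return out


def peak_compressive_stress(state: StepState, model: BiphasicModel,
                            region: str | None = "tibial") -> float:
    """Magnitude of the most negative principal total stress, MPa."""
    ops = model.ops
    s, szz = ops.effective_stress_at_gauss(state.u, model.lam, model.mu,
                                           model.fibre_dir, model.E_f)
    p = ops.pressures_at_gauss(state.p)
    sxx, syy, sxy = s[..., 0] - p, s[..., 1] - p, s[..., 2]
    szz = szz - p
    c = 0.5 * (sxx + syy)
    r = np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy ** 2)
    smin = np.minimum(c - r, szz)
    if region is not None:
        rid = model.mesh.region_names.index(region)
        smin = smin[model.mesh.region_id == rid]
    if smin.size == 0:
        raise ValueError(f"region {region!r} has no elements")
    return float(max(0.0, -smin.min()))


def _patch_centroid_node(state: StepState, model: BiphasicModel,
                         pair_name: str) -> int | None:
    """Traction-weighted centroid of a contact patch, snapped to the nearest
    active secondary pressure node."""
    ps = state.pair_states.get(pair_name)
    if ps is None or not np.any(ps["active"]):
        return None
    act = ps["active"]
    w = (ps["traction"] * ps["ell"])[act]
    xs = model.mesh.nodes[ps["secondary"][act], 0]
    x0 = float((w * xs).sum() / w.sum())
    pn = set(model.mesh.pressure_nodes.tolist())
    cand = [n for n in ps["secondary"][act] if int(n) in pn]
    if not cand:
        return None
    cand = np.asarray(cand)
    return int(cand[np.argmin(np.abs(model.mesh.nodes[cand, 0] - x0))])


def define_probes(ramp_state: StepState, model: BiphasicModel) -> dict[str, int]:
    """Probe node ids on the tibial surface, fixed material points chosen as
    the contact-patch centroids at the end of the ramp."""
    probes = {}
    for side in ("medial", "lateral"):
        tag = "med" if side == "medial" else "lat"
        n = _patch_centroid_node(ramp_state, model, f"femoral-tibial-{tag}")
        if n is not None:
            probes[f"condyle_centre_{side}"] = n
        n = _patch_centroid_node(ramp_state, model, f"meniscus-tibial-{tag}")
        if n is not None:
            probes[f"meniscus_interface_{side}"] = n
    return probes


def fluid_support_ratio(state: StepState, model: BiphasicModel,
                        probe_node: int, window: float = 1.6
                        ) -> tuple[float, float, float]:
    """(pressure MPa, contact pressure MPa, ratio) at a tibial surface probe.

    The contact pressure is the tributary-weighted average of the nodal
    penalty tractions within ``window`` mm of the probe along the surface:
    nodal tractions of a node-to-segment penalty method carry short-wave
    noise, while the pressure field is smooth, so a pointwise ratio is not
    mesh-stable.  NaN when the probe is out of contact.
    """
    pn = model.mesh.pressure_nodes
    x0 = model.mesh.nodes[probe_node, 0]
    pressure = float(state.p[np.searchsorted(pn, probe_node)])
    avg_p = pressure
    traction = 0.0
    for ps in state.pair_states.values():
        hit = np.where(ps["secondary"] == probe_node)[0]
        if not len(hit):
            continue
        xs = model.mesh.nodes[ps["secondary"], 0]
        corner = np.isin(ps["secondary"], pn)
        sel = ps["active"] & corner & (np.abs(xs - x0) <= window)
        if not np.any(sel):
            continue
        w = ps["ell"][sel]
        tr = float((ps["traction"][sel] * w).sum() / w.sum())
        if tr > traction:
            traction = tr
            pvals = state.p[np.searchsorted(pn, ps["secondary"][sel])]
            avg_p = float((pvals * w).sum() / w.sum())
    if traction < TRACTION_THRESHOLD:
        return pressure, traction, float("nan")
    return pressure, traction, avg_p / traction


@dataclass
class CreepTimeSeries:
    """Output trajectories of one creep run."""
    case: str
    times: np.ndarray
    applied_force: np.ndarray            # N
    displacement: np.ndarray             # mm, downward positive
    rotation: np.ndarray                 # rad, varus-valgus analogue
    area_medial: np.ndarray              # mm^2
    area_lateral: np.ndarray
    area_total: np.ndarray
    area_pairs: dict                     # pair name -> mm^2 series
    force_meniscus_path: np.ndarray      # N
    force_direct: np.ndarray
    force_medial: np.ndarray
    force_lateral: np.ndarray
    peak_stress: np.ndarray              # MPa (tibial cartilage)
    probes: dict                         # name -> {pressure, traction, fsr}
    free_travel: float = 0.0             # mm excluded from `displacement`
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "time_s": self.times,
            "applied_force_N": self.applied_force,
            "displacement_mm": self.displacement,
            "rotation_rad": self.rotation,
            "area_medial_mm2": self.area_medial,
            "area_lateral_mm2": self.area_lateral,
            "area_total_mm2": self.area_total,
            "force_meniscus_path_N": self.force_meniscus_path,
            "force_direct_N": self.force_direct,
            "force_medial_N": self.force_medial,
            "force_lateral_N": self.force_lateral,
            "peak_compressive_stress_MPa": self.peak_stress,
        }
        for name, rec in self.probes.items():
            d[f"pressure_{name}_MPa"] = rec["pressure"]
            d[f"fsr_{name}"] = rec["fsr"]
        return pd.DataFrame(d)


def summarize_states(case: str, states: list[StepState], model: BiphasicModel,
                     depth: float, free_travel: float = 0.0) -> CreepTimeSeries:
    nt = len(states)
    times = np.array([s.t for s in states])
    probes = define_probes(states[0], model)
    rec = {name: {"pressure": np.zeros(nt), "traction": np.zeros(nt),
                  "fsr": np.zeros(nt)} for name in probes}
    areas_m = np.zeros(nt)
    areas_l = np.zeros(nt)
    area_pairs: dict[str, np.ndarray] = {n: np.zeros(nt) for n in states[0].pair_states}
    fm = np.zeros(nt)
    fd = np.zeros(nt)
    fmed = np.zeros(nt)
    flat = np.zeros(nt)
    stress = np.zeros(nt)
    disp = np.zeros(nt)
    rot = np.zeros(nt)
    applied = np.zeros(nt)
    for i, s in enumerate(states):
        cm = contact_metrics(s, depth)
        areas_m[i], areas_l[i] = cm["medial"], cm["lateral"]
        for n, a in cm["pairs"].items():
            area_pairs[n][i] = a
        lp = interface_load_partition(s, depth)
        fm[i], fd[i] = lp["meniscus_path"], lp["direct"]
        fmed[i], flat[i] = lp["medial"], lp["lateral"]
        stress[i] = peak_compressive_stress(s, model)
        if s.rigid is not None:
            disp[i] = -s.rigid[0] - free_travel
            rot[i] = s.rigid[1]
        applied[i] = s.applied_force
        for name, node in probes.items():
            pr, tr, ratio = fluid_support_ratio(s, model, node)
            rec[name]["pressure"][i] = pr
            rec[name]["traction"][i] = tr
            rec[name]["fsr"][i] = ratio
    return CreepTimeSeries(
        case=case, times=times, applied_force=applied, displacement=disp,
        rotation=rot, area_medial=areas_m, area_lateral=areas_l,
        area_total=areas_m + areas_l, area_pairs=area_pairs,
        force_meniscus_path=fm, force_direct=fd, force_medial=fmed,
        force_lateral=flat, peak_stress=stress, probes=rec,
        free_travel=free_travel,
        meta={"depth": depth, "probe_nodes": probes})


def run_creep(case: str, geometry: JointGeometryParams | None = None,
              materials: dict[str, TissueMaterial] | None = None,
              schedule: LoadSchedule | None = None,
              settings: SolverSettings | None = None,
              output_times=None,
              penalty_scale: float = 100.0, seal_scale: float = 1e3,
              drainage_switch: bool = True,
              horn_attachment: str = "fixed",
              horn_effective_length: float = 35.0,
              return_model: bool = False):
    """Full pipeline for one joint variant: geometry -> model -> time march
    -> metrics.  ``case`` is "intact" or "meniscectomy"."""
    geometry = geometry or JointGeometryParams()
    if geometry.variant != case:
        geometry = JointGeometryParams(**{**geometry.__dict__, "variant": case})
    schedule = schedule or LoadSchedule()
    settings = settings or SolverSettings()
    mesh = make_coronal_joint(geometry)
    model = build_joint_model(mesh, materials, schedule,
                              penalty_scale=penalty_scale, seal_scale=seal_scale,
                              drainage_switch=drainage_switch,
                              horn_attachment=horn_attachment,
                              horn_effective_length=horn_effective_length)
    if output_times is None:
        output_times = joint_output_times(schedule)
    states, log = time_march(model, schedule, settings, output_times)
    # meniscectomy displacement is conventionally counted from first
    # cartilage-cartilage contact; the free travel across the initial gap
    # left by removing the menisci is excluded
    free_travel = geometry.initial_gap if case == "meniscectomy" else 0.0
    ts = summarize_states(case, states, model, geometry.out_of_plane_depth,
                          free_travel=free_travel)
    ts.meta["log"] = log
    ts.meta["case"] = case
    if return_model:
        return ts, states, model
    return ts


def compartment_shares(ts: CreepTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """(medial, lateral) load fractions over time."""
    tot = ts.force_medial + ts.force_lateral
    return ts.force_medial / tot, ts.force_lateral / tot


def compare_cases(intact: CreepTimeSeries, menisc: CreepTimeSeries) -> dict:
    """Intact vs meniscectomy comparison report (JSON-serializable)."""
    if len(intact.times) != len(menisc.times) or not np.allclose(
            intact.times, menisc.times):
        raise ValueError("time grids differ; rerun with a common output grid")
    t = intact.times
    area_ratio = menisc.area_total / intact.area_total
    stress_ratio = menisc.peak_stress / intact.peak_stress
    report = {
        "times_s": t.tolist(),
        "area_ratio_menisc_over_intact": area_ratio.tolist(),
        "stress_ratio_menisc_over_intact": stress_ratio.tolist(),
        "displacement_intact_mm": intact.displacement.tolist(),
        "displacement_meniscectomy_mm": menisc.displacement.tolist(),
        "orderings": {
            "meniscectomy_area_smaller_at_all_times": bool(np.all(area_ratio < 1)),
            "meniscectomy_stress_larger_at_all_times": bool(np.all(stress_ratio > 1)),
            "displacement_monotone_intact": bool(
                np.all(np.diff(intact.displacement) >= -1e-9)),
            "displacement_monotone_meniscectomy": bool(
                np.all(np.diff(menisc.displacement) >= -1e-9)),
        },
    }
    fsr_centre = intact.probes.get("condyle_centre_medial", {}).get("fsr")
    fsr_edge = intact.probes.get("meniscus_interface_medial", {}).get("fsr")
    if fsr_centre is not None and fsr_edge is not None:
        ok = ~(np.isnan(fsr_centre) | np.isnan(fsr_edge))
        report["orderings"]["centre_fsr_decays_slower_than_meniscus_interface"] = bool(
            np.all(fsr_centre[ok] >= fsr_edge[ok] - 1e-6))
    return report
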