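"""Finite-element engine verified against closed-form biphasic solutions."""

import numpy as np
import pytest

from poroknee.fem import BiphasicModel, SolverSettings, time_march
from poroknee.geometry import make_confined_column, make_unconfined_strip
from poroknee.oracles import (
    ConfinedCreepSpec,
    confined_creep_displacement,
    gel_diffusion_time,
    unconfined_limit_moduli,
)

from conftest import run_confined_column


class TestConfinedCreep:
    def test_matches_series_solution(self, femoral_material):
        out_tg = np.geomspace(0.01, 3.0, 12)
        mesh, model, states, disp, tg, log = run_confined_column(
            femoral_material, out_times_tg=out_tg)
        spec = ConfinedCreepSpec(applied_stress=0.05, thickness=2.0,
                                 aggregate_modulus=femoral_material.aggregate_modulus,
                                 permeability=femoral_material.permeability)
        ana = confined_creep_displacement(spec, out_tg * tg)
        rel_l2 = np.sqrt(np.sum((disp - ana) ** 2) / np.sum(ana ** 2))
        assert rel_l2 < 0.02
        # creep is monotone non-decreasing
        assert np.all(np.diff(disp) > 0)

    def test_confined_response_independent_of_fibrils(self, femoral_material,
                                                      femoral_no_fibrils):
        # fibres lie parallel to the loaded surface: zero fibre strain in
        # confined compression, so the fibril moduli cannot matter
        *_, disp_a, _, _ = run_confined_column(femoral_material,
                                               out_times_tg=(0.2, 1.0))
        *_, disp_b, _, _ = run_confined_column(femoral_no_fibrils,
                                               out_times_tg=(0.2, 1.0))
        assert np.allclose(disp_a, disp_b, rtol=1e-10)

    def test_drained_equilibrium_pressure_vanishes(self, femoral_material):
        mesh, model, states, disp, tg, log = run_confined_column(
            femoral_material, out_times_tg=(10.0,))
        s = states[-1]
        assert np.abs(s.p).max() < 1e-3 * 0.05
        # equilibrium settlement sigma0 h / H_A
        assert disp[-1] == pytest.approx(
            0.05 * 2.0 / femoral_material.aggregate_modulus, rel=1e-3)

    def test_draining_boundary_pressure_is_zero(self, femoral_material):
        mesh, model, states, *_ = run_confined_column(femoral_material,
                                                      out_times_tg=(0.1,))
        pn = list(mesh.pressure_nodes)
        for node in np.intersect1d(mesh.tag("peripheral_draining"),
                                   mesh.pressure_nodes):
            assert states[0].p[pn.index(node)] == 0.0

    def test_time_step_self_convergence(self, femoral_material):
        # halving the initial time step leaves the final settlement unchanged
        # to within 0.1 %
        _, _, _, d1, tg, _ = run_confined_column(femoral_material,
                                                 out_times_tg=(0.5,))
        _, _, _, d2, _, _ = run_confined_column(femoral_material,
                                                out_times_tg=(0.5,),
                                                dt0_frac=0.125)
        assert abs(d2[-1] - d1[-1]) / d1[-1] < 1e-3


@pytest.fixture(scope="module")
def strip_run(femoral_no_fibrils):
    mat = femoral_no_fibrils
    W, H = 4.0, 2.0
    mesh = make_unconfined_strip(W, H, 8)
    model = BiphasicModel(mesh, {"strip": mat})
    tg = gel_diffusion_time(W / 2, mat.aggregate_modulus, mat.permeability)
    t_ramp = 1e-4 * tg
    eps = 0.02
    model.prescribe_nodes(mesh.tag("platen_top"), 1,
                          lambda t: -eps * H * min(t / t_ramp, 1.0))
    model.fix_nodes(mesh.tag("platen_bottom"), components=(1,))
    model.fix_nodes(mesh.tag("pin_x"), components=(0,))
    out = np.array([2e-4 * tg, 10 * tg])
    settings = SolverSettings(dt_initial=t_ramp / 4, dt_max=2 * tg,
                              dt_growth=1.8, must_points=(t_ramp,))
    states, _ = time_march(model, None, settings, out)
    moduli = []
    for s in states:
        f = model.internal_force(np.concatenate([s.u, s.p]))
        F = -sum(f[2 * int(n) + 1] for n in mesh.tag("platen_top"))
        moduli.append((F / W) / eps)
    return mat, moduli


class TestUnconfinedStripLimits:
    def test_instantaneous_modulus_is_4mu(self, strip_run):
        mat, (inst, _) = strip_run
        target, _ = unconfined_limit_moduli(mat.matrix_modulus,
                                            mat.poisson_ratio, mat.lame[1])
        assert inst == pytest.approx(target, rel=0.05)

    def test_equilibrium_modulus_is_plane_strain_E(self, strip_run):
        mat, (_, eq) = strip_run
        _, target = unconfined_limit_moduli(mat.matrix_modulus,
                                            mat.poisson_ratio, mat.lame[1])
        assert eq == pytest.approx(target, rel=0.02)


class TestAssemblyProperties:
    def test_zero_load_zero_residual(self, femoral_material):
        mesh = make_confined_column(2.0, 4)
        model = BiphasicModel(mesh, {"column": femoral_material})
        f = model.internal_force(np.zeros(model.ops.ndof))
        assert np.abs(f).max() == 0.0

    def test_system_matrix_symmetric_without_switching(self, femoral_material):
        mesh = make_confined_column(2.0, 4)
        model = BiphasicModel(mesh, {"column": femoral_material})
        dt = 0.1
        A = (model.K - model.Bc.T - model.Bc - dt * model.H)
        asym = abs(A - A.T).max()
        assert asym < 1e-10

    def test_singular_system_diagnosed(self, femoral_material):
        # loaded body with no displacement constraints: rigid modes make the
        # system singular and the solver must say so
        mesh = make_confined_column(2.0, 2)
        model = BiphasicModel(mesh, {"column": femoral_material})
        model.add_edge_traction(mesh.edges["loaded_top"], (0.0, -1.0),
                                lambda t: 0.05)
        settings = SolverSettings(dt_initial=0.1, max_retries=0,
                                  newton_max_iter=4)
        with pytest.raises(RuntimeError):
            time_march(model, None, settings, [0.1])
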