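import logging

import numpy as np
import pytest

from poroknee.analysis import run_creep
from poroknee.fem import BiphasicModel, SolverSettings, time_march
from poroknee.geometry import make_confined_column, make_unconfined_strip
from poroknee.materials import TissueMaterial, material_preset
from poroknee.oracles import gel_diffusion_time

logging.getLogger("poroknee").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def joint_runs():
    """Full default ramp-hold creep runs of both joint variants.

    Expensive (a few minutes); shared by the joint-behaviour and acceptance
    tests so the protocol is simulated once per session.
    """
    return {
        "intact": run_creep("intact"),
        "meniscectomy": run_creep("meniscectomy"),
    }


@pytest.fixture(scope="session")
def femoral_material():
    return material_preset("femoral_cartilage")


@pytest.fixture(scope="session")
def femoral_no_fibrils():
    return TissueMaterial(name="femoral_no_fibrils", matrix_modulus=0.64,
                          poisson_ratio=0.08, permeability=0.00116,
                          fibril_moduli={})


def run_confined_column(material, sigma0=0.05, height=2.0, n_el=20,
                        out_times_tg=(0.05, 0.5, 2.0), thin_ramp=1e-3,
                        dt0_frac=0.25):
    """Shared driver: Terzaghi creep column under a fast ramp-then-hold load."""
    mesh = make_confined_column(height, n_el)
    model = BiphasicModel(mesh, {"column": material})
    model.fix_nodes(mesh.tag("fixed_base"))
    model.fix_nodes(mesh.tag("roller_x"), components=(0,))
    tg = gel_diffusion_time(height, material.aggregate_modulus,
                            material.permeability)
    t_ramp = thin_ramp * tg
    model.add_edge_traction(mesh.edges["loaded_top"], (0.0, -1.0),
                            lambda t: sigma0 * min(t / t_ramp, 1.0))
    out = np.asarray(out_times_tg) * tg
    settings = SolverSettings(dt_initial=dt0_frac * t_ramp, dt_max=tg / 4,
                              dt_growth=1.6, must_points=(t_ramp,))
    states, log = time_march(model, None, settings, out)
    top_mid = mesh.tag("peripheral_draining")[1]
    disp = np.array([-s.u[2 * top_mid + 1] for s in states])
    return mesh, model, states, disp, tg, log
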