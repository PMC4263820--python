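"""Point-level constitutive law: elastic constants, fibrils, Darcy flow."""

import numpy as np
import pytest

from poroknee.materials import (
    TABLE_PRESETS,
    IncompressibilityError,
    TissueMaterial,
    darcy_flux,
    derived_elastic_constants,
    fibril_stress,
    material_preset,
    matrix_effective_stress,
    total_stress,
)


@pytest.mark.parametrize(
    "E, nu, expected",
    [
        (0.64, 0.08, (0.0564, 0.2963, 0.6490)),   # femoral cartilage constants
        (0.84, 0.03, (0.0260, 0.4078, 0.8416)),   # tibial cartilage constants
        (1.70, 0.0, (0.0, 0.85, 1.70)),           # nu = 0 collapses lambda
    ],
)
def test_derived_elastic_constants(E, nu, expected):
    lam, mu, HA = derived_elastic_constants(E, nu)
    assert lam == pytest.approx(expected[0], abs=5e-5)
    assert mu == pytest.approx(expected[1], abs=5e-5)
    assert HA == pytest.approx(expected[2], abs=5e-5)
    assert HA == pytest.approx(lam + 2 * mu, rel=1e-12)


def test_incompressible_poisson_ratio_rejected():
    with pytest.raises(IncompressibilityError):
        derived_elastic_constants(1.0, 0.5)
    with pytest.raises(IncompressibilityError):
        TissueMaterial(matrix_modulus=1.0, poisson_ratio=0.55, permeability=1e-3)


def test_matrix_effective_stress_uniaxial_and_shear():
    lam, mu, HA = derived_elastic_constants(0.64, 0.08)
    eps = np.array([[0.0, 0.0], [0.0, -0.1]])
    sig = matrix_effective_stress(eps, lam, mu)
    assert sig[1, 1] == pytest.approx(-HA * 0.1, rel=1e-10)       # -0.0649
    assert sig[0, 0] == pytest.approx(-lam * 0.1, rel=1e-10)      # -0.00564
    shear = np.array([[0.0, 0.05], [0.05, 0.0]])
    sig = matrix_effective_stress(shear, lam, mu)
    assert sig[0, 1] == pytest.approx(2 * mu * 0.05, rel=1e-10)   # 0.0296
    assert np.allclose(matrix_effective_stress(np.zeros((2, 2)), lam, mu), 0.0)


def test_matrix_stress_rejects_asymmetric_strain():
    with pytest.raises(ValueError):
        matrix_effective_stress(np.array([[0.0, 0.1], [0.0, 0.0]]), 1.0, 1.0)


def test_fibril_stress_tension_only():
    d = np.array([1.0, 0.0])
    # fibre in compression: no stress
    eps_c = np.diag([-0.05, 0.0])
    assert np.allclose(fibril_stress(eps_c, d, 40.0), 0.0)
    # meniscus circumferential modulus in tension: rank-one along the fibre
    eps_t = np.diag([0.01, 0.0])
    sig = fibril_stress(eps_t, d, 40.0)
    assert sig[0, 0] == pytest.approx(0.4, rel=1e-12)
    assert sig[1, 1] == 0.0 and sig[0, 1] == 0.0
    # degenerate modulus
    assert np.allclose(fibril_stress(eps_t, d, 0.0), 0.0)


def test_fibril_stress_monotone_in_modulus():
    rng = np.random.default_rng(7)
    d = np.array([np.sqrt(0.5), np.sqrt(0.5)])
    e = rng.normal(size=(2, 2))
    eps = 0.05 * (e + e.T)
    if float(d @ eps @ d) <= 0:
        eps = -eps
    prev = -1.0
    for Ef in (1.0, 5.0, 20.0):
        s = float(d @ fibril_stress(eps, d, Ef) @ d)
        assert s > prev
        prev = s


def test_fibril_requires_unit_direction():
    with pytest.raises(ValueError):
        fibril_stress(np.zeros((2, 2)), np.array([1.0, 1.0]), 10.0)


def test_total_stress_decomposition():
    rng = np.random.default_rng(3)
    e = rng.normal(size=(2, 2))
    sig_eff = e + e.T
    p = 0.37
    tot = total_stress(sig_eff, p)
    assert np.allclose(tot, sig_eff - p * np.eye(2), atol=1e-15)
    assert np.trace(tot) == pytest.approx(np.trace(sig_eff) - 2 * p, rel=1e-12)
    assert np.allclose(total_stress(sig_eff, 0.0), sig_eff)
    assert np.allclose(total_stress(np.zeros((2, 2)), 0.5), -0.5 * np.eye(2))


def test_darcy_flux_linearity():
    w = darcy_flux(np.array([1.0, 0.0]), 0.00116)
    assert np.allclose(w, [-0.00116, 0.0])
    assert np.allclose(darcy_flux(np.zeros(2), 0.001), 0.0)
    g = np.array([0.3, -0.2])
    assert np.allclose(darcy_flux(g, 0.002), 2 * darcy_flux(g, 0.001))
    with pytest.raises(ValueError):
        darcy_flux(g, 0.0)


def test_presets_round_trip_through_serialization():
    assert set(TABLE_PRESETS) == {"femoral_cartilage", "tibial_cartilage",
                                  "meniscus", "meniscus_absent"}
    for name in TABLE_PRESETS:
        mat = material_preset(name)
        again = TissueMaterial.from_dict(mat.to_dict())
        assert again == mat
    men = material_preset("meniscus")
    assert men.fibril_moduli == {"circumferential": 40.0, "radial": 10.0}
    assert men.matrix_modulus == 1.0 and men.permeability == 0.001
    fem = material_preset("femoral_cartilage")
    assert (fem.matrix_modulus, fem.poisson_ratio, fem.permeability) == (
        0.64, 0.08, 0.00116)
    assert fem.fibril_moduli["tangent"] == 5.6


def test_unknown_preset_and_unknown_keys_rejected():
    with pytest.raises(KeyError):
        material_preset("ligament")
    with pytest.raises(ValueError):
        TissueMaterial.from_dict({"matrix_modulus": 1.0, "poisson_ratio": 0.1,
                                  "permeability": 1e-3, "osmotic": 0.1})


# property-based checks of the constitutive algebra
from hypothesis import given, settings, strategies as st

sym_strain = st.builds(
    lambda a, b, c: np.array([[a, c], [c, b]]),
    *(st.floats(-0.2, 0.2, allow_nan=False) for _ in range(3)))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(eps=sym_strain, p=st.floats(-1.0, 1.0, allow_nan=False))
def test_total_stress_identity_holds_pointwise(eps, p):
    lam, mu, _ = derived_elastic_constants(0.64, 0.08)
    sig_eff = matrix_effective_stress(eps, lam, mu)
    tot = total_stress(sig_eff, p)
    assert np.allclose(tot + p * np.eye(2), sig_eff, atol=1e-14)
    assert np.allclose(tot, tot.T)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(eps=sym_strain, theta=st.floats(0.0, np.pi, allow_nan=False),
       ef1=st.floats(0.0, 50.0), ef2=st.floats(0.0, 50.0))
def test_fibril_stress_tension_only_and_monotone(eps, theta, ef1, ef2):
    d = np.array([np.cos(theta), np.sin(theta)])
    lo, hi = sorted((ef1, ef2))
    s_lo = float(d @ fibril_stress(eps, d, lo) @ d)
    s_hi = float(d @ fibril_stress(eps, d, hi) @ d)
    assert s_lo >= 0.0 and s_hi >= 0.0        # never compressive
    assert s_hi >= s_lo - 1e-12               # monotone in the modulus
    if float(d @ eps @ d) <= 0:
        assert s_hi == 0.0
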