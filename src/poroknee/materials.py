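"""Fibril-reinforced biphasic material law at a single material point.

The solid skeleton is split into an isotropic non-fibrillar matrix (linear
elastic, parameters ``matrix_modulus``/``poisson_ratio``) and one or more
collagen-fibril families that carry stress only in tension.  The interstitial
fluid contributes a pore pressure ``p`` so that the total (mixture) stress is

    sigma_total = sigma_effective - p * I

with stress tension-positive and pressure compression-positive.  Fluid
transport follows Darcy's law with a constant isotropic permeability.

Units are fixed to the N-mm-s system: stresses and moduli in MPa, lengths in
mm, permeability in mm^4/(N s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IncompressibilityError",
    "TissueMaterial",
    "TABLE_PRESETS",
    "material_preset",
    "derived_elastic_constants",
    "matrix_effective_stress",
    "fibril_stress",
    "total_stress",
    "darcy_flux",
]


class IncompressibilityError(ValueError):
    """Raised when the drained Poisson ratio reaches the incompressible limit.

    Biphasic theory requires a compressible drained skeleton (nu < 0.5);
    instantaneous incompressibility is produced by the trapped fluid, not by
    the matrix itself.
    """


@dataclass
class TissueMaterial:
    """Constants of one tissue region.

    Parameters
    ----------
    matrix_modulus : float
        Equilibrium (drained) compressive Young's modulus of the non-fibrillar
        matrix, MPa.
    poisson_ratio : float
        Drained Poisson ratio of the matrix, dimensionless, in [0, 0.5).
    fibril_moduli : dict
        Tensile modulus per fibril family, keyed by a direction label
        (e.g. ``"tangent"``, ``"radial"``, ``"circumferential"``), MPa.
    permeability : float
        Hydraulic permeability, mm^4/(N s).
    name : str
        Tissue label.
    """

    matrix_modulus: float
    poisson_ratio: float
    permeability: float
    fibril_moduli: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.matrix_modulus <= 0:
            raise ValueError(f"matrix_modulus must be > 0, got {self.matrix_modulus}")
        if not (0.0 <= self.poisson_ratio < 0.5):
            if self.poisson_ratio >= 0.5:
                raise IncompressibilityError(
                    f"poisson_ratio must be < 0.5 (drained matrix must be "
                    f"compressible), got {self.poisson_ratio}"
                )
            raise ValueError(f"poisson_ratio must be >= 0, got {self.poisson_ratio}")
        if self.permeability <= 0:
            raise ValueError(f"permeability must be > 0, got {self.permeability}")
        for label, ef in self.fibril_moduli.items():
            if ef < 0:
                raise ValueError(f"fibril modulus {label!r} must be >= 0, got {ef}")

    @property
    def lame(self) -> tuple[float, float]:
        """Drained Lame constants (lambda, mu), MPa."""
        lam, mu, _ = derived_elastic_constants(self.matrix_modulus, self.poisson_ratio)
        return lam, mu

    @property
    def aggregate_modulus(self) -> float:
        """Confined-compression (aggregate) modulus H_A = lambda + 2 mu, MPa."""
        return derived_elastic_constants(self.matrix_modulus, self.poisson_ratio)[2]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "matrix_modulus": self.matrix_modulus,
            "poisson_ratio": self.poisson_ratio,
            "permeability": self.permeability,
            "fibril_moduli": dict(self.fibril_moduli),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueMaterial":
        known = {"name", "matrix_modulus", "poisson_ratio", "permeability", "fibril_moduli"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TissueMaterial keys: {sorted(unknown)}")
        return cls(**d)


def _presets() -> dict[str, TissueMaterial]:
    # Literature mid-values for adult human knee tissues.  The meniscus matrix
    # modulus is the physiological-strain-rate value (1.0 MPa) rather than the
    # lowest reported equilibrium value, which keeps the wedge cross-section
    # from collapsing onto itself.  "meniscus_absent" is the bookkeeping preset
    # for the double-meniscectomy variant, whose meshes contain no meniscus
    # regions at all.
    return {
        "femoral_cartilage": TissueMaterial(
            name="femoral_cartilage",
            matrix_modulus=0.64,
            poisson_ratio=0.08,
            permeability=0.00116,
            fibril_moduli={"tangent": 5.6},
        ),
        "tibial_cartilage": TissueMaterial(
            name="tibial_cartilage",
            matrix_modulus=0.84,
            poisson_ratio=0.03,
            permeability=0.00326,
            fibril_moduli={"tangent": 5.6},
        ),
        "meniscus": TissueMaterial(
            name="meniscus",
            matrix_modulus=1.0,
            poisson_ratio=0.03,
            permeability=0.00100,
            fibril_moduli={"circumferential": 40.0, "radial": 10.0},
        ),
        "meniscus_absent": TissueMaterial(
            name="meniscus_absent",
            matrix_modulus=1.0,
            poisson_ratio=0.03,
            permeability=0.00100,
            fibril_moduli={},
        ),
    }


TABLE_PRESETS: dict[str, TissueMaterial] = _presets()


def material_preset(name: str) -> TissueMaterial:
    """Return a fresh copy of a shipped tissue preset by name."""
    try:
        src = TABLE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {name!r}; available: {sorted(TABLE_PRESETS)}"
        ) from None
    return TissueMaterial.from_dict(src.to_dict())


def derived_elastic_constants(E: float, nu: float) -> tuple[float, float, float]:
    """Convert (E, nu) to (lambda, mu, aggregate modulus H_A = lambda + 2 mu)."""
    if E <= 0:
        raise ValueError(f"E must be > 0, got {E}")
    if nu >= 0.5:
        raise IncompressibilityError(
            f"nu must be < 0.5 for a drained biphasic matrix, got {nu}"
        )
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu, lam + 2.0 * mu


def _check_symmetric(strain: np.ndarray) -> np.ndarray:
    strain = np.asarray(strain, dtype=float)
    if strain.shape != (2, 2):
        raise ValueError(f"strain must be a 2x2 tensor, got shape {strain.shape}")
    if not np.allclose(strain, strain.T, atol=1e-12):
        raise ValueError("strain tensor must be symmetric")
    return strain


def matrix_effective_stress(strain: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """In-plane effective stress of the non-fibrillar matrix (plane strain).

    sigma = lambda * tr(eps) * I + 2 mu * eps.  The out-of-plane component
    sigma_zz = lambda * tr(eps) is not part of the returned 2x2 tensor.
    """
    strain = _check_symmetric(strain)
    return lam * np.trace(strain) * np.eye(2) + 2.0 * mu * strain


def fibril_stress(strain: np.ndarray, fibre_dir: np.ndarray, E_f: float) -> np.ndarray:
    """Tension-only fibril stress: E_f * <eps_f> * (d x d), rank one along d."""
    strain = _check_symmetric(strain)
    d = np.asarray(fibre_dir, dtype=float)
    if d.shape != (2,) or not np.isclose(np.linalg.norm(d), 1.0, atol=1e-8):
        raise ValueError("fibre_dir must be a unit 2-vector")
    eps_f = float(d @ strain @ d)
    if eps_f <= 0.0 or E_f == 0.0:
        return np.zeros((2, 2))
    return E_f * eps_f * np.outer(d, d)


def total_stress(effective_stress: np.ndarray, p: float) -> np.ndarray:
    """Mixture stress sigma_total = sigma_effective - p * I."""
    effective_stress = np.asarray(effective_stress, dtype=float)
    if not np.isfinite(p):
        raise ValueError("pressure must be finite")
    return effective_stress - p * np.eye(effective_stress.shape[0])


def darcy_flux(grad_p: np.ndarray, k: float) -> np.ndarray:
    """Darcy fluid flux w = -k grad(p), mm/s."""
    if k <= 0:
        raise ValueError(f"permeability must be > 0, got {k}")
    return -k * np.asarray(grad_p, dtype=float)
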