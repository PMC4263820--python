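"""Closed-form biphasic solutions used as verification oracles.

These are the textbook one-dimensional consolidation results for a linear
biphasic layer: the confined-compression creep series and the instantaneous
/ drained stiffness limits of an unconfined plane-strain strip.  They are
public API: besides verifying the finite-element engine they are handy for
sizing time steps (via the gel diffusion time) and for quick parameter
fits to creep data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfinedCreepSpec",
    "confined_creep_displacement",
    "gel_diffusion_time",
    "unconfined_limit_moduli",
]


@dataclass
class ConfinedCreepSpec:
    """Step-load confined-compression creep problem.

    applied_stress : compressive traction magnitude on the draining face, MPa
    thickness      : layer thickness, mm
    aggregate_modulus : H_A = lambda + 2 mu of the drained matrix, MPa
    permeability   : mm^4/(N s)
    series_terms   : number of series terms retained (>= 20 recommended)
    """

    applied_stress: float
    thickness: float
    aggregate_modulus: float
    permeability: float
    series_terms: int = 50

    def __post_init__(self) -> None:
        for name in ("applied_stress", "thickness", "aggregate_modulus", "permeability"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.series_terms < 1:
            raise ValueError("series_terms must be >= 1")

    @property
    def gel_time(self) -> float:
        return gel_diffusion_time(self.thickness, self.aggregate_modulus,
                                  self.permeability)

    @property
    def equilibrium_displacement(self) -> float:
        return self.applied_stress * self.thickness / self.aggregate_modulus


def gel_diffusion_time(h: float, H_A: float, k: float) -> float:
    """Characteristic consolidation time t_g = h^2 / (H_A k), seconds."""
    if h <= 0 or H_A <= 0 or k <= 0:
        raise ValueError("h, H_A and k must all be > 0")
    return h * h / (H_A * k)


def confined_creep_displacement(spec: ConfinedCreepSpec, t) -> np.ndarray:
    """Surface settlement of a confined biphasic layer under a step load.

    u(t) = (sigma0 h / H_A) * [1 - 2 sum_n exp(-pi^2 (n+1/2)^2 t/t_g)
                                       / (pi^2 (n+1/2)^2)]

    u(0) = 0 (instantaneously incompressible), u(inf) = sigma0 h / H_A,
    monotone increasing in between.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tg = spec.gel_time
    n = np.arange(spec.series_terms)
    a = (np.pi * (n + 0.5)) ** 2
    series = np.sum(np.exp(-np.multiply.outer(t, a) / tg) / a, axis=-1)
    # the truncated tail sums exactly to 1/2 - sum(1/a); fold it in with the
    # decay rate of the first dropped mode so u(0) = 0 holds to machine
    # precision at any truncation order
    tail = 0.5 - np.sum(1.0 / a)
    a_next = (np.pi * (spec.series_terms + 0.5)) ** 2
    series = series + tail * np.exp(-t * a_next / tg)
    return spec.equilibrium_displacement * (1.0 - 2.0 * series)


def unconfined_limit_moduli(E: float, nu: float, mu: float) -> tuple[float, float]:
    """Stiffness limits of a plane-strain strip with free-draining sides.

    Instantaneous (undrained, incompressible) apparent modulus is 4 mu;
    drained equilibrium modulus is E / (1 - nu^2).  Valid with fibril
    reinforcement switched off.
    """
    if E <= 0 or mu <= 0 or not (0 <= nu < 0.5):
        raise ValueError("need E > 0, mu > 0, 0 <= nu < 0.5")
    return 4.0 * mu, E / (1.0 - nu * nu)
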