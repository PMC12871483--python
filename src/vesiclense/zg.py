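"""Classical Zilman-Granek stretched-exponential relaxation.

For a large, flat, tensionless membrane the normalized intermediate
scattering function decays as ``exp(-(Gamma_q t)^(2/3))`` with

    Gamma_q = prefactor * gamma * (k_B T / kappa)^(1/2) * (k_B T / eta) * q^3.

The canonical theoretical prefactor is 0.025; a value of 0.0069 has been
widely used in the NSE literature as an empirical rescaling and is provided
as a named convention.  The kappa-dependent factor ``gamma`` is close to 1
whenever ``kappa >> k_B T`` and defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BOLTZMANN
from .errors import DomainError
from .transport import DiffusionSpec, stokes_einstein

__all__ = ["ZGConvention", "zg_rate", "zg_curve", "zg_kappa_from_rate"]

#: canonical theoretical prefactor of the q^3 rate law
PREFACTOR_THEORY = 0.025
#: empirical prefactor widely used in the NSE literature
PREFACTOR_EMPIRICAL = 0.0069

STRETCH_EXPONENT = 2.0 / 3.0


@dataclass(frozen=True)
class ZGConvention:
    """Prefactor convention for the q^3 rate law."""

    prefactor: float = PREFACTOR_THEORY
    gamma_factor: float = 1.0

    def __post_init__(self):
        if not self.prefactor > 0:
            raise DomainError("prefactor must be positive")
        if not self.gamma_factor > 0:
            raise DomainError("gamma_factor must be positive")


def zg_rate(kappa: float, eta: float, temperature: float, q: float,
            convention: ZGConvention = ZGConvention()) -> float:
    """Stretched-exponential relaxation rate Gamma_q, 1/s."""
    if not all(x > 0 for x in (kappa, eta, temperature, q)):
        raise DomainError("all inputs must be positive")
    kT = BOLTZMANN * temperature
    return (convention.prefactor * convention.gamma_factor
            * np.sqrt(kT / kappa) * (kT / eta) * q**3)


def zg_kappa_from_rate(Gamma_q: float, eta: float, temperature: float, q: float,
                       convention: ZGConvention = ZGConvention()) -> float:
    """Exact algebraic inversion of :func:`zg_rate` for the rigidity, J."""
    if not all(x > 0 for x in (Gamma_q, eta, temperature, q)):
        raise DomainError("all inputs must be positive")
    kT = BOLTZMANN * temperature
    pref = convention.prefactor * convention.gamma_factor
    return kT * (pref * (kT / eta) * q**3 / Gamma_q) ** 2


def zg_curve(Gamma_q: float, t_values, q: float | None = None,
             diffusion: DiffusionSpec | None = None,
             radius: float | None = None) -> np.ndarray:
    """Normalized relaxation ``exp(-(Gamma_q t)^(2/3))``.

    If a :class:`DiffusionSpec` (plus ``q`` and, where needed, ``radius``)
    is supplied, the multiplicative translational-diffusion factor
    ``exp(-D q^2 t)`` is included.
    """
    t = np.asarray(t_values, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be non-negative")
    s = np.exp(-((Gamma_q * t) ** STRETCH_EXPONENT))
    if diffusion is not None and diffusion.enabled:
        if q is None:
            raise DomainError("q is required for the diffusion factor")
        if diffusion.mode == "fixed":
            D = diffusion.fixed_D
        else:
            if radius is None:
                raise DomainError("radius is required for Stokes-Einstein diffusion")
            D = float(diffusion.coefficients(np.array([radius]))[0])
        s = s * np.exp(-D * q**2 * t)
    return s
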