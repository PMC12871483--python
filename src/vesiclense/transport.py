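"""Translational diffusion and tension plumbing.

Stokes-Einstein diffusion, the hard-sphere short-time self-diffusion
correction for crowded suspensions, the effective vesicle volume fraction
implied by a lipid mass concentration, and the Laplace tension induced by an
osmotic pressure difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, BOLTZMANN, GAS_CONSTANT
from .errors import ConfigurationError, DomainError, InvalidGeometryError

__all__ = [
    "DiffusionSpec",
    "stokes_einstein",
    "crowded_self_diffusion",
    "vesicle_volume_fraction",
    "laplace_tension",
    "vant_hoff_pressure",
]

log = logging.getLogger(__name__)

#: effective volume fraction above which a crowding correction is suggested
CROWDING_ADVISORY_PHI = 0.05
#: upper end of the validated range of the hard-sphere virial expression
HARD_SPHERE_PHI_MAX = 0.4


def stokes_einstein(radius: float, viscosity: float, temperature: float) -> float:
    """Dilute-limit diffusion coefficient D = k_B T / (6 pi eta R), m^2/s."""
    if not (np.all(np.asarray(radius) > 0) and viscosity > 0 and temperature > 0):
        raise DomainError("radius, viscosity and temperature must be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * viscosity * radius)


def crowded_self_diffusion(D0, phi: float):
    """Short-time self-diffusion of hard spheres at volume fraction ``phi``.

    Uses the second-order virial form
    ``D_s/D0 = 1 - 1.8315 phi (1 + 0.1195 phi - 0.70 phi^2)``
    (Cichocki-type hard-sphere result), validated up to ``phi = 0.4``; in
    this regime it also equals the collective diffusion coefficient at the
    large wavevectors probed by NSE.  Larger ``phi`` triggers a warning but
    is still evaluated.
    """
    if phi < 0:
        raise DomainError("volume fraction must be non-negative")
    if np.any(np.asarray(D0) <= 0):
        raise DomainError("D0 must be positive")
    if phi > HARD_SPHERE_PHI_MAX:
        warnings.warn(
            f"phi = {phi:.3g} is outside the validated hard-sphere range "
            f"(phi <= {HARD_SPHERE_PHI_MAX}); result extrapolated",
            stacklevel=2)
    return D0 * (1.0 - 1.8315 * phi * (1.0 + 0.1195 * phi - 0.70 * phi**2))


def vesicle_volume_fraction(c_L: float, v_L: float, M_L: float,
                            R: float, delta: float) -> float:
    """Effective vesicle volume fraction from the lipid mass concentration.

    The bare lipid volume fraction ``c_L N_A v_L / M_L`` is scaled up by the
    vesicle-to-shell volume ratio ``R^3 / (R^3 - (R - delta)^3)`` because the
    solvent-filled core moves with the vesicle.
    """
    if not all(x > 0 for x in (c_L, v_L, M_L, R, delta)):
        raise DomainError("all inputs must be positive")
    if delta > R:
        raise InvalidGeometryError("membrane thickness cannot exceed the radius")
    phi_lipid = c_L * AVOGADRO * v_L / M_L
    shell = R**3 - (R - delta)**3
    phi = phi_lipid * R**3 / shell
    if phi > CROWDING_ADVISORY_PHI:
        log.info("effective vesicle volume fraction %.3g exceeds %.2g; "
                 "consider diffusion mode 'crowded'", phi, CROWDING_ADVISORY_PHI)
    return phi


def laplace_tension(delta_Pi: float, R: float) -> float:
    """Membrane tension sigma = delta_Pi * R / 2 from an osmotic pressure
    difference (hyper-osmotic side outside), N/m."""
    if delta_Pi < 0:
        raise DomainError("negative pressure difference (floppy hypo-osmotic "
                          "regime) is out of scope")
    if not R > 0:
        raise DomainError("radius must be positive")
    return delta_Pi * R / 2.0


def vant_hoff_pressure(delta_c: float, temperature: float) -> float:
    """Ideal (van't Hoff) osmotic pressure ``delta_c R T`` for a solute
    concentration difference in mol/m^3.  Convenience helper for building
    Laplace tensions from solution recipes."""
    if delta_c < 0 or temperature <= 0:
        raise DomainError("need delta_c >= 0 and temperature > 0")
    return delta_c * GAS_CONSTANT * temperature


_MODES = ("stokes_einstein", "fixed", "crowded", "off")


@dataclass(frozen=True)
class DiffusionSpec:
    """How to assign translational diffusion coefficients to vesicles.

    mode:
      * ``stokes_einstein`` -- D(R) from the SANS radius of each quadrature
        node (default, recommended);
      * ``fixed`` -- one imposed D for every vesicle (e.g. from DLS);
      * ``crowded`` -- Stokes-Einstein rescaled by the hard-sphere factor at
        ``volume_fraction``;
      * ``off`` -- diffusion disabled.

    ``use_mean_radius`` forces a single D evaluated at the population mean
    radius for every node (legacy-analysis comparison switch).
    """

    mode: str = "stokes_einstein"
    fixed_D: float | None = None
    volume_fraction: float | None = None
    solvent_viscosity_out: float = 1.1e-3
    temperature: float = 298.15
    use_mean_radius: bool = False

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ConfigurationError(
                f"unknown diffusion mode {self.mode!r}; choose from {_MODES}")
        if self.mode == "fixed" and not (self.fixed_D and self.fixed_D > 0):
            raise ConfigurationError("mode='fixed' requires fixed_D > 0")
        if self.mode == "crowded":
            if self.volume_fraction is None or not 0 <= self.volume_fraction < 0.5:
                raise ConfigurationError(
                    "mode='crowded' requires volume_fraction in [0, 0.5)")

    @property
    def enabled(self) -> bool:
        return self.mode != "off"

    def coefficients(self, radii, mean_radius: float | None = None) -> np.ndarray:
        """Diffusion coefficient for each radius node, m^2/s."""
        radii = np.asarray(radii, dtype=float)
        if self.mode == "off":
            return np.zeros_like(radii)
        if self.mode == "fixed":
            return np.full_like(radii, self.fixed_D)
        r_eff = radii
        if self.use_mean_radius:
            if mean_radius is None:
                raise ConfigurationError("use_mean_radius requires mean_radius")
            r_eff = np.full_like(radii, mean_radius)
        d0 = stokes_einstein(r_eff, self.solvent_viscosity_out, self.temperature)
        if self.mode == "crowded":
            return crowded_self_diffusion(d0, self.volume_fraction)
        return d0
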