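"""Physical parameter containers.

:class:`MembraneParams` collects the membrane/solvent parameters of a single
vesicle system.  The bending rigidity stored here is the one governing the
nanosecond-scale undulations probed by NSE (often written with a tilde to
distinguish it from the fully relaxed rigidity measured by quasi-static
methods; see :mod:`vesiclense.leaflet` for the conversion).

Reduced quantities -- the dimensionless tension ``sigma R^2 / kappa`` and the
reduced Saffman-Delbrueck length ``eta_m / ((eta_in + eta_out) R)`` -- are
derived accessors, never independent state, so they can not drift out of
sync with the primitive parameters.

:class:`VesiclePopulation` describes the vesicle radius distribution (as
obtained from SANS) plus optional lipid concentration data used for
crowding corrections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import BOLTZMANN, thermal_energy
from .errors import ConfigurationError, DomainError

__all__ = ["MembraneParams", "VesiclePopulation"]


@dataclass(frozen=True)
class MembraneParams:
    """Membrane and solvent parameters of one vesicle system (SI units).

    Parameters
    ----------
    kappa_tilde : float
        Bending rigidity governing the measured undulations, J.
    temperature : float
        Absolute temperature, K.
    eta_in, eta_out : float
        Solvent viscosity inside / outside the vesicle, Pa s.  Usually
        identical; they differ e.g. in hyperosmotic sucrose gradients.
    eta_m : float
        Membrane (surface) viscosity, Pa s m.  Enters the mode relaxation
        rates but not the mode amplitudes.
    sigma : float
        Membrane tension, N/m.  Non-negative; the floppy hypo-osmotic
        regime is not modelled.
    delta : float
        Membrane (bilayer) thickness, m.  Sets the mode cutoff.
    """

    kappa_tilde: float
    temperature: float = 298.15
    eta_in: float = 1.1e-3
    eta_out: float = 1.1e-3
    eta_m: float = 0.0
    sigma: float = 0.0
    delta: float = 4.0e-9

    def __post_init__(self):
        if not self.kappa_tilde > 0:
            raise DomainError("kappa_tilde must be positive")
        if not self.temperature > 0:
            raise DomainError("temperature must be positive")
        if not (self.eta_in > 0 and self.eta_out > 0):
            raise DomainError("solvent viscosities must be positive")
        if self.eta_m < 0:
            raise DomainError("membrane viscosity must be non-negative")
        if self.sigma < 0:
            raise DomainError("negative membrane tension is rejected")
        if not self.delta > 0:
            raise DomainError("membrane thickness must be positive")

    # -- unit helpers -------------------------------------------------
    @classmethod
    def from_kT(cls, kappa_kT: float, temperature: float = 298.15, **kwargs) -> "MembraneParams":
        """Build parameters with the rigidity given in units of k_B T at
        ``temperature``."""
        return cls(kappa_tilde=kappa_kT * BOLTZMANN * temperature,
                   temperature=temperature, **kwargs)

    @property
    def kT(self) -> float:
        """Thermal energy k_B T, J."""
        return thermal_energy(self.temperature)

    @property
    def kappa_tilde_kT(self) -> float:
        """Bending rigidity in units of k_B T."""
        return self.kappa_tilde / self.kT

    def replace(self, **changes) -> "MembraneParams":
        return dataclasses.replace(self, **changes)

    # -- reduced (derived) quantities ---------------------------------
    def reduced_tension(self, radius: float) -> float:
        """Dimensionless tension sigma R^2 / kappa for a vesicle of the
        given radius."""
        return self.sigma * radius**2 / self.kappa_tilde

    def reduced_sd_length(self, radius: float) -> float:
        """Reduced Saffman-Delbrueck length eta_m / ((eta_in+eta_out) R):
        the membrane-viscosity dissipation scale relative to the vesicle
        size."""
        return self.eta_m / ((self.eta_in + self.eta_out) * radius)


_FAMILIES = ("schulz", "lognormal")


@dataclass(frozen=True)
class VesiclePopulation:
    """Vesicle radius distribution and (optional) concentration data.

    ``polydispersity`` is the relative width s/mean of the radius
    distribution; the default family is the Schulz (Gamma) distribution
    conventionally used for SANS size analysis.  The three concentration
    fields must be jointly present or jointly absent; they feed the
    vesicle volume-fraction (crowding) estimate.
    """

    mean_radius: float
    polydispersity: float = 0.0
    family: str = "schulz"
    lipid_concentration: float | None = None    # kg/m^3
    lipid_molecular_volume: float | None = None  # m^3
    lipid_molar_mass: float | None = None        # kg/mol

    def __post_init__(self):
        if not self.mean_radius > 0:
            raise DomainError("mean_radius must be positive")
        if not 0 <= self.polydispersity < 1:
            raise DomainError("polydispersity must lie in [0, 1)")
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; choose from {_FAMILIES}")
        conc = (self.lipid_concentration, self.lipid_molecular_volume,
                self.lipid_molar_mass)
        if any(v is not None for v in conc) and not all(v is not None for v in conc):
            raise ConfigurationError(
                "lipid concentration fields must be jointly present or absent")

    @property
    def monodisperse(self) -> bool:
        return self.polydispersity == 0.0

    def pdf(self, radius: np.ndarray) -> np.ndarray:
        """Number-weighted radius density of the configured family."""
        r = np.asarray(radius, dtype=float)
        p = self.polydispersity
        if p == 0:
            raise ConfigurationError("a monodisperse population has no density")
        if self.family == "schulz":
            # Gamma with shape k = 1/p^2 reproduces mean and relative width
            k = 1.0 / p**2
            return stats.gamma.pdf(r, a=k, scale=self.mean_radius / k)
        s = np.sqrt(np.log1p(p**2))
        scale = self.mean_radius / np.exp(s**2 / 2.0)
        return stats.lognorm.pdf(r, s=s, scale=scale)

    def quadrature(self, n_nodes: int = 21, n_widths: float = 4.0,
                   min_radius: float = 0.0):
        """Gauss-Legendre nodes and number-density weights over
        mean +- ``n_widths`` distribution widths.

        Returns ``(radii, weights)`` with weights summing to the covered
        probability mass (not renormalized; downstream averages divide by
        their own normalization).
        """
        if self.monodisperse:
            return (np.array([self.mean_radius]), np.array([1.0]))
        if n_nodes < 1:
            raise ConfigurationError("quadrature needs at least one node")
        width = self.polydispersity * self.mean_radius
        lo = max(self.mean_radius - n_widths * width, min_radius, 0.0)
        hi = self.mean_radius + n_widths * width
        if not hi > lo:
            raise ConfigurationError("degenerate radius quadrature interval")
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        radii = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        weights = 0.5 * (hi - lo) * w * self.pdf(radii)
        if not np.any(weights > 0):
            raise ConfigurationError("radius quadrature carries no weight")
        return radii, weights
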