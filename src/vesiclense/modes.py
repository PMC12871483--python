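"""Spherical-harmonic undulation mode spectrum of a single vesicle.

A quasi-spherical vesicle of radius ``R`` fluctuates around its mean shape
with radial displacement ``u(Omega, t) = R sum_lm a_lm(t) Y_lm(Omega)``.
With the Helfrich bending energy plus a lateral tension ``sigma``, the
energy of mode ``(l, m)`` is

    E_lm = (kappa/2) (l-1)(l+2) [l(l+1) + sigma_r] |a_lm|^2,

with the reduced tension ``sigma_r = sigma R^2 / kappa``, so equipartition
gives the dimensionless mean-square amplitude

    <|a_lm|^2> = k_B T / ( kappa (l-1)(l+2) [l(l+1) + sigma_r] ).

Each mode relaxes exponentially.  The relaxation rate follows from the
Stokes drag of the solvent inside (viscosity ``eta_in``) and outside
(``eta_out``) the vesicle plus the Boussinesq-Scriven dissipation of an
incompressible membrane with surface viscosity ``eta_m``:

    Gamma_l = kappa (l-1)(l+2)[l(l+1)+sigma_r] l(l+1) /
              { R^3 [ eta_in (l-1)(2l^2+5l+5) + eta_out (l+2)(2l^2-l+2)
                      + 4 (eta_m/R) (l-1)(l+2) ] }.

The friction bracket was derived by solving the Stokes equations on both
sides of the sphere for the kinematically determined mode flow and summing
bulk and membrane dissipation (see docs/methods.md).  At equal solvent
viscosities and ``eta_m = 0`` the bracket reduces to the classical
Milner-Safran denominator ``eta (2l+1)(2l^2+2l-1)``.

The relative mean-square displacement (dimensionless) is the saturating
mode sum

    msd_rel(t) = sum_{l=2}^{l_max} (2l+1)/(4 pi) <|a_l|^2> (1 - e^{-Gamma_l t}),

whose ``t -> inf`` limit is the elastic plateau; multiplying by ``2 R^2``
gives the dimensioned mean-square displacement of a membrane point.  The
mode cutoff ``l_max = floor(pi R / delta)`` corresponds to a shortest
undulation wavelength of twice the membrane thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSpectrumError, DomainError, InvalidGeometryError
from .params import MembraneParams

__all__ = [
    "ModeSpectrum",
    "mode_spectrum",
    "relative_msd",
    "mean_square_displacement",
    "elastic_plateau",
    "roughness",
    "correlation_length",
]


@dataclass(frozen=True)
class ModeSpectrum:
    """Per-mode amplitudes and relaxation rates of one vesicle.

    Attributes
    ----------
    radius : float
        Vesicle radius, m.
    l_values : ndarray of int
        Mode indices, ``2 .. l_max``.
    amp2 : ndarray
        Dimensionless mean-square amplitude ``<|a_lm|^2>`` per mode.
    rate : ndarray
        Relaxation rate ``Gamma_l`` per mode, 1/s.
    l_max : int
        Mode cutoff.
    """

    radius: float
    l_values: np.ndarray
    amp2: np.ndarray
    rate: np.ndarray
    l_max: int

    def __post_init__(self):
        l = np.asarray(self.l_values)
        if l.size == 0 or l[0] != 2 or np.any(np.diff(l) != 1):
            raise DegenerateSpectrumError(
                "l_values must increase by 1 starting at l=2")
        if self.l_max < 2:
            raise DegenerateSpectrumError("l_max must be at least 2")
        if not (np.all(self.amp2 > 0) and np.all(self.rate > 0)):
            raise DomainError("mode amplitudes and rates must be positive")

    def truncated(self, l_max: int) -> "ModeSpectrum":
        """Spectrum restricted to ``l <= l_max`` (diagnostics)."""
        keep = self.l_values <= l_max
        return ModeSpectrum(self.radius, self.l_values[keep],
                            self.amp2[keep], self.rate[keep],
                            min(self.l_max, l_max))


def mode_cutoff(radius: float, delta: float) -> int:
    """Cutoff ``l_max = floor(pi R / delta)``, at least 2."""
    return max(int(math.floor(math.pi * radius / delta)), 2)


def mode_spectrum(params: MembraneParams, radius: float) -> ModeSpectrum:
    """Compute amplitudes and relaxation rates for modes ``l = 2 .. l_max``.

    Parameters
    ----------
    params : MembraneParams
    radius : float
        Vesicle radius, m; must exceed the membrane thickness.

    Raises
    ------
    InvalidGeometryError
        If ``radius <= params.delta``.
    DegenerateSpectrumError
        If the cutoff leaves no mode.
    """
    if not radius > params.delta:
        raise InvalidGeometryError(
            f"radius {radius:g} m must exceed membrane thickness {params.delta:g} m")
    l_max = mode_cutoff(radius, params.delta)
    if l_max < 2:
        raise DegenerateSpectrumError("no undulation mode below the cutoff")

    l = np.arange(2, l_max + 1, dtype=float)
    sigma_r = params.reduced_tension(radius)
    stiff = (l - 1.0) * (l + 2.0) * (l * (l + 1.0) + sigma_r)
    amp2 = params.kT / (params.kappa_tilde * stiff)
    friction = (params.eta_in * (l - 1.0) * (2.0 * l**2 + 5.0 * l + 5.0)
                + params.eta_out * (l + 2.0) * (2.0 * l**2 - l + 2.0)
                + 4.0 * (params.eta_m / radius) * (l - 1.0) * (l + 2.0))
    rate = params.kappa_tilde * stiff * l * (l + 1.0) / (radius**3 * friction)
    return ModeSpectrum(radius=radius, l_values=l.astype(int), amp2=amp2,
                        rate=rate, l_max=l_max)


def _mode_weights(spectrum: ModeSpectrum) -> np.ndarray:
    l = spectrum.l_values.astype(float)
    return (2.0 * l + 1.0) / (4.0 * np.pi) * spectrum.amp2


def relative_msd(spectrum: ModeSpectrum, t) -> np.ndarray | float:
    """Dimensionless relative mean-square displacement at time(s) ``t``.

    Non-negative, non-decreasing in ``t`` and bounded by
    :func:`elastic_plateau`.  Modes are accumulated from ``l_max`` down to
    ``l = 2`` so that the per-mode terms enter in increasing magnitude,
    which keeps the float64 sum accurate even for cutoffs beyond 10^3.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be non-negative")
    w = _mode_weights(spectrum)
    terms = w[::-1, None] * -np.expm1(-np.outer(spectrum.rate[::-1],
                                                np.atleast_1d(t_arr)))
    out = np.add.reduce(terms, axis=0)
    return out if np.ndim(t) else float(out[0])


def mean_square_displacement(spectrum: ModeSpectrum, t) -> np.ndarray | float:
    """Dimensioned mean-square displacement, m^2: ``2 R^2`` times the
    relative mode sum."""
    return 2.0 * spectrum.radius**2 * relative_msd(spectrum, t)


def elastic_plateau(spectrum: ModeSpectrum) -> float:
    """``t -> inf`` limit of :func:`relative_msd` (dimensionless)."""
    return float(np.add.reduce(_mode_weights(spectrum)[::-1]))


def roughness(spectrum: ModeSpectrum) -> float:
    """Mean membrane roughness sigma_R (m): rms static radial displacement,
    equal to the square root of half the long-time mean-square
    displacement."""
    return spectrum.radius * math.sqrt(elastic_plateau(spectrum))


def correlation_length(spectrum: ModeSpectrum, params: MembraneParams) -> float:
    """Undulation correlation length ``xi = sqrt(kappa/k_B T) sigma_R`` (m).

    ``q xi >> 1`` is required for the classical stretched-exponential
    (flat-membrane) limit to be observable.
    """
    return math.sqrt(params.kappa_tilde / params.kT) * roughness(spectrum)
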