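"""Normalized dynamic structure factor of a polydisperse vesicle ensemble.

For one vesicle of radius ``R`` the normalized relaxation at wavevector
``q`` factorizes into the undulation decay and translational diffusion,

    S_R(q, t) / S_R(q, 0) = exp( - q^2 R^2 msd_rel(t) ) * exp( - D(R) q^2 t ),

where ``msd_rel`` is the relative mean-square displacement of the mode
spectrum (:mod:`vesiclense.modes`); ``q^2 R^2 msd_rel`` equals half the
dimensioned point mean-square displacement times ``q^2``, the Gaussian
damping of scattering from a surface displaced along the wavevector.

The measured signal of a polydisperse ensemble is the intensity-weighted
average over the radius distribution: each radius carries the thin-shell
scattering power ``R^4 F(qR)`` with the form factor ``F(x) = (sin x / x)^2``,
and the averaged numerator is normalized by its own ``t = 0`` value:

    S(q,t)/S(q,0) = < R^4 F(qR) e^{-q^2 R^2 msd_rel(t)} e^{-D(R) q^2 t} >
                    / < R^4 F(qR) >.

In the large-radius, tensionless, inviscid-membrane limit the curve
approaches the classical stretched exponential ``exp(-(Gamma_q t)^(2/3))``
with the canonical 0.025 prefactor; :func:`stretch_characterize` provides
the free-exponent fit used to verify that limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, DomainError, InsufficientDataError
from .modes import mode_spectrum, relative_msd
from .params import MembraneParams, VesiclePopulation
from .transport import DiffusionSpec

__all__ = ["ModelCurve", "shell_form_factor", "sqt_model", "stretch_characterize"]

#: default number of Gauss-Legendre radius nodes
N_QUADRATURE_NODES = 21
#: form-factor level (relative to 1) below which a monodisperse evaluation
#: is flagged as numerically degenerate
FORM_FACTOR_FLOOR = 1e-10


@dataclass(frozen=True)
class ModelCurve:
    """One computed relaxation curve S(q,t)/S(q,0)."""

    q: float                 # 1/m
    t_values: np.ndarray     # s
    s_values: np.ndarray     # dimensionless, 1 at t=0
    warnings: tuple = field(default_factory=tuple)


def shell_form_factor(x) -> np.ndarray | float:
    """Form factor of an infinitely thin spherical shell,
    ``(sin x / x)^2``, normalized to 1 at ``x = 0``."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError("qR must be non-negative")
    out = np.square(np.sinc(arr / np.pi))
    return out if np.ndim(x) else float(out)


def _radius_average(params: MembraneParams, population: VesiclePopulation,
                    q: float, t: np.ndarray,
                    diffusion: DiffusionSpec | None,
                    n_nodes: int) -> tuple[np.ndarray, tuple]:
    radii, number_w = population.quadrature(
        n_nodes=n_nodes, min_radius=np.nextafter(params.delta, np.inf))
    form = shell_form_factor(q * radii)
    weights = number_w * radii**4 * form          # scattering power per node
    notes: list[str] = []
    if population.monodisperse and form[0] < FORM_FACTOR_FLOOR:
        msg = (f"q = {q:g} 1/m sits at a deep form-factor zero of the "
               "monodisperse shell; the normalized curve is numerically "
               "degenerate")
        warnings.warn(msg, stacklevel=3)
        notes.append(msg)
        weights = number_w                         # avoid 0/0; shape unaffected
    norm = np.add.reduce(weights)
    if not norm > 0:
        raise ConfigurationError("radius quadrature carries no scattering weight")

    if diffusion is not None and diffusion.enabled:
        d_coef = diffusion.coefficients(radii, mean_radius=population.mean_radius)
    else:
        d_coef = np.zeros_like(radii)

    num = np.zeros_like(t)
    for r, w, d in zip(radii, weights, d_coef):
        if w == 0.0:
            continue
        spec = mode_spectrum(params, r)
        decay = np.exp(-q**2 * r**2 * relative_msd(spec, t) - d * q**2 * t)
        num += w * decay
    return num / norm, tuple(notes)


def sqt_model(params: MembraneParams, population: VesiclePopulation,
              q: float, t_values,
              diffusion: DiffusionSpec | None = None,
              n_nodes: int = N_QUADRATURE_NODES) -> ModelCurve:
    """Normalized dynamic structure factor on a time grid.

    Parameters
    ----------
    params : MembraneParams
    population : VesiclePopulation
        Radius distribution averaged over with its SANS-style
        ``R^4 F(qR)`` scattering weight.
    q : float
        Wavevector, 1/m.
    t_values : array-like
        Fourier times, s, sorted ascending and non-negative.
    diffusion : DiffusionSpec, optional
        ``None`` (or mode ``"off"``) disables translational diffusion.
    n_nodes : int
        Gauss-Legendre nodes for the radius average.

    Returns
    -------
    ModelCurve
        ``s_values`` equals exactly 1 at ``t = 0``.
    """
    if not q > 0:
        raise DomainError("q must be positive")
    t = np.asarray(t_values, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise DomainError("t_values must be a non-empty 1-d array")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise DomainError("t_values must be sorted ascending and non-negative")
    s, notes = _radius_average(params, population, q, t, diffusion, n_nodes)
    return ModelCurve(q=q, t_values=t, s_values=s, warnings=notes)


def stretch_characterize(curve: ModelCurve,
                         window: tuple[float, float] = (0.9, 0.1),
                         beta: float | None = None) -> tuple[float, float]:
    """Least-squares stretched-exponential characterization of a curve.

    Fits ``exp(-(Gamma t)^beta)`` to the points whose S values lie inside
    ``window = (s_high, s_low)``.  With ``beta=None`` the exponent is free;
    passing a value (e.g. ``2/3``) fixes it.

    Returns ``(beta, Gamma)`` with ``Gamma`` in 1/s.
    """
    hi, lo = max(window), min(window)
    if not 0 < lo < hi < 1:
        raise DomainError("window must lie strictly inside (0, 1)")
    s = curve.s_values
    t = curve.t_values
    mask = (s <= hi) & (s >= lo) & (t > 0)
    if np.count_nonzero(mask) < 4:
        raise InsufficientDataError(
            f"only {np.count_nonzero(mask)} points inside S window "
            f"({hi:g}, {lo:g}); need at least 4")
    ts, ss = t[mask], s[mask]
    if np.any(np.diff(ss) >= 0):
        raise DomainError("curve must be strictly decreasing inside the window")

    # log-log linearization gives the starting point; a bounded nonlinear
    # refinement in S-space gives the reported values
    y = np.log(-np.log(ss))
    slope, icept = np.polyfit(np.log(ts), y, 1)
    beta0 = slope if beta is None else beta
    rate0 = np.exp(icept / slope)

    if beta is None:
        def model(tt, b, lg):
            return np.exp(-((10.0**lg) * tt) ** b)
        popt, _ = optimize.curve_fit(
            model, ts, ss, p0=[beta0, np.log10(rate0)],
            bounds=([0.05, np.log10(rate0) - 4], [2.0, np.log10(rate0) + 4]),
            maxfev=10000)
        return float(popt[0]), float(10.0 ** popt[1])

    def model_fixed(tt, lg):
        return np.exp(-((10.0**lg) * tt) ** beta)
    popt, _ = optimize.curve_fit(
        model_fixed, ts, ss, p0=[np.log10(rate0)],
        bounds=([np.log10(rate0) - 4], [np.log10(rate0) + 4]), maxfev=10000)
    return float(beta), float(10.0 ** popt[0])
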