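"""Synthetic NSE datasets with instrument-like grids and known truth.

The grid presets emulate a spin-echo spectrometer: a handful of q values
between 0.02 and 0.13 1/A (``standard``) with Fourier times log-spaced up
to 500 ns, or a long-time configuration from 0.016 to 0.14 1/A reaching
1 us at the lowest q and tapering with q (``long_time``).  The noise model
is additive Gaussian with a standard deviation growing linearly with
Fourier time, ``sigma(t) = noise_level * (1 + t / t_max)`` -- a simple
proxy for the echo-amplitude loss of real measurements, not a calibrated
instrument model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import RelaxationDataset, S_MAX
from .errors import ConfigurationError, DomainError
from .params import MembraneParams, VesiclePopulation
from .structure import sqt_model
from .transport import DiffusionSpec

__all__ = ["InstrumentGrid", "make_grid", "simulate_dataset"]

log = logging.getLogger(__name__)

INV_ANGSTROM = 1e10   # 1/A -> 1/m
NS = 1e-9             # ns -> s

PRESETS = ("standard", "long_time", "custom")


@dataclass(frozen=True)
class InstrumentGrid:
    """q values and per-q Fourier-time grids (SI units)."""

    preset: str
    q_values: np.ndarray                  # 1/m, ascending
    t_values: tuple[np.ndarray, ...]      # s, one ascending array per q

    def __post_init__(self):
        if len(self.q_values) != len(self.t_values):
            raise ConfigurationError("one time grid per q value is required")

    @property
    def n_records(self) -> int:
        return int(sum(len(t) for t in self.t_values))

    def max_time(self, i: int) -> float:
        return float(self.t_values[i][-1])


def _log_times(t_min: float, t_max: float, n: int) -> np.ndarray:
    return np.geomspace(t_min, t_max, n)


def make_grid(preset: str = "standard", *,
              q_values=None, t_values=None,
              n_times: int = 25, t_min: float = 0.05 * NS) -> InstrumentGrid:
    """Build an instrument grid.

    ``standard``: 6 q values spanning 0.02-0.13 1/A, ``n_times`` log-spaced
    times from ``t_min`` to 500 ns at every q.

    ``long_time``: 6 q values spanning 0.016-0.14 1/A; the maximum time is
    1 us at the lowest q and tapers as ``q_min / q`` with q.

    ``custom``: explicit ``q_values`` (1/m) and ``t_values`` (s; a single
    array shared by all q, or one array per q).
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {PRESETS}")
    if preset == "standard":
        q = np.linspace(0.02, 0.13, 6) * INV_ANGSTROM
        t = tuple(_log_times(t_min, 500 * NS, n_times) for _ in q)
        return InstrumentGrid("standard", q, t)
    if preset == "long_time":
        q = np.linspace(0.016, 0.14, 6) * INV_ANGSTROM
        t = tuple(_log_times(t_min, 1000 * NS * (q[0] / qi), n_times)
                  for qi in q)
        return InstrumentGrid("long_time", q, t)
    if q_values is None or t_values is None:
        raise ConfigurationError("custom preset requires q_values and t_values")
    q = np.sort(np.asarray(q_values, dtype=float))
    if np.ndim(t_values[0]) == 0:   # one shared grid
        t_values = [t_values] * len(q)
    t = tuple(np.asarray(ti, dtype=float) for ti in t_values)
    return InstrumentGrid("custom", q, t)


def simulate_dataset(params: MembraneParams,
                     population: VesiclePopulation,
                     diffusion: DiffusionSpec | None,
                     grid: InstrumentGrid,
                     noise_level: float = 0.0,
                     seed: int | None = None) -> RelaxationDataset:
    """Evaluate the spherical-vesicle model on ``grid`` and add NSE-like
    noise.

    The ``err`` column is set to the generating standard deviation, so a
    weighted fit of the returned dataset uses the true noise model.  Truth
    parameters and the seed are embedded in the metadata.
    """
    if noise_level < 0:
        raise DomainError("noise_level must be non-negative")
    if noise_level > 0 and seed is None:
        raise DomainError("a seed is required when noise_level > 0")
    rng = np.random.default_rng(seed)

    q_col, t_col, s_col, e_col = [], [], [], []
    n_clipped = 0
    for i, q in enumerate(grid.q_values):
        t = grid.t_values[i]
        curve = sqt_model(params, population, q, t, diffusion)
        sig = noise_level * (1.0 + t / grid.max_time(i))
        s = curve.s_values.copy()
        if noise_level > 0:
            s = s + rng.normal(0.0, sig)
            over = s > S_MAX
            n_clipped += int(np.count_nonzero(over))
            s = np.clip(s, np.finfo(float).tiny, S_MAX)
        err = sig if noise_level > 0 else np.full_like(t, 1.0)
        q_col.append(np.full_like(t, q)); t_col.append(t)
        s_col.append(s); e_col.append(err)
    if n_clipped:
        log.info("clipped %d noisy S values to <= %.2f", n_clipped, S_MAX)

    meta = {
        "preset": grid.preset,
        "seed": seed,
        "noise_level": noise_level,
        "temperature_K": params.temperature,
        "truth.kappa_tilde_kT": params.kappa_tilde_kT,
        "truth.sigma_N_per_m": params.sigma,
        "truth.eta_m_Pa_s_m": params.eta_m,
        "eta_in_Pa_s": params.eta_in,
        "eta_out_Pa_s": params.eta_out,
        "delta_m": params.delta,
        "mean_radius_m": population.mean_radius,
        "polydispersity": population.polydispersity,
        "family": population.family,
        "diffusion_mode": diffusion.mode if diffusion else "off",
    }
    return RelaxationDataset.from_arrays(
        np.concatenate(q_col), np.concatenate(t_col),
        np.concatenate(s_col), np.concatenate(e_col), meta)
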