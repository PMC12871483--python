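"""Weighted least-squares estimation of membrane parameters from NSE data.

The central object is :class:`SphericalVesicleModel`: it binds a
:class:`~vesiclense.dataset.RelaxationDataset` to the fixed physics
(solvent viscosities, temperature, membrane thickness, radius distribution,
diffusion handling) and exposes

* :meth:`SphericalVesicleModel.fit_per_q` -- independent one-parameter fits
  of the bending rigidity at each q, the primary diagnostic for the
  high-q rigidity plateau;
* :meth:`SphericalVesicleModel.fit` -- a global fit of up to two free
  parameters (rigidity, tension, membrane viscosity) across all q blocks;
* :func:`viscosity_scan` -- rigidity fits on a grid of imposed membrane
  viscosities, supporting the size-consistency upper-bound argument.

Fits use trust-region-reflective least squares with numerical Jacobians,
weights ``1/err^2``, rigidity bounds ``[0.5, 1e5] k_B T`` and a multistart
over ``{10, 50, 200, 1000} k_B T`` to avoid the low-q local-minimum
pathology where a very small rigidity mimics imperfect diffusion modelling.
Reported uncertainties are one standard deviation from the scaled
covariance at the optimum.  Rigidity and membrane viscosity are nearly
degenerate when both are free (a larger imposed membrane viscosity is
compensated by a smaller fitted rigidity); this combination triggers a
warning and, for an ill-conditioned Hessian, uncertainties are refused and
only the correlation matrix is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import RelaxationDataset
from .errors import ConfigurationError, DomainError
from .modes import mode_spectrum, relative_msd
from .params import MembraneParams, VesiclePopulation
from .structure import N_QUADRATURE_NODES, shell_form_factor
from .transport import DiffusionSpec

__all__ = [
    "SphericalVesicleModel",
    "FitResult",
    "PerQFitResult",
    "fit_kappa_per_q",
    "fit_global",
    "viscosity_scan",
]

log = logging.getLogger(__name__)

#: rigidity bounds in units of k_B T
KAPPA_BOUNDS_KT = (0.5, 1.0e5)
#: multistart rigidity values, k_B T
KAPPA_STARTS_KT = (10.0, 50.0, 200.0, 1000.0)
#: tension bounds, mN/m (internal fit scale)
SIGMA_BOUNDS_MN_PER_M = (0.0, 100.0)
#: membrane-viscosity bounds, nPa s m (internal fit scale)
ETA_M_BOUNDS_NPASM = (0.0, 100.0)

_FREE_NAMES = ("kappa_tilde", "sigma", "eta_m")
# internal scale factors: fit-space value * scale = SI value
_SCALES = {"sigma": 1e-3, "eta_m": 1e-9}

DEGENERACY_MESSAGE = (
    "rigidity and membrane viscosity are nearly degenerate in a single-size "
    "fit: larger eta_m is compensated by smaller kappa_tilde; interpret "
    "joint uncertainties with care")


def _flag_bounds(value, lo, hi):
    span = hi - lo
    at_upper = hi - value <= 1e-4 * span
    at_lower = value - lo <= 1e-2 * max(lo, 1e-12 * span)
    return "at_bound" if (at_upper or at_lower) else "ok"


@dataclass
class FitResult:
    """Global fit result: estimates, 1-sigma uncertainties, diagnostics.

    ``params`` and ``bse`` are SI; ``fixed`` records every non-fitted
    physical parameter so the provenance of imposed values is explicit.
    """

    params: dict
    bse: dict | None
    fixed: dict
    chi2: float
    redchi: float
    ndata: int
    nfree: int
    temperature: float
    correlation: np.ndarray | None = None
    flags: tuple = ()
    messages: tuple = ()
    nfev: int = 0
    success: bool = True

    @property
    def kappa_tilde_kT(self) -> float:
        from .constants import BOLTZMANN
        return self.params["kappa_tilde"] / (BOLTZMANN * self.temperature)

    def bse_kT(self) -> float | None:
        from .constants import BOLTZMANN
        if self.bse is None or "kappa_tilde" not in self.bse:
            return None
        return self.bse["kappa_tilde"] / (BOLTZMANN * self.temperature)

    def summary(self) -> str:
        from .constants import BOLTZMANN
        kT = BOLTZMANN * self.temperature
        lines = ["Spherical vesicle NSE fit",
                 "=" * 41,
                 f"{'n data':<22}{self.ndata}",
                 f"{'n free parameters':<22}{self.nfree}",
                 f"{'chi2 / dof':<22}{self.redchi:.4g}",
                 "-" * 41]
        for name, val in self.params.items():
            err = self.bse.get(name) if self.bse else None
            if name == "kappa_tilde":
                txt = f"{val / kT:.4g} kT"
                if err is not None:
                    txt += f" +/- {err / kT:.3g}"
            else:
                unit = {"sigma": "N/m", "eta_m": "Pa s m"}.get(name, "")
                txt = f"{val:.4g} {unit}"
                if err is not None:
                    txt += f" +/- {err:.3g}"
            lines.append(f"{name:<22}{txt}")
        for name, val in self.fixed.items():
            lines.append(f"{name + ' (fixed)':<22}{val:.4g}")
        for fl in self.flags:
            lines.append(f"flag: {fl}")
        for m in self.messages:
            lines.append(f"note: {m}")
        return "\n".join(lines)


@dataclass
class PerQFitResult:
    """Per-q rigidity estimates (one independent fit per q block)."""

    frame: pd.DataFrame    # q_invA, kappa_kT, kappa_err_kT, chi2red, flag
    fixed: dict
    temperature: float
    results: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Per-q rigidity fits", "=" * 41,
                 self.frame.to_string(index=False,
                                      float_format=lambda v: f"{v:.4g}")]
        for name, val in self.fixed.items():
            lines.append(f"{name + ' (fixed)':<22}{val:.4g}")
        return "\n".join(lines)


class SphericalVesicleModel:
    """Finite-size spherical-vesicle relaxation model bound to one dataset.

    Parameters
    ----------
    data : RelaxationDataset
    params : MembraneParams
        Fixed physics and the starting rigidity; fitted parameters override
        the corresponding fields during optimization.
    population : VesiclePopulation
    diffusion : DiffusionSpec or None
        ``None`` disables the diffusion factor.
    n_nodes : int
        Radius-quadrature nodes.
    """

    def __init__(self, data: RelaxationDataset, params: MembraneParams,
                 population: VesiclePopulation,
                 diffusion: DiffusionSpec | None = None,
                 n_nodes: int = N_QUADRATURE_NODES):
        self.data = data
        self.params = params
        self.population = population
        self.diffusion = diffusion
        self.n_nodes = n_nodes

        radii, number_w = population.quadrature(
            n_nodes=n_nodes, min_radius=np.nextafter(params.delta, np.inf))
        self._radii = radii
        if diffusion is not None and diffusion.enabled:
            self._d_coef = diffusion.coefficients(
                radii, mean_radius=population.mean_radius)
        else:
            self._d_coef = np.zeros_like(radii)

        self._blocks = []
        for q, sub in data.blocks():
            t = sub["t"].to_numpy()
            w = number_w * radii**4 * shell_form_factor(q * radii)
            norm = np.add.reduce(w)
            if not norm > 0:
                raise ConfigurationError(
                    f"no scattering weight at q = {q:g} 1/m")
            self._blocks.append({
                "q": q, "t": t,
                "s": sub["s"].to_numpy(), "err": sub["err"].to_numpy(),
                "weights": w / norm,
                "difft": np.outer(self._d_coef, q**2 * t),
            })

    # ------------------------------------------------------------------
    @classmethod
    def from_dataset(cls, data: RelaxationDataset, params: MembraneParams,
                     population: VesiclePopulation,
                     diffusion: DiffusionSpec | None = None,
                     **kwargs) -> "SphericalVesicleModel":
        return cls(data, params, population, diffusion, **kwargs)

    def _params_with(self, kappa_tilde=None, sigma=None, eta_m=None
                     ) -> MembraneParams:
        changes = {}
        if kappa_tilde is not None:
            changes["kappa_tilde"] = kappa_tilde
        if sigma is not None:
            changes["sigma"] = sigma
        if eta_m is not None:
            changes["eta_m"] = eta_m
        return self.params.replace(**changes) if changes else self.params

    def predict(self, kappa_tilde=None, sigma=None, eta_m=None,
                block_indices=None) -> list[np.ndarray]:
        """Model curves for the dataset's (q, t) grid."""
        p = self._params_with(kappa_tilde, sigma, eta_m)
        spectra = [mode_spectrum(p, r) for r in self._radii]
        indices = range(len(self._blocks)) if block_indices is None else block_indices
        out = []
        for i in indices:
            blk = self._blocks[i]
            q, t = blk["q"], blk["t"]
            num = np.zeros_like(t)
            for j, (r, w) in enumerate(zip(self._radii, blk["weights"])):
                if w == 0.0:
                    continue
                expo = q**2 * r**2 * relative_msd(spectra[j], t) + blk["difft"][j]
                num += w * np.exp(-expo)
            out.append(num)
        return out

    def _residuals(self, kappa_tilde, sigma, eta_m, block_indices=None):
        curves = self.predict(kappa_tilde, sigma, eta_m, block_indices)
        indices = range(len(self._blocks)) if block_indices is None else block_indices
        res = [(c - self._blocks[i]["s"]) / self._blocks[i]["err"]
               for c, i in zip(curves, indices)]
        return np.concatenate(res)

    # ------------------------------------------------------------------
    def fit(self, free=("kappa_tilde",), start: dict | None = None,
            block_indices=None) -> FitResult:
        """Global weighted least-squares fit of the ``free`` parameters.

        ``free`` is a subset of ``{"kappa_tilde", "sigma", "eta_m"}`` with
        at most two entries.
        """
        free = tuple(free)
        if not free or any(f not in _FREE_NAMES for f in free):
            raise ConfigurationError(
                f"free parameters must come from {_FREE_NAMES}")
        if len(free) > 2:
            raise ConfigurationError("at most 2 parameters may be free")
        messages = []
        if "kappa_tilde" in free and "eta_m" in free:
            warnings.warn(DEGENERACY_MESSAGE, stacklevel=2)
            messages.append(DEGENERACY_MESSAGE)

        kT = self.params.kT
        start = dict(start or {})

        def to_si(name, x):
            if name == "kappa_tilde":
                return x * kT
            return x * _SCALES[name]

        bounds_map = {
            "kappa_tilde": KAPPA_BOUNDS_KT,
            "sigma": SIGMA_BOUNDS_MN_PER_M,
            "eta_m": ETA_M_BOUNDS_NPASM,
        }
        default_start = {"sigma": 1e-3, "eta_m": 1e-3}

        def resid(x):
            kw = {"kappa_tilde": None, "sigma": None, "eta_m": None}
            for name, xi in zip(free, x):
                kw[name] = to_si(name, xi)
            return self._residuals(kw["kappa_tilde"], kw["sigma"],
                                   kw["eta_m"], block_indices)

        lo = [bounds_map[f][0] for f in free]
        hi = [bounds_map[f][1] for f in free]
        if "kappa_tilde" in free and "kappa_tilde" not in start:
            kappa_starts = KAPPA_STARTS_KT
        else:
            kappa_starts = (start.get("kappa_tilde",
                                      self.params.kappa_tilde_kT),)

        best = None
        nfev = 0
        for k0 in kappa_starts:
            x0 = []
            for f in free:
                if f == "kappa_tilde":
                    x0.append(np.clip(k0, *bounds_map[f]))
                else:
                    x0.append(start.get(f, default_start[f]))
            try:
                sol = optimize.least_squares(
                    resid, x0, bounds=(lo, hi), method="trf",
                    x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception as exc:   # noqa: BLE001 - collected as diagnostics
                messages.append(f"start {x0}: {exc}")
                continue
            nfev += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return FitResult(params={}, bse=None, fixed=self._fixed_record(free),
                             chi2=np.nan, redchi=np.nan,
                             ndata=self.data.n_records, nfree=len(free),
                             temperature=self.params.temperature,
                             flags=("no_convergence",),
                             messages=tuple(messages), nfev=nfev, success=False)

        chi2 = 2.0 * best.cost
        ndata = best.fun.size
        dof = max(ndata - len(free), 1)
        redchi = chi2 / dof

        params_si = {name: to_si(name, xi) for name, xi in zip(free, best.x)}
        flags = []
        for name, xi in zip(free, best.x):
            fl = _flag_bounds(xi, *bounds_map[name])
            if fl != "ok":
                flags.append(f"{name}_at_bound" if len(free) > 1 else "at_bound")

        # scaled covariance; refuse uncertainties for a degenerate Hessian
        J = best.jac
        H = J.T @ J
        bse = None
        correlation = None
        try:
            cond = np.linalg.cond(H)
        except np.linalg.LinAlgError:
            cond = np.inf
        if np.isfinite(cond) and cond < 1e12:
            cov = np.linalg.inv(H) * redchi
            sd = np.sqrt(np.diag(cov))
            with np.errstate(invalid="ignore"):
                correlation = cov / np.outer(sd, sd)
            bse = {}
            for name, s_fit in zip(free, sd):
                bse[name] = to_si(name, s_fit) if name != "kappa_tilde" \
                    else s_fit * kT
        else:
            flags.append("degenerate")
            cov_p = np.linalg.pinv(H)
            sd = np.sqrt(np.clip(np.diag(cov_p), 1e-300, None))
            with np.errstate(invalid="ignore", divide="ignore"):
                correlation = cov_p / np.outer(sd, sd)
            messages.append("degenerate Hessian: uncertainties refused; "
                            "correlation matrix reported instead")

        log.info("fit free=%s fixed=%s flags=%s", free,
                 self._fixed_record(free), flags)
        return FitResult(params=params_si, bse=bse,
                         fixed=self._fixed_record(free),
                         chi2=chi2, redchi=redchi, ndata=ndata,
                         nfree=len(free),
                         temperature=self.params.temperature,
                         correlation=correlation, flags=tuple(flags),
                         messages=tuple(messages), nfev=nfev,
                         success=bool(best.success))

    def _fixed_record(self, free) -> dict:
        rec = {}
        if "kappa_tilde" not in free:
            rec["kappa_tilde_kT"] = self.params.kappa_tilde_kT
        if "sigma" not in free:
            rec["sigma_N_per_m"] = self.params.sigma
        if "eta_m" not in free:
            rec["eta_m_Pa_s_m"] = self.params.eta_m
        rec["eta_in_Pa_s"] = self.params.eta_in
        rec["eta_out_Pa_s"] = self.params.eta_out
        rec["diffusion"] = 0.0 if self.diffusion is None else 1.0
        return rec

    # ------------------------------------------------------------------
    def fit_per_q(self) -> PerQFitResult:
        """Independent one-parameter rigidity fit at every q block."""
        rows = []
        results = []
        for i, blk in enumerate(self._blocks):
            res = self.fit(free=("kappa_tilde",), block_indices=[i])
            results.append(res)
            if res.success and res.params:
                kap = res.kappa_tilde_kT
                err = res.bse_kT()
                flag = res.flags[0] if res.flags else "ok"
            else:
                kap, err, flag = np.nan, np.nan, "no_convergence"
            rows.append({"q_invA": blk["q"] / 1e10, "kappa_kT": kap,
                         "kappa_err_kT": np.nan if err is None else err,
                         "chi2red": res.redchi, "flag": flag})
        frame = pd.DataFrame(rows)
        return PerQFitResult(frame=frame,
                             fixed=self._fixed_record(("kappa_tilde",)),
                             temperature=self.params.temperature,
                             results=results)


# ----------------------------------------------------------------------
# functional wrappers
def fit_kappa_per_q(data: RelaxationDataset, params: MembraneParams,
                    population: VesiclePopulation,
                    diffusion: DiffusionSpec | None = None,
                    **kwargs) -> PerQFitResult:
    """Per-q rigidity fits with tension and membrane viscosity fixed."""
    return SphericalVesicleModel(data, params, population, diffusion,
                                 **kwargs).fit_per_q()


def fit_global(data: RelaxationDataset, free, params: MembraneParams,
               population: VesiclePopulation,
               diffusion: DiffusionSpec | None = None,
               **kwargs) -> FitResult:
    """Single parameter set fitted across all q blocks simultaneously."""
    return SphericalVesicleModel(data, params, population, diffusion,
                                 **kwargs).fit(free=free)


def viscosity_scan(data: RelaxationDataset, eta_m_grid,
                   params: MembraneParams, population: VesiclePopulation,
                   diffusion: DiffusionSpec | None = None,
                   **kwargs) -> pd.DataFrame:
    """Fit the rigidity for each imposed membrane viscosity.

    Returns a table ``(eta_m, kappa_kT, kappa_err_kT, chi2red, flag)``; a
    growing imposed viscosity is typically compensated by a smaller fitted
    rigidity, and the onset of size-dependent rigidity differences bounds
    the physical membrane viscosity from above.
    """
    rows = []
    for eta_m in np.asarray(eta_m_grid, dtype=float):
        if eta_m < 0:
            raise DomainError("eta_m grid values must be non-negative")
        model = SphericalVesicleModel(
            data, params.replace(eta_m=float(eta_m)), population, diffusion,
            **kwargs)
        res = model.fit(free=("kappa_tilde",))
        if res.success and res.params:
            err = res.bse_kT()
            rows.append({"eta_m": eta_m, "kappa_kT": res.kappa_tilde_kT,
                         "kappa_err_kT": np.nan if err is None else err,
                         "chi2red": res.redchi,
                         "flag": res.flags[0] if res.flags else "ok"})
        else:
            rows.append({"eta_m": eta_m, "kappa_kT": np.nan,
                         "kappa_err_kT": np.nan, "chi2red": np.nan,
                         "flag": "no_convergence"})
    return pd.DataFrame(rows)
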