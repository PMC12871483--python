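"""Leaflet-coupling interpretation of the NSE bending rigidity.

At nanosecond times and nanometre scales the two leaflets of a bilayer
cannot exchange lipids fast enough to relax the density asymmetry created
by bending, so the undulations relax with an *unrelaxed* rigidity

    kappa_tilde = kappa + 2 k_m d^2,

where ``k_m`` is the monolayer compression modulus and ``d`` the monolayer
neutral surface height.  With the bilayer area compressibility
``K_A = 2 k_m`` and the polymer-brush closure ``K_A = 24 kappa / t_hc^2``
(``t_hc``: hydrophobic bilayer thickness) this becomes

    kappa_tilde = kappa (1 + 24 (d / t_hc)^2),

which gives exactly a factor 7 at ``d = t_hc / 2``.

The polymer-brush closure is unreliable for polyunsaturated lipids and for
membranes containing cholesterol or peptides; a log notice (never an error)
is emitted when such species are named.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

from .constants import POLYMER_BRUSH_CAVEATS
from .errors import DomainError, NoRealSolutionError

__all__ = [
    "LeafletParams",
    "unrelaxed_kappa",
    "general_unrelaxed_kappa",
    "neutral_surface_from_ratio",
]

log = logging.getLogger(__name__)

#: polymer-brush constant in K_A = BRUSH_CONSTANT * kappa / t_hc^2
BRUSH_CONSTANT = 24.0


def _check_neutral_surface(d: float, t_hc: float) -> None:
    # The assumed range of the neutral surface height, standardized to the
    # hydrophobic *bilayer* thickness t_hc used throughout this module, is
    # [t_hc/2, t_hc].  Outside it we warn but still evaluate.
    if d < 0:
        raise DomainError("neutral surface height must be non-negative")
    if not t_hc / 2.0 <= d <= t_hc:
        warnings.warn(
            f"neutral surface height d = {d:g} m lies outside the usually "
            f"assumed range [{t_hc / 2:g}, {t_hc:g}] m", stacklevel=3)


@dataclass(frozen=True)
class LeafletParams:
    """Relaxed rigidity and bilayer geometry for the leaflet-coupling
    relation.  ``K_A`` is optional; when absent the polymer-brush closure
    supplies it.  ``k_m = K_A / 2`` is derived, never stored."""

    kappa: float            # relaxed bending rigidity, J
    d: float                # monolayer neutral surface height, m
    t_hc: float             # hydrophobic bilayer thickness, m
    K_A: float | None = None  # bilayer area compressibility, N/m
    lipid: str | None = None

    def __post_init__(self):
        if not (self.kappa > 0 and self.t_hc > 0):
            raise DomainError("kappa and t_hc must be positive")
        _check_neutral_surface(self.d, self.t_hc)
        if self.lipid and any(tag.lower() in self.lipid.lower()
                              for tag in POLYMER_BRUSH_CAVEATS):
            log.info("polymer-brush closure may be unreliable for %s",
                     self.lipid)

    @property
    def k_m(self) -> float:
        """Monolayer compression modulus, N/m."""
        K_A = self.K_A
        if K_A is None:
            K_A = BRUSH_CONSTANT * self.kappa / self.t_hc**2
        return K_A / 2.0

    def kappa_tilde(self) -> float:
        if self.K_A is None:
            return unrelaxed_kappa(self.kappa, self.d, self.t_hc)
        return general_unrelaxed_kappa(self.kappa, self.k_m, self.d)


def unrelaxed_kappa(kappa: float, d: float, t_hc: float) -> float:
    """Unrelaxed rigidity via the polymer-brush closure:
    ``kappa (1 + 24 (d/t_hc)^2)``, J.  Strictly increasing in ``d``."""
    if not (kappa > 0 and d >= 0 and t_hc > 0):
        raise DomainError("kappa, t_hc must be positive and d non-negative")
    _check_neutral_surface(d, t_hc)
    return kappa * (1.0 + BRUSH_CONSTANT * (d / t_hc) ** 2)


def general_unrelaxed_kappa(kappa: float, k_m: float, d: float) -> float:
    """Unrelaxed rigidity ``kappa + 2 k_m d^2`` without the polymer-brush
    assumption, J."""
    if kappa < 0 or k_m < 0 or d < 0:
        raise DomainError("inputs must be non-negative")
    return kappa + 2.0 * k_m * d**2


def neutral_surface_from_ratio(kappa_tilde: float, kappa: float,
                               t_hc: float) -> float:
    """Invert the polymer-brush relation for the neutral surface height, m.

    Raises :class:`NoRealSolutionError` when ``kappa_tilde < kappa``.
    """
    if not (kappa > 0 and t_hc > 0):
        raise DomainError("kappa and t_hc must be positive")
    if kappa_tilde < kappa:
        raise NoRealSolutionError(
            "kappa_tilde below kappa has no real neutral-surface height")
    return t_hc * math.sqrt((kappa_tilde / kappa - 1.0) / BRUSH_CONSTANT)
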