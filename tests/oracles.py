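"""Independent oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: mode
sums are accumulated term by term with ``math.fsum`` (exact rounding of
the term stream), and the equal-viscosity relaxation rate is the classical
Milner-Safran closed form, written separately from the package's general
friction bracket.
"""

import math

KB = 1.380649e-23


def milner_safran_rate(kappa, eta, radius, l, sigma_reduced=0.0):
    """Equal-viscosity, inviscid-membrane mode relaxation rate:
    Gamma_l = (kappa / eta R^3) l(l+1)(l-1)(l+2)[l(l+1)+sigma_r]
              / [(2l+1)(2l^2+2l-1)]."""
    num = l * (l + 1) * (l - 1) * (l + 2) * (l * (l + 1) + sigma_reduced)
    den = (2 * l + 1) * (2 * l**2 + 2 * l - 1)
    return kappa / (eta * radius**3) * num / den


def naive_mode_terms(params, radius, t=None):
    """Per-mode contributions to the (relative) mean-square displacement,
    computed scalar-by-scalar; ``t=None`` gives the saturated terms."""
    l_max = max(int(math.floor(math.pi * radius / params.delta)), 2)
    kT = KB * params.temperature
    sigma_r = params.sigma * radius**2 / params.kappa_tilde
    terms = []
    for l in range(2, l_max + 1):
        stiff = (l - 1) * (l + 2) * (l * (l + 1) + sigma_r)
        amp2 = kT / (params.kappa_tilde * stiff)
        if t is None:
            relax = 1.0
        else:
            fric = (params.eta_in * (l - 1) * (2 * l**2 + 5 * l + 5)
                    + params.eta_out * (l + 2) * (2 * l**2 - l + 2)
                    + 4.0 * params.eta_m / radius * (l - 1) * (l + 2))
            rate = (params.kappa_tilde * stiff * l * (l + 1)
                    / (radius**3 * fric))
            relax = -math.expm1(-rate * t)
        terms.append((2 * l + 1) / (4 * math.pi) * amp2 * relax)
    return terms


def naive_relative_msd(params, radius, t):
    return math.fsum(naive_mode_terms(params, radius, t))


def naive_plateau(params, radius):
    return math.fsum(naive_mode_terms(params, radius, None))
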