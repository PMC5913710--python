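"""Independent numerical oracles used by the tests.

These deliberately avoid the package's quadratic-root code path: the
assimilation rate is found by bisecting the supply/demand fixed point
A = g (C - Cc), with Cc the CO2 partial pressure at the carboxylation
site and the demand given by the hyperbolic rate laws evaluated at Cc.
"""

from __future__ import annotations

from scipy.optimize import brentq


def ac_closed_form(C, Vcmax, Rd, Gamma_star, Kc, Ko, O):
    """Infinite-conductance RuBisCO-limited rate."""
    km = Kc * (1.0 + O / Ko)
    return Vcmax * (C - Gamma_star) / (C + km) - Rd


def aj_closed_form(C, J, Rd, Gamma_star):
    """Infinite-conductance RuBP-regeneration-limited rate."""
    return (J / 4.0) * (C - Gamma_star) / (C + 2.0 * Gamma_star) - Rd


def _bisect_fixed_point(C, g, demand, demand_args):
    def h(cc):
        return demand(cc, *demand_args) - g * (C - cc)

    hi = C + 10.0 + abs(demand(C + 1000.0, *demand_args)) / g + 1000.0 / g
    cc = brentq(h, 1e-12, hi, xtol=1e-13, rtol=1e-14)
    return g * (C - cc)


def ac_bisection(C, g, Vcmax, Rd, Gamma_star, Kc, Ko, O):
    """Fixed-point RuBisCO-limited rate at finite conductance."""
    return _bisect_fixed_point(C, g, ac_closed_form, (Vcmax, Rd, Gamma_star, Kc, Ko, O))


def aj_bisection(C, g, J, Rd, Gamma_star):
    """Fixed-point RuBP-limited rate at finite conductance."""
    return _bisect_fixed_point(C, g, aj_closed_form, (J, Rd, Gamma_star))
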