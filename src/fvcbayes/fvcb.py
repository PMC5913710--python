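"""Deterministic Farquhar–von Caemmerer–Berry (FvCB) forward model.

Eight structural variants of the C3 photosynthesis model arranged in a
2x2x2 design:

* mesophyll-conductance limitation estimated (``CiCc`` codes, the rate
  equations become quadratics in A through a finite g_m) versus infinite
  g_m (``CaCc`` codes, ambient CO2 and stomatal conductance drive the
  supply function);
* electron transport rate (ETR) derived from chlorophyll fluorescence
  (``Jf``: J = phiPSII * f * Q * alpha_leaf) versus an empirical
  non-rectangular hyperbola light response (``Jm``: parameters Jmax,
  phiJ, thetaJ);
* Arrhenius temperature constraint on the kinetic parameters (``_Temp``
  suffix) versus parameters treated as constant over the measured leaf
  temperatures.

Net assimilation is the minimum of the RuBisCO-limited rate Ac and the
RuBP-regeneration-limited rate Aj.  All functions operate elementwise on
NumPy broadcastable inputs, so the same code serves a single observation,
a curve, or a (draws x grid) posterior-predictive evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import ALPHA_LEAF, F_PSII, KELVIN_OFFSET, R_GAS, T_REF_K

__all__ = [
    "MODEL_CODES",
    "ModelSpec",
    "StructuralParameters",
    "LimitationPrediction",
    "enumerate_structural_parameters",
    "arrhenius_adjust",
    "compute_jf",
    "compute_jm",
    "ac_solution",
    "aj_solution",
    "cc_drawdown",
    "predict_arrays",
    "predict_assimilation",
]

#: The eight model codes, in the canonical table order.
MODEL_CODES = (
    "CiCc_Jf",
    "CiCc_Jm",
    "CaCc_Jf",
    "CaCc_Jm",
    "CiCc_Jf_Temp",
    "CiCc_Jm_Temp",
    "CaCc_Jf_Temp",
    "CaCc_Jm_Temp",
)

# Parameters that receive an Arrhenius temperature response when the spec
# is temperature-constrained, and the name of their activation energy.
_TEMP_RESPONSIVE = {
    "Vcmax25": "E_Vcmax",
    "Rd25": "E_Rd",
    "Gamma_star25": "E_Gamma_star",
    "Kc25": "E_Kc",
    "Ko25": "E_Ko",
    "Jmax25": "E_Jmax",
    "gm25": "E_gm",
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the eight structural model variants.

    The code string (e.g. ``"CiCc_Jm_Temp"``) is uniquely determined by the
    three boolean assumptions and vice versa.
    """

    gm_limited: bool
    etr_mode: str  # "Jf" or "Jm"
    temp_constrained: bool

    def __post_init__(self) -> None:
        if self.etr_mode not in ("Jf", "Jm"):
            raise ValueError(f"etr_mode must be 'Jf' or 'Jm', got {self.etr_mode!r}")

    @property
    def code(self) -> str:
        base = ("CiCc" if self.gm_limited else "CaCc") + "_" + self.etr_mode
        return base + "_Temp" if self.temp_constrained else base

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        if code not in MODEL_CODES:
            raise ValueError(
                f"unknown model code {code!r}; expected one of {', '.join(MODEL_CODES)}"
            )
        parts = code.split("_")
        return cls(
            gm_limited=parts[0] == "CiCc",
            etr_mode=parts[1],
            temp_constrained=code.endswith("_Temp"),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def enumerate_structural_parameters(spec: ModelSpec) -> list[str]:
    """Ordered list of the free structural parameters of a model variant.

    Base set {Vcmax25, Rd25, Gamma_star25, Kc25, Ko25}; plus gm25 for
    g_m-limited variants; plus {Jmax25, phiJ, thetaJ} for Jm ETR; plus one
    activation energy per temperature-responsive parameter present for
    temperature-constrained variants.  ``len()`` of the result reproduces
    the published per-model parameter counts (5..16).
    """
    names = ["Vcmax25", "Rd25", "Gamma_star25", "Kc25", "Ko25"]
    if spec.gm_limited:
        names.append("gm25")
    if spec.etr_mode == "Jm":
        names.extend(["Jmax25", "phiJ", "thetaJ"])
    if spec.temp_constrained:
        for base, energy in _TEMP_RESPONSIVE.items():
            if base in names:
                names.append(energy)
    return names


@dataclass
class StructuralParameters:
    """Container for one full parameter vector of a model variant.

    Units: rates in umol m-2 s-1; partial pressures (Gamma_star25, Kc25,
    Ko25) in Pa; gm25 in umol m-2 s-1 Pa-1; activation energies in
    kJ mol-1; phiJ in e- photon-1; thetaJ unitless.
    """

    Vcmax25: float
    Rd25: float
    Gamma_star25: float
    Kc25: float
    Ko25: float
    gm25: float | None = None
    Jmax25: float | None = None
    phiJ: float | None = None
    thetaJ: float | None = None
    E_Vcmax: float | None = None
    E_Rd: float | None = None
    E_Gamma_star: float | None = None
    E_Kc: float | None = None
    E_Ko: float | None = None
    E_Jmax: float | None = None
    E_gm: float | None = None

    def as_dict(self, spec: ModelSpec) -> dict[str, float]:
        """Exactly the parameters the spec requires; raises if any is missing."""
        out: dict[str, float] = {}
        for name in enumerate_structural_parameters(spec):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"model {spec.code} requires parameter {name}")
            out[name] = value
        return out


@dataclass
class LimitationPrediction:
    """Per-observation prediction with the limiting pathway identified."""

    Ac: float
    Aj: float
    Aexp: float
    J: float
    limiting: str  # "rubisco" or "RuBP"


def arrhenius_adjust(p25, Ei, T):
    """Arrhenius temperature response of a parameter standardized to 25 C.

    Parameters
    ----------
    p25 : value of the parameter at 25 C (any positive unit).
    Ei : activation energy in kJ mol-1.
    T : leaf temperature in C.

    Returns ``p25 * exp[Ei * (T_K - 298) / (298 * R * T_K)]`` with T_K in
    Kelvin and Ei converted to J mol-1.  Identity at T_K = 298 and at Ei = 0.
    """
    t_k = np.asarray(T, dtype=float) + KELVIN_OFFSET
    ei_j = np.asarray(Ei, dtype=float) * 1000.0
    return p25 * np.exp(ei_j * (t_k - T_REF_K) / (T_REF_K * R_GAS * t_k))


def compute_jf(phiPSII, Q):
    """Fluorescence-derived electron transport rate: phiPSII * f * Q * alpha_leaf."""
    return np.asarray(phiPSII, dtype=float) * F_PSII * np.asarray(Q, dtype=float) * ALPHA_LEAF


def compute_jm(Q, Jmax, phiJ, thetaJ):
    """Light-response electron transport rate (non-rectangular hyperbola).

    Smaller root of ``thetaJ * J^2 - (I2 + Jmax) * J + I2 * Jmax = 0`` with
    ``I2 = Q * phiJ * alpha_leaf``.  Evaluated in the numerically stable
    ``2c / (-b + sqrt(b^2 - 4ac))`` form so the thetaJ -> 0 limit degrades
    gracefully to the rectangular hyperbola ``I2*Jmax/(I2+Jmax)``.
    """
    i2 = np.asarray(Q, dtype=float) * np.asarray(phiJ, dtype=float) * ALPHA_LEAF
    jmax = np.asarray(Jmax, dtype=float)
    theta = np.asarray(thetaJ, dtype=float)
    s = i2 + jmax
    disc = s * s - 4.0 * theta * i2 * jmax
    disc = np.maximum(disc, 0.0)  # >= (I2-Jmax)^2 for theta <= 1
    denom = s + np.sqrt(disc)
    return np.where(denom > 0.0, 2.0 * i2 * jmax / np.where(denom > 0.0, denom, 1.0), 0.0)


def cc_drawdown(C, A, g):
    """Diagnostic CO2 partial pressure at the downstream end of a conductance.

    ``Cc = C - A/g`` — chloroplastic CO2 for a mesophyll conductance, or
    intercellular CO2 for a stomatal one.  Derived output only; it plays no
    role in inference.
    """
    return np.asarray(C, dtype=float) - np.asarray(A, dtype=float) / np.asarray(g, dtype=float)


def _quadratic_smaller_root(g, b, c):
    """Physically admissible root of ``a A^2 + b A + c = 0`` with ``a = -1/g``.

    This is the (-b + sqrt(b^2-4ac)) / (2a) root, computed in the
    algebraically identical form ``2c / (-b - sqrt(b^2-4ac))`` which stays
    stable as g -> infinity (a -> 0) and reduces there to ``-c/b``.
    Returns NaN where the discriminant is negative.
    """
    a = -1.0 / g
    disc = b * b - 4.0 * a * c
    invalid = disc < 0.0
    root = 2.0 * c / (-b - np.sqrt(np.maximum(disc, 0.0)))
    return np.where(invalid, np.nan, root)


def ac_solution(C, g, Vcmax, Rd, Gamma_star, Kc, Ko, O):
    """RuBisCO-limited assimilation rate Ac.

    Solves ``a Ac^2 + b Ac + c = 0`` with ``a = -1/g``,
    ``b = (Vcmax - Rd)/g + C + Km``, ``c = Rd (C + Km) - Vcmax (C - Gamma_star)``
    where ``Km = Kc (1 + O/Ko)`` and C is intercellular (g = g_m) or ambient
    (g = g_s) CO2 partial pressure in Pa.  Elementwise; NaN where the
    discriminant is negative.
    """
    km = Kc * (1.0 + O / Ko)
    b = (Vcmax - Rd) / g + C + km
    c = Rd * (C + km) - Vcmax * (C - Gamma_star)
    return _quadratic_smaller_root(g, b, c)


def aj_solution(C, g, J, Rd, Gamma_star):
    """RuBP-regeneration-limited assimilation rate Aj.

    Solves ``a Aj^2 + b Aj + c = 0`` with ``a = -1/g``,
    ``b = (J/4 - Rd)/g + C + 2 Gamma_star``,
    ``c = Rd (C + 2 Gamma_star) - (J/4)(C - Gamma_star)``.
    """
    b = (J / 4.0 - Rd) / g + C + 2.0 * Gamma_star
    c = Rd * (C + 2.0 * Gamma_star) - (J / 4.0) * (C - Gamma_star)
    return _quadratic_smaller_root(g, b, c)


def _positive(x):
    return np.asarray(x, dtype=float) > 0.0


def predict_arrays(
    spec: ModelSpec,
    theta: Mapping[str, np.ndarray | float],
    drivers: Mapping[str, np.ndarray | float],
) -> dict[str, np.ndarray]:
    """Vectorized forward prediction for arbitrary broadcastable inputs.

    Parameters
    ----------
    spec : model variant.
    theta : structural parameters (per-observation arrays or scalars) named
        as in :func:`enumerate_structural_parameters`.
    drivers : observation drivers; requires ``Ci`` (Pa) for g_m-limited
        variants or ``Ca`` (Pa) and ``gs`` (umol m-2 s-1 Pa-1) otherwise,
        ``O`` (Pa), plus ``T`` (C) for temperature-constrained variants and
        ``Q``/``phiPSII`` as the ETR mode demands.

    Returns
    -------
    dict with broadcast arrays ``Ac``, ``Aj``, ``Aexp``, ``J`` and a boolean
    ``valid`` mask.  Entries are NaN wherever a parameter is inadmissible
    (non-positive where positivity is required, thetaJ outside (0, 1]) or a
    quadratic discriminant is negative.
    """
    th = {k: np.asarray(v, dtype=float) for k, v in theta.items()}

    valid = _positive(th["Vcmax25"]) & _positive(th["Rd25"])
    valid &= _positive(th["Gamma_star25"]) & _positive(th["Kc25"]) & _positive(th["Ko25"])
    if spec.gm_limited:
        valid &= _positive(th["gm25"])
    if spec.etr_mode == "Jm":
        theta_j = np.asarray(th["thetaJ"], dtype=float)
        valid &= _positive(th["Jmax25"]) & _positive(th["phiJ"])
        valid &= (theta_j > 0.0) & (theta_j <= 1.0)

    # Temperature pathway: adjust every temperature-responsive parameter
    # present; non-Temp variants use the 25 C values untouched.
    at_t: dict[str, np.ndarray] = {}
    for base in ("Vcmax25", "Rd25", "Gamma_star25", "Kc25", "Ko25", "Jmax25", "gm25"):
        if base not in th:
            continue
        if spec.temp_constrained:
            at_t[base] = arrhenius_adjust(th[base], th[_TEMP_RESPONSIVE[base]], drivers["T"])
        else:
            at_t[base] = th[base]

    if spec.etr_mode == "Jf":
        j = compute_jf(drivers["phiPSII"], drivers["Q"])
    else:
        j = compute_jm(drivers["Q"], at_t["Jmax25"], th["phiJ"], th["thetaJ"])

    if spec.gm_limited:
        c_drive = np.asarray(drivers["Ci"], dtype=float)
        g = at_t["gm25"]
    else:
        c_drive = np.asarray(drivers["Ca"], dtype=float)
        g = np.asarray(drivers["gs"], dtype=float)

    o_pressure = np.asarray(drivers["O"], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = ac_solution(
            c_drive, g, at_t["Vcmax25"], at_t["Rd25"], at_t["Gamma_star25"],
            at_t["Kc25"], at_t["Ko25"], o_pressure,
        )
        aj = aj_solution(c_drive, g, j, at_t["Rd25"], at_t["Gamma_star25"])
        aexp = np.minimum(ac, aj)

    valid = valid & np.isfinite(ac) & np.isfinite(aj)
    return {
        "Ac": ac,
        "Aj": aj,
        "Aexp": aexp,
        "J": np.broadcast_to(np.asarray(j, dtype=float), np.shape(aexp)).copy()
        if np.shape(j) != np.shape(aexp) else j,
        "valid": np.broadcast_to(valid, np.shape(aexp)).copy()
        if np.shape(valid) != np.shape(aexp) else valid,
    }


def predict_assimilation(
    params: StructuralParameters | Mapping[str, float],
    curve,
    spec: ModelSpec,
) -> list[LimitationPrediction]:
    """Predict the limitation structure of one gas-exchange curve.

    ``params`` may be a :class:`StructuralParameters` or a plain mapping.
    Raises :class:`ValueError` if any observation yields an invalid solution
    (the inference layer instead encodes invalidity as -inf log-likelihood).
    """
    if isinstance(params, StructuralParameters):
        theta = params.as_dict(spec)
    else:
        theta = {k: float(v) for k, v in params.items()}
        for name in enumerate_structural_parameters(spec):
            if name not in theta:
                raise ValueError(f"model {spec.code} requires parameter {name}")
    out = predict_arrays(spec, theta, curve.drivers())
    if not np.all(out["valid"]):
        bad = int(np.sum(~out["valid"]))
        raise ValueError(
            f"invalid FvCB solution for {bad} observation(s) of curve "
            f"({curve.genotype_id}, {curve.individual_id}) under {spec.code}"
        )
    preds = []
    for ac, aj, aexp, j in zip(out["Ac"], out["Aj"], out["Aexp"], out["J"]):
        preds.append(
            LimitationPrediction(
                Ac=float(ac),
                Aj=float(aj),
                Aexp=float(aexp),
                J=float(j),
                limiting="rubisco" if ac <= aj else "RuBP",
            )
        )
    return preds
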