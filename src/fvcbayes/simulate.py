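"""Synthetic A/Ci + fluorescence curve generator.

Emulates the measurement protocol the screen expects — a 12-step CO2
ladder (~50 to 2000 umol mol-1) at saturating irradiance (2000
umol m-2 s-1) and leaf temperature near 22 C — with exactly the
statistical structure the inference assumes: individual trait values drawn
Normal around genotype means (the nesting level of the hierarchy), forward
FvCB prediction under a chosen generating model variant, and Gaussian
observation noise on net assimilation.

PSII quantum yield is derived by inverting the fluorescence ETR relation
from the generating electron transport rate; the optional ``delta_alt``
inflation emulates alternative (non-assimilatory) electron sinks, letting
tests reproduce the qualitative finding that fluorescence-derived ETR
overstates assimilatory electron flow.

The generator's defaults are the study conditions; they are not tuning
knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ALPHA_LEAF, F_PSII, O2_FRACTION
from .fvcb import ModelSpec, compute_jm, enumerate_structural_parameters, predict_arrays
from .hierarchy import default_prior_catalog
from .io import GasExchangeCurve, GasExchangeObservation, ppm_to_pa

__all__ = ["TruthSpec", "default_truth", "generate_dataset", "add_observation_noise",
           "recovery_score", "DEFAULT_CO2_LADDER"]

#: Measurement-protocol CO2 setpoints (umol mol-1).
DEFAULT_CO2_LADDER = (50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0,
                      800.0, 1000.0, 1250.0, 1500.0, 2000.0)

#: Default between-individual trait spread within a genotype (same units as
#: the traits).  Chosen as plausible within-genotype variation for a C3
#: crop: a few percent of the trait scale for the capacity traits, small
#: spreads for ratios and the photocompensation point.
DEFAULT_BETWEEN_INDIVIDUAL_SD = {
    "Vcmax25": 5.0,
    "Jmax25": 8.0,
    "Rd25": 0.15,
    "Gamma_star25": 0.15,
    "gm25": 0.25,
    "phiJ": 0.02,
    "thetaJ": 0.03,
}

# ETR truth symbols always needed to build phiPSII, even for Jf variants.
_ETR_SYMBOLS = ("Jmax25", "phiJ", "thetaJ")


@dataclass
class TruthSpec:
    """Generating structure and study conditions for a synthetic dataset."""

    spec: ModelSpec
    genotype_truth: dict[str, dict[str, float]]
    between_individual_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_INDIVIDUAL_SD)
    )
    process_sigma: float = 0.5
    n_individuals: int = 6
    co2_ladder: tuple[float, ...] = DEFAULT_CO2_LADDER
    Q: float = 2000.0
    T_mean: float = 22.0
    T_sd: float = 0.5
    P: float = 101325.0
    ci_ca_ratio: float = 0.7
    ci_jitter_sd: float = 0.02
    gs_mean: float = 3.0  # umol m-2 s-1 Pa-1, CO2 pressure basis
    gs_between_individual_sd: float = 0.2
    gs_obs_jitter_sd: float = 0.02  # relative per-observation jitter
    delta_alt: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.co2_ladder) != sorted(self.co2_ladder) or len(
            set(self.co2_ladder)
        ) != len(self.co2_ladder):
            raise ValueError("CO2 ladder must be strictly increasing")
        if self.process_sigma < 0 or self.delta_alt < 0:
            raise ValueError("process_sigma and delta_alt must be non-negative")
        needed = set(enumerate_structural_parameters(self.spec)) | set(_ETR_SYMBOLS)
        for geno, means in self.genotype_truth.items():
            missing = sorted(needed - set(means))
            if missing:
                raise ValueError(f"genotype {geno!r} truth lacks {missing}")
            for sym in needed:
                if sym not in ("phiJ", "thetaJ") and means[sym] <= 0:
                    raise ValueError(f"inadmissible truth: {sym} <= 0 for {geno!r}")
            if not (0 < means["phiJ"] <= 1 and 0 < means["thetaJ"] <= 1):
                raise ValueError(f"inadmissible ETR truth for {geno!r}")


def default_truth(
    spec: ModelSpec,
    genotypes: Sequence[str] = ("g1", "g2", "g3", "g4", "g5", "g6"),
    overrides: Mapping[str, Mapping[str, float]] | None = None,
    **kwargs,
) -> TruthSpec:
    """Truth at the literature prior means for every genotype.

    ``overrides`` maps genotype -> {symbol: value} for constructed
    contrasts (e.g. shifting one genotype's Jmax25).
    """
    base = {p.name: p.mean for p in default_prior_catalog()}
    # sorted so the generator's RNG consumption order is process-independent
    needed = sorted(set(enumerate_structural_parameters(spec)) | set(_ETR_SYMBOLS))
    genotype_truth = {}
    for geno in genotypes:
        means = {sym: base[sym] for sym in needed}
        if overrides and geno in overrides:
            means.update(overrides[geno])
        genotype_truth[geno] = means
    return TruthSpec(spec=spec, genotype_truth=genotype_truth, **kwargs)


def _individual_draws(rng, means: dict[str, float], sds: Mapping[str, float],
                      ind_level: set[str]) -> dict[str, float]:
    out = {}
    for sym, mean in means.items():
        sd = sds.get(sym, 0.0) if sym in ind_level else 0.0
        value = rng.normal(mean, sd) if sd > 0 else mean
        # redraw rather than truncate: keeps individuals admissible without
        # biasing the mean noticeably at the default small spreads
        tries = 0
        while value <= 0 and tries < 100:
            value = rng.normal(mean, sd)
            tries += 1
        if sym in ("phiJ", "thetaJ"):
            value = float(np.clip(value, 1e-3, 1.0))
        out[sym] = float(value)
    return out


def generate_dataset(truth: TruthSpec) -> tuple[list[GasExchangeCurve], dict]:
    """Generate curves plus a truth record for recovery scoring.

    Per individual: trait values are drawn around the genotype means; per
    ladder step: ambient CO2 is the setpoint mole fraction at pressure P,
    the generating ETR comes from the light-response at the individual's
    truth, PSII yield is its fluorescence inversion (inflated by
    ``delta_alt``), and net assimilation is the forward FvCB prediction
    plus Normal(0, process_sigma) noise.  For g_m-limited generating
    variants the intercellular CO2 is the configured stomatal drawdown of
    ambient (default 0.7, jittered); for infinite-g_m variants assimilation
    is driven by ambient CO2 through the individual's stomatal conductance
    and the reported Ci is the consistent diagnostic Ca - A/gs.
    """
    rng = np.random.default_rng(truth.seed)
    spec = truth.spec
    ind_level = {p.name for p in default_prior_catalog() if p.level == "individual"}
    ladder = np.asarray(truth.co2_ladder, dtype=float)
    n_steps = ladder.size

    curves: list[GasExchangeCurve] = []
    record_individuals: dict[str, dict[str, dict[str, float]]] = {}

    for geno, means in truth.genotype_truth.items():
        record_individuals[geno] = {}
        for j in range(truth.n_individuals):
            ind_id = f"{geno}_i{j + 1}"
            params = _individual_draws(rng, means, truth.between_individual_sd, ind_level)
            record_individuals[geno][ind_id] = dict(params)

            ca = ppm_to_pa(ladder, truth.P)
            t_leaf = rng.normal(truth.T_mean, truth.T_sd, size=n_steps)
            q = np.full(n_steps, truth.Q)
            o_pa = np.full(n_steps, O2_FRACTION * truth.P)

            # generating ETR and its fluorescence signature
            if spec.temp_constrained:
                from .fvcb import arrhenius_adjust

                jmax_t = arrhenius_adjust(params["Jmax25"], params["E_Jmax"], t_leaf) \
                    if "E_Jmax" in params else params["Jmax25"]
            else:
                jmax_t = params["Jmax25"]
            j_gen = compute_jm(q, jmax_t, params["phiJ"], params["thetaJ"])
            phi_psii = np.clip(
                j_gen * (1.0 + truth.delta_alt) / (F_PSII * q * ALPHA_LEAF), 0.0, 1.0
            )

            gs0 = rng.normal(truth.gs_mean, truth.gs_between_individual_sd)
            gs0 = float(max(gs0, 0.5))
            gs = gs0 * (1.0 + truth.gs_obs_jitter_sd * rng.standard_normal(n_steps))

            theta = {s: params[s] for s in enumerate_structural_parameters(spec)}
            if spec.gm_limited:
                ci = ca * truth.ci_ca_ratio * (
                    1.0 + truth.ci_jitter_sd * rng.standard_normal(n_steps)
                )
                ci = np.clip(ci, 1e-2, ca)
                drivers = {"Ci": ci, "Ca": ca, "gs": gs, "T": t_leaf, "Q": q,
                           "phiPSII": phi_psii, "O": o_pa}
                out = predict_arrays(spec, theta, drivers)
                aexp = out["Aexp"]
                gs = np.maximum(aexp, 0.05) / np.maximum(ca - ci, 1e-6)
            else:
                drivers = {"Ca": ca, "Ci": ca, "gs": gs, "T": t_leaf, "Q": q,
                           "phiPSII": phi_psii, "O": o_pa}
                out = predict_arrays(spec, theta, drivers)
                aexp = out["Aexp"]
                ci = np.clip(ca - aexp / gs, 1e-2, ca)
            if not np.all(out["valid"]):
                raise RuntimeError(
                    f"generating model produced an invalid solution for {ind_id}"
                )

            an = aexp + (
                rng.normal(0.0, truth.process_sigma, size=n_steps)
                if truth.process_sigma > 0 else 0.0
            )
            obs = [
                GasExchangeObservation(
                    An=float(an[i]), Ca=float(ca[i]), Ci=float(ci[i]),
                    gs=float(gs[i]), T=float(t_leaf[i]), P=float(truth.P),
                    Q=float(q[i]), phiPSII=float(phi_psii[i]), O=float(o_pa[i]),
                )
                for i in range(n_steps)
            ]
            curves.append(GasExchangeCurve(geno, ind_id, obs))

    record = {
        "model_code": spec.code,
        "genotype_means": {g: dict(m) for g, m in truth.genotype_truth.items()},
        "individual_values": record_individuals,
        "between_individual_sd": dict(truth.between_individual_sd),
        "process_sigma": truth.process_sigma,
        "ci_ca_ratio": truth.ci_ca_ratio,
        "delta_alt": truth.delta_alt,
        "seed": truth.seed,
        "conditions": {
            "co2_ladder_ppm": list(truth.co2_ladder),
            "Q": truth.Q, "T_mean": truth.T_mean, "T_sd": truth.T_sd, "P": truth.P,
        },
    }
    return curves, record


def add_observation_noise(
    curves: Sequence[GasExchangeCurve], sd: float, seed: int = 0
) -> list[GasExchangeCurve]:
    """Sensitivity harness: add Normal(0, sd^2) noise to net assimilation only."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for curve in curves:
        obs = [
            GasExchangeObservation(
                An=o.An + (rng.normal(0.0, sd) if sd > 0 else 0.0),
                Ca=o.Ca, Ci=o.Ci, gs=o.gs, T=o.T, P=o.P, Q=o.Q,
                phiPSII=o.phiPSII, O=o.O,
            )
            for o in curve.observations
        ]
        out.append(GasExchangeCurve(curve.genotype_id, curve.individual_id, obs))
    return out


def recovery_score(truth_record: Mapping, draws) -> pd.DataFrame:
    """Bias and 95% central-interval coverage of genotype-level truths.

    ``draws`` must come from fitting the generated data of
    ``draws.genotype_id`` with the generating model variant.  Scores the
    genotype means of nested symbols (``mu_<sym>``) and the genotype-level
    symbols directly.
    """
    if truth_record["model_code"] != draws.model_code:
        raise ValueError(
            f"draws fit {draws.model_code} but data were generated under "
            f"{truth_record['model_code']}"
        )
    geno = draws.genotype_id
    if geno not in truth_record["genotype_means"]:
        raise KeyError(f"genotype {geno!r} not in truth record")
    truths = truth_record["genotype_means"][geno]
    rows = []
    for name in draws.parameter_names:
        if name.startswith("mu_"):
            sym = name[3:]
        elif name.startswith("tau_") or name == "sigma" or name.endswith("]"):
            continue
        else:
            sym = name
        if sym not in truths:
            continue
        x = draws.get(name)
        lo, hi = np.quantile(x, [0.025, 0.975])
        rows.append(
            {
                "symbol": sym,
                "truth": truths[sym],
                "posterior_mean": float(np.mean(x)),
                "bias": float(np.mean(x) - truths[sym]),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "covered": bool(lo <= truths[sym] <= hi),
            }
        )
    return pd.DataFrame(rows).set_index("symbol")


def save_truth_record(record: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)


def load_truth_record(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
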