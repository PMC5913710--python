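"""Two-level hierarchical probability model for the photosynthesis screen.

Observation model: net assimilation is Gaussian around the FvCB forward
prediction, ``An ~ N(Aexp, tau)`` with precision ``tau = sigma^-2`` shared
across a genotype's curves.  Individual-level trait parameters are nested
within the genotype, ``mu_Y_i ~ N(mu_Y_geno, tau_Y_geno)``; evolutionarily
conserved parameters (the RuBisCO kinetic constants and the activation
energies) are estimated at the genotype level only.  Genotype means carry
literature-informed Normal priors specified as (mean, precision); each
genotype-level precision carries a weakly-informative Gamma prior, and the
process standard deviation a half-Cauchy prior.

This module is the readable reference implementation of the log densities;
the sampler in :mod:`fvcbayes.mcmc` uses an equivalent vectorized path and
is tested against these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .fvcb import ModelSpec, enumerate_structural_parameters, predict_arrays
from .io import GasExchangeCurve

__all__ = [
    "PriorSpec",
    "HyperPriorConfig",
    "HierarchicalState",
    "default_prior_catalog",
    "catalog_for_spec",
    "individual_level_symbols",
    "genotype_level_symbols",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "load_prior_catalog",
    "save_prior_catalog",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior (mean, precision) for one trait symbol, with its level."""

    name: str
    mean: float
    precision: float
    level: str  # "individual" or "genotype"

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError(f"precision must be positive for {self.name}")
        if self.level not in ("individual", "genotype"):
            raise ValueError(f"level must be 'individual' or 'genotype' for {self.name}")

    @property
    def sd(self) -> float:
        return self.precision ** -0.5


# The sixteen published prior entries.  Means/precisions are the exact
# printed values; "individual" symbols get the nested treatment, "genotype"
# symbols a single genotype-level value.
_PRIOR_TABLE: tuple[tuple[str, float, float, str], ...] = (
    ("gm25", 2.5, 0.025, "individual"),
    ("Jmax25", 171.0, 0.000308, "individual"),
    ("Rd25", 1.17, 1.0, "individual"),
    ("Vcmax25", 90.0, 0.000625, "individual"),
    ("Gamma_star25", 3.86, 10.0, "individual"),
    ("thetaJ", 0.8, 10.0, "individual"),
    ("phiJ", 0.4, 10.0, "individual"),
    ("Kc25", 27.24, 0.5, "genotype"),
    ("Ko25", 30400.0, 1.0e-5, "genotype"),
    ("E_gm", 49.6, 0.1, "genotype"),
    ("E_Jmax", 46.1, 0.01, "genotype"),
    ("E_Kc", 70.4, 0.5, "genotype"),
    ("E_Ko", 36.0, 0.5, "genotype"),
    ("E_Rd", 63.9, 0.1, "genotype"),
    ("E_Vcmax", 65.4, 0.5, "genotype"),
    ("E_Gamma_star", 26.8, 0.5, "genotype"),
)


def default_prior_catalog() -> list[PriorSpec]:
    """The full 16-entry literature prior catalog."""
    return [PriorSpec(*row) for row in _PRIOR_TABLE]


def catalog_for_spec(
    spec: ModelSpec, catalog: Sequence[PriorSpec] | None = None
) -> dict[str, PriorSpec]:
    """Subset of the catalog required by a model variant, keyed by symbol."""
    catalog = default_prior_catalog() if catalog is None else list(catalog)
    by_name = {p.name: p for p in catalog}
    needed = enumerate_structural_parameters(spec)
    missing = [n for n in needed if n not in by_name]
    if missing:
        raise KeyError(f"prior catalog lacks entries for {missing}")
    return {n: by_name[n] for n in needed}


def individual_level_symbols(
    spec: ModelSpec, catalog: Sequence[PriorSpec] | None = None
) -> list[str]:
    return [n for n, p in catalog_for_spec(spec, catalog).items() if p.level == "individual"]


def genotype_level_symbols(
    spec: ModelSpec, catalog: Sequence[PriorSpec] | None = None
) -> list[str]:
    return [n for n, p in catalog_for_spec(spec, catalog).items() if p.level == "genotype"]


@dataclass(frozen=True)
class HyperPriorConfig:
    """Hyperpriors: Gamma(shape, rate) on each genotype-level precision of an
    individual-level symbol, and half-Cauchy(scale) on the process sd."""

    precision_gamma_shape: float = 0.01
    precision_gamma_rate: float = 0.01
    process_sigma_half_cauchy_scale: float = 2.5

    def __post_init__(self) -> None:
        if min(self.precision_gamma_shape, self.precision_gamma_rate,
               self.process_sigma_half_cauchy_scale) <= 0:
            raise ValueError("hyperprior parameters must be positive")


@dataclass
class HierarchicalState:
    """One full parameter vector of the hierarchy for a (model, genotype) run.

    ``genotype_means`` holds mu_Y_geno for individual-level symbols and the
    single value for genotype-level symbols; ``genotype_precisions`` holds
    tau_Y_geno for individual-level symbols only; ``individual_values`` maps
    (individual_id, symbol) to mu_Y_i; ``process_sigma`` is the observation
    sd (tau = sigma^-2).
    """

    genotype_means: dict[str, float]
    genotype_precisions: dict[str, float]
    individual_values: dict[tuple[str, str], float]
    process_sigma: float

    def validate_structure(self, spec: ModelSpec, individual_ids: Sequence[str],
                           catalog: Sequence[PriorSpec] | None = None) -> None:
        """Check the state carries exactly the entries the spec implies."""
        ind_syms = set(individual_level_symbols(spec, catalog))
        geno_syms = set(genotype_level_symbols(spec, catalog))
        if set(self.genotype_means) != ind_syms | geno_syms:
            raise ValueError("genotype_means keys do not match the model's symbols")
        if set(self.genotype_precisions) != ind_syms:
            raise ValueError("genotype_precisions must cover exactly the "
                             "individual-level symbols")
        expected = {(i, s) for i in individual_ids for s in ind_syms}
        if set(self.individual_values) != expected:
            raise ValueError("individual_values must cover every (individual, "
                             "individual-level symbol) pair and nothing else")
        if self.process_sigma <= 0:
            raise ValueError("process_sigma must be positive")

    def theta_for_individual(self, spec: ModelSpec, individual_id: str,
                             catalog: Sequence[PriorSpec] | None = None) -> dict[str, float]:
        """Structural parameter vector seen by one individual's curve."""
        theta = {}
        for sym in enumerate_structural_parameters(spec):
            key = (individual_id, sym)
            theta[sym] = self.individual_values.get(key, self.genotype_means.get(sym))
        return theta


def _normal_logpdf(x, mean, precision):
    return 0.5 * (np.log(precision) - LOG_2PI) - 0.5 * precision * (x - mean) ** 2


def _gamma_logpdf(x, shape, rate):
    from scipy.special import gammaln

    if x <= 0:
        return -np.inf
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _half_cauchy_logpdf(x, scale):
    if x < 0:
        return -np.inf
    return np.log(2.0) - np.log(np.pi * scale * (1.0 + (x / scale) ** 2))


def log_likelihood(
    state: HierarchicalState,
    curves: Sequence[GasExchangeCurve],
    spec: ModelSpec,
) -> float:
    """Gaussian log-likelihood of a genotype's curves given the state.

    Returns -inf if any observation's forward prediction is invalid
    (negative discriminant or inadmissible parameter value).
    """
    sigma = state.process_sigma
    if sigma <= 0:
        return -np.inf
    tau = sigma ** -2
    total = 0.0
    for curve in curves:
        theta = state.theta_for_individual(spec, curve.individual_id)
        out = predict_arrays(spec, theta, curve.drivers())
        if not np.all(out["valid"]):
            return -np.inf
        resid = curve.column("An") - out["Aexp"]
        total += float(np.sum(_normal_logpdf(resid, 0.0, tau)))
    return total


def log_prior(
    state: HierarchicalState,
    spec: ModelSpec,
    hyper: HyperPriorConfig = HyperPriorConfig(),
    catalog: Sequence[PriorSpec] | None = None,
    truncate_at_zero: bool = False,
) -> float:
    """Log prior density of the full hierarchical state.

    Sums (i) the Normal priors on genotype means / genotype-level values,
    (ii) the nesting Normals of individual values around their genotype
    mean and precision, (iii) Gamma hyperpriors on genotype precisions, and
    (iv) the half-Cauchy prior on the process sd.  Priors are untruncated
    Normals by default (physically invalid proposals are instead rejected
    through the -inf likelihood); ``truncate_at_zero`` switches the Normal
    priors of positive-valued symbols to a zero-truncated form.
    """
    priors = catalog_for_spec(spec, catalog)
    total = 0.0
    for sym, prior in priors.items():
        value = state.genotype_means[sym]
        if truncate_at_zero and sym not in ("thetaJ", "phiJ"):
            if value <= 0:
                return -np.inf
            from scipy.stats import norm

            total += float(
                norm.logpdf(value, prior.mean, prior.sd)
                - np.log(norm.sf(0.0, prior.mean, prior.sd))
            )
        else:
            total += float(_normal_logpdf(value, prior.mean, prior.precision))

    ind_syms = [s for s, p in priors.items() if p.level == "individual"]
    for sym in ind_syms:
        tau_g = state.genotype_precisions[sym]
        if tau_g <= 0:
            return -np.inf
        total += _gamma_logpdf(tau_g, hyper.precision_gamma_shape, hyper.precision_gamma_rate)
        mu_g = state.genotype_means[sym]
        for (ind, s), value in state.individual_values.items():
            if s == sym:
                total += float(_normal_logpdf(value, mu_g, tau_g))

    total += _half_cauchy_logpdf(state.process_sigma, hyper.process_sigma_half_cauchy_scale)
    return float(total)


def log_posterior(
    state: HierarchicalState,
    curves: Sequence[GasExchangeCurve],
    spec: ModelSpec,
    hyper: HyperPriorConfig = HyperPriorConfig(),
    catalog: Sequence[PriorSpec] | None = None,
) -> float:
    lp = log_prior(state, spec, hyper, catalog)
    if not np.isfinite(lp):
        return -np.inf
    ll = log_likelihood(state, curves, spec)
    return float(lp + ll)


# ---------------------------------------------------------------------------
# Catalog persistence (supports the prior-updating loop of the screen)


def save_prior_catalog(catalog: Sequence[PriorSpec], path: str | Path) -> None:
    data = {
        p.name: {"mean": float(p.mean), "precision": float(p.precision), "level": p.level}
        for p in catalog
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_prior_catalog(path: str | Path) -> list[PriorSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        PriorSpec(name=name, mean=float(d["mean"]), precision=float(d["precision"]),
                  level=d["level"])
        for name, d in data.items()
    ]
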