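"""Posterior sampling for one (model variant, genotype) inference unit.

The published analysis used JAGS Gibbs/slice sampling; the kernel here is
an adaptive Metropolis-within-Gibbs scheme whose contract is the posterior,
not the kernel: conjugate Gibbs updates for the genotype-level means
(normal-normal) and precisions (gamma) of the nested symbols, random-walk
Metropolis updates for individual trait values and genotype-level kinetic
symbols, and a log-scale Metropolis update for the process sd.  Step sizes
adapt toward a 0.3-0.5 acceptance rate during burn-in only, so the retained
chain is a valid time-homogeneous Markov chain.

Individual trait values for a given symbol are proposed and accepted
per-individual in a single vectorized sweep: the likelihood factorizes over
individuals, so the coordinate blocks are conditionally independent.

The deviance D(theta) = -2 log p(Y | theta) is monitored alongside the
draws for DIC scoring (the data-only standardizing term of the deviance
definition is constant across models and dropped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fvcb import ModelSpec, predict_arrays
from .hierarchy import (
    HierarchicalState,
    HyperPriorConfig,
    PriorSpec,
    catalog_for_spec,
    genotype_level_symbols,
    individual_level_symbols,
)
from .io import GasExchangeCurve, RunConfig

__all__ = [
    "PosteriorDraws",
    "ConvergenceReport",
    "run_mcmc",
    "psrf_univariate",
    "psrf_multivariate",
]

LOG_2PI = float(np.log(2.0 * np.pi))

_ADAPT_BATCH = 50
_TARGET_ACCEPT = 0.44


@dataclass
class ConvergenceReport:
    """Gelman-Rubin diagnostics for a multi-chain run (threshold 1.2)."""

    psrf_univariate: dict[str, float]
    psrf_multivariate: float
    threshold: float = 1.2

    @property
    def converged(self) -> bool:
        values = [v for v in self.psrf_univariate.values() if np.isfinite(v)]
        values.append(self.psrf_multivariate)
        return max(values) <= self.threshold


@dataclass
class PosteriorDraws:
    """Retained MCMC samples for one (model, genotype) run.

    ``draws`` has shape (chains, retained, parameters); ``deviance_trace``
    is aligned with the draws.  Metadata records the flattened layout:
    genotype means ``mu_<sym>``, genotype-level symbols by name, genotype
    precisions ``tau_<sym>``, individual values ``<sym>[<individual>]`` and
    the process sd ``sigma``.
    """

    parameter_names: list[str]
    draws: np.ndarray
    deviance_trace: np.ndarray
    seed: int
    schedule: tuple[int, int, int, int]  # (burn_in, iterations, thin, chains)
    model_code: str
    genotype_id: str
    individual_ids: list[str]
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if self.draws.shape[:2] != self.deviance_trace.shape:
            raise ValueError("deviance trace misaligned with draws")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter names misaligned with draws")

    @property
    def n_retained_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(
                f"symbol {name!r} not in run ({self.model_code}, {self.genotype_id})"
            ) from None

    def get(self, name: str) -> np.ndarray:
        """All retained draws of one symbol, flattened across chains."""
        return self.draws[:, :, self.index_of(name)].reshape(-1)

    def posterior_mean_state(self) -> HierarchicalState:
        """Componentwise posterior mean over all chains, as a state object."""
        means = self.draws.mean(axis=(0, 1))
        genotype_means: dict[str, float] = {}
        genotype_precisions: dict[str, float] = {}
        individual_values: dict[tuple[str, str], float] = {}
        sigma = None
        for name, value in zip(self.parameter_names, means):
            if name == "sigma":
                sigma = float(value)
            elif name.startswith("mu_"):
                genotype_means[name[3:]] = float(value)
            elif name.startswith("tau_"):
                genotype_precisions[name[4:]] = float(value)
            elif name.endswith("]"):
                sym, ind = name[:-1].split("[", 1)
                individual_values[(ind, sym)] = float(value)
            else:
                genotype_means[name] = float(value)
        return HierarchicalState(
            genotype_means=genotype_means,
            genotype_precisions=genotype_precisions,
            individual_values=individual_values,
            process_sigma=sigma,
        )

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path, convergence: ConvergenceReport | None = None) -> None:
        """Persist as tidy CSV (chain, iteration, symbol, value) + JSON sidecar."""
        prefix = Path(prefix)
        chains, n, p = self.draws.shape
        chain_col = np.repeat(np.arange(chains), n * (p + 1))
        iter_col = np.tile(np.repeat(np.arange(n), p + 1), chains)
        sym_col = np.tile(self.parameter_names + ["deviance"], chains * n)
        stacked = np.concatenate(
            [self.draws, self.deviance_trace[:, :, None]], axis=2
        ).reshape(-1)
        pd.DataFrame(
            {"chain": chain_col, "iteration": iter_col, "symbol": sym_col, "value": stacked}
        ).to_csv(prefix.with_suffix(".csv"), index=False)
        meta = {
            "model_code": self.model_code,
            "genotype_id": self.genotype_id,
            "individual_ids": self.individual_ids,
            "parameter_names": self.parameter_names,
            "seed": self.seed,
            "schedule": {
                "burn_in": self.schedule[0],
                "iterations": self.schedule[1],
                "thin": self.schedule[2],
                "chains": self.schedule[3],
            },
        }
        if convergence is not None:
            meta["convergence"] = {
                "psrf_univariate": convergence.psrf_univariate,
                "psrf_multivariate": convergence.psrf_multivariate,
                "converged": convergence.converged,
            }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str | Path) -> "PosteriorDraws":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        tidy = pd.read_csv(prefix.with_suffix(".csv"))
        names = meta["parameter_names"]
        chains = tidy["chain"].nunique()
        n = tidy["iteration"].nunique()
        wide = tidy.pivot_table(
            index=["chain", "iteration"], columns="symbol", values="value", sort=False
        )
        draws = np.stack(
            [wide[name].to_numpy().reshape(chains, n) for name in names], axis=2
        )
        deviance = wide["deviance"].to_numpy().reshape(chains, n)
        sched = meta["schedule"]
        return cls(
            parameter_names=names,
            draws=draws,
            deviance_trace=deviance,
            seed=meta["seed"],
            schedule=(sched["burn_in"], sched["iterations"], sched["thin"], sched["chains"]),
            model_code=meta["model_code"],
            genotype_id=meta["genotype_id"],
            individual_ids=meta["individual_ids"],
        )


# ---------------------------------------------------------------------------
# Compiled per-genotype problem


class _GenotypeProblem:
    """Precompiled data arrays and prior vectors for one genotype's curves."""

    def __init__(
        self,
        curves: Sequence[GasExchangeCurve],
        spec: ModelSpec,
        hyper: HyperPriorConfig,
        catalog: Sequence[PriorSpec] | None,
        prior_only: bool = False,
    ) -> None:
        self.prior_only = prior_only
        genotypes = {c.genotype_id for c in curves}
        if len(genotypes) != 1:
            raise ValueError(f"curves must all share one genotype, got {sorted(genotypes)}")
        self.genotype_id = curves[0].genotype_id
        self.spec = spec
        self.hyper = hyper
        self.individual_ids = [c.individual_id for c in curves]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids within genotype")
        self.n_ind = len(curves)

        priors = catalog_for_spec(spec, catalog)
        self.ind_syms = [s for s, p in priors.items() if p.level == "individual"]
        self.geno_syms = [s for s, p in priors.items() if p.level == "genotype"]
        self.ind_prior_mean = np.array([priors[s].mean for s in self.ind_syms])
        self.ind_prior_prec = np.array([priors[s].precision for s in self.ind_syms])
        self.geno_prior_mean = np.array([priors[s].mean for s in self.geno_syms])
        self.geno_prior_prec = np.array([priors[s].precision for s in self.geno_syms])

        cols = {k: np.concatenate([c.column(k) for c in curves])
                for k in ("An", "Ca", "Ci", "gs", "T", "Q", "phiPSII", "O")}
        self.an = cols.pop("An")
        self.drivers = cols
        self.n_obs = self.an.size
        if spec.etr_mode == "Jf" and not prior_only and \
                np.any(~np.isfinite(self.drivers["phiPSII"])):
            raise ValueError(
                "fluorescence-derived ETR variants need phiPSII (or Fs/Fm') "
                "for every observation; the dataset has missing values"
            )
        self.ind_index = np.concatenate(
            [np.full(len(c), i, dtype=int) for i, c in enumerate(curves)]
        )
        self.n_obs_per_ind = np.bincount(self.ind_index, minlength=self.n_ind).astype(float)

        # Correlated "ridge" proposal directions for Jm variants.  At a single
        # saturating irradiance only the realized electron transport rate J is
        # identified, leaving (Jmax, phiJ, thetaJ) on a near-flat contour; a
        # fixed symmetric proposal along the local J-contour direction
        # (estimated once at the prior means) lets the chain traverse it.
        self.ridge_moves: list[tuple[int, int, float]] = []
        if spec.etr_mode == "Jm" and not self.prior_only:
            from .fvcb import compute_jm

            q_bar = float(np.mean(self.drivers["Q"]))
            jm0, phi0, th0 = (priors["Jmax25"].mean, priors["phiJ"].mean,
                              priors["thetaJ"].mean)
            h = 1e-4
            g_jmax = (compute_jm(q_bar, jm0 * (1 + h), phi0, th0)
                      - compute_jm(q_bar, jm0, phi0, th0)) / (jm0 * h)
            g_phi = (compute_jm(q_bar, jm0, phi0 + h, th0)
                     - compute_jm(q_bar, jm0, phi0, th0)) / h
            g_th = (compute_jm(q_bar, jm0, phi0, th0 + h)
                    - compute_jm(q_bar, jm0, phi0, th0)) / h
            if g_jmax > 1e-8:
                k_jmax = self.ind_syms.index("Jmax25")
                self.ridge_moves = [
                    (self.ind_syms.index("phiJ"), k_jmax, -g_phi / g_jmax),
                    (self.ind_syms.index("thetaJ"), k_jmax, -g_th / g_jmax),
                ]

    # -- likelihood pieces ---------------------------------------------------

    def sse_per_individual(
        self, ind_params: np.ndarray, geno_params: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Residual sum of squares and validity per individual.

        ``ind_params`` is (n_ind_syms, n_ind); ``geno_params`` is (n_geno_syms,).
        """
        if self.prior_only:
            return np.zeros(self.n_ind), np.ones(self.n_ind, dtype=bool)
        theta = {s: ind_params[k][self.ind_index] for k, s in enumerate(self.ind_syms)}
        theta.update({s: geno_params[k] for k, s in enumerate(self.geno_syms)})
        out = predict_arrays(self.spec, theta, self.drivers)
        resid = self.an - out["Aexp"]
        bad = ~out["valid"] | ~np.isfinite(resid)
        resid = np.where(bad, 0.0, resid)
        sse = np.bincount(self.ind_index, weights=resid * resid, minlength=self.n_ind)
        invalid = np.bincount(self.ind_index, weights=bad.astype(float),
                              minlength=self.n_ind) > 0
        return sse, ~invalid

    def deviance(self, sse_total: float, sigma: float) -> float:
        if self.prior_only:
            return 0.0
        return self.n_obs * (LOG_2PI + 2.0 * np.log(sigma)) + sse_total / sigma ** 2

    def parameter_names(self) -> list[str]:
        names = [f"mu_{s}" for s in self.ind_syms]
        names += list(self.geno_syms)
        names += [f"tau_{s}" for s in self.ind_syms]
        names += [f"{s}[{ind}]" for s in self.ind_syms for ind in self.individual_ids]
        names.append("sigma")
        return names


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    if x < 0:
        return -np.inf
    return float(np.log(2.0) - np.log(np.pi * scale * (1.0 + (x / scale) ** 2)))


def _run_single_chain(
    problem: _GenotypeProblem,
    config: RunConfig,
    chain_seed: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.Generator(np.random.PCG64(chain_seed))
    pr = problem
    n_is, n_ind = len(pr.ind_syms), pr.n_ind
    n_gs = len(pr.geno_syms)
    hyper = pr.hyper

    # -- initialization: jittered prior means, retried until valid ----------
    for attempt in range(50):
        jitter = 0.02 * (1 + attempt / 10)
        mu = pr.ind_prior_mean * (1.0 + jitter * rng.standard_normal(n_is))
        geno = pr.geno_prior_mean * (1.0 + jitter * rng.standard_normal(n_gs))
        ind = np.abs(mu[:, None] * (1.0 + jitter * rng.standard_normal((n_is, n_ind))))
        tau = 1.0 / (0.05 * np.abs(mu) + 0.01) ** 2
        sigma = float(np.exp(0.1 * rng.standard_normal()))
        sse, valid = pr.sse_per_individual(ind, geno)
        if valid.all():
            break
    else:
        raise RuntimeError(
            "could not find a valid initialization after 50 jittered attempts; "
            "check the data and model variant"
        )

    # adaptive step sizes (log scale)
    step_ind = np.log(np.maximum(0.02 * np.abs(pr.ind_prior_mean), 1e-3))[:, None] * np.ones(
        (1, n_ind)
    )
    step_geno = np.log(np.maximum(0.02 * np.abs(pr.geno_prior_mean), 1e-3))
    step_sigma = np.log(0.3)
    acc_ind = np.zeros((n_is, n_ind))
    acc_geno = np.zeros(n_gs)
    acc_sigma = 0.0
    n_ridge = len(pr.ridge_moves)
    step_ridge = np.full((n_ridge, n_ind), np.log(0.05))
    acc_ridge = np.zeros((n_ridge, n_ind))

    n_retained = config.iterations // config.thin
    n_params = n_is * 2 + n_gs + n_is * n_ind + 1
    draws = np.empty((n_retained, n_params))
    deviance = np.empty(n_retained)
    retained = 0

    a0, b0 = hyper.precision_gamma_shape, hyper.precision_gamma_rate
    hc_scale = hyper.process_sigma_half_cauchy_scale
    total_iters = config.burn_in + config.iterations

    for it in range(total_iters):
        in_burn = it < config.burn_in
        tau_obs = sigma ** -2

        # (1) individual values: vectorized per-symbol sweep, per-individual MH
        for k in range(n_is):
            proposal = ind.copy()
            proposal[k] = ind[k] + np.exp(step_ind[k]) * rng.standard_normal(n_ind)
            sse_prop, valid_prop = pr.sse_per_individual(proposal, geno)
            d_lik = -0.5 * tau_obs * (sse_prop - sse)
            d_pri = -0.5 * tau[k] * (
                (proposal[k] - mu[k]) ** 2 - (ind[k] - mu[k]) ** 2
            )
            log_alpha = np.where(valid_prop, d_lik + d_pri, -np.inf)
            accept = np.log(rng.random(n_ind)) < log_alpha
            ind[k, accept] = proposal[k, accept]
            sse[accept] = sse_prop[accept]
            acc_ind[k] += accept

        # (1b) ridge moves: joint symmetric proposals along the flat
        # direction of the ETR light response (Jm variants only)
        for r, (k_a, k_b, slope) in enumerate(pr.ridge_moves):
            eps = np.exp(step_ridge[r]) * rng.standard_normal(n_ind)
            proposal = ind.copy()
            proposal[k_a] = ind[k_a] + eps
            proposal[k_b] = ind[k_b] + slope * eps
            sse_prop, valid_prop = pr.sse_per_individual(proposal, geno)
            d_lik = -0.5 * tau_obs * (sse_prop - sse)
            d_pri = -0.5 * tau[k_a] * (
                (proposal[k_a] - mu[k_a]) ** 2 - (ind[k_a] - mu[k_a]) ** 2
            ) - 0.5 * tau[k_b] * (
                (proposal[k_b] - mu[k_b]) ** 2 - (ind[k_b] - mu[k_b]) ** 2
            )
            log_alpha = np.where(valid_prop, d_lik + d_pri, -np.inf)
            accept = np.log(rng.random(n_ind)) < log_alpha
            ind[k_a, accept] = proposal[k_a, accept]
            ind[k_b, accept] = proposal[k_b, accept]
            sse[accept] = sse_prop[accept]
            acc_ridge[r] += accept

        # (2) genotype-level kinetic symbols: scalar MH each
        for k in range(n_gs):
            prop_val = geno[k] + np.exp(step_geno[k]) * rng.standard_normal()
            proposal = geno.copy()
            proposal[k] = prop_val
            sse_prop, valid_prop = pr.sse_per_individual(ind, proposal)
            if valid_prop.all():
                d_lik = -0.5 * tau_obs * (sse_prop.sum() - sse.sum())
                d_pri = -0.5 * pr.geno_prior_prec[k] * (
                    (prop_val - pr.geno_prior_mean[k]) ** 2
                    - (geno[k] - pr.geno_prior_mean[k]) ** 2
                )
                if np.log(rng.random()) < d_lik + d_pri:
                    geno[k] = prop_val
                    sse = sse_prop
                    acc_geno[k] += 1

        # (3) process sd: MH on log sigma (with Jacobian), O(1) via cached SSE
        sse_total = float(sse.sum())
        log_sigma_prop = np.log(sigma) + np.exp(step_sigma) * rng.standard_normal()
        sigma_prop = float(np.exp(log_sigma_prop))
        d = (
            -0.5 * pr.deviance(sse_total, sigma_prop)
            + 0.5 * pr.deviance(sse_total, sigma)
            + _half_cauchy_logpdf(sigma_prop, hc_scale)
            - _half_cauchy_logpdf(sigma, hc_scale)
            + (log_sigma_prop - np.log(sigma))
        )
        if np.log(rng.random()) < d:
            sigma = sigma_prop
            acc_sigma += 1

        # (4) conjugate Gibbs: genotype means and precisions of nested symbols
        sum_ind = ind.sum(axis=1)
        post_prec = pr.ind_prior_prec + n_ind * tau
        post_mean = (pr.ind_prior_prec * pr.ind_prior_mean + tau * sum_ind) / post_prec
        mu = post_mean + rng.standard_normal(n_is) / np.sqrt(post_prec)
        sq = ((ind - mu[:, None]) ** 2).sum(axis=1)
        tau = rng.gamma(shape=a0 + 0.5 * n_ind, scale=1.0 / (b0 + 0.5 * sq))

        # -- adaptation (burn-in only) --------------------------------------
        if in_burn and (it + 1) % _ADAPT_BATCH == 0:
            delta = min(0.1, ((it + 1) / _ADAPT_BATCH) ** -0.5)
            step_ind += np.where(acc_ind / _ADAPT_BATCH > _TARGET_ACCEPT, delta, -delta)
            step_geno += np.where(acc_geno / _ADAPT_BATCH > _TARGET_ACCEPT, delta, -delta)
            step_sigma += delta if acc_sigma / _ADAPT_BATCH > _TARGET_ACCEPT else -delta
            if n_ridge:
                step_ridge += np.where(acc_ridge / _ADAPT_BATCH > _TARGET_ACCEPT,
                                       delta, -delta)
                acc_ridge[:] = 0.0
            acc_ind[:] = 0.0
            acc_geno[:] = 0.0
            acc_sigma = 0.0

        # -- retention ------------------------------------------------------
        if not in_burn and (it - config.burn_in + 1) % config.thin == 0:
            vec = np.concatenate([mu, geno, tau, ind.reshape(-1), [sigma]])
            draws[retained] = vec
            deviance[retained] = pr.deviance(float(sse.sum()), sigma)
            retained += 1

    assert retained == n_retained
    if not np.all(np.isfinite(draws)):
        raise RuntimeError("non-finite value in retained draws; inspect the run")
    # sampling-phase acceptance rates (counters are reset at the last
    # burn-in adaptation batch, so these reflect the frozen kernel)
    rates = {
        "individual": acc_ind / config.iterations,
        "genotype": acc_geno / config.iterations,
        "sigma": acc_sigma / config.iterations,
    }
    if n_ridge:
        rates["ridge"] = acc_ridge / config.iterations
    return draws, deviance, rates


def run_mcmc(
    curves: Sequence[GasExchangeCurve],
    spec: ModelSpec,
    config: RunConfig,
    hyper: HyperPriorConfig = HyperPriorConfig(),
    catalog: Sequence[PriorSpec] | None = None,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior for one genotype under one model variant.

    Runs ``config.chains`` independent chains from jittered prior-mean
    initializations; retains every ``thin``-th post-burn-in state and its
    deviance.  Bit-reproducible given ``config.seed`` (per-chain seeds are
    derived from the master seed by fixed splitting).  ``prior_only``
    disables the likelihood (zero-observation run), turning the sampler
    into a draw from the hierarchical prior — the basis of the
    prior-recovery check.
    """
    problem = _GenotypeProblem(curves, spec, hyper, catalog, prior_only=prior_only)
    chain_draws, chain_dev, chain_rates = [], [], []
    for chain in range(config.chains):
        seed_seq = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(chain,))
        d, dev, rates = _run_single_chain(problem, config, seed_seq)
        chain_draws.append(d)
        chain_dev.append(dev)
        chain_rates.append(rates)
    accept_rates = {
        key: np.mean([r[key] for r in chain_rates], axis=0)
        for key in chain_rates[0]
    }
    return PosteriorDraws(
        parameter_names=problem.parameter_names(),
        draws=np.stack(chain_draws),
        deviance_trace=np.stack(chain_dev),
        seed=config.seed,
        schedule=(config.burn_in, config.iterations, config.thin, config.chains),
        model_code=spec.code,
        genotype_id=problem.genotype_id,
        individual_ids=list(problem.individual_ids),
        diagnostics={"accept_rates": accept_rates},
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics


def psrf_univariate(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one symbol.

    ``chains`` has shape (m, n): m >= 2 chains of n >= 10 retained draws.
    With within-chain variance W and between-chain variance B,
    ``Vhat = (n-1)/n W + B/n`` and ``Rhat = sqrt(Vhat / W)``.  Returns NaN
    when W = 0 (all draws identical within every chain).
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 10:
        raise ValueError("need at least 2 chains of 10 draws")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return float("nan")
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def psrf_multivariate(draws: np.ndarray, ridge: float = 1e-10) -> float:
    """Brooks-Gelman multivariate PSRF over all symbols of a run.

    ``draws`` has shape (m, n, p).  ``RhatM = (n-1)/n + (m+1)/m * lambda1``
    where lambda1 is the largest eigenvalue of ``W^{-1} B/n``.  Symbols with
    zero total variance are dropped; a ridge is added if W is singular.
    """
    draws = np.asarray(draws, dtype=float)
    m, n, p = draws.shape
    if m < 2 or n < 10:
        raise ValueError("need at least 2 chains of 10 draws")
    keep = draws.reshape(-1, p).var(axis=0) > 0
    if not keep.any():
        return (n - 1) / n
    x = draws[:, :, keep]
    p = x.shape[2]
    chain_means = x.mean(axis=1)
    w = np.zeros((p, p))
    for c in range(m):
        d = x[c] - chain_means[c]
        w += d.T @ d / (n - 1)
    w /= m
    b_over_n = np.cov(chain_means.T, ddof=1).reshape(p, p)
    try:
        solved = np.linalg.solve(w, b_over_n)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular within-chain covariance; ridge-regularized",
                      stacklevel=2)
        solved = np.linalg.solve(w + ridge * np.eye(p), b_over_n)
    lam1 = float(np.max(np.linalg.eigvals(solved).real))
    return float((n - 1) / n + (m + 1) / m * lam1)


def convergence_report(draws: PosteriorDraws, threshold: float = 1.2) -> ConvergenceReport:
    """Univariate PSRF per symbol plus the multivariate PSRF of the run."""
    uni = {
        name: psrf_univariate(draws.draws[:, :, j])
        for j, name in enumerate(draws.parameter_names)
    }
    multi = psrf_multivariate(draws.draws)
    return ConvergenceReport(psrf_univariate=uni, psrf_multivariate=multi,
                             threshold=threshold)
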