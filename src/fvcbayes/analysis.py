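"""Posterior analysis: predictive checks, HDIs, and the genotype trait screen.

The trait-variance screen works on differences of genotype-level posterior
mean distributions: for each trait and genotype pair, the difference sample
is graded by the largest highest-density-interval (HDI) mass — over the
eight standard levels 50..99% — whose interval excludes zero.  Credible
intervals for assimilation predictions use central quantiles; HDIs are
reserved for the differencing test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .fvcb import ModelSpec, predict_arrays
from .io import DEFAULT_HDI_LEVELS
from .mcmc import PosteriorDraws

__all__ = [
    "HDInterval",
    "TraitVarianceResult",
    "hdi",
    "max_hdi_level_excluding_zero",
    "genotype_difference_distribution",
    "summarize_posterior",
    "posterior_predictive_interval",
    "pooled_accession_prediction",
    "residual_summary",
]


@dataclass(frozen=True)
class HDInterval:
    """Shortest interval containing ``mass`` of a sample."""

    mass: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def excludes(self, value: float) -> bool:
        return not (self.lower <= value <= self.upper)


def hdi(samples: np.ndarray, mass: float) -> HDInterval:
    """Highest-density interval of a sample.

    The shortest contiguous window over the sorted sample containing
    ``ceil(mass * n)`` points.  Requires at least 100 samples for a stable
    estimate.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HDI, got {n}")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly inside (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return HDInterval(mass=mass, lower=float(x[j]), upper=float(x[j + k - 1]))


@dataclass(frozen=True)
class TraitVarianceResult:
    """Outcome of the HDI differencing test for one trait and genotype pair."""

    symbol: str
    genotype_pair: tuple[str, str]
    max_hdi_level: float | None  # None: zero inside the HDI at every level
    levels: tuple[float, ...] = DEFAULT_HDI_LEVELS


def max_hdi_level_excluding_zero(
    differences: np.ndarray,
    levels: Sequence[float] = DEFAULT_HDI_LEVELS,
    symbol: str = "",
    genotype_pair: tuple[str, str] = ("A", "B"),
) -> TraitVarianceResult:
    """Largest HDI mass whose interval excludes zero, or None.

    For a unimodal difference sample the exclusion set is monotone in the
    level (if the 95% HDI excludes zero so does the 50%); violations — which
    can only arise from multimodality or sampling noise — are reported with
    a warning and resolved conservatively in favour of the largest
    consistent level.
    """
    levels = tuple(sorted(levels))
    excluded = [hdi(differences, lvl).excludes(0.0) for lvl in levels]
    best = None
    for lvl, out in zip(levels, excluded):
        if out:
            best = lvl
    if best is not None:
        # monotonicity check: all levels below the best should also exclude
        below = [lvl for lvl, out in zip(levels, excluded) if lvl < best and not out]
        if below:
            warnings.warn(
                f"non-monotone HDI exclusion for {symbol or 'trait'} at levels "
                f"{below}; sample may be multimodal",
                stacklevel=2,
            )
            best = max(
                (lvl for lvl, out in zip(levels, excluded)
                 if out and all(o for l2, o in zip(levels, excluded) if l2 < lvl)),
                default=None,
            )
    return TraitVarianceResult(symbol=symbol, genotype_pair=genotype_pair,
                               max_hdi_level=best, levels=levels)


def genotype_difference_distribution(
    draws_a: PosteriorDraws,
    draws_b: PosteriorDraws,
    symbol: str,
    seed: int = 0,
    permute: bool = True,
) -> np.ndarray:
    """Difference sample of a genotype-level trait between two runs.

    The runs are independent, so pairing is arbitrary: both draw vectors
    are shuffled with a seeded generator and differenced elementwise
    (statistically equivalent to sampling the convolution).  ``symbol``
    must name a genotype-level quantity (``mu_<trait>`` or a genotype-level
    trait) present in both runs.  ``permute=False`` keeps the retained
    order (identity pairing).
    """
    if draws_a.model_code != draws_b.model_code:
        raise ValueError(
            f"runs use different model variants: {draws_a.model_code} vs "
            f"{draws_b.model_code}"
        )
    a = draws_a.get(symbol)
    b = draws_b.get(symbol)
    n = min(a.size, b.size)
    if permute:
        rng = np.random.default_rng(seed)
        a = rng.permutation(a)
        b = rng.permutation(b)
    return a[:n] - b[:n]


def summarize_posterior(
    draws: PosteriorDraws, symbols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Boxplot statistics (median, quartiles, min, max) per symbol.

    Quartiles use the linear-interpolation convention of NumPy's default
    quantile method.
    """
    symbols = list(draws.parameter_names) if symbols is None else list(symbols)
    rows = []
    for sym in symbols:
        x = draws.get(sym)
        q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
        rows.append(
            {"symbol": sym, "median": q50, "q25": q25, "q75": q75,
             "min": float(np.min(x)), "max": float(np.max(x))}
        )
    return pd.DataFrame(rows).set_index("symbol")


# ---------------------------------------------------------------------------
# Posterior predictive intervals


def _draw_matrix(draws: PosteriorDraws, spec: ModelSpec, scope: str,
                 individual_id: str | None) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-draw structural parameter columns and the sigma vector."""
    from .fvcb import enumerate_structural_parameters

    theta = {}
    for sym in enumerate_structural_parameters(spec):
        if scope == "genotype":
            name = f"mu_{sym}" if f"mu_{sym}" in draws.parameter_names else sym
        else:
            if individual_id is None:
                raise ValueError("individual scope needs an individual_id")
            name = (f"{sym}[{individual_id}]"
                    if f"{sym}[{individual_id}]" in draws.parameter_names else sym)
        theta[sym] = draws.get(name)
    return theta, draws.get("sigma")


def posterior_predictive_interval(
    draws: PosteriorDraws,
    spec: ModelSpec,
    grid: Mapping[str, np.ndarray],
    level: float = 0.95,
    scope: str = "genotype",
    individual_id: str | None = None,
    include_observation_noise: bool = False,
    seed: int = 0,
    max_draws: int = 2000,
) -> pd.DataFrame:
    """Central credible interval of predicted assimilation over a driver grid.

    ``grid`` maps driver names (Ci or Ca+gs, O, Q, phiPSII, T as the variant
    demands) to equal-length arrays.  Each retained draw predicts the grid;
    the interval is the central (1-level)/2 quantile band; optionally a
    Normal(0, sigma_draw) observation error is added per draw.  At most
    ``max_draws`` draws are used (evenly subsampled) to bound memory.
    """
    theta, sigma = _draw_matrix(draws, spec, scope, individual_id)
    n_draws = sigma.size
    if n_draws > max_draws:
        idx = np.linspace(0, n_draws - 1, max_draws).astype(int)
        theta = {k: v[idx] for k, v in theta.items()}
        sigma = sigma[idx]
        n_draws = max_draws

    grid_arrays = {k: np.asarray(v, dtype=float)[None, :] for k, v in grid.items()}
    theta_cols = {k: v[:, None] for k, v in theta.items()}
    out = predict_arrays(spec, theta_cols, grid_arrays)
    pred = out["Aexp"]
    invalid = ~out["valid"]
    frac_bad = float(invalid.mean())
    if frac_bad > 0.01:
        warnings.warn(
            f"{int(invalid.sum())} invalid predictions "
            f"({100 * frac_bad:.1f}% of draws x gridpoints)",
            stacklevel=2,
        )
    if include_observation_noise:
        rng = np.random.default_rng(seed)
        pred = pred + rng.standard_normal(pred.shape) * sigma[:, None]
    lo, hi = np.nanquantile(pred, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    mean = np.nanmean(pred, axis=0)
    frame = {k: np.asarray(v, dtype=float) for k, v in grid.items()}
    frame.update({"mean": mean, "lower": lo, "upper": hi, "level": level})
    return pd.DataFrame(frame)


def pooled_accession_prediction(
    runs: Sequence[PosteriorDraws],
    spec: ModelSpec,
    grid: Mapping[str, np.ndarray],
    level: float = 0.95,
    include_observation_noise: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictive interval from pooled genotype-level posteriors.

    Concatenates an equal count of retained draws from each run (the
    minimum across runs) and computes the genotype-scope interval of the
    mixture — the machinery behind species-level parameterization checks.
    """
    if len(runs) < 1:
        raise ValueError("need at least one run")
    codes = {r.model_code for r in runs}
    if codes != {spec.code}:
        raise ValueError(f"all runs must use {spec.code}, got {sorted(codes)}")
    from .fvcb import enumerate_structural_parameters

    n = min(r.get("sigma").size for r in runs)
    theta = {}
    for sym in enumerate_structural_parameters(spec):
        cols = []
        for r in runs:
            name = f"mu_{sym}" if f"mu_{sym}" in r.parameter_names else sym
            cols.append(r.get(name)[:n])
        theta[sym] = np.concatenate(cols)
    sigma = np.concatenate([r.get("sigma")[:n] for r in runs])

    grid_arrays = {k: np.asarray(v, dtype=float)[None, :] for k, v in grid.items()}
    theta_cols = {k: v[:, None] for k, v in theta.items()}
    out = predict_arrays(spec, theta_cols, grid_arrays)
    pred = out["Aexp"]
    if include_observation_noise:
        rng = np.random.default_rng(seed)
        pred = pred + rng.standard_normal(pred.shape) * sigma[:, None]
    lo, hi = np.nanquantile(pred, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    frame = {k: np.asarray(v, dtype=float) for k, v in grid.items()}
    frame.update({"mean": np.nanmean(pred, axis=0), "lower": lo, "upper": hi,
                  "level": level})
    return pd.DataFrame(frame)


def residual_summary(
    draws: PosteriorDraws, curves, spec: ModelSpec
) -> dict[str, float]:
    """RMSE and standard error of residuals at the posterior-mean state.

    Both are reported because 'standard error of the expected assimilation'
    admits more than one reading; neither is privileged.
    """
    state = draws.posterior_mean_state()
    residuals = []
    for curve in curves:
        theta = state.theta_for_individual(spec, curve.individual_id)
        out = predict_arrays(spec, theta, curve.drivers())
        residuals.append(curve.column("An") - out["Aexp"])
    r = np.concatenate(residuals)
    return {
        "rmse": float(np.sqrt(np.mean(r ** 2))),
        "residual_se": float(np.std(r, ddof=1) / np.sqrt(r.size)),
        "residual_sd": float(np.std(r, ddof=1)),
    }
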