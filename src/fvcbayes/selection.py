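"""DIC scoring and per-genotype multimodel ranking.

DIC combines fit and complexity: with the deviance D(theta) = -2 log
p(Y|theta) monitored along the chain, the effective number of parameters
is ``pD = Dbar - D(theta_bar)`` (posterior mean deviance minus deviance at
the componentwise posterior mean), and ``DIC = D(theta_bar) + 2 pD =
Dbar + pD`` (Spiegelhalter definition).  Within a genotype, models are
ranked by ``dDIC = DIC - min DIC``; models within the top-tier threshold
(10 by convention) are treated as equally supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fvcb import ModelSpec
from .hierarchy import log_likelihood
from .io import GasExchangeCurve
from .mcmc import PosteriorDraws

__all__ = ["DICScore", "DeltaDICTable", "dic_from_deviance", "compute_dic", "delta_dic"]


@dataclass(frozen=True)
class DICScore:
    """DIC decomposition for one (model, genotype) run."""

    mean_deviance: float  # Dbar
    deviance_at_mean: float  # D(theta_bar)
    pD: float
    DIC: float


def dic_from_deviance(deviance_trace: np.ndarray, deviance_at_mean: float) -> DICScore:
    """Assemble a DIC score from a monitored deviance trace and the deviance
    evaluated at the componentwise posterior mean."""
    mean_dev = float(np.mean(deviance_trace))
    p_d = mean_dev - float(deviance_at_mean)
    return DICScore(
        mean_deviance=mean_dev,
        deviance_at_mean=float(deviance_at_mean),
        pD=p_d,
        DIC=float(deviance_at_mean) + 2.0 * p_d,
    )


def compute_dic(
    draws: PosteriorDraws,
    curves: Sequence[GasExchangeCurve],
    spec: ModelSpec,
) -> DICScore:
    """DIC for a completed run, re-evaluating the deviance at the posterior mean."""
    if spec.code != draws.model_code:
        raise ValueError(f"draws are for {draws.model_code}, not {spec.code}")
    state = draws.posterior_mean_state()
    ll = log_likelihood(state, curves, spec)
    if not np.isfinite(ll):
        raise ValueError(
            "deviance at the posterior mean is not finite; the posterior mean "
            "state is inadmissible — inspect chain convergence before scoring"
        )
    return dic_from_deviance(draws.deviance_trace, -2.0 * ll)


@dataclass
class DeltaDICTable:
    """Per-genotype dDIC ranking: genotype -> model code -> row."""

    rows: dict[str, dict[str, dict[str, float | bool]]]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        records = []
        for geno, models in self.rows.items():
            for code, row in models.items():
                records.append({"genotype": geno, "model": code, **row})
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"threshold": self.threshold, "rows": self.rows}, fh, indent=1)

    def top_tier(self, genotype: str) -> list[str]:
        return [m for m, row in self.rows[genotype].items() if row["top_tier"]]


def delta_dic(
    scores: Mapping[tuple[str, str], DICScore],
    threshold: float = 10.0,
) -> DeltaDICTable:
    """dDIC table from per-(genotype, model) scores.

    ``scores`` maps (genotype, model_code) to a :class:`DICScore`.  Within
    each genotype, dDIC = DIC - min DIC; ties on the minimum all get 0; the
    top tier is dDIC < threshold.
    """
    by_geno: dict[str, dict[str, DICScore]] = {}
    for (geno, code), score in scores.items():
        by_geno.setdefault(geno, {})[code] = score
    rows: dict[str, dict[str, dict[str, float | bool]]] = {}
    for geno, models in by_geno.items():
        best = min(s.DIC for s in models.values())
        rows[geno] = {
            code: {
                "DIC": s.DIC,
                "pD": s.pD,
                "delta_DIC": s.DIC - best,
                "top_tier": bool(s.DIC - best < threshold),
            }
            for code, s in models.items()
        }
    return DeltaDICTable(rows=rows, threshold=threshold)
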