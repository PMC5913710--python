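"""Gas-exchange data model, CSV input/output, and run configuration.

The internal unit convention is: all partial pressures (Ca, Ci, O, and the
kinetic constants) in Pa, conductances in umol m-2 s-1 Pa-1, rates in
umol m-2 s-1, temperatures in C.  Instrument files (Li-6400 style) report
CO2 as mole fractions (umol mol-1), stomatal conductance to water vapour
in mol m-2 s-1 and pressure in kPa; a column *dialect* describes how to map
and convert such files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
import yaml

from .constants import H2O_CO2_DIFFUSIVITY_RATIO, O2_FRACTION

__all__ = [
    "GasExchangeObservation",
    "GasExchangeCurve",
    "RunConfig",
    "ColumnDialect",
    "LI6400_DIALECT",
    "CANONICAL_DIALECT",
    "ppm_to_pa",
    "gs_water_to_co2_pressure",
    "read_curves",
    "write_curves",
    "n_parameterizations",
]

#: The eight HDI masses used by the genotype trait-differencing screen.
DEFAULT_HDI_LEVELS = (0.50, 0.60, 0.70, 0.80, 0.85, 0.90, 0.95, 0.99)


def ppm_to_pa(x, P):
    """CO2 mole fraction (umol mol-1) to partial pressure (Pa) at pressure P (Pa)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("mole fraction must be non-negative")
    if np.any(np.asarray(P, dtype=float) <= 0):
        raise ValueError("pressure must be positive")
    return x * 1e-6 * P


def gs_water_to_co2_pressure(gsw, P):
    """Stomatal conductance to H2O (mol m-2 s-1) to conductance to CO2 on a
    pressure basis (umol m-2 s-1 Pa-1): divide by the 1.6 diffusivity ratio,
    scale mol to umol, and convert the mole-fraction basis to pressure via P (Pa)."""
    gsw = np.asarray(gsw, dtype=float)
    if np.any(gsw < 0):
        raise ValueError("conductance must be non-negative")
    if np.any(np.asarray(P, dtype=float) <= 0):
        raise ValueError("pressure must be positive")
    return gsw / H2O_CO2_DIFFUSIVITY_RATIO * 1e6 / P


@dataclass(frozen=True)
class GasExchangeObservation:
    """One steady-state gas-exchange + fluorescence observation (internal units)."""

    An: float  # net CO2 assimilation, umol m-2 s-1
    Ca: float  # ambient CO2 partial pressure, Pa
    Ci: float  # intercellular CO2 partial pressure, Pa
    gs: float  # stomatal conductance to CO2, umol m-2 s-1 Pa-1
    T: float  # leaf temperature, C
    P: float  # air pressure, Pa
    Q: float  # photon flux, umol m-2 s-1
    phiPSII: float  # effective PSII quantum yield, e- photon-1
    O: float  # O2 partial pressure, Pa

    def __post_init__(self) -> None:
        if self.P <= 0 or self.Ca <= 0 or self.Ci <= 0 or self.O <= 0:
            raise ValueError("pressures must be strictly positive")
        # NaN marks absent fluorescence; tolerated until a Jf-variant fit
        if not np.isnan(self.phiPSII) and not (0.0 <= self.phiPSII <= 1.0):
            raise ValueError(f"phiPSII must be in [0, 1], got {self.phiPSII}")
        if self.Ci > self.Ca * (1 + 1e-9):
            raise ValueError(f"Ci ({self.Ci}) must not exceed Ca ({self.Ca})")


@dataclass
class GasExchangeCurve:
    """One leaf's A/Ci curve: ordered observations with genotype/individual labels."""

    genotype_id: str
    individual_id: str
    observations: list[GasExchangeObservation]

    def __post_init__(self) -> None:
        if len(self.observations) < 3:
            raise ValueError(
                "a curve needs at least 3 observations to separate the "
                "RuBisCO- and RuBP-limited regions"
            )

    def __len__(self) -> int:
        return len(self.observations)

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(o, name) for o in self.observations], dtype=float)

    def drivers(self) -> dict[str, np.ndarray]:
        """Driver arrays for the forward model."""
        return {k: self.column(k) for k in ("Ca", "Ci", "gs", "T", "P", "Q", "phiPSII", "O")}


@dataclass
class RunConfig:
    """MCMC schedule and screening configuration.

    The ``paper`` preset is the full published schedule (4 chains, 250,000
    iterations after a 200,000 burn-in, thinned by 20, i.e. 50,000 retained
    draws per model x genotype); ``desk`` is a laptop-scale default.
    """

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    dic_top_tier_threshold: float = 10.0
    hdi_levels: tuple[float, ...] = DEFAULT_HDI_LEVELS
    models: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if any(not (0.0 < lvl < 1.0) for lvl in self.hdi_levels):
            raise ValueError("hdi_levels must lie strictly inside (0, 1)")

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin

    @property
    def retained_total(self) -> int:
        return self.chains * self.retained_per_chain

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        presets = {
            "desk": dict(chains=4, iterations=5000, burn_in=5000, thin=5),
            "paper": dict(chains=4, iterations=250_000, burn_in=200_000, thin=20),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        kwargs = presets[name] | overrides
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hdi_levels" in raw:
            raw["hdi_levels"] = tuple(raw["hdi_levels"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "chains": self.chains,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
            "dic_top_tier_threshold": self.dic_top_tier_threshold,
            "hdi_levels": list(self.hdi_levels),
            "models": list(self.models),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Column dialects


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from file columns to internal quantities, with unit handling.

    ``columns`` maps internal names to file column names.  Unit flags say
    how the file reports quantities; the reader converts everything to the
    internal convention.
    """

    columns: dict[str, str]
    co2_in_ppm: bool = True  # Ca/Ci as mole fractions, converted via pressure
    pressure_in_kpa: bool = True
    gs_is_water_molar: bool = True  # Cond column: mol H2O m-2 s-1

    def get(self, key: str) -> str | None:
        return self.columns.get(key)


#: Default Li-6400 style dialect.
LI6400_DIALECT = ColumnDialect(
    columns={
        "genotype": "genotype",
        "individual": "individual",
        "An": "Photo",
        "Ca": "CO2S",
        "Ci": "Ci",
        "gs": "Cond",
        "T": "Tleaf",
        "P": "Press",
        "Q": "PARi",
        "phiPSII": "PhiPS2",
        "Fs": "Fs",
        "Fm_prime": "Fm'",
    },
)

#: Dialect for files already in internal units (what ``write_curves`` emits).
CANONICAL_DIALECT = ColumnDialect(
    columns={
        "genotype": "genotype",
        "individual": "individual",
        "An": "An",
        "Ca": "Ca_Pa",
        "Ci": "Ci_Pa",
        "gs": "gs",
        "T": "Tleaf_C",
        "P": "P_Pa",
        "Q": "Q",
        "phiPSII": "phiPSII",
        "O": "O_Pa",
    },
    co2_in_ppm=False,
    pressure_in_kpa=False,
    gs_is_water_molar=False,
)

_REQUIRED = ("genotype", "individual", "An", "Ca", "Ci", "gs", "T", "P", "Q")


def read_curves(
    path: str | Path,
    dialect: ColumnDialect = LI6400_DIALECT,
    pressure_pa: float | None = None,
) -> list[GasExchangeCurve]:
    """Read gas-exchange curves from a CSV file.

    One row per steady-state observation; rows are grouped by
    (genotype, individual) preserving file order within each curve.  phiPSII
    is taken from its column when present, otherwise computed as
    (Fm' - Fs)/Fm' from the fluorescence columns; with neither it is left
    missing (fitting a fluorescence-ETR variant then fails, at fit time).
    O2 partial pressure defaults to 0.21 * P unless an O column is mapped
    and present.  ``pressure_pa`` supplies a configured constant pressure
    when the file has no pressure column.
    """
    df = pd.read_csv(path, comment="#")

    for key in _REQUIRED:
        if key == "P" and pressure_pa is not None:
            continue
        col = dialect.get(key)
        if col is None or col not in df.columns:
            raise KeyError(
                f"required column for {key!r} "
                f"({col or 'unmapped'}) missing from {path}"
            )

    def numeric(col: str) -> np.ndarray:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row(s) "
                f"{list(df.index[bad][:5])}"
            )
        return series.to_numpy(dtype=float)

    p_col = dialect.get("P")
    if p_col is not None and p_col in df.columns:
        p_raw = numeric(p_col)
        p_pa = p_raw * 1000.0 if dialect.pressure_in_kpa else p_raw
    else:
        p_pa = np.full(len(df), float(pressure_pa))

    ca_raw = numeric(dialect.get("Ca"))
    ci_raw = numeric(dialect.get("Ci"))
    if dialect.co2_in_ppm:
        ca = ppm_to_pa(ca_raw, p_pa)
        ci = ppm_to_pa(ci_raw, p_pa)
    else:
        ca, ci = ca_raw, ci_raw

    gs_raw = numeric(dialect.get("gs"))
    gs = gs_water_to_co2_pressure(gs_raw, p_pa) if dialect.gs_is_water_molar else gs_raw

    phi_col = dialect.get("phiPSII")
    if phi_col is not None and phi_col in df.columns:
        phi = numeric(phi_col)
    else:
        fs_col, fm_col = dialect.get("Fs"), dialect.get("Fm_prime")
        if fs_col in df.columns and fm_col in df.columns:
            fs, fm = numeric(fs_col), numeric(fm_col)
            phi = (fm - fs) / fm
        else:
            # no fluorescence: tolerated here, rejected when fitting Jf
            phi = np.full(len(df), np.nan)

    o_col = dialect.get("O")
    if o_col is not None and o_col in df.columns:
        o_pa = numeric(o_col)
    else:
        o_pa = O2_FRACTION * p_pa

    an = numeric(dialect.get("An"))
    t_leaf = numeric(dialect.get("T"))
    q = numeric(dialect.get("Q"))
    genotype = df[dialect.get("genotype")].astype(str)
    individual = df[dialect.get("individual")].astype(str)

    # duplicate setpoints (same genotype, individual and Ca) are kept with a warning
    dup = df.duplicated(subset=[dialect.get("genotype"), dialect.get("individual"),
                                dialect.get("Ca")], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (genotype, individual, CO2 setpoint) "
            "rows found; keeping all",
            stacklevel=2,
        )

    curves: list[GasExchangeCurve] = []
    seen: dict[tuple[str, str], list[int]] = {}
    for idx, key in enumerate(zip(genotype, individual)):
        seen.setdefault(key, []).append(idx)
    for (geno, ind), rows in seen.items():
        obs = [
            GasExchangeObservation(
                An=float(an[i]), Ca=float(ca[i]), Ci=float(min(ci[i], ca[i])),
                gs=float(gs[i]), T=float(t_leaf[i]), P=float(p_pa[i]),
                Q=float(q[i]), phiPSII=float(phi[i]), O=float(o_pa[i]),
            )
            for i in rows
        ]
        curves.append(GasExchangeCurve(genotype_id=geno, individual_id=ind, observations=obs))
    return curves


_CANONICAL_HEADER = (
    "# fvcbayes canonical gas-exchange export: An (umol m-2 s-1), Ca_Pa/Ci_Pa/"
    "O_Pa/P_Pa (Pa), gs (umol m-2 s-1 Pa-1, CO2 pressure basis), Tleaf_C (C), "
    "Q (umol m-2 s-1), phiPSII (unitless)"
)


def write_curves(curves: Iterable[GasExchangeCurve], path: str | Path) -> None:
    """Write curves as canonical CSV (internal units, documented header comment)."""
    rows = []
    for curve in curves:
        for o in curve.observations:
            rows.append(
                dict(
                    genotype=curve.genotype_id,
                    individual=curve.individual_id,
                    An=o.An, Ca_Pa=o.Ca, Ci_Pa=o.Ci, gs=o.gs,
                    Tleaf_C=o.T, P_Pa=o.P, Q=o.Q, phiPSII=o.phiPSII, O_Pa=o.O,
                )
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_CANONICAL_HEADER + "\n")
        df.to_csv(fh, index=False)


def group_by_genotype(curves: Sequence[GasExchangeCurve]) -> dict[str, list[GasExchangeCurve]]:
    """Curves grouped by genotype, preserving order of first appearance."""
    out: dict[str, list[GasExchangeCurve]] = {}
    for c in curves:
        out.setdefault(c.genotype_id, []).append(c)
    return out


def n_parameterizations(curves: Sequence[GasExchangeCurve], models: Sequence[str]) -> int:
    """Study-design bookkeeping: number of unique individual-level
    parameterizations implied by fitting every model to every curve."""
    return len(models) * len(curves)
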