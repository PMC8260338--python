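"""Synthetic biomarker cohorts with the statistical structure of the study population.

Marker marginals per diagnosis group are log-normal, parameterized so the
distribution's median and interquartile range reproduce the printed group
statistics exactly: mu = ln(median), sigma = ln(q3/q1) / (2 z_0.75).  The
log-normal family is the natural choice for strictly positive, right-skewed
assay values summarised as median (IQR).

Three generation modes:

``marginal``
    every marker drawn independently from its group's log-normal; used for
    distribution-fidelity checks against the printed medians/IQRs.
``mechanistic_from_free``
    sFlt-1 and free PlGF drawn, total PlGF derived through the equilibrium
    binding model at the configured K_D; used for round-trip/parameter-
    recovery tests.  Multiplicative log-normal measurement noise (default
    CV 5%, typical automated-immunoassay imprecision) is applied
    independently to each reported value; CV 0 gives exact model states.
``mechanistic_from_total``
    sFlt-1 and total PlGF drawn, free PlGF derived by the quadratic
    inversion; same noise model.

The postpartum simulator decays each marker exponentially toward a
nonpregnant floor, with default half-lives chosen so that two days after
delivery less than 20% of the sFlt-1 excess and less than 10% of the total
PlGF excess remain, the pattern reported for AFLP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._exceptions import ConfigError, InputError
from .binding import (
    DEFAULT_KD_PMOL_L,
    BiomarkerSample,
    equilibrate_after_spike,
    free_from_total,
    predict_total_plgf,
)
from .units import PLGF, molar_to_mass

__all__ = [
    "GroupDistribution",
    "SimConfig",
    "DEFAULT_REGISTRY",
    "lognormal_from_median_iqr",
    "simulate_group",
    "simulate_cohort",
    "simulate_postpartum",
    "simulate_spike_experiment",
    "registry_to_dict",
    "registry_from_dict",
]

_Z75 = float(norm.ppf(0.75))  # 0.674489750196...

MARKERS = ("sflt1", "free_plgf", "total_plgf")

#: Default postpartum decay half-lives (days) and nonpregnant floors (pg/mL).
HALF_LIFE_SFLT1_DAYS = 0.85
HALF_LIFE_PLGF_DAYS = 0.58
FLOOR_SFLT1_PG_ML = 76.0
FLOOR_PLGF_PG_ML = 16.0


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple:
    """(mu, sigma) of the log-normal whose median and quartiles match the inputs.

    mu = ln(median); sigma = ln(q3/q1) / (2 z_0.75).  A degenerate
    q1 = median = q3 gives sigma = 0 (point mass).
    """
    if not (0 < q1 <= median <= q3):
        raise InputError(f"need 0 < q1 <= median <= q3, got ({q1}, {median}, {q3})")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


@dataclass(frozen=True)
class GroupDistribution:
    """Log-normal marginal of one marker in one diagnosis group (pg/mL)."""

    group: str
    marker: str
    median: float
    q1: float
    q3: float
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        mu, sigma = lognormal_from_median_iqr(self.median, self.q1, self.q3)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    def quantile(self, q: float) -> float:
        return math.exp(self.mu + self.sigma * norm.ppf(q))


def _dist(group: str, marker: str, median: float, q1: float, q3: float) -> GroupDistribution:
    return GroupDistribution(group=group, marker=marker, median=median, q1=q1, q3=q3)


def _dist_from_sigma(group: str, marker: str, median: float, sigma: float) -> GroupDistribution:
    """Distribution for a marker whose spread was not printed: borrow sigma."""
    half = math.exp(sigma * _Z75)
    return GroupDistribution(group=group, marker=marker, median=median, q1=median / half, q3=median * half)


def _build_default_registry() -> Dict[str, Dict[str, GroupDistribution]]:
    reg: Dict[str, Dict[str, GroupDistribution]] = {}

    # Antepartum pregnancy groups: printed medians [IQRs].  Markers whose IQR
    # was not printed borrow the group's free-PlGF sigma when available,
    # otherwise the group's sFlt-1 sigma.
    no_pe_sflt1 = _dist("no_pe", "sflt1", 2518, 1744, 3903)
    reg["no_pe"] = {
        "sflt1": no_pe_sflt1,
        "free_plgf": _dist_from_sigma("no_pe", "free_plgf", 349, no_pe_sflt1.sigma),
        "total_plgf": _dist_from_sigma("no_pe", "total_plgf", 354, no_pe_sflt1.sigma),
    }
    pe_sflt1 = _dist("pe", "sflt1", 8772, 6410, 10_736)
    reg["pe"] = {
        "sflt1": pe_sflt1,
        "free_plgf": _dist_from_sigma("pe", "free_plgf", 117, pe_sflt1.sigma),
        "total_plgf": _dist_from_sigma("pe", "total_plgf", 435, pe_sflt1.sigma),
    }
    hellp_free = _dist("hellp", "free_plgf", 59, 39, 97)
    reg["hellp"] = {
        "sflt1": _dist("hellp", "sflt1", 14_572, 5641, 20_056),
        "free_plgf": hellp_free,
        "total_plgf": _dist_from_sigma("hellp", "total_plgf", 344, hellp_free.sigma),
    }
    aflp_free = _dist("aflp", "free_plgf", 208, 106, 293)
    reg["aflp"] = {
        "sflt1": _dist("aflp", "sflt1", 77_762, 45_044, 116_657),
        "free_plgf": aflp_free,
        "total_plgf": _dist_from_sigma("aflp", "total_plgf", 2054, aflp_free.sigma),
    }
    reg["aflp_postpartum"] = {
        "total_plgf": _dist_from_sigma("aflp_postpartum", "total_plgf", 163, aflp_free.sigma),
    }
    # Nonpregnant references
    reg["healthy"] = {
        "sflt1": _dist("healthy", "sflt1", 76, 67, 84),
        "free_plgf": _dist("healthy", "free_plgf", 16, 14, 18),
    }
    reg["liver_failure"] = {
        "sflt1": _dist("liver_failure", "sflt1", 446, 211, 1414),
        "total_plgf": _dist("liver_failure", "total_plgf", 22, 12, 51),
    }
    return reg


#: Default per-group marker distributions (medians/IQRs of the study groups).
DEFAULT_REGISTRY: Dict[str, Dict[str, GroupDistribution]] = _build_default_registry()


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: cohort size, seed, generation mode, K_D and noise."""

    n_per_group: int = 12
    seed: int = 0
    mode: Literal["marginal", "mechanistic_from_free", "mechanistic_from_total"] = "marginal"
    kd: float = DEFAULT_KD_PMOL_L
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.mode not in ("marginal", "mechanistic_from_free", "mechanistic_from_total"):
            raise ConfigError(f"unknown mode {self.mode!r}")


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _draw(rng: np.random.Generator, dist: GroupDistribution, n: int) -> np.ndarray:
    if dist.sigma == 0:
        return np.full(n, dist.median)
    return rng.lognormal(mean=dist.mu, sigma=dist.sigma, size=n)


def simulate_group(
    group: str,
    cfg: SimConfig,
    registry: Optional[Dict[str, Dict[str, GroupDistribution]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Simulate one diagnosis group as a list of :class:`BiomarkerSample`.

    In ``marginal`` mode every marker with a registry entry is drawn
    independently.  In the mechanistic modes sFlt-1 plus one PlGF marker are
    drawn and the other is derived through the binding model at ``cfg.kd``,
    then measurement noise of ``cfg.noise_cv`` is applied to each reported
    value independently.  Identical config (and seed) gives identical output.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    if group not in registry:
        raise ConfigError(f"no distributions registered for group {group!r}")
    dists = registry[group]
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_per_group
    postpartum = group.endswith("_postpartum")
    base_group = group[: -len("_postpartum")] if postpartum else group

    if cfg.mode == "marginal":
        cols = {m: _draw(rng, dists[m], n) for m in MARKERS if m in dists}
        if not cols:
            raise ConfigError(f"group {group!r} has no marker distributions")
    else:
        if "sflt1" not in dists:
            raise ConfigError(f"mechanistic mode needs an sFlt-1 distribution for {group!r}")
        sflt1 = _draw(rng, dists["sflt1"], n)
        if cfg.mode == "mechanistic_from_free":
            if "free_plgf" not in dists:
                raise ConfigError(f"mechanistic_from_free needs a free-PlGF distribution for {group!r}")
            free = _draw(rng, dists["free_plgf"], n)
            total = np.array([predict_total_plgf(f, s, cfg.kd) for f, s in zip(free, sflt1)])
        else:
            if "total_plgf" not in dists:
                raise ConfigError(f"mechanistic_from_total needs a total-PlGF distribution for {group!r}")
            total = _draw(rng, dists["total_plgf"], n)
            free = np.array([free_from_total(t, s, cfg.kd) for t, s in zip(total, sflt1)])
        cols = {
            "sflt1": sflt1 * _noise_factors(rng, cfg.noise_cv, n),
            "free_plgf": free * _noise_factors(rng, cfg.noise_cv, n),
            "total_plgf": total * _noise_factors(rng, cfg.noise_cv, n),
        }

    zeros = np.zeros(n)
    sflt1_col = cols.get("sflt1", zeros)
    free_col = cols.get("free_plgf", zeros)
    total_col = cols.get("total_plgf")
    timepoint = "postpartum" if postpartum else "antepartum"
    day = 2 if postpartum else None
    samples = []
    for i in range(n):
        samples.append(
            BiomarkerSample(
                sample_id=f"{group}-{i + 1:04d}",
                group=base_group,
                timepoint=timepoint,
                day_postpartum=day,
                sflt1=float(sflt1_col[i]),
                free_plgf=float(free_col[i]),
                total_plgf=float(total_col[i]) if total_col is not None else None,
            )
        )
    return samples


def simulate_cohort(
    group_sizes: Dict[str, int],
    cfg: SimConfig,
    registry: Optional[Dict[str, Dict[str, GroupDistribution]]] = None,
) -> list:
    """Simulate several groups with one seeded stream; sizes given per group."""
    rng = np.random.default_rng(cfg.seed)
    samples: list = []
    for group, n in group_sizes.items():
        samples.extend(simulate_group(group, replace(cfg, n_per_group=n), registry, rng=rng))
    return samples


def simulate_postpartum(
    ante: Sequence[BiomarkerSample],
    days: Sequence[int],
    half_life_sflt1: float = HALF_LIFE_SFLT1_DAYS,
    half_life_plgf: float = HALF_LIFE_PLGF_DAYS,
    floor_sflt1: float = FLOOR_SFLT1_PG_ML,
    floor_plgf: float = FLOOR_PLGF_PG_ML,
) -> list:
    """Postpartum trajectories: exponential decay toward nonpregnant floors.

    value(d) = floor + (antepartum - floor) * 2^(-d / half_life).  Defaults
    leave <20% of the sFlt-1 excess and <10% of the PlGF excess at day 2.
    """
    if any(d < 0 for d in days):
        raise InputError("postpartum days must be non-negative")
    out = []
    for s in ante:
        if s.timepoint != "antepartum":
            raise InputError(f"sample {s.sample_id} is not antepartum")
        for d in days:
            def decay(v: Optional[float], floor: float, h: float) -> Optional[float]:
                if v is None:
                    return None
                return floor + (v - floor) * 2.0 ** (-d / h)

            out.append(
                BiomarkerSample(
                    sample_id=f"{s.sample_id}-pp{d}",
                    group=s.group,
                    timepoint="postpartum",
                    day_postpartum=int(d),
                    sflt1=decay(s.sflt1, floor_sflt1, half_life_sflt1),
                    free_plgf=decay(s.free_plgf, floor_plgf, half_life_plgf),
                    total_plgf=decay(s.total_plgf, floor_plgf, half_life_plgf),
                    ga_weeks=s.ga_weeks,
                )
            )
    return out


def simulate_spike_experiment(
    cohort: Sequence[BiomarkerSample],
    added_pg_ml: float,
    cfg: SimConfig,
) -> pd.DataFrame:
    """In-silico spike-recovery experiment over a cohort.

    Each sample is re-equilibrated after adding ``added_pg_ml`` of exogenous
    PlGF at ``cfg.kd``.  The table reports what the free-PlGF assay would see
    before heating (equilibrium free) and after heating (the full spiked
    total), each with measurement noise of ``cfg.noise_cv``.
    """
    if added_pg_ml < 0:
        raise InputError("added ligand must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for s in cohort:
        state = equilibrate_after_spike(s, added_pg_ml, cfg.kd)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "endogenous_free_pg_ml": s.free_plgf,
                "detected_free_before_heat_pg_ml": molar_to_mass(state.d_free, PLGF),
                "detected_total_after_heat_pg_ml": molar_to_mass(state.d_total, PLGF),
            }
        )
    df = pd.DataFrame(rows)
    for col in ("detected_free_before_heat_pg_ml", "detected_total_after_heat_pg_ml"):
        df[col] = df[col].to_numpy() * _noise_factors(rng, cfg.noise_cv, len(df))
    return df


def registry_to_dict(registry: Dict[str, Dict[str, GroupDistribution]]) -> dict:
    """Plain-dict form of a registry, suitable for YAML/JSON serialization."""
    return {
        g: {m: {"median": d.median, "q1": d.q1, "q3": d.q3} for m, d in markers.items()}
        for g, markers in registry.items()
    }


def registry_from_dict(data: dict) -> Dict[str, Dict[str, GroupDistribution]]:
    """Inverse of :func:`registry_to_dict`."""
    return {
        g: {
            m: GroupDistribution(group=g, marker=m, median=v["median"], q1=v["q1"], q3=v["q3"])
            for m, v in markers.items()
        }
        for g, markers in data.items()
    }
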