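"""1:1 equilibrium binding model for the sFlt-1 / PlGF system.

The model treats sFlt-1 as a soluble receptor R and free PlGF as the ligand D,
with [sFlt-1] + [PlGF] <=> [sFlt-1-PlGF] at equilibrium:

    K_D = [D] [R] / [DR],   [R]_total = [R] + [DR]

so that bound ligand at equilibrium is

    [DR] = [D] [R]_total / (K_D + [D]).

Total PlGF is free plus bound: the quantity a free-PlGF immunoassay reports
after sFlt-1 has been heat-denatured, or that this module predicts from the
measured free PlGF and sFlt-1 alone.  Inverting the mass balance
T = D + D R / (K_D + D) for D gives the quadratic

    D^2 + D (K_D + R - T) - K_D T = 0,

whose unique non-negative root is the free concentration consistent with a
known total; that inversion drives both the simulator and the in-silico
spike experiment.

All functions accept pg/mL at the interface (matching assay reports) and
convert internally to pmol/L.  The default dissociation constant is
50 pmol/L, within the reported Flt-1 affinity range for PlGF/VEGF
(~20-200 pmol/L); every function lets callers override it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from ._exceptions import (
    DomainError,
    InconsistentSampleError,
    NoEstimableSamplesError,
    NotEstimableError,
    UndefinedOccupancyError,
)
from .units import PLGF, SFLT1, mass_to_molar, molar_to_mass

__all__ = [
    "DEFAULT_KD_PMOL_L",
    "BindingState",
    "BiomarkerSample",
    "KdEstimate",
    "occupancy",
    "predict_total_plgf",
    "kd_from_sample",
    "estimate_mean_kd",
    "free_from_total",
    "equilibrate_after_spike",
]

#: Default dissociation constant, pmol/L.
DEFAULT_KD_PMOL_L = 50.0

#: Diagnosis groups recognised throughout the package.
GROUPS = ("no_pe", "pe", "hellp", "aflp", "liver_failure", "healthy")

_EQ_RTOL = 1e-9


@dataclass(frozen=True)
class BindingState:
    """Molar snapshot of the ligand-receptor system at equilibrium.

    All concentrations in pmol/L: ``d_free`` is unbound ligand [D],
    ``r_total`` total receptor [R]_total, ``dr`` the complex [DR], and ``kd``
    the dissociation constant.
    """

    d_free: float
    r_total: float
    dr: float
    kd: float

    def __post_init__(self) -> None:
        if min(self.d_free, self.r_total, self.dr, self.kd) < 0:
            raise DomainError("binding-state concentrations must be non-negative")
        if self.dr > self.r_total * (1 + _EQ_RTOL) + 1e-30:
            raise DomainError("complex concentration exceeds total receptor")

    def at_equilibrium(self, rtol: float = _EQ_RTOL) -> bool:
        """Whether K_D * [DR] = [D] ([R]_total - [DR]) holds to relative ``rtol``."""
        lhs = self.kd * self.dr
        rhs = self.d_free * (self.r_total - self.dr)
        scale = max(abs(lhs), abs(rhs), 1e-300)
        return abs(lhs - rhs) <= rtol * scale

    @property
    def d_total(self) -> float:
        """Total ligand [D] + [DR], pmol/L."""
        return self.d_free + self.dr


@dataclass
class BiomarkerSample:
    """One blood draw: measured concentrations (pg/mL) plus metadata.

    ``total_plgf`` is the post-heating measurement when available; ``None``
    otherwise.  ``day_postpartum`` must be present exactly when the timepoint
    is postpartum.
    """

    sample_id: str
    sflt1: float
    free_plgf: float
    total_plgf: Optional[float] = None
    group: Optional[str] = None
    timepoint: str = "antepartum"
    day_postpartum: Optional[int] = None
    ga_weeks: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sflt1 < 0 or self.free_plgf < 0:
            raise DomainError(f"sample {self.sample_id}: concentrations must be non-negative")
        if self.total_plgf is not None and self.total_plgf < 0:
            raise DomainError(f"sample {self.sample_id}: total PlGF must be non-negative")
        if self.timepoint not in ("antepartum", "postpartum"):
            raise DomainError(f"sample {self.sample_id}: unknown timepoint {self.timepoint!r}")
        if (self.day_postpartum is not None) != (self.timepoint == "postpartum"):
            raise DomainError(
                f"sample {self.sample_id}: day_postpartum must be present "
                "iff timepoint is postpartum"
            )


@dataclass(frozen=True)
class KdEstimate:
    """Per-sample dissociation constants with their mean and SEM (pmol/L)."""

    per_sample_kd: tuple
    mean_kd: float
    sem_kd: float
    n_used: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "mean_kd_pmol_l": self.mean_kd,
            "sem_kd_pmol_l": self.sem_kd,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "per_sample_kd_pmol_l": list(self.per_sample_kd),
        }


def occupancy(d_free: float, r_total: float, kd: float) -> float:
    """Bound ligand [DR] = [D][R]_total / (K_D + [D]), all in pmol/L.

    Half the receptors are occupied at [D] = K_D; occupancy tends to
    [R]_total as K_D -> 0 with [D] > 0.
    """
    if min(d_free, r_total, kd) < 0:
        raise DomainError("occupancy inputs must be non-negative")
    if kd == 0 and d_free == 0:
        raise UndefinedOccupancyError("occupancy undefined when K_D = 0 and [D] = 0")
    return d_free * r_total / (kd + d_free)


def predict_total_plgf(
    free_plgf_pg_ml: float, sflt1_pg_ml: float, kd_pmol_l: float = DEFAULT_KD_PMOL_L
) -> float:
    """Predict total PlGF (pg/mL) from measured free PlGF and sFlt-1.

    Total = free + bound, where bound PlGF is the equilibrium complex
    concentration converted back to PlGF mass units.  Always >= free.
    """
    if free_plgf_pg_ml < 0 or sflt1_pg_ml < 0:
        raise DomainError("concentrations must be non-negative")
    if not kd_pmol_l > 0:
        raise DomainError(f"K_D must be positive, got {kd_pmol_l}")
    d = mass_to_molar(free_plgf_pg_ml, PLGF)
    r = mass_to_molar(sflt1_pg_ml, SFLT1)
    dr = occupancy(d, r, kd_pmol_l)
    return free_plgf_pg_ml + molar_to_mass(dr, PLGF)


def kd_from_sample(
    free_plgf_pg_ml: float, total_plgf_pg_ml: float, sflt1_pg_ml: float
) -> float:
    """Per-sample dissociation constant (pmol/L) from free, total and sFlt-1.

    The complex is the molar difference total - free (both PlGF mass units);
    then K_D = [D] ([R]_total - [DR]) / [DR].  Requires total > free (some
    PlGF actually bound) and implied [DR] < [R]_total.
    """
    if free_plgf_pg_ml < 0 or sflt1_pg_ml < 0:
        raise DomainError("concentrations must be non-negative")
    if total_plgf_pg_ml <= free_plgf_pg_ml:
        raise NotEstimableError(
            "K_D not estimable: total PlGF must exceed free PlGF "
            f"(free={free_plgf_pg_ml}, total={total_plgf_pg_ml})"
        )
    if sflt1_pg_ml <= 0:
        raise NotEstimableError("K_D not estimable: sFlt-1 must be positive")
    d = mass_to_molar(free_plgf_pg_ml, PLGF)
    dr = mass_to_molar(total_plgf_pg_ml - free_plgf_pg_ml, PLGF)
    r_total = mass_to_molar(sflt1_pg_ml, SFLT1)
    if dr >= r_total:
        raise InconsistentSampleError(
            "implied bound PlGF meets or exceeds total sFlt-1 "
            f"({dr:.6g} >= {r_total:.6g} pmol/L)"
        )
    return d * (r_total - dr) / dr


def estimate_mean_kd(
    samples: Sequence[BiomarkerSample],
    mean: Literal["arithmetic", "geometric"] = "arithmetic",
) -> KdEstimate:
    """Mean dissociation constant across a cohort.

    Follows the study's inclusion rule: a sample contributes a per-sample K_D
    only when a total-PlGF measurement exists and total > free; others are
    counted in ``n_excluded``.  The mean is arithmetic by default (a
    geometric mean is available); SEM is the sample standard deviation over
    sqrt(n).
    """
    if len(samples) == 0:
        raise NoEstimableSamplesError("empty sample list")
    kds: list[float] = []
    n_excluded = 0
    for s in samples:
        if s.total_plgf is None:
            n_excluded += 1
            continue
        try:
            kds.append(kd_from_sample(s.free_plgf, s.total_plgf, s.sflt1))
        except (NotEstimableError, InconsistentSampleError):
            n_excluded += 1
    if not kds:
        raise NoEstimableSamplesError("no sample admits a K_D estimate")
    arr = np.asarray(kds, dtype=float)
    if mean == "geometric":
        center = float(np.exp(np.mean(np.log(arr))))
    else:
        center = float(np.mean(arr))
    sem = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return KdEstimate(
        per_sample_kd=tuple(kds),
        mean_kd=center,
        sem_kd=sem,
        n_used=len(kds),
        n_excluded=n_excluded,
    )


def free_from_total(
    total_plgf_pg_ml: float, sflt1_pg_ml: float, kd_pmol_l: float = DEFAULT_KD_PMOL_L
) -> float:
    """Free PlGF (pg/mL) consistent with a known total PlGF and sFlt-1.

    Solves D^2 + D (K_D + R - T) - K_D T = 0 (molar units) for its unique
    non-negative root, using the cancellation-safe root form when
    K_D + R - T >= 0.  Exact inverse of :func:`predict_total_plgf`.
    """
    if total_plgf_pg_ml < 0 or sflt1_pg_ml < 0:
        raise DomainError("concentrations must be non-negative")
    if not kd_pmol_l > 0:
        raise DomainError(f"K_D must be positive, got {kd_pmol_l}")
    t = mass_to_molar(total_plgf_pg_ml, PLGF)
    r = mass_to_molar(sflt1_pg_ml, SFLT1)
    b = kd_pmol_l + r - t
    disc = b * b + 4.0 * kd_pmol_l * t
    if disc < 0:  # pragma: no cover - impossible for valid inputs
        raise AssertionError("negative discriminant in free-ligand quadratic")
    sq = math.sqrt(disc)
    if b >= 0:
        # 2qc/(b+sqrt) form avoids subtracting nearly equal numbers when K_D << R
        d = 2.0 * kd_pmol_l * t / (b + sq) if (b + sq) > 0 else 0.0
    else:
        d = (-b + sq) / 2.0
    return molar_to_mass(d, PLGF)


def equilibrate_after_spike(
    sample: BiomarkerSample,
    added_ligand_pg_ml: float,
    kd_pmol_l: float = DEFAULT_KD_PMOL_L,
) -> BindingState:
    """Re-equilibrate a serum sample after spiking in exogenous PlGF.

    Models the spike-recovery design: recombinant PlGF raises the total
    ligand pool by ``added_ligand_pg_ml``; the mixture re-equilibrates with
    the sample's sFlt-1 at the given K_D.  The returned state's ``d_free``
    is what a free-PlGF assay would detect before heating; ``d_total``
    (free + complex) is the post-heating readout, independent of sFlt-1.

    If the sample lacks a measured total PlGF it is first predicted from
    free PlGF and sFlt-1 at the same K_D.
    """
    if added_ligand_pg_ml < 0:
        raise DomainError("added ligand must be non-negative")
    endogenous_total = (
        sample.total_plgf
        if sample.total_plgf is not None
        else predict_total_plgf(sample.free_plgf, sample.sflt1, kd_pmol_l)
    )
    spiked_total = endogenous_total + added_ligand_pg_ml
    free = free_from_total(spiked_total, sample.sflt1, kd_pmol_l)
    d = mass_to_molar(free, PLGF)
    t = mass_to_molar(spiked_total, PLGF)
    r = mass_to_molar(sample.sflt1, SFLT1)
    dr = max(t - d, 0.0)
    return BindingState(d_free=d, r_total=r, dr=dr, kd=kd_pmol_l)
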