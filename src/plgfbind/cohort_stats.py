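"""Descriptive and inferential statistics for biomarker cohorts.

Implements the study-style analysis pipeline: median (IQR) summaries,
normality-gated two-group tests (Student t vs Mann-Whitney U, gated by
Shapiro-Wilk at alpha 0.05 per group), multi-group omnibus tests (one-way
ANOVA vs Kruskal-Wallis) with Bonferroni-corrected pairwise follow-up,
sFlt-1/PlGF ratio cutoff classification (<=38 low, >=85 high), postpartum
percent-remaining arithmetic, and the ISSHP clinical definitions of
preeclampsia (2001) and HELLP syndrome (2013) as commonly operationalised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from ._exceptions import IncompleteRecordError, InputError, UndefinedRatioError
from .validation import ComparisonResult

__all__ = [
    "GroupSummary",
    "ClinicalRecord",
    "GroupComparison",
    "median_iqr",
    "compare_two",
    "compare_groups",
    "ratio_classify",
    "percent_remaining",
    "classify_pe",
    "classify_hellp",
]

#: Shapiro-Wilk alpha for the normality gate.
NORMALITY_ALPHA = 0.05

#: Largest per-group n at which the Mann-Whitney null is enumerated exactly.
EXACT_MWU_MAX_N = 8

RATIO_LOW_CUTOFF = 38.0
RATIO_HIGH_CUTOFF = 85.0


@dataclass(frozen=True)
class GroupSummary:
    """Median and interquartile range of one group's values."""

    group: str
    n: int
    median: float
    q1: float
    q3: float

    def to_dict(self) -> dict:
        return {"group": self.group, "n": self.n, "median": self.median, "q1": self.q1, "q3": self.q3}


@dataclass
class ClinicalRecord:
    """Clinical variables needed by the hypertensive-disorder classifications.

    Units: blood pressure mm Hg; protein-to-creatinine ratio mg/mmol;
    24-hour proteinuria mg/24h; dipstick 0-4; platelets 10^9/L; ALT/AST/LDH
    IU/L with their upper limits of normal (ULN); gestational age in weeks.
    """

    sbp: Optional[float] = None
    dbp: Optional[float] = None
    ga_weeks: Optional[float] = None
    proteinuria_pcr: Optional[float] = None
    proteinuria_24h: Optional[float] = None
    dipstick: Optional[int] = None
    platelets: Optional[float] = None
    alt: Optional[float] = None
    ast: Optional[float] = None
    ldh: Optional[float] = None
    uln_alt: Optional[float] = None
    uln_ast: Optional[float] = None
    uln_ldh: Optional[float] = None


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus multi-group result plus Bonferroni-corrected pairwise follow-up."""

    omnibus: ComparisonResult
    pairwise: dict  # (label_a, label_b) -> ComparisonResult (corrected p)


def median_iqr(values: Sequence[float], group: str = "") -> GroupSummary:
    """Median and quartiles by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("cannot summarise an empty list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return GroupSummary(group=group, n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))


def _shapiro_normal(values: np.ndarray) -> bool:
    if np.ptp(values) == 0:
        return False  # degenerate; Shapiro is undefined, treat as non-normal
    return stats.shapiro(values).pvalue > NORMALITY_ALPHA


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> tuple:
    """Exact two-sided Mann-Whitney p by enumerating all C(n1+n2, n1) group
    assignments of the pooled (tie-averaged) ranks.

    Returns (U of group a, p).  Two-sided p counts assignments whose U is at
    least as far from the null mean n1*n2/2 as observed; correct under ties.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    center = n1 * n2 / 2.0
    obs_dev = abs(u_obs - center)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - offset)
        if abs(u - center) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple = ("a", "b"),
    test: Literal["auto", "t", "mwu"] = "auto",
) -> ComparisonResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    With ``test="auto"``: both groups normal (Shapiro-Wilk p > 0.05 each) ->
    Student t test; otherwise Mann-Whitney U, exact by enumeration when both
    groups have n <= 8 and the normal approximation with tie correction
    otherwise.  ``test="t"`` / ``test="mwu"`` force a branch.  Two-sided
    throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InputError("each group needs at least 3 observations")
    use_t = test == "t" or (test == "auto" and _shapiro_normal(a) and _shapiro_normal(b))
    if use_t:
        res = stats.ttest_ind(a, b)
        return ComparisonResult(
            statistic_name="t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=int(a.size + b.size),
            method_notes=f"Student t test ({labels[0]} vs {labels[1]}); Shapiro-Wilk passed both groups",
        )
    if a.size <= EXACT_MWU_MAX_N and b.size <= EXACT_MWU_MAX_N:
        u, p = _exact_mwu_p(a, b)
        notes = f"Mann-Whitney U, exact enumeration ({labels[0]} vs {labels[1]})"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        notes = f"Mann-Whitney U, normal approximation with tie correction ({labels[0]} vs {labels[1]})"
    return ComparisonResult(
        statistic_name="U", statistic=u, p_value=p, n=int(a.size + b.size), method_notes=notes
    )


def _dunn_pairwise(groups: list, labels: list) -> dict:
    """Dunn's z-test on pooled ranks after Kruskal-Wallis, Bonferroni-corrected."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction term for the pooled ranking
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    splits = np.cumsum([g.size for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = [rg.mean() for rg in rank_groups]
    m = len(groups) * (len(groups) - 1) // 2
    out = {}
    for (i, j) in combinations(range(len(groups)), 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / groups[i].size + 1.0 / groups[j].size)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        out[(labels[i], labels[j])] = ComparisonResult(
            statistic_name="dunn_z",
            statistic=float(z),
            p_value=float(p),
            n=int(groups[i].size + groups[j].size),
            method_notes="Dunn z on pooled ranks, Bonferroni-corrected",
        )
    return out


def compare_groups(
    groups: Sequence[tuple],
    posthoc: Literal["pairwise_bonferroni", "dunn"] = "pairwise_bonferroni",
    test: Literal["auto", "anova", "kruskal"] = "auto",
) -> GroupComparison:
    """Multi-group comparison: normality-gated omnibus plus corrected pairwise tests.

    All groups normal -> one-way ANOVA with pairwise t tests; otherwise
    Kruskal-Wallis with pairwise Mann-Whitney (default) or Dunn's test.
    ``test`` forces the omnibus branch.  Pairwise p-values are
    Bonferroni-corrected for the number of pairs.
    """
    if len(groups) < 3:
        raise InputError("need at least 3 groups (use compare_two otherwise)")
    labels = [g[0] for g in groups]
    arrays = [np.asarray(g[1], dtype=float) for g in groups]
    if any(arr.size < 3 for arr in arrays):
        raise InputError("each group needs at least 3 observations")
    all_normal = test == "anova" or (
        test == "auto" and all(_shapiro_normal(arr) for arr in arrays)
    )
    if all_normal:
        res = stats.f_oneway(*arrays)
        omnibus = ComparisonResult(
            statistic_name="F",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=int(sum(arr.size for arr in arrays)),
            method_notes="one-way ANOVA; Shapiro-Wilk passed all groups",
        )
    else:
        res = stats.kruskal(*arrays)
        omnibus = ComparisonResult(
            statistic_name="H",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=int(sum(arr.size for arr in arrays)),
            method_notes="Kruskal-Wallis",
        )
    if not all_normal and posthoc == "dunn":
        pairwise = _dunn_pairwise(arrays, labels)
    else:
        m = len(arrays) * (len(arrays) - 1) // 2
        pairwise = {}
        for (i, j) in combinations(range(len(arrays)), 2):
            raw = compare_two(
                arrays[i], arrays[j], labels=(labels[i], labels[j]),
                test="t" if all_normal else "mwu",
            )
            pairwise[(labels[i], labels[j])] = ComparisonResult(
                statistic_name=raw.statistic_name,
                statistic=raw.statistic,
                p_value=min(1.0, raw.p_value * m),
                n=raw.n,
                method_notes=raw.method_notes + f"; Bonferroni x{m}",
            )
    return GroupComparison(omnibus=omnibus, pairwise=pairwise)


def ratio_classify(sflt1_pg_ml: float, free_plgf_pg_ml: float) -> str:
    """Classify angiogenic imbalance by the sFlt-1/free-PlGF ratio.

    <= 38 -> "low" (short-term absence of preeclampsia predicted);
    >= 85 -> "high" (high risk of adverse outcome); otherwise "intermediate".
    Boundaries are inclusive on both cutoffs.
    """
    if free_plgf_pg_ml <= 0:
        raise UndefinedRatioError("ratio undefined: free PlGF must be positive")
    if sflt1_pg_ml < 0:
        raise InputError("sFlt-1 must be non-negative")
    ratio = sflt1_pg_ml / free_plgf_pg_ml
    if ratio <= RATIO_LOW_CUTOFF:
        return "low"
    if ratio >= RATIO_HIGH_CUTOFF:
        return "high"
    return "intermediate"


def percent_remaining(antepartum: float, postpartum: float) -> float:
    """Postpartum level as a percentage of the antepartum level."""
    if antepartum <= 0:
        raise InputError("antepartum value must be positive")
    if postpartum < 0:
        raise InputError("postpartum value must be non-negative")
    return 100.0 * postpartum / antepartum


def _has_proteinuria(rec: ClinicalRecord) -> bool:
    if rec.proteinuria_pcr is not None and rec.proteinuria_pcr >= 30:
        return True
    if rec.proteinuria_24h is not None and rec.proteinuria_24h >= 300:
        return True
    if rec.dipstick is not None and rec.dipstick >= 2:
        return True
    return False


def classify_pe(rec: ClinicalRecord) -> str:
    """ISSHP 2001-style classification of hypertensive disorder of pregnancy.

    Hypertension: SBP >= 140 or DBP >= 90 mm Hg at >= 20 weeks' gestation.
    Preeclampsia: hypertension plus proteinuria (PCR >= 30 mg/mmol, or
    >= 300 mg/24h, or dipstick >= 2+).  Hypertension without proteinuria is
    gestational hypertension; otherwise "none".
    """
    if rec.sbp is None or rec.dbp is None or rec.ga_weeks is None:
        raise IncompleteRecordError("classify_pe requires sbp, dbp and ga_weeks")
    hypertensive = (rec.sbp >= 140 or rec.dbp >= 90) and rec.ga_weeks >= 20
    if not hypertensive:
        return "none"
    return "preeclampsia" if _has_proteinuria(rec) else "gestational_hypertension"


def classify_hellp(rec: ClinicalRecord) -> str:
    """HELLP syndrome per the ISSHP 2013 criteria.

    The three criteria: platelets < 100 x 10^9/L; ALT or AST >= 2x ULN;
    LDH >= 2x ULN or > 650 IU/L.  All three -> "hellp"; exactly two ->
    "partial_hellp"; otherwise "none".
    """
    if rec.platelets is None:
        raise IncompleteRecordError("classify_hellp requires a platelet count")
    has_alt = rec.alt is not None and rec.uln_alt is not None
    has_ast = rec.ast is not None and rec.uln_ast is not None
    if not (has_alt or has_ast):
        raise IncompleteRecordError("classify_hellp requires ALT or AST with its ULN")
    if rec.ldh is None or rec.uln_ldh is None:
        raise IncompleteRecordError("classify_hellp requires LDH and its ULN")
    low_platelets = rec.platelets < 100
    enzymes = (has_alt and rec.alt >= 2 * rec.uln_alt) or (has_ast and rec.ast >= 2 * rec.uln_ast)
    ldh_high = rec.ldh >= 2 * rec.uln_ldh or rec.ldh > 650
    n_criteria = int(low_platelets) + int(enzymes) + int(ldh_high)
    if n_criteria == 3:
        return "hellp"
    if n_criteria == 2:
        return "partial_hellp"
    return "none"
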