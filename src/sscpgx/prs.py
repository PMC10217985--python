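"""Normalized polygenic risk score and rank-based outcome comparison.

Each variant contributes points by minor-allele dosage — 0 for
normal-function homozygotes, 0.5 for heterozygotes, 1 for minor-allele
homozygotes — and the score is the β-weighted mean of those points:

    score = Σᵢ βᵢ·xᵢ / Σᵢ βᵢ,   xᵢ ∈ {0, 0.5, 1},

so it always lies in [0, 1], reaching the endpoints only at the
all-major / all-minor extremes.  Scores are compared between subjects
with and without each severe outcome, per therapy stratum, with the
Mann-Whitney U test; a stratum where one group is empty is reported as a
NaN p-value with an explanatory note rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import (
    Cohort,
    CohortError,
    GenotypeCall,
    OUTCOME_NAMES,
    STRATA,
    ValidationError,
)
from .association import stratum_members


class UndefinedScoreError(CohortError):
    """All usable weights are zero; the normalized score is undefined."""


class MissingScoreError(CohortError):
    """No variant with a non-missing call and positive weight."""


@dataclass(frozen=True)
class WeightSet:
    """Non-negative GWAS β weights keyed by rsid or merged marker name."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for marker, beta in self.weights.items():
            if beta < 0:
                raise ValidationError(
                    f"negative beta for {marker}: β measures impact toward "
                    "reduced enzymatic efficiency and must be non-negative"
                )
        if not any(b > 0 for b in self.weights.values()):
            raise ValidationError("at least one weight must be positive")


@dataclass(frozen=True)
class PRSResult:
    subject_id: str
    score: float
    n_variants_used: int


@dataclass(frozen=True)
class PRSComparison:
    outcome: str
    stratum: str
    n_with: int
    n_without: int
    u_statistic: float
    p_value: float
    note: str = ""


def genotype_points(call: GenotypeCall) -> float:
    """PRS points by minor-allele dosage: 0 / 0.5 / 1."""
    if call is None or call.is_missing:
        raise ValidationError("genotype_points requires a non-missing call")
    return call.minor_allele_count / 2.0


def compute_prs(calls: Iterable[GenotypeCall], weights: WeightSet) -> PRSResult:
    """Normalized weighted score over a subject's usable calls.

    Variants with a missing call are excluded and the weight sum is
    renormalized over the variants actually used; ``n_variants_used``
    records how many (positive-weight) variants entered the score.
    """
    calls = list(calls)
    sids = {c.subject_id for c in calls}
    if len(sids) > 1:
        raise ValidationError(f"calls span multiple subjects: {sorted(sids)}")
    num = 0.0
    denom = 0.0
    n_used = 0
    for call in calls:
        if call.is_missing or call.rsid not in weights.weights:
            continue
        beta = weights.weights[call.rsid]
        if beta > 0:
            n_used += 1
        num += beta * genotype_points(call)
        denom += beta
    if n_used == 0:
        raise MissingScoreError(
            "no usable variant (non-missing call with positive weight)"
        )
    if denom == 0:
        raise UndefinedScoreError("usable weights sum to zero")
    return PRSResult(
        subject_id=next(iter(sids)) if sids else "",
        score=num / denom,
        n_variants_used=n_used,
    )


def cohort_prs(cohort: Cohort, weights: WeightSet) -> pd.DataFrame:
    """Per-subject scores; subjects with no usable variant get a NaN score."""
    rows = []
    for s in cohort.subjects:
        calls = [
            c
            for rsid in cohort.rsids
            if (c := cohort.call(s.subject_id, rsid)) is not None
        ]
        try:
            res = compute_prs(calls, weights)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "score": res.score,
                    "n_variants_used": res.n_variants_used,
                }
            )
        except (MissingScoreError, UndefinedScoreError):
            rows.append(
                {"subject_id": s.subject_id, "score": math.nan, "n_variants_used": 0}
            )
    return pd.DataFrame(rows, columns=["subject_id", "score", "n_variants_used"])


def scores_from_counts(counts: pd.DataFrame, weights: WeightSet) -> pd.Series:
    """Vectorized scores from a subjects × markers minor-allele-count table.

    NaN entries are treated as missing calls (weight sum renormalized per
    subject, as in :func:`compute_prs`).
    """
    cols = [c for c in counts.columns if c in weights.weights]
    if not cols:
        raise MissingScoreError("no table column matches a weighted marker")
    betas = np.array([weights.weights[c] for c in cols], dtype=float)
    raw = counts[cols].to_numpy(dtype=float)
    present = ~np.isnan(raw)
    pts = np.where(present, raw / 2.0, 0.0)
    denom = present @ betas
    num = pts @ betas
    with np.errstate(invalid="ignore"):
        return pd.Series(np.where(denom > 0, num / denom, np.nan), index=counts.index)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "normal-approx-tie-corrected" | "undefined"
    note: str = ""


def mann_whitney_u(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U is reported for the first group.

    Exact enumeration when both groups have at most 8 observations and
    the pooled sample is tie-free; otherwise the tie-corrected normal
    approximation with continuity correction (matching R's wilcox.test
    convention).  An empty group gives a NaN p-value with a note (no
    rank comparison exists); two identical constant samples carry no
    shift evidence and give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return MannWhitneyResult(
            u=math.nan,
            p=math.nan,
            method="undefined",
            note="empty group: no rank comparison possible",
        )
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:  # degenerate: tie variance is zero
        return MannWhitneyResult(
            u=a.size * b.size / 2.0,
            p=1.0,
            method="normal-approx-tie-corrected",
            note="all observations tied",
        )
    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and tie_free:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(
        u=float(res.statistic),
        p=float(res.pvalue),
        method="normal-approx-tie-corrected",
    )


def prs_outcome_matrix(
    cohort: Cohort,
    weights: WeightSet,
    outcomes: Sequence[str] = OUTCOME_NAMES,
    strata: Sequence[str] = STRATA,
    policy: str = "both",
) -> list[PRSComparison]:
    """Score comparison (with vs without each outcome) per stratum."""
    score_df = cohort_prs(cohort, weights).set_index("subject_id")
    comparisons: list[PRSComparison] = []
    for outcome in outcomes:
        for stratum in strata:
            members = stratum_members(cohort, stratum, policy)
            with_scores, without_scores = [], []
            for s in members:
                sc = float(score_df.loc[s.subject_id, "score"])
                if math.isnan(sc):
                    continue
                (with_scores if s.outcomes.get(outcome) else without_scores).append(sc)
            mw = mann_whitney_u(with_scores, without_scores)
            note = mw.note
            if not with_scores:
                note = f"no subject in stratum {stratum!r} developed {outcome}"
            elif not without_scores:
                note = f"every subject in stratum {stratum!r} developed {outcome}"
            comparisons.append(
                PRSComparison(
                    outcome=outcome,
                    stratum=stratum,
                    n_with=len(with_scores),
                    n_without=len(without_scores),
                    u_statistic=mw.u,
                    p_value=mw.p,
                    note=note,
                )
            )
    return comparisons


def comparison_frame(comparisons: Iterable[PRSComparison]) -> pd.DataFrame:
    """Matrix layout: rows are outcomes, columns strata, cells p-values."""
    df = pd.DataFrame(
        [
            {"outcome": c.outcome, "stratum": c.stratum, "p_value": c.p_value}
            for c in comparisons
        ]
    )
    wide = df.pivot(index="outcome", columns="stratum", values="p_value")
    order_rows = [o for o in OUTCOME_NAMES if o in wide.index]
    order_cols = [s for s in STRATA if s in wide.columns]
    return wide.loc[order_rows, order_cols]


def comparison_long_frame(comparisons: Iterable[PRSComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": c.outcome,
                "stratum": c.stratum,
                "n_with": c.n_with,
                "n_without": c.n_without,
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
                "note": c.note,
            }
            for c in comparisons
        ]
    )
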