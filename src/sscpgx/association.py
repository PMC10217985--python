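"""Dominant-model stratified logistic association analysis.

For every marker × outcome × therapy-stratum cell the pipeline fits a
logistic regression of the binary outcome on the dominant genotype code
(normal-function homozygotes as referent), unadjusted and adjusted for
age (years, continuous) and sex (female referent).  The exposure odds
ratio, its Wald 95% confidence interval and the two-sided Wald p-value
populate the association grid; cells with no events, no genotype
variation, or perfect separation are flagged non-estimable instead of
raising.  A Firth-penalized fit is available behind an explicit flag for
separated cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort_model import (
    Cohort,
    CohortError,
    OUTCOME_NAMES,
    STRATA,
    ValidationError,
)

#: 97.5% standard-normal quantile used for all Wald intervals.
Z975 = 1.959964

# |coefficient| beyond this on the log-odds scale, or a standard error
# beyond the SE bound, is treated as a diverging MLE (separation);
# finite data cannot support such estimates.
_SEPARATION_COEF_BOUND = 15.0
_SEPARATION_SE_BOUND = 50.0


class NoVariationError(CohortError):
    """The response is all zeros or all ones; the model is not estimable."""


@dataclass(frozen=True)
class LogisticFit:
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_used: int
    separated: bool = False
    method: str = "newton-mle"


def _check_inputs(y: np.ndarray, design: np.ndarray) -> None:
    if y.ndim != 1 or design.ndim != 2 or design.shape[0] != y.shape[0]:
        raise ValidationError("y must be 1-D and match the design's row count")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise NoVariationError("y has no variation (all zeros or all ones)")


def fit_logistic(
    y: Sequence[float],
    design: np.ndarray,
    maxiter: int = 100,
    tol: float = 1e-8,
    firth: bool = False,
) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton iterations).

    ``design`` must already contain the intercept column.  Standard
    errors come from the inverse observed information at the optimum.
    Perfect separation is detected (diverging coefficients or a singular
    information matrix) and reported through ``separated`` rather than
    raised.  ``firth=True`` switches to the Firth-penalized fit, whose
    estimates stay finite under separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    _check_inputs(y, X)
    if firth:
        return _fit_firth(y, X, maxiter=max(maxiter, 200), tol=tol)
    p = X.shape[1]
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        separated = any(
            issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning))
            for w in caught
        )
        coefficients = np.asarray(res.params, dtype=float)
        standard_errors = np.asarray(res.bse, dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
        n_iter = int(res.mle_retvals.get("iterations", 0))
        llf = float(res.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(
            coefficients=np.full(p, np.nan),
            standard_errors=np.full(p, np.nan),
            converged=False,
            n_iterations=maxiter,
            log_likelihood=math.nan,
            n_used=len(y),
            separated=True,
        )
    if (
        not np.isfinite(standard_errors).all()
        or np.abs(coefficients).max() > _SEPARATION_COEF_BOUND
        or standard_errors.max() > _SEPARATION_SE_BOUND
    ):
        separated = True
    return LogisticFit(
        coefficients=coefficients,
        standard_errors=standard_errors,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=llf,
        n_used=len(y),
        separated=separated,
    )


def _penalized_llf(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    mu = expit(eta)
    llf = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    W = mu * (1 - mu)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    return llf + 0.5 * logdet if sign > 0 else -math.inf


def _fit_firth(
    y: np.ndarray, X: np.ndarray, maxiter: int = 200, tol: float = 1e-8
) -> LogisticFit:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    The modified score adds h_i(1/2 − μ_i) per observation, h the hat
    diagonal; the penalized MLE exists even under complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pll = _penalized_llf(y, X, beta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat diagonal: h_i = w_i x_i' info^{-1} x_i
        h = W * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # step-halving keeps the penalized likelihood non-decreasing
        for _ in range(20):
            new_beta = beta + step
            new_pll = _penalized_llf(y, X, new_beta)
            if new_pll >= pll - 1e-12:
                break
            step = step / 2.0
        rel = np.max(np.abs(new_beta - beta) / (np.abs(beta) + 1.0))
        beta, pll = new_beta, new_pll
        if rel < tol:
            converged = True
            break
    mu = expit(X @ beta)
    W = mu * (1 - mu)
    info = X.T @ (X * W[:, None])
    standard_errors = np.sqrt(np.diag(np.linalg.inv(info)))
    return LogisticFit(
        coefficients=beta,
        standard_errors=standard_errors,
        converged=converged,
        n_iterations=it,
        log_likelihood=pll,
        n_used=n,
        separated=False,
        method="firth",
    )


# ---------------------------------------------------------------------------
# Association grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    rsid_or_marker: str
    outcome: str
    stratum: str
    n_used: int
    n_events: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    covariates: tuple[str, ...]
    estimable: bool
    note: str = ""
    method: str = "newton-mle"


def stratum_members(cohort: Cohort, stratum: str, policy: str = "both"):
    """Subjects belonging to an analysis stratum.

    ``policy`` decides where combination-therapy (AZA+MTX) subjects go:
    ``"both"`` places them in both the AZA and MTX strata (never in
    Other); ``"exclusive"`` places them in no single-drug stratum.
    """
    if policy not in ("both", "exclusive"):
        raise ValidationError("stratum policy must be 'both' or 'exclusive'")
    if stratum == "all":
        return list(cohort.subjects)
    if stratum in ("AZA", "MTX"):
        allowed = {stratum} | ({"AZA+MTX"} if policy == "both" else set())
        return [s for s in cohort.subjects if s.therapy in allowed]
    if stratum == "Other":
        return [s for s in cohort.subjects if s.therapy == "Other"]
    raise ValidationError(f"unknown stratum {stratum!r}; valid: {STRATA}")


def _not_estimable(
    marker: str, outcome: str, stratum: str, adjust: bool, n_used: int,
    n_events: int, note: str, covariates: tuple[str, ...],
) -> AssociationResult:
    return AssociationResult(
        rsid_or_marker=marker,
        outcome=outcome,
        stratum=stratum,
        n_used=n_used,
        n_events=n_events,
        odds_ratio=math.nan,
        ci_low=math.nan,
        ci_high=math.nan,
        p_value=math.nan,
        adjusted=adjust,
        covariates=covariates,
        estimable=False,
        note=note,
    )


def odds_ratio_for_cell(
    cohort: Cohort,
    marker: str,
    outcome: str,
    stratum: str,
    adjust: bool,
    policy: str = "both",
    firth: bool = False,
) -> AssociationResult:
    """One cell of the association grid.

    Exposure is the dominant genotype code; the adjusted model adds age
    (years) and sex (male indicator, female referent).  OR = exp(β̂),
    95% CI = exp(β̂ ± z₀.₉₇₅·SE), p two-sided Wald.
    """
    covariates = ("age_years", "sex_male") if adjust else ()
    members = stratum_members(cohort, stratum, policy)
    codes = cohort.dominant_codes(marker)
    rows = [
        s
        for s in members
        if s.subject_id in codes and (not adjust or s.age_years is not None)
    ]
    n_used = len(rows)
    if n_used == 0:
        return _not_estimable(
            marker, outcome, stratum, adjust, 0, 0,
            "empty stratum after completeness filtering", covariates,
        )
    y = np.array([1.0 if s.outcomes.get(outcome) else 0.0 for s in rows])
    x = np.array([float(codes[s.subject_id]) for s in rows])
    n_events = int(y.sum())
    if n_events == 0:
        return _not_estimable(
            marker, outcome, stratum, adjust, n_used, 0, "no events", covariates
        )
    if n_events == n_used:
        return _not_estimable(
            marker, outcome, stratum, adjust, n_used, n_events,
            "all subjects experienced the outcome", covariates,
        )
    if x.min() == x.max():
        return _not_estimable(
            marker, outcome, stratum, adjust, n_used, n_events,
            "no genotype variation in stratum", covariates,
        )
    cols = [np.ones(n_used), x]
    if adjust:
        cols.append(np.array([float(s.age_years) for s in rows]))
        cols.append(np.array([1.0 if s.sex == "male" else 0.0 for s in rows]))
    X = np.column_stack(cols)
    fit = fit_logistic(y, X)
    note = ""
    if fit.separated:
        if firth:
            fit = fit_logistic(y, X, firth=True)
            note = "separation: Firth-penalized estimate"
        else:
            return _not_estimable(
                marker, outcome, stratum, adjust, n_used, n_events,
                "perfect separation: MLE not finite", covariates,
            )
    b = float(fit.coefficients[1])
    se = float(fit.standard_errors[1])
    z = b / se
    return AssociationResult(
        rsid_or_marker=marker,
        outcome=outcome,
        stratum=stratum,
        n_used=n_used,
        n_events=n_events,
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - Z975 * se)),
        ci_high=float(np.exp(b + Z975 * se)),
        p_value=float(2.0 * norm.sf(abs(z))),
        adjusted=adjust,
        covariates=covariates,
        estimable=True,
        note=note,
        method=fit.method,
    )


def run_association_grid(
    cohort: Cohort,
    markers: Optional[Sequence[str]] = None,
    outcomes: Sequence[str] = OUTCOME_NAMES,
    strata: Sequence[str] = STRATA,
    policy: str = "both",
    firth: bool = False,
) -> list[AssociationResult]:
    """The complete grid: one unadjusted and one adjusted result per
    marker × outcome × stratum, in deterministic order."""
    markers = list(markers) if markers is not None else cohort.rsids
    results: list[AssociationResult] = []
    for marker in markers:
        for outcome in outcomes:
            for stratum in strata:
                for adjust in (False, True):
                    results.append(
                        odds_ratio_for_cell(
                            cohort, marker, outcome, stratum, adjust,
                            policy=policy, firth=firth,
                        )
                    )
    return results


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Tabular grid with a supplementary Benjamini-Hochberg column.

    The primary inference is unadjusted for multiplicity (per-cell alpha);
    ``p_bh`` is emitted as clearly-labeled supplementary output, computed
    within each adjustment level across estimable cells.
    """
    rows = [
        {
            "marker": r.rsid_or_marker,
            "outcome": r.outcome,
            "stratum": r.stratum,
            "adjusted": r.adjusted,
            "covariates": "+".join(r.covariates),
            "n_used": r.n_used,
            "n_events": r.n_events,
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "estimable": r.estimable,
            "method": r.method,
            "note": r.note,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df["p_bh"] = np.nan
    for adj in (False, True):
        mask = (df["adjusted"] == adj) & df["estimable"]
        if mask.any():
            df.loc[mask, "p_bh"] = multipletests(
                df.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    return df


def _sig6(v: float) -> float:
    return float(f"{v:.6g}")


def forest_plot_data(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Estimable cells in forest-plot layout (OR, CI whiskers, null line).

    Values are rounded to 6 significant digits, enough to round-trip
    through text without visible loss.
    """
    rows = [
        {
            "marker": r.rsid_or_marker,
            "outcome": r.outcome,
            "stratum": r.stratum,
            "adjusted": r.adjusted,
            "odds_ratio": _sig6(r.odds_ratio),
            "ci_low": _sig6(r.ci_low),
            "ci_high": _sig6(r.ci_high),
            "null_line": 1.0,
        }
        for r in results
        if r.estimable
    ]
    columns = [
        "marker", "outcome", "stratum", "adjusted",
        "odds_ratio", "ci_low", "ci_high", "null_line",
    ]
    return pd.DataFrame(rows, columns=columns)
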