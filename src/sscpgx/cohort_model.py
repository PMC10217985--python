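"""Domain model for a pharmacogenetic outcome cohort.

A cohort is a set of subjects (sex, age, therapy group, five binary
disease-outcome flags) together with genotype calls at a small panel of
candidate pharmacovariants.  This module holds the domain types plus the
genotype-level QC and summary machinery:

* allele frequencies and Hardy-Weinberg equilibrium chi-square QC,
* dominant-model genotype coding (normal-function homozygotes are the
  referent, carriers of one or two minor alleles are the exposed group),
* collapse of a perfectly concordant variant pair into a single haplotype
  marker (e.g. two TPMT variants that always travel together as *3A),
* derivation of threshold outcomes from raw measurements
  (RVSP > 35 mmHg, FVC/DLCO > 1.6),
* therapy-group cohort summaries with chi-square / Fisher-exact
  between-group tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

OUTCOME_NAMES: tuple[str, ...] = (
    "pf",
    "kidney_insufficiency",
    "rvsp_high",
    "huv",
    "fvc_dlco_high",
)
THERAPY_GROUPS: tuple[str, ...] = ("AZA", "MTX", "AZA+MTX", "Other")
#: Analysis strata: the whole cohort plus the three therapy strata of interest.
STRATA: tuple[str, ...] = ("all", "AZA", "MTX", "Other")

RVSP_THRESHOLD_MMHG = 35.0
FVC_DLCO_THRESHOLD = 1.6


class CohortError(Exception):
    """Base class for cohort-model errors."""


class PanelError(CohortError):
    """An rsid was not found in the variant panel."""


class EmptyDataError(CohortError):
    """An operation was asked to run on no data."""


class MissingGenotypeError(CohortError):
    """A genotype call required by an operation is missing."""


class ConsistencyError(CohortError):
    """Raw measurement and pre-derived flag contradict each other."""


class ValidationError(CohortError):
    """An input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A candidate pharmacovariant.

    ``major_allele`` is the allele associated with normal enzymatic
    function (the referent allele of the dominant model), ``beta`` the
    non-negative GWAS effect weight toward reduced enzymatic efficiency
    used by the polygenic risk score.
    """

    rsid: str
    gene: str
    major_allele: str
    minor_allele: str
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValidationError(
                f"{self.rsid}: major and minor allele must differ"
            )
        if self.beta < 0:
            raise ValidationError(
                f"{self.rsid}: beta must be non-negative (got {self.beta}); "
                "beta measures impact toward reduced enzymatic efficiency"
            )


@dataclass(frozen=True)
class GenotypeCall:
    """One subject's genotype at one variant, as a minor-allele count."""

    subject_id: str
    rsid: str
    minor_allele_count: Optional[int]

    def __post_init__(self) -> None:
        if self.minor_allele_count is not None and self.minor_allele_count not in (0, 1, 2):
            raise ValidationError(
                f"minor_allele_count must be 0, 1, 2 or missing "
                f"(got {self.minor_allele_count} for {self.subject_id}/{self.rsid})"
            )

    @property
    def is_missing(self) -> bool:
        return self.minor_allele_count is None


@dataclass(frozen=True)
class OutcomeFlags:
    """The five binary severe-outcome flags followed per subject."""

    pf: bool
    kidney_insufficiency: bool
    rvsp_high: bool
    huv: bool
    fvc_dlco_high: bool

    def get(self, name: str) -> bool:
        if name not in OUTCOME_NAMES:
            raise ValidationError(f"unknown outcome {name!r}; valid: {OUTCOME_NAMES}")
        return getattr(self, name)


@dataclass(frozen=True)
class Subject:
    """A cohort subject. ``age_years`` may be None (excluded from adjusted
    models only)."""

    subject_id: str
    sex: str  # "female" | "male"
    age_years: Optional[float]
    therapy: str
    outcomes: OutcomeFlags

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.therapy not in THERAPY_GROUPS:
            raise ValidationError(
                f"therapy must be one of {THERAPY_GROUPS}, got {self.therapy!r}"
            )
        if self.age_years is not None and not self.age_years > 0:
            raise ValidationError(f"age_years must be positive, got {self.age_years}")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts: normal-function homozygote / het / minor homozygote."""

    n_major_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self) -> None:
        if min(self.n_major_hom, self.n_het, self.n_minor_hom) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom


@dataclass
class Cohort:
    """Subjects + genotype calls + variant panel."""

    subjects: list[Subject]
    genotypes: dict[tuple[str, str], GenotypeCall]
    panel: list[Variant]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_id(s): {dupes}")
        rsids = [v.rsid for v in self.panel]
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsid in panel")
        known_sid = set(ids)
        known_rsid = set(rsids)
        for (sid, rsid), call in self.genotypes.items():
            if sid not in known_sid:
                raise ValidationError(f"genotype references unknown subject {sid!r}")
            if rsid not in known_rsid:
                raise ValidationError(f"genotype references unknown rsid {rsid!r}")
            if (call.subject_id, call.rsid) != (sid, rsid):
                raise ValidationError(f"genotype key/call mismatch at ({sid}, {rsid})")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.panel]

    def variant(self, rsid: str) -> Variant:
        for v in self.panel:
            if v.rsid == rsid:
                return v
        raise PanelError(f"rsid {rsid!r} not in panel {self.rsids}")

    def call(self, subject_id: str, rsid: str) -> Optional[GenotypeCall]:
        return self.genotypes.get((subject_id, rsid))

    def calls_for(self, rsid: str) -> dict[str, GenotypeCall]:
        """Non-missing calls at ``rsid``, keyed by subject_id."""
        self.variant(rsid)
        return {
            s.subject_id: c
            for s in self.subjects
            if (c := self.genotypes.get((s.subject_id, rsid))) is not None
            and not c.is_missing
        }

    def genotype_counts(self, rsid: str) -> GenotypeCounts:
        calls = self.calls_for(rsid)
        counts = [0, 0, 0]
        for c in calls.values():
            counts[c.minor_allele_count] += 1
        return GenotypeCounts(*counts)

    def dominant_codes(self, rsid: str) -> dict[str, int]:
        """Dominant-model exposure codes for subjects with a non-missing call."""
        return {sid: dominant_code(c) for sid, c in self.calls_for(rsid).items()}


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleFrequencies:
    minor_freq: float
    major_freq: float
    counts: GenotypeCounts


def allele_frequencies(cohort: Cohort, rsid: str) -> AlleleFrequencies:
    """Observed allele frequencies at ``rsid``, missing calls excluded."""
    counts = cohort.genotype_counts(rsid)
    n_called = counts.total
    if n_called == 0:
        raise EmptyDataError(f"no non-missing genotype calls at {rsid}")
    minor = (counts.n_het + 2 * counts.n_minor_hom) / (2 * n_called)
    return AlleleFrequencies(minor_freq=minor, major_freq=1.0 - minor, counts=counts)


@dataclass(frozen=True)
class HWETestResult:
    chi2: float
    df: int
    p: float


def hwe_chi_square(counts: GenotypeCounts) -> HWETestResult:
    """Hardy-Weinberg equilibrium goodness-of-fit chi-square.

    Expected genotype counts are taken from the observed allele frequency
    p̂: (n·p̂², 2n·p̂q̂, n·q̂²).  The statistic sums (obs − exp)²/exp over
    classes with positive expectation and is referred to chi-square with
    one degree of freedom (three classes, one estimated allele frequency).
    """
    n = counts.total
    if n == 0:
        raise EmptyDataError("cannot test HWE on zero genotype counts")
    q = (counts.n_het + 2 * counts.n_minor_hom) / (2 * n)
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_major_hom, counts.n_het, counts.n_minor_hom)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
    return HWETestResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))


def dominant_code(call: GenotypeCall) -> int:
    """Dominant-model exposure: 0 for normal-function homozygotes (referent),
    1 for carriers of one or two minor alleles."""
    if call is None or call.is_missing:
        raise MissingGenotypeError(
            "cannot code a missing genotype call; exclude the subject from "
            "this variant's analyses instead of imputing"
        )
    return 0 if call.minor_allele_count == 0 else 1


# ---------------------------------------------------------------------------
# Perfect-LD collapse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDCollapse:
    concordant: bool
    marker_name: Optional[str]
    n_overlap: int
    note: str = ""


def collapse_perfect_ld(
    cohort: Cohort,
    rsid_a: str,
    rsid_b: str,
    marker_name: Optional[str] = None,
) -> LDCollapse:
    """Check whether two panel variants are perfectly concordant under
    dominant coding and, if so, name a merged haplotype marker.

    Every subject with non-missing calls at both loci must carry the same
    dominant code at both.  With zero overlapping calls concordance is
    vacuous, so the merge is refused with a warning: perfect LD cannot be
    asserted from no data.
    """
    var_a = cohort.variant(rsid_a)
    cohort.variant(rsid_b)
    codes_a = cohort.dominant_codes(rsid_a)
    codes_b = cohort.dominant_codes(rsid_b)
    overlap = sorted(set(codes_a) & set(codes_b))
    if not overlap:
        warnings.warn(
            f"no subjects with calls at both {rsid_a} and {rsid_b}; "
            "perfect-LD merge refused",
            stacklevel=2,
        )
        return LDCollapse(
            concordant=True,
            marker_name=None,
            n_overlap=0,
            note="vacuous concordance: no overlapping calls, merge refused",
        )
    for sid in overlap:
        if codes_a[sid] != codes_b[sid]:
            return LDCollapse(
                concordant=False,
                marker_name=None,
                n_overlap=len(overlap),
                note=f"discordant dominant codes (e.g. subject {sid})",
            )
    name = marker_name or f"{var_a.gene}*haplotype"
    return LDCollapse(concordant=True, marker_name=name, n_overlap=len(overlap))


def apply_ld_collapse(
    cohort: Cohort,
    rsid_a: str,
    rsid_b: str,
    marker_name: Optional[str] = None,
) -> tuple[Cohort, LDCollapse]:
    """Replace a perfectly concordant variant pair by one merged marker.

    The merged marker inherits gene, alleles and beta from the first
    member; per subject the call at ``rsid_a`` is used, falling back to
    ``rsid_b`` when only the second is called.  If the pair is discordant
    or the concordance is vacuous, the cohort is returned unchanged.
    """
    result = collapse_perfect_ld(cohort, rsid_a, rsid_b, marker_name)
    if not result.concordant or result.marker_name is None:
        return cohort, result
    var_a = cohort.variant(rsid_a)
    merged = Variant(
        rsid=result.marker_name,
        gene=var_a.gene,
        major_allele=var_a.major_allele,
        minor_allele=var_a.minor_allele,
        beta=var_a.beta,
    )
    new_panel = [v for v in cohort.panel if v.rsid not in (rsid_a, rsid_b)]
    new_panel.append(merged)
    new_genotypes: dict[tuple[str, str], GenotypeCall] = {
        k: c for k, c in cohort.genotypes.items() if k[1] not in (rsid_a, rsid_b)
    }
    for s in cohort.subjects:
        call = cohort.call(s.subject_id, rsid_a) or cohort.call(s.subject_id, rsid_b)
        if call is not None:
            new_genotypes[(s.subject_id, merged.rsid)] = GenotypeCall(
                subject_id=s.subject_id,
                rsid=merged.rsid,
                minor_allele_count=call.minor_allele_count,
            )
    return Cohort(list(cohort.subjects), new_genotypes, new_panel), result


# ---------------------------------------------------------------------------
# Outcome derivation
# ---------------------------------------------------------------------------


def _derive_threshold(
    raw: Mapping[str, object],
    value_key: str,
    flag_key: str,
    derive,
) -> bool:
    value = raw.get(value_key)
    flag = raw.get(flag_key)
    if value is not None:
        derived = derive(value)
        if flag is not None and bool(flag) != derived:
            raise ConsistencyError(
                f"{flag_key}={flag} contradicts {value_key}={value!r}"
            )
        return derived
    if flag is None:
        raise ValidationError(
            f"need either {value_key} or {flag_key} to derive the outcome"
        )
    return bool(flag)


def derive_outcomes(raw: Mapping[str, object]) -> OutcomeFlags:
    """Build the five outcome flags from raw measurements and/or pre-derived
    booleans.

    Thresholds use strict inequalities: RVSP elevated when > 35 mmHg,
    FVC/DLCO ratio flagged when > 1.6.  A raw value contradicting a
    supplied flag raises :class:`ConsistencyError`.
    """
    for k in ("pf", "kidney_insufficiency", "huv"):
        if raw.get(k) is None:
            raise ValidationError(f"outcome flag {k!r} is required")
    rvsp_high = _derive_threshold(
        raw, "rvsp_mmHg", "rvsp_high", lambda v: float(v) > RVSP_THRESHOLD_MMHG
    )

    fvc = raw.get("fvc")
    dlco = raw.get("dlco")
    if (fvc is None) != (dlco is None):
        raise ValidationError("fvc and dlco must be supplied together")
    if fvc is not None and float(dlco) == 0.0:
        raise ValidationError("dlco must be nonzero to form the FVC/DLCO ratio")
    flag = raw.get("fvc_dlco_high")
    if fvc is not None:
        derived = float(fvc) / float(dlco) > FVC_DLCO_THRESHOLD
        if flag is not None and bool(flag) != derived:
            raise ConsistencyError(
                f"fvc_dlco_high={flag} contradicts fvc/dlco="
                f"{float(fvc) / float(dlco):.3f}"
            )
        fvc_dlco_high = derived
    elif flag is not None:
        fvc_dlco_high = bool(flag)
    else:
        raise ValidationError("need either fvc+dlco or fvc_dlco_high")

    return OutcomeFlags(
        pf=bool(raw["pf"]),
        kidney_insufficiency=bool(raw["kidney_insufficiency"]),
        rvsp_high=rvsp_high,
        huv=bool(raw["huv"]),
        fvc_dlco_high=fvc_dlco_high,
    )


# ---------------------------------------------------------------------------
# Cohort summary (therapy-group demographics table)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    n: int
    pct: float  # % of the FULL cohort
    n_women: int
    pct_women: float  # % of the FULL cohort
    age_median: float
    age_q1: float
    age_q3: float
    outcome_counts: Mapping[str, int]
    outcome_pct: Mapping[str, float]  # % of the FULL cohort


@dataclass(frozen=True)
class Table1Summary:
    total_n: int
    groups: Mapping[str, GroupSummary]
    overall: GroupSummary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in (*THERAPY_GROUPS, "overall"):
            g = self.overall if name == "overall" else self.groups[name]
            row = {
                "group": name,
                "n": g.n,
                "pct": g.pct,
                "n_women": g.n_women,
                "pct_women": g.pct_women,
                "age_median": g.age_median,
                "age_q1": g.age_q1,
                "age_q3": g.age_q3,
            }
            for o in OUTCOME_NAMES:
                row[f"{o}_n"] = g.outcome_counts[o]
                row[f"{o}_pct"] = g.outcome_pct[o]
            rows.append(row)
        return pd.DataFrame(rows)


def _summarize_group(subjects: Sequence[Subject], total_n: int) -> GroupSummary:
    n = len(subjects)
    ages = [s.age_years for s in subjects if s.age_years is not None]
    if ages:
        # linear-interpolation quantiles, the convention matching IQRs
        # reported as non-integers like 53.25
        q1, med, q3 = np.percentile(ages, [25, 50, 75], method="linear")
    else:
        q1 = med = q3 = math.nan
    n_women = sum(1 for s in subjects if s.sex == "female")
    counts = {
        o: sum(1 for s in subjects if s.outcomes.get(o)) for o in OUTCOME_NAMES
    }
    return GroupSummary(
        n=n,
        pct=100.0 * n / total_n,
        n_women=n_women,
        pct_women=100.0 * n_women / total_n,
        age_median=float(med),
        age_q1=float(q1),
        age_q3=float(q3),
        outcome_counts=counts,
        outcome_pct={o: 100.0 * c / total_n for o, c in counts.items()},
    )


def summarize_cohort(cohort: Cohort) -> Table1Summary:
    """Per-therapy-group demographic and outcome summary.

    Percentages use the full cohort size as denominator, so the group
    percentages of any characteristic sum to its whole-cohort percentage.
    """
    if not cohort.subjects:
        raise EmptyDataError("cannot summarize an empty cohort")
    total = cohort.n_subjects
    groups = {
        g: _summarize_group([s for s in cohort.subjects if s.therapy == g], total)
        for g in THERAPY_GROUPS
    }
    return Table1Summary(
        total_n=total,
        groups=groups,
        overall=_summarize_group(cohort.subjects, total),
    )


# ---------------------------------------------------------------------------
# Between-group tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p: float
    method: str  # "chi-square" | "fisher-exact" | "degenerate"
    table: np.ndarray
    note: str = ""


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×k table by full enumeration.

    Enumerates all tables with the observed margins; the p-value sums the
    conditional (multivariate hypergeometric) probabilities of tables as
    or less probable than the observed one.  Reduces to the standard
    two-sided 2×2 Fisher exact test at k = 2.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ValidationError("fisher_exact_2xk requires a 2×k table")
    r0 = int(t[0].sum())
    cols = t.sum(axis=0).astype(int)
    n = int(t.sum())
    k = len(cols)
    log_denom = _log_binom(n, r0)
    log_obs = sum(_log_binom(cols[j], t[0, j]) for j in range(k)) - log_denom
    tol = 1e-7 * abs(log_obs) + 1e-9

    total = 0.0

    def rec(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                lp = acc + _log_binom(cols[j], remaining) - log_denom
                if lp <= log_obs + tol:
                    total += math.exp(lp)
            return
        tail = int(cols[j + 1 :].sum())
        lo = max(0, remaining - tail)
        hi = min(cols[j], remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, acc + _log_binom(cols[j], x))

    rec(0, r0, 0.0)
    return min(total, 1.0)


def group_difference_test(
    summary: Table1Summary, characteristic: str
) -> GroupTestResult:
    """Chi-square / Fisher-exact test of a binary characteristic across
    therapy groups.

    The chi-square test (no continuity correction) is used when every
    expected cell count is at least 5; otherwise the Fisher exact test
    (full enumeration for 2×k).  A degenerate table (zero margin) is
    reported as p = 1 with a note.
    """
    if characteristic == "sex":
        yes = np.array([summary.groups[g].n_women for g in THERAPY_GROUPS])
    elif characteristic in OUTCOME_NAMES:
        yes = np.array(
            [summary.groups[g].outcome_counts[characteristic] for g in THERAPY_GROUPS]
        )
    else:
        raise ValidationError(
            f"characteristic must be 'sex' or one of {OUTCOME_NAMES}"
        )
    ns = np.array([summary.groups[g].n for g in THERAPY_GROUPS])
    table = np.vstack([yes, ns - yes])
    # drop empty therapy groups (zero column margin carries no information)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return GroupTestResult(
            statistic=math.nan,
            p=1.0,
            method="degenerate",
            table=table,
            note="degenerate table (zero margin); no between-group contrast",
        )
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupTestResult(float(chi2), float(p), "chi-square", table)
    if table.shape[1] == 2:
        res = stats.fisher_exact(table, alternative="two-sided")
        return GroupTestResult(float(res[0]), float(res[1]), "fisher-exact", table)
    if table.sum() <= 500:
        return GroupTestResult(
            math.nan, fisher_exact_2xk(table), "fisher-exact", table
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    warnings.warn(
        "expected cell < 5 but table too large for exact enumeration; "
        "falling back to chi-square",
        stacklevel=2,
    )
    return GroupTestResult(
        float(chi2), float(p), "chi-square", table, note="exact test infeasible"
    )
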