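"""Synthetic cohort generator with known ground truth.

Generates cohorts with the statistical structure the analysis modules
assume: genotypes in Hardy-Weinberg equilibrium, an optional perfectly
concordant variant pair (one latent haplotype realized at both loci,
emulating TPMT*3A), demographics (sex, truncated-normal age, categorical
therapy assignment), and five binary outcomes drawn from a forward
logistic model with planted dominant-model log-odds-ratios plus age and
sex effects.  The returned :class:`GroundTruth` echoes the generative
parameters next to the realized frequencies so parameter-recovery tests
can compare estimate against truth.

The default configuration emulates the motivating 102-patient systemic
sclerosis cohort: ~85% women, median age 59.5 (IQR 53.25–63), therapy
arms AZA/MTX/AZA+MTX/Other in shares 16/43/3/40, a four-variant panel
with the two TPMT variants in perfect LD, European-like minor-allele
frequencies, outcome prevalences between ~6% and ~38%, and planted
genotype effects in the published 0.6–2.1 odds-ratio range.

All randomness flows through one explicitly seeded NumPy PCG64
generator; a fixed seed yields bit-identical cohorts and fixture files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort_model import (
    Cohort,
    GenotypeCall,
    OutcomeFlags,
    OUTCOME_NAMES,
    Subject,
    THERAPY_GROUPS,
    ValidationError,
    Variant,
)
from .prs import WeightSet

_Z75 = float(norm.ppf(0.75))  # 0.6744897…, converts an IQR to a normal sd
_MIN_ADULT_AGE = 18.0

#: Genomic coordinates used when writing VCF fixtures (GRCh38-like, only
#: needed so emitted files are structurally valid VCF).
VARIANT_LOCI: dict[str, tuple[str, int]] = {
    "rs1800460": ("6", 18139228),
    "rs1142345": ("6", 18130918),
    "rs1801133": ("1", 11796321),
    "rs4149056": ("12", 21178615),
}


@dataclass(frozen=True)
class OutcomeModel:
    """Forward logistic model for one outcome.

    P(outcome) = expit(intercept + Σ log_or·dominant_code
                       + log_or_age_per_year·age + log_or_male·male).
    """

    intercept: float
    log_or_per_marker: Mapping[str, float] = field(default_factory=dict)
    log_or_age_per_year: float = 0.0
    log_or_male: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int
    panel: tuple[Variant, ...]
    minor_freqs: Mapping[str, float]
    outcome_models: Mapping[str, OutcomeModel]
    ld_pairs: tuple[tuple[str, str], ...] = ()
    female_fraction: float = 0.5
    age_median: float = 60.0
    age_iqr: tuple[float, float] = (50.0, 70.0)
    therapy_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.therapy_probs) - 1.0) > 1e-12:
            raise ValidationError("therapy_probs must sum to 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValidationError("female_fraction must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        rsids = {v.rsid for v in self.panel}
        for rsid, f in self.minor_freqs.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"minor_freq for {rsid} must lie in [0, 1]")
        for rsid in rsids:
            if rsid not in self.minor_freqs:
                raise ValidationError(f"no minor_freq configured for {rsid}")
        for a, b in self.ld_pairs:
            if a not in rsids or b not in rsids:
                raise ValidationError(f"ld_pair ({a}, {b}) references unknown rsid")
        missing = [o for o in OUTCOME_NAMES if o not in self.outcome_models]
        if missing:
            raise ValidationError(f"outcome_models missing for {missing}")
        for name, m in self.outcome_models.items():
            for rsid in m.log_or_per_marker:
                if rsid not in rsids:
                    raise ValidationError(
                        f"outcome model {name!r} references unknown marker {rsid!r}"
                    )


@dataclass(frozen=True)
class GroundTruth:
    config: SimulationConfig
    realized_minor_freqs: Mapping[str, float]
    realized_prevalences: Mapping[str, float]
    generator: str = "numpy.random.Generator(PCG64)"

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def default_panel() -> tuple[Variant, ...]:
    """The four-variant thiopurine/folate/transporter panel.

    β weights are an illustrative, non-authoritative example set
    (relative ordering: the TPMT haplotype variants impair enzyme
    activity most strongly, the transporter variant moderately, the
    MTHFR variant least); real analyses should supply GWAS-derived
    weights through the panel/weights configuration.
    """
    return (
        Variant("rs1800460", "TPMT", "G", "A", beta=0.9),
        Variant("rs1142345", "TPMT", "A", "G", beta=0.9),
        Variant("rs1801133", "MTHFR", "C", "T", beta=0.3),
        Variant("rs4149056", "SLCO1B1", "T", "C", beta=0.45),
    )


def example_weights(collapsed_marker: Optional[str] = "TPMT*haplotype") -> WeightSet:
    """Example (non-authoritative) weight set matching :func:`default_panel`.

    When the TPMT pair is collapsed, the merged marker carries the TPMT
    weight; otherwise both member rsids do.
    """
    weights = {"rs1801133": 0.3, "rs4149056": 0.45}
    if collapsed_marker:
        weights[collapsed_marker] = 0.9
    else:
        weights["rs1800460"] = 0.9
        weights["rs1142345"] = 0.9
    return WeightSet(weights)


def _intercept_for(prev: float, age_coef: float, male_coef: float,
                   age_median: float, female_fraction: float) -> float:
    # offsets the covariate contribution at typical covariate values so the
    # marginal prevalence stays near the target
    return float(
        logit(prev) - age_coef * age_median - male_coef * (1.0 - female_fraction)
    )


def study_like_config(seed: int = 0, n_subjects: int = 102, **overrides) -> SimulationConfig:
    """The default study-like configuration (see module docstring)."""
    female_fraction = 87 / 102
    age_median = 59.5
    age_coef, male_coef = 0.02, 0.3
    prevalences = {
        "pf": 39 / 102,
        "kidney_insufficiency": 28 / 102,
        "rvsp_high": 22 / 102,
        "huv": 31 / 102,
        "fvc_dlco_high": 6 / 102,
    }
    # planted dominant-model effects in the published OR range (0.6–2.1)
    marker_effects = {
        "pf": {"rs4149056": math.log(0.66)},
        "kidney_insufficiency": {
            "rs1801133": math.log(0.74),
            "rs4149056": math.log(0.77),
        },
        "rvsp_high": {"rs1801133": math.log(1.45), "rs1800460": math.log(2.11)},
        "huv": {"rs4149056": math.log(1.11)},
        "fvc_dlco_high": {},
    }
    outcome_models = {
        name: OutcomeModel(
            intercept=_intercept_for(
                prevalences[name], age_coef, male_coef, age_median, female_fraction
            ),
            log_or_per_marker=marker_effects[name],
            log_or_age_per_year=age_coef,
            log_or_male=male_coef,
        )
        for name in OUTCOME_NAMES
    }
    config = dict(
        n_subjects=n_subjects,
        panel=default_panel(),
        minor_freqs={
            "rs1800460": 0.032,
            "rs1142345": 0.032,
            "rs1801133": 0.365,
            "rs4149056": 0.16,
        },
        outcome_models=outcome_models,
        ld_pairs=(("rs1800460", "rs1142345"),),
        female_fraction=female_fraction,
        age_median=age_median,
        age_iqr=(53.25, 63.0),
        therapy_probs=(16 / 102, 43 / 102, 3 / 102, 40 / 102),
        missing_rate=0.0,
        seed=seed,
    )
    config.update(overrides)
    return SimulationConfig(**config)


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Simulation stages
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Minor-allele-count table (subjects × rsids) under HWE.

    Independent variants draw two Bernoulli(minor_freq) alleles; each LD
    pair is realized from one latent haplotype genotype copied to both
    member loci, so dominant codes (indeed full genotypes) agree exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    ld_followers = {b: a for a, b in config.ld_pairs}
    data: dict[str, np.ndarray] = {}
    for v in config.panel:
        if v.rsid in ld_followers:
            continue  # filled from the pair leader below
        q = config.minor_freqs[v.rsid]
        data[v.rsid] = rng.binomial(1, q, size=n) + rng.binomial(1, q, size=n)
    for follower, leader in ld_followers.items():
        data[follower] = data[leader].copy()
    df = pd.DataFrame(data, index=_subject_ids(n))
    return df[[v.rsid for v in config.panel]]


def simulate_covariates(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Subject table: sex, age (truncated normal), therapy assignment."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    female = rng.random(n) < config.female_fraction
    q1, q3 = config.age_iqr
    sd = (q3 - q1) / (2 * _Z75)
    age = rng.normal(config.age_median, sd, size=n)
    while True:  # resample below the adult truncation bound
        under = age < _MIN_ADULT_AGE
        if not under.any():
            break
        age[under] = rng.normal(config.age_median, sd, size=int(under.sum()))
    therapy_idx = rng.choice(len(THERAPY_GROUPS), size=n, p=config.therapy_probs)
    return pd.DataFrame(
        {
            "sex": np.where(female, "female", "male"),
            "age_years": np.round(age, 6),
            "therapy": [THERAPY_GROUPS[i] for i in therapy_idx],
        },
        index=_subject_ids(n),
    )


def simulate_outcomes(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Independent Bernoulli draws per outcome from the forward logistic
    model on dominant codes, age and sex."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    male = (covariates["sex"] == "male").to_numpy(dtype=float)
    age = covariates["age_years"].to_numpy(dtype=float)
    out: dict[str, np.ndarray] = {}
    for name in OUTCOME_NAMES:
        m = config.outcome_models[name]
        lp = np.full(len(covariates), m.intercept, dtype=float)
        for rsid, log_or in m.log_or_per_marker.items():
            code = (genotypes[rsid].to_numpy() > 0).astype(float)
            lp += log_or * code
        lp += m.log_or_age_per_year * age + m.log_or_male * male
        if not np.isfinite(lp).all():
            raise ValidationError(f"non-finite linear predictor for {name!r}")
        out[name] = rng.random(len(lp)) < expit(lp)
    return pd.DataFrame(out, index=covariates.index)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Assemble a full cohort and its ground truth from one seeded stream.

    ``missing_rate`` knocks out genotype calls completely at random
    (MCAR) after simulation.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    covariates = simulate_covariates(config, rng)
    outcomes = simulate_outcomes(genotypes, covariates, config, rng)

    calls: dict[tuple[str, str], GenotypeCall] = {}
    for rsid in genotypes.columns:
        counts = genotypes[rsid].to_numpy()
        missing = (
            rng.random(len(counts)) < config.missing_rate
            if config.missing_rate > 0
            else np.zeros(len(counts), dtype=bool)
        )
        for sid, count, miss in zip(genotypes.index, counts, missing):
            calls[(sid, rsid)] = GenotypeCall(
                subject_id=sid,
                rsid=rsid,
                minor_allele_count=None if miss else int(count),
            )

    subjects = [
        Subject(
            subject_id=sid,
            sex=str(covariates.loc[sid, "sex"]),
            age_years=float(covariates.loc[sid, "age_years"]),
            therapy=str(covariates.loc[sid, "therapy"]),
            outcomes=OutcomeFlags(
                **{o: bool(outcomes.loc[sid, o]) for o in OUTCOME_NAMES}
            ),
        )
        for sid in covariates.index
    ]
    cohort = Cohort(subjects, calls, list(config.panel))

    realized_freqs = {}
    for rsid in genotypes.columns:
        present = [
            c.minor_allele_count
            for (sid, r), c in calls.items()
            if r == rsid and not c.is_missing
        ]
        realized_freqs[rsid] = (
            float(np.sum(present)) / (2 * len(present)) if present else math.nan
        )
    truth = GroundTruth(
        config=config,
        realized_minor_freqs=realized_freqs,
        realized_prevalences={
            o: float(outcomes[o].mean()) for o in OUTCOME_NAMES
        },
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Fixture writing (interchange formats)
# ---------------------------------------------------------------------------

_GT_STRINGS = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _vcf_text(cohort: Cohort, seed: Optional[int]) -> str:
    sids = [s.subject_id for s in cohort.subjects]
    chroms = []
    for i, v in enumerate(cohort.panel):
        chrom = VARIANT_LOCI.get(v.rsid, ("1", 1000 + i))[0]
        if chrom not in chroms:
            chroms.append(chrom)
    chroms.sort(key=lambda c: int(c) if str(c).isdigit() else 99)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=sscpgx-synthetic{'' if seed is None else f'(seed={seed})'}",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sids),
    ]
    rows = []
    for i, v in enumerate(cohort.panel):
        chrom, pos = VARIANT_LOCI.get(v.rsid, ("1", 1000 + i))
        gts = []
        for sid in sids:
            call = cohort.call(sid, v.rsid)
            count = None if call is None else call.minor_allele_count
            gts.append(_GT_STRINGS[count])
        rows.append(
            (chrom, pos,
             f"{chrom}\t{pos}\t{v.rsid}\t{v.major_allele}\t{v.minor_allele}"
             f"\t.\tPASS\t.\tGT\t" + "\t".join(gts))
        )
    rows.sort(key=lambda r: (int(r[0]) if str(r[0]).isdigit() else 99, r[1]))
    lines.extend(r[2] for r in rows)
    return "\n".join(lines) + "\n"


def _phenotype_text(cohort: Cohort) -> str:
    header = [
        "subject_id", "sex", "age_years", "therapy",
        "pf", "kidney_insufficiency", "rvsp_high", "huv", "fvc_dlco_high",
    ]
    lines = ["\t".join(header)]
    for s in cohort.subjects:
        age = "" if s.age_years is None else repr(float(s.age_years))
        lines.append(
            "\t".join(
                [
                    s.subject_id,
                    "F" if s.sex == "female" else "M",
                    age,
                    s.therapy,
                ]
                + [str(int(s.outcomes.get(o))) for o in OUTCOME_NAMES]
            )
        )
    return "\n".join(lines) + "\n"


def _panel_text(cohort: Cohort, ld_pairs: Sequence[tuple[str, str]] = ()) -> str:
    groups: dict[str, str] = {}
    for i, (a, b) in enumerate(ld_pairs, start=1):
        groups[a] = groups[b] = f"ld{i}"
    lines = ["rsid\tgene\tmajor_allele\tminor_allele\tbeta\tld_group"]
    for v in cohort.panel:
        lines.append(
            f"{v.rsid}\t{v.gene}\t{v.major_allele}\t{v.minor_allele}"
            f"\t{v.beta!r}\t{groups.get(v.rsid, '')}"
        )
    return "\n".join(lines) + "\n"


def write_fixture(
    cohort: Cohort,
    directory: str | Path,
    ground_truth: Optional[GroundTruth] = None,
) -> dict[str, Path]:
    """Write the cohort in the interchange formats the readers consume.

    Emits ``genotypes.vcf`` (VCF v4.2 subset), ``phenotypes.tsv``,
    ``panel.tsv`` and, when ground truth is supplied,
    ``ground_truth.json``.  Output bytes are a pure function of the
    cohort, so a fixed simulation seed reproduces files exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seed = ground_truth.config.seed if ground_truth is not None else None
    ld_pairs = ground_truth.config.ld_pairs if ground_truth is not None else ()
    paths = {
        "genotypes": directory / "genotypes.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "panel": directory / "panel.tsv",
    }
    paths["genotypes"].write_text(_vcf_text(cohort, seed))
    paths["phenotypes"].write_text(_phenotype_text(cohort))
    paths["panel"].write_text(_panel_text(cohort, ld_pairs))
    if ground_truth is not None:
        paths["ground_truth"] = directory / "ground_truth.json"
        paths["ground_truth"].write_text(ground_truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# Deterministic fixed-margin cohort
# ---------------------------------------------------------------------------

_DEFAULT_MARGINS = {
    "group_sizes": {"AZA": 16, "MTX": 43, "AZA+MTX": 3, "Other": 40},
    "n_women": {"AZA": 14, "MTX": 37, "AZA+MTX": 3, "Other": 33},
    "outcome_counts": {
        "pf": {"AZA": 6, "MTX": 14, "AZA+MTX": 0, "Other": 19},
        "kidney_insufficiency": {"AZA": 4, "MTX": 10, "AZA+MTX": 0, "Other": 14},
        "rvsp_high": {"AZA": 2, "MTX": 8, "AZA+MTX": 0, "Other": 12},
        "huv": {"AZA": 7, "MTX": 12, "AZA+MTX": 0, "Other": 12},
        "fvc_dlco_high": {"AZA": 0, "MTX": 4, "AZA+MTX": 0, "Other": 2},
    },
}


def margins_cohort(
    group_sizes: Optional[Mapping[str, int]] = None,
    n_women: Optional[Mapping[str, int]] = None,
    outcome_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
) -> Cohort:
    """Deterministic cohort with exactly the requested per-group margins.

    Within each therapy group the first ``n_women`` subjects are female
    and the first ``count`` subjects carry each outcome, so group counts
    (not joint distributions) are reproduced exactly.  Defaults encode
    the demographic margins of the motivating 102-patient SSc cohort.
    Ages are a deterministic spread around 59.5; genotypes cycle through
    the three genotype classes so every marker has variation.
    """
    group_sizes = dict(group_sizes or _DEFAULT_MARGINS["group_sizes"])
    n_women = dict(n_women or _DEFAULT_MARGINS["n_women"])
    outcome_counts = {
        o: dict((outcome_counts or _DEFAULT_MARGINS["outcome_counts"])[o])
        for o in OUTCOME_NAMES
    }
    panel = default_panel()
    subjects: list[Subject] = []
    calls: dict[tuple[str, str], GenotypeCall] = {}
    idx = 0
    for group in THERAPY_GROUPS:
        size = group_sizes.get(group, 0)
        for j in range(size):
            idx += 1
            sid = f"T{idx:03d}"
            flags = {o: j < outcome_counts[o].get(group, 0) for o in OUTCOME_NAMES}
            subjects.append(
                Subject(
                    subject_id=sid,
                    sex="female" if j < n_women.get(group, 0) else "male",
                    age_years=59.5 + ((idx % 21) - 10) * 0.5,
                    therapy=group,
                    outcomes=OutcomeFlags(**flags),
                )
            )
            for k, v in enumerate(panel):
                count = (idx + k) % 3  # cycles 0/1/2: variation everywhere
                if v.rsid == "rs1142345":  # keep the TPMT pair concordant
                    count = calls[(sid, "rs1800460")].minor_allele_count
                calls[(sid, v.rsid)] = GenotypeCall(sid, v.rsid, count)
    return Cohort(subjects, calls, list(panel))
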