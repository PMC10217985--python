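"""Readers and writers for the pipeline's interchange formats.

Genotypes arrive either as a VCF v4.2 subset (rsID in the ID column,
``GT`` per sample, phased or unphased) or as a tab-separated table of
allele-pair strings like ``G/A`` (``./.`` for missing).  Phenotypes and
the variant panel are tab-separated.  Every emitted table carries
"#"-prefixed provenance header lines (seed, version, config digest) and
stays valid TSV for the package's own readers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .cohort_model import (
    Cohort,
    GenotypeCall,
    OUTCOME_NAMES,
    Subject,
    THERAPY_GROUPS,
    ValidationError,
    Variant,
    derive_outcomes,
)
from .prs import WeightSet

logger = logging.getLogger("sscpgx")

_SEX_LABELS = {"f": "female", "female": "female", "m": "male", "male": "male"}


def read_panel(path: str | Path) -> tuple[list[Variant], list[tuple[str, str]]]:
    """Read the variant panel config; returns (variants, perfect-LD pairs)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"rsid", "gene", "major_allele", "minor_allele", "beta"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel file missing columns: {sorted(missing)}")
    variants = [
        Variant(
            rsid=row["rsid"],
            gene=row["gene"],
            major_allele=row["major_allele"],
            minor_allele=row["minor_allele"],
            beta=float(row["beta"]),
        )
        for _, row in df.iterrows()
    ]
    pairs: list[tuple[str, str]] = []
    if "ld_group" in df.columns:
        groups = df[df["ld_group"].fillna("") != ""].groupby("ld_group")["rsid"]
        for label, members in groups:
            members = list(members)
            if len(members) != 2:
                raise ValidationError(
                    f"ld_group {label!r} must contain exactly two rsids, "
                    f"got {members}"
                )
            pairs.append((members[0], members[1]))
    return variants, pairs


def _count_minor(alleles: Sequence[str], variant: Variant, where: str) -> Optional[int]:
    if all(a in (".", "") for a in alleles):
        return None
    valid = {variant.major_allele, variant.minor_allele}
    bad = [a for a in alleles if a not in valid]
    if bad:
        raise ValidationError(
            f"{where}: allele(s) {bad} at {variant.rsid} do not match panel "
            f"alleles {variant.major_allele}>{variant.minor_allele}"
        )
    return sum(a == variant.minor_allele for a in alleles)


def _read_genotypes_vcf(
    path: Path, panel: Sequence[Variant]
) -> dict[tuple[str, str], GenotypeCall]:
    by_rsid = {v.rsid: v for v in panel}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for record in vcf:
        variant = by_rsid.get(record.ID)
        if variant is None:
            continue
        alts = list(record.ALT)
        file_alleles = {record.REF, *alts}
        panel_alleles = {variant.major_allele, variant.minor_allele}
        if not file_alleles <= panel_alleles:
            raise ValidationError(
                f"VCF alleles {sorted(file_alleles)} at {variant.rsid} do not "
                f"match panel alleles {sorted(panel_alleles)}"
            )
        index_to_base = {0: record.REF, **{i + 1: a for i, a in enumerate(alts)}}
        for sample, gt in zip(samples, record.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                count = None
            else:
                count = sum(
                    index_to_base[i] == variant.minor_allele for i in (a, b)
                )
            calls[(sample, variant.rsid)] = GenotypeCall(sample, variant.rsid, count)
    return calls


def _read_genotypes_tsv(
    path: Path, panel: Sequence[Variant]
) -> dict[tuple[str, str], GenotypeCall]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "subject_id" not in df.columns:
        raise ValidationError("genotype table needs a subject_id column")
    by_rsid = {v.rsid: v for v in panel}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        sid = getattr(row, "subject_id")
        for rsid, variant in by_rsid.items():
            if rsid not in df.columns:
                continue
            raw = getattr(row, rsid)
            raw = "" if pd.isna(raw) else str(raw).strip()
            if raw in ("", ".", "./.", ".|."):
                calls[(sid, rsid)] = GenotypeCall(sid, rsid, None)
                continue
            alleles = re.split(r"[/|]", raw)
            if len(alleles) != 2:
                raise ValidationError(
                    f"line {row_number}: malformed genotype {raw!r} at {rsid}"
                )
            count = _count_minor(alleles, variant, f"line {row_number}")
            calls[(sid, rsid)] = GenotypeCall(sid, rsid, count)
    return calls


def read_genotypes(
    path: str | Path,
    panel: Sequence[Variant],
    fmt: Optional[str] = None,
) -> dict[tuple[str, str], GenotypeCall]:
    """Read genotype calls; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix.lower() == ".vcf" else "tsv")
    if fmt == "vcf":
        return _read_genotypes_vcf(path, panel)
    if fmt == "tsv":
        return _read_genotypes_tsv(path, panel)
    raise ValidationError(f"unknown genotype format {fmt!r} (use 'vcf' or 'tsv')")


def read_phenotypes(path: str | Path) -> list[Subject]:
    """Read the phenotype table; outcomes are derived where raw
    measurements (rvsp_mmHg, fvc, dlco) are supplied instead of flags."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"subject_id", "sex", "therapy"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype file missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
        raise ValidationError(f"duplicate subject_id(s): {dupes}")
    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        sex_raw = str(row["sex"]).strip().lower()
        if sex_raw not in _SEX_LABELS:
            raise ValidationError(
                f"{sid}: unknown sex label {row['sex']!r} "
                "(accepted: F, M, female, male)"
            )
        therapy = str(row["therapy"]).strip()
        if therapy not in THERAPY_GROUPS:
            raise ValidationError(
                f"{sid}: unknown therapy {therapy!r}; valid values: "
                f"{', '.join(THERAPY_GROUPS)}"
            )
        age = row.get("age_years")
        if age is None or pd.isna(age):
            logger.warning(
                "%s: missing age; subject excluded from adjusted models only", sid
            )
            age = None
        else:
            age = float(age)
        raw = {}
        for key in ("pf", "kidney_insufficiency", "huv", "rvsp_high", "fvc_dlco_high"):
            if key in df.columns and not pd.isna(row[key]):
                raw[key] = bool(int(row[key]))
        for key in ("rvsp_mmHg", "fvc", "dlco"):
            if key in df.columns and not pd.isna(row[key]):
                raw[key] = float(row[key])
        subjects.append(
            Subject(
                subject_id=sid,
                sex=_SEX_LABELS[sex_raw],
                age_years=age,
                therapy=therapy,
                outcomes=derive_outcomes(raw),
            )
        )
    return subjects


def read_weights(path: str | Path) -> WeightSet:
    """Read a marker → β weight table (columns: marker, beta)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker": str})
    if not {"marker", "beta"} <= set(df.columns):
        raise ValidationError("weights file needs columns: marker, beta")
    return WeightSet({row["marker"]: float(row["beta"]) for _, row in df.iterrows()})


def panel_weights(panel: Sequence[Variant]) -> WeightSet:
    """Weight set taken from the panel's per-variant β columns."""
    return WeightSet({v.rsid: v.beta for v in panel})


def write_weights(weights: WeightSet, path: str | Path) -> None:
    lines = ["marker\tbeta"]
    lines += [f"{m}\t{b!r}" for m, b in weights.weights.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def build_cohort(
    panel: Sequence[Variant],
    genotypes: dict[tuple[str, str], GenotypeCall],
    subjects: Sequence[Subject],
) -> Cohort:
    known = {s.subject_id for s in subjects}
    genotypes = {k: c for k, c in genotypes.items() if k[0] in known}
    return Cohort(list(subjects), genotypes, list(panel))


def config_digest(payload: dict) -> str:
    """Short stable digest of a run configuration for output provenance."""
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    digest: Optional[str] = None,
    index: bool = False,
) -> Path:
    """Write a TSV with "#"-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# sscpgx {__version__}"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    if digest is not None:
        header.append(f"# config: {digest}")
    body = df.to_csv(sep="\t", index=index)
    path.write_text("\n".join(header) + "\n" + body)
    return path
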