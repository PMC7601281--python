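"""Reading, normalization and deduplication of annotated germline variants.

Variants arrive either as an annotated VCF (one record per site, carriers
identified from sample genotypes, annotations in INFO) or as a flat TSV
with one row per subject x variant. Both are normalized into
:class:`AnnotatedVariant` records carrying exactly the annotations the
filtration cascade consumes. No annotation is computed here — consequence,
population frequencies, ClinVar class, repeat-region and last-exon flags
are taken from the input as produced by the upstream annotation pipeline
(hg19, 1-based VCF coordinates).
"""

from __future__ import annotations

import enum
import gzip
import logging
from dataclasses import dataclass, field, asdict
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "ClinvarClass",
    "CohortRole",
    "AnnotatedVariant",
    "CohortVariantSet",
    "read_variants",
    "read_variants_tsv",
    "read_variants_vcf",
    "write_variants_tsv",
    "unique_variants",
    "TSV_COLUMNS",
]


class Consequence(enum.Enum):
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    CANONICAL_SPLICE = "canonical_splice"
    INTRONIC_NONCANONICAL = "intronic_noncanonical"
    INFRAME_INDEL = "inframe_indel"
    UTR_OR_INTERGENIC = "utr_or_intergenic"
    CNV_FRAMESHIFTING = "cnv_frameshifting"
    CNV_OTHER = "cnv_other"

    @property
    def is_cnv(self) -> bool:
        return self in (Consequence.CNV_FRAMESHIFTING, Consequence.CNV_OTHER)


class ClinvarClass(enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    NONE = "NONE"


# ClinVar-style spellings tolerated on input.
_CLNSIG_SYNONYMS = {
    "PATHOGENIC": ClinvarClass.P,
    "LIKELY_PATHOGENIC": ClinvarClass.LP,
    "UNCERTAIN_SIGNIFICANCE": ClinvarClass.VUS,
    "LIKELY_BENIGN": ClinvarClass.LB,
    "BENIGN": ClinvarClass.B,
    "": ClinvarClass.NONE,
    ".": ClinvarClass.NONE,
}


class CohortRole(enum.Enum):
    CASES = "CASES"
    CONTROLS = "CONTROLS"


def _parse_clnsig(value) -> ClinvarClass:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ClinvarClass.NONE
    s = str(value).strip()
    try:
        return ClinvarClass[s.upper()]
    except KeyError:
        pass
    key = s.upper().replace(" ", "_")
    if key in _CLNSIG_SYNONYMS:
        return _CLNSIG_SYNONYMS[key]
    raise ValueError(f"unrecognized ClinVar class {value!r}")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no", "", "."):
        return False
    raise ValueError(f"unrecognized boolean flag {value!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One subject x variant observation with cascade-ready annotations.

    ``max_ext_maf`` is the maximum minor-allele frequency across the
    external reference databases (ExAC / ESP6500 / 1000 Genomes);
    ``control_allele_count`` counts alternate alleles among the
    population-matched control alleles. CNV records may carry placeholder
    ref/alt but keep gene and a ``chrom:start-end:CNV:type`` key.
    """

    subject_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    quality: float
    max_ext_maf: float = 0.0
    control_allele_count: int = 0
    clinvar_class: ClinvarClass = ClinvarClass.NONE
    in_repeat_region: bool = False
    in_last_exon: bool = False
    functional_deleterious: bool = False
    variant_key: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not (0.0 <= self.max_ext_maf <= 1.0):
            raise ValueError(f"max_ext_maf outside [0,1]: {self.max_ext_maf}")
        if self.quality < 0:
            raise ValueError(f"negative quality: {self.quality}")
        if self.control_allele_count < 0:
            raise ValueError("negative control allele count")
        if not self.consequence.is_cnv and self.ref == self.alt:
            raise ValueError(f"ref == alt for SNV at {self.chrom}:{self.pos}")
        if not self.variant_key:
            object.__setattr__(self, "variant_key", self.default_key())

    def default_key(self) -> str:
        if self.consequence.is_cnv:
            # CNVs are keyed by their span and type, not ref/alt literals.
            end = self.pos + max(len(self.ref), 1) - 1
            return f"{self.chrom}:{self.pos}-{end}:CNV:{self.consequence.value}"
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CohortVariantSet:
    """All variant observations for one arm of the study."""

    role: CohortRole
    variants: list[AnnotatedVariant]
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def subject_ids(self) -> set[str]:
        return {v.subject_id for v in self.variants}


TSV_COLUMNS = [
    "subject_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "quality",
    "max_ext_maf",
    "control_allele_count",
    "clinvar_class",
    "in_repeat_region",
    "in_last_exon",
    "functional_deleterious",
    "variant_key",
]

_MANDATORY = ["subject_id", "gene", "chrom", "pos", "ref", "alt", "consequence", "quality"]

# Permissive defaults used when an optional annotation column is absent.
_OPTIONAL_DEFAULTS = {
    "max_ext_maf": 0.0,
    "control_allele_count": 0,
    "clinvar_class": "NONE",
    "in_repeat_region": False,
    "in_last_exon": False,
    "functional_deleterious": False,
    "variant_key": "",
}


def read_variants_tsv(path: str | PathLike, role: CohortRole, n_subjects: int) -> CohortVariantSet:
    """Read a per-subject variant TSV (gzip handled transparently)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            logger.warning("%s: column %r absent, defaulting to %r", path, col, default)
            df[col] = str(default) if not isinstance(default, bool) else default
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line numbers incl. header
        try:
            pos = int(row.pos)
        except ValueError:
            raise ValueError(f"{path}, line {i}: malformed position {row.pos!r}") from None
        try:
            variants.append(
                AnnotatedVariant(
                    subject_id=row.subject_id,
                    gene=row.gene,
                    chrom=str(row.chrom),
                    pos=pos,
                    ref=row.ref,
                    alt=row.alt,
                    consequence=Consequence(row.consequence),
                    quality=float(row.quality),
                    max_ext_maf=float(row.max_ext_maf or 0.0),
                    control_allele_count=int(float(row.control_allele_count or 0)),
                    clinvar_class=_parse_clnsig(row.clinvar_class),
                    in_repeat_region=_parse_bool(row.in_repeat_region),
                    in_last_exon=_parse_bool(row.in_last_exon),
                    functional_deleterious=_parse_bool(row.functional_deleterious),
                    variant_key=str(row.variant_key or ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from None
    return CohortVariantSet(role=role, variants=variants, n_subjects=n_subjects)


def read_variants_vcf(path: str | PathLike, role: CohortRole, n_subjects: int) -> CohortVariantSet:
    """Read an annotated VCF; one record is emitted per carrier sample x ALT.

    Expected INFO keys: GENE, CSQ (consequence label), MAX_EXT_MAF,
    CTRL_AC, CLNSIG, REPEAT, LAST_EXON, FUNC_DEL. Record QUAL is used as
    the caller quality. Multi-allelic records are split per ALT allele;
    a sample carries ALT *k* if any genotype allele equals *k*+1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ")
        if gene is None or csq is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks mandatory INFO GENE/CSQ")
        quality = float(rec.QUAL) if rec.QUAL is not None else 0.0
        common = dict(
            gene=str(gene),
            chrom=str(rec.CHROM),
            pos=int(rec.POS),
            ref=str(rec.REF),
            consequence=Consequence(str(csq)),
            quality=quality,
            max_ext_maf=float(rec.INFO.get("MAX_EXT_MAF", 0.0)),
            control_allele_count=int(rec.INFO.get("CTRL_AC", 0)),
            clinvar_class=_parse_clnsig(rec.INFO.get("CLNSIG")),
            in_repeat_region=bool(rec.INFO.get("REPEAT", False)),
            in_last_exon=bool(rec.INFO.get("LAST_EXON", False)),
            functional_deleterious=bool(rec.INFO.get("FUNC_DEL", False)),
        )
        genotypes = rec.genotypes  # [allele1, allele2, phased] per sample
        for alt_index, alt in enumerate(rec.ALT, start=1):
            for sample, gt in zip(samples, genotypes):
                if alt_index in gt[:-1]:
                    variants.append(
                        AnnotatedVariant(subject_id=sample, alt=str(alt), **common)
                    )
    return CohortVariantSet(role=role, variants=variants, n_subjects=n_subjects)


def read_variants(path: str | PathLike, role: CohortRole, n_subjects: int) -> CohortVariantSet:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` → VCF reader, else TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_variants_vcf(path, role, n_subjects)
    return read_variants_tsv(path, role, n_subjects)


def write_variants_tsv(variants: Iterable[AnnotatedVariant], path: str | PathLike) -> None:
    rows = []
    for v in variants:
        d = asdict(v)
        d["consequence"] = v.consequence.value
        d["clinvar_class"] = v.clinvar_class.value
        rows.append(d)
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def unique_variants(cohort: CohortVariantSet) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Collapse per-subject observations to one representative per key.

    Returns ``(representatives, carrier_counts)`` where carrier counts
    record per-key subject multiplicity (one count per distinct subject).
    Idempotent; |unique| <= |records|.
    """
    reps: dict[str, AnnotatedVariant] = {}
    carriers: dict[str, set[str]] = {}
    for v in cohort.variants:
        reps.setdefault(v.variant_key, v)
        carriers.setdefault(v.variant_key, set()).add(v.subject_id)
    return list(reps.values()), {k: len(s) for k, s in carriers.items()}
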