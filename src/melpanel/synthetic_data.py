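"""Synthetic case/control cohorts with known ground truth.

The generator emulates the statistical structure the panel analysis
assumes: per-subject carrier status drawn per risk class (Bernoulli, with
class-specific carrier frequencies for 264 cases and 1479 controls),
planted pathogenic variants whose annotations guarantee they survive the
filtration cascade, a Poisson background of decoy variants engineered to
be eliminated at a chosen cascade step (or retained as VUS), and
per-case clinical metadata drawn from realistic personal/family
cancer-history marginals with a multiplicity enrichment among carriers
of clinically relevant mutations.

Every stochastic draw flows from one seeded :func:`numpy.random.default_rng`
generator; the same config and seed reproduce byte-identical outputs.
A :class:`TruthLedger` records the intended fate of every emitted variant
and the planted carrier status of every subject, so the whole pipeline
can be checked end to end against ground truth.

What this does *not* emulate: real transcript structure (gene loci are
synthetic dummy intervals on hg19-style coordinates), linkage or
haplotype structure, annotation noise (every annotation is internally
consistent by construction), and the long tail of recurrent population
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden_stats import TwoByTwo
from .clinico_strata import (
    ClinicalRecord,
    FamilyCancerHistory,
    MelanomaSite,
    PersonalCategory,
    Sex,
)
from .gene_panel import GeneRiskRegistry, RiskClass, default_registry, precedence_assign
from .variant_io import (
    AnnotatedVariant,
    ClinvarClass,
    CohortRole,
    CohortVariantSet,
    Consequence,
)

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "simulate_cohort",
    "simulate_carrier_table",
    "expected_or",
]

# Class-specific carrier frequencies mirroring the observed class-level
# burden (cases 264, controls 1479): 3.4% vs 0.07% high-to-moderate,
# 8.3% vs 3.9% syndrome, 4.5% vs 2.4% low-risk, 10.6% vs 8.9% unknown.
_DEFAULT_CASE_PROBS = {
    RiskClass.HIGH_MODERATE_MELANOMA: 0.034,
    RiskClass.CANCER_SYNDROME: 0.083,
    RiskClass.LOW_MELANOMA: 0.045,
    RiskClass.UNKNOWN_MELANOMA_RISK: 0.106,
}
_DEFAULT_CONTROL_PROBS = {
    RiskClass.HIGH_MODERATE_MELANOMA: 0.0007,
    RiskClass.CANCER_SYNDROME: 0.039,
    RiskClass.LOW_MELANOMA: 0.024,
    RiskClass.UNKNOWN_MELANOMA_RISK: 0.089,
}

# Intended fate mix of background decoy variants. Keys 1-9 are cascade
# steps; 0 means "survives as VUS". Weighted toward out-of-bait and
# common variation, with a small VUS share so survivors are dominated by
# VUS as in real panel data (~87% of cascade survivors).
_DEFAULT_ELIMINATION_MIX = {
    1: 0.05,
    2: 0.25,
    3: 0.17,
    4: 0.20,
    5: 0.08,
    6: 0.10,
    7: 0.02,
    8: 0.02,
    9: 0.01,
    0: 0.10,
}

# Personal cancer-history category counts of the 264-case cohort
# (multi melanoma + other / multi melanoma / melanoma + other /
# melanoma only < 25 yrs / melanoma only >= 25 yrs).
_PERSONAL_MARGINALS = {
    PersonalCategory.MULTI_MEL_PLUS_OTHER: 6,
    PersonalCategory.MULTI_MEL: 17,
    PersonalCategory.MEL_PLUS_OTHER: 71,
    PersonalCategory.MEL_ONLY_LT25: 36,
    PersonalCategory.MEL_ONLY_GE25: 134,
}
# Family cancer-history column counts of the same cohort.
_FCH_MARGINALS = {
    FamilyCancerHistory.POSITIVE_WITH_MELANOMA: 60,
    FamilyCancerHistory.POSITIVE_OTHER_CANCERS: 136,
    FamilyCancerHistory.NEGATIVE: 47,
    FamilyCancerHistory.UNKNOWN: 21,
}

# Consequence mix of planted pathogenic variants: truncating classes
# dominate; a ClinVar-P missense and a functionally deleterious missense
# exercise both rescue routes.
_PLANTED_KINDS = (
    ("frameshift", 0.40),
    ("stop_gain", 0.25),
    ("canonical_splice", 0.20),
    ("clinvar_p_missense", 0.10),
    ("functional_missense", 0.05),
)

_CLINICALLY_RELEVANT = frozenset(
    {RiskClass.HIGH_MODERATE_MELANOMA, RiskClass.CANCER_SYNDROME}
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated case/control cohort pair.

    ``background_intensity`` is the Poisson mean number of decoy variants
    per subject; ``multiplicity_theta`` tilts the odds of multi-tumor
    personal-history categories for clinically relevant carriers;
    ``extra_double_class_fraction`` promotes single-class carriers to a
    second class to exercise precedence/exclusion logic (observed
    multi-variant carrier share in the reference cohort: ~4%).
    """

    n_cases: int = 264
    n_controls: int = 1479
    carrier_probs_cases: Mapping[RiskClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_CASE_PROBS)
    )
    carrier_probs_controls: Mapping[RiskClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTROL_PROBS)
    )
    background_intensity: float = 12.0
    elimination_mix: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_ELIMINATION_MIX)
    )
    multiplicity_theta: float = 3.0
    extra_double_class_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        for probs in (self.carrier_probs_cases, self.carrier_probs_controls):
            for cls, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"carrier probability for {cls} outside [0,1]: {p}")
        if self.background_intensity < 0:
            raise ValueError("background_intensity must be >= 0")
        total = sum(self.elimination_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"elimination_mix fractions must sum to 1, got {total}")
        if not (0.0 <= self.extra_double_class_fraction <= 1.0):
            raise ValueError("extra_double_class_fraction outside [0,1]")
        if self.multiplicity_theta <= 0:
            raise ValueError("multiplicity_theta must be positive")


@dataclass
class TruthLedger:
    """Ground truth for one simulated cohort pair.

    ``variants`` holds one row per emitted variant record (role, subject,
    key, planted/decoy kind, intended first elimination step — 0 for
    survivors — and intended final verdict). ``carriers`` holds one row
    per subject per planted class. ``expected_class_or`` is the odds
    ratio implied by the configured carrier probabilities.
    """

    variants: pd.DataFrame
    carriers: pd.DataFrame
    expected_class_or: dict[RiskClass, float]

    def verdict_of(self, role: str, subject_id: str, variant_key: str) -> str:
        df = self.variants
        hit = df[
            (df["role"] == role)
            & (df["subject_id"] == subject_id)
            & (df["variant_key"] == variant_key)
        ]
        return hit["intended_verdict"].iloc[0]


def expected_or(config: SimulationConfig) -> dict[RiskClass, float]:
    """Per-class odds ratio implied by the planted carrier probabilities."""
    out = {}
    for cls in RiskClass:
        p1 = config.carrier_probs_cases[cls]
        p0 = config.carrier_probs_controls[cls]
        if p1 >= 1.0 or p0 >= 1.0 or p0 == 0.0:
            out[cls] = float("nan")
        else:
            out[cls] = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return out


# --- gene coordinate model -------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _gene_loci(registry: GeneRiskRegistry) -> dict[str, tuple[str, int]]:
    """Synthetic dummy locus per gene: (chrom, start). Deterministic in
    sorted gene order; syntactically valid hg19-style coordinates."""
    loci = {}
    for i, gene in enumerate(sorted(registry.entries)):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 + (i // 22) * 1_000_000
        loci[gene] = (chrom, start)
    return loci


def _draw_bases(rng: np.random.Generator) -> tuple[str, str]:
    i = rng.integers(0, 4)
    j = (i + 1 + rng.integers(0, 3)) % 4
    return _BASES[i], _BASES[j]


def _planted_variant(
    rng: np.random.Generator,
    subject_id: str,
    gene: str,
    loci: Mapping[str, tuple[str, int]],
) -> AnnotatedVariant:
    """A pathogenic variant guaranteed to survive the cascade and be
    called P/LP. Drawn from a small per-gene pool of recurrent alleles so
    variants recur across carriers (founder-style sharing). The pool slot
    fixes allele identity *and* annotation, so two carriers of the same
    variant never disagree."""
    weights = np.array([w for _, w in _PLANTED_KINDS])
    pool_idx = int(rng.choice(len(_PLANTED_KINDS), p=weights))
    chrom, start = loci[gene]
    pos = start + 100 * pool_idx + 1
    ref = _BASES[pool_idx % 4]
    alt = _BASES[(pool_idx + 1) % 4]
    consequence = [
        Consequence.FRAMESHIFT,
        Consequence.STOP_GAIN,
        Consequence.CANONICAL_SPLICE,
        Consequence.MISSENSE,
        Consequence.MISSENSE,
    ][pool_idx]
    clinvar = ClinvarClass.P if pool_idx == 3 else ClinvarClass.NONE
    functional = pool_idx == 4
    return AnnotatedVariant(
        subject_id=subject_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        quality=float(np.round(rng.uniform(200, 1500), 1)),
        max_ext_maf=float(np.round(rng.uniform(0, 0.0009), 6)),
        control_allele_count=int(rng.integers(0, 3)),
        clinvar_class=clinvar,
        in_repeat_region=False,
        in_last_exon=False,
        functional_deleterious=functional,
    )


def _decoy_variant(
    rng: np.random.Generator,
    subject_id: str,
    gene: str,
    fate: int,
    loci: Mapping[str, tuple[str, int]],
) -> AnnotatedVariant:
    """A background variant whose annotations force elimination at cascade
    step ``fate`` (or survival as VUS when ``fate`` is 0)."""
    chrom, start = loci[gene]
    pos = int(start + 500 + rng.integers(0, 9_000))
    ref, alt = _draw_bases(rng)
    quality = float(np.round(rng.uniform(150, 1500), 1))
    kwargs = dict(
        subject_id=subject_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=Consequence.MISSENSE,
        quality=quality,
        max_ext_maf=float(np.round(rng.uniform(0, 0.002), 6)),
        control_allele_count=int(rng.integers(0, 3)),
        clinvar_class=ClinvarClass.NONE,
        in_repeat_region=False,
        in_last_exon=False,
        functional_deleterious=False,
    )
    if fate == 1:
        kwargs["quality"] = float(np.round(rng.uniform(10, 149.9), 1))
    elif fate == 2:
        kwargs["consequence"] = Consequence.UTR_OR_INTERGENIC
    elif fate == 3:
        kwargs["consequence"] = Consequence.INTRONIC_NONCANONICAL
    elif fate == 4:
        kwargs["max_ext_maf"] = float(np.round(rng.uniform(0.004, 0.4), 6))
    elif fate == 5:
        kwargs["control_allele_count"] = int(rng.integers(3, 60))
    elif fate == 6:
        kwargs["consequence"] = Consequence.SYNONYMOUS
    elif fate == 7:
        kwargs["clinvar_class"] = ClinvarClass.B if rng.integers(0, 2) else ClinvarClass.LB
    elif fate == 8:
        kwargs["in_repeat_region"] = True
    elif fate == 9:
        kwargs["consequence"] = (
            Consequence.FRAMESHIFT if rng.integers(0, 2) else Consequence.STOP_GAIN
        )
        kwargs["in_last_exon"] = True
    elif fate == 0:
        kwargs["clinvar_class"] = ClinvarClass.VUS if rng.integers(0, 2) else ClinvarClass.NONE
    else:
        raise ValueError(f"invalid decoy fate {fate}")
    return AnnotatedVariant(**kwargs)


def _simulate_arm(
    rng: np.random.Generator,
    role: CohortRole,
    n_subjects: int,
    carrier_probs: Mapping[RiskClass, float],
    config: SimulationConfig,
    registry: GeneRiskRegistry,
    loci: Mapping[str, tuple[str, int]],
) -> tuple[CohortVariantSet, list[dict], list[dict], dict[str, set[RiskClass]]]:
    prefix = "case" if role is CohortRole.CASES else "ctrl"
    class_order = sorted(RiskClass, key=lambda c: c.precedence_rank)
    genes_by_class = {cls: registry.genes_in_class(cls) for cls in class_order}
    fates = sorted(config.elimination_mix)
    fate_probs = np.array([config.elimination_mix[f] for f in fates])

    variants: list[AnnotatedVariant] = []
    variant_truth: list[dict] = []
    carrier_truth: list[dict] = []
    classes_by_subject: dict[str, set[RiskClass]] = {}

    for i in range(n_subjects):
        subject = f"{prefix}{i + 1:04d}"
        hit = {cls for cls in class_order if rng.random() < carrier_probs[cls]}
        if len(hit) == 1 and rng.random() < config.extra_double_class_fraction:
            remaining = [c for c in class_order if c not in hit]
            hit.add(remaining[int(rng.integers(0, len(remaining)))])
        classes_by_subject[subject] = hit
        for cls in sorted(hit, key=lambda c: c.precedence_rank):
            gene = genes_by_class[cls][int(rng.integers(0, len(genes_by_class[cls])))]
            v = _planted_variant(rng, subject, gene, loci)
            variants.append(v)
            variant_truth.append(
                {
                    "role": role.value,
                    "subject_id": subject,
                    "variant_key": v.variant_key,
                    "gene": gene,
                    "risk_class": cls.name,
                    "kind": "planted",
                    "intended_step": 0,
                    "intended_verdict": "RETAINED_PLP",
                }
            )
            carrier_truth.append(
                {"role": role.value, "subject_id": subject, "risk_class": cls.name}
            )
        n_decoys = int(rng.poisson(config.background_intensity))
        all_genes = sorted(registry.entries)
        for _ in range(n_decoys):
            fate = fates[int(rng.choice(len(fates), p=fate_probs))]
            gene = all_genes[int(rng.integers(0, len(all_genes)))]
            v = _decoy_variant(rng, subject, gene, fate, loci)
            variants.append(v)
            variant_truth.append(
                {
                    "role": role.value,
                    "subject_id": subject,
                    "variant_key": v.variant_key,
                    "gene": gene,
                    "risk_class": "",
                    "kind": "decoy",
                    "intended_step": fate,
                    "intended_verdict": "RETAINED_VUS" if fate == 0 else "ELIMINATED",
                }
            )
    cohort = CohortVariantSet(role=role, variants=variants, n_subjects=n_subjects)
    return cohort, variant_truth, carrier_truth, classes_by_subject


def _simulate_clinical(
    rng: np.random.Generator,
    classes_by_subject: Mapping[str, set[RiskClass]],
    config: SimulationConfig,
) -> list[ClinicalRecord]:
    cats = list(_PERSONAL_MARGINALS)
    base = np.array([_PERSONAL_MARGINALS[c] for c in cats], dtype=float)
    base /= base.sum()
    tilted = base * np.array(
        [config.multiplicity_theta if c.multi_tumor else 1.0 for c in cats]
    )
    tilted /= tilted.sum()
    fch_levels = list(_FCH_MARGINALS)
    fch_probs = np.array([_FCH_MARGINALS[f] for f in fch_levels], dtype=float)
    fch_probs /= fch_probs.sum()
    sites = [s for s in MelanomaSite]

    records = []
    for subject in sorted(classes_by_subject):
        relevant = bool(classes_by_subject[subject] & _CLINICALLY_RELEVANT)
        probs = tilted if relevant else base
        cat = cats[int(rng.choice(len(cats), p=probs))]
        if cat is PersonalCategory.MEL_ONLY_LT25:
            age = float(rng.integers(9, 25))
        elif cat is PersonalCategory.MEL_ONLY_GE25:
            age = float(rng.integers(25, 76))
        else:
            age = float(rng.integers(14, 76))
        n_mel = (
            int(rng.integers(2, 5))
            if cat in (PersonalCategory.MULTI_MEL, PersonalCategory.MULTI_MEL_PLUS_OTHER)
            else 1
        )
        other = cat in (
            PersonalCategory.MULTI_MEL_PLUS_OTHER,
            PersonalCategory.MEL_PLUS_OTHER,
        )
        records.append(
            ClinicalRecord(
                subject_id=subject,
                sex=Sex.F if rng.random() < 0.73 else Sex.M,
                age_first_melanoma=age,
                n_primary_melanomas=n_mel,
                has_other_primary_cancer=other,
                melanoma_site=sites[int(rng.integers(0, len(sites)))],
                fch=fch_levels[int(rng.choice(len(fch_levels), p=fch_probs))],
            )
        )
    return records


def simulate_cohort(
    config: SimulationConfig | None = None,
    registry: GeneRiskRegistry | None = None,
) -> tuple[CohortVariantSet, CohortVariantSet, list[ClinicalRecord], TruthLedger]:
    """Generate one case/control cohort pair with full ground truth."""
    config = config or SimulationConfig()
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    loci = _gene_loci(registry)

    cases, case_vt, case_ct, case_classes = _simulate_arm(
        rng, CohortRole.CASES, config.n_cases, config.carrier_probs_cases, config, registry, loci
    )
    controls, ctrl_vt, ctrl_ct, _ = _simulate_arm(
        rng,
        CohortRole.CONTROLS,
        config.n_controls,
        config.carrier_probs_controls,
        config,
        registry,
        loci,
    )
    clinical = _simulate_clinical(rng, case_classes, config)
    vt_cols = [
        "role",
        "subject_id",
        "variant_key",
        "gene",
        "risk_class",
        "kind",
        "intended_step",
        "intended_verdict",
    ]
    truth = TruthLedger(
        variants=pd.DataFrame(case_vt + ctrl_vt, columns=vt_cols),
        carriers=pd.DataFrame(
            case_ct + ctrl_ct, columns=["role", "subject_id", "risk_class"]
        ),
        expected_class_or=expected_or(config),
    )
    return cases, controls, clinical, truth


def simulate_carrier_table(
    rng: np.random.Generator,
    p_case: float,
    p_control: float,
    n_cases: int = 264,
    n_controls: int = 1479,
) -> TwoByTwo:
    """Carrier-level fast path: draw one class's 2x2 carrier table directly.

    Statistically identical to planting carriers via :func:`simulate_cohort`
    and counting them after filtration (the variant layer is lossless for
    planted carriers by construction); used for large replicate studies
    of OR recovery and test calibration.
    """
    a = int(rng.binomial(n_cases, p_case))
    c = int(rng.binomial(n_controls, p_control))
    return TwoByTwo(a, n_cases - a, c, n_controls - c)
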