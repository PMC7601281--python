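"""Nine-step germline variant filtration cascade with rescue and P/LP calling.

The cascade eliminates, in order: (i) low-quality calls (quality < 150);
(ii) out-of-bait UTR/intergenic/deep-intronic variants; (iii) intronic
variants outside canonical splice sites (the +/-1-2 intronic positions);
(iv) variants with MAF > 0.003 in any external database
(ExAC/ESP6500/1000 Genomes); (v) variants too frequent in the
population-matched controls (allele count > 2, i.e. MAF > ~0.001 of 2958
control alleles); (vi) synonymous variants; (vii) ClinVar benign/likely
benign variants; (viii) variants inside repeat-masked regions;
(ix) frameshift/stop-gain variants whose new stop falls in the last exon.

Variants classified pathogenic/likely pathogenic in ClinVar, or shown
deleterious by functional assay, are *rescued*: steps ii-ix are skipped
for them. The quality filter (step i) applies to every variant, rescued
or not — a bad call is a bad call regardless of the allele's annotation.

Survivors are then called: pathogenic/likely pathogenic (P/LP) if the
consequence is frameshift, stop-gain, frameshifting CNV or canonical
splice, or if ClinVar/functional evidence says so; everything else is a
variant of uncertain significance (VUS) and is excluded from all
downstream statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .variant_io import AnnotatedVariant, ClinvarClass, Consequence

__all__ = [
    "FilterParams",
    "Verdict",
    "FilterOutcome",
    "rescue_flag",
    "apply_cascade",
    "call_plp",
    "run_filtration",
    "audit_report",
    "N_STEPS",
    "STEP_DESCRIPTIONS",
]

N_STEPS = 9

STEP_DESCRIPTIONS = {
    1: "quality below threshold",
    2: "UTR / intergenic / deep intronic",
    3: "intronic outside canonical splice sites",
    4: "external database MAF above threshold",
    5: "control allele count above threshold",
    6: "synonymous",
    7: "ClinVar benign / likely benign",
    8: "repeat-masked region",
    9: "frameshift/stop-gain in last exon",
}


@dataclass(frozen=True)
class FilterParams:
    """Cascade thresholds.

    ``control_count_threshold`` is the authoritative form of the control
    frequency filter: eliminate when the control alternate-allele count
    exceeds it (>2 of 2958 alleles corresponds to MAF > ~0.001, which is
    what ``control_maf_max`` documents).
    """

    min_quality: float = 150.0
    ext_maf_max: float = 0.003
    control_maf_max: float = 0.001
    control_count_threshold: int = 2

    def __post_init__(self) -> None:
        if self.min_quality < 0 or self.control_count_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 <= self.ext_maf_max <= 1) or not (0 <= self.control_maf_max <= 1):
            raise ValueError("MAF thresholds must lie in [0, 1]")


class Verdict(enum.Enum):
    ELIMINATED = "ELIMINATED"
    RETAINED_VUS = "RETAINED_VUS"
    RETAINED_PLP = "RETAINED_PLP"


@dataclass(frozen=True)
class FilterOutcome:
    variant_key: str
    subject_id: str
    gene: str
    verdict: Verdict
    eliminated_at_step: int | None
    rescued: bool

    def __post_init__(self) -> None:
        if (self.verdict is Verdict.ELIMINATED) != (self.eliminated_at_step is not None):
            raise ValueError("eliminated_at_step must be set iff verdict is ELIMINATED")
        if self.rescued and self.verdict is Verdict.ELIMINATED and self.eliminated_at_step != 1:
            raise ValueError("a rescued variant can only be eliminated at step 1")


def rescue_flag(v: AnnotatedVariant) -> bool:
    """True iff ClinVar calls the variant P/LP or functional assays did."""
    return v.clinvar_class in (ClinvarClass.P, ClinvarClass.LP) or v.functional_deleterious


def _first_elimination_step(v: AnnotatedVariant, params: FilterParams) -> int | None:
    """First cascade step (1-9) that removes ``v``, or None if it survives.

    Steps short-circuit: only the first matching step is recorded. A
    rescued variant is only subject to step 1.
    """
    if v.quality < params.min_quality:
        return 1
    if rescue_flag(v):
        return None
    if v.consequence is Consequence.UTR_OR_INTERGENIC:
        return 2
    if v.consequence is Consequence.INTRONIC_NONCANONICAL:
        return 3
    if v.max_ext_maf > params.ext_maf_max:
        return 4
    if v.control_allele_count > params.control_count_threshold:
        return 5
    if v.consequence is Consequence.SYNONYMOUS:
        return 6
    if v.clinvar_class in (ClinvarClass.B, ClinvarClass.LB):
        return 7
    if v.in_repeat_region:
        return 8
    if v.consequence in (Consequence.FRAMESHIFT, Consequence.STOP_GAIN) and v.in_last_exon:
        return 9
    return None


_PLP_CONSEQUENCES = frozenset(
    {
        Consequence.FRAMESHIFT,
        Consequence.STOP_GAIN,
        Consequence.CNV_FRAMESHIFTING,
        Consequence.CANONICAL_SPLICE,
    }
)


def call_plp(v: AnnotatedVariant, outcome: FilterOutcome) -> Verdict:
    """Final call for a cascade survivor: P/LP or VUS.

    P/LP requires a protein-truncating class of consequence (frameshift,
    stop-gain, frameshifting CNV, canonical splice) or direct ClinVar /
    functional evidence of pathogenicity. Everything else retained by the
    cascade is a VUS.
    """
    if outcome.verdict is Verdict.ELIMINATED:
        raise ValueError(f"call_plp on eliminated variant {v.variant_key}")
    if v.consequence in _PLP_CONSEQUENCES or rescue_flag(v):
        return Verdict.RETAINED_PLP
    return Verdict.RETAINED_VUS


def apply_cascade(
    variants: Sequence[AnnotatedVariant], params: FilterParams | None = None
) -> list[FilterOutcome]:
    """Run steps i-ix plus the final P/LP call over ``variants``.

    Pure function: one :class:`FilterOutcome` per input record, in input
    order. Survivors carry their final RETAINED_PLP / RETAINED_VUS call.
    """
    params = params or FilterParams()
    outcomes: list[FilterOutcome] = []
    for v in variants:
        step = _first_elimination_step(v, params)
        rescued = rescue_flag(v) and v.quality >= params.min_quality
        if step is not None:
            outcome = FilterOutcome(
                variant_key=v.variant_key,
                subject_id=v.subject_id,
                gene=v.gene,
                verdict=Verdict.ELIMINATED,
                eliminated_at_step=step,
                rescued=False,
            )
        else:
            provisional = FilterOutcome(
                variant_key=v.variant_key,
                subject_id=v.subject_id,
                gene=v.gene,
                verdict=Verdict.RETAINED_VUS,
                eliminated_at_step=None,
                rescued=rescued,
            )
            outcome = FilterOutcome(
                variant_key=v.variant_key,
                subject_id=v.subject_id,
                gene=v.gene,
                verdict=call_plp(v, provisional),
                eliminated_at_step=None,
                rescued=rescued,
            )
        outcomes.append(outcome)
    return outcomes


def run_filtration(
    variants: Sequence[AnnotatedVariant], params: FilterParams | None = None
) -> tuple[list[FilterOutcome], list[tuple[AnnotatedVariant, FilterOutcome]]]:
    """Cascade + calling; also returns the surviving P/LP (variant, outcome) pairs."""
    outcomes = apply_cascade(variants, params)
    plp = [
        (v, o)
        for v, o in zip(variants, outcomes)
        if o.verdict is Verdict.RETAINED_PLP
    ]
    return outcomes, plp


def audit_report(outcomes: Iterable[FilterOutcome]) -> pd.DataFrame:
    """Per-step elimination table plus survivor rows; counts sum to input size."""
    outcomes = list(outcomes)
    counts = {step: 0 for step in range(1, N_STEPS + 1)}
    vus = plp = 0
    for o in outcomes:
        if o.verdict is Verdict.ELIMINATED:
            counts[o.eliminated_at_step] += 1
        elif o.verdict is Verdict.RETAINED_VUS:
            vus += 1
        else:
            plp += 1
    rows = [
        {"stage": f"step{step}", "description": STEP_DESCRIPTIONS[step], "count": n}
        for step, n in counts.items()
    ]
    rows.append({"stage": "retained_vus", "description": "survivors called VUS", "count": vus})
    rows.append({"stage": "retained_plp", "description": "survivors called P/LP", "count": plp})
    rows.append({"stage": "total", "description": "input records", "count": len(outcomes)})
    return pd.DataFrame(rows)
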