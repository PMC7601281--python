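"""Clinicopathological stratification of mutation carriers.

Cases are partitioned into five personal cancer-history categories
(multiple primary melanoma with/without another cancer, single melanoma
plus another cancer, and single melanoma split at age 25 at diagnosis)
and four family cancer-history (FCH) levels. Carrier proportions are then
compared across categories, and the tumor-multiplicity odds ratio asks
whether probands with >=2 primary tumors (melanoma and/or other cancer)
are more likely to carry a P/LP variant in a clinically relevant gene
(high-to-moderate melanoma risk or cancer syndrome tier). Multi-variant
carriers are excluded from these comparisons.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .burden_stats import BurdenMode, BurdenResult, CarrierProfile, TwoByTwo, burden_from_table
from .gene_panel import RiskClass

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "MelanomaSite",
    "FamilyCancerHistory",
    "PersonalCategory",
    "ClinicalRecord",
    "CLINICALLY_RELEVANT_CLASSES",
    "read_clinical_tsv",
    "assign_personal_category",
    "multiplicity_or",
    "category_carrier_table",
]

CLINICALLY_RELEVANT_CLASSES = frozenset(
    {RiskClass.HIGH_MODERATE_MELANOMA, RiskClass.CANCER_SYNDROME}
)


class Sex(enum.Enum):
    F = "F"
    M = "M"


class MelanomaSite(enum.Enum):
    TRUNK = "trunk"
    HEAD = "head"
    UPPER_EXTREMITY = "upper_extremity"
    LOWER_EXTREMITY = "lower_extremity"
    EYE = "eye"
    UNKNOWN = "unknown"


class FamilyCancerHistory(enum.Enum):
    POSITIVE_WITH_MELANOMA = "POSITIVE_WITH_MELANOMA"
    POSITIVE_OTHER_CANCERS = "POSITIVE_OTHER_CANCERS"
    NEGATIVE = "NEGATIVE"
    UNKNOWN = "UNKNOWN"


class PersonalCategory(enum.Enum):
    MULTI_MEL_PLUS_OTHER = "MULTI_MEL_PLUS_OTHER"
    MULTI_MEL = "MULTI_MEL"
    MEL_PLUS_OTHER = "MEL_PLUS_OTHER"
    MEL_ONLY_LT25 = "MEL_ONLY_LT25"
    MEL_ONLY_GE25 = "MEL_ONLY_GE25"

    @property
    def multi_tumor(self) -> bool:
        """>=2 primary tumors (melanoma and/or other cancer) in the proband."""
        return self in (
            PersonalCategory.MULTI_MEL_PLUS_OTHER,
            PersonalCategory.MULTI_MEL,
            PersonalCategory.MEL_PLUS_OTHER,
        )


@dataclass(frozen=True)
class ClinicalRecord:
    subject_id: str
    sex: Sex
    age_first_melanoma: float
    n_primary_melanomas: int
    has_other_primary_cancer: bool
    melanoma_site: MelanomaSite = MelanomaSite.UNKNOWN
    fch: FamilyCancerHistory = FamilyCancerHistory.UNKNOWN

    def __post_init__(self) -> None:
        if self.age_first_melanoma < 0:
            raise ValueError("age_first_melanoma must be >= 0")
        if self.n_primary_melanomas < 1:
            raise ValueError("n_primary_melanomas must be >= 1")


def read_clinical_tsv(path: str | PathLike) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "subject_id",
        "sex",
        "age_first_melanoma",
        "n_primary_melanomas",
        "other_primary_cancer",
        "melanoma_site",
        "fch",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ClinicalRecord(
                subject_id=row.subject_id,
                sex=Sex[row.sex.upper()],
                age_first_melanoma=float(row.age_first_melanoma),
                n_primary_melanomas=int(row.n_primary_melanomas),
                has_other_primary_cancer=row.other_primary_cancer in ("1", "true", "True"),
                melanoma_site=MelanomaSite(row.melanoma_site),
                fch=FamilyCancerHistory[row.fch],
            )
        )
    return records


def assign_personal_category(r: ClinicalRecord) -> PersonalCategory:
    """Partition rule for personal cancer history.

    Multiplicity of melanoma takes priority, then the presence of another
    primary cancer, then age at first melanoma (strictly < 25 years; a
    diagnosis exactly at 25 falls in the >= 25 group).
    """
    multi_mel = r.n_primary_melanomas >= 2
    if multi_mel and r.has_other_primary_cancer:
        return PersonalCategory.MULTI_MEL_PLUS_OTHER
    if multi_mel:
        return PersonalCategory.MULTI_MEL
    if r.has_other_primary_cancer:
        return PersonalCategory.MEL_PLUS_OTHER
    if r.age_first_melanoma < 25:
        return PersonalCategory.MEL_ONLY_LT25
    return PersonalCategory.MEL_ONLY_GE25


def _profile_map(profiles: Iterable[CarrierProfile]) -> Mapping[str, CarrierProfile]:
    return {p.subject_id: p for p in profiles}


def _is_relevant_carrier(
    profile: CarrierProfile | None, relevant: frozenset[RiskClass]
) -> bool:
    return profile is not None and bool(profile.classes_hit & relevant)


def multiplicity_or(
    records: Sequence[ClinicalRecord],
    profiles: Sequence[CarrierProfile],
    clinically_relevant_classes: frozenset[RiskClass] = CLINICALLY_RELEVANT_CLASSES,
) -> BurdenResult:
    """Odds ratio for carrying a clinically relevant mutation given tumor
    multiplicity in the proband's personal history.

    Rows: >=2 primary tumors vs single melanoma; columns: carrier of a
    P/LP variant in a clinically relevant class vs non-carrier.
    Multi-variant carriers are excluded from both rows. Uses the burden
    machinery for OR/CI/p (no independent math here).
    """
    pmap = _profile_map(profiles)
    a = b = c = d = 0
    for r in records:
        profile = pmap.get(r.subject_id)
        if profile is not None and profile.is_multi:
            continue
        carrier = _is_relevant_carrier(profile, clinically_relevant_classes)
        if assign_personal_category(r).multi_tumor:
            a += carrier
            b += not carrier
        else:
            c += carrier
            d += not carrier
    return burden_from_table("tumor_multiplicity", TwoByTwo(a, b, c, d))


def category_carrier_table(
    records: Sequence[ClinicalRecord],
    profiles: Sequence[CarrierProfile],
    axis: str = "personal",
    carrier_classes: frozenset[RiskClass] | None = None,
) -> pd.DataFrame:
    """Carrier counts/proportions per category with pairwise Fisher p.

    ``axis='personal'`` groups by the five personal-history categories
    (reference: single melanoma, i.e. the two melanoma-only categories
    pooled); ``axis='family'`` groups by FCH with UNKNOWN records dropped
    (reference: negative FCH). Multi-variant carriers are excluded.
    ``carrier_classes=None`` counts carriers of any risk class; pass
    :data:`CLINICALLY_RELEVANT_CLASSES` to restrict.
    """
    if axis not in ("personal", "family"):
        raise ValueError(f"axis must be 'personal' or 'family', got {axis!r}")
    pmap = _profile_map(profiles)
    kept = [r for r in records if not (pmap.get(r.subject_id) and pmap[r.subject_id].is_multi)]
    if axis == "family":
        dropped = sum(1 for r in kept if r.fch is FamilyCancerHistory.UNKNOWN)
        if dropped:
            logger.info("dropping %d records with unknown family cancer history", dropped)
        kept = [r for r in kept if r.fch is not FamilyCancerHistory.UNKNOWN]

    def is_carrier(r: ClinicalRecord) -> bool:
        profile = pmap.get(r.subject_id)
        if profile is None:
            return False
        if carrier_classes is None:
            return True
        return bool(profile.classes_hit & carrier_classes)

    def group_of(r: ClinicalRecord) -> str:
        if axis == "personal":
            return assign_personal_category(r).name
        return r.fch.name

    groups: dict[str, list[bool]] = {}
    for r in kept:
        groups.setdefault(group_of(r), []).append(is_carrier(r))

    if axis == "personal":
        ref_flags = [
            is_carrier(r)
            for r in kept
            if not assign_personal_category(r).multi_tumor
        ]
        ref_label = "MEL_ONLY (pooled)"
    else:
        ref_flags = groups.get(FamilyCancerHistory.NEGATIVE.name, [])
        ref_label = FamilyCancerHistory.NEGATIVE.name

    ref_car = sum(ref_flags)
    ref_n = len(ref_flags)
    rows = []
    for label in sorted(groups):
        flags = groups[label]
        car, n = sum(flags), len(flags)
        if label == ref_label or n == 0 or ref_n == 0:
            p = float("nan")
        else:
            _, p = stats.fisher_exact([[car, n - car], [ref_car, ref_n - ref_car]])
        rows.append(
            {
                "category": label,
                "carriers": car,
                "n": n,
                "proportion": car / n if n else float("nan"),
                "p_fisher_vs_reference": p,
            }
        )
    rows.append(
        {
            "category": f"reference:{ref_label}",
            "carriers": ref_car,
            "n": ref_n,
            "proportion": ref_car / ref_n if ref_n else float("nan"),
            "p_fisher_vs_reference": float("nan"),
        }
    )
    return pd.DataFrame(rows)
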