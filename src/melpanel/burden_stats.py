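"""Case-control carrier burden: 2x2 tables, odds ratios, Woolf CIs, exact tests.

A *carrier* is a subject with at least one P/LP variant in the stratum
under consideration (a gene or a risk class); each subject contributes at
most once to any numerator. Subjects with P/LP variants in several risk
classes are attributed to the highest-risk class (precedence rule), and
the burden tables can be built either with multi-variant carriers
included (each counted once, in their assigned class) or with them
excluded from the case arm altogether.

The odds ratio is the 2x2 cross-product ad/bc; its 95% CI is Woolf's
log-normal interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
Both the two-sided Fisher exact p and the Pearson chi-square p (1 df,
no continuity correction) are always computed and reported side by side.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .gene_panel import GeneRiskRegistry, OFF_PANEL, RiskClass, precedence_assign, risk_class_of

logger = logging.getLogger(__name__)

__all__ = [
    "TwoByTwo",
    "BurdenMode",
    "BurdenResult",
    "CarrierProfile",
    "UNDEFINED",
    "build_carrier_profiles",
    "class_table",
    "odds_ratio",
    "woolf_ci",
    "fisher_p",
    "chi2_p",
    "gene_burden",
    "class_burden",
    "bh_adjust",
]

Z_975 = 1.959964  # standard normal 97.5% quantile

UNDEFINED = float("nan")


class BurdenMode(enum.Enum):
    INCLUDE_MULTI = "INCLUDE_MULTI"
    EXCLUDE_MULTI = "EXCLUDE_MULTI"


@dataclass(frozen=True)
class TwoByTwo:
    """Carrier counts: a/b = case carriers/non-carriers, c/d = control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def corrected(self) -> "TwoByTwoFloat":
        """Haldane-Anscombe 0.5 continuity correction on every cell."""
        return TwoByTwoFloat(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class TwoByTwoFloat:
    a: float
    b: float
    c: float
    d: float


@dataclass(frozen=True)
class CarrierProfile:
    """Per-subject summary of P/LP findings."""

    subject_id: str
    plp_variants: tuple[tuple[str, str], ...]  # (gene, variant_key)
    classes_hit: frozenset[RiskClass]
    assigned_class: RiskClass
    is_multi: bool

    def __post_init__(self) -> None:
        if self.assigned_class not in self.classes_hit:
            raise ValueError("assigned_class must be one of classes_hit")
        if self.is_multi != (len(self.plp_variants) >= 2):
            raise ValueError("is_multi inconsistent with variant count")

    def genes(self) -> set[str]:
        return {g for g, _ in self.plp_variants}


@dataclass(frozen=True)
class BurdenResult:
    stratum: str
    table: TwoByTwo
    or_point: float
    ci_low: float
    ci_high: float
    p_fisher: float
    p_chi2: float
    mode: BurdenMode | None = None

    @property
    def or_defined(self) -> bool:
        return not math.isnan(self.or_point)


def build_carrier_profiles(
    calls: Iterable[tuple[str, str, str]], registry: GeneRiskRegistry
) -> list[CarrierProfile]:
    """Aggregate P/LP calls ``(subject_id, gene, variant_key)`` into profiles.

    Off-panel genes are logged and excluded from profiles (they cannot be
    attributed to a risk class). Duplicate (subject, variant_key) pairs
    collapse to one finding. Subjects with no on-panel P/LP call yield no
    profile.
    """
    per_subject: dict[str, dict[str, str]] = {}
    for subject_id, gene, variant_key in calls:
        cls = risk_class_of(registry, gene)
        if cls is OFF_PANEL:
            logger.warning("off-panel gene %s in P/LP call for %s; excluded", gene, subject_id)
            continue
        per_subject.setdefault(subject_id, {})[variant_key] = gene.strip().upper()
    profiles = []
    for subject_id, findings in per_subject.items():
        pairs = tuple(sorted((gene, key) for key, gene in findings.items()))
        classes = frozenset(risk_class_of(registry, g) for g, _ in pairs)
        profiles.append(
            CarrierProfile(
                subject_id=subject_id,
                plp_variants=pairs,
                classes_hit=classes,
                assigned_class=precedence_assign(classes),
                is_multi=len(pairs) >= 2,
            )
        )
    return sorted(profiles, key=lambda p: p.subject_id)


def _arm_counts(
    profiles: Sequence[CarrierProfile], cls: RiskClass, n_subjects: int, mode: BurdenMode
) -> tuple[int, int]:
    """(carriers, non-carriers) for one arm and one risk class.

    EXCLUDE_MULTI removes multi-variant carriers from numerator and
    denominator; INCLUDE_MULTI counts each subject once, in the class
    assigned by precedence.
    """
    if mode is BurdenMode.EXCLUDE_MULTI:
        kept = [p for p in profiles if not p.is_multi]
        denom = n_subjects - sum(1 for p in profiles if p.is_multi)
    elif mode is BurdenMode.INCLUDE_MULTI:
        kept = list(profiles)
        denom = n_subjects
    else:
        raise ValueError(f"invalid burden mode: {mode!r}")
    carriers = sum(1 for p in kept if p.assigned_class is cls)
    return carriers, denom - carriers


def class_table(
    case_profiles: Sequence[CarrierProfile],
    control_profiles: Sequence[CarrierProfile],
    cls: RiskClass,
    n_cases: int,
    n_controls: int,
    mode: BurdenMode,
) -> TwoByTwo:
    """2x2 class-level carrier table.

    Multi-carrier exclusion applies to the case arm only: the reference
    analysis keeps the full control denominator in both modes even though
    controls also include multi-variant carriers.
    """
    a, b = _arm_counts(case_profiles, cls, n_cases, mode)
    c, d = _arm_counts(control_profiles, cls, n_controls, BurdenMode.INCLUDE_MULTI)
    return TwoByTwo(a, b, c, d)


def odds_ratio(t: TwoByTwo | TwoByTwoFloat, correction: bool = False) -> float:
    """Cross-product odds ratio ad/bc.

    NaN (undefined) when bc = 0 without the Haldane-Anscombe correction;
    with ``correction=True`` 0.5 is added to every cell first.
    """
    if correction and isinstance(t, TwoByTwo):
        t = t.corrected()
    if t.b * t.c == 0:
        return UNDEFINED
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(
    t: TwoByTwo | TwoByTwoFloat, alpha: float = 0.05, correction: bool = False
) -> tuple[float, float]:
    """Woolf log-normal CI for the odds ratio.

    Requires all cells > 0 (otherwise returns (NaN, NaN) unless the
    continuity correction is requested).
    """
    if correction and isinstance(t, TwoByTwo):
        t = t.corrected()
    if min(t.a, t.b, t.c, t.d) <= 0:
        return (UNDEFINED, UNDEFINED)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def fisher_p(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p (hypergeometric tail mass <= observed)."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def chi2_p(t: TwoByTwo) -> float:
    """Pearson chi-square p (1 df, no Yates correction); NaN on a zero margin."""
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        return UNDEFINED
    chi2, p, _, _ = stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)
    return float(p)


def _result(stratum: str, t: TwoByTwo, mode: BurdenMode | None, correction: bool) -> BurdenResult:
    low, high = woolf_ci(t, correction=correction)
    return BurdenResult(
        stratum=stratum,
        table=t,
        or_point=odds_ratio(t, correction=correction),
        ci_low=low,
        ci_high=high,
        p_fisher=fisher_p(t),
        p_chi2=chi2_p(t),
        mode=mode,
    )


def gene_burden(
    gene: str,
    case_profiles: Sequence[CarrierProfile],
    control_profiles: Sequence[CarrierProfile],
    n_cases: int,
    n_controls: int,
    registry: GeneRiskRegistry,
    mode: BurdenMode = BurdenMode.INCLUDE_MULTI,
    correction: bool = False,
) -> BurdenResult:
    """Per-gene carrier burden; a carrier has >=1 P/LP variant in ``gene``."""
    if risk_class_of(registry, gene) is OFF_PANEL:
        raise ValueError(f"gene {gene!r} is not on the panel")
    sym = gene.strip().upper()

    def arm(profiles: Sequence[CarrierProfile], n: int, exclude: bool) -> tuple[int, int]:
        kept = [p for p in profiles if not (exclude and p.is_multi)]
        denom = n - (sum(1 for p in profiles if p.is_multi) if exclude else 0)
        carriers = sum(1 for p in kept if sym in p.genes())
        return carriers, denom - carriers

    a, b = arm(case_profiles, n_cases, mode is BurdenMode.EXCLUDE_MULTI)
    c, d = arm(control_profiles, n_controls, False)
    return _result(sym, TwoByTwo(a, b, c, d), mode, correction)


def class_burden(
    case_profiles: Sequence[CarrierProfile],
    control_profiles: Sequence[CarrierProfile],
    n_cases: int,
    n_controls: int,
    mode: BurdenMode,
    correction: bool = False,
) -> list[BurdenResult]:
    """Burden per risk class, in precedence order (the class-level table twin)."""
    results = []
    for cls in sorted(RiskClass, key=lambda c: c.precedence_rank):
        t = class_table(case_profiles, control_profiles, cls, n_cases, n_controls, mode)
        results.append(_result(cls.name, t, mode, correction))
    return results


def burden_from_table(stratum: str, t: TwoByTwo, correction: bool = False) -> BurdenResult:
    """Burden statistics for a pre-assembled 2x2 table."""
    return _result(stratum, t, None, correction)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional column; never alters
    the primary per-stratum output)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
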