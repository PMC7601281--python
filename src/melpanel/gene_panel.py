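"""Melanoma gene risk registry.

The panel groups 217 genes into four melanoma-risk tiers: eight
high-to-moderate melanoma risk genes (*CDKN2A*, *CDK4*, *BAP1*, the
shelterin genes *POT1*/*ACD*/*TERF2IP*, *TERT*, *MITF*), 26 low-risk
melanoma genes (mostly pigmentation / GWAS loci), 37 hereditary cancer
syndrome genes with uncertain melanoma risk, and 146 genes with unknown
impact on familial melanoma. When one subject carries pathogenic
variants in genes from several tiers, the subject is attributed to the
highest-risk tier (precedence rule).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RiskClass",
    "OFF_PANEL",
    "GeneRiskRegistry",
    "load_gene_registry",
    "default_registry",
    "risk_class_of",
    "precedence_assign",
]

DEFAULT_PANEL_NAME = "CZMELAC"
_DEFAULT_RESOURCE = "czmelac_panel.tsv"


class RiskClass(enum.Enum):
    """Melanoma-risk tier of a panel gene.

    ``precedence_rank`` orders the tiers for multi-class carriers:
    1 = highest risk, assigned first.
    """

    HIGH_MODERATE_MELANOMA = 1
    CANCER_SYNDROME = 2
    LOW_MELANOMA = 3
    UNKNOWN_MELANOMA_RISK = 4

    @property
    def precedence_rank(self) -> int:
        return self.value


class _OffPanel:
    """Sentinel returned for gene symbols absent from the registry."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "OFF_PANEL"

    def __bool__(self) -> bool:
        return False


OFF_PANEL = _OffPanel()


@dataclass(frozen=True)
class GeneRiskRegistry:
    """Mapping of upper-cased gene symbols to their :class:`RiskClass`."""

    entries: Mapping[str, RiskClass]
    panel_name: str = DEFAULT_PANEL_NAME

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("gene registry has no entries")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.entries

    def class_sizes(self) -> dict[RiskClass, int]:
        sizes = {cls: 0 for cls in RiskClass}
        for cls in self.entries.values():
            sizes[cls] += 1
        return sizes

    def genes_in_class(self, cls: RiskClass) -> list[str]:
        return sorted(g for g, c in self.entries.items() if c is cls)


def load_gene_registry(path: str | PathLike, panel_name: str = DEFAULT_PANEL_NAME) -> GeneRiskRegistry:
    """Load a registry from a two-column TSV (``gene_symbol``, ``risk_class``).

    Gene symbols are upper-cased before storage; duplicate symbols (after
    normalization) and unrecognized class labels are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_symbol", "risk_class"} - set(df.columns)
    if missing:
        raise ValueError(f"registry file missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("gene registry has no entries")
    entries: dict[str, RiskClass] = {}
    for _, row in df.iterrows():
        sym = str(row["gene_symbol"]).strip().upper()
        label = str(row["risk_class"]).strip()
        try:
            cls = RiskClass[label]
        except KeyError:
            raise ValueError(f"unknown risk class label {label!r} for gene {sym}") from None
        if sym in entries:
            raise ValueError(f"duplicate gene symbol in registry: {sym}")
        entries[sym] = cls
    return GeneRiskRegistry(entries=entries, panel_name=panel_name)


def default_registry() -> GeneRiskRegistry:
    """The packaged 217-gene default panel (8 / 26 / 37 / 146 per tier)."""
    ref = resources.files("melpanel.data").joinpath(_DEFAULT_RESOURCE)
    with resources.as_file(ref) as path:
        return load_gene_registry(path)


def risk_class_of(registry: GeneRiskRegistry, gene: str):
    """Risk class of ``gene`` (case-insensitive), or :data:`OFF_PANEL`.

    Off-panel symbols are tolerated, not errors: input variant tables may
    legitimately contain genes outside the panel and downstream code
    reports them rather than dropping them silently.
    """
    return registry.entries.get(gene.strip().upper(), OFF_PANEL)


def precedence_assign(classes: Iterable[RiskClass]) -> RiskClass:
    """Attribute a multi-class carrier to the highest-risk tier.

    High-to-moderate melanoma > cancer syndrome > low-risk melanoma >
    unknown melanoma risk. Order-independent and idempotent (set
    semantics); an empty set is an error.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("precedence_assign requires a non-empty set of risk classes")
    if not all(isinstance(c, RiskClass) for c in classes):
        raise TypeError("precedence_assign expects RiskClass members")
    return min(classes, key=lambda c: c.precedence_rank)
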