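"""End-to-end orchestration: filter -> call -> profiles -> burden -> strata.

Produces the paper-shaped outputs as TSVs (class-level burden table in
both multi-carrier modes, per-category carrier strata, per-step audit
trail) plus a JSON run manifest capturing the parameter snapshot, input
checksums, seed and tool version. Display columns round the way the
field prints them (OR and percentages to one decimal) but full-precision
columns are always present alongside, so rounding can never mask a
regression.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .burden_stats import (
    BurdenMode,
    BurdenResult,
    build_carrier_profiles,
    class_burden,
)
from .clinico_strata import ClinicalRecord, category_carrier_table, multiplicity_or
from .filtration import FilterParams, Verdict, audit_report, run_filtration
from .gene_panel import GeneRiskRegistry, default_registry
from .variant_io import CohortVariantSet

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "burden_frame"]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def burden_frame(results: Sequence[BurdenResult], n_cases: int, n_controls: int) -> pd.DataFrame:
    """Burden results as a display table (rounded + full precision columns)."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "stratum": r.stratum,
                "mode": r.mode.value if r.mode else "",
                "case_carriers": t.a,
                "case_n": t.n_cases,
                "case_pct": round(100 * t.a / t.n_cases, 1) if t.n_cases else float("nan"),
                "control_carriers": t.c,
                "control_n": t.n_controls,
                "control_pct": round(100 * t.c / t.n_controls, 1) if t.n_controls else float("nan"),
                "OR": round(r.or_point, 1),
                "CI_low": round(r.ci_low, 1),
                "CI_high": round(r.ci_high, 1),
                "OR_full": r.or_point,
                "CI_low_full": r.ci_low,
                "CI_high_full": r.ci_high,
                "p_fisher": r.p_fisher,
                "p_chi2": r.p_chi2,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cases: CohortVariantSet,
    controls: CohortVariantSet,
    clinical: Sequence[ClinicalRecord] | None,
    outdir: str | Path,
    registry: GeneRiskRegistry | None = None,
    params: FilterParams | None = None,
    seed: int | None = None,
    input_paths: Mapping[str, str | Path] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage over already-loaded cohorts and write the outputs.

    Returns the output tables keyed by name; writes ``outcomes_{arm}.tsv``,
    ``audit_{arm}.tsv``, ``profiles_{arm}.tsv``, ``burden_classes.tsv``,
    ``strata_personal.tsv`` / ``strata_family.tsv`` / ``multiplicity.tsv``
    (when clinical records are given) and ``manifest.json`` under
    ``outdir``.
    """
    registry = registry or default_registry()
    params = params or FilterParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}

    profiles = {}
    for arm_name, cohort in (("cases", cases), ("controls", controls)):
        outcomes, plp = run_filtration(cohort.variants, params)
        out_df = pd.DataFrame(
            {
                "subject_id": [o.subject_id for o in outcomes],
                "gene": [o.gene for o in outcomes],
                "variant_key": [o.variant_key for o in outcomes],
                "verdict": [o.verdict.value for o in outcomes],
                "eliminated_at_step": [
                    "" if o.eliminated_at_step is None else o.eliminated_at_step
                    for o in outcomes
                ],
                "rescued": [o.rescued for o in outcomes],
            }
        )
        outputs[f"outcomes_{arm_name}"] = out_df
        outputs[f"audit_{arm_name}"] = audit_report(outcomes)
        calls = [(o.subject_id, o.gene, o.variant_key) for _, o in plp]
        profiles[arm_name] = build_carrier_profiles(calls, registry)
        outputs[f"profiles_{arm_name}"] = pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in profiles[arm_name]],
                "n_plp": [len(p.plp_variants) for p in profiles[arm_name]],
                "genes": [";".join(sorted(p.genes())) for p in profiles[arm_name]],
                "assigned_class": [p.assigned_class.name for p in profiles[arm_name]],
                "is_multi": [p.is_multi for p in profiles[arm_name]],
            }
        )

    results = []
    for mode in (BurdenMode.INCLUDE_MULTI, BurdenMode.EXCLUDE_MULTI):
        results.extend(
            class_burden(
                profiles["cases"],
                profiles["controls"],
                cases.n_subjects,
                controls.n_subjects,
                mode,
            )
        )
    outputs["burden_classes"] = burden_frame(results, cases.n_subjects, controls.n_subjects)

    if clinical is not None:
        outputs["strata_personal"] = category_carrier_table(
            clinical, profiles["cases"], axis="personal"
        )
        outputs["strata_family"] = category_carrier_table(
            clinical, profiles["cases"], axis="family"
        )
        mult = multiplicity_or(clinical, profiles["cases"])
        outputs["multiplicity"] = burden_frame([mult], mult.table.n_cases, mult.table.n_controls)

    for name, df in outputs.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    manifest = {
        "tool": "melpanel",
        "version": __version__,
        "seed": seed,
        "params": dataclasses.asdict(params),
        "n_cases": cases.n_subjects,
        "n_controls": controls.n_subjects,
        "inputs": {
            name: _checksum(Path(p)) for name, p in (input_paths or {}).items()
        },
        "outputs": sorted(f"{name}.tsv" for name in outputs),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outputs
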