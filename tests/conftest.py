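from pathlib import Path

import pandas as pd
import pytest

from melpanel import (
    AnnotatedVariant,
    ClinvarClass,
    Consequence,
    default_registry,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fixture_frame() -> pd.DataFrame:
    """The packaged 60-variant filtration conformance fixture with its
    hand-enumerated expected fate per row."""
    return pd.read_csv(DATA_DIR / "filtration_fixture.tsv", sep="\t", keep_default_na=False)


def make_variant(
    consequence=Consequence.MISSENSE,
    quality=200.0,
    max_ext_maf=0.0,
    control_allele_count=0,
    clinvar_class=ClinvarClass.NONE,
    in_repeat_region=False,
    in_last_exon=False,
    functional_deleterious=False,
    subject_id="S1",
    gene="CDKN2A",
    chrom="chr9",
    pos=21_970_916,
    ref="C",
    alt="T",
) -> AnnotatedVariant:
    """Terse variant factory for unit tests."""
    return AnnotatedVariant(
        subject_id=subject_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        quality=quality,
        max_ext_maf=max_ext_maf,
        control_allele_count=control_allele_count,
        clinvar_class=clinvar_class,
        in_repeat_region=in_repeat_region,
        in_last_exon=in_last_exon,
        functional_deleterious=functional_deleterious,
    )


def variants_from_frame(df: pd.DataFrame) -> list[AnnotatedVariant]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AnnotatedVariant(
                subject_id=row.subject_id,
                gene=row.gene,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                consequence=Consequence(row.consequence),
                quality=float(row.quality),
                max_ext_maf=float(row.max_ext_maf),
                control_allele_count=int(row.control_allele_count),
                clinvar_class=ClinvarClass[str(row.clinvar_class)],
                in_repeat_region=bool(row.in_repeat_region),
                in_last_exon=bool(row.in_last_exon),
                functional_deleterious=bool(row.functional_deleterious),
            )
        )
    return out
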