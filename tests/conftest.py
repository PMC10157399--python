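"""Shared fixtures: small on-disk stores and alert factories."""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path

import pytest

from litquery.alerts import (
    AssociationCategory,
    GeneAlert,
    InheritanceMode,
    OmimStatus,
    VariantClass,
)
from litquery.store_io import (
    SCHEMAS,
    AnnotatedVariantRow,
    VariantKey,
    scan_store,
    write_variant_table,
)


def make_row(
    gene="GENE1",
    sample="S001",
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    af=None,
    protein="p.(Arg100*)",
    **extra_scores,
):
    af_fields = {} if af is None else {"GNOMAD_EXOME_AF": af}
    return AnnotatedVariantRow(
        key=VariantKey(chrom, pos, ref, alt),
        sample_id=sample,
        gene=gene,
        protein_change=protein,
        af_fields=af_fields,
        score_fields=dict(extra_scores),
    )


def build_store(root: Path, analyses):
    """Write a store from (sample, iso_timestamp, version, rows) tuples."""
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (sample, stamp, version, rows) in enumerate(analyses):
        schema = SCHEMAS[version]
        path = f"{sample}_a{i}_{version}.tsv"
        write_variant_table(rows, schema, root / path)
        entries.append({
            "path": path,
            "sample_id": sample,
            "analysis_timestamp": stamp,
            "version_tag": version,
        })
    (root / "manifest.json").write_text(json.dumps({"files": entries}, indent=2))
    return scan_store(root)


def make_alert(
    gene="GENE1",
    modes=(InheritanceMode.DE_NOVO_DOMINANT,),
    classes=(VariantClass.PROTEIN_TRUNCATING,),
    domains=(),
    category=AssociationCategory.NOVEL_DISORDER,
    omim=OmimStatus.NON_MORBID,
):
    return GeneAlert(
        gene=gene,
        publication_date=date(2020, 1, 15),
        association_category=category,
        omim_status=omim,
        inheritance_modes=frozenset(modes),
        reported_variant_classes=frozenset(classes),
        domains=tuple(domains),
        source_ref=f"test:{gene}",
    )


@pytest.fixture
def two_analysis_store(tmp_path):
    """One sample analyzed twice (v1 then v2) carrying the same GENE1 variant,
    plus a second single-analysis sample with a GENE10 variant."""
    shared = make_row(gene="GENE1", sample="S001", pos=5000, af=1e-4)
    other = make_row(gene="GENE10", sample="S002", pos=7000, af=1e-4,
                     protein="p.(Gly50Asp)")
    return build_store(tmp_path / "store", [
        ("S001", "2019-06-01T00:00:00", "v1", [shared]),
        ("S001", "2020-02-01T00:00:00", "v2", [shared]),
        ("S002", "2020-03-01T00:00:00", "v2", [other]),
    ])
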