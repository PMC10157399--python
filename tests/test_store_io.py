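"""Variant-table parsing, writing, HGVS-g keys and store scanning."""

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litquery.exceptions import (
    AmbiguousAnalysisError,
    MalformedStoreError,
    ParseWarning,
    SchemaMismatchError,
)
from litquery.store_io import (
    CORE_COLUMNS,
    MASTER_SCHEMA,
    SCHEMA_V1,
    SCHEMA_V2,
    AnnotationSchema,
    VariantKey,
    format_hgvs_g,
    parse_hgvs_g,
    read_variant_table,
    scan_store,
    write_variant_table,
)

from conftest import build_store, make_row


# ---------------------------------------------------------------------------
# HGVS-g parsing (worked examples from the published candidate table)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, expected",
    [
        ("chr6:g.31637615T>C", VariantKey("chr6", 31637615, "T", "C")),
        ("chr6:g.170594361del", VariantKey("chr6", 170594361, "N", "DEL")),
        ("chr2:g.130914204_130914206del", VariantKey("chr2", 130914204, "NNN", "DEL")),
        ("chr2:g.160287462dup", VariantKey("chr2", 160287462, "N", "DUP")),
        ("chr1:g.45793162_45793165dup", VariantKey("chr1", 45793162, "NNNN", "DUP")),
    ],
)
def test_parse_hgvs_g(text, expected):
    key = parse_hgvs_g(text)
    assert key == expected
    assert parse_hgvs_g(format_hgvs_g(key)) == key


@pytest.mark.parametrize("bad", ["chr1:c.100A>T", "g.100A>T", "chr1:g.5_3del", "garbage"])
def test_parse_hgvs_g_rejects(bad):
    with pytest.raises(ValueError):
        parse_hgvs_g(bad)


def test_variant_key_invariants():
    with pytest.raises(ValueError):
        VariantKey("chr1", 0, "A", "T")
    with pytest.raises(ValueError):
        VariantKey("", 10, "A", "T")


# ---------------------------------------------------------------------------
# Table reading
# ---------------------------------------------------------------------------


def _write(path, lines):
    path.write_text("\n".join("\t".join(cells) for cells in lines) + "\n")


def test_parse_core_plus_one_annotation(tmp_path):
    """A minimal 8-core + CADD table parses into fully populated rows."""
    path = tmp_path / "t.tsv"
    header = list(CORE_COLUMNS) + ["CADD"]
    _write(path, [
        header,
        ["chr1", "100", ".", "A", "T", ".", "PASS", ".", "22.5"],
        ["chr2", "200", ".", "G", "C", ".", "PASS", ".", "31.0"],
    ])
    schema = AnnotationSchema(tuple(header), "mini")
    rows = read_variant_table(path, schema)
    assert len(rows) == 2
    assert [r.score_fields["CADD"] for r in rows] == [22.5, 31.0]


def test_master_schema_reports_absent_columns_missing(tmp_path):
    """Columns a file's pipeline version lacked surface as missing, not zero."""
    row = make_row(af=0.001, CADD=10.0)
    write_variant_table([row], SCHEMA_V1, tmp_path / "old.tsv")
    got = read_variant_table(tmp_path / "old.tsv", MASTER_SCHEMA)
    assert got[0].score_fields["CCR"] is None
    assert got[0].score_fields["SPIP"] is None
    assert got[0].score_fields["CADD"] == 10.0


def test_fewer_than_eight_columns_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    _write(path, [list(CORE_COLUMNS), ["chr1", "100", ".", "A", "T", "."]])
    with pytest.raises(MalformedStoreError, match=":2:"):
        read_variant_table(path)


def test_non_numeric_af_warns_and_sets_missing(tmp_path):
    header = list(CORE_COLUMNS) + ["GNOMAD_EXOME_AF"]
    path = tmp_path / "t.tsv"
    _write(path, [header, ["chr1", "100", ".", "A", "T", ".", ".", ".", "oops"]])
    with pytest.warns(ParseWarning, match="GNOMAD_EXOME_AF"):
        rows = read_variant_table(path)
    assert rows[0].af_fields["GNOMAD_EXOME_AF"] is None


def test_af_out_of_range_warns_and_sets_missing(tmp_path):
    header = list(CORE_COLUMNS) + ["GNOMAD_EXOME_AF"]
    path = tmp_path / "t.tsv"
    _write(path, [header, ["chr1", "100", ".", "A", "T", ".", ".", ".", "1.7"]])
    with pytest.warns(ParseWarning):
        rows = read_variant_table(path)
    assert rows[0].af_fields["GNOMAD_EXOME_AF"] is None


def test_mixed_chromosome_styles_rejected(tmp_path):
    path = tmp_path / "t.tsv"
    _write(path, [
        list(CORE_COLUMNS),
        ["chr1", "100", ".", "A", "T", ".", ".", "."],
        ["2", "200", ".", "G", "C", ".", ".", "."],
    ])
    with pytest.raises(MalformedStoreError, match="mixed chromosome label styles"):
        read_variant_table(path)


# ---------------------------------------------------------------------------
# Writing and round-trip
# ---------------------------------------------------------------------------


def test_empty_rows_write_header_only(tmp_path):
    path = write_variant_table([], SCHEMA_V2, tmp_path / "e.tsv")
    lines = path.read_text().splitlines()
    assert lines == ["\t".join(SCHEMA_V2.columns)]


def test_missing_score_renders_gap_token(tmp_path):
    row = make_row(af=0.001)  # no SPIP value
    path = write_variant_table([row], SCHEMA_V2, tmp_path / "t.tsv")
    header, data = path.read_text().splitlines()
    cells = dict(zip(header.split("\t"), data.split("\t")))
    assert cells["SPIP"] == "."


def test_schema_mismatch_on_write(tmp_path):
    row = make_row(SPIP=0.9)  # SPIP is a v2-only column
    with pytest.raises(SchemaMismatchError, match="SPIP"):
        write_variant_table([row], SCHEMA_V1, tmp_path / "t.tsv")


@st.composite
def random_rows(draw):
    n = draw(st.integers(1, 8))
    rows = []
    for i in range(n):
        af = draw(st.one_of(
            st.none(),
            st.floats(min_value=0, max_value=1, allow_nan=False),
        ))
        cadd = draw(st.one_of(st.none(), st.floats(0, 60, allow_nan=False)))
        rows.append(make_row(
            gene=draw(st.sampled_from(["GENE1", "GENE2", "NKX2-5"])),
            pos=100 + i,
            ref=draw(st.sampled_from("ACGT")),
            alt=draw(st.sampled_from(["A", "C", "G", "T", "DEL", "DUP"])),
            af=af,
            protein=draw(st.sampled_from(["p.(Arg100*)", "p.?", "p.(Ala5Gly)", None])),
            **({} if cadd is None else {"CADD": cadd}),
        ))
    return rows


@settings(max_examples=60, derandomize=True, deadline=None)
@given(random_rows())
def test_round_trip_identity(tmp_path_factory, rows):
    """write then read reproduces rows exactly, including missingness."""
    path = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_variant_table(rows, SCHEMA_V2, path)
    got = read_variant_table(path, SCHEMA_V2, sample_id="S001")
    assert len(got) == len(rows)
    for a, b in zip(rows, got):
        assert a.key == b.key
        assert a.gene == b.gene
        assert a.protein_change == b.protein_change
        assert a.af_fields.get("GNOMAD_EXOME_AF") == b.af_fields.get("GNOMAD_EXOME_AF")
        assert a.score_fields.get("CADD") == b.score_fields.get("CADD")


# ---------------------------------------------------------------------------
# Store scanning
# ---------------------------------------------------------------------------


def test_scan_empty_directory(tmp_path):
    store = scan_store(tmp_path)
    assert store.files == []


def test_scan_three_files_two_samples(tmp_path):
    store = build_store(tmp_path / "s", [
        ("S002", "2020-01-01T00:00:00", "v2", [make_row(sample="S002")]),
        ("S001", "2019-01-01T00:00:00", "v1", [make_row()]),
        ("S001", "2020-01-01T00:00:00", "v2", [make_row()]),
    ])
    assert sorted(store.index) == ["S001", "S002"]
    assert [f.sample_id for f in store.files] == ["S001", "S001", "S002"]
    stamps = [f.analysis_timestamp for f in store.index["S001"]]
    assert stamps == sorted(stamps)


def test_scan_is_independent_of_manifest_order(tmp_path):
    analyses = [
        (f"S{i:03d}", f"2020-0{i}-01T00:00:00", "v2", [make_row(sample=f"S{i:03d}")])
        for i in range(1, 6)
    ]
    listings = []
    for seed in (0, 1, 2):
        shuffled = analyses[:]
        random.Random(seed).shuffle(shuffled)
        root = tmp_path / f"s{seed}"
        store = build_store(root, shuffled)
        listings.append([(f.sample_id, f.analysis_timestamp, f.path) for f in store.files])
    # paths differ per shuffle (index-based names), compare sample/timestamp order
    orders = [[(s, t) for s, t, _ in listing] for listing in listings]
    assert orders[0] == orders[1] == orders[2]


def test_scan_rejects_hard_timestamp_tie(tmp_path):
    root = tmp_path / "s"
    build_store(root, [
        ("S001", "2020-01-01T00:00:00", "v2", [make_row()]),
    ])
    manifest = json.loads((root / "manifest.json").read_text())
    entry = dict(manifest["files"][0])
    entry["path"] = "copy.tsv"
    (root / "copy.tsv").write_text((root / manifest["files"][0]["path"]).read_text())
    manifest["files"].append(entry)
    (root / "manifest.json").write_text(json.dumps(manifest))
    with pytest.raises(AmbiguousAnalysisError):
        scan_store(root)


def test_vcf_ingestion_maps_info_keys(tmp_path):
    """VCF 4.x records map onto the eight core columns; INFO keys matching
    annotation names are lifted, everything else ignored."""
    from litquery.store_io import read_vcf

    vcf = tmp_path / "sampleX.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GNOMAD_EXOME_AF,Number=1,Type=Float,Description="af">\n'
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="score">\n'
        '##INFO=<ID=GENE,Number=1,Type=String,Description="symbol">\n'
        '##INFO=<ID=IRRELEVANT,Number=1,Type=String,Description="noise">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t12345\t.\tG\tT\t50\tPASS\t"
        "GNOMAD_EXOME_AF=0.0002;CADD=24.1;GENE=GENE1;IRRELEVANT=x\n"
    )
    (row,) = read_vcf(vcf)
    assert row.sample_id == "sampleX"
    assert row.key == VariantKey("chr1", 12345, "G", "T")
    assert row.gene == "GENE1"
    assert row.af_fields["GNOMAD_EXOME_AF"] == pytest.approx(0.0002)
    assert row.score_fields["CADD"] == pytest.approx(24.1)
    assert "IRRELEVANT" not in row.extra_fields


def test_tables_without_manifest_rejected(tmp_path):
    write_variant_table([make_row()], SCHEMA_V2, tmp_path / "orphan.tsv")
    with pytest.raises(MalformedStoreError, match="manifest"):
        scan_store(tmp_path)
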