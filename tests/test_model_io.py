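"""Round-trip and validation behavior of the readers and writers."""
import json

import pytest

from ampliscan import io as asio
from ampliscan.model import (
    Catalog,
    DataValidationError,
    SampleMeta,
    Tissue,
    VariantKey,
)
from ampliscan.scan import scan_cohort
from conftest import make_obs


def test_variant_key_validation():
    with pytest.raises(DataValidationError):
        VariantKey("chr5", 0, "G", "A")
    with pytest.raises(DataValidationError):
        VariantKey("chr5", 100, "G", "G")
    with pytest.raises(DataValidationError):
        VariantKey("chr5", 100, "G", "X")
    key = VariantKey("chr5", 100, "GA", "G")  # deletion
    assert not key.is_snv


def test_variant_table_roundtrip(tmp_path):
    obs = [
        make_obs("s1", 112043384, 0.5, novel=True),
        make_obs("s1", 79966029, 0.72, gene="MSH3"),
        make_obs("s2", 48033545, 1.0, gene="MSH6", chrom="chr2", ref="A", alt="C"),
    ]
    path = tmp_path / "variants.tsv"
    asio.write_variant_table(obs, path)
    back, stubs = asio.read_variant_table(path, "annovar_tsv")
    assert [o.key for o in back] == [o.key for o in obs]
    assert [(o.ref_reads, o.var_reads, o.gene, o.novel) for o in back] == [
        (o.ref_reads, o.var_reads, o.gene, o.novel) for o in obs
    ]
    assert {s.sample_id for s in stubs} == {"s1", "s2"}


def test_tsv_chromosome_inferred_from_gene(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text(
        "sample_id\tposition\tref\talt\tgene\tref_reads\tvar_reads\n"
        "s1\t79966029\tG\tA\tMSH3\t40\t60\n"
        "s1\t48033545\tA\tC\tMSH6\t50\t50\n"
    )
    obs, _ = asio.read_variant_table(path, "annovar_tsv")
    assert obs[0].key.chromosome == "chr5"
    assert obs[1].key.chromosome == "chr2"


def test_malformed_row_reported_with_line_number(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text(
        "sample_id\tposition\tref\talt\tgene\tref_reads\tvar_reads\n"
        "s1\t100\tG\tA\tMSH3\t40\t60\n"
        "s1\tabc\tG\tA\tMSH3\t40\t60\n"
    )
    with pytest.raises(DataValidationError, match=r":3:"):
        asio.read_variant_table(path, "annovar_tsv")


def test_unknown_dialect_rejected(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text("x\n")
    with pytest.raises(DataValidationError, match="dialect"):
        asio.read_variant_table(path, "excel")


def test_vcf_ad_field_copied(tmp_path):
    vcf = tmp_path / "v.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        "##contig=<ID=chr5>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr5\t79966029\t.\tG\tA\t.\t.\tGENE=MSH3\tGT:AD\t0/1:40,60\t0/0:100,0\n"
    )
    obs, _ = asio.read_variant_table(vcf, "vcf")
    assert len(obs) == 1  # s2 carries no variant reads
    assert (obs[0].ref_reads, obs[0].var_reads) == (40, 60)
    assert obs[0].gene == "MSH3"


def test_vcf_multiallelic_split_and_gene_from_position(tmp_path):
    vcf = tmp_path / "v.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        "##contig=<ID=chr2>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "chr2\t48032908\t.\tA\tG,C\t.\t.\t.\tGT:AD\t1/2:10,30,60\n"
    )
    obs, _ = asio.read_variant_table(vcf, "vcf")
    assert [(o.key.alt, o.ref_reads, o.var_reads) for o in obs] == [
        ("G", 10, 30),
        ("C", 10, 60),
    ]
    assert all(o.gene == "MSH6" for o in obs)


def test_sample_sheet_roundtrip_and_pairing_heuristic(tmp_path):
    path = tmp_path / "sheet.csv"
    path.write_text(
        "sample_id,patient_id,tissue\n"
        "CC1018N,CC1018,normal\n"
        "CC1018,CC1018,crc\n"
        "CC1109,CC1109,adenoma\n"
    )
    samples = asio.read_sample_sheet(path)
    by_id = {s.sample_id: s for s in samples}
    assert by_id["CC1018N"].paired_sample_id == "CC1018"
    assert by_id["CC1018"].paired_sample_id == "CC1018N"
    assert by_id["CC1109"].paired_sample_id is None
    out = tmp_path / "sheet2.csv"
    asio.write_sample_sheet(samples, out)
    assert asio.read_sample_sheet(out) == samples


def test_catalog_roundtrip(tmp_path):
    cat = Catalog("dbSNP", frozenset({
        VariantKey("chr5", 79966029, "G", "A"),
        VariantKey("chr2", 48033545, "A", "C"),
    }))
    path = tmp_path / "cat.tsv"
    asio.write_catalog(cat, path)
    back = asio.read_catalog(path, "dbSNP")
    assert back.entries == cat.entries


def test_empty_event_report_has_header_only(tmp_path):
    path = tmp_path / "events.tsv"
    asio.write_report([], path, "tsv")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1
    assert lines[0].split("\t")[0] == "patient_id"


def test_event_report_roundtrips_through_dataframe(tmp_path, tiny_cohort):
    obs = [make_obs("p1T", 100 + i, 0.75) for i in range(3)]
    obs += [make_obs("p1N", 100 + i, 0.5) for i in range(3)]
    events, _ = scan_cohort(obs, tiny_cohort)
    path = tmp_path / "events.tsv"
    asio.write_report(events, path, "tsv")
    df = asio.read_events(path)
    assert df.loc[0, "label"] == "somatic"
    assert df.loc[0, "n_variants"] == 3


def test_frequency_table_roundtrip(tmp_path, table2):
    path = tmp_path / "freq.tsv"
    asio.write_report(table2, path, "tsv")
    back = asio.read_frequency_table(path)
    assert back.group_sizes == table2.group_sizes
    assert back.counts(79966029, Tissue.NORMAL) == (6, 1)
    assert (back.df.values == table2.df.values).all()


def test_json_report_parses_back(tmp_path):
    payload = {"a": 1, "b": [1, 2, 3]}
    path = tmp_path / "r.json"
    asio.write_report(payload, path, "json")
    assert json.loads(path.read_text()) == payload
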