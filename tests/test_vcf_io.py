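"""VCF ingestion rules and allele-fraction extraction on small inline VCFs."""

import numpy as np
import pytest

from gtdiscord.encoding import NULL, build_region_map
from gtdiscord.errors import ManifestError
from gtdiscord.vcf_io import (
    AlleleFractionTable,
    IngestConfig,
    IngestStats,
    extract_allele_fractions,
    ingest_manifest,
    ingest_vcfs,
    read_manifest,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, records):
    body = "\n".join("\t".join(r) for r in records)
    path.write_text(HEADER.format(samples="\t".join(samples)) + body + "\n")
    return path


@pytest.fixture
def region():
    # panel: chr1:101, chr1:201, chr1:301
    return build_region_map([("chr1", 100, 101), ("chr1", 200, 201), ("chr1", 300, 301)])


def test_single_sample_basic_encoding(tmp_path, region):
    """GT 0/0, 0/1, ./. at the three panel loci encode A, R, NUL."""
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [
            ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/0"),
            ("chr1", "201", ".", "A", "G", "60", "PASS", ".", "GT", "0/1"),
            ("chr1", "301", ".", "A", "G", "60", "PASS", ".", "GT", "./."),
        ],
    )
    panel = ingest_vcfs([vcf], region)
    assert panel.genotype_string("s1") == b"AR\0"


def test_absent_locus_policies(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [("chr1", "101", ".", "C", "T", "60", "PASS", ".", "GT", "1/1")],
    )
    missing = ingest_vcfs([vcf], region, IngestConfig(absent_policy="missing"))
    assert missing.genotype_string("s1") == b"T\0\0"
    homref = ingest_vcfs(
        [vcf],
        region,
        IngestConfig(absent_policy="homref"),
        reference={("chr1", 201): "G", ("chr1", 301): "T"},
    )
    assert homref.genotype_string("s1") == b"TGT"


def test_homref_uses_ref_seen_in_other_file(tmp_path, region):
    a = write_vcf(
        tmp_path / "a.vcf",
        ["a"],
        [
            ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1"),
            ("chr1", "201", ".", "C", "T", "60", "PASS", ".", "GT", "0/0"),
            ("chr1", "301", ".", "G", "A", "60", "PASS", ".", "GT", "0/0"),
        ],
    )
    b = write_vcf(
        tmp_path / "b.vcf",
        ["b"],
        [("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "1/1")],
    )
    panel = ingest_vcfs([a, b], region, IngestConfig(absent_policy="homref"))
    # sample b's absent loci filled from REF bases observed in file a
    assert panel.genotype_string("b") == b"GCG"


def test_site_qual_filter(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [
            ("chr1", "101", ".", "A", "G", "5", "PASS", ".", "GT", "1/1"),
            ("chr1", "201", ".", "A", "G", "60", "PASS", ".", "GT", "1/1"),
        ],
    )
    panel = ingest_vcfs([vcf], region, IngestConfig(min_site_qual=20))
    assert panel.genotype_string("s1") == b"\0G\0"


def test_min_depth_filter(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [
            ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT:DP", "1/1:3"),
            ("chr1", "201", ".", "A", "G", "60", "PASS", ".", "GT:DP", "1/1:30"),
        ],
    )
    panel = ingest_vcfs([vcf], region, IngestConfig(min_depth=10))
    assert panel.genotype_string("s1") == b"\0G\0"


def test_pass_only_filter(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [
            ("chr1", "101", ".", "A", "G", "60", "LowQual", ".", "GT", "1/1"),
            ("chr1", "201", ".", "A", "G", "60", "PASS", ".", "GT", "1/1"),
        ],
    )
    default = ingest_vcfs([vcf], region)
    assert default.genotype_string("s1") == b"GG\0"
    strict = ingest_vcfs([vcf], region, IngestConfig(pass_only=True))
    assert strict.genotype_string("s1") == b"\0G\0"


def test_non_snv_records_become_missing(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [
            ("chr1", "101", ".", "AT", "A", "60", "PASS", ".", "GT", "1/1"),
            ("chr1", "201", ".", "A", "AGG", "60", "PASS", ".", "GT", "0/1"),
        ],
    )
    panel = ingest_vcfs([vcf], region)
    assert panel.genotype_string("s1") == b"\0\0\0"


def test_first_record_wins_and_duplicates_counted(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [
            ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1"),
            ("chr1", "101", ".", "A", "C", "60", "PASS", ".", "GT", "1/1"),
        ],
    )
    stats = IngestStats()
    panel = ingest_vcfs([vcf], region, stats=stats)
    assert panel.genotype_string("s1")[0:1] == b"R"
    assert stats.duplicate_records == 1


def test_contig_normalization(tmp_path):
    region = build_region_map([("1", 100, 101)])
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "1/1")],
    )
    strict = ingest_vcfs([vcf], region)
    assert strict.genotype_string("s1") == b"\0"
    relaxed = ingest_vcfs([vcf], region, IngestConfig(contig_normalization=True))
    assert relaxed.genotype_string("s1") == b"G"


def test_multisample_equals_split_files(tmp_path, region):
    """A multi-sample VCF and the same calls split per sample yield the same
    panel bytes (sample order aside)."""
    records = [
        ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1", "1/1"),
        ("chr1", "201", ".", "C", "T", "60", "PASS", ".", "GT", "0/0", "./."),
        ("chr1", "301", ".", "G", "T", "60", "PASS", ".", "GT", "1/1", "0/1"),
    ]
    multi = write_vcf(tmp_path / "multi.vcf", ["s1", "s2"], records)
    only1 = write_vcf(
        tmp_path / "only1.vcf", ["s1"], [r[:10] for r in records]
    )
    only2 = write_vcf(
        tmp_path / "only2.vcf", ["s2"], [r[:9] + (r[10],) for r in records]
    )
    p_multi = ingest_vcfs([multi], region)
    p_split = ingest_vcfs([only1, only2], region)
    for s in ("s1", "s2"):
        assert p_multi.genotype_string(s) == p_split.genotype_string(s)


def test_ingest_is_deterministic(tmp_path, region):
    vcf = write_vcf(
        tmp_path / "s1.vcf",
        ["s1"],
        [("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1")],
    )
    p1 = ingest_vcfs([vcf], region)
    p2 = ingest_vcfs([vcf], region)
    assert (p1.data == p2.data).all()


def test_duplicate_samples_across_files_rejected(tmp_path, region):
    a = write_vcf(
        tmp_path / "a.vcf", ["s1"],
        [("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1")],
    )
    b = write_vcf(
        tmp_path / "b.vcf", ["s1"],
        [("chr1", "201", ".", "A", "G", "60", "PASS", ".", "GT", "0/1")],
    )
    with pytest.raises(ManifestError, match="duplicate"):
        ingest_vcfs([a, b], region)


def test_zero_overlap_warns(tmp_path, region, caplog):
    vcf = write_vcf(
        tmp_path / "s1.vcf", ["s1"],
        [("chr2", "9999", ".", "A", "G", "60", "PASS", ".", "GT", "0/1")],
    )
    with caplog.at_level("WARNING"):
        panel = ingest_vcfs([vcf], region)
    assert "zero panel positions" in caplog.text
    assert panel.genotype_string("s1") == b"\0\0\0"


class TestAlleleFractions:
    def test_fraction_rules(self, tmp_path, region):
        vcf = write_vcf(
            tmp_path / "s1.vcf",
            ["s1"],
            [
                ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT:AD", "0/1:10,10"),
                ("chr1", "201", ".", "A", "G", "60", "PASS", ".", "GT:AD", "0/0:20,0"),
                ("chr1", "301", ".", "A", "G", "60", "PASS", ".", "GT:AD", "./.:0,0"),
            ],
        )
        table = extract_allele_fractions([vcf], region)
        assert table.available
        sub = table.for_sample("s1").set_index("pos")
        assert sub.loc[101, "fraction"] == pytest.approx(0.5)
        assert sub.loc[201, "fraction"] == pytest.approx(0.0)
        assert 301 not in sub.index  # zero depth omitted

    def test_missing_ad_degrades_gracefully(self, tmp_path, region):
        vcf = write_vcf(
            tmp_path / "s1.vcf",
            ["s1"],
            [("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1")],
        )
        table = extract_allele_fractions([vcf], region)
        assert not table.available
        assert len(table.table) == 0


class TestManifest:
    def test_read_and_resolve_paths(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "sample_name\tvcf_path\tindividual_id\ns1\ta.vcf\tI1\n"
        )
        df = read_manifest(tmp_path / "m.tsv")
        assert df.loc[0, "vcf_path"] == str(tmp_path / "a.vcf")

    def test_duplicate_sample_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "sample_name\tvcf_path\ns1\ta.vcf\ns1\tb.vcf\n"
        )
        with pytest.raises(ManifestError, match="duplicate"):
            read_manifest(tmp_path / "m.tsv")

    def test_manifest_order_drives_panel_order(self, tmp_path, region):
        records = [
            ("chr1", "101", ".", "A", "G", "60", "PASS", ".", "GT", "0/1", "1/1"),
        ]
        write_vcf(tmp_path / "multi.vcf", ["s1", "s2"], records)
        (tmp_path / "m.tsv").write_text(
            "sample_name\tvcf_path\ns2\tmulti.vcf\ns1\tmulti.vcf\n"
        )
        panel = ingest_manifest(tmp_path / "m.tsv", region)
        assert panel.sample_names == ["s2", "s1"]
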