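"""SVCR-VCF serialization, dense exports, and cross-parser checks."""

import io

import pytest

from svcr.combine import merge
from svcr.core import validate_dataset
from svcr.densify import densify_stream
from svcr.gvcf import import_gvcf
from svcr.vcfio import (
    MAX_BLOCK_KEY,
    SvcrVcfError,
    decode_payload,
    encode_payload,
    export_dense_pvcf,
    export_hardcalls_pvcf,
    read_svcr_vcf,
    write_svcr_vcf,
)


def render(ds, **kw) -> str:
    buf = io.StringIO()
    write_svcr_vcf(ds, buf, **kw)
    return buf.getvalue()


@pytest.fixture(scope="module")
def merged4(cohort4):
    return merge(cohort4.import_all())


class TestPayloadCodec:
    def test_round_trip_with_reserved_characters(self):
        payload = {"END": "42", "FLAG": None, "odd;key": "a:b|c=d %", "_QUAL": "9.1"}
        assert decode_payload(encode_payload(payload)) == payload

    def test_empty_is_dot(self):
        assert encode_payload({}) == "."
        assert decode_payload(".") == {}


class TestWriteRead:
    def test_header_declares_format_fields_and_max_block_length(self, merged4):
        text = render(merged4)
        header = [l for l in text.splitlines() if l.startswith("##")]
        for key in ("LA", "LEN", "LGT", "LAD", "LPL"):
            assert any(l.startswith(f"##FORMAT=<ID={key},") for l in header), key
        assert any(
            l == f"##{MAX_BLOCK_KEY}={merged4.max_ref_block_length}" for l in header
        )
        assert any(l.startswith("##contig=<ID=chr1") for l in header)

    def test_single_sample_rows(self, cohort4):
        from svcr.gvcf import GvcfRecord

        recs = [
            GvcfRecord("chr1", 10, "A", ("<NON_REF>",), info={"END": "99"},
                       fmt={"GT": "0/0", "DP": "30", "GQ": "50"}),
            GvcfRecord("chr1", 150, "A", ("T",), fmt={"GT": "0/1"}),
        ]
        ds = import_gvcf(recs, "S1")
        text = render(ds)
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == 2
        block_row, var_row = data
        assert block_row.split("\t")[4] == "."  # ALT of block-only row
        fmt = var_row.split("\t")[8].split(":")
        sample = dict(zip(fmt, var_row.split("\t")[9].split(":")))
        assert sample["LA"] == "0,1" and sample["LEN"] == "."
        block_sample = dict(zip(fmt, block_row.split("\t")[9].split(":")))
        assert block_sample["LEN"] == "90" and block_sample["LA"] == "."

    def test_round_trip_equality(self, merged4):
        ds2 = read_svcr_vcf(io.StringIO(render(merged4)))
        assert ds2 == merged4

    def test_byte_stable_output(self, merged4):
        assert render(merged4) == render(merged4)

    def test_bgzip_round_trip(self, tmp_path, merged4):
        path = str(tmp_path / "ds.svcr.vcf.gz")
        write_svcr_vcf(merged4, path)
        assert read_svcr_vcf(path) == merged4

    def test_shared_locus_block_and_variant_in_one_row(self):
        from svcr.gvcf import GvcfRecord

        a = import_gvcf(
            [GvcfRecord("chr1", 100, "A", ("T",), fmt={"GT": "0/1"})], "a"
        )
        b = import_gvcf(
            [GvcfRecord("chr1", 100, "A", ("<NON_REF>",), info={"END": "180"},
                        fmt={"GT": "0/0", "DP": "22", "GQ": "44"})], "b"
        )
        merged = merge([a, b])
        text = render(merged)
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == 1
        cols = data[0].split("\t")
        fmt = cols[8].split(":")
        ga = dict(zip(fmt, cols[9].split(":")))
        gb = dict(zip(fmt, cols[10].split(":")))
        assert ga["LA"] != "." and ga["LEN"] == "."
        assert gb["LEN"] == "81" and gb["LA"] == "."
        back = read_svcr_vcf(io.StringIO(text))
        assert back == merged

    def test_invalid_dataset_rejected_before_writing(self, merged4):
        import copy

        broken = copy.deepcopy(merged4)
        broken.max_ref_block_length = 1  # understates every block
        with pytest.raises(SvcrVcfError, match="invalid dataset"):
            write_svcr_vcf(broken, io.StringIO())

    def test_understated_header_maximum_rejected_on_read(self, merged4):
        text = render(merged4)
        bad = text.replace(
            f"##{MAX_BLOCK_KEY}={merged4.max_ref_block_length}",
            f"##{MAX_BLOCK_KEY}=1",
        )
        with pytest.raises(SvcrVcfError, match="understates"):
            read_svcr_vcf(io.StringIO(bad))

    def test_len_and_la_together_rejected(self):
        text = (
            "##fileformat=VCFv4.3\n##MAXIMUM_REFERENCE_BLOCK_LENGTH=10\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=LA,Number=.,Type=Integer,Description="x">\n'
            '##FORMAT=<ID=LEN,Number=1,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t5\t.\tA\tT\t.\t.\t.\tLA:LEN\t0,1:7\n"
        )
        with pytest.raises(SvcrVcfError, match="both LEN and LA"):
            read_svcr_vcf(io.StringIO(text))

    def test_fields_inside_block_rejected(self):
        text = (
            "##fileformat=VCFv4.3\n##MAXIMUM_REFERENCE_BLOCK_LENGTH=50\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=LA,Number=.,Type=Integer,Description="x">\n'
            '##FORMAT=<ID=LEN,Number=1,Type=Integer,Description="x">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t10\t.\tA\t.\t.\t.\t.\tLA:LEN:DP\t.:40:30\n"
            "chr1\t20\t.\tA\tT\t.\t.\t.\tLA:LEN:DP\t0,1:.:9\n"
        )
        with pytest.raises(SvcrVcfError, match="inside its block"):
            read_svcr_vcf(io.StringIO(text))

    def test_missing_la_len_declarations_rejected(self):
        text = (
            "##fileformat=VCFv4.3\n##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t5\t.\tA\tT\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(SvcrVcfError, match="declare LA and LEN"):
            read_svcr_vcf(io.StringIO(text))


class TestHandWrittenTwoSampleFile:
    """A hand-authored two-sample SVCR-VCF whose densification is known.

    Both samples share a reference block 10-29; at chr1:30 sample 01 has a het
    SNV and sample 02 a hom-alt insertion at the same (multiallelic) site;
    sample 01 then resumes reference coverage 31-49 while sample 02's
    coverage ends, mirroring the GVCF/PVCF/sparse three-way picture.
    """

    TEXT = (
        "##fileformat=VCFv4.3\n"
        "##MAXIMUM_REFERENCE_BLOCK_LENGTH=20\n"
        "##contig=<ID=chr1>\n"
        '##FORMAT=<ID=LGT,Number=1,Type=String,Description="x">\n'
        '##FORMAT=<ID=LA,Number=.,Type=Integer,Description="x">\n'
        '##FORMAT=<ID=LEN,Number=1,Type=Integer,Description="x">\n'
        '##FORMAT=<ID=LAD,Number=.,Type=Integer,Description="x">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t01\t02\n"
        "chr1\t10\t.\tA\t.\t.\t.\t.\tLGT:LA:LEN:LAD:DP:GQ\t"
        "0/0:.:20:.:31:52\t0/0:.:20:.:27:48\n"
        "chr1\t30\t.\tA\tT,ATT\t.\t.\t.\tLGT:LA:LEN:LAD:DP:GQ\t"
        "0/1:0,1:.:15,14:29:45\t1/1:0,2:.:0,26:26:39\n"
        "chr1\t31\t.\tC\t.\t.\t.\t.\tLGT:LA:LEN:LAD:DP:GQ\t"
        "0/0:.:19:.:31:52\t.:.:.:.:.:.\n"
    )

    def test_densification_matches_expected_calls(self):
        ds = read_svcr_vcf(io.StringIO(self.TEXT))
        assert validate_dataset(ds) == []
        (row,) = densify_stream(ds)
        assert row.alleles.alts == ("T", "ATT")
        assert str(row.calls["01"].gt) == "0/1"
        assert row.calls["01"].ad == (15, 14, 0)
        assert str(row.calls["02"].gt) == "2/2"
        assert row.calls["02"].ad == (0, 0, 26)

    def test_point_query_between_records_uses_blocks(self):
        from svcr.core import GenomicLocus
        from svcr.densify import densify_at_locus

        ds = read_svcr_vcf(io.StringIO(self.TEXT))
        row = densify_at_locus(ds, GenomicLocus("chr1", 45))
        assert row.calls["01"].from_block and row.calls["01"].dp == 31
        assert row.calls["02"] is None  # block 10-29 has ended


class TestDenseExports:
    def test_hardcalls_has_gt_only_and_no_blocks(self, merged4):
        buf = io.StringIO()
        export_hardcalls_pvcf(merged4, buf)
        text = buf.getvalue()
        for forbidden in ("LEN", "LA", "LAD", "LPL", "\tAD", "PL"):
            assert forbidden not in text
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == len(merged4.variant_matrix)
        assert all(l.split("\t")[8] == "GT" for l in data)

    def test_hardcalls_gt_matches_source_gvcf(self, cohort4):
        sg = cohort4.samples[0]
        ds = import_gvcf(sg.records, sg.sample_id, "drop", [cohort4.model.contig])
        buf = io.StringIO()
        export_hardcalls_pvcf(ds, buf)
        data = [l for l in buf.getvalue().splitlines() if not l.startswith("#")]
        variant_recs = [r for r in sg.records if not r.is_reference_row()]
        assert [l.split("\t")[9] for l in data] == \
            [r.fmt["GT"] for r in variant_recs]

    def test_dense_pvcf_matches_stream(self, merged4):
        buf = io.StringIO()
        export_dense_pvcf(merged4, buf)
        data = [l for l in buf.getvalue().splitlines() if not l.startswith("#")]
        rows = list(densify_stream(merged4))
        assert len(data) == len(rows)
        line = data[0].split("\t")
        assert line[8] == "GT:AD:DP:GQ:PL"
        first = rows[0]
        for idx, s in enumerate(merged4.samples):
            call = first.calls[s]
            got_gt = line[9 + idx].split(":")[0]
            if call is None:
                assert got_gt == "./."
            else:
                assert got_gt == str(call.gt)

    def test_empty_dataset_dense_export_is_header_only(self):
        from svcr.core import SvcrDataset

        buf = io.StringIO()
        export_dense_pvcf(SvcrDataset(["S1"], ["chr1"]), buf)
        assert all(l.startswith("#") for l in buf.getvalue().splitlines())


class TestPysamCrossCheck:
    """An independent, standards-compliant VCF parser must agree with ours."""

    def test_pysam_reads_our_output(self, tmp_path, merged4):
        pysam = pytest.importorskip("pysam")
        path = str(tmp_path / "ds.svcr.vcf")
        write_svcr_vcf(merged4, path)
        with pysam.VariantFile(path) as vf:
            assert list(vf.header.samples) == merged4.samples
            n_rows = 0
            n_len = 0
            for rec in vf:
                n_rows += 1
                for s in rec.samples.values():
                    if s.get("LEN") is not None:
                        n_len += 1
            row_loci = {ds_loc for ds_loc, _ in merged4.reference_matrix} | {
                s.locus for s in merged4.variant_matrix
            }
            assert n_rows == len(row_loci)
            assert n_len == merged4.n_reference_blocks()
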