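"""Access-policy VCF filtering: modes, masking, header fidelity."""

import gzip
import io

import pytest

from dsgd.disclosure import (
    AccessPolicy,
    count_matching,
    filter_vcf,
    normalize_policy,
)
from dsgd.errors import PolicyError, VcfParseError
from dsgd.fixtures import gen_vcf


def _filter_text(text, policy):
    out = io.StringIO()
    result = filter_vcf(io.StringIO(text), policy, out)
    return out.getvalue(), result


class TestNormalizePolicy:
    def test_overlapping_regions_merge(self):
        p = normalize_policy({"mode": "regions", "regions": ["chr1:10-20", "chr1:15-30"]})
        assert p.regions == (("chr1", 10, 30),)

    def test_empty_config_releases_nothing(self):
        assert normalize_policy({}).mode == "none"
        assert normalize_policy(None).mode == "none"

    def test_inverted_region_rejected(self):
        with pytest.raises(PolicyError):
            normalize_policy({"mode": "regions", "regions": ["chr1:20-10"]})

    def test_negative_coordinates_rejected(self):
        with pytest.raises(PolicyError):
            normalize_policy({"mode": "regions", "regions": [("chr1", 0, 10)]})

    def test_unknown_mode_rejected(self):
        with pytest.raises(PolicyError):
            normalize_policy({"mode": "some"})

    def test_duplicate_variant_ids_deduplicated(self):
        p = normalize_policy({"mode": "id_list", "variant_ids": ["rs1", "rs1", "rs2"]})
        assert p.variant_ids == frozenset({"rs1", "rs2"})


class TestFilterModes:
    def test_mode_none_header_only(self, small_vcf_text):
        text, result = _filter_text(small_vcf_text, {"mode": "none"})
        assert result.records_out == 0
        assert all(l.startswith("#") for l in text.splitlines() if l)

    def test_mode_all_passes_everything(self, small_vcf_text):
        _, result = _filter_text(small_vcf_text, {"mode": "all"})
        assert result.records_out == result.records_in == 3000

    def test_count_mode_first_n_in_order(self, small_vcf_text):
        text, result = _filter_text(
            small_vcf_text, {"mode": "count", "max_records": 30}
        )
        assert result.records_out == 30
        expected_first_30 = [
            l for l in small_vcf_text.splitlines() if not l.startswith("#")
        ][:30]
        got = [l for l in text.splitlines() if not l.startswith("#")]
        assert got == expected_first_30

    def test_region_mode_planted_positions(self):
        # regular spacing makes the in-range count exactly known
        lines = ["##fileformat=VCFv4.2",
                 "##contig=<ID=chr1,length=2000>",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        for i in range(100):
            lines.append(f"chr1\t{(i + 1) * 10}\trs{i}\tA\tG\t.\tPASS\tDP=10")
        text = "\n".join(lines) + "\n"
        _, result = _filter_text(text, {"mode": "regions", "regions": ["chr1:1-500"]})
        assert result.records_out == 50  # positions 10..500 step 10

    def test_region_boundaries_inclusive(self):
        text = ("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                "chr1\t100\t.\tA\tG\t.\t.\t.\nchr1\t101\t.\tA\tG\t.\t.\t.\n"
                "chr1\t200\t.\tA\tG\t.\t.\t.\nchr1\t201\t.\tA\tG\t.\t.\t.\n")
        _, r = _filter_text(text, {"mode": "regions", "regions": ["chr1:100-200"]})
        assert r.records_out == 3

    def test_id_list_mode(self, small_vcf_text):
        pol = {"mode": "id_list", "variant_ids": ["rs5", "rs100", "rs2999", "rs99999"]}
        _, result = _filter_text(small_vcf_text, pol)
        assert result.records_out == 3  # rs99999 does not exist

    def test_unknown_chromosome_yields_zero_not_error(self, small_vcf_text):
        _, result = _filter_text(
            small_vcf_text, {"mode": "regions", "regions": ["chrZ:1-1000"]}
        )
        assert result.records_out == 0


class TestFieldMasking:
    def test_info_allow_list(self, small_vcf_text):
        pol = {"mode": "all", "info_fields": ["DP"]}
        text, result = _filter_text(small_vcf_text, pol)
        assert result.fields_masked == 3000  # AF removed from every record
        for line in text.splitlines():
            if line.startswith("#"):
                continue
            info = line.split("\t")[7]
            assert "AF=" not in info and "DP=" in info

    def test_info_mask_all_yields_dot(self, small_vcf_text):
        text, _ = _filter_text(small_vcf_text, {"mode": "all", "info_fields": []})
        record = next(l for l in text.splitlines() if not l.startswith("#"))
        assert record.split("\t")[7] == "."

    def test_format_allow_list_keeps_gt(self, small_vcf_text):
        text, _ = _filter_text(small_vcf_text, {"mode": "all", "format_fields": ["GT"]})
        record = next(l for l in text.splitlines() if not l.startswith("#"))
        fields = record.split("\t")
        assert fields[8] == "GT" and fields[9] in ("0/1", "1/1")


class TestStreamFidelity:
    def test_header_preserved_verbatim_plus_provenance(self, small_vcf_text):
        text, _ = _filter_text(small_vcf_text, {"mode": "count", "max_records": 5})
        original_header = [l for l in small_vcf_text.splitlines() if l.startswith("#")]
        new_header = [l for l in text.splitlines() if l.startswith("#")]
        added = [l for l in new_header if l not in original_header]
        assert len(added) == 1 and added[0].startswith("##dsgd_filter=")
        assert [l for l in new_header if l in original_header] == original_header

    def test_idempotent_under_same_policy(self, small_vcf_text):
        pol = normalize_policy({"mode": "count", "max_records": 100, "user_id": "u"})
        once, _ = _filter_text(small_vcf_text, pol)
        twice, _ = _filter_text(once, pol)
        assert once == twice

    def test_monotone_in_max_records(self, small_vcf_text):
        counts = [
            count_matching(io.StringIO(small_vcf_text), {"mode": "count", "max_records": n})
            for n in (0, 10, 100, 5000)
        ]
        assert counts == sorted(counts) == [0, 10, 100, 3000]

    def test_monotone_in_regions(self, small_vcf_text):
        small = count_matching(
            io.StringIO(small_vcf_text), {"mode": "regions", "regions": ["chr1:1-100"]}
        )
        large = count_matching(
            io.StringIO(small_vcf_text), {"mode": "regions", "regions": ["chr1:1-10000"]}
        )
        assert small <= large

    def test_gzip_and_plain_input_identical(self, small_vcf_text, tmp_path):
        plain = tmp_path / "records.vcf"
        gz = tmp_path / "records.vcf.gz"
        plain.write_text(small_vcf_text)
        with gzip.open(gz, "wt") as fh:
            fh.write(small_vcf_text)
        pol = {"mode": "count", "max_records": 77}
        out_plain = tmp_path / "a.vcf"
        out_gz_src = tmp_path / "b.vcf"
        filter_vcf(str(plain), pol, str(out_plain))
        filter_vcf(str(gz), pol, str(out_gz_src))
        assert out_plain.read_text() == out_gz_src.read_text()

    def test_count_matching_agrees_with_filter(self, small_vcf_text):
        for pol in (
            {"mode": "none"},
            {"mode": "count", "max_records": 123},
            {"mode": "regions", "regions": ["chr2:1-5000"]},
            {"mode": "id_list", "variant_ids": [f"rs{i}" for i in range(0, 400, 7)]},
            {"mode": "all"},
        ):
            _, result = _filter_text(small_vcf_text, pol)
            assert count_matching(io.StringIO(small_vcf_text), pol) == result.records_out

    def test_malformed_record_reports_line_number(self):
        text = ("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                "chr1\tnotanumber\t.\tA\tG\t.\t.\t.\n")
        with pytest.raises(VcfParseError) as err:
            _filter_text(text, {"mode": "all"})
        assert err.value.line_number == 3


class TestAgainstHtslibParser:
    """Independent oracle: pysam parses our filtered output and agrees on
    record counts and region membership."""

    def test_filtered_output_parses_and_counts_match(self, small_vcf_text, tmp_path):
        pysam = pytest.importorskip("pysam")
        src = tmp_path / "in.vcf"
        src.write_text(small_vcf_text)
        out = tmp_path / "out.vcf"
        result = filter_vcf(
            str(src), {"mode": "regions", "regions": ["chr1:1-3000"]}, str(out)
        )
        with pysam.VariantFile(str(out)) as vf:
            records = list(vf)
        assert len(records) == result.records_out
        assert all(r.chrom == "chr1" and 1 <= r.pos <= 3000 for r in records)

    def test_region_count_matches_pysam_on_input(self, small_vcf_text, tmp_path):
        pysam = pytest.importorskip("pysam")
        src = tmp_path / "in.vcf"
        src.write_text(small_vcf_text)
        with pysam.VariantFile(str(src)) as vf:
            oracle = sum(1 for r in vf if r.chrom == "chr2" and 50 <= r.pos <= 4000)
        ours = count_matching(
            str(src), {"mode": "regions", "regions": ["chr2:50-4000"]}
        )
        assert ours == oracle
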