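"""Parsers for the ClinVar VCF dialect and the three annotator dialects."""

from __future__ import annotations

import pysam
import pytest

from varconcord.model import ClinSig, GenomicVariant, ParseStats, Tool, ToolAnnotation
from varconcord.simulate import write_outputs
from varconcord.variant_io import (
    DEFAULT_CSQ_ORDER,
    csq_field_order_from_header,
    format_snpeff_ann,
    format_vep_csq,
    parse_annovar_table,
    parse_snpeff_ann,
    parse_vep_csq,
    read_annotation_table,
    read_clinvar_vcf,
    write_annotation_table,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n##contig=<ID=13>\n##contig=<ID=MT>\n"
    '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="sig">\n'
    '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="rev">\n'
    '##INFO=<ID=MC,Number=.,Type=String,Description="mc">\n'
    '##INFO=<ID=ANN,Number=.,Type=String,Description="ann">\n'
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations'
    " from VEP. Format: " + "|".join(DEFAULT_CSQ_ORDER) + '">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(tmp_path, lines, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in lines))
    return str(path)


class TestReadClinvarVcf:
    @pytest.mark.parametrize(
        "info, expected",
        [
            ("CLNSIG=Pathogenic;CLNREVSTAT=reviewed_by_expert_panel;MC=SO:0001575|splice_donor_variant",
             dict(clnsig=ClinSig.P, stars=3, mcs=[(None, "splice_donor_variant")])),
            ("CLNSIG=Uncertain_significance;CLNREVSTAT=criteria_provided,_single_submitter",
             dict(clnsig=ClinSig.VUS, stars=1, mcs=[])),
            ("CLNSIG=Likely_benign;CLNREVSTAT=practice_guideline;MC=SO:0001583|missense_variant,SO:0001627|intron_variant",
             dict(clnsig=ClinSig.LB, stars=4,
                  mcs=[(None, "missense_variant"), (None, "intron_variant")])),
        ],
    )
    def test_info_parsing(self, tmp_path, info, expected):
        path = write_vcf(tmp_path, [f"13\t100\t42\tA\tG\t.\t.\t{info}"])
        (rec,) = list(read_clinvar_vcf(path))
        assert rec.clnsig is expected["clnsig"]
        assert rec.stars == expected["stars"]
        assert rec.molecular_consequences == expected["mcs"]
        assert rec.variant == GenomicVariant("13", 100, "A", "G", clinvar_id=42)

    def test_multiallelic_split(self, tmp_path):
        path = write_vcf(tmp_path, [
            "1\t50\t7\tA\tG,T\t.\t.\tCLNSIG=Benign;CLNREVSTAT=criteria_provided,_multiple_submitters,_no_conflicts"
        ])
        recs = list(read_clinvar_vcf(path))
        assert [r.variant.alt for r in recs] == ["G", "T"]
        assert all(r.stars == 2 for r in recs)

    def test_unparseable_info_flags_not_crashes(self, tmp_path):
        stats = ParseStats()
        path = write_vcf(tmp_path, [
            "1\t60\t8\tC\tT\t.\t.\tCLNREVSTAT=no_assertion_provided;MC=garbage_without_pipes"
        ])
        (rec,) = list(read_clinvar_vcf(path, stats=stats))
        assert rec.clnsig is ClinSig.OTHER
        assert rec.stars == 0
        assert any(f.startswith("malformed_mc") for f in rec.flags)
        assert stats.get("malformed_mc") == 1

    def test_missing_file_is_fatal(self):
        with pytest.raises(OSError):
            list(read_clinvar_vcf("/nonexistent/x.vcf"))


class TestSnpeffAnn:
    def test_ampersand_terms_split(self, tmp_path):
        ann = "G|splice_donor_variant&intron_variant|HIGH|X|X|transcript|NM_001048174.2|protein_coding||c.1434+2del||||||"
        path = write_vcf(tmp_path, [f"1\t10\t.\tGA\tG\t.\t.\tANN={ann}"])
        rec = next(pysam.VariantFile(path))
        (a,) = parse_snpeff_ann(rec)
        assert a.raw_consequences == ["splice_donor_variant", "intron_variant"]
        assert a.transcript_accession == "NM_001048174"
        assert a.transcript_version == 2
        assert a.hgvs_p is None  # empty subfield -> absent

    def test_two_entries_two_annotations(self, tmp_path):
        anns = ",".join([
            "G|missense_variant|MOD|X|X|transcript|NM_000001.1|protein_coding||c.1A>G|p.Met1Val|||||",
            "G|intron_variant|MOD|X|X|transcript|NM_000002.1|protein_coding||c.2-5A>G||||||",
        ])
        path = write_vcf(tmp_path, [f"1\t10\t.\tA\tG\t.\t.\tANN={anns}"])
        rec = next(pysam.VariantFile(path))
        assert len(parse_snpeff_ann(rec)) == 2

    def test_short_entry_counted_malformed(self, tmp_path):
        stats = ParseStats()
        path = write_vcf(tmp_path, ["1\t10\t.\tA\tG\t.\t.\tANN=G|missense_variant|only|four"])
        rec = next(pysam.VariantFile(path))
        assert parse_snpeff_ann(rec, stats) == []
        assert stats.get("malformed_ann_entry") == 1

    def test_non_transcript_accession_rejected(self, tmp_path):
        stats = ParseStats()
        ann = "G|missense_variant|MOD|X|X|transcript|XR_99.1|protein_coding||c.1A>G||||||"
        path = write_vcf(tmp_path, [f"1\t10\t.\tA\tG\t.\t.\tANN={ann}"])
        assert parse_snpeff_ann(next(pysam.VariantFile(path)), stats) == []
        assert stats.get("rejected_accession") == 1


class TestVepCsq:
    def _annotation(self):
        return ToolAnnotation(
            tool=Tool.VEP,
            variant=GenomicVariant("1", 10, "A", "G"),
            transcript_accession="ENST00000544455",
            transcript_version=6,
            protein_accession="NP_000001.1",
            hgvs_c="ENST00000544455.6:c.2T>C",
            hgvs_p="NP_000001.1:p.Met1=",
            raw_consequences=["missense_variant"],
        )

    def test_header_driven_order_and_percent_decode(self, tmp_path):
        csq = format_vep_csq(self._annotation())
        assert "%3D" in csq
        path = write_vcf(tmp_path, [f"1\t10\t.\tA\tG\t.\t.\tCSQ={csq}"])
        vcf = pysam.VariantFile(path)
        order = csq_field_order_from_header(vcf)
        assert order == DEFAULT_CSQ_ORDER
        (a,) = parse_vep_csq(next(vcf), order)
        assert a.transcript_accession == "ENST00000544455"
        assert a.transcript_version == 6
        assert a.hgvs_p == "NP_000001.1:p.Met1="  # %3D decoded

    def test_permuted_header_same_result(self, tmp_path):
        ann = self._annotation()
        order = list(reversed(DEFAULT_CSQ_ORDER))
        csq = format_vep_csq(ann, order)
        header = VCF_HEADER.replace("|".join(DEFAULT_CSQ_ORDER), "|".join(order))
        path = tmp_path / "perm.vcf"
        path.write_text(header + f"1\t10\t.\tA\tG\t.\t.\tCSQ={csq}\n")
        vcf = pysam.VariantFile(str(path))
        (a,) = parse_vep_csq(next(vcf), csq_field_order_from_header(vcf))
        assert (a.transcript_accession, a.hgvs_c) == (ann.transcript_accession, ann.hgvs_c)

    def test_field_count_mismatch_flagged(self, tmp_path):
        stats = ParseStats()
        path = write_vcf(tmp_path, ["1\t10\t.\tA\tG\t.\t.\tCSQ=G|missense_variant|too|short"])
        assert parse_vep_csq(next(pysam.VariantFile(path)), DEFAULT_CSQ_ORDER, stats) == []
        assert stats.get("csq_field_count_mismatch") == 1


class TestAnnovarTable:
    HEADER = "Chr\tStart\tEnd\tRef\tAlt\tFunc.refGene\tGene.refGene\tGeneDetail.refGene\tExonicFunc.refGene\tAAChange.refGene\n"

    def _table(self, tmp_path, rows):
        path = tmp_path / "multianno.tsv"
        path.write_text(self.HEADER + "".join("\t".join(r) + "\n" for r in rows))
        return str(path)

    def test_aachange_cell(self, tmp_path):
        path = self._table(tmp_path, [
            ["2", "2662", "2662", "G", "A", "exonic", "OTOF", ".",
             "nonsynonymous SNV", "OTOF:NM_194248:exon22:c.2662G>A:p.E888K"],
        ])
        (a,) = parse_annovar_table(path)
        assert a.transcript_accession == "NM_194248"
        assert a.transcript_version is None  # ANNOVAR is versionless
        assert a.protein_accession is None
        assert (a.hgvs_c, a.hgvs_p) == ("c.2662G>A", "p.E888K")
        assert a.raw_consequences == ["nonsynonymous SNV"]

    def test_dot_cell_counted_missing(self, tmp_path):
        stats = ParseStats()
        path = self._table(tmp_path, [["1", "5", "5", "A", "G", ".", ".", ".", ".", "."]])
        assert parse_annovar_table(path, stats=stats) == []
        assert stats.get("missing_annotation") == 1

    def test_two_transcript_entries(self, tmp_path):
        cell = "G1:NM_000001:exon1:c.1A>G:p.M1V,G1:NM_000002:exon1:c.7A>G:p.M3V"
        path = self._table(tmp_path, [
            ["1", "5", "5", "A", "G", "exonic", "G1", ".", "nonsynonymous SNV", cell]
        ])
        assert [a.transcript_accession for a in parse_annovar_table(path)] == [
            "NM_000001", "NM_000002"
        ]

    def test_missing_columns_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Chr\tStart\n1\t5\n")
        with pytest.raises(ValueError, match="missing required columns"):
            parse_annovar_table(str(path))


class TestRoundTrips:
    def test_dialect_round_trip_on_simulated_world(self, small_sim, tmp_path):
        """Each parser re-reads what write_outputs wrote, identically."""
        paths = write_outputs(small_sim, tmp_path / "out")
        # reference VCF round-trip
        recs = list(read_clinvar_vcf(paths["reference"]))
        by_key = {r.variant.key: r for r in recs}
        assert len(recs) == len(small_sim.reference)
        for ref in small_sim.reference:
            got = by_key[ref.variant.key]
            assert got.clnsig is ref.clnsig
            assert got.stars == ref.stars
            assert got.clinvar_hgvs_c == ref.clinvar_hgvs_c
            assert [t for _, t in got.molecular_consequences] == [
                t for _, t in ref.molecular_consequences
            ]
        # SnpEff ANN round-trip
        vcf = pysam.VariantFile(paths["snpeff"])
        parsed = [a for rec in vcf for a in parse_snpeff_ann(rec)]
        expected = {(a.variant.key, a.versioned_accession): a
                    for a in small_sim.tool_annotations["snpeff"]}
        assert len(parsed) == len(expected)
        for a in parsed:
            e = expected[(a.variant.key, a.versioned_accession)]
            assert (a.hgvs_c, a.hgvs_p, a.raw_consequences) == (
                e.hgvs_c, e.hgvs_p, e.raw_consequences
            )
        # VEP CSQ round-trip
        vcf = pysam.VariantFile(paths["vep"])
        order = csq_field_order_from_header(vcf)
        parsed = [a for rec in vcf for a in parse_vep_csq(rec, order)]
        expected = {(a.variant.key, a.versioned_accession): a
                    for a in small_sim.tool_annotations["vep"]}
        assert len(parsed) == len(expected)
        for a in parsed:
            e = expected[(a.variant.key, a.versioned_accession)]
            assert (a.hgvs_c, a.hgvs_p, a.raw_consequences) == (
                e.hgvs_c, e.hgvs_p, e.raw_consequences
            )
        # ANNOVAR table round-trip
        parsed = parse_annovar_table(paths["annovar"])
        expected = {(a.variant.key, a.transcript_accession): a
                    for a in small_sim.tool_annotations["annovar"]}
        assert len(parsed) == len(expected)
        for a in parsed:
            e = expected[(a.variant.key, a.transcript_accession)]
            assert (a.hgvs_c, a.hgvs_p, a.raw_consequences) == (
                e.hgvs_c, e.hgvs_p, e.raw_consequences
            )

    def test_annotation_table_round_trip(self, small_sim, tmp_path):
        anns = small_sim.tool_annotations["vep"][:50]
        path = tmp_path / "table.tsv"
        write_annotation_table(anns, path)
        got = read_annotation_table(path)
        for a, e in zip(got, anns):
            assert a.variant.key == e.variant.key
            assert (a.tool, a.transcript_accession, a.transcript_version) == (
                e.tool, e.transcript_accession, e.transcript_version
            )
            assert (a.hgvs_c, a.hgvs_p, a.raw_consequences) == (
                e.hgvs_c, e.hgvs_p, e.raw_consequences
            )

    def test_missing_sentinels_agree(self, tmp_path):
        """'.', '' and absent fields all map to the same internal absence."""
        ann = "G|missense_variant|MOD|X|X|transcript|NM_000001.1|protein_coding||c.1A>G||||||"
        path = write_vcf(tmp_path, [f"1\t10\t.\tA\tG\t.\t.\tANN={ann}"])
        (a1,) = parse_snpeff_ann(next(pysam.VariantFile(path)))
        assert a1.hgvs_p is None
        table = (
            "Chr\tStart\tEnd\tRef\tAlt\tFunc.refGene\tGene.refGene\t"
            "GeneDetail.refGene\tExonicFunc.refGene\tAAChange.refGene\n"
            "1\t10\t10\tA\tG\texonic\tG1\t.\tnonsynonymous SNV\tG1:NM_000001:exon1:c.1A>G\n"
        )
        tsv = tmp_path / "t.tsv"
        tsv.write_text(table)
        (a2,) = parse_annovar_table(str(tsv))
        assert a2.hgvs_p is None
        assert a1.hgvs_p == a2.hgvs_p
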