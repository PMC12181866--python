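"""HGVS parsing, canonicalization, the sequence oracle, and comparison."""

from __future__ import annotations

import numpy as np
import pytest

from varconcord.hgvs import (
    HgvsParseError,
    Position,
    TranscriptModel,
    accession_match,
    apply_edit,
    canonicalize_protein,
    compare_hgvs,
    parse_hgvs,
    shift3,
)
from varconcord.model import GenomicVariant, Tool, ToolAnnotation


class TestParse:
    def test_dup_with_accession(self):
        d = parse_hgvs("NM_001009944.3:c.5824dup")
        assert (d.molecule, d.edit, d.start.base) == ("c", "dup", 5824)
        assert (d.accession, d.version) == ("NM_001009944", 3)

    def test_intron_offset_range(self):
        d = parse_hgvs("NM_000419.5:c.310+3_310+6del")
        assert d.start == Position(310, 3)
        assert d.end == Position(310, 6)
        assert d.edit == "del"

    def test_one_letter_frameshift(self):
        d = parse_hgvs("p.F12Lfs*13")
        assert (d.ref_allele, d.start.base, d.fs_new_aa, d.fs_ter_offset) == (
            "Phe", 12, "Leu", 13
        )

    @pytest.mark.parametrize("text, edit", [
        ("c.2662G>A", "sub"), ("c.4_6del", "del"), ("c.4_5insAC", "ins"),
        ("c.4_6delinsT", "delins"), ("c.4_6inv", "inv"), ("c.-12G>A", "sub"),
        ("c.*5del", "del"), ("c.5=", "identity"), ("c.5_7ACG[4]", "repeat"),
        ("p.Gln480Ter", "sub"), ("p.Val17=", "identity"), ("p.(Arg1942fs)", "fs"),
        ("p.Lys2_Met3del", "del"), ("p.Lys2delinsGlnSer", "delins"),
        ("p.Ter110GlnextTer17", "ext"),
    ])
    def test_edit_kinds(self, text, edit):
        assert parse_hgvs(text).edit == edit

    def test_utr_zones(self):
        assert parse_hgvs("c.-12G>A").start == Position(12, utr="5")
        assert parse_hgvs("c.*5del").start == Position(5, utr="3")

    @pytest.mark.parametrize("bad", ["", "c.", "nonsense", "p.Zzz5Gln", "c.4flip"])
    def test_unparseable_carries_token(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs(bad)

    def test_reversed_range_rejected(self):
        with pytest.raises(HgvsParseError):
            parse_hgvs("c.10_4del")


class TestCanonicalizeProtein:
    @pytest.mark.parametrize("raw, canonical", [
        ("p.Q480X", "p.Gln480Ter"),
        ("p.Val17Val", "p.Val17="),
        ("p.V17V", "p.Val17="),
        ("p.Gln480Ter", "p.Gln480Ter"),
        ("p.Cys188Cys", "p.Cys188="),
        ("p.F12Lfs*13", "p.Phe12LeufsTer13"),
    ])
    def test_examples(self, raw, canonical):
        assert canonicalize_protein(parse_hgvs(raw)).render() == canonical

    def test_idempotent(self):
        for text in ["p.Q480X", "p.Val17Val", "p.Arg1942ProfsTer48", "p.Lys2_Met3del"]:
            once = canonicalize_protein(parse_hgvs(text)).render()
            assert canonicalize_protein(parse_hgvs(once)).render() == once

    def test_rejects_nucleotide(self):
        with pytest.raises(ValueError):
            canonicalize_protein(parse_hgvs("c.4del"))


class TestApplyEdit:
    @pytest.mark.parametrize("seq, desc, expected", [
        ("ATGTTTTGC", "c.4del", "ATGTTTGC"),
        ("ATGTTTTGC", "c.7del", "ATGTTTGC"),   # same edited sequence
        ("ACGT", "c.2dup", "ACCGT"),
        ("ACGT", "c.2C>G", "AGGT"),
        ("ACGT", "c.2_3insTT", "ACTTGT"),
        ("ACGT", "c.2_3delinsAAA", "AAAAT"),
        ("ACGT", "c.1_4inv", "ACGT"),          # palindrome
        ("AACGTT", "c.2_5inv", "AACGTT"),
    ])
    def test_semantics(self, seq, desc, expected):
        assert apply_edit(seq, parse_hgvs(desc)) == expected

    def test_reference_discordance(self):
        with pytest.raises(ValueError, match="discordant"):
            apply_edit("ACGT", parse_hgvs("c.2A>G"))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            apply_edit("ACGT", parse_hgvs("c.9del"))

    def test_cds_offset_frame(self):
        tm = TranscriptModel("NM_1", "GGGATGCCC", cds_start=4, cds_end=9)
        assert apply_edit(tm, parse_hgvs("c.1A>T")) == "GGGTTGCCC"
        # c.-1 is the base immediately 5' of the CDS
        assert apply_edit(tm, parse_hgvs("c.-1G>A")) == "GGAATGCCC"


class TestShift3:
    def test_del_shifts_through_run(self):
        assert shift3(parse_hgvs("c.4del"), "ATGTTTTGC").render() == "c.7del"

    def test_ins_becomes_dup(self):
        ctx = "G" * 5823 + "C" + "A" * 5
        assert shift3(parse_hgvs("c.5824_5825insC"), ctx).render() == "c.5824dup"

    def test_fixed_point_without_repeat(self):
        assert shift3(parse_hgvs("c.2del"), "ACGT").render() == "c.2del"

    def test_idempotent_and_sequence_preserving_fuzz(self):
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            L = int(rng.integers(30, 80))
            seq = "".join(rng.choice(bases, size=L))
            pos = int(rng.integers(2, L - 6))
            kind = ["del", "dup", "ins"][int(rng.integers(3))]
            if kind == "ins":
                unit = "".join(rng.choice(bases, size=int(rng.integers(1, 3))))
                text = f"c.{pos}_{pos + 1}ins{unit}"
            elif kind == "del":
                end = pos + int(rng.integers(0, 3))
                text = f"c.{pos}_{end}del" if end > pos else f"c.{pos}del"
            else:
                text = f"c.{pos}dup"
            d = parse_hgvs(text)
            shifted = shift3(d, seq)
            assert apply_edit(seq, shifted) == apply_edit(seq, d)
            again = shift3(shifted, seq)
            assert again.render() == shifted.render()
            # 3' monotonicity holds whenever the edit kind is preserved;
            # an ins collapsing onto a dup names the 5' duplicated interval
            if shifted.edit == d.edit and shifted.start.simple and d.start.simple:
                assert shifted.start.base >= d.start.base


class TestAccessionMatch:
    def test_versionless_matches_any_version(self):
        q = ToolAnnotation(Tool.ANNOVAR, GenomicVariant("1", 1, "A", "G"),
                           "NM_000059", None, raw_consequences=["x"])
        r = ToolAnnotation(Tool.CLINVAR, GenomicVariant("1", 1, "A", "G"),
                           "NM_000059", 4, raw_consequences=["x"])
        assert accession_match(q, r, ignore_version=True)
        assert accession_match(q, r, ignore_version=False)  # versionless is blind

    def test_strict_version_mismatch(self):
        assert not accession_match("NM_000059.3", "NM_000059.4", ignore_version=False)
        assert accession_match("NM_000059.3", "NM_000059.4", ignore_version=True)

    def test_cross_namespace_never_matches(self):
        assert not accession_match("NM_000059.4", "ENST00000544455.6", ignore_version=True)


class TestCompareHgvs:
    def test_missing_query(self):
        res = compare_hgvs(None, "c.310+3_310+6del")
        assert (res.verdict, res.cause) == ("missing", "missing_na")
        assert compare_hgvs("  ", "c.4del").verdict == "missing"
        assert compare_hgvs(".", "c.4del").verdict == "missing"

    def test_exact_after_whitespace_case(self):
        assert compare_hgvs("c.4del ", "c.4del").verdict == "exact"

    def test_frameshift_short_long(self):
        res = compare_hgvs("p.Arg1942fs", "p.Arg1942ProfsTer48")
        assert (res.verdict, res.cause) == ("equivalent", "non_preferred")
        # two long forms that disagree are genuine mismatches
        res2 = compare_hgvs("p.Arg1942LeufsTer48", "p.Arg1942ProfsTer48")
        assert (res2.verdict, res2.cause) == ("mismatch", "position_or_type")

    def test_dup_ins_full_level(self):
        ctx = "G" * 5823 + "C" + "A" * 5
        res = compare_hgvs("c.5824_5825insC", "c.5824dup", tm=ctx, level="full")
        assert res.verdict == "equivalent"

    def test_repeat_region_placements(self):
        seq = "ATG" + "C" * 27 + "ATATAT" + "G" * 10
        res = compare_hgvs("c.31_32del", "c.35_36del", tm=seq, level="full")
        assert res.verdict == "equivalent"
        # at canonical level the same pair cannot be resolved
        res2 = compare_hgvs("c.31_32del", "c.35_36del", level="canonical")
        assert (res2.verdict, res2.cause) == ("mismatch", "position_or_type")

    def test_parse_failure_is_unknown(self):
        res = compare_hgvs("c.banana", "c.4del")
        assert (res.verdict, res.cause) == ("mismatch", "unknown")

    def test_accession_mismatch(self):
        res = compare_hgvs("NM_000001.1:c.4del", "NM_000002.1:c.4del")
        assert (res.verdict, res.cause) == ("mismatch", "position_or_type")

    def test_levels_are_nested(self):
        """strict matches stay matches at canonical; canonical matches stay
        matches at full — on a battery of expression pairs."""
        seq = "ATGTTTTGC"
        pairs = [
            ("c.4del", "c.4del"), ("c.4del", "c.7del"), ("c.4del", "c.2del"),
            ("p.Q480X", "p.Gln480Ter"), ("p.Val17Val", "p.Val17="),
            ("c.4delT", "c.4del"), ("c.2T>C", "c.2T>C"), ("c.2T>C", "c.2T>A"),
        ]
        rank = {"strict": 0, "canonical": 1, "full": 2}
        for q, r in pairs:
            verdicts = {
                lvl: compare_hgvs(q, r, tm=seq, level=lvl).is_match() for lvl in rank
            }
            assert verdicts["strict"] <= verdicts["canonical"] <= verdicts["full"]

    def test_equivalence_reflexive_symmetric(self):
        seq = "ATGTTTTGC"
        exprs = ["c.4del", "c.7del", "c.2T>C", "p.Gln480Ter", "p.Q480X"]
        for a in exprs:
            assert compare_hgvs(a, a, tm=seq, level="full").verdict == "exact"
            for b in exprs:
                ab = compare_hgvs(a, b, tm=seq, level="full").is_match()
                ba = compare_hgvs(b, a, tm=seq, level="full").is_match()
                assert ab == ba
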