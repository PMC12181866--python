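"""HGVS coding/protein nomenclature: parsing, canonicalization, equivalence.

The same variant can legally be written many ways: one- vs three-letter
amino-acid codes (``p.Q480X`` vs ``p.Gln480Ter``), synonymous forms
(``p.Val17Val`` vs ``p.Val17=``), short vs long frameshifts
(``p.Arg1942fs`` vs ``p.Arg1942ProfsTer48``), duplication vs insertion
(``c.5824dup`` vs ``c.5824_5825insC``), and left- vs right-aligned
placements inside repeat runs (``c.31_32del`` vs ``c.35_36del``). This
module parses all of these, renders a preferred canonical form, and judges
whether two expressions are exact matches, equivalent, or mismatches — at
three strictness levels:

``strict``
    raw string equality after whitespace/case normalization;
``canonical``
    equality after notation normalization (no sequence needed);
``full``
    additionally, equality of the edited sequences produced by applying
    both descriptions to a transcript (covers repeat-region placements —
    the HGVS 3' rule vs VCF left alignment).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .model import ToolAnnotation, split_accession

# --- amino-acid code tables -------------------------------------------------

AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "U": "Sec", "*": "Ter", "X": "Ter",
}
AA_3SET = frozenset(AA_1TO3.values())
AA_3TO1 = {"Ter": "*", "Sec": "U"}
AA_3TO1.update({v: k for k, v in AA_1TO3.items() if k not in ("*", "X", "U")})

_AA3_RE = "|".join(sorted(AA_3SET, key=len, reverse=True))
_AA_TOKEN = rf"(?:{_AA3_RE}|[A-Z*])"


class HgvsParseError(ValueError):
    """Unparseable HGVS expression; carries the offending token."""

    def __init__(self, token: str, message: str | None = None):
        self.token = token
        super().__init__(message or f"cannot parse HGVS token: {token!r}")


@dataclass(frozen=True)
class Position:
    """A c./n./g. position: base plus optional intron offset or UTR zone."""

    base: int
    intron_offset: int | None = None
    utr: str | None = None  # "5" (c.-N) or "3" (c.*N)

    def render(self) -> str:
        prefix = {"5": "-", "3": "*", None: ""}[self.utr]
        off = f"{self.intron_offset:+d}" if self.intron_offset is not None else ""
        return f"{prefix}{self.base}{off}"

    @property
    def simple(self) -> bool:
        return self.intron_offset is None and self.utr is None


@dataclass(frozen=True)
class HgvsDescription:
    """Parsed HGVS expression (coding, non-coding, genomic, or protein)."""

    molecule: str                       # c, n, g, p
    edit: str                           # sub del dup ins delins inv identity fs ext repeat
    start: Position | None = None
    end: Position | None = None
    ref_allele: str | None = None       # DNA for c/n/g; 3-letter aa text for p
    alt_allele: str | None = None
    fs_new_aa: str | None = None
    fs_ter_offset: int | None = None    # e.g. 48 in ProfsTer48
    accession: str | None = None
    version: int | None = None
    raw: str = ""

    @property
    def span(self) -> tuple[int, int] | None:
        if self.start is None or not self.start.simple:
            return None
        e = self.end if self.end is not None else self.start
        if not e.simple:
            return None
        return (self.start.base, e.base)

    def render(self, with_accession: bool = False, keep_alleles: bool = False) -> str:
        """Preferred canonical text for this description."""
        body = _render_body(self, keep_alleles=keep_alleles)
        text = f"{self.molecule}.{body}"
        if with_accession and self.accession:
            acc = self.accession if self.version is None else f"{self.accession}.{self.version}"
            return f"{acc}:{text}"
        return text


# --- rendering ---------------------------------------------------------------

def _render_range(d: HgvsDescription) -> str:
    s = d.start.render()
    if d.end is not None and d.end != d.start:
        return f"{s}_{d.end.render()}"
    return s


def _render_body(d: HgvsDescription, keep_alleles: bool = False) -> str:
    if d.molecule == "p":
        return _render_protein_body(d)
    rng = _render_range(d) if d.start is not None else ""
    if d.edit == "sub":
        return f"{rng}{d.ref_allele}>{d.alt_allele}"
    if d.edit in ("del", "dup", "inv"):
        allele = d.ref_allele if (keep_alleles and d.ref_allele) else ""
        return f"{rng}{d.edit}{allele}"
    if d.edit == "ins":
        return f"{rng}ins{d.alt_allele}"
    if d.edit == "delins":
        return f"{rng}delins{d.alt_allele}"
    if d.edit == "identity":
        return f"{rng}="
    if d.edit == "repeat":
        # recognized, reported back as written (normalization out of scope)
        return f"{rng}{d.ref_allele}[{d.alt_allele}]"
    raise HgvsParseError(d.edit, f"cannot render edit kind {d.edit!r}")


def _render_protein_body(d: HgvsDescription) -> str:
    if d.start is None:  # p.(=) / p.?
        return d.alt_allele or "="
    pos = d.start.base
    if d.edit == "identity":
        return f"{d.ref_allele}{pos}="
    if d.edit == "fs":
        tail = f"Ter{d.fs_ter_offset}" if d.fs_ter_offset is not None else ""
        new = d.fs_new_aa or ""
        if not new and tail:
            new = "?"  # offset without the new residue is not expressible
        return f"{d.ref_allele}{pos}{new}fs{tail}"
    if d.edit == "sub":
        return f"{d.ref_allele}{pos}{d.alt_allele}"
    if d.edit in ("del", "dup", "inv"):
        return f"{_render_protein_range(d)}{d.edit}"
    if d.edit == "ins":
        return f"{_render_protein_range(d)}ins{d.alt_allele}"
    if d.edit == "delins":
        return f"{_render_protein_range(d)}delins{d.alt_allele}"
    if d.edit == "ext":
        return f"{d.ref_allele}{pos}{d.alt_allele or ''}ext{d.fs_new_aa or ''}" + (
            f"{d.fs_ter_offset}" if d.fs_ter_offset is not None else ""
        )
    raise HgvsParseError(d.edit, f"cannot render protein edit {d.edit!r}")


def _render_protein_range(d: HgvsDescription) -> str:
    s = f"{d.ref_allele}{d.start.base}"
    if d.end is not None and d.end != d.start:
        # ref_allele holds "Xxx_Yyy" for protein ranges
        parts = (d.ref_allele or "").split("_")
        first = parts[0] if parts else ""
        last = parts[1] if len(parts) > 1 else ""
        return f"{first}{d.start.base}_{last}{d.end.base}"
    return s


# --- parsing -----------------------------------------------------------------

_ACC_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]+(?:\.\d+)?):(.*)$")
_POS_RE = re.compile(r"([*-]?)(\d+)([+-]\d+)?")
_NT_EDIT_RE = re.compile(
    r"^(?P<range>[*-]?\d+(?:[+-]\d+)?(?:_[*-]?\d+(?:[+-]\d+)?)?)"
    r"(?P<rest>.*)$"
)


def _parse_position(text: str) -> Position:
    m = _POS_RE.fullmatch(text)
    if not m:
        raise HgvsParseError(text)
    sign, base, off = m.groups()
    utr = {"-": "5", "*": "3", "": None}[sign]
    return Position(int(base), int(off) if off else None, utr)


def _parse_range(text: str) -> tuple[Position, Position | None]:
    if "_" in text:
        a, b = text.split("_", 1)
        return _parse_position(a), _parse_position(b)
    return _parse_position(text), None


def _parse_nucleotide(molecule: str, body: str, acc, ver, raw) -> HgvsDescription:
    m = _NT_EDIT_RE.match(body)
    if not m:
        raise HgvsParseError(body)
    start, end = _parse_range(m.group("range"))
    if end is not None and start.simple and end.simple and end.base < start.base:
        raise HgvsParseError(body, f"range end precedes start in {raw!r}")
    rest = m.group("rest")
    common = dict(molecule=molecule, start=start, end=end,
                  accession=acc, version=ver, raw=raw)
    if (sub := re.fullmatch(r"([ACGTUacgtu])>([ACGTUacgtu])", rest)):
        return HgvsDescription(edit="sub", ref_allele=sub.group(1).upper(),
                               alt_allele=sub.group(2).upper(), **common)
    if (m2 := re.fullmatch(r"delins([ACGTUacgtu]+)", rest)):
        return HgvsDescription(edit="delins", alt_allele=m2.group(1).upper(), **common)
    if (m2 := re.fullmatch(r"del([ACGTUacgtu]*)", rest)):
        return HgvsDescription(edit="del", ref_allele=m2.group(1).upper() or None, **common)
    if (m2 := re.fullmatch(r"dup([ACGTUacgtu]*)", rest)):
        return HgvsDescription(edit="dup", ref_allele=m2.group(1).upper() or None, **common)
    if (m2 := re.fullmatch(r"ins([ACGTUacgtu]+)", rest)):
        return HgvsDescription(edit="ins", alt_allele=m2.group(1).upper(), **common)
    if rest == "inv":
        return HgvsDescription(edit="inv", **common)
    if rest == "=":
        return HgvsDescription(edit="identity", **common)
    if (m2 := re.fullmatch(r"([ACGTUacgtu]+)\[(\d+)\]", rest)):
        # repeat notation: unit in ref_allele, count in alt_allele (as text)
        return HgvsDescription(edit="repeat", ref_allele=m2.group(1).upper(),
                               alt_allele=m2.group(2), **common)
    raise HgvsParseError(rest or body)


def _aa3(token: str) -> str:
    """Normalize an amino-acid token to the three-letter code (Ter for stops)."""
    if token in AA_3SET:
        return token
    up = token.upper()
    if up in AA_1TO3:
        return AA_1TO3[up]
    raise HgvsParseError(token, f"invalid amino-acid code {token!r}")


def _parse_aa_seq(text: str) -> str:
    """Parse a run of amino acids (either code style) to 3-letter text."""
    m = re.fullmatch(rf"(?:{_AA3_RE})+", text)
    if m:
        return text
    try:
        return "".join(_aa3(ch) for ch in text)
    except HgvsParseError:
        raise HgvsParseError(text, f"invalid amino-acid run {text!r}")


_P_FS_RE = re.compile(
    rf"^(?P<ref>{_AA_TOKEN})(?P<pos>\d+)(?P<new>{_AA_TOKEN})?fs"
    rf"(?:(?:Ter|\*)(?P<ter>\d+|\?))?$"
)
_P_SUB_RE = re.compile(rf"^(?P<ref>{_AA_TOKEN})(?P<pos>\d+)(?P<alt>{_AA_TOKEN}|=|\?)$")
_P_RANGE_RE = re.compile(
    rf"^(?P<ref1>{_AA_TOKEN})(?P<pos1>\d+)(?:_(?P<ref2>{_AA_TOKEN})(?P<pos2>\d+))?"
    rf"(?P<op>delins|del|dup|inv|ins)(?P<allele>[A-Za-z*]*)$"
)
_P_EXT_RE = re.compile(
    rf"^(?P<ref>{_AA_TOKEN})(?P<pos>\d+)(?P<alt>{_AA_TOKEN})?ext"
    rf"(?P<tail>.*)$"
)


def _parse_protein(body: str, acc, ver, raw) -> HgvsDescription:
    body = body.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    common = dict(molecule="p", accession=acc, version=ver, raw=raw)
    if body in ("=", "?"):
        return HgvsDescription(edit="identity" if body == "=" else "sub",
                               alt_allele=body, **common)
    if (m := _P_FS_RE.match(body)):
        ter = m.group("ter")
        return HgvsDescription(
            edit="fs", start=Position(int(m.group("pos"))),
            ref_allele=_aa3(m.group("ref")),
            fs_new_aa=_aa3(m.group("new")) if m.group("new") else None,
            fs_ter_offset=int(ter) if ter and ter != "?" else None,
            **common,
        )
    if (m := _P_EXT_RE.match(body)):
        return HgvsDescription(
            edit="ext", start=Position(int(m.group("pos"))),
            ref_allele=_aa3(m.group("ref")),
            alt_allele=_aa3(m.group("alt")) if m.group("alt") else None,
            **common,
        )
    m = _P_RANGE_RE.match(body)
    if m and (m.group("op") != "ins" or m.group("pos2")):
        op = m.group("op")
        ref = _aa3(m.group("ref1"))
        end = None
        if m.group("pos2"):
            ref = f"{ref}_{_aa3(m.group('ref2'))}"
            end = Position(int(m.group("pos2")))
        allele = m.group("allele")
        return HgvsDescription(
            edit=op, start=Position(int(m.group("pos1"))), end=end,
            ref_allele=ref,
            alt_allele=_parse_aa_seq(allele) if allele else None,
            **common,
        )
    if (m := _P_SUB_RE.match(body)):
        ref = _aa3(m.group("ref"))
        alt_raw = m.group("alt")
        if alt_raw == "=":
            return HgvsDescription(edit="identity", start=Position(int(m.group("pos"))),
                                   ref_allele=ref, **common)
        alt = alt_raw if alt_raw == "?" else _aa3(alt_raw)
        if alt == ref:
            # p.Val17Val: a synonymous change written substitution-style
            return HgvsDescription(edit="identity", start=Position(int(m.group("pos"))),
                                   ref_allele=ref, **common)
        return HgvsDescription(edit="sub", start=Position(int(m.group("pos"))),
                               ref_allele=ref, alt_allele=alt, **common)
    raise HgvsParseError(body)


def parse_hgvs(text: str) -> HgvsDescription:
    """Parse an HGVS expression, with or without an accession prefix."""
    raw = text
    text = text.strip()
    if not text:
        raise HgvsParseError(text, "empty HGVS expression")
    acc = ver = None
    if (m := _ACC_RE.match(text)):
        acc, ver = split_accession(m.group(1))
        text = m.group(2)
    if len(text) < 3 or text[1] != ".":
        raise HgvsParseError(text, f"missing molecule prefix in {raw!r}")
    molecule, body = text[0], text[2:]
    if molecule == "p":
        return _parse_protein(body, acc, ver, raw)
    if molecule in ("c", "n", "g", "m", "r"):
        mol = "c" if molecule in ("m", "r") else molecule
        return _parse_nucleotide(mol, body, acc, ver, raw)
    raise HgvsParseError(molecule, f"unknown molecule type in {raw!r}")


# --- protein canonicalization ------------------------------------------------

def canonicalize_protein(desc: HgvsDescription) -> HgvsDescription:
    """Render-normalize a protein description: three-letter codes, Ter for
    stops, ``=`` for synonymous. Short frameshifts are NOT expanded (that
    would need the sequence); the longest stated information is kept.
    Idempotent."""
    if desc.molecule != "p":
        raise ValueError("canonicalize_protein requires a protein description")
    # parsing already stores three-letter/Ter internally; re-render settles
    # substitution-style synonymous forms onto "="
    return replace(desc, raw=desc.render())


# --- transcript model and the sequence oracle --------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A cDNA with CDS bounds; the coordinate frame for c. descriptions."""

    accession: str
    cdna_sequence: str
    version: int | None = None
    cds_start: int = 1            # 1-based index of c.1 in cdna_sequence
    cds_end: int | None = None    # 1-based index of the last CDS base
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] | None = None  # genomic intervals

    def __post_init__(self):
        if not 1 <= self.cds_start <= len(self.cdna_sequence):
            raise ValueError("cds_start outside the cDNA")
        if self.cds_end is not None and not self.cds_start <= self.cds_end <= len(self.cdna_sequence):
            raise ValueError("cds_end outside the cDNA")


def _abs_index(pos: Position, cds_start: int, cds_end: int | None, seq_len: int) -> int:
    """Map a c./n. position to a 1-based index into the cDNA."""
    if pos.intron_offset is not None:
        raise ValueError("intron offsets are not representable on the cDNA")
    if pos.utr == "5":
        idx = cds_start - pos.base
    elif pos.utr == "3":
        if cds_end is None:
            raise ValueError("3'UTR position requires cds_end")
        idx = cds_end + pos.base
    else:
        idx = cds_start - 1 + pos.base
    if not 1 <= idx <= seq_len:
        raise ValueError(f"position {pos.render()} outside the sequence")
    return idx


def _edit_span(desc: HgvsDescription, cds_start: int, cds_end: int | None,
               seq_len: int) -> tuple[int, int]:
    s = _abs_index(desc.start, cds_start, cds_end, seq_len)
    e = _abs_index(desc.end, cds_start, cds_end, seq_len) if desc.end else s
    if e < s:
        raise ValueError("edit range end precedes start")
    return s, e


def apply_edit(seq: str | TranscriptModel, desc: HgvsDescription) -> str:
    """Apply a coding/non-coding HGVS edit to a sequence (the equivalence
    oracle). Raises on reference-allele discordance or out-of-range
    positions."""
    if isinstance(seq, TranscriptModel):
        cds_start, cds_end, s_ = seq.cds_start, seq.cds_end, seq.cdna_sequence
    else:
        cds_start, cds_end, s_ = 1, None, seq
    s_ = s_.upper()
    if desc.molecule not in ("c", "n", "g"):
        raise ValueError("apply_edit requires a nucleotide-level description")
    if desc.edit == "identity":
        return s_
    if desc.start is None:
        raise ValueError("edit lacks a position")
    s, e = _edit_span(desc, cds_start, cds_end, len(s_))
    segment = s_[s - 1:e]
    if desc.edit == "sub":
        if desc.ref_allele and segment != desc.ref_allele:
            raise ValueError(f"reference discordant: expected {desc.ref_allele}, found {segment}")
        return s_[: s - 1] + (desc.alt_allele or "") + s_[e:]
    if desc.edit == "del":
        if desc.ref_allele and segment != desc.ref_allele:
            raise ValueError(f"reference discordant: expected {desc.ref_allele}, found {segment}")
        return s_[: s - 1] + s_[e:]
    if desc.edit == "dup":
        if desc.ref_allele and segment != desc.ref_allele:
            raise ValueError(f"reference discordant: expected {desc.ref_allele}, found {segment}")
        return s_[:e] + segment + s_[e:]
    if desc.edit == "ins":
        if desc.end is None or e != s + 1:
            raise ValueError("insertion requires two flanking positions")
        if not desc.alt_allele:
            raise ValueError("insertion lacks an inserted allele")
        return s_[:s] + desc.alt_allele + s_[s:]
    if desc.edit == "delins":
        if not desc.alt_allele:
            raise ValueError("delins lacks an inserted allele")
        return s_[: s - 1] + desc.alt_allele + s_[e:]
    if desc.edit == "inv":
        return s_[: s - 1] + str(Seq(segment).reverse_complement()) + s_[e:]
    if desc.edit == "repeat":
        if desc.end is None:
            raise ValueError("repeat notation without an explicit range is unsupported")
        unit, count = desc.ref_allele or "", int(desc.alt_allele or 0)
        return s_[: s - 1] + unit * count + s_[e:]
    raise ValueError(f"edit kind {desc.edit!r} has no sequence semantics")


def _to_c_position(idx: int, cds_start: int, cds_end: int | None) -> Position:
    """Inverse of _abs_index for exonic positions."""
    if cds_end is not None and idx > cds_end:
        return Position(idx - cds_end, utr="3")
    if idx < cds_start:
        return Position(cds_start - idx, utr="5")
    return Position(idx - cds_start + 1)


def shift3(desc: HgvsDescription, tm: TranscriptModel | str) -> HgvsDescription:
    """Shift a del/dup/ins maximally 3' (the HGVS 3' rule) and prefer
    duplication over insertion. Idempotent; preserves the edited sequence."""
    if isinstance(tm, TranscriptModel):
        seq, cds_start, cds_end = tm.cdna_sequence.upper(), tm.cds_start, tm.cds_end
    else:
        seq, cds_start, cds_end = tm.upper(), 1, None
    if desc.edit not in ("del", "dup", "ins"):
        return desc
    if desc.start is None or not desc.start.simple or (
        desc.end is not None and not desc.end.simple
    ):
        return desc  # intronic placements cannot be shifted on the cDNA

    if desc.edit in ("del", "dup"):
        s, e = _edit_span(desc, cds_start, cds_end, len(seq))
        if desc.ref_allele and seq[s - 1:e] != desc.ref_allele:
            raise ValueError("reference discordant")
        while e < len(seq) and seq[s - 1] == seq[e]:
            s += 1
            e += 1
        return replace(
            desc,
            start=_to_c_position(s, cds_start, cds_end),
            end=_to_c_position(e, cds_start, cds_end) if e != s else None,
            ref_allele=seq[s - 1:e] if desc.ref_allele else None,
        )

    # insertion: rotate the inserted unit 3' through the reference, then
    # collapse onto a duplication when the unit equals the segment 5' of it
    s, e = _edit_span(desc, cds_start, cds_end, len(seq))
    if e != s + 1:
        raise ValueError("insertion requires two flanking positions")
    allele = desc.alt_allele or ""
    if not allele:
        raise ValueError("insertion lacks an inserted allele")
    while s < len(seq) and seq[s] == allele[0]:
        allele = allele[1:] + allele[0]
        s += 1
    k = len(allele)
    if s >= k and seq[s - k:s] == allele:
        return replace(
            desc, edit="dup",
            start=_to_c_position(s - k + 1, cds_start, cds_end),
            end=_to_c_position(s, cds_start, cds_end) if k > 1 else None,
            ref_allele=None, alt_allele=None,
        )
    return replace(
        desc,
        start=_to_c_position(s, cds_start, cds_end),
        end=_to_c_position(s + 1, cds_start, cds_end),
        alt_allele=allele,
    )


# --- accession and expression comparison -------------------------------------

def accession_match(query, reference, ignore_version: bool = True) -> bool:
    """Compare transcript accessions, optionally version-blind. Accepts
    ToolAnnotations, HgvsDescriptions, or accession strings. Versionless
    accessions always compare version-blind."""

    def fields(x) -> tuple[str | None, int | None]:
        if isinstance(x, ToolAnnotation):
            return x.transcript_accession, x.transcript_version
        if isinstance(x, HgvsDescription):
            return x.accession, x.version
        return split_accession(str(x))

    q_acc, q_ver = fields(query)
    r_acc, r_ver = fields(reference)
    if q_acc is None or r_acc is None or q_acc != r_acc:
        return False
    if ignore_version or q_ver is None or r_ver is None:
        return True
    return q_ver == r_ver


@dataclass(frozen=True)
class MatchResult:
    verdict: str                 # exact | equivalent | mismatch | missing
    cause: str | None = None     # missing_na | position_or_type | non_preferred | unknown
    detail: str = ""

    def is_match(self, treat_equivalent_as_match: bool = True) -> bool:
        if self.verdict == "exact":
            return True
        return treat_equivalent_as_match and self.verdict == "equivalent"


def _norm_text(text: str) -> str:
    return "".join(text.split()).casefold()


def _syntax_part(text: str) -> str:
    m = _ACC_RE.match(text.strip())
    return m.group(2) if m else text.strip()


def _fs_equivalent(a: HgvsDescription, b: HgvsDescription) -> bool:
    """Short-form frameshift matches any long form sharing ref & position;
    two long forms must agree on everything they both state."""
    if a.ref_allele != b.ref_allele or a.start != b.start:
        return False
    if a.fs_new_aa and b.fs_new_aa and a.fs_new_aa != b.fs_new_aa:
        return False
    if a.fs_ter_offset is not None and b.fs_ter_offset is not None \
            and a.fs_ter_offset != b.fs_ter_offset:
        return False
    # a pure short form (p.Xfs) matches; partial long forms must nest
    return True


def _dup_ins_equivalent(a: HgvsDescription, b: HgvsDescription) -> bool:
    """dup vs ins without sequence context: the insertion must sit
    immediately 3' of the duplicated interval and state an allele equal to
    the duplication's stated allele."""
    dup, ins = (a, b) if a.edit == "dup" else (b, a)
    if dup.edit != "dup" or ins.edit != "ins":
        return False
    if dup.ref_allele is None or ins.alt_allele is None:
        return False
    span, ispan = dup.span, ins.span
    if span is None or ispan is None:
        return False
    return (
        ins.alt_allele == dup.ref_allele
        and ispan == (span[1], span[1] + 1)
        and len(dup.ref_allele) == span[1] - span[0] + 1
    )


def _canonical_equal(q: HgvsDescription, r: HgvsDescription) -> bool:
    if q.molecule != r.molecule:
        return False
    if q.molecule == "p":
        if q.edit == "fs" and r.edit == "fs":
            return _fs_equivalent(q, r)
        return canonicalize_protein(q).render() == canonicalize_protein(r).render()
    if q.edit == "repeat" or r.edit == "repeat":
        return False  # repeat notation needs the sequence to resolve
    if {q.edit, r.edit} == {"dup", "ins"}:
        return _dup_ins_equivalent(q, r)
    return q.render() == r.render()


def _full_equal(q: HgvsDescription, r: HgvsDescription, tm: TranscriptModel | str) -> bool:
    try:
        return apply_edit(tm, q) == apply_edit(tm, r)
    except ValueError:
        return False


def compare_hgvs(
    query: str | None,
    reference: str,
    tm: TranscriptModel | str | None = None,
    level: str = "canonical",
) -> MatchResult:
    """Judge a query HGVS expression against a reference expression.

    Returns ``missing`` for an absent query (a missing annotation counts
    against the tool), ``exact`` for raw string identity, ``equivalent``
    for a different-but-synonymous form (cause ``non_preferred``), and
    ``mismatch`` otherwise (cause ``position_or_type``, or ``unknown`` when
    the query does not parse).
    """
    if level not in ("strict", "canonical", "full"):
        raise ValueError(f"unknown comparison level {level!r}")
    if query is None or not query.strip() or query.strip() == ".":
        return MatchResult("missing", "missing_na")
    q_text, r_text = _syntax_part(query), _syntax_part(reference)
    try:
        r_desc = parse_hgvs(reference)
    except HgvsParseError as err:
        return MatchResult("mismatch", "unknown", f"reference unparseable: {err.token!r}")
    try:
        q_desc = parse_hgvs(query)
    except HgvsParseError as err:
        return MatchResult("mismatch", "unknown", f"query unparseable: {err.token!r}")
    if q_desc.accession and r_desc.accession and not accession_match(
        q_desc, r_desc, ignore_version=True
    ):
        return MatchResult("mismatch", "position_or_type", "transcript accession differs")
    if _norm_text(q_text) == _norm_text(r_text):
        return MatchResult("exact")
    if level == "strict":
        return MatchResult("mismatch", "position_or_type")
    if _canonical_equal(q_desc, r_desc):
        return MatchResult("equivalent", "non_preferred", "notation-level equivalence")
    if level == "full" and tm is not None and q_desc.molecule in ("c", "n") \
            and r_desc.molecule in ("c", "n"):
        if _full_equal(q_desc, r_desc, tm):
            return MatchResult("equivalent", "non_preferred", "sequence-level equivalence")
    return MatchResult("mismatch", "position_or_type")
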