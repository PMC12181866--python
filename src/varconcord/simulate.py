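"""Ground-truthed synthetic datasets: variants, corrupted tool annotations,
and ACMG evidence features.

The generator emulates the statistical structure the concordance analysis
assumes: a P/LP/B/LB mixture with class-conditional consequence mixes (the
pathogenic side is weighted toward LoF and indels, the benign side toward
SNVs and synonymous changes), three "tools" that corrupt a known-true
annotation via missingness, non-preferred-syntax substitution, transcript
unavailability, version stripping, and consequence confusion, plus
class-conditional CADD/SpliceAI scores and review-star labels.

Coordinate realism is deliberately limited: transcripts are synthetic
60-300 nt cDNA windows with planted repeat runs (so 3'-rule shifting is
exercised under full control), and all emitted HGVSc use exonic
coordinates — splice/intronic consequences are conveyed by the SO term
only. Every emitted annotation is reproducible from the truth record plus
its corruption labels alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acmg import EvidenceInput
from .hgvs import (
    AA_3TO1,
    HgvsDescription,
    Position,
    TranscriptModel,
    apply_edit,
    parse_hgvs,
    shift3,
)
from .model import ClinSig, ClinVarRecord, GenomicVariant, Tool, ToolAnnotation
from .so_normalize import FunctionalCategory, functional_category

# paper-scale class composition of the curated test set
DEFAULT_CLASS_MIX = {
    "P": 38278 / 164549, "LP": 6073 / 164549,
    "B": 57081 / 164549, "LB": 63117 / 164549,
}

# class-conditional consequence mixes: pathogenic truth is more diverse and
# LoF-heavy; benign truth is dominated by SNVs and synonymous changes
PLP_CATEGORY_MIX = {
    "stop_gained": 0.18, "frameshift_variant": 0.22,
    "splice_donor_variant": 0.08, "splice_acceptor_variant": 0.07,
    "missense_variant": 0.25, "inframe_deletion": 0.05,
    "synonymous_variant": 0.05, "intron_variant": 0.10,
}
BLB_CATEGORY_MIX = {
    "missense_variant": 0.20, "synonymous_variant": 0.40,
    "intron_variant": 0.25, "5_prime_UTR_variant": 0.05,
    "3_prime_UTR_variant": 0.05, "inframe_deletion": 0.02,
    "stop_gained": 0.03,
}

_SPLICE_TERMS = frozenset({"splice_donor_variant", "splice_acceptor_variant"})
_SNV_TERMS = frozenset({
    "missense_variant", "stop_gained", "synonymous_variant",
    "splice_donor_variant", "splice_acceptor_variant", "intron_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant",
})
#: terms whose HGVSp is defined (coding consequences)
_CODING_TERMS = frozenset({
    "missense_variant", "stop_gained", "synonymous_variant",
    "frameshift_variant", "inframe_deletion",
})

SO_IDS = {
    "missense_variant": "SO:0001583", "synonymous_variant": "SO:0001819",
    "stop_gained": "SO:0001587", "frameshift_variant": "SO:0001589",
    "splice_donor_variant": "SO:0001575", "splice_acceptor_variant": "SO:0001574",
    "intron_variant": "SO:0001627", "5_prime_UTR_variant": "SO:0001623",
    "3_prime_UTR_variant": "SO:0001624", "inframe_deletion": "SO:0001822",
    "inframe_insertion": "SO:0001821", "splice_region_variant": "SO:0001630",
}

STARS_TO_REVSTAT = {
    2: "criteria_provided,_multiple_submitters,_no_conflicts",
    3: "reviewed_by_expert_panel",
    4: "practice_guideline",
}
CLNSIG_TOKENS = {"P": "Pathogenic", "LP": "Likely_pathogenic",
                 "B": "Benign", "LB": "Likely_benign"}

# each tool's raw vocabulary for terms where a reversible dialect synonym
# exists (anything else is emitted as the canonical SO term)
_ANNOVAR_DIALECT = {
    "stop_gained": "stopgain", "missense_variant": "nonsynonymous SNV",
    "synonymous_variant": "synonymous SNV",
    "frameshift_variant": "frameshift deletion",
    "inframe_deletion": "nonframeshift deletion",
    "intron_variant": "intronic", "5_prime_UTR_variant": "UTR5",
    "3_prime_UTR_variant": "UTR3",
}


@dataclass
class ToolCorruption:
    missing_rate: float = 0.0
    nonpreferred_rate: float = 0.0
    transcript_absent_rate: float = 0.0
    strip_version: bool = False
    confusion: dict[str, dict[str, float]] = field(default_factory=dict)

    def confusion_row(self, term: str) -> dict[str, float]:
        return self.confusion.get(term, {term: 1.0})

    def validate(self) -> None:
        for rate in (self.missing_rate, self.nonpreferred_rate, self.transcript_absent_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"corruption rate {rate} outside [0, 1]")
        for term, row in self.confusion.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"confusion row for {term} does not sum to 1")


def default_tool_corruptions() -> dict[str, ToolCorruption]:
    """The stated world: ANNOVAR drops versions and HGVS most often, SnpEff
    lacks the most transcripts, VEP is cleanest — echoing the relative
    behavior of the real tools."""
    lof_confusion = {
        "stop_gained": {"stop_gained": 0.98, "missense_variant": 0.02},
        "splice_donor_variant": {"splice_donor_variant": 0.97, "intron_variant": 0.03},
        "splice_acceptor_variant": {"splice_acceptor_variant": 0.97, "intron_variant": 0.03},
        "frameshift_variant": {"frameshift_variant": 0.98, "inframe_deletion": 0.02},
    }
    return {
        "annovar": ToolCorruption(0.05, 0.20, 0.03, True, lof_confusion),
        "snpeff": ToolCorruption(0.02, 0.05, 0.08, False, lof_confusion),
        "vep": ToolCorruption(0.01, 0.03, 0.01, False, lof_confusion),
    }


@dataclass
class SimConfig:
    n_variants: int = 2000
    seed: int = 17
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    category_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "P": dict(PLP_CATEGORY_MIX), "LP": dict(PLP_CATEGORY_MIX),
            "B": dict(BLB_CATEGORY_MIX), "LB": dict(BLB_CATEGORY_MIX),
        }
    )
    tools: dict[str, ToolCorruption] = field(default_factory=default_tool_corruptions)
    cadd_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PLP": (30.0, 4.0), "BLB": (12.0, 5.0)}
    )
    spliceai_splice: tuple[float, float] = (0.6, 1.0)     # uniform bounds
    spliceai_nonsplice: tuple[float, float] = (0.0, 0.2)
    stars_mix: dict[int, float] = field(
        default_factory=lambda: {2: 0.85, 3: 0.12, 4: 0.03}
    )

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        for name, mix in [("class_mix", self.class_mix), ("stars_mix", self.stars_mix)]:
            if not mix:
                raise ValueError(f"{name} is empty")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
        for cls, mix in self.category_mix.items():
            if not mix or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"category_mix[{cls}] does not sum to 1")
        for tool in self.tools.values():
            tool.validate()

    def truth_mass(self) -> dict[str, float]:
        """Marginal probability of each true consequence term."""
        mass: dict[str, float] = {}
        for cls, p_cls in self.class_mix.items():
            for term, p_term in self.category_mix[cls].items():
                mass[term] = mass.get(term, 0.0) + p_cls * p_term
        return mass


@dataclass
class TruthRecord:
    """Ground truth for one simulated variant plus its per-tool emissions."""

    variant: GenomicVariant
    transcript: TranscriptModel
    clinvar_class: str
    stars: int
    true_term: str
    true_category: FunctionalCategory
    hgvs_c: str                       # preferred, accession-qualified
    hgvs_p: str | None
    cadd: float
    spliceai: float
    emitted: dict[str, ToolAnnotation | None] = field(default_factory=dict)
    labels: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    truth: list[TruthRecord]
    reference: list[ClinVarRecord]
    tool_annotations: dict[str, list[ToolAnnotation]]
    evidence: pd.DataFrame


# --- non-preferred form machinery -------------------------------------------

def _protein_oneletter(desc: HgvsDescription) -> str:
    """Render a protein description with one-letter codes (X for stops) —
    a legal but non-preferred synonym."""
    one = lambda aa: AA_3TO1.get(aa, "X") if aa != "Ter" else "X"  # noqa: E731
    pos = desc.start.base
    if desc.edit == "identity":
        return f"p.{desc.ref_allele}{pos}{desc.ref_allele}"  # Val17Val style
    if desc.edit == "sub":
        return f"p.{one(desc.ref_allele)}{pos}{one(desc.alt_allele)}"
    if desc.edit == "fs":
        new = one(desc.fs_new_aa) if desc.fs_new_aa else ""
        tail = f"*{desc.fs_ter_offset}" if desc.fs_ter_offset is not None else ""
        return f"p.{one(desc.ref_allele)}{pos}{new}fs{tail}"
    if desc.edit == "del":
        return f"p.{one(desc.ref_allele)}{pos}del"
    return desc.render()


def _protein_shortfs(desc: HgvsDescription) -> str:
    return f"p.{desc.ref_allele}{desc.start.base}fs"


def _shift5(desc: HgvsDescription, seq: str) -> HgvsDescription:
    """Maximally 5'-shifted placement of a del/dup (the VCF-style synonym)."""
    span = desc.span
    if span is None:
        return desc
    s, e = span
    while s > 1 and seq[s - 2] == seq[e - 1]:
        s -= 1
        e -= 1
    return replace(desc, start=Position(s), end=Position(e) if e != s else None)


def protein_nonpreferred_forms(desc: HgvsDescription) -> dict[str, str]:
    forms: dict[str, str] = {}
    if desc.start is None:
        return forms
    if desc.edit in ("identity", "sub", "fs", "del"):
        forms["oneletter"] = _protein_oneletter(desc)
    if desc.edit == "fs" and (desc.fs_new_aa or desc.fs_ter_offset is not None):
        forms["shortfs"] = _protein_shortfs(desc)
    return {k: v for k, v in forms.items() if v != desc.render()}


def coding_nonpreferred_forms(desc: HgvsDescription, seq: str) -> dict[str, str]:
    forms: dict[str, str] = {}
    if desc.edit == "sub":
        # substitution written delins-style: legal, strongly non-preferred
        forms["sub_as_delins"] = f"c.{desc.start.render()}delins{desc.alt_allele}"
    if desc.edit == "dup":
        s, e = desc.span
        unit = seq[s - 1:e]
        forms["ins_for_dup"] = f"c.{e}_{e + 1}ins{unit}"
    if desc.edit in ("del", "dup") and desc.span is not None:
        s, e = desc.span
        seg = seq[s - 1:e]
        # allele-bearing form (c.4delT): legal, non-preferred, resolvable
        forms["with_allele"] = replace(desc, ref_allele=seg).render(keep_alleles=True)
        shifted = _shift5(desc, seq)
        if shifted.span != desc.span:
            forms["left_shift"] = shifted.render()
    return forms


# --- truth construction ------------------------------------------------------

_BASES = "ACGT"


def _random_cdna(rng: np.random.Generator, length: int) -> str:
    seq = rng.choice(list(_BASES), size=length)
    # plant a homopolymer run so 3'-shifting has something to chew on
    run_len = int(rng.integers(4, 9))
    start = int(rng.integers(10, length - run_len - 10))
    base = str(rng.choice(list(_BASES)))
    seq[start:start + run_len] = base
    return "".join(seq)


def _aa_at(seq: str, aa_pos: int) -> str:
    """Deterministic pseudo-translation: the amino acid letter is derived
    from the codon's bases (no real genetic code needed for bookkeeping)."""
    from .hgvs import AA_1TO3
    codon = seq[(aa_pos - 1) * 3:(aa_pos - 1) * 3 + 3]
    letters = sorted(set(AA_1TO3) - {"*", "X", "U"})
    idx = sum(_BASES.index(b) * 4**i for i, b in enumerate(codon)) % len(letters)
    return AA_1TO3[letters[idx]]


def _find_run(seq: str) -> tuple[int, int]:
    best = (1, 1)
    for m in re.finditer(r"(A+|C+|G+|T+)", seq):
        if m.end() - m.start() > best[1] - best[0]:
            best = (m.start() + 1, m.end())
    return best


def _make_truth_edit(
    rng: np.random.Generator, term: str, tm: TranscriptModel
) -> tuple[HgvsDescription, str | None, GenomicVariant]:
    """Construct the preferred HGVSc (3'-shifted), the HGVSp, and a
    consistent-length genomic variant for one true consequence term."""
    seq = tm.cdna_sequence
    L = len(seq)
    chrom = str(int(rng.integers(1, 23)))
    gpos = int(rng.integers(10_000, 5_000_000))

    def random_base(exclude: str) -> str:
        choices = [b for b in _BASES if b != exclude]
        return str(rng.choice(choices))

    if term in _SNV_TERMS:
        k = int(rng.integers(10, L - 10))
        ref = seq[k - 1]
        alt = random_base(ref)
        c = HgvsDescription(molecule="c", edit="sub", start=Position(k),
                            ref_allele=ref, alt_allele=alt,
                            accession=tm.accession, version=tm.version)
        p: str | None = None
        if term in _CODING_TERMS:
            aa_pos = (k - 1) // 3 + 1
            ref_aa = _aa_at(seq, aa_pos)
            if term == "missense_variant":
                from .hgvs import AA_3SET
                others = sorted(AA_3SET - {ref_aa, "Ter"})
                alt_aa = str(rng.choice(others))
                p = f"p.{ref_aa}{aa_pos}{alt_aa}"
            elif term == "stop_gained":
                p = f"p.{ref_aa}{aa_pos}Ter"
            else:  # synonymous
                p = f"p.{ref_aa}{aa_pos}="
        gv = GenomicVariant(chrom, gpos, ref, alt)
        return c, p, gv

    if term == "frameshift_variant":
        run_s, run_e = _find_run(seq)
        if bool(rng.random() < 0.4):
            # single-base duplication inside the repeat run
            c = HgvsDescription(molecule="c", edit="dup", start=Position(run_s),
                                accession=tm.accession, version=tm.version)
            gv_ref = seq[run_s - 1]
            gv = GenomicVariant(chrom, gpos, gv_ref, gv_ref + gv_ref)
        else:
            c = HgvsDescription(molecule="c", edit="del", start=Position(run_s),
                                accession=tm.accession, version=tm.version)
            gv = GenomicVariant(chrom, gpos, seq[run_s - 1] + seq[run_s % L], seq[run_s - 1])
        c = shift3(c, tm)
        aa_pos = (c.start.base - 1) // 3 + 1
        ref_aa = _aa_at(seq, aa_pos)
        new_aa = _aa_at(seq, aa_pos + 1)
        ter = int(rng.integers(2, 60))
        p = f"p.{ref_aa}{aa_pos}{new_aa}fsTer{ter}"
        return c, p, gv

    if term == "inframe_deletion":
        k = int(rng.integers(10, L - 14))
        c = HgvsDescription(molecule="c", edit="del", start=Position(k),
                            end=Position(k + 2),
                            accession=tm.accession, version=tm.version)
        c = shift3(c, tm)
        aa_pos = (c.start.base - 1) // 3 + 1
        p = f"p.{_aa_at(seq, aa_pos)}{aa_pos}del"
        ref = "".join(str(rng.choice(list(_BASES))) for _ in range(4))
        gv = GenomicVariant(chrom, gpos, ref, ref[0])
        return c, p, gv

    raise ValueError(f"no construction rule for term {term!r}")


# --- emission ----------------------------------------------------------------

def _dialect_term(tool: str, term: str) -> str:
    if tool == "annovar":
        return _ANNOVAR_DIALECT.get(term, term)
    return term


def emit_from_labels(
    truth: TruthRecord, tool: str, labels: list[str], corruption: ToolCorruption
) -> ToolAnnotation | None:
    """Deterministically rebuild a tool's emitted annotation from the truth
    record and its corruption labels (the replay contract)."""
    if "transcript_dropped" in labels or "missing" in labels:
        return None
    term = truth.true_term
    for lab in labels:
        if lab.startswith("term_confused:"):
            term = lab.split(":", 1)[1]
    hgvs_c: str | None = truth.hgvs_c.split(":", 1)[1]
    hgvs_p = truth.hgvs_p
    seq = truth.transcript.cdna_sequence
    for lab in labels:
        if lab.startswith("nonpreferred_c:"):
            form = lab.split(":", 1)[1]
            hgvs_c = coding_nonpreferred_forms(parse_hgvs(hgvs_c), seq)[form]
        elif lab.startswith("nonpreferred_p:") and hgvs_p is not None:
            form = lab.split(":", 1)[1]
            hgvs_p = protein_nonpreferred_forms(parse_hgvs(hgvs_p))[form]
    version = None if corruption.strip_version else truth.transcript.version
    if tool == "vep" and hgvs_c:
        hgvs_c = f"{truth.transcript.accession}.{truth.transcript.version}:{hgvs_c}"
    return ToolAnnotation(
        tool=Tool(tool) if tool in Tool._value2member_map_ else Tool.SYNTHETIC,
        variant=truth.variant,
        transcript_accession=truth.transcript.accession,
        transcript_version=version,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        raw_consequences=[_dialect_term(tool, term)],
    )


def _draw_labels(
    rng: np.random.Generator, truth: TruthRecord, corruption: ToolCorruption
) -> list[str]:
    labels: list[str] = []
    if rng.random() < corruption.transcript_absent_rate:
        return ["transcript_dropped"]
    if rng.random() < corruption.missing_rate:
        return ["missing"]
    row = corruption.confusion_row(truth.true_term)
    terms = sorted(row)
    drawn = str(rng.choice(terms, p=[row[t] for t in terms]))
    if drawn != truth.true_term:
        labels.append(f"term_confused:{drawn}")
    if rng.random() < corruption.nonpreferred_rate:
        seq = truth.transcript.cdna_sequence
        c_forms = coding_nonpreferred_forms(
            parse_hgvs(truth.hgvs_c.split(":", 1)[1]), seq
        )
        if c_forms:
            labels.append(f"nonpreferred_c:{sorted(c_forms)[int(rng.integers(len(c_forms)))]}")
        if truth.hgvs_p is not None:
            p_forms = protein_nonpreferred_forms(parse_hgvs(truth.hgvs_p))
            if p_forms:
                labels.append(
                    f"nonpreferred_p:{sorted(p_forms)[int(rng.integers(len(p_forms)))]}"
                )
    return labels


# --- the simulator -----------------------------------------------------------

def simulate(cfg: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Generate the full ground-truthed dataset. Deterministic given
    (config, seed); ``seed`` overrides ``cfg.seed`` when given."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    classes = sorted(cfg.class_mix)
    class_p = [cfg.class_mix[c] for c in classes]
    stars_vals = sorted(cfg.stars_mix)
    stars_p = [cfg.stars_mix[s] for s in stars_vals]

    truth: list[TruthRecord] = []
    for i in range(cfg.n_variants):
        cls = str(rng.choice(classes, p=class_p))
        mix = cfg.category_mix[cls]
        terms = sorted(mix)
        term = str(rng.choice(terms, p=[mix[t] for t in terms]))
        stars = int(rng.choice(stars_vals, p=stars_p))
        length = int(rng.integers(60, 301))
        tm = TranscriptModel(
            accession=f"NM_{900000 + i}", version=1,
            cdna_sequence=_random_cdna(rng, length),
        )
        c_desc, hgvs_p, gv = _make_truth_edit(rng, term, tm)
        # deterministic unique genomic placement (chrom cycles, pos strides)
        gv = GenomicVariant(
            str(1 + i % 22), 1_000 + (i // 22) * 100, gv.ref, gv.alt,
            clinvar_id=100_000 + i,
        )
        group = "PLP" if cls in ("P", "LP") else "BLB"
        mean, sd = cfg.cadd_by_group[group]
        cadd = max(0.0, float(rng.normal(mean, sd)))
        lo, hi = cfg.spliceai_splice if term in _SPLICE_TERMS else cfg.spliceai_nonsplice
        spliceai = float(rng.uniform(lo, hi))
        rec = TruthRecord(
            variant=gv, transcript=tm, clinvar_class=cls, stars=stars,
            true_term=term, true_category=functional_category(term),
            hgvs_c=f"{tm.accession}.{tm.version}:{c_desc.render()}",
            hgvs_p=hgvs_p, cadd=round(cadd, 3), spliceai=round(spliceai, 4),
        )
        for tool, corruption in cfg.tools.items():
            labels = _draw_labels(rng, rec, corruption)
            rec.labels[tool] = labels
            rec.emitted[tool] = emit_from_labels(rec, tool, labels, corruption)
        truth.append(rec)

    reference = [
        ClinVarRecord(
            variant=t.variant,
            clnsig=ClinSig(t.clinvar_class),
            review_status_raw=STARS_TO_REVSTAT[t.stars],
            stars=t.stars,
            molecular_consequences=[(None, t.true_term)],
            clinvar_hgvs_c=t.hgvs_c,
            clinvar_hgvs_p=t.hgvs_p,
            clinvar_selected_transcript=f"{t.transcript.accession}.{t.transcript.version}",
        )
        for t in truth
    ]
    tool_annotations = {
        tool: [t.emitted[tool] for t in truth if t.emitted[tool] is not None]
        for tool in cfg.tools
    }
    evidence = pd.DataFrame(
        {
            "chrom": [t.variant.chrom for t in truth],
            "pos": [t.variant.pos for t in truth],
            "ref": [t.variant.ref for t in truth],
            "alt": [t.variant.alt for t in truth],
            "clinvar_class": [t.clinvar_class for t in truth],
            "stars": [t.stars for t in truth],
            "functional_category": [t.true_category.value for t in truth],
            "cadd": [t.cadd for t in truth],
            "spliceai": [t.spliceai for t in truth],
        }
    )
    return SimResult(cfg, truth, reference, tool_annotations, evidence)


def evidence_for(truth: TruthRecord, category: FunctionalCategory | None = None) -> EvidenceInput:
    """ACMG evidence features for one simulated variant, optionally with the
    functional category overridden (the tool-side reassessment input)."""
    return EvidenceInput(
        functional_category=category or truth.true_category,
        cadd=truth.cadd,
        spliceai_max=truth.spliceai,
        clinvar_class=truth.clinvar_class,
        stars=truth.stars,
    )


# --- analytic expectations ---------------------------------------------------

_LOF_SET = frozenset({
    "frameshift_variant", "splice_donor_variant", "splice_acceptor_variant",
    "stop_gained",
})


def expected_metrics(cfg: SimConfig) -> dict[str, dict[str, float]]:
    """Closed-form recovery targets for the pipeline's measured fractions.

    ``hgvsc``/``hgvsp`` are match fractions with equivalence credit (all
    generated non-preferred forms are equivalence-resolvable at the full
    comparison level); ``*_strict`` without it; ``term`` is the most-severe
    consequence match; ``pvs1_loss``/``pvs1_gain`` are rates among pairs
    where the tool produced an annotation.
    """
    cfg.validate()
    mass = cfg.truth_mass()
    coding_mass = sum(p for t, p in mass.items() if t in _CODING_TERMS)
    out: dict[str, dict[str, float]] = {}
    for tool, cor in cfg.tools.items():
        present = (1.0 - cor.missing_rate) * (1.0 - cor.transcript_absent_rate)
        diag = sum(p * cor.confusion_row(t).get(t, 1.0) for t, p in mass.items())
        loss = sum(
            p * sum(q for t2, q in cor.confusion_row(t).items() if t2 not in _LOF_SET)
            for t, p in mass.items() if t in _LOF_SET
        )
        gain = sum(
            p * sum(q for t2, q in cor.confusion_row(t).items() if t2 in _LOF_SET)
            for t, p in mass.items() if t not in _LOF_SET
        )
        out[tool] = {
            "present": present,
            "hgvsc": present,
            "hgvsc_strict": present * (1.0 - cor.nonpreferred_rate),
            "hgvsp": present,
            "hgvsp_strict": present * (1.0 - cor.nonpreferred_rate),
            "term": present * diag,
            "pvs1_loss": loss,
            "pvs1_gain": gain,
            "coding_mass": coding_mass,
        }
    return out


# --- file emission -----------------------------------------------------------

def _vcf_sort_key(chrom: str, pos: int) -> tuple:
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c), pos


def write_outputs(sim: SimResult, outdir) -> dict[str, str]:
    """Write the simulated world to disk in each tool's real dialect:

    reference.vcf (ClinVar INFO keys), snpeff.vcf (ANN), vep.vcf (CSQ),
    annovar.tsv (multianno table), transcripts.fa, truth.tsv. The files are
    byte-deterministic for a given (config, seed).
    """
    from pathlib import Path

    from .variant_io import DEFAULT_CSQ_ORDER, format_snpeff_ann, format_vep_csq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: str(outdir / fname) for name, fname in [
        ("reference", "reference.vcf"), ("snpeff", "snpeff.vcf"),
        ("vep", "vep.vcf"), ("annovar", "annovar.tsv"),
        ("transcripts", "transcripts.fa"), ("truth", "truth.tsv"),
    ]}
    order = sorted(range(len(sim.truth)),
                   key=lambda i: _vcf_sort_key(sim.truth[i].variant.chrom,
                                               sim.truth[i].variant.pos))
    contigs = sorted({t.variant.chrom for t in sim.truth},
                     key=lambda c: _vcf_sort_key(c, 0)[0])

    def header(extra_info: list[str]) -> str:
        lines = ["##fileformat=VCFv4.2"]
        lines += [f"##contig=<ID={c}>" for c in contigs]
        lines += extra_info
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        return "\n".join(lines) + "\n"

    def vcf_line(t: TruthRecord, info: str) -> str:
        v = t.variant
        vid = str(v.clinvar_id) if v.clinvar_id is not None else "."
        return f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"

    # reference (ClinVar dialect)
    with open(paths["reference"], "w") as fh:
        fh.write(header([
            '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
            '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">',
            '##INFO=<ID=MC,Number=.,Type=String,Description="Molecular consequence SO:id|term">',
            '##INFO=<ID=CLNHGVSC,Number=1,Type=String,Description="Selected-transcript HGVSc">',
            '##INFO=<ID=CLNHGVSP,Number=1,Type=String,Description="Selected-transcript HGVSp">',
        ]))
        for i in order:
            t = sim.truth[i]
            so_id = SO_IDS.get(t.true_term, "SO:0000000")
            info = (
                f"CLNSIG={CLNSIG_TOKENS[t.clinvar_class]}"
                f";CLNREVSTAT={STARS_TO_REVSTAT[t.stars]}"
                f";MC={so_id}|{t.true_term}"
                f";CLNHGVSC={t.hgvs_c}"
            )
            if t.hgvs_p:
                info += f";CLNHGVSP={t.hgvs_p}"
            fh.write(vcf_line(t, info))

    # SnpEff / VEP dialects: one line per variant; absent annotation -> bare line
    with open(paths["snpeff"], "w") as fh:
        fh.write(header([
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        ]))
        for i in order:
            t = sim.truth[i]
            ann = t.emitted.get("snpeff")
            fh.write(vcf_line(t, f"ANN={format_snpeff_ann(ann)}" if ann else "."))

    csq_format = "|".join(DEFAULT_CSQ_ORDER)
    with open(paths["vep"], "w") as fh:
        fh.write(header([
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations'
            f' from VEP. Format: {csq_format}">',
        ]))
        for i in order:
            t = sim.truth[i]
            ann = t.emitted.get("vep")
            fh.write(vcf_line(t, f"CSQ={format_vep_csq(ann)}" if ann else "."))

    # ANNOVAR multianno table
    with open(paths["annovar"], "w") as fh:
        cols = ["Chr", "Start", "End", "Ref", "Alt", "Func.refGene", "Gene.refGene",
                "GeneDetail.refGene", "ExonicFunc.refGene", "AAChange.refGene"]
        fh.write("\t".join(cols) + "\n")
        for i in order:
            t = sim.truth[i]
            v = t.variant
            ann = t.emitted.get("annovar")
            if ann is None:
                func, exonic, detail, aachange = ".", ".", ".", "."
            else:
                from .variant_io import format_annovar_entry
                func = "exonic"
                exonic = ann.raw_consequences[0] if ann.raw_consequences else "."
                detail = "."
                aachange = format_annovar_entry(ann)
            end = v.pos + len(v.ref) - 1
            fh.write("\t".join([v.chrom, str(v.pos), str(end), v.ref, v.alt,
                                func, "GENE", detail, exonic, aachange]) + "\n")

    with open(paths["transcripts"], "w") as fh:
        for t in sim.truth:
            tm = t.transcript
            fh.write(f">{tm.accession}.{tm.version}\n{tm.cdna_sequence}\n")

    rows = []
    for t in sim.truth:
        row = {
            "chrom": t.variant.chrom, "pos": t.variant.pos,
            "ref": t.variant.ref, "alt": t.variant.alt,
            "clinvar_class": t.clinvar_class, "stars": t.stars,
            "true_term": t.true_term, "category": t.true_category.value,
            "hgvs_c": t.hgvs_c, "hgvs_p": t.hgvs_p or "",
            "cadd": t.cadd, "spliceai": t.spliceai,
        }
        for tool in sim.config.tools:
            row[f"labels_{tool}"] = ";".join(t.labels[tool])
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def transcript_models(sim: SimResult) -> dict[str, TranscriptModel]:
    """Transcript lookup (both versioned and bare accessions) for compare."""
    out: dict[str, TranscriptModel] = {}
    for t in sim.truth:
        tm = t.transcript
        out[tm.accession] = tm
        out[f"{tm.accession}.{tm.version}"] = tm
    return out
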