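"""Curation of a raw ClinVar-style variant stream into the benchmark test set.

The filter chain retains small, well-reviewed, unambiguous variants:
indels under 50 bp, review status of at least two stars, assertions limited
to P/LP/B/LB, no mitochondrial records, molecular-consequence information
present and unambiguous (one SO term per transcript).

Allele normalization follows VCF convention: parsimony (trim shared
suffix, then shared prefix, keeping at least one base on each side) and
left alignment of indels against the reference context.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

from .model import ClinSig, ClinVarRecord, GenomicVariant

_DNA = frozenset("ACGT")

#: fixed filter order: an excluded record is attributed to the FIRST failure
FILTER_ORDER = ["size", "stars", "clnsig", "chrom", "mc_present", "multi_mc"]


class NormalizationError(ValueError):
    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(message)


@dataclass
class CurationConfig:
    max_indel_len: int = 49          # bases; indels >= 50 bp are excluded
    min_stars: int = 2
    exclude_clnsig: frozenset[ClinSig] = frozenset(
        {ClinSig.VUS, ClinSig.CONFLICTING, ClinSig.OTHER}
    )
    exclude_chroms: frozenset[str] = frozenset({"MT"})
    require_mc: bool = True
    exclude_multi_mc_per_transcript: bool = True

    def __post_init__(self) -> None:
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")
        if not 0 <= self.min_stars <= 4:
            raise ValueError("min_stars must be within 0..4")


@dataclass
class CurationSummary:
    input_count: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)
    retained_count: int = 0
    type_composition: dict[str, int] = field(default_factory=dict)
    class_composition: dict[str, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return (
            self.input_count == self.retained_count + sum(self.exclusions.values())
            and sum(self.type_composition.values()) == self.retained_count
            and sum(self.class_composition.values()) == self.retained_count
        )

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "exclusions": dict(self.exclusions),
            "retained_count": self.retained_count,
            "type_composition": dict(self.type_composition),
            "class_composition": dict(self.class_composition),
        }


def normalize_allele(
    variant: GenomicVariant,
    reference_context: str | None = None,
    context_start: int = 1,
) -> GenomicVariant:
    """Trim to the parsimonious representation and left-align indels.

    ``reference_context`` is the reference sequence covering the variant
    locus; ``context_start`` is the 1-based genomic position of its first
    base. Without context only trimming is performed (left-shifting across
    repeats needs the flanking sequence).
    """
    ref, alt, pos = variant.ref.upper(), variant.alt.upper(), variant.pos
    if not (set(ref) <= _DNA and set(alt) <= _DNA):
        raise NormalizationError("degenerate", f"degenerate base in {ref}>{alt}")

    def left_base(p: int) -> str | None:
        if reference_context is None:
            return None
        i = p - context_start
        if 0 <= i < len(reference_context):
            return reference_context[i].upper()
        return None

    # One loop does suffix-parsimony and left alignment: while the alleles
    # share their last base, either trim it (both alleles still > 1 base) or
    # rotate one reference base in from the left (pure-indel shift).
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        else:
            b = left_base(pos - 1)
            if b is None:
                break
            pos -= 1
            ref, alt = b + ref[:-1], b + alt[:-1]
    # trim shared prefix keeping >= 1 base each side
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise NormalizationError("non_variant", f"ref == alt after trimming at {pos}")
    return GenomicVariant(variant.chrom, pos, ref, alt, variant.clinvar_id)


def classify_variant_class(ref: str, alt: str) -> str:
    """Classify normalized alleles into SNV / MNV / Indel / Other."""
    if not ref or not alt:
        raise ValueError("empty allele: normalization contract breached")
    if not (set(ref.upper()) <= _DNA and set(alt.upper()) <= _DNA):
        return "Other"
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "Indel"


def indel_span(ref: str, alt: str) -> int:
    """Inserted/deleted length used by the size filter."""
    return max(len(ref), len(alt)) - 1


def deduplicate(records: Iterable[ClinVarRecord]) -> list[ClinVarRecord]:
    """Drop exact (chrom,pos,ref,alt) duplicates, keeping the first record."""
    seen: set[tuple] = set()
    out = []
    for rec in records:
        if rec.variant.key in seen:
            continue
        seen.add(rec.variant.key)
        out.append(rec)
    return out


def _first_failing_filter(rec: ClinVarRecord, cfg: CurationConfig) -> str | None:
    v = rec.variant
    if classify_variant_class(v.ref, v.alt) == "Indel" and indel_span(v.ref, v.alt) > cfg.max_indel_len:
        return "size"
    if rec.stars < cfg.min_stars:
        return "stars"
    if rec.clnsig in cfg.exclude_clnsig:
        return "clnsig"
    if v.chrom.removeprefix("chr") in cfg.exclude_chroms:
        return "chrom"
    if cfg.require_mc and not rec.molecular_consequences:
        return "mc_present"
    if cfg.exclude_multi_mc_per_transcript and rec.multi_mc_per_transcript:
        return "multi_mc"
    return None


def apply_filters(
    records: Iterable[ClinVarRecord], config: CurationConfig | None = None
) -> tuple[list[ClinVarRecord], CurationSummary]:
    """Run the curation chain; exclusions are attributed to the first failure."""
    cfg = config or CurationConfig()
    summary = CurationSummary(exclusions={name: 0 for name in FILTER_ORDER})
    retained: list[ClinVarRecord] = []
    for rec in records:
        summary.input_count += 1
        failed = _first_failing_filter(rec, cfg)
        if failed is not None:
            summary.exclusions[failed] += 1
            continue
        retained.append(rec)
        vclass = classify_variant_class(rec.variant.ref, rec.variant.alt)
        summary.type_composition[vclass] = summary.type_composition.get(vclass, 0) + 1
        cls = rec.clnsig.value
        summary.class_composition[cls] = summary.class_composition.get(cls, 0) + 1
    summary.retained_count = len(retained)
    return retained, summary
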