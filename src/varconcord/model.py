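"""Shared domain types for the annotation-concordance pipeline.

The unit of accounting everywhere is a genomic variant (VCF convention,
1-based, explicit ref/alt alleles) plus the per-tool annotations attached
to it on a particular transcript.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


class ClinSig(str, enum.Enum):
    """Collapsed ClinVar clinical-significance classes."""

    P = "P"
    LP = "LP"
    B = "B"
    LB = "LB"
    VUS = "VUS"
    CONFLICTING = "conflicting"
    OTHER = "other"


class Tool(str, enum.Enum):
    ANNOVAR = "annovar"
    SNPEFF = "snpeff"
    VEP = "vep"
    CLINVAR = "clinvar"
    SYNTHETIC = "synthetic"


#: transcript accession namespaces accepted at ingest
ACCESSION_RE = re.compile(r"^(NM_|NR_|ENST)\d+")

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class GenomicVariant:
    """One ALT allele at one genomic position (VCF 1-based convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    clinvar_id: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_acgt(self) -> bool:
        return set(self.ref) <= _DNA and set(self.alt) <= _DNA


@dataclass
class ClinVarRecord:
    """Curated view of one ClinVar VCF line (one ALT allele)."""

    variant: GenomicVariant
    clnsig: ClinSig
    review_status_raw: str
    stars: int
    molecular_consequences: list[tuple[str | None, str]] = field(default_factory=list)
    clinvar_hgvs_c: str | None = None
    clinvar_hgvs_p: str | None = None
    clinvar_selected_transcript: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def multi_mc_per_transcript(self) -> bool:
        """True when any single transcript carries more than one SO term."""
        seen: dict[str | None, int] = {}
        for acc, _term in self.molecular_consequences:
            seen[acc] = seen.get(acc, 0) + 1
        return any(n > 1 for n in seen.values())


@dataclass
class ToolAnnotation:
    """One (tool, variant, transcript) annotation."""

    tool: Tool
    variant: GenomicVariant
    transcript_accession: str
    transcript_version: int | None = None
    protein_accession: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    raw_consequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.raw_consequences and self.hgvs_c is None and self.hgvs_p is None:
            raise ValueError(
                "annotation must carry at least one of: consequences, HGVSc, HGVSp"
            )

    @property
    def versioned_accession(self) -> str:
        if self.transcript_version is None:
            return self.transcript_accession
        return f"{self.transcript_accession}.{self.transcript_version}"


@dataclass
class ParseStats:
    """Counted warnings accumulated while ingesting a file.

    Parsers never crash on a malformed entry; they count it here so callers
    can reconcile totals.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def bump(self, key: str, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, key: str) -> int:
        return self.counts.get(key, 0)


def split_accession(text: str) -> tuple[str, int | None]:
    """Split ``NM_000059.4`` into (``NM_000059``, 4); versionless passes through."""
    if "." in text:
        acc, _, ver = text.rpartition(".")
        if ver.isdigit():
            return acc, int(ver)
    return text, None
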