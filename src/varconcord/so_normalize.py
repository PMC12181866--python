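"""Sequence Ontology normalization, severity ranking, and functional binning.

Each annotator emits consequence terms in its own vocabulary (ANNOVAR's
``stopgain``, SnpEff's ``disruptive_inframe_deletion``, ...). This module
maps every raw term onto a canonical SO term, ranks canonical terms by a
strict severity order (Ensembl's published consequence ranking, shipped as
an editable TSV so an alternative table can be slotted in), and bins
canonical terms into the five functional categories that drive ACMG
criteria: LoF, Missense, ProteinLengthChange, Synonymous, Other.
"""

from __future__ import annotations

import csv
import enum
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .model import ParseStats, Tool

#: sentinel for raw terms outside every known vocabulary
UNMAPPED = "unmapped"


class FunctionalCategory(str, enum.Enum):
    LOF = "LoF"
    MISSENSE = "Missense"
    PROTEIN_LENGTH_CHANGE = "ProteinLengthChange"
    SYNONYMOUS = "Synonymous"
    OTHER = "Other"


# the trigger set for PVS1: frameshift, splice donor/acceptor, nonsense
_LOF_TERMS = frozenset(
    {"frameshift_variant", "splice_donor_variant", "splice_acceptor_variant", "stop_gained"}
)
# inframe indels, stop-loss, initiator-codon variants; start_lost is binned
# here (not LoF) because initiator-codon changes alter protein length/start
_PLC_TERMS = frozenset(
    {"inframe_insertion", "inframe_deletion", "protein_altering_variant",
     "stop_lost", "start_lost"}
)
_SYN_TERMS = frozenset(
    {"synonymous_variant", "stop_retained_variant", "start_retained_variant"}
)


class SeverityTable:
    """Strict total severity order over canonical SO terms plus synonym maps."""

    def __init__(
        self,
        order: list[str],
        synonyms: dict[tuple[str, str], str],
    ):
        if len(set(order)) != len(order):
            raise ValueError("severity order contains duplicate terms")
        unknown = {c for c in synonyms.values() if c not in set(order)}
        if unknown:
            raise ValueError(f"synonym targets missing from severity order: {unknown}")
        self.order = list(order)
        self.rank = {term: i for i, term in enumerate(order)}
        self._canonical_ci = {term.lower(): term for term in order}
        self.synonyms = dict(synonyms)

    @classmethod
    def from_files(cls, severity_path: str | Path, synonyms_path: str | Path) -> "SeverityTable":
        with open(severity_path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        order = [r["canonical_term"] for r in sorted(rows, key=lambda r: int(r["rank"]))]
        synonyms: dict[tuple[str, str], str] = {}
        with open(synonyms_path, newline="") as fh:
            for r in csv.DictReader(fh, delimiter="\t"):
                synonyms[(r["tool"].lower(), r["raw_term"].lower())] = r["canonical_term"]
        return cls(order, synonyms)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "SeverityTable":
        data = resources.files("varconcord.data")
        return cls.from_files(
            str(data / "so_severity.tsv"), str(data / "so_synonyms.tsv")
        )

    # -- operations ---------------------------------------------------------

    def normalize_term(
        self, raw: str, tool: Tool | str, stats: ParseStats | None = None
    ) -> str:
        """Map a raw tool term onto its canonical SO term (total function)."""
        tool_name = tool.value if isinstance(tool, Tool) else str(tool).lower()
        key = raw.strip().lower()
        mapped = self.synonyms.get((tool_name, key))
        if mapped is not None:
            return mapped
        if key in self._canonical_ci:  # already canonical (case-insensitive)
            return self._canonical_ci[key]
        if stats is not None:
            stats.bump("unmapped_term")
        return UNMAPPED

    def most_severe(self, terms: list[str]) -> str:
        """Pick the most severe canonical term; unmapped ranks last."""
        if not terms:
            raise ValueError("most_severe requires a non-empty term list")
        return min(terms, key=lambda t: self.rank.get(t, len(self.order)))


def normalize_term(raw: str, tool: Tool | str, stats: ParseStats | None = None) -> str:
    return SeverityTable.default().normalize_term(raw, tool, stats)


def most_severe(terms: list[str]) -> str:
    return SeverityTable.default().most_severe(terms)


def functional_category(term: str, stats: ParseStats | None = None) -> FunctionalCategory:
    """Bin a canonical SO term into the ACMG-facing functional category."""
    if term == UNMAPPED:
        if stats is not None:
            stats.bump("unmapped_category")
        return FunctionalCategory.OTHER
    if term in _LOF_TERMS:
        return FunctionalCategory.LOF
    if term == "missense_variant":
        return FunctionalCategory.MISSENSE
    if term in _PLC_TERMS:
        return FunctionalCategory.PROTEIN_LENGTH_CHANGE
    if term in _SYN_TERMS:
        return FunctionalCategory.SYNONYMOUS
    return FunctionalCategory.OTHER


def representative_term(
    raw_terms: list[str], tool: Tool | str, table: SeverityTable | None = None,
    stats: ParseStats | None = None,
) -> str:
    """Normalize all raw terms for one (variant, transcript) and keep the
    most severe — the paper-style per-transcript representative consequence."""
    tbl = table or SeverityTable.default()
    return tbl.most_severe([tbl.normalize_term(t, tool, stats) for t in raw_terms])
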