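"""Concordance accounting: Venn partitions, match fractions, stratification.

The unit of the three-way comparison is the (variant, transcript, value)
tuple, where the value is a canonicalized HGVSc, HGVSp, or most-severe SO
term; equivalent syntaxes are canonicalized upstream so they collide into
one tuple. Per-tool match fractions against a reference count a missing
annotation in the denominator (a missing annotation is an incorrect one).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .hgvs import MatchResult
from .model import split_accession

REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class TupleKey:
    """One (variant, transcript, value) tuple in a Venn universe."""

    variant_key: tuple
    transcript_accession: str
    value: str

    def __post_init__(self):
        if not self.value:
            raise ValueError("TupleKey value must be non-empty")


@dataclass
class VennPartition:
    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REGIONS})

    @property
    def union_total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        return {**self.counts, "union": self.union_total}


def venn_partition(set_a: set, set_b: set, set_c: set) -> VennPartition:
    """Exact 7-region partition of three finite sets."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    part = VennPartition()
    for x in a | b | c:
        key = ("A" if x in a else "") + ("B" if x in b else "") + ("C" if x in c else "")
        part.counts[key] += 1
    return part


def _blind(accession: str) -> str:
    return split_accession(accession)[0]


def transcript_venn(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> VennPartition:
    """Venn partition over bare transcript accessions, version-blind."""
    return venn_partition(
        {_blind(x) for x in set_a}, {_blind(x) for x in set_b}, {_blind(x) for x in set_c}
    )


@dataclass
class FractionReport:
    fraction: float
    n: int
    n_match: int
    causes: dict[str, float] = field(default_factory=dict)


def _fraction_of(results: list[MatchResult], treat_equivalent_as_match: bool) -> FractionReport:
    n = len(results)
    if n == 0:
        raise ValueError("empty reference set: no comparable entries")
    matches = sum(1 for r in results if r.is_match(treat_equivalent_as_match))
    nonmatches = [r for r in results if not r.is_match(treat_equivalent_as_match)]
    causes: dict[str, int] = {}
    for r in nonmatches:
        cause = r.cause or "unknown"
        causes[cause] = causes.get(cause, 0) + 1
    total_bad = sum(causes.values())
    cause_mix = {k: v / total_bad for k, v in causes.items()} if total_bad else {}
    return FractionReport(fraction=matches / n, n=n, n_match=matches, causes=cause_mix)


def match_fraction(
    results_by_tool: Mapping[str, list[MatchResult]],
    treat_equivalent_as_match: bool = True,
) -> dict[str, FractionReport]:
    """Per-tool fraction of reference entries matched, plus a mismatch-cause
    breakdown normalized over the non-matches."""
    return {
        tool: _fraction_of(results, treat_equivalent_as_match)
        for tool, results in results_by_tool.items()
    }


def stratify(
    results: Iterable[tuple[MatchResult, Mapping[str, str]]],
    by: str,
    treat_equivalent_as_match: bool = True,
) -> pd.DataFrame:
    """Per-stratum match fractions. Each result comes with its stratum
    labels (e.g. {"variant_class": "SNV", "functional_category": "LoF"}).
    Strata with zero denominator are simply absent from the table; results
    whose label is missing are grouped under "other".
    """
    groups: dict[str, list[MatchResult]] = {}
    for res, labels in results:
        stratum = labels.get(by, "other")
        groups.setdefault(stratum, []).append(res)
    rows = []
    for stratum in sorted(groups):
        rep = _fraction_of(groups[stratum], treat_equivalent_as_match)
        rows.append(
            {"stratum": stratum, "fraction": round(rep.fraction, 4),
             "n": rep.n, "n_match": rep.n_match}
        )
    return pd.DataFrame(rows, columns=["stratum", "fraction", "n", "n_match"])
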