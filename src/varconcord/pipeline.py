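"""End-to-end glue: reference records vs per-tool annotations.

Given a ClinVar-style reference and per-tool annotation lists, this module
matches annotations onto the reference's selected transcript (version-
blind), judges HGVSc/HGVSp syntax, normalizes consequence terms to their
most severe representative, and accounts PVS1-relevant category changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .concordance import TupleKey, match_fraction
from .delta import pvs1_delta
from .hgvs import HgvsParseError, MatchResult, TranscriptModel, compare_hgvs, parse_hgvs
from .model import ClinVarRecord, ToolAnnotation, split_accession
from .so_normalize import FunctionalCategory, functional_category, normalize_term, representative_term


@dataclass
class ToolComparison:
    """Per-tool comparison results, aligned with the reference order."""

    hgvsc: list[MatchResult] = field(default_factory=list)
    hgvsp: list[MatchResult] = field(default_factory=list)
    term: list[MatchResult] = field(default_factory=list)
    category_pairs: list[tuple[FunctionalCategory, FunctionalCategory]] = field(
        default_factory=list
    )
    strata: list[dict] = field(default_factory=list)


def _index_annotations(
    annotations: list[ToolAnnotation],
) -> dict[tuple, ToolAnnotation]:
    """Index by (variant key, version-blind accession); first entry wins."""
    idx: dict[tuple, ToolAnnotation] = {}
    for a in annotations:
        key = (a.variant.key, a.transcript_accession)
        idx.setdefault(key, a)
    return idx


def compare_all(
    reference: list[ClinVarRecord],
    tool_annotations: dict[str, list[ToolAnnotation]],
    transcripts: dict[str, TranscriptModel | str] | None = None,
    level: str = "full",
) -> dict[str, ToolComparison]:
    """Compare every tool against the reference on its selected transcript."""
    transcripts = transcripts or {}
    out = {tool: ToolComparison() for tool in tool_annotations}
    indexes = {tool: _index_annotations(anns) for tool, anns in tool_annotations.items()}
    for rec in reference:
        sel = rec.clinvar_selected_transcript
        sel_blind = split_accession(sel)[0] if sel else None
        tm = None
        if sel is not None:
            tm = transcripts.get(sel) or (transcripts.get(sel_blind) if sel_blind else None)
        ref_term = None
        if rec.molecular_consequences:
            ref_term = normalize_term(rec.molecular_consequences[0][1], "clinvar")
        ref_cat = functional_category(ref_term) if ref_term else None
        from .curation import classify_variant_class
        strata = {
            "variant_class": classify_variant_class(rec.variant.ref, rec.variant.alt),
            "functional_category": ref_cat.value if ref_cat else "other",
            "clinvar_class": rec.clnsig.value,
        }
        for tool, comp in out.items():
            ann = indexes[tool].get((rec.variant.key, sel_blind)) if sel_blind else None
            if rec.clinvar_hgvs_c:
                comp.hgvsc.append(
                    compare_hgvs(ann.hgvs_c if ann else None, rec.clinvar_hgvs_c,
                                 tm=tm, level=level)
                )
                comp.strata.append(strata)
            if rec.clinvar_hgvs_p:
                comp.hgvsp.append(
                    compare_hgvs(ann.hgvs_p if ann else None, rec.clinvar_hgvs_p,
                                 tm=tm, level=level)
                )
            if ref_term is not None:
                if ann is None or not ann.raw_consequences:
                    comp.term.append(MatchResult("missing", "missing_na"))
                else:
                    rep = representative_term(ann.raw_consequences, tool)
                    if rep == ref_term:
                        comp.term.append(MatchResult("exact"))
                    else:
                        comp.term.append(
                            MatchResult("mismatch", "position_or_type", f"{rep} vs {ref_term}")
                        )
                    if ref_cat is not None:
                        comp.category_pairs.append((ref_cat, functional_category(rep)))
    return out


def measured_metrics(
    comparisons: dict[str, ToolComparison], treat_equivalent_as_match: bool = True
) -> dict[str, dict[str, float]]:
    """Collapse comparisons into per-tool fractions and PVS1 flip rates."""
    out: dict[str, dict[str, float]] = {}
    for tool, comp in comparisons.items():
        metrics: dict[str, float] = {}
        for name, results in (("hgvsc", comp.hgvsc), ("hgvsp", comp.hgvsp),
                              ("term", comp.term)):
            if results:
                rep = match_fraction({tool: results}, treat_equivalent_as_match)[tool]
                metrics[name] = rep.fraction
                strict = match_fraction({tool: results}, False)[tool]
                metrics[f"{name}_strict"] = strict.fraction
        if comp.category_pairs:
            _, summary = pvs1_delta(comp.category_pairs)
            n = summary["n"]
            metrics["pvs1_loss"] = summary["pvs1_loss"] / n
            metrics["pvs1_gain"] = summary["pvs1_gain"] / n
        out[tool] = metrics
    return out


def cause_mix(
    comparisons: dict[str, ToolComparison], metric: str = "hgvsc",
    treat_equivalent_as_match: bool = True,
) -> dict[str, dict[str, float]]:
    """Mismatch-cause breakdown per tool for one metric."""
    out = {}
    for tool, comp in comparisons.items():
        results = getattr(comp, metric)
        if results:
            out[tool] = match_fraction({tool: results}, treat_equivalent_as_match)[tool].causes
    return out


def _in_scope(
    a: ToolAnnotation, scope: str, selected: set[tuple] | None
) -> bool:
    if scope == "refseq":
        return a.transcript_accession.startswith(("NM_", "NR_"))
    if scope == "ensembl":
        return a.transcript_accession.startswith("ENST")
    if scope == "clinvar_selected":
        if selected is None:
            raise ValueError("clinvar_selected scope needs the selected-transcript set")
        return (a.variant.key, a.transcript_accession) in selected
    raise ValueError(f"unknown transcript scope {scope!r}")


def selected_transcript_set(reference: list[ClinVarRecord]) -> set[tuple]:
    """(variant key, version-blind accession) pairs of the reference's
    selected transcripts — the clinvar_selected comparison frame."""
    out = set()
    for rec in reference:
        if rec.clinvar_selected_transcript:
            out.add((rec.variant.key, split_accession(rec.clinvar_selected_transcript)[0]))
    return out


def venn_tuples(
    tool_annotations: dict[str, list[ToolAnnotation]],
    value: str = "hgvs_c",
    scope: str | None = None,
    selected: set[tuple] | None = None,
) -> dict[str, set[TupleKey]]:
    """Canonicalized (variant, transcript, value) tuple sets per tool.

    Values are canonical renders of the HGVS expression (so equivalent
    syntaxes collide) or the normalized most-severe term; annotations
    without the value are excluded from the Venn universe. ``scope``
    restricts the comparison frame: ``refseq`` (NM/NR accessions),
    ``ensembl`` (ENST), or ``clinvar_selected`` (pairs from
    :func:`selected_transcript_set`).
    """
    out: dict[str, set[TupleKey]] = {}
    for tool, anns in tool_annotations.items():
        tuples: set[TupleKey] = set()
        for a in anns:
            if scope is not None and not _in_scope(a, scope, selected):
                continue
            if value in ("hgvs_c", "hgvs_p"):
                text = getattr(a, value)
                if not text:
                    continue
                try:
                    canon = parse_hgvs(text).render()
                except HgvsParseError:
                    canon = text.strip()
            else:
                if not a.raw_consequences:
                    continue
                canon = representative_term(a.raw_consequences, tool)
            tuples.add(TupleKey(a.variant.key, a.transcript_accession, canon))
        out[tool] = tuples
    return out
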