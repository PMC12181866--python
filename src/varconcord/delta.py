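"""How discordant consequence calls flip PVS1 and the final classification.

A reference (ClinVar-derived) functional category and a tool-derived
category are compared per variant: a variant leaving the LoF category loses
PVS1, one entering it gains PVS1. For variants with a PVS1 flip, the full
criterion set is re-evaluated on both sides — all evidence held fixed
except the functional category — and the resulting class pair is scored as
upgraded / unchanged / downgraded under the order B < LB < VUS < LP < P.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import pandas as pd

from .acmg import CLASS_ORDER, Classification, CriterionConfig, EvidenceInput, classify, with_category
from .so_normalize import FunctionalCategory


@dataclass(frozen=True)
class Pvs1Delta:
    variant_key: tuple | int | str
    reference_category: FunctionalCategory
    tool_category: FunctionalCategory
    status: str                 # pvs1_loss | pvs1_gain | none
    category_changed: bool


@dataclass(frozen=True)
class ClassDelta:
    variant_key: tuple | int | str
    reference_class: Classification
    tool_class: Classification
    direction: str              # upgraded | unchanged | downgraded


def _pvs1_status(ref: FunctionalCategory, tool: FunctionalCategory) -> str:
    ref_lof = ref is FunctionalCategory.LOF
    tool_lof = tool is FunctionalCategory.LOF
    if ref_lof and not tool_lof:
        return "pvs1_loss"
    if tool_lof and not ref_lof:
        return "pvs1_gain"
    return "none"


def pvs1_delta(
    pairs: Iterable[tuple[FunctionalCategory, FunctionalCategory]],
    keys: Iterable | None = None,
) -> tuple[list[Pvs1Delta], dict[str, int]]:
    """Score each (reference, tool) category pair for PVS1 loss/gain."""
    pairs = list(pairs)
    keys = list(keys) if keys is not None else list(range(len(pairs)))
    deltas = [
        Pvs1Delta(k, ref, tool, _pvs1_status(ref, tool), ref != tool)
        for k, (ref, tool) in zip(keys, pairs)
    ]
    summary = {
        "pvs1_loss": sum(1 for d in deltas if d.status == "pvs1_loss"),
        "pvs1_gain": sum(1 for d in deltas if d.status == "pvs1_gain"),
        "within_lof_change": sum(
            1 for d in deltas if d.status == "none" and d.category_changed
            and d.reference_category is FunctionalCategory.LOF
        ),
        "unchanged": sum(1 for d in deltas if not d.category_changed),
        "n": len(deltas),
    }
    return deltas, summary


def _direction(ref: Classification, tool: Classification) -> str:
    if CLASS_ORDER[tool] > CLASS_ORDER[ref]:
        return "upgraded"
    if CLASS_ORDER[tool] < CLASS_ORDER[ref]:
        return "downgraded"
    return "unchanged"


def _classes_agree(cls: Classification, clinvar_class: str | None) -> bool:
    """Group-level agreement with the ClinVar assertion (P/LP vs B/LB)."""
    if clinvar_class is None:
        return False
    plp = {Classification.P, Classification.LP}
    blb = {Classification.B, Classification.LB}
    if clinvar_class in ("P", "LP"):
        return cls in plp
    if clinvar_class in ("B", "LB"):
        return cls in blb
    return False


def reclassify_delta(
    evidence_pairs: Iterable[tuple[EvidenceInput, EvidenceInput]],
    cfg: CriterionConfig | None = None,
    keys: Iterable | None = None,
    no_conflict_only: bool = True,
) -> tuple[list[ClassDelta], pd.DataFrame]:
    """Classify both sides of each evidence pair and score the direction.

    With ``no_conflict_only`` (the default) only variants whose
    reference-side automatic class agrees with their ClinVar assertion at
    the P/LP-vs-B/LB level are scored — the reassessment pre-filter.
    Direction counts are grouped by the reference ClinVar class.
    """
    cfg = cfg or CriterionConfig()
    pairs = list(evidence_pairs)
    keys = list(keys) if keys is not None else list(range(len(pairs)))
    deltas: list[ClassDelta] = []
    rows = []
    for key, (ref_e, tool_e) in zip(keys, pairs):
        ref_cls, _ = classify(ref_e, cfg)
        if no_conflict_only and not _classes_agree(ref_cls, ref_e.clinvar_class):
            continue
        tool_cls, _ = classify(tool_e, cfg)
        d = ClassDelta(key, ref_cls, tool_cls, _direction(ref_cls, tool_cls))
        deltas.append(d)
        rows.append({"clinvar_class": ref_e.clinvar_class or "NA", "direction": d.direction})
    if rows:
        counts = (
            pd.DataFrame(rows)
            .groupby(["clinvar_class", "direction"])
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["clinvar_class", "direction", "count"])
    return deltas, counts


def summarize(deltas: Iterable[Pvs1Delta | ClassDelta]) -> pd.DataFrame:
    """Stacked-bar-ready counts and proportions per group.

    For Pvs1Delta inputs groups are changed/unchanged category status; for
    ClassDelta inputs groups are the upgrade direction. Proportions sum to
    one (over a non-empty input).
    """
    deltas = list(deltas)
    if not deltas:
        return pd.DataFrame(columns=["group", "count", "proportion"])
    if isinstance(deltas[0], Pvs1Delta):
        labels = ["changed" if d.category_changed else "unchanged" for d in deltas]
    else:
        labels = [d.direction for d in deltas]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels)
    rows = [
        {"group": g, "count": c, "proportion": round(c / n, 3)}
        for g, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["group", "count", "proportion"])
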