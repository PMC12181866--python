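"""ACMG/AMP 2015 criterion evaluation and rule combining.

Evaluated criteria and their triggers (all other criteria are pass-through
external flags):

* PVS1 — functional category is LoF (frameshift, splice donor/acceptor,
  nonsense); PP3 is disabled whenever PVS1 fires.
* PP3  — CADD >= 25.3 or SpliceAI >= 0.5 (ClinGen-recommended thresholds).
* BP4  — CADD < 22.7 and SpliceAI (if present) < 0.5.
* PP5 / BP6 — reputable-source criteria keyed to the ClinVar assertion,
  with strength scaled by review stars: two-star -> PP5 moderate / BP6
  strong; three or more stars -> very strong.
* PM4  — protein-length-changing category.
* BP7  — synonymous category with no splice signal.

PS4, PM3, PP4, BP2 and BP5 are excluded (they need cohort, phasing, or
gene-disease data unavailable to an automated pipeline).

Combining follows the 2015 guideline's table over counts of applied
strengths per direction; pathogenic and benign sides are evaluated
independently and a conflict collapses to VUS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .so_normalize import FunctionalCategory


class Strength(str, enum.Enum):
    STANDALONE = "standalone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Classification(str, enum.Enum):
    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"


#: total order used for upgrade/downgrade direction
CLASS_ORDER = {c: i for i, c in enumerate(
    [Classification.B, Classification.LB, Classification.VUS,
     Classification.LP, Classification.P]
)}

PATHOGENIC_CRITERIA = frozenset(
    {"PVS1"} | {f"PS{i}" for i in range(1, 5)} | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CRITERIA = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)

_DEFAULT_STRENGTH = {
    "PVS": Strength.VERY_STRONG, "PS": Strength.STRONG, "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING, "BA": Strength.STANDALONE, "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}


def direction(criterion: str) -> str:
    if criterion in PATHOGENIC_CRITERIA:
        return "pathogenic"
    if criterion in BENIGN_CRITERIA:
        return "benign"
    raise ValueError(f"unknown criterion {criterion!r}")


def default_strength(criterion: str) -> Strength:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if criterion.startswith(prefix):
            return _DEFAULT_STRENGTH[prefix]
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass(frozen=True)
class AppliedCriterion:
    criterion: str
    strength: Strength

    @classmethod
    def at_default(cls, criterion: str) -> "AppliedCriterion":
        return cls(criterion, default_strength(criterion))


@dataclass
class CriterionConfig:
    pp3_cadd_min: float = 25.3
    bp4_cadd_max: float = 22.7
    spliceai_min: float = 0.5
    pp5_star_map: dict[int, Strength] = field(
        default_factory=lambda: {2: Strength.MODERATE, 3: Strength.VERY_STRONG}
    )
    bp6_star_map: dict[int, Strength] = field(
        default_factory=lambda: {2: Strength.STRONG, 3: Strength.VERY_STRONG}
    )
    disabled: frozenset[str] = frozenset({"PS4", "PM3", "PP4", "BP2", "BP5"})
    # one benign very_strong (BP6 at >= 3 stars) suffices for Benign; the
    # 2015 benign table has no very-strong slot, so it is weighted like two
    # strong-benign criteria (configurable)
    benign_very_strong_is_ba: bool = True

    def __post_init__(self):
        if self.pp3_cadd_min <= self.bp4_cadd_max:
            raise ValueError("pp3_cadd_min must exceed bp4_cadd_max")

    def star_strength(self, star_map: dict[int, Strength], stars: int) -> Strength | None:
        for threshold in sorted(star_map, reverse=True):
            if stars >= threshold:
                return star_map[threshold]
        return None


@dataclass
class EvidenceInput:
    functional_category: FunctionalCategory = FunctionalCategory.OTHER
    cadd: float | None = None
    spliceai_max: float | None = None
    clinvar_class: str | None = None     # P | LP | B | LB
    stars: int = 0
    external: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.spliceai_max is not None and not 0.0 <= self.spliceai_max <= 1.0:
            raise ValueError("spliceai_max must lie in [0, 1]")


def evaluate_criteria(
    e: EvidenceInput, cfg: CriterionConfig | None = None
) -> set[AppliedCriterion]:
    """Evaluate the automated criteria for one variant's evidence."""
    cfg = cfg or CriterionConfig()
    applied: dict[str, AppliedCriterion] = {}

    def fire(criterion: str, strength: Strength | None = None) -> None:
        if criterion in cfg.disabled or criterion in applied:
            return
        applied[criterion] = AppliedCriterion(
            criterion, strength or default_strength(criterion)
        )

    pvs1 = e.functional_category is FunctionalCategory.LOF
    if pvs1:
        fire("PVS1")

    splice_hit = e.spliceai_max is not None and e.spliceai_max >= cfg.spliceai_min
    splice_quiet = e.spliceai_max is None or e.spliceai_max < cfg.spliceai_min
    if not pvs1 and ((e.cadd is not None and e.cadd >= cfg.pp3_cadd_min) or splice_hit):
        fire("PP3")
    if e.cadd is not None and e.cadd < cfg.bp4_cadd_max and splice_quiet:
        fire("BP4")

    if e.clinvar_class in ("P", "LP"):
        s = cfg.star_strength(cfg.pp5_star_map, e.stars)
        if s is not None:
            fire("PP5", s)
    elif e.clinvar_class in ("B", "LB"):
        s = cfg.star_strength(cfg.bp6_star_map, e.stars)
        if s is not None:
            fire("BP6", s)

    if e.functional_category is FunctionalCategory.PROTEIN_LENGTH_CHANGE:
        fire("PM4")
    if e.functional_category is FunctionalCategory.SYNONYMOUS and splice_quiet:
        fire("BP7")

    for criterion, flag in e.external.items():
        if flag:
            fire(criterion)
    return set(applied.values())


def _counts(applied: set[AppliedCriterion], side: str) -> dict[Strength, int]:
    out = {s: 0 for s in Strength}
    for a in applied:
        if direction(a.criterion) == side:
            out[a.strength] += 1
    return out


def _pathogenic_met(c: dict[Strength, int]) -> bool:
    vs, s, m, p = (c[Strength.VERY_STRONG], c[Strength.STRONG],
                   c[Strength.MODERATE], c[Strength.SUPPORTING])
    if vs >= 2:
        return True
    if vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p == 1) or p >= 2):
        return True
    if s >= 2:
        return True
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return True
    return False


def _likely_pathogenic_met(c: dict[Strength, int]) -> bool:
    vs, s, m, p = (c[Strength.VERY_STRONG], c[Strength.STRONG],
                   c[Strength.MODERATE], c[Strength.SUPPORTING])
    if vs == 1 and m == 1:
        return True
    if s == 1 and 1 <= m <= 2:
        return True
    if s == 1 and p >= 2:
        return True
    if m >= 3:
        return True
    if m == 2 and p >= 2:
        return True
    if m == 1 and p >= 4:
        return True
    return False


def _benign_met(c: dict[Strength, int], cfg: CriterionConfig) -> bool:
    if c[Strength.STANDALONE] >= 1:
        return True
    strong = c[Strength.STRONG]
    if cfg.benign_very_strong_is_ba and c[Strength.VERY_STRONG] >= 1:
        return True
    strong += c[Strength.VERY_STRONG]
    return strong >= 2


def _likely_benign_met(c: dict[Strength, int]) -> bool:
    strong = c[Strength.STRONG] + c[Strength.VERY_STRONG]
    if strong >= 1 and c[Strength.SUPPORTING] >= 1:
        return True
    return c[Strength.SUPPORTING] >= 2


def combine(
    applied: set[AppliedCriterion], cfg: CriterionConfig | None = None
) -> Classification:
    """Combine applied criteria into the five-class call. Total and
    deterministic; evidence satisfying both directions yields VUS."""
    cfg = cfg or CriterionConfig()
    pc = _counts(applied, "pathogenic")
    bc = _counts(applied, "benign")
    if _pathogenic_met(pc):
        patho: Classification | None = Classification.P
    elif _likely_pathogenic_met(pc):
        patho = Classification.LP
    else:
        patho = None
    if _benign_met(bc, cfg):
        benign: Classification | None = Classification.B
    elif _likely_benign_met(bc):
        benign = Classification.LB
    else:
        benign = None
    if patho is not None and benign is not None:
        return Classification.VUS
    return patho or benign or Classification.VUS


def classify(
    e: EvidenceInput, cfg: CriterionConfig | None = None
) -> tuple[Classification, set[AppliedCriterion]]:
    """Evaluate then combine; the applied set is returned for audit."""
    cfg = cfg or CriterionConfig()
    applied = evaluate_criteria(e, cfg)
    return combine(applied, cfg), applied


def with_category(e: EvidenceInput, category: FunctionalCategory) -> EvidenceInput:
    """Copy the evidence with only the functional category swapped — the
    reassessment contract for tool-vs-reference deltas."""
    return replace(e, functional_category=category, external=dict(e.external))
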