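"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from varconcord.simulate import SimConfig, simulate


# --- independent transcription of the 2015 rule-combining table --------------
#
# Deliberately coded from the rule list itself (counts of applied strengths),
# independent of varconcord.acmg's implementation, to serve as the oracle.

def brute_force_combine(applied, benign_very_strong_is_ba: bool = True) -> str:
    """applied: iterable of (direction, strength) pairs with direction in
    {"pathogenic", "benign"} and strength in {"standalone", "very_strong",
    "strong", "moderate", "supporting"}. Returns one of P/LP/VUS/LB/B."""
    pvs = sum(1 for d, s in applied if d == "pathogenic" and s == "very_strong")
    ps = sum(1 for d, s in applied if d == "pathogenic" and s == "strong")
    pm = sum(1 for d, s in applied if d == "pathogenic" and s == "moderate")
    pp = sum(1 for d, s in applied if d == "pathogenic" and s == "supporting")
    ba = sum(1 for d, s in applied if d == "benign" and s == "standalone")
    bvs = sum(1 for d, s in applied if d == "benign" and s == "very_strong")
    bs = sum(1 for d, s in applied if d == "benign" and s == "strong")
    bp = sum(1 for d, s in applied if d == "benign" and s == "supporting")

    pathogenic = (
        pvs >= 2
        or (pvs == 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and pm in (1, 2))
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    strong_equiv = bs + (bvs if not benign_very_strong_is_ba else 0)
    benign = ba >= 1 or (benign_very_strong_is_ba and bvs >= 1) or (bs + bvs) >= 2
    likely_benign = ((bs + bvs) >= 1 and bp >= 1) or bp >= 2
    del strong_equiv

    patho_call = "P" if pathogenic else ("LP" if likely_pathogenic else None)
    benign_call = "B" if benign else ("LB" if likely_benign else None)
    if patho_call and benign_call:
        return "VUS"
    return patho_call or benign_call or "VUS"


@pytest.fixture(scope="session")
def small_sim():
    """A modest default-world simulation shared across read-only tests."""
    return simulate(SimConfig(n_variants=300, seed=11))


@pytest.fixture(scope="session")
def noiseless_sim():
    """All corruption rates zero: every tool reproduces the truth exactly."""
    from varconcord.simulate import ToolCorruption

    cfg = SimConfig(
        n_variants=200, seed=5,
        tools={name: ToolCorruption() for name in ("annovar", "snpeff", "vep")},
    )
    # even the version-stripping and dialect quirks stay: only noise is off
    return simulate(cfg)
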