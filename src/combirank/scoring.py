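"""The composite scoring core: sp, comm, Cscore, Dscore, Combiscore.

A candidate (one natural product, or an unordered mixture of two or three)
is scored from two annotated target profiles:

* the *knowledgebase-side* profile (literature/bioassay predictions merged
  with Ki-screened docking targets) feeds the Cscore;
* the *docking-side* profile (docking hits restricted to the forward-docking
  protein panel of size N) feeds the Dscore.

With Ac = cancer-related, Am = AML-related and Ah = hub target counts,
comm = number of targets shared by ≥2 constituents, and
sp = (Ac − non-cancer count) / total:

    Cscore     = 0.2·(Ac − (Am + Ah)) + 0.4·Am + 0.3·Ah − 0.1·comm + sp
    Dscore     = [0.2·(Ac − (Am + Ah)) + 0.4·Am + 0.3·Ah − 0.1·comm] / N
    Combiscore = 0.6·Cscore + 0.4·Dscore

Higher Combiscores indicate better candidates. The Dscore divisor is N by
default: although the formula is sometimes quoted with N−1, every published
nonzero singlet Dscore is an exact multiple of 0.1/59, which pins the
divisor to N (see :func:`select_divisor_mode`); N−1 remains available as a
configuration mode.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .datamodel import (
    Owner,
    ScoreRecord,
    ScoringWeights,
    TargetProfile,
    make_owner,
    merge_profiles,
)
from .errors import ConfigurationError, UnsupportedArityError


def specificity(profile: TargetProfile) -> float:
    """sp = (Ac − n_noncancer)/n_total; 0 for an empty profile.

    Lies in [−1, 1]: +1 when every target is cancer-related, −1 when none
    is. An empty profile carries no specificity information and is scored 0.
    """
    if profile.n_total == 0:
        return 0.0
    return (profile.ac - profile.n_noncancer) / profile.n_total


def common_targets(member_profiles: Sequence[TargetProfile]) -> int:
    """Number of proteins shared by at least two mixture constituents."""
    if not 1 <= len(member_profiles) <= 3:
        raise UnsupportedArityError(
            f"mixtures have 1-3 constituents, got {len(member_profiles)}"
        )
    if len(member_profiles) == 1:
        return 0
    counts: dict[str, int] = {}
    for profile in member_profiles:
        for protein in profile.proteins:
            counts[protein] = counts.get(protein, 0) + 1
    return sum(1 for c in counts.values() if c >= 2)


def _category_numerator(profile: TargetProfile, comm: int, w: ScoringWeights) -> float:
    # Written exactly as the formula reads: the AML/hub counts are first
    # subtracted from the cancer count (the residual may go negative), then
    # re-added at their own weights.
    return (
        w.w_cancer * (profile.ac - (profile.am + profile.ah))
        + w.w_aml * profile.am
        + w.w_hub * profile.ah
        - w.w_comm * comm
    )


def cscore(
    profile: TargetProfile,
    comm: int,
    sp: float,
    weights: Optional[ScoringWeights] = None,
) -> float:
    """Knowledgebase-side score of a candidate's annotated target profile."""
    w = weights or ScoringWeights()
    return _category_numerator(profile, comm, w) + sp


def dscore(
    docking_profile: TargetProfile,
    comm_docking: int,
    weights: Optional[ScoringWeights] = None,
) -> float:
    """Docking-side score, normalised by the forward-docking panel size."""
    w = weights or ScoringWeights()
    divisor = w.dscore_divisor
    if divisor <= 0:
        raise ConfigurationError(f"Dscore divisor must be positive, got {divisor}")
    return _category_numerator(docking_profile, comm_docking, w) / divisor


def combiscore(c: float, d: float, weights: Optional[ScoringWeights] = None) -> float:
    """Blend the two scores (default 0.6·Cscore + 0.4·Dscore)."""
    w = weights or ScoringWeights()
    return w.w_cscore * c + w.w_dscore * d


def score_candidate(
    owner: Owner,
    kb_member_profiles: Sequence[TargetProfile],
    docking_member_profiles: Sequence[TargetProfile],
    weights: Optional[ScoringWeights] = None,
) -> ScoreRecord:
    """Score one candidate from its constituents' per-compound profiles.

    ``kb_member_profiles`` and ``docking_member_profiles`` hold one profile
    per constituent, in matching order. Mixture profiles are the union of
    the member profiles; comm is computed separately on each side (the
    knowledgebase-side comm enters the Cscore and is the one reported).
    """
    w = weights or ScoringWeights()
    owner = make_owner(owner)
    if not len(kb_member_profiles) == len(docking_member_profiles) == len(owner):
        raise ConfigurationError(
            "one knowledgebase-side and one docking-side profile required "
            f"per constituent of {owner}"
        )
    kb_union = merge_profiles(kb_member_profiles)
    dock_union = merge_profiles(docking_member_profiles)
    comm_kb = common_targets(kb_member_profiles)
    comm_dock = common_targets(docking_member_profiles)
    sp = specificity(kb_union)
    c = cscore(kb_union, comm_kb, sp, w)
    d = dscore(dock_union, comm_dock, w)
    detail = {
        "kb_ac": kb_union.ac,
        "kb_am": kb_union.am,
        "kb_ah": kb_union.ah,
        "kb_n_total": kb_union.n_total,
        "dock_ac": dock_union.ac,
        "dock_am": dock_union.am,
        "dock_ah": dock_union.ah,
        "dock_n_total": dock_union.n_total,
        "comm_kb": comm_kb,
        "comm_dock": comm_dock,
    }
    return ScoreRecord(
        owner=owner,
        cscore=c,
        dscore=d,
        combiscore=combiscore(c, d, w),
        comm=comm_kb,
        sp=sp,
        detail=detail,
    )


def select_divisor_mode(
    dscores: Sequence[float],
    n_forward: int = 59,
    penalty_quantum: float = 0.1,
    tol: float = 1e-5,
) -> str:
    """Infer the Dscore divisor (N vs N−1) from published Dscore values.

    Every Dscore numerator is a sum of integer counts times weights that are
    multiples of 0.1, so ``dscore × divisor`` must land on the 0.1 grid.
    Zero Dscores are uninformative and skipped. Returns ``"n"`` or
    ``"n_minus_1"``; raises if neither (or both) divisors are consistent
    with all supplied values.
    """
    informative = [d for d in dscores if abs(d) > tol]
    if not informative:
        raise ConfigurationError("no nonzero Dscore values to calibrate against")

    def consistent(divisor: int) -> bool:
        for d in informative:
            quanta = d * divisor / penalty_quantum
            if abs(quanta - round(quanta)) > tol * divisor:
                return False
        return True

    ok = {"n": consistent(n_forward), "n_minus_1": consistent(n_forward - 1)}
    if ok["n"] and not ok["n_minus_1"]:
        return "n"
    if ok["n_minus_1"] and not ok["n"]:
        return "n_minus_1"
    raise ConfigurationError(
        f"divisor mode ambiguous or inconsistent for N={n_forward}: {ok}"
    )
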