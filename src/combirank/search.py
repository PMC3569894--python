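"""Tiered mean-threshold combination search.

The search scores every single compound, keeps those whose Combiscore is
greater than or equal to the tier threshold (by default the tier's mean
Combiscore — the published procedure), then enumerates pairs seeded by the
surviving singlets, scores and thresholds them, and finally triples seeded
by the surviving pairs. Thirteen compounds give 78 unconstrained pairs and
286 unconstrained triples; the seed constraint prunes that space.

Seeding defaults to *contains a selected member*: a pair/triple is admitted
when at least one constituent appeared in the previous tier's selection.
This is deliberately weaker than requiring every constituent to be
selected — in the published run, compounds that failed the singlet cut
(limonene) still surfaced inside selected pairs, which is only possible
under the weaker rule. The stricter ``all_members_selected`` mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

from .datamodel import (
    Owner,
    ScoreRecord,
    ScoringWeights,
    TierResult,
)
from .errors import ConfigurationError, ValidationError
from .scoring import score_candidate
from .screen import ScreenConfig, member_profiles
from .synthetic import Dataset

TIER_NAMES = {1: "singlet", 2: "pair", 3: "triple"}


@dataclass(frozen=True)
class SearchConfig:
    max_arity: int = 3
    threshold_mode: str = "mean"  # mean | fixed
    fixed_thresholds: Optional[Tuple[float, ...]] = None  # one per tier
    seed_constraint: str = "contains_selected_member"  # or all_members_selected

    def __post_init__(self) -> None:
        if self.max_arity not in (2, 3):
            raise ConfigurationError(f"max_arity must be 2 or 3, got {self.max_arity}")
        if self.threshold_mode not in ("mean", "fixed"):
            raise ConfigurationError(
                f"threshold_mode must be 'mean' or 'fixed', got {self.threshold_mode!r}"
            )
        if (self.threshold_mode == "fixed") != (self.fixed_thresholds is not None):
            raise ConfigurationError(
                "fixed_thresholds must be supplied iff threshold_mode is 'fixed'"
            )
        if self.seed_constraint not in (
            "contains_selected_member",
            "all_members_selected",
        ):
            raise ConfigurationError(
                f"unknown seed_constraint {self.seed_constraint!r}"
            )

    def threshold_for(self, tier_index: int, mean: float) -> float:
        if self.threshold_mode == "mean":
            return mean
        assert self.fixed_thresholds is not None
        if tier_index > len(self.fixed_thresholds):
            raise ConfigurationError(
                f"no fixed threshold configured for tier {tier_index}"
            )
        return self.fixed_thresholds[tier_index - 1]


def enumerate_candidates(
    compound_ids: Sequence[str],
    k: int,
    constraint: Optional[str] = None,
    selected_previous: Optional[Sequence[Owner]] = None,
) -> List[Owner]:
    """All unordered k-subsets of the compounds, optionally seed-constrained.

    Unconstrained, returns all C(n, k) subsets in lexicographic order.
    With ``constraint='contains_selected_member'`` only subsets sharing at
    least one compound with the previous tier's selected candidates are
    kept; with ``'all_members_selected'`` every constituent must appear
    there. ``k > n`` yields an empty list.
    """
    if not 1 <= k <= 3:
        raise ConfigurationError(f"candidate arity must be 1-3, got {k}")
    ids = sorted(set(compound_ids))
    if len(ids) != len(list(compound_ids)):
        raise ValidationError("duplicate compound ids in enumeration input")
    subsets: List[Owner] = [tuple(s) for s in combinations(ids, k)]
    if constraint is None:
        return subsets
    members: set = set()
    for owner in selected_previous or ():
        members.update(owner)
    if constraint == "contains_selected_member":
        return [s for s in subsets if members.intersection(s)]
    if constraint == "all_members_selected":
        return [s for s in subsets if members.issuperset(s)]
    raise ConfigurationError(f"unknown constraint {constraint!r}")


def select_tier(
    scored: Sequence[ScoreRecord],
    cfg: Optional[SearchConfig] = None,
    tier: str = "singlet",
    tier_index: Optional[int] = None,
) -> TierResult:
    """Apply the inclusive ≥-threshold rule to one tier of scored candidates.

    The threshold is the tier's arithmetic mean Combiscore (mode ``mean``)
    or the configured fixed value; candidates exactly at the threshold are
    selected. Output is sorted descending by Combiscore, then
    lexicographically by owner, so selection is invariant to input order.
    """
    if not scored:
        raise ValidationError("select_tier requires at least one scored candidate")
    cfg = cfg or SearchConfig()
    if tier_index is None:
        tier_index = {"singlet": 1, "pair": 2, "triple": 3}[tier]
    ranked = sorted(scored, key=lambda r: (-r.combiscore, r.owner))
    mean = sum(r.combiscore for r in ranked) / len(ranked)
    threshold = cfg.threshold_for(tier_index, mean)
    selected = tuple(r.owner for r in ranked if r.combiscore >= threshold)
    return TierResult(
        tier=tier,
        scored=tuple(ranked),
        mean_combiscore=mean,
        threshold=threshold,
        selected=selected,
    )


def run_search(
    dataset: Dataset,
    weights: Optional[ScoringWeights] = None,
    screen_cfg: Optional[ScreenConfig] = None,
    search_cfg: Optional[SearchConfig] = None,
) -> List[TierResult]:
    """Full tiered search: singlets → seeded pairs → seeded triples.

    Per-compound knowledgebase-side and docking-side profiles are built
    once; each candidate is scored on the union of its members' profiles.
    A tier whose enumeration is empty (nothing selected upstream under
    ``all_members_selected``) produces an empty-tier placeholder rather
    than an error, so the cascade always reports ``max_arity`` tiers.
    """
    weights = weights or ScoringWeights()
    screen_cfg = screen_cfg or dataset.screen_config()
    search_cfg = search_cfg or SearchConfig()

    ids = [c.compound_id for c in dataset.compounds]
    kb, dock = member_profiles(
        ids, dataset.predictions, dataset.docking, dataset.universe_map, screen_cfg
    )

    def score(owner: Owner) -> ScoreRecord:
        return score_candidate(
            owner, [kb[c] for c in owner], [dock[c] for c in owner], weights
        )

    tiers: List[TierResult] = []
    selected_prev: Sequence[Owner] = ()
    for k in range(1, search_cfg.max_arity + 1):
        name = TIER_NAMES[k]
        if k == 1:
            owners = enumerate_candidates(ids, 1)
        else:
            owners = enumerate_candidates(
                ids, k, search_cfg.seed_constraint, selected_prev
            )
        if not owners:
            tiers.append(
                TierResult(
                    tier=name,
                    scored=(),
                    mean_combiscore=float("nan"),
                    threshold=float("nan"),
                    selected=(),
                )
            )
            selected_prev = ()
            continue
        records = [score(o) for o in owners]
        tier = select_tier(records, search_cfg, name, tier_index=k)
        tiers.append(tier)
        selected_prev = tier.selected
    return tiers


def tiers_as_dict(tiers: Sequence[TierResult]) -> Dict:
    """JSON-ready view of a tier cascade (used by tiers.json and reports)."""
    out: Dict = {"tiers": []}
    for t in tiers:
        out["tiers"].append(
            {
                "tier": t.tier,
                "n_scored": len(t.scored),
                "mean_combiscore": t.mean_combiscore,
                "threshold": t.threshold,
                "selected": ["+".join(o) for o in t.selected],
                "scores": [
                    {
                        "owner": "+".join(r.owner),
                        "cscore": r.cscore,
                        "dscore": r.dscore,
                        "combiscore": r.combiscore,
                        "comm": r.comm,
                        "sp": r.sp,
                        "detail": dict(r.detail) if r.detail else None,
                    }
                    for r in t.scored
                ],
            }
        )
    return out
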