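"""Inhibition-constant screening and target-profile assembly.

Docking results are screened on the predicted inhibition constant Ki (μM):
a record survives when Ki is strictly below the cutoff (default <10 μM; a
high-stringency <1 μM subset is also conventional). Screened docking
targets are merged with knowledgebase/bioassay predictions into the
knowledgebase-side :class:`~combirank.datamodel.TargetProfile` of each
candidate; the docking-side profile used by the Dscore is restricted to the
forward-docking protein panel (N proteins, default 59).

Mixture profiles are the set-union of member-compound profiles: a protein
shared by two constituents counts once in the profile (the sharing itself
is penalised separately via comm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence

from .datamodel import (
    DockingRecord,
    Owner,
    TargetPrediction,
    TargetProfile,
    TargetProtein,
    make_owner,
)
from .errors import ConfigurationError, ValidationError

DEFAULT_KI_CUTOFF_UM = 10.0
DEFAULT_KI_STRICT_UM = 1.0


@dataclass(frozen=True)
class ScreenConfig:
    """Ki cutoffs, forward-docking panel, and confidence filter."""

    ki_cutoff_um: float = DEFAULT_KI_CUTOFF_UM
    ki_strict_um: float = DEFAULT_KI_STRICT_UM
    forward_protein_set: frozenset[str] = frozenset()
    confidence_filter: frozenset[str] = frozenset({"high", "medium", "low"})

    def __post_init__(self) -> None:
        if not self.ki_cutoff_um > 0 or not self.ki_strict_um > 0:
            raise ConfigurationError("Ki cutoffs must be positive")
        if self.ki_strict_um > self.ki_cutoff_um:
            raise ConfigurationError(
                f"ki_strict_um ({self.ki_strict_um}) must be <= "
                f"ki_cutoff_um ({self.ki_cutoff_um})"
            )
        object.__setattr__(
            self, "forward_protein_set", frozenset(self.forward_protein_set)
        )
        object.__setattr__(
            self, "confidence_filter", frozenset(self.confidence_filter)
        )
        bad = self.confidence_filter - {"high", "medium", "low"}
        if bad:
            raise ConfigurationError(f"unknown confidence level(s): {sorted(bad)}")


def screen_by_ki(
    docking_records: Sequence[DockingRecord], cutoff_um: float
) -> List[DockingRecord]:
    """Retain records with Ki strictly below the cutoff; order preserved.

    The cutoff is strict ("<10 μM"): a record at exactly the cutoff is
    dropped.
    """
    if not cutoff_um > 0:
        raise ConfigurationError(f"Ki cutoff must be positive, got {cutoff_um}")
    return [r for r in docking_records if r.ki_um < cutoff_um]


def _universe_map(
    universe: Mapping[str, TargetProtein] | Iterable[TargetProtein],
) -> Mapping[str, TargetProtein]:
    if isinstance(universe, Mapping):
        return universe
    return {p.protein_id: p for p in universe}


def build_profile(
    owner: Owner | Iterable[str],
    predictions: Sequence[TargetPrediction],
    docking_records: Sequence[DockingRecord],
    universe: Mapping[str, TargetProtein] | Iterable[TargetProtein],
    cfg: Optional[ScreenConfig] = None,
) -> TargetProfile:
    """Knowledgebase-side profile of a candidate.

    The protein set is the union of (a) knowledgebase/bioassay predictions
    for the candidate's compounds that pass the confidence filter and (b)
    docking records passing the Ki cutoff. For mixtures the union runs over
    all member compounds.
    """
    cfg = cfg or ScreenConfig()
    owner = make_owner(owner)
    members = set(owner)
    universe = _universe_map(universe)

    proteins: set[str] = set()
    for pred in predictions:
        if pred.compound_id not in members:
            continue
        if pred.source == "docking":
            # Docking-sourced predictions are Ki-screened like docking rows.
            if pred.ki_um is not None and pred.ki_um < cfg.ki_cutoff_um:
                proteins.add(pred.protein_id)
            continue
        if pred.confidence in cfg.confidence_filter:
            proteins.add(pred.protein_id)
    for rec in screen_by_ki(
        [r for r in docking_records if r.compound_id in members], cfg.ki_cutoff_um
    ):
        proteins.add(rec.protein_id)

    unknown = sorted(p for p in proteins if p not in universe)
    if unknown:
        raise ValidationError(
            f"prediction references unknown protein id(s): {unknown[:5]}"
        )
    return TargetProfile.from_proteins(owner, proteins, universe)


def build_docking_profile(
    owner: Owner | Iterable[str],
    docking_records: Sequence[DockingRecord],
    universe: Mapping[str, TargetProtein] | Iterable[TargetProtein],
    cfg: ScreenConfig,
) -> TargetProfile:
    """Docking-side profile: Ki-screened hits within the forward panel."""
    if not cfg.forward_protein_set:
        raise ConfigurationError(
            "forward_protein_set must be non-empty for docking profiles"
        )
    owner = make_owner(owner)
    members = set(owner)
    universe = _universe_map(universe)
    hits = screen_by_ki(
        [
            r
            for r in docking_records
            if r.compound_id in members and r.protein_id in cfg.forward_protein_set
        ],
        cfg.ki_cutoff_um,
    )
    return TargetProfile.from_proteins(owner, {r.protein_id for r in hits}, universe)


def member_profiles(
    compound_ids: Sequence[str],
    predictions: Sequence[TargetPrediction],
    docking_records: Sequence[DockingRecord],
    universe: Mapping[str, TargetProtein] | Iterable[TargetProtein],
    cfg: Optional[ScreenConfig] = None,
) -> tuple[dict[str, TargetProfile], dict[str, TargetProfile]]:
    """Per-compound knowledgebase-side and docking-side profiles.

    Convenience for the combination search: profiles are built once per
    compound and unioned per candidate downstream.
    """
    cfg = cfg or ScreenConfig()
    universe = _universe_map(universe)
    kb = {
        cid: build_profile((cid,), predictions, docking_records, universe, cfg)
        for cid in compound_ids
    }
    dock = {
        cid: build_docking_profile((cid,), docking_records, universe, cfg)
        for cid in compound_ids
    }
    return kb, dock
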