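"""Domain types for combination ranking.

The central objects are:

* :class:`CompoundRecord` — a natural product with a functional-group
  fingerprint (a set of group labels, presence/absence only).
* :class:`TargetProtein` — a protein with cancer / AML (acute myeloid
  leukemia) / hub annotations and pathway memberships.
* :class:`TargetPrediction` — one predicted compound→protein binding, from a
  knowledgebase, a bioassay record, or docking (docking rows carry a Ki).
* :class:`TargetProfile` — the annotated predicted-binding-protein set of a
  compound or a 2–3-compound mixture; exposes the counts Ac (cancer-related),
  Am (AML-related), Ah (hub) that the scoring formulas consume.
* :class:`ScoreRecord` — Cscore, Dscore, Combiscore for one candidate.
* :class:`ScoringWeights` — the category weights and the docking divisor N.
* :class:`TierResult` — one selection tier (singlets, pairs, or triples).

A *candidate* is identified by a tuple of one, two, or three compound ids,
always stored sorted so identity is order-insensitive; the display form is
the "+"-joined string (``a+b+c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .errors import UnsupportedArityError, ValidationError

PREDICTION_SOURCES = ("knowledgebase", "bioassay", "docking")
CONFIDENCE_LEVELS = ("high", "medium", "low")
TIERS = ("singlet", "pair", "triple")

Owner = Tuple[str, ...]


def make_owner(compound_ids: Iterable[str]) -> Owner:
    """Canonical order-insensitive candidate identifier (sorted tuple)."""
    owner = tuple(sorted(compound_ids))
    if not 1 <= len(owner) <= 3:
        raise UnsupportedArityError(
            f"candidates have 1-3 constituents, got {len(owner)}"
        )
    if len(set(owner)) != len(owner):
        raise ValidationError(f"duplicate compound in candidate: {owner}")
    return owner


def owner_label(owner: Owner) -> str:
    return "+".join(owner)


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    functional_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        object.__setattr__(
            self, "functional_groups", frozenset(self.functional_groups)
        )


@dataclass(frozen=True)
class TargetProtein:
    protein_id: str
    name: str
    is_cancer: bool = False
    is_aml: bool = False
    is_hub: bool = False
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        object.__setattr__(self, "pathways", frozenset(self.pathways))


@dataclass(frozen=True)
class TargetPrediction:
    """A compound→protein prediction; ki_um present iff source is docking."""

    compound_id: str
    protein_id: str
    source: str
    confidence: str
    ki_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in PREDICTION_SOURCES:
            raise ValidationError(
                f"source must be one of {PREDICTION_SOURCES}, got {self.source!r}"
            )
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"confidence must be one of {CONFIDENCE_LEVELS}, "
                f"got {self.confidence!r}"
            )
        if self.source == "docking":
            if self.ki_um is None:
                raise ValidationError(
                    f"docking prediction {self.compound_id}->{self.protein_id} "
                    "is missing ki_um"
                )
            if not self.ki_um > 0:
                raise ValidationError(
                    f"ki_um must be > 0, got {self.ki_um} for "
                    f"{self.compound_id}->{self.protein_id}"
                )
        elif self.ki_um is not None:
            raise ValidationError(
                f"ki_um only allowed on docking predictions "
                f"({self.compound_id}->{self.protein_id}, source={self.source})"
            )


@dataclass(frozen=True)
class DockingRecord:
    """One reverse/forward docking outcome: interaction energy and Ki (μM)."""

    compound_id: str
    protein_id: str
    docking_score: float
    ki_um: float

    def __post_init__(self) -> None:
        if not self.ki_um > 0:
            raise ValidationError(
                f"ki_um must be > 0, got {self.ki_um} for "
                f"{self.compound_id}->{self.protein_id}"
            )


@dataclass(frozen=True)
class TargetProfile:
    """Annotated predicted-binding-protein set of a candidate.

    The annotation subsets (cancer / AML / hub proteins) are stored as id
    sets rather than bare counts so that profiles of mixture constituents
    can be unioned without re-consulting the protein universe. The counts
    the scoring formulas use are derived properties:

    * ``ac`` — number of cancer-related proteins,
    * ``am`` — number of AML-related proteins,
    * ``ah`` — number of hub proteins,
    * ``n_noncancer`` — proteins not cancer-related,
    * ``n_total`` — profile size.

    ``ac + n_noncancer == n_total`` holds by construction. AML and hub flags
    are taken as supplied; no containment among the subsets is assumed.
    """

    owner: Owner
    proteins: frozenset[str]
    cancer_proteins: frozenset[str] = frozenset()
    aml_proteins: frozenset[str] = frozenset()
    hub_proteins: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "owner", make_owner(self.owner))
        for attr in ("proteins", "cancer_proteins", "aml_proteins", "hub_proteins"):
            object.__setattr__(self, attr, frozenset(getattr(self, attr)))
        for attr in ("cancer_proteins", "aml_proteins", "hub_proteins"):
            extra = getattr(self, attr) - self.proteins
            if extra:
                raise ValidationError(
                    f"{attr} not a subset of proteins: {sorted(extra)[:5]}"
                )

    @property
    def ac(self) -> int:
        return len(self.cancer_proteins)

    @property
    def am(self) -> int:
        return len(self.aml_proteins)

    @property
    def ah(self) -> int:
        return len(self.hub_proteins)

    @property
    def n_total(self) -> int:
        return len(self.proteins)

    @property
    def n_noncancer(self) -> int:
        return self.n_total - self.ac

    @classmethod
    def from_proteins(
        cls,
        owner: Iterable[str],
        protein_ids: Iterable[str],
        universe: Mapping[str, TargetProtein],
    ) -> "TargetProfile":
        """Annotate a protein-id set against a universe of TargetProteins."""
        ids = frozenset(protein_ids)
        unknown = [p for p in ids if p not in universe]
        if unknown:
            raise ValidationError(
                f"prediction references unknown protein id(s): {sorted(unknown)[:5]}"
            )
        return cls(
            owner=make_owner(owner),
            proteins=ids,
            cancer_proteins=frozenset(p for p in ids if universe[p].is_cancer),
            aml_proteins=frozenset(p for p in ids if universe[p].is_aml),
            hub_proteins=frozenset(p for p in ids if universe[p].is_hub),
        )


def merge_profiles(profiles: Sequence[TargetProfile]) -> TargetProfile:
    """Union the member profiles of a mixture (shared proteins counted once)."""
    if not 1 <= len(profiles) <= 3:
        raise UnsupportedArityError(
            f"mixtures have 1-3 constituents, got {len(profiles)}"
        )
    members: list[str] = []
    for p in profiles:
        members.extend(p.owner)
    return TargetProfile(
        owner=make_owner(members),
        proteins=frozenset().union(*(p.proteins for p in profiles)),
        cancer_proteins=frozenset().union(*(p.cancer_proteins for p in profiles)),
        aml_proteins=frozenset().union(*(p.aml_proteins for p in profiles)),
        hub_proteins=frozenset().union(*(p.hub_proteins for p in profiles)),
    )


@dataclass(frozen=True)
class ScoringWeights:
    """Category weights of the composite scores.

    Defaults are the published weighting: cancer-only targets 0.2, AML
    targets 0.4, hub targets 0.3, a 0.1 penalty per target shared between
    mixture constituents, and a 0.6/0.4 blend of Cscore and Dscore. N is the
    number of proteins in the forward-docking panel (default 59);
    ``dscore_divisor_mode`` selects whether Dscore divides by N or N−1.
    """

    w_cancer: float = 0.2
    w_aml: float = 0.4
    w_hub: float = 0.3
    w_comm: float = 0.1
    w_cscore: float = 0.6
    w_dscore: float = 0.4
    n_forward: int = 59
    dscore_divisor_mode: str = "n"

    def __post_init__(self) -> None:
        for attr in ("w_cancer", "w_aml", "w_hub", "w_comm", "w_cscore", "w_dscore"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be >= 0")
        if self.n_forward < 2:
            raise ValidationError("n_forward must be >= 2")
        if self.dscore_divisor_mode not in ("n", "n_minus_1"):
            raise ValidationError(
                "dscore_divisor_mode must be 'n' or 'n_minus_1', "
                f"got {self.dscore_divisor_mode!r}"
            )

    @property
    def dscore_divisor(self) -> int:
        return self.n_forward if self.dscore_divisor_mode == "n" else self.n_forward - 1


@dataclass(frozen=True)
class ScoreRecord:
    """Cscore / Dscore / Combiscore of one candidate, with audit counts."""

    owner: Owner
    cscore: float
    dscore: float
    combiscore: float
    comm: int
    sp: float
    detail: Optional[Mapping[str, int]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "owner", make_owner(self.owner))
        if self.comm < 0:
            raise ValidationError("comm must be >= 0")

    @property
    def label(self) -> str:
        return owner_label(self.owner)


@dataclass(frozen=True)
class TierResult:
    """One selection tier: scored candidates, the threshold, the survivors.

    ``selected`` is exactly the set of owners whose Combiscore is greater
    than or equal to ``threshold`` (inclusive), sorted descending by
    Combiscore then lexicographically.
    """

    tier: str
    scored: Tuple[ScoreRecord, ...]
    mean_combiscore: float
    threshold: float
    selected: Tuple[Owner, ...]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"tier must be one of {TIERS}, got {self.tier!r}")
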