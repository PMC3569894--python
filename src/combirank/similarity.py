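"""Functional-group similarity and threshold clustering.

The similarity threshold (ST) between two molecules is the number of
functional groups present in both, divided by the larger distinct-group
count of the two — a presence/absence statistic over a flat group
vocabulary, in [0, 1].

Clusters form by single-link closure of the pairwise rule "ST satisfies the
threshold". The published rule groups molecules when ST ≤ 0.7 — i.e. at LOW
similarity, which is unusual for a quantity called similarity — and is
implemented exactly as stated, with the comparison direction configurable
(``le``, the default, or ``ge``) for users who want conventional
similarity clustering. After cluster formation, any cluster whose member
set is a subset of (or equal to) another's is absorbed into it.

Clustering is a standalone descriptive stage: its output characterises the
compound set but does not enter the scoring formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .datamodel import CompoundRecord
from .errors import ConfigurationError, UndefinedSimilarityError, ValidationError


@dataclass(frozen=True)
class SimilarityConfig:
    st_threshold: float = 0.7
    direction: str = "le"  # cluster when ST <= threshold (as published) or >=

    def __post_init__(self) -> None:
        if not 0.0 <= self.st_threshold <= 1.0:
            raise ConfigurationError(
                f"st_threshold must be in [0,1], got {self.st_threshold}"
            )
        if self.direction not in ("le", "ge"):
            raise ConfigurationError(
                f"direction must be 'le' or 'ge', got {self.direction!r}"
            )

    def satisfied(self, st: float) -> bool:
        return st <= self.st_threshold if self.direction == "le" else st >= self.st_threshold


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("cluster members must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class ClusteringResult:
    clusters: List[Cluster]
    excluded: List[str] = field(default_factory=list)  # empty-fingerprint compounds
    st_matrix: Dict[Tuple[str, str], float] = field(default_factory=dict)


def similarity_threshold(a: CompoundRecord, b: CompoundRecord) -> float:
    """ST = |groups(a) ∩ groups(b)| / max(|groups(a)|, |groups(b)|)."""
    if not a.functional_groups or not b.functional_groups:
        empty = a.compound_id if not a.functional_groups else b.compound_id
        raise UndefinedSimilarityError(
            f"similarity undefined: compound {empty!r} has no functional groups"
        )
    common = len(a.functional_groups & b.functional_groups)
    return common / max(len(a.functional_groups), len(b.functional_groups))


class _UnionFind:
    def __init__(self, items: Sequence[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def form_clusters(
    compounds: Sequence[CompoundRecord],
    cfg: SimilarityConfig | None = None,
) -> ClusteringResult:
    """Partition compounds by single-link closure of the ST rule.

    Compounds with an empty fingerprint have undefined similarity; they are
    excluded from clustering and reported in ``ClusteringResult.excluded``
    rather than silently grouped.
    """
    if not compounds:
        raise ValidationError("form_clusters requires at least one compound")
    cfg = cfg or SimilarityConfig()
    usable = [c for c in compounds if c.functional_groups]
    excluded = sorted(c.compound_id for c in compounds if not c.functional_groups)

    uf = _UnionFind([c.compound_id for c in usable])
    st_matrix: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            st = similarity_threshold(a, b)
            key = tuple(sorted((a.compound_id, b.compound_id)))
            st_matrix[key] = st  # type: ignore[index]
            if cfg.satisfied(st):
                uf.union(a.compound_id, b.compound_id)

    groups: Dict[str, set] = {}
    for c in usable:
        groups.setdefault(uf.find(c.compound_id), set()).add(c.compound_id)
    clusters = sorted(
        (Cluster(frozenset(m)) for m in groups.values()),
        key=lambda cl: sorted(cl.members),
    )
    return ClusteringResult(clusters=clusters, excluded=excluded, st_matrix=st_matrix)


def merge_clusters(clusters: Sequence[Cluster]) -> List[Cluster]:
    """Absorb any cluster whose members are a subset of another's.

    Applied to a fixpoint; keeping only the maximal member sets (after
    deduplication) reaches it in one pass, and the result is independent of
    input order. Idempotent.
    """
    unique = sorted({c.members for c in clusters}, key=lambda m: (-len(m), sorted(m)))
    kept: List[frozenset] = []
    for members in unique:
        if not any(members <= other for other in kept):
            kept.append(members)
    return sorted((Cluster(m) for m in kept), key=lambda cl: sorted(cl.members))
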