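"""Pathway overrepresentation by one-sided Fisher's exact test.

For a candidate's predicted-binding-protein set of size n drawn from a
background universe of size M, a pathway with K members and k overlapping
targets is scored with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(M, K, n)

(the one-sided Fisher's exact test for overrepresentation; depletion is
deliberately not tested). Raw p-values are always reported; a
Benjamini–Hochberg adjustment across the tested pathways accompanies them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datamodel import TargetProfile, TargetProtein
from .errors import ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    k: int  # overlap: pathway members in the target set
    K: int  # pathway size within the background
    n: int  # target-set size
    M: int  # background size
    p_value: float
    adjusted_p: float


def fisher_overrepresentation(
    target_set: Iterable[str],
    pathway_memberships: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> List[EnrichmentResult]:
    """One-sided overrepresentation p-value per pathway, BH-adjusted.

    Results are sorted ascending by raw p-value (ties broken by pathway
    id). An empty target set gives p = 1 for every pathway.
    """
    background = frozenset(background)
    targets = frozenset(target_set)
    outside = sorted(targets - background)
    if outside:
        raise ValidationError(
            f"target protein(s) outside background: {outside[:5]}"
        )
    M, n = len(background), len(targets)
    rows: List[EnrichmentResult] = []
    raw: List[float] = []
    for pathway_id in sorted(pathway_memberships):
        members = frozenset(pathway_memberships[pathway_id])
        stray = sorted(members - background)
        if stray:
            raise ValidationError(
                f"pathway {pathway_id!r} member(s) outside background: {stray[:5]}"
            )
        K = len(members)
        k = len(members & targets)
        # Upper tail P(X >= k); sf is exclusive, hence k-1.
        p = float(hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        raw.append(p)
        rows.append(EnrichmentResult(pathway_id, k, K, n, M, p, p))
    if rows:
        adjusted = multipletests(raw, method="fdr_bh")[1]
        rows = [
            EnrichmentResult(r.pathway_id, r.k, r.K, r.n, r.M, r.p_value,
                             float(max(adj, r.p_value)))
            for r, adj in zip(rows, adjusted)
        ]
    return sorted(rows, key=lambda r: (r.p_value, r.pathway_id))


def pathway_memberships_from_universe(
    universe: Iterable[TargetProtein],
) -> Dict[str, set]:
    """Invert the per-protein pathway annotation into pathway → members."""
    memberships: Dict[str, set] = {}
    for protein in universe:
        for pw in protein.pathways:
            memberships.setdefault(pw, set()).add(protein.protein_id)
    return memberships


def enrich_candidates(
    profiles: Sequence[TargetProfile],
    pathway_memberships: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> Dict[str, List[EnrichmentResult]]:
    """Run the overrepresentation test on each candidate profile.

    Returns a mapping from the candidate's "+"-joined identifier to its
    sorted enrichment table. With no pathways supplied, every report is
    empty (the condition is reported by the caller, not an error).
    """
    background = frozenset(background)
    out: Dict[str, List[EnrichmentResult]] = {}
    for profile in profiles:
        key = "+".join(profile.owner)
        out[key] = fisher_overrepresentation(
            profile.proteins, pathway_memberships, background
        )
    return out
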