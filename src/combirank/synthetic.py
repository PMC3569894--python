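"""Synthetic datasets with the statistical structure the ranking assumes.

The real analysis drew on proprietary knowledgebases (curated
literature/bioassay target predictions), a ~1,100-structure docking
database, and hub annotations derived from leukemia expression data. None
of those are redistributable, so this module generates datasets that mimic
their *shape*: a small panel of natural products with functional-group
fingerprints, a protein universe with configurable cancer / AML / hub
annotation fractions and pathway memberships, per-compound prediction sets
with a tunable inter-compound overlap, and docking tables whose Ki values
are log-uniform around the 10 μM screening cutoff.

All generators are pure functions of their configuration: one global
integer seed, with an independent deterministic sub-stream per generator,
so regenerating any one table never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .datamodel import (
    CompoundRecord,
    DockingRecord,
    TargetPrediction,
    TargetProtein,
)
from .errors import ConfigurationError, ValidationError
from .screen import ScreenConfig

# ΔG ≈ RT·ln(Ki), RT ≈ 0.593 kcal/mol at 298 K; Ki converted from μM to M.
_RT_KCAL = 0.593

_GROUP_VOCAB_STEMS = (
    "hydroxyl", "phenyl", "ketone", "ester", "amine", "carboxyl", "methoxy",
    "aldehyde", "lactone", "glycoside", "isoprenyl", "quinone", "furan",
    "thiol", "amide", "nitro", "halogen", "sulfonyl", "epoxide", "alkene",
    "alkyne", "ether", "imine", "pyridyl", "indole", "chromene",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Shapes of the generated tables; the seed fixes all randomness."""

    n_compounds: int = 13
    n_groups_vocab: int = 24
    groups_per_compound: Tuple[int, int] = (3, 8)
    n_proteins: int = 800
    frac_cancer: float = 0.3
    frac_aml_given_cancer: float = 0.4
    frac_hub: float = 0.1
    targets_per_compound: Tuple[int, int] = (20, 50)
    overlap_rate: float = 0.3
    ki_log10_range: Tuple[float, float] = (-2.0, 2.0)
    n_pathways: int = 25
    pathway_size_range: Tuple[int, int] = (10, 40)
    seed: int = 0
    # Extra shape knobs for the prediction/docking generators.
    shared_pool_size: Optional[int] = None
    docking_per_compound: Tuple[int, int] = (10, 30)
    confidence_probs: Tuple[float, float, float] = (0.25, 0.15, 0.60)
    p_knowledgebase: float = 0.73
    n_forward: int = 59

    def __post_init__(self) -> None:
        for attr in ("frac_cancer", "frac_aml_given_cancer", "frac_hub",
                     "overlap_rate", "p_knowledgebase"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{attr} must be in [0,1], got {v}")
        for attr in ("groups_per_compound", "targets_per_compound",
                     "pathway_size_range", "docking_per_compound"):
            lo, hi = getattr(self, attr)
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{attr} range ({lo},{hi}) is empty")
        if self.n_compounds < 1 or self.n_proteins < 1:
            raise ConfigurationError("need at least one compound and one protein")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9:
            raise ConfigurationError("confidence_probs must sum to 1")

    @property
    def effective_shared_pool(self) -> int:
        if self.shared_pool_size is not None:
            return self.shared_pool_size
        return min(100, max(1, self.n_proteins // 4))


@dataclass
class Dataset:
    """One complete synthetic study: the four tables plus the forward panel."""

    compounds: List[CompoundRecord]
    universe: List[TargetProtein]
    predictions: List[TargetPrediction]
    docking: List[DockingRecord]
    forward_protein_set: frozenset[str] = frozenset()
    config: Optional[SimulationConfig] = None

    @property
    def universe_map(self) -> Dict[str, TargetProtein]:
        return {p.protein_id: p for p in self.universe}

    def screen_config(self, **kwargs) -> ScreenConfig:
        kwargs.setdefault("forward_protein_set", self.forward_protein_set)
        return ScreenConfig(**kwargs)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent deterministic sub-stream per generator.
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _vocab(cfg: SimulationConfig) -> List[str]:
    stems = list(_GROUP_VOCAB_STEMS)
    vocab = [stems[i % len(stems)] + ("" if i < len(stems) else f"_{i // len(stems)}")
             for i in range(cfg.n_groups_vocab)]
    return vocab


def gen_compounds(cfg: SimulationConfig) -> List[CompoundRecord]:
    """Compound panel with random functional-group fingerprints."""
    rng = _rng(cfg, 1)
    vocab = np.array(_vocab(cfg))
    lo, hi = cfg.groups_per_compound
    out = []
    for i in range(cfg.n_compounds):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(vocab))
        groups = rng.choice(vocab, size=k, replace=False) if k else []
        out.append(
            CompoundRecord(
                compound_id=f"C{i + 1:02d}",
                name=f"compound-{i + 1:02d}",
                functional_groups=frozenset(map(str, groups)),
            )
        )
    return out


def gen_protein_universe(cfg: SimulationConfig) -> List[TargetProtein]:
    """Protein universe with cancer/AML/hub flags and pathway memberships.

    AML flags are drawn only among cancer-flagged proteins (biologically
    coherent default); hub flags are independent of both.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_proteins
    is_cancer = rng.random(n) < cfg.frac_cancer
    is_aml = is_cancer & (rng.random(n) < cfg.frac_aml_given_cancer)
    is_hub = rng.random(n) < cfg.frac_hub
    pathways: List[set] = [set() for _ in range(n)]
    lo, hi = cfg.pathway_size_range
    for p in range(cfg.n_pathways):
        size = min(int(rng.integers(lo, hi + 1)), n)
        members = rng.choice(n, size=size, replace=False)
        for m in members:
            pathways[int(m)].add(f"pw{p + 1:02d}")
    return [
        TargetProtein(
            protein_id=f"P{i + 1:04d}",
            name=f"protein-{i + 1:04d}",
            is_cancer=bool(is_cancer[i]),
            is_aml=bool(is_aml[i]),
            is_hub=bool(is_hub[i]),
            pathways=frozenset(pathways[i]),
        )
        for i in range(n)
    ]


def gen_predictions(
    compounds: Sequence[CompoundRecord],
    universe: Sequence[TargetProtein],
    cfg: SimulationConfig,
) -> List[TargetPrediction]:
    """Knowledgebase/bioassay prediction table with controlled overlap.

    Each target draw comes from a shared pool with probability
    ``overlap_rate`` (creating inter-compound overlap) and otherwise from a
    per-compound private pool; private pools are disjoint across compounds,
    so ``overlap_rate = 0`` yields pairwise-disjoint prediction sets.
    """
    if not universe:
        raise ConfigurationError("protein universe is empty")
    rng = _rng(cfg, 2)
    ids = [p.protein_id for p in universe]
    n_shared = min(cfg.effective_shared_pool, len(ids))
    shared = ids[:n_shared]
    remaining = list(rng.permutation(ids[n_shared:]))
    n_cpd = len(compounds)
    chunk = len(remaining) // n_cpd if n_cpd else 0
    private = {
        c.compound_id: remaining[i * chunk : (i + 1) * chunk]
        for i, c in enumerate(compounds)
    }
    lo, hi = cfg.targets_per_compound
    if hi > 0 and chunk < hi and cfg.overlap_rate < 1.0:
        raise ConfigurationError(
            f"private pools too small ({chunk} per compound) for up to {hi} "
            "targets; raise n_proteins or lower targets_per_compound"
        )
    out: List[TargetPrediction] = []
    confidences = np.array(["high", "medium", "low"])
    for c in compounds:
        n_t = int(rng.integers(lo, hi + 1))
        k_shared = min(int(rng.binomial(n_t, cfg.overlap_rate)), len(shared))
        k_private = min(n_t - k_shared, len(private[c.compound_id]))
        chosen = list(rng.choice(shared, size=k_shared, replace=False)) if k_shared else []
        if k_private:
            chosen += list(
                rng.choice(private[c.compound_id], size=k_private, replace=False)
            )
        for pid in chosen:
            source = "knowledgebase" if rng.random() < cfg.p_knowledgebase else "bioassay"
            conf = str(rng.choice(confidences, p=cfg.confidence_probs))
            out.append(
                TargetPrediction(
                    compound_id=c.compound_id,
                    protein_id=str(pid),
                    source=source,
                    confidence=conf,
                )
            )
    return out


def _docking_score_from_ki(ki_um: float, noise: float) -> float:
    # Binding free energy proxy: RT·ln(Ki in M) plus docking noise; lower
    # (more negative) score = tighter binding, monotone in −log10(Ki).
    return _RT_KCAL * math.log(ki_um * 1e-6) + noise


def gen_docking(
    compounds: Sequence[CompoundRecord],
    universe: Sequence[TargetProtein],
    cfg: SimulationConfig,
) -> List[DockingRecord]:
    """Docking table with log-uniform Ki over ``ki_log10_range`` (μM)."""
    if not universe:
        raise ConfigurationError("protein universe is empty")
    rng = _rng(cfg, 3)
    ids = np.array([p.protein_id for p in universe])
    lo, hi = cfg.docking_per_compound
    klo, khi = cfg.ki_log10_range
    out: List[DockingRecord] = []
    for c in compounds:
        n_d = min(int(rng.integers(lo, hi + 1)), len(ids))
        if n_d == 0:
            continue
        chosen = rng.choice(ids, size=n_d, replace=False)
        kis = 10.0 ** rng.uniform(klo, khi, size=n_d)
        noise = rng.normal(0.0, 0.5, size=n_d)
        for pid, ki, nz in zip(chosen, kis, noise):
            out.append(
                DockingRecord(
                    compound_id=c.compound_id,
                    protein_id=str(pid),
                    docking_score=_docking_score_from_ki(float(ki), float(nz)),
                    ki_um=float(ki),
                )
            )
    return out


def _forward_panel(
    docking: Sequence[DockingRecord],
    universe: Sequence[TargetProtein],
    cfg: SimulationConfig,
) -> frozenset[str]:
    # Panel mirrors the study design: docked proteins first (most-hit first),
    # padded deterministically from the rest of the universe up to n_forward.
    hits: Dict[str, int] = {}
    for r in docking:
        hits[r.protein_id] = hits.get(r.protein_id, 0) + 1
    ranked = sorted(hits, key=lambda p: (-hits[p], p))
    panel = ranked[: cfg.n_forward]
    if len(panel) < cfg.n_forward:
        for p in universe:
            if p.protein_id not in hits:
                panel.append(p.protein_id)
            if len(panel) == cfg.n_forward:
                break
    return frozenset(panel)


def gen_dataset(cfg: SimulationConfig) -> Dataset:
    """Generate one complete coherent dataset from a single seed."""
    compounds = gen_compounds(cfg)
    universe = gen_protein_universe(cfg)
    predictions = gen_predictions(compounds, universe, cfg)
    docking = gen_docking(compounds, universe, cfg)
    return Dataset(
        compounds=compounds,
        universe=universe,
        predictions=predictions,
        docking=docking,
        forward_protein_set=_forward_panel(docking, universe, cfg),
        config=cfg,
    )


def gen_scenario_planted(
    cfg: SimulationConfig,
    planted_compound: Union[str, Sequence[str]],
    extra_aml: int = 10,
    extra_hub: int = 6,
) -> Dataset:
    """Dataset with a known answer planted for parameter-recovery tests.

    The planted compound(s) receive ``extra_aml`` additional AML-related
    cancer targets and ``extra_hub`` additional cancer hub targets that no
    other compound binds — both as high-confidence knowledgebase predictions
    and as sub-μM docking hits inside the forward panel — so their profiles
    strictly dominate all others in Am and Ah. Compounds planted with the
    same boost share the same boost proteins.
    """
    planted = [planted_compound] if isinstance(planted_compound, str) else list(planted_compound)
    base = gen_dataset(cfg)
    known = {c.compound_id for c in base.compounds}
    missing = [p for p in planted if p not in known]
    if missing:
        raise ValidationError(f"planted compound(s) not in dataset: {missing}")

    boost: List[TargetProtein] = []
    for i in range(extra_aml):
        boost.append(
            TargetProtein(
                protein_id=f"PBAML{i + 1:03d}",
                name=f"planted-aml-target-{i + 1}",
                is_cancer=True,
                is_aml=True,
                is_hub=False,
            )
        )
    for i in range(extra_hub):
        boost.append(
            TargetProtein(
                protein_id=f"PBHUB{i + 1:03d}",
                name=f"planted-hub-target-{i + 1}",
                is_cancer=True,
                is_aml=False,
                is_hub=True,
            )
        )

    predictions = list(base.predictions)
    docking = list(base.docking)
    for cid in planted:
        for prot in boost:
            predictions.append(
                TargetPrediction(
                    compound_id=cid,
                    protein_id=prot.protein_id,
                    source="knowledgebase",
                    confidence="high",
                )
            )
            docking.append(
                DockingRecord(
                    compound_id=cid,
                    protein_id=prot.protein_id,
                    docking_score=_docking_score_from_ki(1.0, 0.0),
                    ki_um=1.0,
                )
            )
    return Dataset(
        compounds=base.compounds,
        universe=base.universe + boost,
        predictions=predictions,
        docking=docking,
        forward_protein_set=base.forward_protein_set
        | frozenset(p.protein_id for p in boost),
        config=cfg,
    )
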