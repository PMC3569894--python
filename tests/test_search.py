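"""Candidate enumeration, inclusive mean-threshold selection, tiered search."""

from __future__ import annotations

from itertools import combinations

import pytest

from combirank.datamodel import (
    ScoreRecord,
    ScoringWeights,
    TargetPrediction,
    TargetProtein,
)
from combirank.errors import ConfigurationError, ValidationError
from combirank.search import (
    SearchConfig,
    enumerate_candidates,
    run_search,
    select_tier,
)
from combirank.synthetic import Dataset, SimulationConfig, gen_scenario_planted


def score_rec(owner, combiscore):
    return ScoreRecord(owner=owner, cscore=combiscore, dscore=0.0,
                       combiscore=combiscore, comm=0, sp=0.0)


class TestEnumeration:
    def test_thirteen_compounds_give_published_counts(self):
        ids = [f"c{i:02d}" for i in range(13)]
        assert len(enumerate_candidates(ids, 2)) == 78
        assert len(enumerate_candidates(ids, 3)) == 286

    def test_matches_brute_force_subsets(self):
        for n in range(1, 8):
            ids = [f"c{i}" for i in range(n)]
            for k in (1, 2, 3):
                expected = sorted(tuple(sorted(s)) for s in combinations(ids, k))
                got = enumerate_candidates(ids, k)
                assert got == expected
                assert len(set(got)) == len(got)

    def test_two_compounds_one_pair(self):
        assert enumerate_candidates(["a", "b"], 2) == [("a", "b")]

    def test_k_above_n_is_empty(self):
        assert enumerate_candidates(["a", "b"], 3) == []

    def test_contains_selected_member_constraint(self):
        ids = ["a", "b", "c", "d"]
        selected = [("a",)]
        pairs = enumerate_candidates(ids, 2, "contains_selected_member", selected)
        assert pairs == [("a", "b"), ("a", "c"), ("a", "d")]

    def test_all_members_selected_constraint(self):
        ids = ["a", "b", "c", "d"]
        selected = [("a",), ("b",)]
        pairs = enumerate_candidates(ids, 2, "all_members_selected", selected)
        assert pairs == [("a", "b")]


class TestSelectTier:
    def test_inclusive_mean_rule(self):
        scored = [score_rec(("a",), 2.0), score_rec(("b",), 1.0), score_rec(("c",), 0.0)]
        tier = select_tier(scored, tier="singlet")
        assert tier.mean_combiscore == pytest.approx(1.0)
        assert tier.selected == (("a",), ("b",))  # 1.0 == mean is kept

    def test_all_equal_all_selected(self):
        scored = [score_rec((c,), 3.0) for c in "abc"]
        tier = select_tier(scored, tier="singlet")
        assert len(tier.selected) == 3

    def test_single_candidate_selected(self):
        tier = select_tier([score_rec(("a",), -2.0)], tier="singlet")
        assert tier.selected == (("a",),)

    def test_empty_tier_is_an_error(self):
        with pytest.raises(ValidationError):
            select_tier([], tier="singlet")

    def test_order_invariance(self):
        scored = [score_rec((c,), s) for c, s in zip("abcd", (0.5, 2.0, 2.0, -1.0))]
        forward = select_tier(scored, tier="singlet")
        backward = select_tier(list(reversed(scored)), tier="singlet")
        assert forward == backward

    def test_fixed_threshold_mode(self):
        cfg = SearchConfig(threshold_mode="fixed", fixed_thresholds=(1.5,))
        scored = [score_rec(("a",), 2.0), score_rec(("b",), 1.0)]
        tier = select_tier(scored, cfg, "singlet")
        assert tier.threshold == 1.5
        assert tier.selected == (("a",),)

    def test_config_contract(self):
        with pytest.raises(ConfigurationError):
            SearchConfig(threshold_mode="fixed")
        with pytest.raises(ConfigurationError):
            SearchConfig(threshold_mode="mean", fixed_thresholds=(1.0,))


def constructed_dataset(target_map, universe):
    """Dataset with hand-assigned knowledgebase targets and no docking."""
    from combirank.datamodel import CompoundRecord

    compounds = [CompoundRecord(c, c, frozenset({"hydroxyl"})) for c in target_map]
    predictions = [
        TargetPrediction(cid, pid, "knowledgebase", "high")
        for cid, pids in target_map.items()
        for pid in pids
    ]
    return Dataset(
        compounds=compounds,
        universe=list(universe.values()),
        predictions=predictions,
        docking=[],
        forward_protein_set=frozenset(universe),
    )


class TestRunSearch:
    def test_max_arity_two_gives_two_tiers(self):
        cfg = SimulationConfig(n_compounds=4, n_proteins=120, shared_pool_size=20,
                               targets_per_compound=(5, 10),
                               docking_per_compound=(3, 6), seed=1)
        ds = gen_scenario_planted(cfg, "C02")
        tiers = run_search(ds, search_cfg=SearchConfig(max_arity=2))
        assert [t.tier for t in tiers] == ["singlet", "pair"]

    def test_planted_compound_tops_singlets_and_joins_top_pair_and_triple(self):
        cfg = SimulationConfig(n_compounds=6, n_proteins=300, shared_pool_size=30,
                               targets_per_compound=(8, 15),
                               docking_per_compound=(5, 10), seed=2)
        tiers = run_search(gen_scenario_planted(cfg, "C04"))
        assert tiers[0].scored[0].owner == ("C04",)
        assert "C04" in tiers[1].scored[0].owner
        assert "C04" in tiers[2].scored[0].owner

    def test_selected_pairs_share_a_member_with_selected_singlets(self):
        cfg = SimulationConfig(n_compounds=8, n_proteins=400, shared_pool_size=40,
                               targets_per_compound=(8, 15),
                               docking_per_compound=(5, 10), seed=3)
        tiers = run_search(gen_scenario_planted(cfg, "C01"))
        singlet_members = {c for owner in tiers[0].selected for c in owner}
        for owner in tiers[1].selected:
            assert singlet_members.intersection(owner)

    def test_degenerate_cascade_under_strict_seeding(self):
        # one dominant compound; under all_members_selected pairs need two
        # selected singlets, so tiers 2-3 can come up empty without error
        universe = {
            "pA": TargetProtein("pA", "pA", is_cancer=True, is_aml=True),
            "pB": TargetProtein("pB", "pB"),  # non-cancer: drags b's sp to -1
        }
        ds = constructed_dataset(
            {"a": ["pA"], "b": ["pB"], "c": [], "d": []}, universe
        )
        tiers = run_search(
            ds, search_cfg=SearchConfig(seed_constraint="all_members_selected")
        )
        assert len(tiers) == 3
        assert tiers[0].selected == (("a",),)
        assert tiers[1].scored == () and tiers[1].selected == ()
        assert tiers[2].scored == ()

    def test_weak_singlet_can_surface_in_selected_pairs(self):
        # "b" misses the singlet cut but complements the dominant "a";
        # the pair a+b is selected even though b alone never was.
        universe = {}
        for i in range(30):
            pid = f"aml{i:02d}"
            universe[pid] = TargetProtein(pid, pid, is_cancer=True, is_aml=True)
        for i in range(6):
            pid = f"can{i:02d}"
            universe[pid] = TargetProtein(pid, pid, is_cancer=True)
        target_map = {
            "a": [p for p in universe if p.startswith("aml")],
            "b": ["can00", "can01", "can02", "can03", "can04", "can05"],
            "c": ["can00", "can01"],
            "d": ["can02", "can03"],
        }
        tiers = run_search(constructed_dataset(target_map, universe))
        assert ("b",) not in tiers[0].selected
        assert ("a", "b") in tiers[1].selected

    def test_deterministic_rank_order_under_same_seed(self):
        cfg = SimulationConfig(n_compounds=5, n_proteins=150, shared_pool_size=20,
                               targets_per_compound=(5, 10),
                               docking_per_compound=(3, 6), seed=13)
        from combirank.synthetic import gen_dataset

        t1 = run_search(gen_dataset(cfg))
        t2 = run_search(gen_dataset(cfg))
        assert [r.owner for r in t1[0].scored] == [r.owner for r in t2[0].scored]
        assert t1 == t2
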