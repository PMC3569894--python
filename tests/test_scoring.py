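"""The scoring core: sp, comm, Cscore, Dscore, Combiscore, divisor check."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combirank.datamodel import ScoringWeights, TargetProfile, TargetProtein
from combirank.errors import ConfigurationError, UnsupportedArityError
from combirank.fixtures import load_table3_fixture
from combirank.scoring import (
    combiscore,
    common_targets,
    cscore,
    dscore,
    score_candidate,
    select_divisor_mode,
    specificity,
)
from tests.conftest import make_universe, profile_with_counts


def profile_from(owner, ids, universe):
    return TargetProfile.from_proteins(owner, ids, universe)


class TestSpecificity:
    def test_hand_value(self):
        # 12 cancer of 20 targets: (12 - 8) / 20 = 0.2
        profile = profile_with_counts(("c1",), ac=12, n_plain=8)
        assert specificity(profile) == pytest.approx(0.2)

    def test_all_cancer_is_one(self):
        assert specificity(profile_with_counts(("c1",), ac=4)) == 1.0

    def test_empty_profile_is_zero(self):
        empty = TargetProfile(("c1",), frozenset())
        assert specificity(empty) == 0.0

    @given(ac=st.integers(0, 30), plain=st.integers(0, 30))
    @settings(derandomize=True, max_examples=100)
    def test_bounded(self, ac, plain):
        profile = profile_with_counts(("c1",), ac=ac, n_plain=plain)
        if profile.n_total:
            assert -1.0 <= specificity(profile) <= 1.0


class TestCommonTargets:
    def test_singlet_has_none(self):
        assert common_targets([profile_with_counts(("c1",), ac=3)]) == 0

    def test_pairwise_overlap_hand_count(self):
        universe = make_universe(n_plain=4)
        p1, p2, p3, p4 = sorted(universe)
        a = profile_from(("c1",), {p1, p2, p3}, universe)
        b = profile_from(("c2",), {p2, p3, p4}, universe)
        assert common_targets([a, b]) == 2

    def test_triple_sharing_one_protein(self):
        universe = make_universe(n_plain=7)
        ids = sorted(universe)
        shared = ids[0]
        members = [
            profile_from((f"c{i+1}",), {shared, ids[1 + 2 * i], ids[2 + 2 * i]}, universe)
            for i in range(3)
        ]
        assert common_targets(members) == 1

    def test_arity_above_three_rejected(self):
        profiles = [profile_with_counts((f"c{i}",), ac=1, prefix=f"Q{i}") for i in range(4)]
        with pytest.raises(UnsupportedArityError):
            common_targets(profiles)


class TestCscore:
    def test_hand_arithmetic(self):
        # Ac=12, Am=4, Ah=2: 0.2*(12-6) + 0.4*4 + 0.3*2 + sp(0.2) = 3.6
        profile = profile_with_counts(("c1",), ac=8, am=4, ah=2, n_plain=6)
        assert (profile.ac, profile.am, profile.ah) == (12, 4, 2)
        assert cscore(profile, comm=0, sp=0.2) == pytest.approx(3.6)

    def test_all_zero_counts(self):
        assert cscore(TargetProfile(("c1",), frozenset()), 0, 0.0) == 0.0

    def test_negative_residual_case(self):
        # Ac=3 all AML: 0.2*(3-3) + 0.4*3 = 1.2 ... but spec case Ac=0:
        # hand value 0.2*(0-3) + 1.2 = 0.6 requires Am not subset of Ac.
        universe = {
            f"p{i}": TargetProtein(f"p{i}", f"p{i}", is_cancer=False, is_aml=True)
            for i in range(3)
        }
        profile = TargetProfile.from_proteins(("c1",), set(universe), universe)
        assert (profile.ac, profile.am) == (0, 3)
        assert cscore(profile, comm=0, sp=0.0) == pytest.approx(0.6)

    def test_monotone_steps_in_am_and_comm(self):
        base = profile_with_counts(("c1",), ac=5, am=2, ah=1, n_plain=2)
        up = profile_with_counts(("c1",), ac=4, am=3, ah=1, n_plain=2)
        # +1 Am at fixed Ac: cscore rises by w_aml - w_cancer = 0.2
        assert cscore(up, 0, 0.0) - cscore(base, 0, 0.0) == pytest.approx(0.2)
        assert cscore(base, 3, 0.0) - cscore(base, 2, 0.0) == pytest.approx(-0.1)

    def test_equal_weights_collapse_to_weighted_count(self):
        w = ScoringWeights(w_cancer=0.25, w_aml=0.25, w_hub=0.25, w_comm=0.0)
        profile = profile_with_counts(("c1",), ac=4, am=3, ah=2, n_plain=1)
        # residual algebra: 0.25*(Ac - Am - Ah) + 0.25*Am + 0.25*Ah = 0.25*Ac
        assert cscore(profile, comm=5, sp=0.0, weights=w) == pytest.approx(0.25 * profile.ac)


class TestDscore:
    def test_published_singlet_value_mode_n(self):
        profile = profile_with_counts(("c1",), ac=8)
        assert dscore(profile, 0, ScoringWeights(dscore_divisor_mode="n")) == pytest.approx(
            0.027118644, abs=5e-10
        )

    def test_zero_counts_zero_either_mode(self):
        empty = TargetProfile(("c1",), frozenset())
        for mode in ("n", "n_minus_1"):
            assert dscore(empty, 0, ScoringWeights(dscore_divisor_mode=mode)) == 0.0

    def test_mode_n_minus_1_differs(self):
        profile = profile_with_counts(("c1",), ac=8)
        value = dscore(profile, 0, ScoringWeights(dscore_divisor_mode="n_minus_1"))
        assert value == pytest.approx(1.6 / 58)

    def test_invariant_to_out_of_panel_proteins(self):
        # the profile builder owns the panel restriction; here the formula
        # itself must depend only on the supplied counts
        small = profile_with_counts(("c1",), ac=3, prefix="A")
        same_counts = profile_with_counts(("c1",), ac=3, prefix="B")
        assert dscore(small, 0) == dscore(same_counts, 0)


class TestCombiscore:
    @pytest.mark.parametrize(
        "c, d, expected",
        [
            (9.409090909, 0.027118644, 5.656302003),
            (0.0, 0.0, 0.0),
            (10.33333333, 2.125423729, 7.050169492),
        ],
    )
    def test_published_blends(self, c, d, expected):
        assert combiscore(c, d) == pytest.approx(expected, abs=5e-9)

    @given(c=st.floats(-100, 100), d=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=200)
    def test_exact_blend_identity(self, c, d):
        assert abs(combiscore(c, d) - (0.6 * c + 0.4 * d)) <= 1e-12


class TestScoreCandidate:
    def test_empty_profiles_score_zero(self):
        empty_kb = TargetProfile(("c1",), frozenset())
        empty_dock = TargetProfile(("c1",), frozenset())
        rec = score_candidate(("c1",), [empty_kb], [empty_dock])
        assert (rec.cscore, rec.dscore, rec.combiscore, rec.comm, rec.sp) == (0, 0, 0, 0, 0)

    def test_disjoint_pair_has_zero_comm(self):
        a = profile_with_counts(("c1",), ac=3, prefix="A")
        b = profile_with_counts(("c2",), ac=2, prefix="B")
        empty = [TargetProfile(("c1",), frozenset()), TargetProfile(("c2",), frozenset())]
        rec = score_candidate(("c1", "c2"), [a, b], empty)
        assert rec.comm == 0
        assert rec.detail["kb_n_total"] == 5

    def test_shared_targets_penalised_once_counted_once(self):
        universe = make_universe(n_cancer=4)
        ids = sorted(universe)
        a = profile_from(("c1",), ids[:3], universe)
        b = profile_from(("c2",), ids[1:], universe)
        empty = [TargetProfile(("c1",), frozenset()), TargetProfile(("c2",), frozenset())]
        rec = score_candidate(("c1", "c2"), [a, b], empty)
        assert rec.comm == 2  # ids[1], ids[2]
        assert rec.detail["kb_n_total"] == 4  # union, not 6
        # 0.2*4 - 0.1*2 + sp(1.0)
        assert rec.cscore == pytest.approx(0.2 * 4 - 0.2 + 1.0)


class TestDivisorSelection:
    def test_published_dscores_pin_divisor_to_n(self):
        singlets = [r.dscore for r in load_table3_fixture("singlet")]
        assert select_divisor_mode(singlets, n_forward=59) == "n"

    def test_n_minus_1_grid_detected(self):
        values = [1.6 / 58, 3.2 / 58, 0.3 / 58]
        assert select_divisor_mode(values, n_forward=59) == "n_minus_1"

    def test_all_zero_is_uninformative(self):
        with pytest.raises(ConfigurationError):
            select_divisor_mode([0.0, 0.0])
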