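from __future__ import annotations

import pytest

from combirank.datamodel import TargetProfile, TargetProtein


def make_universe(n_cancer=0, n_aml=0, n_hub=0, n_plain=0, prefix="P"):
    """Small labelled protein universe: AML proteins are also cancer-flagged,
    hub proteins are cancer-free, plain proteins carry no flags."""
    universe = {}
    i = 0
    for _ in range(n_cancer):
        i += 1
        pid = f"{prefix}C{i:03d}"
        universe[pid] = TargetProtein(pid, pid, is_cancer=True)
    for _ in range(n_aml):
        i += 1
        pid = f"{prefix}A{i:03d}"
        universe[pid] = TargetProtein(pid, pid, is_cancer=True, is_aml=True)
    for _ in range(n_hub):
        i += 1
        pid = f"{prefix}H{i:03d}"
        universe[pid] = TargetProtein(pid, pid, is_hub=True)
    for _ in range(n_plain):
        i += 1
        pid = f"{prefix}N{i:03d}"
        universe[pid] = TargetProtein(pid, pid)
    return universe


def profile_with_counts(owner, ac=0, am=0, ah=0, n_plain=0, prefix="P"):
    """TargetProfile with exactly the requested category counts.

    ``ac`` counts cancer-only proteins; AML proteins add to both Am and Ac;
    hub proteins here are non-cancer, so Ac(total) = ac + am.
    """
    universe = make_universe(ac, am, ah, n_plain, prefix=prefix)
    return TargetProfile.from_proteins(owner, set(universe), universe)


@pytest.fixture
def mixed_universe():
    return make_universe(n_cancer=5, n_aml=3, n_hub=2, n_plain=6)
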