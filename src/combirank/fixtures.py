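"""Packaged reference fixture: the published singlet/pair/triple score table.

The fixture ships the printed Cscore, Dscore and Combiscore for all 13
single natural products and for every printed pair and triple row. The pair
and triple tables were printed truncated (ellipsis rows), so those tiers are
flagged as incomplete; the singlet tier is complete. ``selected`` marks the
rows the source highlighted as passing that tier's threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional

import pandas as pd

#: Tier thresholds as published (mean-Combiscore cutoffs for tiers 1-3).
PUBLISHED_THRESHOLDS: Dict[str, float] = {
    "singlet": 1.36,
    "pair": 4.25,
    "triple": 6.15,
}

#: Tiers whose printed table is truncated (ellipsis rows not recoverable).
TRUNCATED_TIERS = frozenset({"pair", "triple"})


@dataclass(frozen=True)
class FixtureRow:
    table: str  # singlet | pair | triple
    owner: str  # display name, constituents "+"-joined
    cscore: float
    dscore: float
    combiscore: float
    selected: bool

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(m.strip().lower() for m in self.owner.split("+"))


def load_table3_fixture(table: Optional[str] = None) -> List[FixtureRow]:
    """Return the packaged score-table rows, optionally one tier only."""
    with resources.files("combirank.data").joinpath("table3.tsv").open("r") as fh:
        frame = pd.read_csv(fh, sep="\t")
    rows = [
        FixtureRow(
            table=r.table,
            owner=r.owner,
            cscore=float(r.cscore),
            dscore=float(r.dscore),
            combiscore=float(r.combiscore),
            selected=bool(int(r.selected)),
        )
        for r in frame.itertuples(index=False)
    ]
    if table is not None:
        rows = [r for r in rows if r.table == table]
    return rows


def fixture_row(owner: str, table: Optional[str] = None) -> FixtureRow:
    """Look up a fixture row by owner name (case-insensitive)."""
    want = owner.strip().lower()
    for row in load_table3_fixture(table):
        if row.owner.strip().lower() == want:
            return row
    raise KeyError(f"no fixture row for owner {owner!r}")
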