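"""Shared fixtures: tree/stand builders and the frozen 12-tree plot."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from standopt import Stand, Tree

# ---------------------------------------------------------------------------
# The frozen 12-tree fixture: a 10 m plot (2 m buffer) with four species,
# mixed sizes and sloping terrain.  The expected index values in
# TWELVE_TREE_EXPECTED were derived once by the independent first-principles
# implementation in tests/oracles.py (see test_indexes.py, which re-runs the
# derivation and checks the frozen numbers have not drifted).
# ---------------------------------------------------------------------------

TWELVE_TREE_ROWS = [
    # id, species, x,    y,    dbh,  height, cw,  cl,  age, rel_elev
    (1, "pinus", 0.5, 0.8, 22.0, 14.0, 4.2, 6.0, 45, 1.10),
    (2, "pinus", -3.1, 2.2, 16.5, 11.0, 3.4, 4.5, 38, 0.40),
    (3, "quercus", 2.8, -2.4, 12.0, 8.5, 2.8, 3.2, 30, 1.60),
    (4, "pinus", -1.9, -3.4, 26.0, 15.5, 4.8, 7.0, 52, 0.70),
    (5, "betula", 4.1, 2.9, 9.0, 7.0, 2.2, 2.6, 22, 2.10),
    (6, "pinus", -4.6, -1.2, 14.0, 10.0, 3.0, 4.0, 33, 0.30),
    (7, "camellia", 1.2, 4.6, 7.5, 4.5, 1.8, 1.9, 18, 1.90),
    (8, "pinus", -0.6, -6.2, 19.0, 12.5, 3.8, 5.2, 41, 0.90),
    (9, "quercus", 6.3, -0.8, 11.0, 8.0, 2.6, 3.0, 28, 2.40),
    (10, "pinus", -6.8, 3.1, 15.0, 10.5, 3.2, 4.2, 35, 0.10),
    (11, "betula", 3.4, 6.9, 8.0, 6.5, 2.0, 2.4, 20, 2.70),
    (12, "pinus", -7.9, -3.6, 17.5, 11.5, 3.5, 4.8, 39, 0.20),
]

TWELVE_TREE_RADIUS = 10.0


def twelve_tree_dicts():
    keys = ("id", "species", "x", "y", "dbh", "height", "crown_width",
            "crown_length", "age", "rel_elev")
    return [dict(zip(keys, row)) for row in TWELVE_TREE_ROWS]


@pytest.fixture(scope="session")
def twelve_tree_stand() -> Stand:
    trees = [
        Tree(id=r[0], species=r[1], x=r[2], y=r[3], dbh=r[4], height=r[5],
             crown_width=r[6], crown_length=r[7], age=r[8], rel_elev=r[9])
        for r in TWELVE_TREE_ROWS
    ]
    return Stand(radius=TWELVE_TREE_RADIUS, slope_deg=15.0, aspect="SE",
                 trees=trees, buffer_width=2.0)


def make_tree(tid=1, species="pinus", x=0.0, y=0.0, dbh=20.0, height=12.0,
              cw=3.5, cl=5.0, age=40.0, rel_elev=0.0, alive=True,
              origin="original") -> Tree:
    return Tree(id=tid, species=species, x=x, y=y, dbh=dbh, height=height,
                crown_width=cw, crown_length=cl, age=age, rel_elev=rel_elev,
                alive=alive, origin=origin)


def make_stand(trees, radius=20.0, slope=0.0, aspect="N",
               buffer_width=2.0) -> Stand:
    return Stand(radius=radius, slope_deg=slope, aspect=aspect,
                 trees=list(trees), buffer_width=buffer_width)
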