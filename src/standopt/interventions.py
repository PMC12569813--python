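"""Silvicultural interventions: selective harvesting, replanting-location
choice, and the replant-count trend search.

Harvest candidates are drawn uniformly at random from the living core
trees (the felling policy the optimizer learns to accept or reject),
subject to two hard guards: cumulative removal never exceeds 35% of the
initial stem count, and the last living individual of a species is never
felled.

Replanting locations are chosen inside canopy gaps: the incenters of the
largest Delaunay triangles are ranked by the replanting foreground index

    RFI = (1 + DAA/d_DAA)(1 + Mc/d_Mc)(1 + U/d_U) / (1 + CI/d_CI)

where DAA is the area of the triangle containing the candidate and Mc, U,
CI are the indexes a 5 cm virtual tree of the candidate species would have
there.  Species rotate round-robin through the seven native species so the
planted shares stay equal.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .config import DEFAULT_CONFIG, StructureConfig
from .geometry import DegenerateGeometryError, lens_area_vec, triangulation_from_points
from .growth_models import (REPLANT_DBH, REPLANT_SPECIES, evaluate_growth_model,
                            initialize_replant)
from .objective import DENSITY_RANGE, MAX_HARVEST_FRACTION
from .stand import Stand, Tree

__all__ = [
    "HarvestBudgetError", "ReplantPlan", "harvest_budget", "replant_cap",
    "select_harvest_candidates", "apply_harvest",
    "replanting_foreground_index", "PlantingScorer",
    "propose_planting_locations", "curve_trend_count_search",
    "write_intervention_ledger",
]


class HarvestBudgetError(RuntimeError):
    """Raised when a harvest request exceeds the 35% removal budget."""


def harvest_budget(n_initial: int) -> int:
    """Maximum number of stems that may ever be removed."""
    return int(math.floor(MAX_HARVEST_FRACTION * n_initial))


def replant_cap(stand: Stand) -> int:
    """Stems that may still be planted before density exceeds 3333/ha."""
    return max(0, int(math.floor(DENSITY_RANGE[1] * stand.area_ha))
               - stand.n_living)


def select_harvest_candidates(stand: Stand, k: int,
                              rng: np.random.Generator,
                              n_initial: int | None = None,
                              already_harvested: int = 0) -> list[int]:
    """Draw ``k`` distinct felling candidates uniformly from living core trees.

    Never selects the last living individual of a species.  Raises
    :class:`HarvestBudgetError` when the request would push cumulative
    removals beyond 35% of the initial count.
    """
    if k == 0:
        return []
    n0 = n_initial if n_initial is not None else stand.n_living
    if already_harvested + k > harvest_budget(n0):
        raise HarvestBudgetError(
            f"harvesting {k} more stems would exceed the "
            f"{MAX_HARVEST_FRACTION:.0%} budget ({harvest_budget(n0)} of {n0})")
    limit = stand.core_radius + 1e-9
    pool = [t for t in stand.living() if t.r <= limit]
    species_counts: dict[str, int] = {}
    for t in stand.living():
        species_counts[t.species] = species_counts.get(t.species, 0) + 1
    order = rng.permutation(len(pool))
    chosen: list[int] = []
    for idx in order:
        t = pool[idx]
        if species_counts[t.species] <= 1:
            continue  # would eliminate the species
        species_counts[t.species] -= 1
        chosen.append(t.id)
        if len(chosen) == k:
            return chosen
    raise HarvestBudgetError(
        f"only {len(chosen)} of {k} requested stems can be felled without "
        "eliminating a species")


def apply_harvest(stand: Stand, ids: list[int]) -> Stand:
    """Return a new stand with the given trees marked removed."""
    idset = set(ids)
    out = []
    for t in stand.trees:
        if t.id in idset:
            if not t.alive:
                raise ValueError(f"tree {t.id} is not alive")
            out.append(replace(t, alive=False))
            idset.discard(t.id)
        else:
            out.append(t)
    if idset:
        raise KeyError(f"unknown tree id(s): {sorted(idset)}")
    return stand.with_trees(out)


@dataclass
class ReplantPlan:
    """An ordered replanting plan: trees (location+species) and their RFI."""

    trees: list[Tree]
    rfi: list[float]

    @property
    def count(self) -> int:
        return len(self.trees)


class PlantingScorer:
    """Scores candidate planting locations on a fixed stand state.

    Caches the stand's Delaunay triangulation, triangle areas and the
    index standard deviations so that many candidates can be scored
    cheaply.  The virtual tree's Voronoi neighbours are read from the
    Delaunay adjacency of the augmented point set (the planar dual).
    """

    def __init__(self, stand: Stand, deltas: dict[str, float],
                 config: StructureConfig = DEFAULT_CONFIG):
        self.stand = stand
        self.config = config
        living = stand.living()
        self.living = living
        self.points = np.array([[t.x, t.y] for t in living])
        self.tri, self.records = triangulation_from_points(
            self.points, [t.id for t in living])
        areas = np.array([r.area for r in self.records])
        d_daa = float(np.std(areas))
        self.deltas = {
            "DAA": d_daa if d_daa > 1e-12 else 1.0,
            "Mc": deltas.get("Mc", 1.0),
            "U": deltas.get("U", 1.0),
            "CI": deltas.get("CI", 1.0),
        }
        self.kdtree = cKDTree(self.points)

    def _virtual_neighbours(self, location: tuple[float, float]) -> np.ndarray:
        pts = np.vstack([self.points, location])
        try:
            tri = Delaunay(pts)
        except QhullError as exc:
            raise DegenerateGeometryError(str(exc)) from exc
        indptr, indices = tri.vertex_neighbor_vertices
        k = len(pts) - 1
        return indices[indptr[k]:indptr[k + 1]]

    def rfi(self, location: tuple[float, float], species: str) -> float:
        x, y = location
        if math.hypot(x, y) > self.stand.core_radius + 1e-9:
            raise ValueError("candidate planting location outside core region")
        simplex = int(self.tri.find_simplex(np.array(location)))
        if simplex >= 0:
            a, b, c = self.points[self.tri.simplices[simplex]]
            daa = 0.5 * abs((b[0] - a[0]) * (c[1] - a[1])
                            - (c[0] - a[0]) * (b[1] - a[1]))
        else:
            daa = 0.0
        neigh = self._virtual_neighbours(location)
        neigh_trees = [self.living[j] for j in neigh]
        n = len(neigh_trees)
        if n == 0:
            raise DegenerateGeometryError("virtual tree has no neighbours")
        dbh = np.array([t.dbh for t in neigh_trees])
        u = float(np.mean(dbh > REPLANT_DBH))
        sp = [t.species for t in neigh_trees]
        m = sum(1 for s in sp if s != species) / n
        counts: dict[str, int] = {}
        for s in sp:
            counts[s] = counts.get(s, 0) + 1
        simpson = 1.0 - sum(v * v for v in counts.values()) / (n + 1) ** 2
        mc = min(1.0, 0.5 * m * (simpson + len(counts) / n))
        h = evaluate_growth_model(species, "H", REPLANT_DBH)
        cw = evaluate_growth_model(species, "CW", REPLANT_DBH)
        cl = min(evaluate_growth_model(species, "CL", REPLANT_DBH), h)
        r2 = np.array([t.crown_width / 2.0 for t in neigh_trees])
        d = np.array([math.hypot(t.x - x, t.y - y) for t in neigh_trees])
        ao = lens_area_vec(cw / 2.0, r2, d, self.config.no_overlap_value)
        lj = np.array([t.height * t.crown_width * t.crown_length
                       for t in neigh_trees])
        ci = float(np.sum(ao * lj / (h * cw * cl)) / (math.pi * (cw / 2) ** 2))
        dl = self.deltas
        value = ((1.0 + daa / dl["DAA"]) * (1.0 + mc / dl["Mc"])
                 / (1.0 + ci / dl["CI"]))
        u_factor = 1.0 + u / dl["U"]
        return value / u_factor if self.config.rfi_u_in_denominator \
            else value * u_factor


def replanting_foreground_index(location: tuple[float, float], species: str,
                                stand: Stand, deltas: dict[str, float],
                                config: StructureConfig = DEFAULT_CONFIG
                                ) -> float:
    """RFI of one candidate location (convenience over PlantingScorer)."""
    return PlantingScorer(stand, deltas, config).rfi(location, species)


def propose_planting_locations(
    stand: Stand, m: int, deltas: dict[str, float],
    config: StructureConfig = DEFAULT_CONFIG,
    k_candidates: int = 10,
    species_offset: int = 0,
    min_core_margin: float = 1.0,
    min_stem_distance: float = 0.5,
) -> ReplantPlan:
    """Choose ``m`` planting locations with species, best-RFI-first.

    Iteratively: take the incenters of the ``k_candidates`` largest
    Delaunay triangles that lie at least ``min_core_margin`` inside the
    core boundary and ``min_stem_distance`` from any stem, score each by
    RFI for the next round-robin species, plant at the argmax, and
    retriangulate.  With ``k_candidates=1`` this reduces to the pure
    max-area incenter rule.
    """
    if m == 0:
        return ReplantPlan(trees=[], rfi=[])
    working = stand
    trees: list[Tree] = []
    scores: list[float] = []
    next_id = stand.next_id()
    r_limit = stand.core_radius - min_core_margin
    for step in range(m):
        species = REPLANT_SPECIES[(species_offset + step)
                                  % len(REPLANT_SPECIES)]
        scorer = PlantingScorer(working, deltas, config)
        candidates = []
        for rec in scorer.records:
            cx, cy = rec.incenter
            if math.hypot(cx, cy) > r_limit:
                continue
            dist, _ = scorer.kdtree.query([cx, cy])
            if dist < min_stem_distance:
                continue
            candidates.append((cx, cy))
            if len(candidates) >= k_candidates:
                break
        if not candidates:
            break  # no physically plausible gap left
        values = [scorer.rfi(c, species) for c in candidates]
        best = int(np.argmax(values))
        tree = initialize_replant(species, candidates[best], working,
                                  tree_id=next_id)
        next_id += 1
        trees.append(tree)
        scores.append(float(values[best]))
        working = working.with_trees(working.trees + [tree])
    return ReplantPlan(trees=trees, rfi=scores)


def curve_trend_count_search(cap: int, spacing: int, evaluate,
                             start: int | None = None) -> int:
    """Windowed three-point search for the best replant count in [0, cap].

    Evaluates the triple {c-s, c, c+s}; an interior maximum shrinks the
    spacing, a boundary maximum slides the window toward it; terminates
    when the window cannot move and the spacing has reached 1.  Returns
    the argmax over all evaluated counts.  Matches an exhaustive grid on
    unimodal objectives; on multimodal ones it returns a local optimum at
    least as good as its start.
    """
    if cap <= 0:
        return 0
    memo: dict[int, float] = {}

    def f(c: int) -> float:
        if c not in memo:
            memo[c] = float(evaluate(c))
        return memo[c]

    c = cap // 2 if start is None else int(np.clip(start, 0, cap))
    s = max(1, int(spacing))
    while True:
        window = sorted({max(0, c - s), c, min(cap, c + s)})
        vals = {x: f(x) for x in window}
        # ties resolve to the point closest to the current centre
        best = max(window, key=lambda x: (vals[x], -abs(x - c)))
        if best != c:
            c = best
            continue
        if s == 1:
            break
        s = max(1, s // 2)
    return max(memo, key=lambda x: (memo[x], -x))


def write_intervention_ledger(actions: list[dict], path: str | Path) -> None:
    """Write a harvest/replant action ledger as CSV."""
    if not actions:
        raise ValueError("empty ledger")
    fields = ["cycle", "step", "agent", "action", "tree_id", "species",
              "x", "y", "accepted", "reward", "L_before", "L_after"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        for row in actions:
            writer.writerow(row)
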