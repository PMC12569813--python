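"""Per-tree stand structure indexes and competition covariates.

Five spatial indexes are evaluated per core reference tree over its
Voronoi spatial structure unit:

* ``W`` uniform angle index — fraction of angular gaps between successive
  neighbours (smaller form) strictly below the standard angle
  ``360/(n+1)``; describes the horizontal pattern (regular/random/clustered).
* ``U`` neighborhood comparison — fraction of neighbours with strictly
  larger DBH; size dominance of the reference tree.
* ``Mc`` complete mingling — heterospecific-neighbour proportion upgraded
  with a Simpson-diversity term and neighbour species richness.
* ``S`` stratification — vertical-layer diversity from thirds of the
  terrain-adjusted dominant height.
* ``CI`` crown competition — crown-overlap areas weighted by neighbour /
  reference size products, normalised by the reference crown projection.

Non-spatial quantities: canopy density (grid union of crown projections),
dominant height, and the competition covariates HCI (Hegyi), BAL (basal
area of larger trees, m²/ha), HDR and Reineke's SDI used by the prediction
models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, StructureConfig
from .geometry import SpatialUnit, lens_area_vec, voronoi_adjacency, voronoi_units
from .stand import Stand, StandSummary, Tree, stand_summary

__all__ = [
    "IndexTable", "Covariates", "StructureReport",
    "uniform_angle_index", "neighborhood_comparison", "complete_mingling",
    "dominant_height", "stratification_index", "crown_competition_index",
    "canopy_density", "competition_covariates", "structure_report",
    "write_index_report", "FIVE_INTERVALS",
]

#: Five-interval classification bounds shared by W, U and Mc.
FIVE_INTERVALS = (0.0, 0.25, 0.5, 0.75, 1.0)

_INDEX_KEYS = ("W", "U", "Mc", "S", "CI")


@dataclass
class IndexTable:
    """Per-tree index values with stand means and standard deviations.

    ``stds`` holds the population standard deviations used by the
    objective: keys U, Mc, S, CI, and ``W_abs`` taken over
    ``|W_i - w_reference|``.  Any zero deviation is replaced by 1 so the
    corresponding objective factor degenerates to ``1 + value``.
    """

    table: pd.DataFrame
    means: dict[str, float]
    stds: dict[str, float]


@dataclass
class Covariates:
    """Per-tree competition covariates and stand-level density measures."""

    table: pd.DataFrame      # id, HCI, BAL, HDR
    sdi: float
    nt: float


@dataclass
class StructureReport:
    """Everything the objective and constraints need for one stand state."""

    units: list[SpatialUnit]
    indexes: IndexTable
    h_dominant: float
    canopy: float
    summary: StandSummary
    density: float

    @property
    def n_core(self) -> int:
        return len(self.units)


def _tree_map(stand: Stand) -> dict[int, Tree]:
    return {t.id: t for t in stand.living()}


def uniform_angle_index(unit: SpatialUnit, stand: Stand,
                        _trees: dict[int, Tree] | None = None,
                        config: StructureConfig = DEFAULT_CONFIG) -> float:
    """Fraction of angular gaps strictly below the standard angle.

    By default the classical construction is used: the reference tree's
    ``w_neighbours`` (4) nearest living stems, standard angle
    ``360/(n+1)`` = 72°, for which a random pattern averages ~0.496.
    With ``w_use_unit_neighbours`` the gap fractions are instead taken
    over all Voronoi neighbours of the unit.
    """
    trees = _trees if _trees is not None else _tree_map(stand)
    ref = trees[unit.reference_id]
    if config.w_use_unit_neighbours:
        neigh = [trees[j] for j in unit.neighbour_ids]
    else:
        others = sorted(
            (t for t in trees.values() if t.id != unit.reference_id),
            key=lambda t: (t.x - ref.x) ** 2 + (t.y - ref.y) ** 2)
        neigh = others[:config.w_neighbours]
    n = len(neigh)
    if n < 2:
        raise ValueError("uniform angle index is undefined for n < 2")
    az = np.array([
        math.degrees(math.atan2(t.x - ref.x, t.y - ref.y)) % 360.0
        for t in neigh
    ])
    az.sort()
    gaps = np.diff(np.append(az, az[0] + 360.0))
    alpha = np.minimum(gaps, 360.0 - gaps)
    return float(np.mean(alpha < 360.0 / (n + 1)))


def neighborhood_comparison(unit: SpatialUnit, stand: Stand,
                            _trees: dict[int, Tree] | None = None) -> float:
    """Fraction of neighbours with strictly larger DBH (ties count 0)."""
    trees = _trees if _trees is not None else _tree_map(stand)
    ref = trees[unit.reference_id]
    return float(np.mean([trees[j].dbh > ref.dbh for j in unit.neighbour_ids]))


def complete_mingling(unit: SpatialUnit, stand: Stand,
                      include_reference: bool = False,
                      _trees: dict[int, Tree] | None = None) -> float:
    """Simpson-augmented species mingling of the reference tree, in [0, 1].

    ``Mc = (M/2) * [(1 - sum n_j² / (n+1)²) + n'/n]`` where ``M`` is the
    heterospecific-neighbour fraction, ``n_j`` the neighbour count of
    species j, and ``n'`` the number of distinct neighbour species.  The
    reference tree enters only through the ``(n+1)²`` denominator unless
    ``include_reference`` adds it to the species counts.
    """
    trees = _trees if _trees is not None else _tree_map(stand)
    ref = trees[unit.reference_id]
    neigh_species = [trees[j].species for j in unit.neighbour_ids]
    n = unit.n
    m = sum(1 for s in neigh_species if s != ref.species) / n
    counts: dict[str, int] = {}
    for s in neigh_species:
        counts[s] = counts.get(s, 0) + 1
    if include_reference:
        counts[ref.species] = counts.get(ref.species, 0) + 1
    simpson = 1.0 - sum(c * c for c in counts.values()) / (n + 1) ** 2
    richness = len(set(neigh_species)) / n
    return float(np.clip(0.5 * m * (simpson + richness), 0.0, 1.0))


def dominant_height(stand: Stand,
                    config: StructureConfig = DEFAULT_CONFIG) -> float:
    """Terrain-adjusted dominant height: mean of height + relative
    elevation over the ``floor(100 * area_ha)`` tallest living trees.

    The top-k selection sorts by height alone (literal reading); with
    ``terrain_adjusted_layers`` it sorts by height + elevation instead.
    """
    k = int(math.floor(100.0 * stand.area_ha))
    if k < 1:
        raise ValueError("plot too small: floor(100*area_ha) < 1")
    living = stand.living()
    key = ((lambda t: t.height + t.rel_elev) if config.terrain_adjusted_layers
           else (lambda t: t.height))
    top = sorted(living, key=key, reverse=True)[:k]
    return float(np.mean([t.height + t.rel_elev for t in top]))


def _floor_layer(h: float, h_d: float) -> int:
    # overlapping printed boundaries resolve to the middle layer
    if h_d / 3.0 <= h <= 2.0 * h_d / 3.0:
        return 0
    return -1 if h < h_d / 3.0 else 1


def stratification_index(unit: SpatialUnit, stand: Stand, h_d: float,
                         config: StructureConfig = DEFAULT_CONFIG,
                         _trees: dict[int, Tree] | None = None) -> float:
    """Vertical stratification of the unit: (layers/3) x same-layer fraction."""
    if h_d <= 0:
        raise ValueError("dominant height must be positive")
    trees = _trees if _trees is not None else _tree_map(stand)

    def eff_height(t: Tree) -> float:
        return t.height + t.rel_elev if config.terrain_adjusted_layers \
            else t.height

    ref = trees[unit.reference_id]
    fl_ref = _floor_layer(eff_height(ref), h_d)
    fls = [_floor_layer(eff_height(trees[j]), h_d)
           for j in unit.neighbour_ids]
    z = len(set(fls) | {fl_ref})
    same = np.mean([
        1.0 - abs(fl_ref - fl) / max(abs(fl_ref - fl), 1) for fl in fls
    ])
    return float(z / 3.0 * same)


def crown_competition_index(unit: SpatialUnit, stand: Stand,
                            config: StructureConfig = DEFAULT_CONFIG,
                            _trees: dict[int, Tree] | None = None) -> float:
    """Crown competition pressure on the reference tree.

    ``CI = (1/Z) * sum_j AO_ij * L_j / L_i`` with ``L = H*CW*CL``,
    ``Z = pi (CW/2)²`` and ``AO`` the crown-disk overlap area (sentinel
    ``no_overlap_value`` for disjoint crowns).
    """
    trees = _trees if _trees is not None else _tree_map(stand)
    ref = trees[unit.reference_id]
    l_ref = ref.height * ref.crown_width * ref.crown_length
    if l_ref <= 0:
        raise ValueError("reference tree has zero H*CW*CL volume proxy")
    z = math.pi * (ref.crown_width / 2.0) ** 2
    neigh = [trees[j] for j in unit.neighbour_ids]
    r2 = np.array([t.crown_width / 2.0 for t in neigh])
    d = np.array([math.hypot(t.x - ref.x, t.y - ref.y) for t in neigh])
    ao = lens_area_vec(ref.crown_width / 2.0, r2, d,
                       config.no_overlap_value)
    lj = np.array([t.height * t.crown_width * t.crown_length for t in neigh])
    return float(np.sum(ao * lj / l_ref) / z)


def canopy_density(stand: Stand,
                   config: StructureConfig = DEFAULT_CONFIG) -> float:
    """Fraction of the plot disk covered by the union of living crowns.

    Deterministic: evaluated on a fixed square grid (default 0.25 m)
    restricted to the disk.
    """
    g = config.canopy_grid
    r = stand.radius
    axis = np.arange(-r + g / 2.0, r, g)
    gx, gy = np.meshgrid(axis, axis)
    inside = gx ** 2 + gy ** 2 <= r * r
    covered = np.zeros_like(inside)
    m = len(axis)
    for t in stand.living():
        cr = t.crown_width / 2.0
        if cr <= 0:
            continue
        i0 = max(0, int((t.x - cr + r) / g) - 1)
        i1 = min(m, int((t.x + cr + r) / g) + 2)
        j0 = max(0, int((t.y - cr + r) / g) - 1)
        j1 = min(m, int((t.y + cr + r) / g) + 2)
        sub = ((gx[j0:j1, i0:i1] - t.x) ** 2
               + (gy[j0:j1, i0:i1] - t.y) ** 2) <= cr * cr
        covered[j0:j1, i0:i1] |= sub
    n_inside = int(inside.sum())
    if n_inside == 0:
        return 0.0
    return float((covered & inside).sum() / n_inside)


def competition_covariates(stand: Stand) -> Covariates:
    """HCI, BAL, HDR per living tree plus stand SDI and density.

    HCI is the Hegyi size-ratio/distance sum over Voronoi neighbours; BAL
    the basal area (m²/ha) of strictly larger trees; SDI Reineke's index
    with reference diameter 25 cm and slope 1.605.
    """
    living = stand.living()
    if not living:
        raise ValueError("empty stand")
    points = np.array([[t.x, t.y] for t in living])
    pairs = voronoi_adjacency(points, stand.radius)
    dbh = np.array([t.dbh for t in living])
    hci = np.zeros(len(living))
    for p, q in pairs:
        d = math.hypot(*(points[p] - points[q]))
        if d == 0.0:
            raise ValueError(
                f"coincident stems: trees {living[p].id} and {living[q].id}")
        hci[p] += dbh[q] / (dbh[p] * d)
        hci[q] += dbh[p] / (dbh[q] * d)

    ba = math.pi * (dbh / 200.0) ** 2  # m² per stem
    order = np.argsort(-dbh, kind="stable")
    bal = np.zeros(len(living))
    cum = 0.0
    i = 0
    while i < len(order):  # group ties so equal DBH gets equal BAL
        j = i
        while j < len(order) and dbh[order[j]] == dbh[order[i]]:
            j += 1
        for k in order[i:j]:
            bal[k] = cum / stand.area_ha
        cum += ba[order[i:j]].sum()
        i = j

    hdr = np.array([t.height / t.dbh for t in living])
    summary = stand_summary(stand)
    nt = summary.density_per_ha
    sdi = nt * (summary.quadratic_mean_dbh / 25.0) ** 1.605
    table = pd.DataFrame({
        "id": [t.id for t in living], "HCI": hci, "BAL": bal, "HDR": hdr,
    }).set_index("id")
    return Covariates(table=table, sdi=float(sdi), nt=float(nt))


def structure_report(stand: Stand,
                     config: StructureConfig = DEFAULT_CONFIG,
                     units: list[SpatialUnit] | None = None) -> StructureReport:
    """Compute all per-tree indexes, stand means/deviations, dominant
    height, canopy density and the non-spatial summary for one stand state.
    """
    if units is None:
        units = voronoi_units(stand)
    if config.reference_min_dbh > 0.0:
        # sub-threshold stems keep their neighbour role but are not
        # reference trees (measurement-class-floor semantics)
        sizes = {t.id: t.dbh for t in stand.living()}
        units = [u for u in units
                 if sizes[u.reference_id] >= config.reference_min_dbh]
    if not units:
        raise ValueError("stand has no core reference trees")
    h_d = dominant_height(stand, config)
    living = stand.living()
    ids = [t.id for t in living]
    id2idx = {tid: i for i, tid in enumerate(ids)}
    x = np.array([t.x for t in living])
    y = np.array([t.y for t in living])
    dbh = np.array([t.dbh for t in living])
    cw = np.array([t.crown_width for t in living])
    h = np.array([t.height for t in living])
    cl = np.array([t.crown_length for t in living])
    rel = np.array([t.rel_elev for t in living])
    codes = pd.factorize(np.array([t.species for t in living]))[0]

    m_units = len(units)
    ref_idx = np.array([id2idx[u.reference_id] for u in units])
    counts = np.array([u.n for u in units])
    nb_idx = np.array([id2idx[j] for u in units for j in u.neighbour_ids])
    offsets = np.zeros(m_units, dtype=int)
    offsets[1:] = np.cumsum(counts)[:-1]
    ref_pair = np.repeat(ref_idx, counts)

    # U: fraction of strictly larger neighbours
    u_vals = np.add.reduceat(
        (dbh[nb_idx] > dbh[ref_pair]).astype(float), offsets) / counts

    # CI: overlap-weighted size ratios over the crown projection
    dist = np.hypot(x[nb_idx] - x[ref_pair], y[nb_idx] - y[ref_pair])
    ao = lens_area_vec(cw[ref_pair] / 2.0, cw[nb_idx] / 2.0, dist,
                       config.no_overlap_value)
    lvol = h * cw * cl
    ci_vals = (np.add.reduceat(ao * lvol[nb_idx] / lvol[ref_pair], offsets)
               / (np.pi * (cw[ref_idx] / 2.0) ** 2))

    # S: layer membership from thirds of the dominant height
    eff = h + rel if config.terrain_adjusted_layers else h
    fl = np.where((eff >= h_d / 3.0) & (eff <= 2.0 * h_d / 3.0), 0,
                  np.where(eff < h_d / 3.0, -1, 1))
    frac_same = np.add.reduceat(
        (fl[nb_idx] == fl[ref_pair]).astype(float), offsets) / counts
    bits = np.left_shift(1, fl + 1)
    zmask = np.bitwise_or.reduceat(bits[nb_idx], offsets) | bits[ref_idx]
    z = (zmask & 1 > 0).astype(int) + (zmask & 2 > 0) + (zmask & 4 > 0)
    s_vals = z / 3.0 * frac_same

    # Mc: Simpson-augmented mingling (small per-unit loop)
    n_codes = int(codes.max()) + 1
    mc_vals = np.empty(m_units)
    for k, unit in enumerate(units):
        sl = nb_idx[offsets[k]:offsets[k] + counts[k]]
        cvec = np.bincount(codes[sl], minlength=n_codes)
        nn = counts[k]
        mixing = float(np.mean(codes[sl] != codes[ref_idx[k]]))
        richness = int(np.count_nonzero(cvec)) / nn
        if config.mingling_include_reference:
            cvec = cvec.copy()
            cvec[codes[ref_idx[k]]] += 1
        simpson = 1.0 - float((cvec.astype(float) ** 2).sum()) / (nn + 1) ** 2
        mc_vals[k] = min(1.0, max(0.0, 0.5 * mixing * (simpson + richness)))

    # W: classical k-nearest construction (or unit-based variant)
    if config.w_use_unit_neighbours:
        trees = _tree_map(stand)
        w_vals = np.array([
            uniform_angle_index(u, stand, trees, config) if u.n >= 2
            else np.nan for u in units])
    else:
        kn = min(config.w_neighbours, len(living) - 1)
        if kn < 2:
            w_vals = np.full(m_units, np.nan)
        else:
            points = np.column_stack([x, y])
            kdt = cKDTree(points)
            _, ii = kdt.query(points[ref_idx], k=kn + 1)
            mask = ii != ref_idx[:, None]
            # drop the self column; every stem position is unique
            extra = mask.sum(axis=1) - kn
            for row in np.nonzero(extra > 0)[0]:  # degenerate safeguard
                on = np.nonzero(mask[row])[0]
                mask[row, on[kn:]] = False
            nb = ii[mask].reshape(m_units, kn)
            dx = x[nb] - x[ref_idx][:, None]
            dy = y[nb] - y[ref_idx][:, None]
            az = np.degrees(np.arctan2(dx, dy)) % 360.0
            az.sort(axis=1)
            gaps = np.diff(np.concatenate([az, az[:, :1] + 360.0], axis=1),
                           axis=1)
            alpha = np.minimum(gaps, 360.0 - gaps)
            w_vals = (alpha < 360.0 / (kn + 1)).mean(axis=1)

    table = pd.DataFrame({
        "id": [u.reference_id for u in units],
        "W": w_vals, "U": u_vals, "Mc": mc_vals, "S": s_vals, "CI": ci_vals,
    }).set_index("id")
    means = {k: float(np.nanmean(table[k])) for k in _INDEX_KEYS}
    w_abs = np.abs(table["W"].to_numpy(dtype=float) - config.w_reference)
    stds = {
        "W_abs": float(np.nanstd(w_abs)),
        "U": float(np.nanstd(table["U"])),
        "Mc": float(np.nanstd(table["Mc"])),
        "S": float(np.nanstd(table["S"])),
        "CI": float(np.nanstd(table["CI"])),
    }
    stds = {k: (v if v > 1e-12 else 1.0) for k, v in stds.items()}
    return StructureReport(
        units=units,
        indexes=IndexTable(table=table, means=means, stds=stds),
        h_dominant=h_d,
        canopy=canopy_density(stand, config),
        summary=stand_summary(stand),
        density=stand.density_per_ha,
    )


def _histogram(values: np.ndarray) -> dict[str, int]:
    """Five-interval histogram: 0, (0,.25], (.25,.5], (.5,.75], (.75,1]."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    out = {"0": int(np.sum(v == 0.0))}
    for lo, hi in zip(FIVE_INTERVALS[:-1], FIVE_INTERVALS[1:]):
        out[f"({lo},{hi}]"] = int(np.sum((v > lo) & (v <= hi)))
    return out


def write_index_report(report: StructureReport, csv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    """Export the per-tree index table (CSV) and a stand-level JSON summary."""
    report.indexes.table.to_csv(csv_path)
    if json_path is not None:
        payload = {
            "means": report.indexes.means,
            "stds": report.indexes.stds,
            "dominant_height": report.h_dominant,
            "canopy_density": report.canopy,
            "density_per_ha": report.density,
            "histograms": {
                k: _histogram(report.indexes.table[k].to_numpy())
                for k in ("W", "U", "Mc")
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
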