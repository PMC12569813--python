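"""Domain types for circular forest plots: trees, stands, summaries, I/O.

Coordinates are Cartesian metres with the plot centre at the origin and
y pointing north; azimuths are measured clockwise from north.  A stand is a
circular plot with a buffer ring (default 2 m) along its boundary: trees in
the buffer act only as neighbours of interior ("core") reference trees so
that edge effects do not bias the spatial structure indexes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "Stand",
    "StandSummary",
    "TreeListError",
    "read_tree_list",
    "write_tree_list",
    "stand_summary",
    "diameter_class",
    "ASPECT_AZIMUTH",
]


class TreeListError(ValueError):
    """Raised when a tree list violates the schema or a stand invariant."""


#: Azimuth (degrees clockwise from north) of the eight aspect sectors.
ASPECT_AZIMUTH = {
    "N": 0.0, "NE": 45.0, "E": 90.0, "SE": 135.0,
    "S": 180.0, "SW": 225.0, "W": 270.0, "NW": 315.0,
}

#: Ordinal code of each aspect sector, used as a model covariate.
ASPECT_ORDINAL = {k: i for i, k in enumerate(ASPECT_AZIMUTH)}

TREE_COLUMNS = [
    "id", "species", "x", "y", "dbh", "height", "crown_width",
    "crown_length", "age", "rel_elev", "alive", "origin",
]

_NUMERIC_COLUMNS = ["x", "y", "dbh", "height", "crown_width",
                    "crown_length", "age", "rel_elev"]


@dataclass(frozen=True)
class Tree:
    """One measured or simulated stem.

    ``dbh`` is in cm; all other size variables in metres; ``age`` in years.
    ``rel_elev`` is elevation above the plot minimum.  ``origin`` is
    ``"original"`` for surveyed/generated stems and ``"replanted"`` for
    stems added by the replanting optimizer.
    """

    id: int
    species: str
    x: float
    y: float
    dbh: float
    height: float
    crown_width: float
    crown_length: float
    age: float
    rel_elev: float
    alive: bool = True
    origin: str = "original"

    @property
    def r(self) -> float:
        """Distance from the plot centre."""
        return math.hypot(self.x, self.y)


@dataclass
class Stand:
    """A circular plot: metadata plus its tree collection.

    ``aspect`` is one of the eight sector codes ("N", "NE", ...).  The core
    region is the disk of radius ``radius - buffer_width``; trees outside it
    are buffer trees.  ``elev_datum`` records the value subtracted from the
    planar elevation ramp so that the minimum relative elevation is zero;
    it lets replanted trees receive a consistent ``rel_elev``.
    """

    radius: float
    slope_deg: float
    aspect: str
    trees: list[Tree] = field(default_factory=list)
    buffer_width: float = 2.0
    survey_year: int | None = None
    elev_datum: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise TreeListError("plot radius must be positive")
        if self.buffer_width >= self.radius:
            raise TreeListError(
                f"buffer_width {self.buffer_width} must be smaller than "
                f"radius {self.radius}"
            )
        if self.aspect not in ASPECT_AZIMUTH:
            raise TreeListError(f"unknown aspect {self.aspect!r}")

    # -- geometry -----------------------------------------------------
    @property
    def area_ha(self) -> float:
        return math.pi * self.radius ** 2 / 1e4

    @property
    def core_radius(self) -> float:
        return self.radius - self.buffer_width

    def rel_elev_at(self, x: float, y: float) -> float:
        """Relative elevation of a point from the planar terrain ramp.

        The ramp rises toward the direction opposite the aspect (the
        aspect is the downslope-facing direction) at tan(slope).
        """
        az = math.radians(ASPECT_AZIMUTH[self.aspect])
        downslope = np.array([math.sin(az), math.cos(az)])
        raw = -(x * downslope[0] + y * downslope[1]) * math.tan(
            math.radians(self.slope_deg))
        return max(0.0, raw - self.elev_datum)

    # -- tree access --------------------------------------------------
    def living(self) -> list[Tree]:
        return [t for t in self.trees if t.alive]

    @property
    def n_living(self) -> int:
        return sum(1 for t in self.trees if t.alive)

    @property
    def density_per_ha(self) -> float:
        return self.n_living / self.area_ha

    def frame(self, living_only: bool = True) -> pd.DataFrame:
        """Tree list as a DataFrame (copy), optionally living trees only."""
        rows = self.living() if living_only else self.trees
        return pd.DataFrame([t.__dict__ for t in rows], columns=TREE_COLUMNS)

    def tree_by_id(self, tid: int) -> Tree:
        for t in self.trees:
            if t.id == tid:
                return t
        raise KeyError(f"no tree with id {tid}")

    def next_id(self) -> int:
        return max((int(t.id) for t in self.trees), default=0) + 1

    def with_trees(self, trees: Iterable[Tree]) -> "Stand":
        return replace(self, trees=list(trees))

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Check every tree against the stand invariants."""
        for i, t in enumerate(self.trees):
            if t.r > self.radius + 1e-9:
                raise TreeListError(
                    f"tree {t.id} (row {i}): position ({t.x:.2f}, {t.y:.2f}) "
                    f"lies outside plot radius {self.radius}")
            if t.origin == "original" and t.dbh < 5.0 - 1e-9:
                raise TreeListError(
                    f"tree {t.id} (row {i}): dbh {t.dbh} below the 5 cm "
                    "measurement threshold")
            if t.crown_width <= 0:
                raise TreeListError(
                    f"tree {t.id} (row {i}): crown_width must be positive")
            if t.crown_length > t.height + 1e-9:
                raise TreeListError(
                    f"tree {t.id} (row {i}): crown_length {t.crown_length} "
                    f"exceeds height {t.height}")


@dataclass(frozen=True)
class StandSummary:
    """Non-spatial stand facts: density, diameter classes, species."""

    n_living: int
    density_per_ha: float
    n_diameter_classes: int
    n_species: int
    quadratic_mean_dbh: float
    class_counts: dict[int, int]
    species_counts: dict[str, int]


def diameter_class(dbh: float) -> int:
    """2 cm diameter class starting at 6 cm: [6,8) -> 1, [8,10) -> 2, ...

    Stems with 5 <= dbh < 6 (e.g. fresh replants) fall in pre-class 0 and
    do not count toward the number of diameter classes, so planting cannot
    break the class-preservation constraint.
    """
    if dbh < 6.0:
        return 0
    return 1 + int(math.floor((dbh - 6.0) / 2.0))


def stand_summary(stand: Stand) -> StandSummary:
    """Summarise the living trees of a stand (density, D, T, Dq)."""
    living = stand.living()
    if not living:
        raise TreeListError("cannot summarise an empty stand")
    classes = [diameter_class(t.dbh) for t in living]
    class_counts: dict[int, int] = {}
    for c in classes:
        class_counts[c] = class_counts.get(c, 0) + 1
    species_counts: dict[str, int] = {}
    for t in living:
        species_counts[t.species] = species_counts.get(t.species, 0) + 1
    dq = math.sqrt(sum(t.dbh ** 2 for t in living) / len(living))
    return StandSummary(
        n_living=len(living),
        density_per_ha=len(living) / stand.area_ha,
        n_diameter_classes=len([c for c in class_counts if c >= 1]),
        n_species=len(species_counts),
        quadratic_mean_dbh=dq,
        class_counts=class_counts,
        species_counts=species_counts,
    )


# ---------------------------------------------------------------------------
# Tree-list I/O
# ---------------------------------------------------------------------------
# The on-disk format is a plain CSV with the columns of TREE_COLUMNS, preceded
# by '#'-prefixed metadata lines (key: value) for the plot block.

_METADATA_KEYS = {
    "radius_m": float,
    "slope_deg": float,
    "aspect": str,
    "buffer_width_m": float,
    "survey_year": int,
    "elev_datum": float,
}


def write_tree_list(stand: Stand, path: str | Path) -> None:
    """Write a stand to CSV such that reading it back reproduces the stand."""
    path = Path(path)
    meta = {
        "radius_m": stand.radius,
        "slope_deg": stand.slope_deg,
        "aspect": stand.aspect,
        "buffer_width_m": stand.buffer_width,
        "elev_datum": stand.elev_datum,
    }
    if stand.survey_year is not None:
        meta["survey_year"] = stand.survey_year
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    frame = stand.frame(living_only=False)
    frame.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())


def read_tree_list(path: str | Path) -> Stand:
    """Read a stand from CSV, validating schema and invariants.

    Raises
    ------
    TreeListError
        On a missing column, a non-numeric size field, or a tree outside
        the plot radius; the message names the offending column or row.
    """
    path = Path(path)
    meta: dict[str, object] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            key = key.strip()
            if key in _METADATA_KEYS:
                meta[key] = _METADATA_KEYS[key](value.strip())
            body_start = i + 1
        else:
            break
    if "radius_m" not in meta:
        raise TreeListError("metadata header missing required key 'radius_m'")
    frame = pd.read_csv(io.StringIO("\n".join(lines[body_start:])),
                        float_precision="round_trip")
    missing = [c for c in TREE_COLUMNS if c not in frame.columns]
    if missing:
        raise TreeListError(f"tree list missing column(s): {', '.join(missing)}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if frame[col].isna().any():
            row = int(frame.index[frame[col].isna()][0])
            raise TreeListError(f"column '{col}' has a missing value (row {row})")
        if len(bad):
            raise TreeListError(
                f"column '{col}' has a non-numeric value (row {int(bad[0])})")
        frame[col] = coerced

    trees = [
        Tree(
            id=int(r.id), species=str(r.species), x=float(r.x), y=float(r.y),
            dbh=float(r.dbh), height=float(r.height),
            crown_width=float(r.crown_width), crown_length=float(r.crown_length),
            age=float(r.age), rel_elev=float(r.rel_elev),
            alive=bool(r.alive), origin=str(r.origin),
        )
        for r in frame.itertuples()
    ]
    stand = Stand(
        radius=float(meta["radius_m"]),
        slope_deg=float(meta.get("slope_deg", 0.0)),
        aspect=str(meta.get("aspect", "N")),
        trees=trees,
        buffer_width=float(meta.get("buffer_width_m", 2.0)),
        survey_year=int(meta["survey_year"]) if "survey_year" in meta else None,
        elev_datum=float(meta.get("elev_datum", 0.0)),
    )
    stand.validate()
    return stand
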