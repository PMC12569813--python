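"""Multiplicative-divisive stand objective, constraint system, and the
ideal-structure test.

The objective rewards mingling and vertical stratification and penalises
size suppression, crown competition, and departure of the uniform angle
index from the random-pattern reference 0.496:

    L = (1/n) * sum_i [(1 + Mc_i/d_Mc)(1 + S_i/d_S)]
              / [(1 + U_i/d_U)(1 + CI_i/d_CI)(1 + |W_i - 0.496|/d_|W-0.496|)]

summed over core reference trees, with d_* the population standard
deviations of the same stand state (zero deviations replaced by 1).

Optimization moves are subject to a constraint system: after harvesting,
every index mean must be at least as good as initially, diameter classes
and species must be preserved, canopy density must stay >= 0.7 and at most
35% of stems may be removed; after replanting, mingling and the horizontal
pattern must improve further and the final density must lie in the optimal
planting band [1667, 3333] stems/ha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, StructureConfig
from .indexes import StructureReport, structure_report
from .stand import Stand

__all__ = [
    "ObjectiveValue", "Clause", "ConstraintReport",
    "stand_objective", "objective_from_report", "constraint_report",
    "is_ideal_structure", "IDEAL_U_MAX", "IDEAL_MC_MIN", "IDEAL_W_RANGE",
    "DENSITY_RANGE", "MAX_HARVEST_FRACTION", "MIN_CANOPY",
]

#: Ideal-structure thresholds used as the dynamic-loop stopping rule.
IDEAL_U_MAX = 0.5
IDEAL_MC_MIN = 0.75
IDEAL_W_RANGE = (0.475, 0.517)

#: Optimal planting-density band (stems/ha) and the harvest cap.
DENSITY_RANGE = (1667.0, 3333.0)
MAX_HARVEST_FRACTION = 0.35
MIN_CANOPY = 0.7

_EPS = 1e-9  # tolerance so self-comparisons of identical states pass


@dataclass
class ObjectiveValue:
    """Objective score with its per-tree contributions and deltas used."""

    value: float
    contributions: "np.ndarray"
    deltas: dict[str, float]


def objective_from_report(report: StructureReport,
                          config: StructureConfig = DEFAULT_CONFIG,
                          deltas: dict[str, float] | None = None
                          ) -> ObjectiveValue:
    """Objective from a precomputed structure report.

    ``deltas`` overrides the report's standard deviations (used with the
    ``freeze_deltas`` optimizer switch).
    """
    d = deltas if deltas is not None else report.indexes.stds
    t = report.indexes.table
    w_abs = np.abs(t["W"].to_numpy(dtype=float) - config.w_reference)
    w_abs = np.nan_to_num(w_abs, nan=0.0)
    num = ((1.0 + t["Mc"].to_numpy() / d["Mc"])
           * (1.0 + t["S"].to_numpy() / d["S"]))
    den = ((1.0 + t["U"].to_numpy() / d["U"])
           * (1.0 + t["CI"].to_numpy() / d["CI"])
           * (1.0 + w_abs / d["W_abs"]))
    contrib = num / den
    return ObjectiveValue(value=float(contrib.mean()),
                          contributions=contrib, deltas=dict(d))


def stand_objective(stand: Stand,
                    config: StructureConfig = DEFAULT_CONFIG,
                    deltas: dict[str, float] | None = None) -> ObjectiveValue:
    """Objective of a stand state (computes the structure report)."""
    return objective_from_report(structure_report(stand, config),
                                 config, deltas)


@dataclass(frozen=True)
class Clause:
    name: str
    passed: bool
    value: float
    bound: float


@dataclass
class ConstraintReport:
    """Outcome of every constraint clause for a harvest+replant proposal."""

    clauses: list[Clause] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.clauses)

    def as_dict(self) -> dict[str, dict]:
        return {c.name: {"passed": bool(c.passed), "value": c.value,
                         "bound": c.bound} for c in self.clauses}

    def __getitem__(self, name: str) -> Clause:
        for c in self.clauses:
            if c.name == name:
                return c
        raise KeyError(name)


def constraint_report(initial: StructureReport,
                      after_harvest: StructureReport,
                      after_replant: StructureReport,
                      config: StructureConfig = DEFAULT_CONFIG
                      ) -> ConstraintReport:
    """Evaluate every constraint clause on three stand states.

    States share the plot geometry: the initial stand, the stand after
    selective harvesting (original stems only), and the final stand after
    replanting.  Violations are reported, never raised.
    """
    wref = config.w_reference
    m0, m1, m2 = (s.indexes.means for s in (initial, after_harvest,
                                            after_replant))
    clauses = [
        Clause("Mc_up_harvest", m1["Mc"] >= m0["Mc"] - _EPS, m1["Mc"], m0["Mc"]),
        Clause("S_up_harvest", m1["S"] >= m0["S"] - _EPS, m1["S"], m0["S"]),
        Clause("U_down_harvest", m1["U"] <= m0["U"] + _EPS, m1["U"], m0["U"]),
        Clause("CI_down_harvest", m1["CI"] <= m0["CI"] + _EPS, m1["CI"],
               m0["CI"]),
        Clause("W_closer_harvest",
               abs(m1["W"] - wref) <= abs(m0["W"] - wref) + _EPS,
               abs(m1["W"] - wref), abs(m0["W"] - wref)),
        Clause("D_preserved",
               after_harvest.summary.n_diameter_classes
               == initial.summary.n_diameter_classes,
               after_harvest.summary.n_diameter_classes,
               initial.summary.n_diameter_classes),
        Clause("T_preserved",
               after_harvest.summary.n_species == initial.summary.n_species,
               after_harvest.summary.n_species, initial.summary.n_species),
        Clause("Cd_after_harvest", after_harvest.canopy >= MIN_CANOPY - _EPS,
               after_harvest.canopy, MIN_CANOPY),
        Clause("Cd_final", after_replant.canopy >= MIN_CANOPY - _EPS,
               after_replant.canopy, MIN_CANOPY),
        Clause("N_retention",
               after_harvest.summary.n_living
               >= initial.summary.n_living * (1.0 - MAX_HARVEST_FRACTION)
               - _EPS,
               after_harvest.summary.n_living,
               initial.summary.n_living * (1.0 - MAX_HARVEST_FRACTION)),
        Clause("W_closer_replant",
               abs(m2["W"] - wref) <= abs(m1["W"] - wref) + _EPS,
               abs(m2["W"] - wref), abs(m1["W"] - wref)),
        Clause("Mc_up_replant", m2["Mc"] >= m1["Mc"] - _EPS, m2["Mc"],
               m1["Mc"]),
        Clause("PD_range",
               DENSITY_RANGE[0] - _EPS <= after_replant.density
               <= DENSITY_RANGE[1] + _EPS,
               after_replant.density, DENSITY_RANGE[1]),
    ]
    return ConstraintReport(clauses=clauses)


def is_ideal_structure(report: StructureReport) -> bool:
    """True iff the stand means satisfy the ideal-structure thresholds
    (U <= 0.5, Mc >= 0.75, 0.475 <= W <= 0.517), taken over core trees."""
    m = report.indexes.means
    return (m["U"] <= IDEAL_U_MAX
            and m["Mc"] >= IDEAL_MC_MIN
            and IDEAL_W_RANGE[0] <= m["W"] <= IDEAL_W_RANGE[1])
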