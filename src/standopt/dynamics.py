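"""Dynamic predict-optimize loop driving a stand to the ideal structure.

Each cycle optimizes the current stand with the two-agent solver, stops if
the stand means reach the ideal-structure thresholds (U <= 0.5,
Mc >= 0.75, 0.475 <= W <= 0.517), and otherwise advances the stand five
years through the prediction bank before the next cycle.  Reported
"years" count only the growth advances (optimization itself is treated as
instantaneous).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .config import DEFAULT_CONFIG, StructureConfig
from .indexes import structure_report
from .objective import is_ideal_structure, objective_from_report
from .optimizer import LearnerConfig, OptimizationResult, optimize_madqn, optimize_maql
from .prediction import PredictorBank, advance_stand
from .stand import Stand

__all__ = ["CycleRecord", "Trajectory", "dynamic_optimize",
           "trajectory_report"]


@dataclass
class CycleRecord:
    """One optimization cycle: year offset, indexes and actions taken."""

    cycle: int
    years: int
    l_before: float
    l_after: float
    w: float
    u: float
    mc: float
    s: float
    ci: float
    canopy: float
    density: float
    n_harvested: int
    n_replanted: int
    feasible: bool


@dataclass
class Trajectory:
    """Per-cycle records, archived stand snapshots and the stop reason."""

    records: list[CycleRecord]
    stands: list[Stand]
    stop_reason: str  # 'ideal', 'max_cycles' or 'no_feasible_action'
    config_hash: str = ""
    results: list[OptimizationResult] = field(default_factory=list)


def _config_hash(lcfg: LearnerConfig, scfg: StructureConfig,
                 max_cycles: int) -> str:
    payload = json.dumps({"learner": asdict(lcfg), "structure": asdict(scfg),
                          "max_cycles": max_cycles}, sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def dynamic_optimize(stand: Stand, bank: PredictorBank,
                     lcfg: LearnerConfig | None = None,
                     scfg: StructureConfig = DEFAULT_CONFIG,
                     max_cycles: int = 8,
                     algorithm: str = "madqn") -> Trajectory:
    """Run predict-optimize cycles until the ideal structure or the cap.

    ``max_cycles=0`` optimizes the current state only (static mode).  The
    hard default cap of 8 cycles spans 40 years of growth.
    """
    lcfg = lcfg or LearnerConfig()
    solver = optimize_madqn if algorithm == "madqn" else optimize_maql
    records: list[CycleRecord] = []
    stands: list[Stand] = []
    results: list[OptimizationResult] = []
    current = stand
    years = 0
    stop = "max_cycles"

    def record(cycle, l_before, l_after, report, result=None):
        m = report.indexes.means
        records.append(CycleRecord(
            cycle=cycle, years=years, l_before=l_before, l_after=l_after,
            w=m["W"], u=m["U"], mc=m["Mc"], s=m["S"], ci=m["CI"],
            canopy=report.canopy, density=report.density,
            n_harvested=len(result.harvest_ids) if result else 0,
            n_replanted=len(result.replants) if result else 0,
            feasible=result.feasible if result else True))
        stands.append(current)

    for cycle in range(max_cycles + 1):
        pre = structure_report(current, scfg)
        if is_ideal_structure(pre):
            l_now = objective_from_report(pre, scfg).value
            record(cycle, l_now, l_now, pre)
            stop = "ideal"
            break
        result = solver(current, lcfg, scfg)
        results.append(result)
        current = result.best_stand
        report = structure_report(current, scfg)
        record(cycle, result.initial_l, result.best_l, report, result)
        if is_ideal_structure(report):
            stop = "ideal"
            break
        if cycle == max_cycles:
            stop = "max_cycles"
            break
        current = advance_stand(current, bank, scfg)
        if current.n_living == 0:
            stop = "no_feasible_action"
            break
        years += 5
    return Trajectory(records=records, stands=stands, stop_reason=stop,
                      config_hash=_config_hash(lcfg, scfg, max_cycles),
                      results=results)


def trajectory_report(trajectory: Trajectory, path: str | Path,
                      seeds: dict | None = None,
                      plots: bool = True) -> list[Path]:
    """Write the trajectory as CSV + JSON provenance (+ optional plots).

    The CSV columns mirror the per-cycle summary (years, W, Mc, CI, S, U,
    L); regeneration from the archived records is byte-deterministic.
    """
    if not trajectory.records:
        raise ValueError("empty trajectory")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([{
        "Years": r.years, "W": r.w, "Mc": r.mc, "CI": r.ci, "S": r.s,
        "U": r.u, "L_before": r.l_before, "L_after": r.l_after,
        "Cd": r.canopy, "density": r.density,
        "harvested": r.n_harvested, "replanted": r.n_replanted,
    } for r in trajectory.records])
    csv_path = path / "trajectory.csv"
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "stop_reason": trajectory.stop_reason,
        "config_hash": trajectory.config_hash,
        "cycles": len(trajectory.records),
        "seeds": seeds or {},
    }
    json_path = path / "provenance.json"
    json_path.write_text(json.dumps(meta, indent=2))
    written = [csv_path, json_path]
    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].plot(frame["Years"], frame["L_after"], "o-", label="L")
        axes[0].set_xlabel("years")
        axes[0].set_ylabel("objective L")
        for key in ("W", "U", "Mc", "S"):
            axes[1].plot(frame["Years"], frame[key], "o-", label=key)
        axes[1].set_xlabel("years")
        axes[1].legend()
        fig.tight_layout()
        png_path = path / "trajectory.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written.append(png_path)
    return written
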