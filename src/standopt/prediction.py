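"""Stand-structure prediction: features, collinearity screening, pluggable
learners, PSO hyperparameter tuning, and the five-year update cycle.

Six per-tree prediction tasks drive the stand forward in time, applied
sequentially — age, diameter growth, height, mortality, crown width, crown
length — with the feature matrix refreshed between steps so each model
sees the already-updated state.  Diameter growth is modelled on the log
scale, ``ln(DGI + 1)`` with DGI the five-year diameter increment (cm), so
predictions are non-negative after the inverse transform.  A tree dies
when its predicted mortality probability exceeds 0.5 *and* it is under
high competition pressure (Hegyi index > 0.75).

The learner bank is pluggable: any estimator with the fit/predict (and
predict_proba for mortality) contract can be dropped in.  The shipped
defaults are gradient-boosted and random-forest ensembles chosen for
deterministic, accurate recovery of smooth growth laws; the per-task
feature sets are fixed, and candidate features with a variance inflation
factor above 10 are screened out before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import (GradientBoostingClassifier,
                              GradientBoostingRegressor,
                              RandomForestRegressor)
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import train_test_split
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .config import DEFAULT_CONFIG, StructureConfig
from .indexes import competition_covariates
from .stand import ASPECT_ORDINAL, Stand, Tree
from .synthetic import DEFAULT_LAW, KnownGrowthLaw

__all__ = [
    "FEATURE_SETS", "PredictorBank", "compute_features", "vif_filter",
    "fit_default_predictors", "pso_tune", "mortality_decision",
    "advance_stand",
]

#: Fixed per-task feature subsets.
FEATURE_SETS = {
    "age": ["DBH_inv", "H", "ASP", "SLO", "NT", "SDI"],
    "dbh": ["AGE", "ASP", "NT", "SLO", "SDI", "BAL", "DBH_sq"],
    "height": ["AGE", "ASP", "DBH", "SLO"],
    "cw": ["AGE", "DBH_inv", "CL", "ASP", "SDI", "HDR", "NT"],
    "cl": ["AGE", "DBH_inv", "ASP", "SDI", "HDR", "NT"],
    "mortality": ["DBH_inv", "H", "BAL", "HCI"],
}

_ALL_COLUMNS = ["AGE", "DBH", "DBH_inv", "DBH_sq", "H", "CW", "CL",
                "NT", "SDI", "SLO", "ASP", "HDR", "BAL", "HCI"]


def compute_features(stand: Stand) -> pd.DataFrame:
    """Per-living-tree feature matrix (indexed by tree id).

    Aspect is encoded as an eight-sector ordinal; NT, SDI and SLO repeat
    the stand-level values on every row.
    """
    cov = competition_covariates(stand)
    living = stand.living()
    asp = ASPECT_ORDINAL[stand.aspect]
    rows = []
    for t in living:
        rows.append({
            "id": t.id, "AGE": t.age, "DBH": t.dbh, "DBH_inv": 1.0 / t.dbh,
            "DBH_sq": t.dbh ** 2, "H": t.height, "CW": t.crown_width,
            "CL": t.crown_length, "NT": cov.nt, "SDI": cov.sdi,
            "SLO": stand.slope_deg, "ASP": asp,
            "HDR": t.height / t.dbh,
            "BAL": float(cov.table.loc[t.id, "BAL"]),
            "HCI": float(cov.table.loc[t.id, "HCI"]),
        })
    return pd.DataFrame(rows, columns=["id", *_ALL_COLUMNS]).set_index("id")


def vif_filter(matrix: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the highest-VIF column while any exceeds the cut.

    VIF_k = 1/(1 - R²_k) from regressing column k on the remaining
    columns (with intercept).  A singular design yields an infinite VIF
    and the first offending column (by column order) is dropped.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns for VIF screening")
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("need more rows than columns for VIF screening")
    kept = list(matrix.columns)
    while len(kept) >= 2:
        x = np.column_stack([matrix[kept].to_numpy(dtype=float),
                             np.ones(len(matrix))])
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(x, i)
                             for i in range(len(kept))])
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        if np.all(vifs <= threshold):
            break
        kept.pop(int(np.argmax(vifs)))
    return kept


@dataclass
class PredictorBank:
    """Fitted learners for the six prediction tasks plus metadata."""

    models: dict[str, object]
    features: dict[str, list[str]]
    metrics: dict[str, float]
    seed: int
    law: KnownGrowthLaw = field(default_factory=KnownGrowthLaw)

    def predict(self, task: str, frame: pd.DataFrame) -> np.ndarray:
        cols = self.features[task]
        x = frame[cols].to_numpy(dtype=float)
        model = self.models[task]
        if task == "mortality":
            return model.predict_proba(x)[:, 1]
        return model.predict(x)


def _training_rows(stands: list[Stand], law: KnownGrowthLaw
                   ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    frames = []
    for stand in stands:
        frames.append(compute_features(stand))
    x = pd.concat(frames, ignore_index=True)
    targets = {
        "age": x["AGE"].to_numpy(),
        "dbh": np.log1p(law.dgi(x["DBH"], x["AGE"], x["BAL"])),
        "height": np.asarray(law.height(x["DBH"], x["AGE"], x["SLO"])),
        "cw": np.asarray(law.crown_width(x["DBH"], x["AGE"])),
        "cl": np.asarray(law.crown_length(x["DBH"], x["AGE"], x["SLO"])),
        "mortality": np.asarray(law.dead(x["HCI"], x["DBH"]), dtype=int),
    }
    return x, targets


def fit_default_predictors(training_stands: list[Stand], seed: int = 0,
                           law: KnownGrowthLaw = DEFAULT_LAW,
                           vif_threshold: float = 10.0) -> PredictorBank:
    """Fit the default learner bank on pooled per-tree rows.

    Labels come from the analytic growth law the training stands were
    generated under, giving a recoverable truth; held-out metrics per task
    are stored.  Deterministic for a fixed seed.
    """
    x, targets = _training_rows(training_stands, law)
    if len(x) < 50:
        raise ValueError(f"need at least 50 training rows, got {len(x)}")
    factories = {
        "age": lambda: RandomForestRegressor(
            n_estimators=150, random_state=seed, n_jobs=1),
        "dbh": lambda: GradientBoostingRegressor(
            n_estimators=400, learning_rate=0.06, max_depth=3,
            random_state=seed),
        "height": lambda: RandomForestRegressor(
            n_estimators=200, random_state=seed, n_jobs=1),
        "cw": lambda: RandomForestRegressor(
            n_estimators=200, random_state=seed, n_jobs=1),
        "cl": lambda: GradientBoostingRegressor(
            n_estimators=300, learning_rate=0.08, max_depth=3,
            random_state=seed),
        "mortality": lambda: GradientBoostingClassifier(
            n_estimators=200, learning_rate=0.1, max_depth=3,
            random_state=seed),
    }
    models: dict[str, object] = {}
    features: dict[str, list[str]] = {}
    metrics: dict[str, float] = {}
    for task, factory in factories.items():
        cols = vif_filter(x[FEATURE_SETS[task]], vif_threshold)
        y = targets[task]
        if task == "mortality" and len(np.unique(y)) < 2:
            # nothing dies in the training window: degenerate but valid
            model = _ConstantClassifier(float(np.mean(y)))
            model.fit(None, None)
            models[task] = model
            features[task] = cols
            metrics[task] = 1.0
            continue
        xt, xv, yt, yv = train_test_split(
            x[cols].to_numpy(dtype=float), y, test_size=0.25,
            random_state=seed,
            stratify=y if task == "mortality" else None)
        model = factory()
        model.fit(xt, yt)
        if task == "mortality":
            metrics[task] = float(accuracy_score(yv, model.predict(xv)))
        else:
            metrics[task] = float(r2_score(yv, model.predict(xv)))
        models[task] = model
        features[task] = cols
    return PredictorBank(models=models, features=features, metrics=metrics,
                         seed=seed, law=law)


class _ConstantClassifier:
    """Fallback classifier when the training labels are single-class."""

    def __init__(self, p: float):
        self.p = p

    def fit(self, x, y):
        return self

    def predict_proba(self, x):
        n = len(x) if x is not None else 1
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])

    def predict(self, x):
        return (self.predict_proba(x)[:, 1] > 0.5).astype(int)


def pso_tune(objective, bounds: list[tuple[float, float]],
             swarm: int = 15, iterations: int = 60, seed: int = 0,
             inertia: float = 0.72, cognitive: float = 1.49,
             social: float = 1.49) -> tuple[np.ndarray, float]:
    """Canonical particle swarm minimisation over a box.

    Returns (best position, best objective).  Particles are clamped to
    the box; deterministic for a fixed seed.  Used to tune learner
    hyperparameters against a validation loss, but accepts any callable.
    """
    if not bounds:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    pos = lo + rng.random((swarm, len(bounds))) * (hi - lo)
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pval = np.array([objective(p) for p in pos], dtype=float)
    g = int(np.argmin(pval))
    gbest, gval = pbest[g].copy(), float(pval[g])
    for _ in range(iterations):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = (inertia * vel + cognitive * r1 * (pbest - pos)
               + social * r2 * (gbest - pos))
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([objective(p) for p in pos], dtype=float)
        better = vals < pval
        pbest[better] = pos[better]
        pval[better] = vals[better]
        g = int(np.argmin(pval))
        if pval[g] < gval:
            gbest, gval = pbest[g].copy(), float(pval[g])
    return gbest, gval


def mortality_decision(prob: float, hci: float,
                       hci_threshold: float = 0.75) -> bool:
    """Dead iff mortality probability > 0.5 and HCI above the pressure cut."""
    return prob > 0.5 and hci > hci_threshold


def advance_stand(stand: Stand, bank: PredictorBank,
                  config: StructureConfig = DEFAULT_CONFIG,
                  predict_age: bool = False,
                  hci_threshold: float = 0.75) -> Stand:
    """Advance every living tree five years through the prediction cycle.

    Order: age, diameter growth, height, mortality, crown width, crown
    length — recomputing the feature matrix between steps so later models
    see the updated state.  Ages advance deterministically by +5 unless
    ``predict_age`` (in simulation the age is known); diameter updates by
    ``exp(pred) - 1 >= 0``; trees flagged dead are excluded from the
    crown updates and all later structure computations.
    """
    trees = {t.id: t for t in stand.trees}

    # 1. age
    frame = compute_features(stand)
    if predict_age:
        ages = bank.predict("age", frame) + 5.0
        for tid, a in zip(frame.index, ages):
            trees[tid] = replace(trees[tid], age=float(a))
    else:
        for tid in frame.index:
            trees[tid] = replace(trees[tid], age=trees[tid].age + 5.0)
    stand = stand.with_trees(trees.values())

    # 2. diameter growth on the log scale
    frame = compute_features(stand)
    dgi = np.expm1(np.maximum(bank.predict("dbh", frame), 0.0))
    for tid, g in zip(frame.index, dgi):
        trees[tid] = replace(trees[tid], dbh=trees[tid].dbh + float(g))
    stand = stand.with_trees(trees.values())

    # 3. height
    frame = compute_features(stand)
    h = bank.predict("height", frame)
    for tid, v in zip(frame.index, h):
        t = trees[tid]
        trees[tid] = replace(t, height=float(max(v, t.height)),
                             crown_length=min(t.crown_length,
                                              float(max(v, t.height))))
    stand = stand.with_trees(trees.values())

    # 4. mortality
    frame = compute_features(stand)
    probs = bank.predict("mortality", frame)
    hci = frame["HCI"].to_numpy(dtype=float)
    for tid, p, c in zip(frame.index, probs, hci):
        if mortality_decision(float(p), float(c), hci_threshold):
            trees[tid] = replace(trees[tid], alive=False)
    stand = stand.with_trees(trees.values())

    # 5./6. crown width and crown length for survivors
    frame = compute_features(stand)
    cw = bank.predict("cw", frame)
    for tid, v in zip(frame.index, cw):
        trees[tid] = replace(trees[tid], crown_width=float(max(v, 0.2)))
    stand = stand.with_trees(trees.values())
    frame = compute_features(stand)
    cl = bank.predict("cl", frame)
    for tid, v in zip(frame.index, cl):
        t = trees[tid]
        trees[tid] = replace(t, crown_length=float(min(max(v, 0.1),
                                                       t.height)))
    return stand.with_trees(trees.values())
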