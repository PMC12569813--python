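"""Pinned synthetic benchmark conditions for the optimization experiments.

Five circular plots emulating the surveyed secondary-forest conditions:
12 m radius, densities spanning 2100-2800 stems/ha, a strongly dominant
conifer (88%, hence very low initial mingling), clumped regeneration
(moderately clustered positions), 15 degree slopes, and closed canopy
(cover >= 0.7, the constraint system's applicability precondition).  All
stands are deterministic functions of a seed, so every experiment is
exactly reproducible.
"""

from __future__ import annotations

from .config import StructureConfig
from .prediction import PredictorBank, fit_default_predictors
from .stand import Stand
from .synthetic import DEFAULT_LAW, generate_synthetic_stand

__all__ = ["BENCHMARK_DENSITIES", "benchmark_stand", "benchmark_bank",
           "benchmark_config", "comparison_stand"]


def benchmark_config() -> StructureConfig:
    """Structure configuration used by the optimization benchmarks.

    Disjoint crowns contribute zero overlap (``no_overlap_value=0``):
    under the literal unit-area sentinel, felling a stem creates fresh
    disjoint Voronoi pairs that each add a unit of "overlap", so thinning
    can *raise* the crown competition index and the thin-to-reduce-
    competition constraint clause becomes unsatisfiable; zero overlap for
    disjoint crowns restores the index's stated meaning.

    Reference trees start at the 6 cm diameter-class floor: freshly
    replanted 5 cm saplings contribute to their neighbours' mingling,
    size-dominance and competition but do not carry their own index
    values into the stand means until they grow past the class floor.
    Under the alternative (every sapling a reference tree immediately)
    each gap-centre sapling enters with a near-regular uniform-angle
    value, and any replanting large enough to raise stand mingling
    materially drives the mean uniform angle index far below the random
    band, contradicting the reported coexistence of heavy replanting
    with a stable horizontal pattern.
    """
    return StructureConfig(no_overlap_value=0.0, reference_min_dbh=6.0)

#: Per-plot densities (stems/ha) of the five benchmark plots.
BENCHMARK_DENSITIES = (2100.0, 2300.0, 2400.0, 2600.0, 2800.0)

#: Pinned generator seeds per plot.  Point-process realisations vary, so
#: the pinned plots are screened once to instantiate the intended study
#: conditions: closed canopy (Cd >= 0.72), a clustered horizontal pattern
#: (mean W in [0.515, 0.62], i.e. clearly above the random band so the
#: improvement clauses have slack), and low mingling (mean Mc <= 0.2).
_PLOT_SEEDS = (3, 2, 1, 4, 1)
_COMPARISON_SEED = 6


def benchmark_stand(plot: int = 0, seed: int = 1, radius_m: float = 12.0,
                    clustering: float = 0.6) -> Stand:
    """One of the five pinned benchmark plots (plot index 0-4).

    ``seed=1`` gives the screened reference plots; other seeds shift the
    realisation (unscreened).
    """
    density = BENCHMARK_DENSITIES[plot % len(BENCHMARK_DENSITIES)]
    return generate_synthetic_stand(
        radius_m=radius_m, density_per_ha=density, clustering=clustering,
        slope_deg=15.0, aspect="SE",
        seed=_PLOT_SEEDS[plot % len(_PLOT_SEEDS)] + 1000 * (seed - 1))


def comparison_stand(seed: int = 1) -> Stand:
    """The ~160-stem plot used for the MADQN vs MAQL comparison."""
    return generate_synthetic_stand(
        radius_m=14.5, density_per_ha=2400.0, clustering=0.6,
        slope_deg=15.0, aspect="SE",
        seed=_COMPARISON_SEED + 1000 * (seed - 1))


def benchmark_bank(seed: int = 1, n_stands: int = 10) -> PredictorBank:
    """Prediction bank trained on noiseless stands from the known law.

    Training stands span mean diameters 11-29 cm and densities
    1600-2800/ha so the learners cover the age/size/competition states a
    stand visits over several five-year cycles, not just its initial one.
    """
    stands = [generate_synthetic_stand(
        radius_m=12.0,
        density_per_ha=1600.0 + 1200.0 * (i % 4) / 3.0,
        clustering=0.4,
        mean_dbh_cm=11.0 + 18.0 * i / max(1, n_stands - 1),
        slope_deg=15.0, aspect="SE", seed=seed * 1000 + i,
        law=DEFAULT_LAW, noise_sd=0.0) for i in range(n_stands)]
    return fit_default_predictors(stands, seed=seed, law=DEFAULT_LAW)
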