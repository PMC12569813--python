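"""Seeded synthetic-stand generator and the reference growth law.

The generator emulates the surveyed circular plots of a *Pinus yunnanensis*
secondary forest: radii 12-35 m, densities ~1400-3900 stems/ha, mean DBH
13-21 cm, one strongly dominant conifer (low initial species mingling),
sloped terrain that gives each stem a relative elevation.  Positions come
from a point process whose single clustering parameter spans a jittered
lattice (regular), complete spatial randomness, and a Thomas cluster
process; diameters follow a two-parameter Weibull law shifted to the 5 cm
measurement threshold; heights and crowns follow the species allometries of
the replant model bank with lognormal noise.

`KnownGrowthLaw` is the analytic truth used by the simulation experiments:
deterministic height/crown allometries, a smooth five-year diameter
increment law, and a competition-threshold mortality rule.  Training the
prediction learners on stands generated under this law gives a
parameter-recovery benchmark with a closed-form oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .growth_models import REPLANT_SPECIES, evaluate_growth_model
from .stand import ASPECT_AZIMUTH, Stand, Tree

__all__ = ["generate_synthetic_stand", "KnownGrowthLaw", "DEFAULT_LAW"]

_WEIBULL_SHAPE = 2.2


@dataclass(frozen=True)
class KnownGrowthLaw:
    """Analytic growth truth for simulation benchmarks.

    The five-year diameter increment (DGI, cm) declines with age and with
    competition (basal area of larger neighbours, BAL) and saturates in
    size; mortality strikes trees whose Hegyi competition index exceeds a
    fixed threshold.  All member functions are deterministic.
    """

    dgi_scale: float = 5.5
    age_efold: float = 55.0
    bal_efold: float = 25.0
    size_half: float = 120.0
    #: Competition-mortality threshold.  The Hegyi index scales with the
    #: reciprocal of the subject's DBH, so a flat cut would kill roughly
    #: half of all 5 cm saplings per five-year step; the size adjustment
    #: (1 + 5/DBH) yields ~10% adult and ~15% sapling mortality, in line
    #: with typical secondary-forest self-thinning and planted-stock
    #: survival.
    hci_death: float = 7.0

    def height(self, dbh: np.ndarray | float, age, slope_deg) -> np.ndarray:
        dbh = np.asarray(dbh, dtype=float)
        age = np.asarray(age, dtype=float)
        return (1.3 + 0.85 * dbh ** 0.85
                * (1.0 + 0.08 * np.tanh(np.asarray(age) / 50.0))
                * np.exp(-np.asarray(slope_deg) / 400.0))

    def crown_width(self, dbh, age) -> np.ndarray:
        return 0.45 * np.asarray(dbh, dtype=float) ** 0.72

    def crown_length(self, dbh, age, slope_deg) -> np.ndarray:
        return 0.45 * self.height(dbh, age, slope_deg)

    def dgi(self, dbh, age, bal) -> np.ndarray:
        """Five-year diameter increment (cm) as a function of state."""
        dbh = np.asarray(dbh, dtype=float)
        return (self.dgi_scale
                * np.exp(-np.asarray(age, dtype=float) / self.age_efold)
                * np.exp(-np.asarray(bal, dtype=float) / self.bal_efold)
                * (1.0 - np.exp(-dbh ** 2 / self.size_half)))

    def dead(self, hci, dbh) -> np.ndarray:
        """Competition mortality with a size-adjusted threshold."""
        hci = np.asarray(hci, dtype=float)
        dbh = np.asarray(dbh, dtype=float)
        return hci > self.hci_death * (1.0 + 5.0 / dbh)

    def age_from_dbh(self, dbh) -> np.ndarray:
        return 5.0 + 2.4 * (np.asarray(dbh, dtype=float) - 5.0)


DEFAULT_LAW = KnownGrowthLaw()


def _positions(n: int, radius: float, clustering: float,
               rng: np.random.Generator) -> np.ndarray:
    """Point pattern in the plot disk; clustering in [-1, 1].

    -1 is a strict square lattice, 0 complete spatial randomness, +1 a
    tight Thomas cluster process; intermediate values interpolate.
    """
    if clustering < 0:
        spacing = math.sqrt(math.pi * radius ** 2 / n)
        m = int(math.ceil(2 * radius / spacing)) + 2
        ax = (np.arange(m) - (m - 1) / 2) * spacing
        gx, gy = np.meshgrid(ax, ax)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        jitter_sd = 0.5 * spacing * (1.0 + clustering)
        pts = pts + rng.normal(0.0, max(jitter_sd, 1e-9), size=pts.shape)
        inside = np.hypot(pts[:, 0], pts[:, 1]) <= radius * 0.999
        pts = pts[inside]
        if len(pts) >= n:
            idx = rng.permutation(len(pts))[:n]
            return pts[idx]
        extra = _positions(n - len(pts), radius, 0.0, rng)
        return np.vstack([pts, extra])
    if clustering == 0:
        r = radius * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2 * math.pi
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # Thomas process: parents uniform, offspring Gaussian around parents
    mean_cluster = 1.0 + 9.0 * clustering
    n_parents = max(1, int(round(n / mean_cluster)))
    pr = radius * np.sqrt(rng.random(n_parents))
    pt = rng.random(n_parents) * 2 * math.pi
    parents = np.column_stack([pr * np.cos(pt), pr * np.sin(pt)])
    sigma = radius * (0.30 - 0.22 * clustering)
    out = np.empty((n, 2))
    for i in range(n):
        parent = parents[rng.integers(n_parents)]
        for _ in range(100):
            p = parent + rng.normal(0.0, sigma, size=2)
            if math.hypot(p[0], p[1]) <= radius:
                out[i] = p
                break
        else:
            rr = radius * math.sqrt(rng.random())
            th = rng.random() * 2 * math.pi
            out[i] = (rr * math.cos(th), rr * math.sin(th))
    return out


def generate_synthetic_stand(
    radius_m: float,
    density_per_ha: float,
    species_mix: dict[str, float] | None = None,
    clustering: float = 0.0,
    slope_deg: float = 15.0,
    aspect: str = "SE",
    seed: int = 0,
    mean_dbh_cm: float = 16.0,
    noise_sd: float = 0.08,
    law: KnownGrowthLaw | None = None,
    survey_year: int | None = None,
) -> Stand:
    """Generate a deterministic synthetic circular plot.

    Parameters
    ----------
    radius_m, density_per_ha
        Plot radius (m) and target stem density (trees/ha, 500-5000); the
        tree count is ``round(density * area_ha)``.
    species_mix
        Proportions per species code summing to 1.  Default is a
        low-mingling secondary stand: 88% dominant conifer, the balance
        spread over the other native species.
    clustering
        Point-pattern parameter in [-1, 1]: -1 strict lattice, 0 random,
        +1 strongly clustered.
    slope_deg, aspect
        Terrain: a planar ramp rising opposite the aspect gives each stem
        its relative elevation (minimum shifted to zero).
    mean_dbh_cm, noise_sd
        Mean diameter of the Weibull size law and the lognormal noise sd
        applied to height/crown allometries.
    law
        If given, heights and crowns follow this analytic law exactly
        (plus noise), and ages are its deterministic age-diameter curve;
        used to build training data with a recoverable truth.
    """
    if not 500 <= density_per_ha <= 5000:
        raise ValueError("density_per_ha must lie in [500, 5000]")
    if species_mix is None:
        rest = (1.0 - 0.88) / (len(REPLANT_SPECIES) - 1)
        species_mix = {s: (0.88 if s == "pinus_yunnanensis" else rest)
                       for s in REPLANT_SPECIES}
    total = sum(species_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"species_mix proportions sum to {total}, not 1")
    area_ha = math.pi * radius_m ** 2 / 1e4
    n = int(round(density_per_ha * area_ha))
    if n < 3:
        raise ValueError(
            f"density {density_per_ha}/ha on a {radius_m} m plot yields "
            f"only {n} trees; infeasible")

    rng = np.random.default_rng(seed)
    pts = _positions(n, radius_m * 0.999, clustering, rng)

    names = list(species_mix)
    species = rng.choice(names, size=n, p=[species_mix[s] for s in names])

    lam = (mean_dbh_cm - 5.0) / math.gamma(1.0 + 1.0 / _WEIBULL_SHAPE)
    dbh = 5.0 + lam * rng.weibull(_WEIBULL_SHAPE, size=n)

    noise = np.exp(rng.normal(0.0, noise_sd, size=(3, n)))
    if law is not None:
        age = law.age_from_dbh(dbh)
        height = law.height(dbh, age, slope_deg) * noise[0]
        cw = law.crown_width(dbh, age) * noise[1]
        cl = law.crown_length(dbh, age, slope_deg) * noise[2]
    else:
        age = np.maximum(5.0, 5.0 + 2.4 * (dbh - 5.0)
                         + rng.normal(0.0, 3.0, size=n))
        height = np.empty(n)
        cw = np.empty(n)
        cl = np.empty(n)
        for i in range(n):
            sp = species[i] if (species[i], "H") in _bank_keys() else \
                "pinus_yunnanensis"
            height[i] = evaluate_growth_model(sp, "H", dbh[i]) * noise[0, i]
            cw[i] = evaluate_growth_model(sp, "CW", dbh[i]) * noise[1, i]
            cl[i] = evaluate_growth_model(sp, "CL", dbh[i]) * noise[2, i]
    # allometric sanity clamps: a few published crown models are pinned at
    # the 5 cm replant diameter and extrapolate wildly at field diameters
    height = np.minimum(height, 40.0)
    cw = np.clip(cw, 0.2, 0.35 * dbh)
    cl = np.minimum(cl, height)

    # planar terrain ramp; datum shifts the minimum to zero
    az = math.radians(ASPECT_AZIMUTH[aspect])
    ramp = -(pts[:, 0] * math.sin(az) + pts[:, 1] * math.cos(az)) \
        * math.tan(math.radians(slope_deg))
    datum = float(ramp.min())

    trees = [
        Tree(id=i + 1, species=str(species[i]), x=float(pts[i, 0]),
             y=float(pts[i, 1]), dbh=float(dbh[i]), height=float(height[i]),
             crown_width=float(cw[i]), crown_length=float(cl[i]),
             age=float(age[i]), rel_elev=float(ramp[i] - datum))
        for i in range(n)
    ]
    stand = Stand(radius=radius_m, slope_deg=slope_deg, aspect=aspect,
                  trees=trees, survey_year=survey_year, elev_datum=datum)
    stand.validate()
    return stand


def _bank_keys():
    from .growth_models import load_model_bank
    return load_model_bank()
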