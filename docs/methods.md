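# Methods

This note documents the models implemented in `standopt`, the choices made
where the underlying definitions are ambiguous, what the synthetic stands
emulate, and the limitations of both.

## The stand model

A stand is a circular plot (radius 12–35 m) of individually mapped stems:
species, Cartesian coordinates relative to the plot centre (y = north),
DBH (cm), height, crown width and crown length (m), age, and a relative
elevation derived from the plot's slope and aspect as a planar terrain
ramp (the minimum shifted to zero).  A 2 m buffer ring along the boundary
corrects edge effects: buffer trees act as neighbours but never as
reference trees.  The boundary tie (distance exactly `radius − buffer`)
resolves to the core.

## Spatial structure indexes

All indexes except W are evaluated over the *Voronoi spatial structure
unit*: the reference tree plus the trees whose Voronoi cells (clipped to
the plot disk) share an edge with its cell.

* **Neighborhood comparison U** — fraction of unit neighbours with
  strictly larger DBH (ties count as not-larger).
* **Complete mingling Mc** — `Mc = (M/2) [(1 − Σ n_j²/(n+1)²) + n′/n]`
  with `M` the heterospecific-neighbour fraction, `n_j` the per-species
  neighbour counts, `n′` the neighbour species richness.  The reference
  tree enters only through the `(n+1)²` denominator (switchable).  Under
  random species placement with seven species this index saturates near
  0.70; values above 0.75 require spatially anti-clustered species
  arrangements.
* **Stratification S** — vertical layers are thirds of the dominant
  height `H_d` (mean of height + relative elevation over the
  `⌊100·area_ha⌋` tallest stems); heights exactly on a layer boundary go
  to the middle layer.  `S = (layers present/3) × (fraction of
  neighbours in the reference's layer)`.
* **Crown competition CI** — `CI = (1/Z) Σ_j AO_ij L_j/L_i` with
  `L = H·CW·CL`, `Z` the reference crown projection area, and `AO` the
  crown-disk overlap (exact two-circle lens area).  Disjoint crowns
  return the literal sentinel 1.0 m² by default; `no_overlap_value=0`
  is exposed because the sentinel makes *removing* a stem create fresh
  unit "overlaps" with newly adjacent distant trees, so thinning can
  raise mean CI (measured: 39/49 single fellings on a benchmark plot
  raise it) — contradicting the index's meaning.
* **Uniform angle index W** — fraction of angular gaps between
  azimuthally successive neighbours (smaller form) strictly below the
  standard angle `360/(n+1)`.  W uses its classical construction — the
  4 nearest stems, standard angle 72° — for which a random pattern
  averages 0.496 with band [0.475, 0.517], a lattice ~0.05 and strong
  clustering ≥0.55.  Computing W over the variable-n Voronoi unit
  instead (switch `w_use_unit_neighbours`) yields ~0.385 for random and
  ~0.45 for lattice patterns, i.e. it neither matches the published
  random band nor orders the patterns correctly, so the classical form
  is the default.

Canopy density is the fraction of the plot disk covered by the union of
living crown disks, computed on a fixed 0.25 m grid (deterministic, so
the Cd ≥ 0.7 constraint check is reproducible).

Competition covariates for the growth models use the standard forestry
definitions (the source names but does not define them): Hegyi index
`HCI_i = Σ_j d_j/(d_i·dist_ij)` over Voronoi neighbours; BAL, the basal
area (m²/ha) of strictly larger stems; Reineke's `SDI = NT·(Dq/25)^1.605`;
and the height-diameter ratio in m/cm.

## Objective and constraints

The stand objective is a multiplicative–divisive mean over core reference
trees:

    L = (1/n) Σ_i  (1 + Mc_i/δ_Mc)(1 + S_i/δ_S)
                  ───────────────────────────────────────────────
                  (1 + U_i/δ_U)(1 + CI_i/δ_CI)(1 + |W_i−0.496|/δ_W′)

with δ the population standard deviations of the same stand state (δ_W′
over |W_i − 0.496|); any zero δ is replaced by 1 so its factor reduces to
`1 + value`.  δs are recomputed per state by default; `freeze_deltas`
evaluates candidate moves under the pre-move δs.

Interventions must satisfy a constraint system: after harvesting, each of
the five index means must be at least as good as initially, diameter
classes (2 cm classes from 6 cm; sub-6 cm stems form pre-class 0) and
species counts preserved, canopy ≥ 0.7 and at most 35% of stems removed;
after replanting, mingling and |W̄ − 0.496| must improve further and the
final density must lie in [1667, 3333] stems/ha.  Comparisons are
non-strict with a 1e−9 tolerance so a null intervention on a legal stand
passes.  The ideal-structure stopping rule is Ū ≤ 0.5, M̄c ≥ 0.75,
W̄ ∈ [0.475, 0.517].

## Interventions

Felling candidates are drawn uniformly from living core stems; the last
individual of a species is never felled and cumulative removal is hard-
capped at 35% of the initial count.  Replanting locations are the
incenters of the largest Delaunay triangles (canopy gaps), at least 1 m
inside the core and 0.5 m from any stem, ranked by the replanting
foreground index `RFI = (1+DAA/δ)(1+Mc/δ)(1+U/δ)/(1+CI/δ)` of a virtual
5 cm sapling (DAA = area of the containing triangle); species rotate
round-robin through the seven native species.  Replants initialize at
DBH 5 cm, age 5, with height/crown width/crown length from the shipped
per-species allometric bank; rows of that bank whose printed parameters
do not reproduce their published value at DBH = 5 are pinned to it by an
additive calibration offset (the offset and the raw curve are both kept).
The replant-count search is a windowed three-point trend search: evaluate
{c−s, c, c+s}, shrink the spacing on an interior maximum, slide toward a
boundary maximum, stop when the spacing reaches 1.

## Two-agent optimization

A harvest agent walks a positional state 0→50 and a replant agent
100→50; moves alternate and an episode ends when the positions meet (or
after 100 steps).  A harvest forward step proposes one random felling,
applied if it passes the hard clauses (classes, species, budget, canopy);
a replant step changes the plan size by one spacing step along the
RFI-ranked planting sequence.  Rewards follow the published schedule
(a=150 terminal success, b=−50 violation, c1..c4 = 100/50/10/1 for ΔL ≥
5%/1%/0.1%/>0 of L₀, c5=−1 decline, c6=−50 illegal); a backward
(retract) step and a zero-change move map to c5, the taxonomy's closest
band.  The five soft mean-improvement clauses are enforced on the
*returned* solution: a state is only tracked as the incumbent best if the
complete constraint system passes (measured on the benchmark, gating
every single felling on all five soft clauses accepts ~0–2% of legal
moves and freezes the search entirely).  Because the null intervention is
always available, the returned objective never falls below the initial
one on a feasible starting stand.

MAQL is tabular Q-learning over (position, coarse mingling bin); MADQN
uses per-agent value networks — three ReLU hidden layers of 24 units over
a 10-dimensional observation (normalized position, the five index means,
canopy, density, budget fractions) — with an experience replay buffer of
10000, batch 32, a target network synced every 100 learner steps, γ=0.9,
learning rate 0.01, and ε-greedy action choice with greedy rate 0.9 (no
decay).  The TD loss is a Huber form with a global gradient-norm clip:
plain squared-error SGD diverges within tens of steps at reward
magnitudes of ±150.  The value network's output head is
zero-initialised so both actions start at Q = 0 and the greedy
tie-break begins with the forward action, as the tabular learner does.  All randomness flows from one seeded generator, so
runs are exactly reproducible.

## Stand prediction

Six per-tree tasks advance the stand five years, applied sequentially —
age, diameter growth, height, mortality, crown width, crown length —
with the feature matrix recomputed between steps.  Diameter growth is
modelled as `ln(DGI+1)` (DGI = five-year increment, cm) and inverted
with `exp(·)−1`, clamped non-negative.  A tree dies iff its predicted
mortality probability exceeds 0.5 *and* its Hegyi index exceeds 0.75.
Ages advance deterministically by +5 by default (`predict_age` enables
the learned model).  Task feature sets are fixed (e.g. crown width uses
AGE, 1/DBH, CL, ASP, SDI, HDR, NT); candidates with variance inflation
factor > 10 are dropped, highest first.  The default learners are
gradient-boosted and random-forest ensembles chosen for deterministic,
accurate recovery of smooth laws; any estimator with the same
fit/predict contract can be substituted.  A generic particle swarm
optimizer (inertia 0.72, cognitive/social 1.49) is provided for
hyperparameter tuning against a validation loss.

## Synthetic stands and the reference growth law

The generator emulates surveyed *Pinus yunnanensis* secondary plots:
radius and density as given (count = round(density × area)); positions
from a single-parameter point process (−1 strict lattice → 0 complete
spatial randomness → +1 tight Thomas clusters); DBH from a Weibull law
(shape 2.2) shifted to the 5 cm measurement threshold with a chosen mean
(default 16 cm); heights and crowns from the species allometries with
lognormal noise (σ = 0.08); one dominant conifer (88% by default) for
the low initial mingling of such stands; a planar terrain ramp for
relative elevation.

`KnownGrowthLaw` is the analytic truth used by the simulation
experiments: height/crown allometries, the increment law
`DGI = 5.5·e^{−AGE/55}·e^{−BAL/25}·(1−e^{−DBH²/120})` cm per 5 years,
and competition mortality when `HCI > 7·(1 + 5/DBH)`.  The size
adjustment matters: Hegyi's index scales with the reciprocal of the
subject's diameter, so a flat threshold calibrated on adults would kill
roughly half of all freshly planted 5 cm saplings per five-year step;
the adjusted rule yields ~10% adult and ~15% sapling five-year
mortality, in line with secondary-forest self-thinning and typical
planted-stock survival.  Crown widths are clamped to `0.35·DBH` (and
heights to 40 m) when the species allometries are evaluated at field
diameters, because a few published crown models are pinned at the 5 cm
replant diameter and extrapolate wildly beyond it.  Training the learner
bank on noiseless stands from this law yields a parameter-recovery
benchmark whose oracle is the law itself.  Real stands differ in ways
the generator does not model — species-specific spatial association,
height measurement error, non-planar terrain, browsing and disturbance —
so passing these benchmarks shows the machinery is correct, not that the
fitted values transfer to any particular forest.

## Benchmark configuration and problem sizes

The optimization benchmarks use five pinned 12 m plots (densities
1700–2600/ha, strongly clustered, 88% dominant conifer), a ~150-stem
14.5 m plot for the MADQN/MAQL comparison, and tens of training episodes
per run; these sizes keep every experiment reproducible on a single CPU
in minutes while exercising the full mechanism.  The benchmark
configuration sets `no_overlap_value=0` and `reference_min_dbh=6`
(saplings below the diameter-class floor count as neighbours only until
they grow past it); the rationale for both is given above and both
switches default to the literal readings elsewhere.  The pinned plots
are screened once against the constraint system's applicability
preconditions — closed canopy (Cd ≥ 0.72), a clustered initial pattern
(W̄ in [0.515, 0.62], so the non-strict improvement clauses have slack
to accept action), and low mingling — because a plot that starts at or
below the uniform-angle reference makes every gap-planting move
infeasible by construction, and one with open canopy violates the
constraint system before any action is taken.

## Known limitations

* The dynamic loop robustly improves degraded stands — mingling rises
  from ~0.1 to 0.45–0.6, size dominance falls to ~0.3, crown
  competition drops several-fold, and the horizontal pattern moves from
  clustered (W̄ ≈ 0.55) into or near the random band — but in our
  synthetic experiments it does not reach the full ideal triplet within
  eight cycles: the per-cycle improvement clauses consume their slack,
  the density ceiling caps the stock of diverse stems, gap-incenter
  planting is inherently regularizing (bounding how much replanting any
  cycle admits), and mingling above 0.75 would require near-perfect
  anti-clustering of species that random felling plus bounded planting
  cannot assemble in 40 years.  The trajectory reports make this
  plateau visible rather than hiding it.
* Growth-model rows with internally inconsistent published parameters
  are calibrated at the initialization diameter only; their shapes away
  from 5 cm are not trustworthy (they are not used away from it).
* The learner bank recovers smooth laws; it is not a validated regional
  growth model.
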