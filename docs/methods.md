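# Methods

`enzopt` simulates and benchmarks closed-loop optimization of enzymatic
reaction conditions. This note records the models, the defaults and why
they are what they are, the numerical choices, and the limits of what the
simulations can show.

## The optimization problem

The objective is the initial specific enzymatic activity v (U mg⁻¹) as a
function of five reaction parameters: pH, temperature (°C), added salt
(Na₂SO₄, mM), organic co-solvent (acetonitrile, %(v/v)), and cosubstrate
(H₂O₂, mM). Activities are measured in batches of eight conditions per
cycle (one multichannel-pipetting round on a 96-well plate), and each
measurement carries multiplicative assay noise with a coefficient of
variation (CV) of about 13 %. An optimization campaign starts from a Latin
hypercube batch, and each subsequent batch is proposed by an
experiment-planning strategy from everything measured so far. Campaigns
stop when a target activity is exceeded, when the best-so-far value
improves by less than 5 % over the last 5 cycles, when the cycle budget is
spent, or when a discrete search space is exhausted.

Two search-space variants are built in: the continuous screening box
(pH 2.5–8, 20–60 °C, 0–500 mM, 0–30 %(v/v), 0–10 mM) and the discretized
deployment grid (pH 2.4–8 step 0.2; temperature step 2; salt step 25;
solvent step 2.5; cosubstrate step 0.2 — about 8.5 million grid points).
Intervals are closed; snapping to a grid takes the nearest level with ties
broken toward the lower level (a deterministic rule; any fixed tie-break
would do, but reproducibility needs one).

## Landscapes

A `Landscape` is any deterministic map from a condition to a clean
activity; noise is always applied outside it, so a campaign's randomness is
fully controlled by seeds.

**Interpolated surrogate.** Scattered screening data are averaged per
condition over replicates (arithmetic mean) and interpolated
piecewise-linearly over a Delaunay triangulation. Coordinates are mapped to
the unit cube before triangulating: a linear interpolant's values at the
data points are unaffected by the affine map, but the triangulation of
raw coordinates spanning 5.6 pH units × 500 mM is badly conditioned.
Queries outside the convex hull either raise (`policy="error"`) or fall
back to the nearest data point (`policy="nearest"`, the default): campaigns
legitimately probe box corners that scattered screening data do not span,
and clamping to the nearest observed activity is the least-surprising
extension. The interpolant is exact at every data point and bounded by the
data range.

**Synthetic landscape.** For tests and self-contained runs the package
ships a multiplicative five-factor landscape,
`A(x) = A_max · Π_i m_i(x_i)`, with every factor multiplier in [0, 1] and
equal to 1 only at that factor's optimum, giving a single global optimum at
(pH 3.5, 30 °C, 125 mM salt, 0 % solvent, 8.75 mM cosubstrate) with
`A_max = 790.4` U mg⁻¹ (the peak screening activity of the emulated
system). The factor shapes emulate what the screening projections show:

* pH and temperature: two-sided Gaussians (bell curves with different
  widths left and right of the optimum), calibrated so the relative
  activity is 61.1 % at pH 2.4, 2.0 % at pH 8, 85.5 % at 20 °C and 10.2 %
  at 60 °C;
* solvent: exponential decay with τ = 9.879 %(v/v), i.e. 4.8 % remaining
  at 30 %(v/v);
* salt: a mild two-sided quadratic about 125 mM (87.2 % at 0 mM, 64.8 % at
  500 mM);
* cosubstrate: a Michaelis-type saturation (K = 1 mM) rescaled to reach 1
  at 8.75 mM, then a linear decline of 0.0952 per mM (88.1 % at 10 mM).
  The rise-then-decline reflects rate enhancement by H₂O₂ at low
  concentration and oxidative enzyme inactivation beyond the optimum.

The solvent optimum sits on the lower boundary (activity is maximal
without co-solvent); all other factor optima are strictly interior, so the
landscape's argmax is unique. Construction rejects parameter sets that
break this (e.g. a zero post-peak cosubstrate slope).

The synthetic landscape reproduces the *one-dimensional* anchor
percentages and the single-optimum topology. It does not reproduce
parameter *interactions* (its factors are separable by construction),
the irregular simplex geometry of a real scattered-data interpolant, or
heteroscedastic noise. Campaign-level conclusions drawn on it (e.g. "BO
beats random search") therefore demonstrate correct mechanics and sensible
relative behaviour, not quantitative agreement with any particular real
dataset.

**Noise.** Measured activity = clean activity × (1 + u), u ~
Uniform(−cv, +cv), cv = 0.132 by default. The half-width is equated with
the reported assay CV; the noise is symmetric and mean-preserving. An
additive reading of "uniform noise in the range of 13.2 %" would break the
scale-invariance that a CV implies, so the multiplicative reading is used.

**Synthetic screening protocol.** `generate_synthetic_dataset` emits
duplicate (n = 2) noisy observations per design point. The emulated
screening runs three sequential 3-level full-factorial designs (3⁵ = 243
points each), halving and recentring the ranges on the best replicate-mean
condition after each round; recentring shifts (never shrinks) the new
interval back inside the global box so conditions stay feasible. The
plate-execution helper (`chunk_design`) sorts a design by pH and
temperature, splits it into near-equal contiguous chunks, adds the centre
point to every chunk as a repeated control, and shuffles each chunk with a
seeded permutation. Chunk count and centre-replication are parameters: the
exact per-plate accounting of a physical screening run (which also depends
on labware) is not reconstructible from design arithmetic alone.

## Gaussian-process surrogate and batch BO

The GP works on a normalized problem: inputs scaled to the unit cube by the
*global* box, outputs min–max scaled to [0, 1] over the current history
(an all-equal history maps to 0.5). Normalization is what makes the two
fixed constants meaningful: the homoscedastic noise variance 0.02 on the
unit output scale corresponds to a 13–15 % CV near the top of the range,
and the posterior-variance convergence band 0.01–0.0225 is that same noise
floor. The nugget should mirror the actual measurement noise: campaigns
simulated *without* noise use a jitter-level nugget (1e-6) instead — an
inflated nugget makes sub-2 % improvements statistically invisible and
stalls exploitation one grid step short of the optimum. The kernel amplitude is pinned at 1 (unit prior variance, zero prior
mean); only the isotropic length scale is fitted, by log-marginal-likelihood
maximization restarted from 10 seeded random points (scikit-learn's
`GaussianProcessRegressor` underneath). Kernels: Matérn ν = 1/2, 3/2, 5/2
and squared-exponential; the default variant is Matérn 3/2 with expected
improvement.

Acquisition functions operate on the scaled outputs with the incumbent
`best` = max scaled observation (= 1 under min–max scaling of real
history): EI with offset ξ = 0.01, PI with the same ξ, UCB with κ = 2.0
("typical literature values"; the screening that selected the variant did
not tune them). Degenerate sd = 0 cases reduce to their limits
(max(μ−best−ξ, 0), an indicator, and μ respectively).

Batches of q = 8 use the Kriging-believer construction: evaluate the
acquisition on every untested grid candidate, take the argmax (ties go to
the first candidate in deterministic grid order), append the posterior
mean at the chosen point as a pseudo-observation, update the posterior,
and repeat. Kernel hyperparameters are *not* re-optimized inside a batch —
only once per cycle — trading a slight staleness for stability and an
8-fold cost saving; pseudo-observations are discarded once the batch is
chosen. On grids too large to enumerate (above 200,000 points) each
believer step scores a seeded uniform subsample (100,000 candidates by
default, configurable via `candidate_subsample`); this is a documented
deviation knob, exhaustive evaluation remains available.

The posterior variance reported by `mean_posterior_variance` is the
*latent* predictive variance (noise variance not added), averaged over a
seeded 1,000-point grid sample. With one observation per location and unit
prior amplitude the latent variance at a training point is
σ²/(1+σ²) ≈ 0.0196 for σ² = 0.02, so a saturated model sits inside the
0.01–0.0225 convergence band; adding the noise term would instead floor
the statistic at 0.02 and blur the band's lower half.

## Stochastic strategies

All strategies operate on the discrete grid (proposals are clipped to the
box and snapped), keep population = batch size = 8, and obey a global
no-repeat rule: a proposal colliding with anything already tested is
re-drawn by the strategy's own variation operator (up to 100 attempts) and
finally replaced by a seeded random untested grid point.

* **GA** — linear rank selection (probability i/Σranks for the i-th worst
  of n), crossover either per-gene uniform ("random") or single seeded cut
  point, per-gene mutation with probability p adding
  Uniform(−extent, +extent) × range. The top `elitism` individuals carry
  into the next generation with their recorded scores; their experiments
  are not re-spent, so a GA cycle measures 8 − elitism new conditions.
  Defaults (elitism 2, p 0.4, extent 0.3, random crossover, rank
  selection) are the best-ranked screened variant.
* **PSO** — canonical global-best update
  v ← w·v + c₁r₁∘(pbest−x) + c₂r₂∘(gbest−x) with per-dimension U(0,1)
  draws, velocity clipped to ± the parameter range, inertia decaying
  geometrically (w ← w·c_d) each cycle. A particle landing on a tested
  condition is jittered by one grid step in a seeded random dimension.
  Defaults: w₀ 0.9, c_d 0.95, c₁ 2.5, c₂ 1.0.
* **SA** — eight independent walkers; proposals add
  Uniform(−S₀, +S₀) × range per dimension; after measurement a worse move
  is accepted with probability exp(Δ/T), T = T₀·c_T^k cooling once per
  cycle, Δ in raw activity units. Step size stays at S₀ (no schedule — the
  screened variants varied only T₀, c_T, S₀). Defaults: T₀ 380, c_T 0.7,
  S₀ 0.8.
* **RS** — seeded uniform draws of untested grid points; the unguided
  baseline.

## RSM baseline

Three rounds of a face-centred central composite design: 2⁵ corner points,
10 axial face points (α = 1, so every point stays in bounds), and 8 centre
replicates — 50 experiments per round, 150 in total. The 8 centre
replicates are an inference: the classical CCD for d = 5 fixes 42
corner+axial runs, and equal 50-point rounds over a 150-experiment budget
leave 8 centre runs. After each round a full quadratic interaction model
(21 coefficients for d = 5, inputs scaled to [−1, 1] within the round's
bounds, ordinary least squares) is fitted; its argmax over a dense grid
scan (21 levels per dimension by default) recentres the region, which is
then halved per dimension, clamped to the global box. RSM follows a fixed
design, so repeated runs differ only through measurement noise; centre
replicates are intentional repeats and the no-repeat rule is waived.
Degenerate fits: a constant response reports R² = 1 with a
`degenerate_variance` flag (zero residual over zero variance); fewer
observations than coefficients yields the minimum-norm solution with a
`rank_deficient` flag.

## Campaigns and benchmarking

Cycle 0 is the initial batch; `max_iterations` counts batches including
it, so "400 experiments (50 iterations)" is 50 batches of 8. Convergence
compares best-so-far now against best-so-far `window` cycles earlier:
relative improvement < threshold (default 5 % over 5 cycles) stops the
campaign. The "iterations until convergence" statistic reported by the
benchmark excludes cycle 0; campaign manifests record both conventions.

Benchmarks evaluate each algorithm variant on the identical shared initial
LHS sets (30 in the reference protocol), with per-set seeds derived from a
master seed, so iteration-0 batches and noise streams match across
variants set-by-set. Aggregates are means and sample (n−1) SDs of the best
activity and of cycles-to-stop; ranking is by mean best activity, ties
broken by fewer mean cycles, then label (the reference reports both
metrics without naming its sort key; mean best is the natural primary).
Per-cell results can be cached to disk keyed by a content hash for
resumable screens.

All randomness flows from explicit seeds through named substreams
(initial sets, noise, proposals); there is no global-state RNG, and a
campaign re-run with the same configuration is bit-identical.

## Assay arithmetic

Buffer recipes follow the stock-dilution equations: each additive volume is
(target/stock) × V_total with defaults V_total = 200 µL, substrate aliquot
20 µL, stocks 2 M Na₂SO₄, 100 mM H₂O₂, 100 %(v/v) ACN; the low-salt buffer
takes up the remainder. As printed, the enzyme aliquot is *not* subtracted
from the make-up volume; because the deployment protocol dispenses 20 µL
substrate *and* 20 µL enzyme, a `subtract_enzyme_volume` switch (default
off) is provided. A negative make-up volume raises an infeasible-recipe
error naming the condition; over the default box with default stocks no
condition is infeasible (worst corner leaves 50 µL).

Buffer volumes split into 0.1 M citric acid and 0.2 M Na₂HPO₄ parts via an
embedded McIlvaine mixing table (pH 2.2–8.0 in 0.2 steps), linearly
interpolated between entries; the two parts sum to the input volume
exactly, and the citrate fraction decreases monotonically with pH.

Concentrations come from Beer–Lambert, c = ΔA/(ε·d), with user-supplied
extinction coefficients (no credible default exists; negative
concentrations from noisy blanks pass through for the caller to flag).
Specific activity is v = c/(t·c_enzyme): for µmol-based units c in mM is
µmol mL⁻¹ and t is in minutes; for the pyrogallol convention (1 U oxidizes
1 mg pyrogallol in 20 s) c converts to mg mL⁻¹ via M = 126.11 g mol⁻¹ and
t counts 20-s blocks. Assay presets cover the four screened enzyme–
substrate pairings (UPO–ABTS, HRP–ABTS, HRP–pyrogallol, HRP–TMB).

## Problem sizes in the shipped checks

The test suite exercises campaign behaviour on a coarse 9×9×9×7×11 grid
(56,133 points — small enough for exhaustive argmax scans) and the
acceptance script runs the full pipeline at reduced replication: a
three-round synthetic factorial screening (729 design points, duplicates),
campaigns over 15 shared initial sets for 13 batches (104 experiments)
with a 5,000-candidate believer subsample on the full deployment grid, and
10 RSM repeats with an 11-level argmax scan. These sizes are the package's
own defaults for a self-contained demonstration; every one of them is a
parameter.

## Known limitations

* The synthetic landscape has separable factors; real screening data show
  interactions (that is precisely why RSM's quadratic model underperforms
  on them), so algorithm rankings measured on the synthetic landscape need
  not transfer quantitatively.
* The GP uses a single isotropic length scale on the unit cube;
  per-dimension (ARD) length scales and heteroscedastic noise are not
  implemented.
* SA fills batches with independent walkers; coupled-walker or
  temperature-ladder variants are out of scope.
* Checks that verify published statistics of the deposited screening
  dataset require that dataset locally (`data/htps_screening.csv`); they
  fail with an explanatory message when it is absent rather than being
  skipped.
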