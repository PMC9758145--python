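# Methods

`protonarc` optimizes proton arc pencil-beam-scanning (PBS) treatment plans
in which every gantry control point delivers exactly one energy layer, with
optional per-beamlet trimmer collimation. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## The optimization problem

An arc delivery couples gantry angle and beam energy: the arc is discretized
into control points, and each control point carries a single energy (a
single range in water). A plan therefore has two coupled unknowns:

1. the energy-layer assignment per control point — a combinatorial choice;
2. the non-negative beamlet (spot) weights — a continuous fluence problem.

The package solves the combinatorial part with a staged genetic algorithm
and the continuous part, inside every fitness evaluation, with
projected-gradient descent on a DVH-penalty objective.

### Objective

For structures k with voxel sets τ_k (T_k voxels):

F = Σ_k (1/T_k) Σ_{i∈τ_k} [ β⁺ c²₍₀,∞₎(d_i − d⁺) + β⁻ c²₍₋∞,₀₎(d_i − d⁻)
    + β^{V+} c²₍₀,ΔD^{V+}₎(d_i − d^{V+}) + β^{V−} c²₍ΔD^{V−},0₎(d_i − d^{V−}) ]

where c₍a,b₎(x) zeroes the residual outside [a, b]. The dose-volume window
ΔD^{V±} is the gap between the current dose at volume level V and the
desired threshold, so the penalty targets only the voxels cheapest to move.
All constraints are soft; weights β ≥ 0.

Numerical choices:

* **Window freezing.** ΔD^{V±} is recomputed at every outer iterate of the
  weight optimizer and held fixed through the backtracking line search. The
  gradient ignores the (weak) dependence of ΔD on the dose, the standard
  treatment for DVH penalties.
* **Monotonicity guarantee.** The weight optimizer tracks the true F at
  every iterate and returns the best one, so F never increases across a
  call regardless of window refreezing.
* **Step size.** Each projected-gradient step starts from the exact
  minimizer of the local quadratic model along the negative gradient
  (Gauss–Newton curvature over the currently active penalty voxels) and
  backtracks by halving until the frozen objective decreases. This makes
  the method scale-free in both dose and weight units.
* **D(V) conventions.** For penalties and normalization, the dose at volume
  V is rank-interpolated from the sorted voxel doses (the i-th hottest voxel
  sits at volume 100·i/n %). Reported DVH metrics (D2, D50, D90, D95) are
  read by linear interpolation from binned cumulative curves (0.1 Gy bins);
  Dmean always comes from raw voxel doses.

### Genetic optimizer

A chromosome is a haploid vector: one energy-layer index per control point.
Per generation: every member's weights are re-optimized (warm-started) and
ranked by F; the best member (alpha) is cloned into the next generation;
the worst R members (runts) are replaced by freshly randomized members;
every remaining member produces one child by uniform per-locus
recombination with a partner drawn with rank-linear probability
p(rank r) = 2(P − r + 1)/(P(P + 1)), self excluded.

The arc resolution refines in stages: stage s spans the arc with 2^s + 1
evenly spaced control points (3, 5, 9, …, 129 for seven stages), each new
stage inserting midpoints. The alpha of a finished stage carries over; its
loci at carried angles are locked for the rest of the run, so each stage
optimizes only the newly inserted angles while all weights remain free.

Defaults (all configurable): population P = 10, G = 15 generations per
stage, R = 2 runts, 25 weight-optimizer iterations per generation, 5 stages
at desk scale (7 matches the 129-control-point geometry). Per-generation
weight optimization is deliberately truncated for throughput; the returned
plan's weights receive a final converged optimization (500 iterations),
re-run after trimmer assignment when collimation is enabled. Rank-linear
(rather than fitness-inverse) mating keeps selection pressure invariant
under objective rescaling. All randomness flows from one seed through named
streams (init / partner / mating / runts), so the pipeline is a pure
function of (configuration, seed) and changing one subsystem cannot shift
another's draws.

### Collimation

Trimmer collimation is applied after the genetic search, to the final
chromosome only, one beamlet at a time: each lateral side (beam's-eye-view
x and y) is trimmed at the target cross-section boundary whenever that
boundary lies within 3σ of the spot centre (σ at the Bragg peak); farther
sides stay open, so interior spots are untouched. The weights are then
re-optimized and the plan re-normalized. Whether the original study
re-ran the full genetic search after adding collimation is not determinable
from its description; re-optimizing weights only is the cheaper and, in our
runs, sufficient choice.

## Dose model

The engine is an analytic pencil-beam model, deliberately simple but with
every property the optimizer exploits.

* **Depth dose.** A Bortfeld-style analytic pristine Bragg curve
  (parabolic-cylinder functions; p = 1.77, α = 0.0022, β = 0.012 cm⁻¹,
  γ = 0.6, ε = 0.2) evaluated at water-equivalent depth. Range straggling
  σ = 0.012·R^0.935 cm is combined in quadrature with a beam-line range
  spread (default 0.2 cm) modelling momentum spread — without it,
  sub-millimetre straggling at shallow ranges (< 8 cm) would scallop any
  SOBP built on 5 mm layer spacing. More than 10σ upstream of the range the
  straggled form is replaced by its exact power-law asymptote to avoid
  overflow.
* **Lateral profile.** Bivariate Gaussian whose sigma grows from the in-air
  spot size σ₀ (linear in range: 6 mm at R = 5 cm to 3 mm at R = 25 cm)
  by a Highland-shaped MCS term k·R·(d/R)^1.7 (k = 0.025) in quadrature.
  Collimated beamlets multiply the kernel by per-side erf edge
  transmissions with penumbra σ_t = 1.1 mm at the surface, broadened with
  depth in quadrature — so a collimated profile never exceeds the
  uncollimated one, and the sharpening fades with range exactly as MCS
  predicts.
* **Ray model.** Spots travel on straight parallel rays; radiological depth
  maps are ray-marched per gantry angle at half the smallest voxel
  dimension with nearest-voxel sampling. Beamlet columns are truncated at
  0.1% of their own (uncollimated) maximum; the support is fixed before
  edge transmission is applied so collimation can only remove dose.
* **Geometry.** Gantry 0° enters anteriorly, angles increase toward
  patient-left, beams lie in the axial plane. The reference arc starts at
  the patient's lateral right (−90°) and wraps 140° posteriorly.

None of the machine parameters (spot sigma vs energy, penumbra width, beam
range spread) are taken from a specific delivery system; they are plausible
PBS values and configurable, and no headline result depends on their exact
values.

## Synthetic phantoms

Phantoms are rasterized from geometric primitives by voxel-centre
containment on anisotropic grids; margins (rings, skin shells) use exact
Euclidean distance transforms in millimetres. The reference phantom is a
single 2 mm axial slice of a 64×64 grid: a water cylinder body (r = 60 mm),
a spherical target (r = 12 mm) offset 20 mm toward patient-right, and an
abutting 6 mm cylindrical OAR ("brainstem"). Derived structures follow the
planning-study conventions: a 10 mm ring around the target, a 5 mm skin
shell, and the remaining healthy brain; integral dose is accumulated over
body ∖ (target ∪ ring ∪ skin).

What this phantom does *not* emulate: 3-D scatter and out-of-plane arcs,
tissue heterogeneity (it is water), realistic organ shapes, setup/range
uncertainty, and the sheer scale of a patient case (129 control points and
tens of thousands of beamlets vs 33 control points and ~170 beamlets at
desk scale). Passing tests therefore demonstrate algorithmic correctness
and directional dosimetric behaviour, not clinical plan quality.

## Study configurations

* **Prescription and normalization:** every plan is scaled by a single
  global factor so the target D95 (binned-curve read-back) equals 50 Gy;
  the factor is found by root-finding to well inside one DVH bin.
* **Default objective:** target underdose at 50 Gy and overdose at 52.5 Gy
  (β = 100 each), ring overdose at 25 Gy (β = 10), brainstem at 20 Gy
  (β = 10), healthy brain at 15 Gy (β = 2), skin at 20 Gy (β = 2). The OAR
  avoidance scenario replaces these with a heavily weighted dose-volume
  goal of 10 Gy to 2% of the brainstem plus target D2 ≤ 112% and
  D50 ≥ 96% of prescription goals — all still soft.
* **Stability study:** ten full optimizations with consecutive seeds at
  stages = 5, P = 10, G = 15 (~15 s each single-threaded). Outputs:
  per-seed DVH metrics, per-angle selected-range histograms, and the
  nearest-adjacent-range difference distribution (for each plan and
  interior control point, the minimum |ΔR| to the other plans' ranges at
  the neighbouring control points).
* **Two-field comparison:** an IMPT reference with anterior and
  right-lateral fields, every candidate layer available, weights optimized
  to convergence, normalized identically.

## Known limitations

* The degeneracy of the energy-vs-angle solution is weaker at desk scale
  than at patient scale: across ten seeds the target D95 agrees to ≤ 0.16%
  and many control points select three or more distinct ranges, but the
  full target DVH curves do not collapse onto each other to within 1%
  volume at every dose level — independently converged weight optima for
  different chromosomes still differ by ~10% in F at this problem size, a
  spread the much larger patient-scale problem averages away.
* Collimator scatter (and its surface-dose increase), nuclear halo, range
  shifters, delivery-time/trimmer sequencing, and robust optimization are
  out of scope.
* Rasterization uses voxel-centre containment without partial-volume
  weighting; single-voxel-thick axes are treated as replicated slabs.
* Mirror-symmetric configurations reproduce each other's plans only up to
  floating-point reduction order and voxel-centre sampling ties at ray
  boundaries (relative differences ~10⁻³ in F).
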