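"""Staged genetic optimizer for arc energy-layer sequencing.

Each candidate plan is a haploid chromosome assigning one energy layer to
every control point of the arc.  A population of such chromosomes evolves
over generations: every member's beamlet weights are (re)optimized against
the DVH objective at the start of each generation, members are ranked by
fitness F, the best member (the alpha) is cloned into the next generation,
the worst members (the runts) are replaced with freshly randomized members,
and the remainder produce offspring by per-locus recombination with a
partner drawn with rank-proportional probability.

The arc resolution refines across evolutionary stages: stage s has
``2**s + 1`` control points; the alpha of a finished stage is carried over,
its loci are locked at the carried angles, and only the newly inserted
midpoint angles remain free.  Weight optimization is a projected-gradient
descent with backtracking line search on the non-negative orthant,
warm-started from the parent so weights persist through the evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import Beamlet, BeamModel, DoseEngine
from .objective import ObjectiveEvaluator, ObjectiveTerm, normalize_plan
from .phantom import Phantom
from .plan import (ArcPlan, Chromosome, ControlPoint, build_control_points,
                   chromosome_beamlets, segment_sizes, set_collimation,
                   stage_angles)

# named RNG streams so a change in one subsystem cannot shift the draws of
# another under the same seed
_STREAMS = {"init": 1, "partner": 2, "mating": 3, "runts": 4}


def rng_stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed),
                                                         _STREAMS[name]]))


@dataclass
class GAParams:
    """Genetic-optimizer hyperparameters (all configurable)."""

    population: int = 10
    generations: int = 15
    runts: int = 2
    weight_iters: int = 25
    stages: int = 5
    final_polish_iters: int = 500

    def validate(self) -> None:
        if self.population < 3:
            raise ValueError("population must be >= 3")
        if not (1 <= self.runts <= self.population - 2):
            raise ValueError("runts must lie in [1, population - 2]")
        if self.stages < 1 or self.generations < 1:
            raise ValueError("stages and generations must be >= 1")


@dataclass
class Population:
    members: list[Chromosome]
    generation: int = 0
    stage: int = 1
    n_created: int = 0


@dataclass
class Trace:
    """Per-generation optimization record."""

    rows: list[tuple] = field(default_factory=list)   # (stage, gen, best F, mean F)
    stage_alphas: list[np.ndarray] = field(default_factory=list)
    seed: int | None = None

    def best_per_stage(self) -> dict[int, list[float]]:
        out: dict[int, list[float]] = {}
        for s, _, best, _ in self.rows:
            out.setdefault(s, []).append(best)
        return out


# ---------------------------------------------------------------------------
# Weight optimization
# ---------------------------------------------------------------------------

def optimize_weights_dense(M: np.ndarray, w0: np.ndarray,
                           evaluator: ObjectiveEvaluator, iters: int,
                           step0: float | None = None):
    """Projected-gradient descent of F over non-negative weights.

    ``M`` is the (beamlet x voxel) influence submatrix on the evaluation
    subset.  Dose-volume windows are refrozen at each outer iterate and held
    fixed through the backtracking line search; the best true-F iterate seen
    is returned, so F never increases across a call.
    """
    w = np.maximum(np.asarray(w0, dtype=M.dtype), 0.0)
    dose = w @ M
    windows = evaluator.freeze_windows(dose.astype(float))
    f_true = evaluator.value(dose.astype(float))
    best_w, best_f = w.copy(), f_true
    alpha = step0
    for _ in range(iters):
        g_d = evaluator.dose_gradient(dose.astype(float), windows)
        g = M @ g_d.astype(M.dtype)
        gnorm2 = float(g @ g)
        if gnorm2 <= 0:
            break
        # trial step from the exact minimizer of the local quadratic model
        # along -g (Gauss-Newton curvature of the active penalties)
        ddose = g @ M
        curv = evaluator.directional_curvature(dose.astype(float),
                                               ddose.astype(float), windows)
        if curv > 0:
            alpha = gnorm2 / curv
        elif alpha is None:
            alpha = 1.0
        f_frozen = evaluator.value(dose.astype(float), windows)
        improved = False
        for _ in range(30):
            w_try = np.maximum(w - alpha * g, 0.0)
            dose_try = w_try @ M
            if evaluator.value(dose_try.astype(float), windows) < f_frozen:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
        w, dose = w_try, dose_try
        windows = evaluator.freeze_windows(dose.astype(float))
        f_true = evaluator.value(dose.astype(float))
        if f_true < best_f:
            best_f, best_w = f_true, w.copy()
    return best_w.astype(float), float(best_f), alpha


# ---------------------------------------------------------------------------
# GA context: ties the phantom, dose engine, layout and objective together
# ---------------------------------------------------------------------------

class ArcOptimizationProblem:
    """Caches per-(angle, layer) dense dose blocks on the evaluation subset
    and evaluates chromosomes."""

    def __init__(self, phantom: Phantom, terms: list[ObjectiveTerm],
                 model: BeamModel | None = None,
                 spacing_wet: float = 0.5, pitch: float = 4.0,
                 target: str = "target", dtype=np.float32):
        self.phantom = phantom
        self.engine = DoseEngine(phantom, model)
        self.terms = terms
        self.spacing_wet = spacing_wet
        self.pitch = pitch
        self.target = target
        self.dtype = dtype
        self.subset = np.flatnonzero(phantom.body.ravel())
        self._pos = np.full(int(np.prod(phantom.grid_shape)), -1, dtype=np.int64)
        self._pos[self.subset] = np.arange(len(self.subset))
        self.evaluator = ObjectiveEvaluator(terms, phantom, self.subset)
        self._blocks: dict[tuple, np.ndarray] = {}

    # -- layout -------------------------------------------------------------

    def control_points(self, angles) -> list[ControlPoint]:
        return build_control_points(self.engine, angles, self.spacing_wet,
                                    self.pitch, self.target)

    # -- dense influence blocks --------------------------------------------

    def _beamlet_column(self, beamlet) -> np.ndarray:
        idx, vals = self.engine.beamlet_dose(beamlet)
        col = np.zeros(len(self.subset), dtype=self.dtype)
        pos = self._pos[idx]
        ok = pos >= 0
        col[pos[ok]] = vals[ok]
        return col

    def layer_block(self, cp: ControlPoint, layer: int) -> np.ndarray:
        """(n_spots, n_subset) dense dose block of one control point layer."""
        key = (round(cp.gantry_angle, 6), int(layer))
        if key not in self._blocks:
            r = float(cp.candidate_ranges[layer])
            s0 = float(self.engine.model.sigma0(r))
            cols = [self._beamlet_column(Beamlet(cp.gantry_angle, r,
                                                 (s[0], s[1]), s0))
                    for s in cp.spots[layer]]
            self._blocks[key] = (np.stack(cols) if cols else
                                 np.zeros((0, len(self.subset)),
                                          dtype=self.dtype))
        return self._blocks[key]

    def member_matrix(self, cps: list[ControlPoint],
                      chrom: Chromosome) -> np.ndarray:
        blocks = [self.layer_block(cp, int(li))
                  for cp, li in zip(cps, chrom.loci)]
        return np.concatenate(blocks, axis=0) if blocks else \
            np.zeros((0, len(self.subset)), dtype=self.dtype)

    def initial_weight_scale(self, M: np.ndarray,
                             prescription: float = 50.0) -> float:
        """Uniform positive weight putting the mean target dose near the
        prescription — a sane starting point for the descent."""
        tmask = self.phantom.mask(self.target).ravel()[self.subset]
        mean_t = float((np.ones(M.shape[0], dtype=M.dtype) @ M)[tmask].mean())
        return prescription / mean_t if mean_t > 0 else 1.0


# ---------------------------------------------------------------------------
# Population lifecycle
# ---------------------------------------------------------------------------

def random_loci(cps: list[ControlPoint], locked_template: Chromosome | None,
                rng: np.random.Generator) -> np.ndarray:
    """Uniform layer draw at unlocked control points; locked loci copied."""
    loci = np.empty(len(cps), dtype=np.int64)
    for i, cp in enumerate(cps):
        if cp.n_layers() == 0:
            raise ValueError(f"no candidate layers at angle {cp.gantry_angle}")
        if cp.locked and locked_template is not None:
            loci[i] = locked_template.loci[i]
        else:
            loci[i] = rng.integers(cp.n_layers())
    return loci


def init_population(cps: list[ControlPoint], P: int,
                    rng: np.random.Generator,
                    locked_template: Chromosome | None = None,
                    start_index: int = 0) -> Population:
    locked = np.array([cp.locked for cp in cps])
    members = []
    for m in range(P):
        loci = random_loci(cps, locked_template, rng)
        members.append(Chromosome(loci=loci, locked=locked.copy(),
                                  creation_index=start_index + m))
    return Population(members=members, n_created=start_index + P)


def rank_members(pop: Population) -> list[Chromosome]:
    """Ascending fitness; ties broken by creation index (older first)."""
    for m in pop.members:
        if m.fitness is None:
            raise ValueError("unevaluated member")
    return sorted(pop.members, key=lambda m: (m.fitness, m.creation_index))


def partner_probabilities(P: int) -> np.ndarray:
    """Rank-linear mating law: p(rank r) = 2 (P - r + 1) / (P (P + 1))."""
    r = np.arange(1, P + 1)
    return 2.0 * (P - r + 1) / (P * (P + 1))


def select_partner(ranked: list[Chromosome], parent_rank: int,
                   rng: np.random.Generator) -> Chromosome:
    """Draw a partner with rank-linear probability, excluding the parent."""
    P = len(ranked)
    if P < 2:
        raise ValueError("need at least two members to mate")
    p = partner_probabilities(P)
    p[parent_rank] = 0.0
    p /= p.sum()
    return ranked[int(rng.choice(P, p=p))]


def mate(parent: Chromosome, partner: Chromosome, rng: np.random.Generator,
         cps: list[ControlPoint], creation_index: int) -> Chromosome:
    """Uniform per-locus recombination; locked loci are copied verbatim and
    the child's weights are warm-started from the parent per control point."""
    if parent.loci.shape != partner.loci.shape or \
            np.any(parent.locked != partner.locked):
        raise ValueError("locus count / locked mask mismatch")
    take_partner = rng.random(len(parent.loci)) < 0.5
    loci = np.where(parent.locked | ~take_partner, parent.loci, partner.loci)
    child = Chromosome(loci=loci, locked=parent.locked.copy(),
                       creation_index=creation_index)
    child.weights = warm_start_weights(cps, parent, child)
    return child


def warm_start_weights(cps: list[ControlPoint], parent: Chromosome,
                       child: Chromosome) -> np.ndarray | None:
    """Copy the parent's weight block wherever the child kept the parent's
    layer; new layers start at the parent's mean positive weight."""
    if parent.weights is None:
        return None
    psz = segment_sizes(cps, parent)
    csz = segment_sizes(cps, child)
    pov = np.concatenate([[0], np.cumsum(psz)])
    fill = float(parent.weights.mean()) if parent.weights.size else 1.0
    out = []
    for i in range(len(cps)):
        if child.loci[i] == parent.loci[i]:
            out.append(parent.weights[pov[i]:pov[i + 1]])
        else:
            out.append(np.full(csz[i], fill))
    return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# Generations and stages
# ---------------------------------------------------------------------------

def evaluate_member(problem: ArcOptimizationProblem, cps, member: Chromosome,
                    iters: int, prescription: float) -> None:
    M = problem.member_matrix(cps, member)
    if member.weights is None or member.weights.size != M.shape[0]:
        member.weights = np.full(M.shape[0],
                                 problem.initial_weight_scale(M, prescription))
    w, f, _ = optimize_weights_dense(M, member.weights, problem.evaluator,
                                     iters)
    member.weights, member.fitness = w, f


def evolve_generation(problem: ArcOptimizationProblem, cps,
                      pop: Population, params: GAParams,
                      rng_partner, rng_mating, rng_runts,
                      prescription: float) -> Population:
    """One generation: elitist clone + recombined offspring + fresh runts,
    then weight re-optimization and fitness evaluation for every member."""
    ranked = rank_members(pop)
    P, R = params.population, params.runts
    alpha = ranked[0]
    next_members = [alpha.copy()]
    # non-runt, non-alpha members each produce one child
    for r in range(1, P - R):
        parent = ranked[r]
        partner = select_partner(ranked, r, rng_partner)
        child = mate(parent, partner, rng_mating, cps, pop.n_created)
        pop.n_created += 1
        next_members.append(child)
    locked_template = alpha if np.any(alpha.locked) else None
    for _ in range(R):
        loci = random_loci(cps, locked_template, rng_runts)
        next_members.append(Chromosome(loci=loci, locked=alpha.locked.copy(),
                                       creation_index=pop.n_created))
        pop.n_created += 1
    new_pop = Population(members=next_members, generation=pop.generation + 1,
                         stage=pop.stage, n_created=pop.n_created)
    for m in new_pop.members:
        evaluate_member(problem, cps, m, params.weight_iters, prescription)
    return new_pop


def advance_stage(problem: ArcOptimizationProblem, arc_start: float,
                  arc_stop: float, stage: int, alpha: Chromosome,
                  prev_cps: list[ControlPoint], P: int,
                  rng_init: np.random.Generator,
                  n_created: int) -> tuple[list[ControlPoint], Population]:
    """Refine the arc to the next stage, locking the alpha's loci at the
    carried-over angles and randomizing only the new midpoints."""
    angles = stage_angles(arc_start, arc_stop, stage)
    cps = problem.control_points(angles)
    prev_angles = {round(cp.gantry_angle, 9): i
                   for i, cp in enumerate(prev_cps)}
    template_loci = np.zeros(len(cps), dtype=np.int64)
    for i, cp in enumerate(cps):
        j = prev_angles.get(round(cp.gantry_angle, 9))
        if j is not None:
            cp.locked = True
            template_loci[i] = alpha.loci[j]
    template = Chromosome(loci=template_loci,
                          locked=np.array([cp.locked for cp in cps]))
    pop = init_population(cps, P, rng_init, locked_template=template,
                          start_index=n_created)
    pop.stage = stage
    # carry the alpha's optimized weights into every member at locked points
    alpha_by_angle = {}
    ov = np.concatenate([[0], np.cumsum(segment_sizes(prev_cps, alpha))])
    for j, cp in enumerate(prev_cps):
        alpha_by_angle[round(cp.gantry_angle, 9)] = \
            alpha.weights[ov[j]:ov[j + 1]] if alpha.weights is not None else None
    fill = float(alpha.weights.mean()) if alpha.weights is not None else None
    for m in pop.members:
        if fill is None:
            break
        parts = []
        for i, cp in enumerate(cps):
            key = round(cp.gantry_angle, 9)
            if cp.locked and alpha_by_angle.get(key) is not None:
                parts.append(alpha_by_angle[key])
            else:
                parts.append(np.full(len(cp.spots[m.loci[i]]), fill))
        m.weights = np.concatenate(parts)
    return cps, pop


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_dna(phantom: Phantom, terms: list[ObjectiveTerm], seed: int,
            arc_start: float = -90.0, arc_stop: float = -230.0,
            params: GAParams | None = None, collimated: bool = False,
            prescription: float = 50.0, normalization_level: float = 95.0,
            model: BeamModel | None = None, spacing_wet: float = 0.5,
            pitch: float = 4.0) -> tuple[ArcPlan, Trace]:
    """Run the staged genetic arc optimization end to end.

    Stages 1..S are evolved with G generations each; the final stage's alpha
    becomes the plan.  With ``collimated=True`` the alpha's beamlets are then
    trimmed individually at the target boundary and the weights re-optimized
    before normalization to the prescription at the requested volume level.
    The whole pipeline is a pure function of its arguments and the seed.
    """
    params = params or GAParams()
    params.validate()
    problem = ArcOptimizationProblem(phantom, terms, model, spacing_wet, pitch)
    rngs = {n: rng_stream(seed, n) for n in _STREAMS}
    trace = Trace(seed=seed)

    cps = problem.control_points(stage_angles(arc_start, arc_stop, 1))
    pop = init_population(cps, params.population, rngs["init"])
    for m in pop.members:
        evaluate_member(problem, cps, m, params.weight_iters, prescription)

    for stage in range(1, params.stages + 1):
        if stage > 1:
            alpha = rank_members(pop)[0]
            cps, pop = advance_stage(problem, arc_start, arc_stop, stage,
                                     alpha, cps, params.population,
                                     rngs["init"], pop.n_created)
            for m in pop.members:
                evaluate_member(problem, cps, m, params.weight_iters,
                                prescription)
        for _ in range(params.generations):
            pop = evolve_generation(problem, cps, pop, params,
                                    rngs["partner"], rngs["mating"],
                                    rngs["runts"], prescription)
            ranked = rank_members(pop)
            trace.rows.append((stage, pop.generation,
                               float(ranked[0].fitness),
                               float(np.mean([m.fitness
                                              for m in pop.members]))))
        trace.stage_alphas.append(rank_members(pop)[0].loci.copy())

    alpha = rank_members(pop)[0]
    beamlets = chromosome_beamlets(cps, alpha, problem.engine.model)
    weights = alpha.weights
    if collimated:
        beamlets = set_collimation(problem.engine, beamlets,
                                   "per_beamlet_edge", pitch,
                                   spacing_wet / 2.0)
    # per-generation weight optimization is truncated for GA throughput; the
    # delivered plan carries converged weights (re-optimized after trimmer
    # assignment in the collimated case)
    M = np.stack([problem._beamlet_column(b) for b in beamlets])
    weights, _, _ = optimize_weights_dense(
        M, weights, problem.evaluator, params.final_polish_iters)

    ranges = np.array([cps[i].candidate_ranges[alpha.loci[i]]
                       for i in range(len(cps))])
    plan = ArcPlan(angles=np.array([cp.gantry_angle for cp in cps]),
                   ranges=ranges, beamlets=beamlets,
                   weights=np.asarray(weights, dtype=float),
                   collimated=collimated, seed=seed)
    influence = problem.engine.build_influence(beamlets)
    normalize_plan(plan, influence, phantom, prescription,
                   normalization_level)
    return plan, trace


def optimize_static_fields(phantom: Phantom, terms: list[ObjectiveTerm],
                           angles, iters: int = 300,
                           prescription: float = 50.0,
                           normalization_level: float = 95.0,
                           model: BeamModel | None = None,
                           spacing_wet: float = 0.5,
                           pitch: float = 4.0) -> ArcPlan:
    """Multi-field IMPT reference plan: every candidate energy layer of each
    field is available and all spot weights are optimized jointly."""
    problem = ArcOptimizationProblem(phantom, terms, model, spacing_wet, pitch)
    cps = problem.control_points(np.asarray(angles, dtype=float))
    beamlets, blocks, ranges = [], [], []
    for cp in cps:
        for li in range(cp.n_layers()):
            blocks.append(problem.layer_block(cp, li))
            r = float(cp.candidate_ranges[li])
            s0 = float(problem.engine.model.sigma0(r))
            for s in cp.spots[li]:
                beamlets.append(Beamlet(cp.gantry_angle, r, (s[0], s[1]), s0))
        ranges.append(cp.candidate_ranges)
    M = np.concatenate(blocks, axis=0)
    w0 = np.full(M.shape[0], problem.initial_weight_scale(M, prescription))
    w, _, _ = optimize_weights_dense(M, w0, problem.evaluator, iters)
    plan = ArcPlan(angles=np.asarray(angles, dtype=float),
                   ranges=np.array([np.nan] * len(cps)),
                   beamlets=beamlets, weights=w, collimated=False)
    influence = problem.engine.build_influence(beamlets)
    normalize_plan(plan, influence, phantom, prescription,
                   normalization_level)
    return plan
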