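"""Genetic-optimizer lifecycle: init, ranking, mating, generations, stages,
weight optimization, determinism and gene locking."""

import numpy as np
import pytest

import protonarc as pa
from protonarc.optimizer import (ArcOptimizationProblem, GAParams, Population,
                                 init_population, mate, optimize_weights_dense,
                                 partner_probabilities, rank_members,
                                 rng_stream, select_partner, run_dna)
from protonarc.plan import Chromosome, ControlPoint


def dummy_cps(n_cp=4, n_layers=3, n_spots=2):
    return [ControlPoint(gantry_angle=float(10 * i),
                         candidate_ranges=5.0 + 0.5 * np.arange(n_layers),
                         spots=[np.zeros((n_spots, 2))] * n_layers)
            for i in range(n_cp)]


def dummy_members(fs):
    out = []
    for i, f in enumerate(fs):
        m = Chromosome(loci=np.zeros(3, dtype=int),
                       locked=np.zeros(3, dtype=bool), creation_index=i)
        m.fitness = f
        out.append(m)
    return out


class TestInitPopulation:
    def test_degenerate_gene_pool_identical_members(self):
        cps = dummy_cps(n_layers=1)
        pop = init_population(cps, 5, rng_stream(0, "init"))
        for m in pop.members:
            assert np.array_equal(m.loci, pop.members[0].loci)

    def test_seeded_reproducibility(self):
        cps = dummy_cps()
        a = init_population(cps, 8, rng_stream(3, "init"))
        b = init_population(cps, 8, rng_stream(3, "init"))
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.loci, mb.loci)

    def test_locus_distribution_uniform(self):
        """Chi-square sanity on the per-locus layer marginal over 1e4 draws."""
        cps = dummy_cps(n_cp=1, n_layers=4)
        rng = rng_stream(5, "init")
        draws = np.concatenate(
            [m.loci for m in init_population(cps, 10_000, rng).members])
        counts = np.bincount(draws, minlength=4)
        chi2 = np.sum((counts - 2500.0) ** 2 / 2500.0)
        # 3 dof; 0.001 critical value ~ 16.27
        assert chi2 < 16.27

    def test_missing_candidates_rejected(self):
        cps = dummy_cps()
        cps[1].candidate_ranges = np.array([])
        cps[1].spots = []
        with pytest.raises(ValueError):
            init_population(cps, 4, rng_stream(0, "init"))


class TestRanking:
    def test_sorts_by_fitness(self):
        pop = Population(members=dummy_members([3.0, 1.0, 2.0]))
        order = [m.creation_index for m in rank_members(pop)]
        assert order == [1, 2, 0]

    def test_ties_broken_by_creation_index(self):
        pop = Population(members=dummy_members([2.0, 1.0, 1.0]))
        order = [m.creation_index for m in rank_members(pop)]
        assert order == [1, 2, 0]

    def test_alpha_is_argmin(self):
        fs = [5.0, 0.5, 3.3, 0.9]
        pop = Population(members=dummy_members(fs))
        assert rank_members(pop)[0].fitness == min(fs)

    def test_unevaluated_member_rejected(self):
        ms = dummy_members([1.0, 2.0])
        ms[1].fitness = None
        with pytest.raises(ValueError):
            rank_members(Population(members=ms))


class TestPartnerSelection:
    def test_rank_linear_law_p3(self):
        np.testing.assert_allclose(partner_probabilities(3),
                                   [3 / 6, 2 / 6, 1 / 6])

    def test_probabilities_sum_to_one_after_self_exclusion(self):
        p = partner_probabilities(6)
        p[2] = 0.0
        assert (p / p.sum()).sum() == pytest.approx(1.0)

    def test_empirical_frequencies_match(self):
        """1e5 seeded draws vs the stated law within 3-sigma multinomial."""
        ranked = dummy_members([1.0, 2.0, 3.0, 4.0])
        rng = rng_stream(7, "partner")
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            counts[select_partner(ranked, 0, rng).creation_index] += 1
        p = partner_probabilities(4)
        p[0] = 0.0
        p = p / p.sum()
        for k in range(1, 4):
            sigma = np.sqrt(n * p[k] * (1 - p[k]))
            assert abs(counts[k] - n * p[k]) < 3 * sigma
        assert counts[0] == 0  # never the parent itself

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            select_partner(dummy_members([1.0]), 0, rng_stream(0, "partner"))


class _AllParentRng:
    """Degenerate generator: every uniform draw is >= 0.5."""

    def random(self, n):
        return np.ones(n)


class TestMating:
    def test_partner_equal_parent_gives_clone(self):
        cps = dummy_cps()
        rng = rng_stream(1, "mating")
        p = init_population(cps, 2, rng_stream(2, "init")).members[0]
        child = mate(p, p, rng, cps, 99)
        assert np.array_equal(child.loci, p.loci)

    def test_forced_all_parent_draw(self):
        cps = dummy_cps()
        pop = init_population(cps, 2, rng_stream(4, "init"))
        p, q = pop.members
        child = mate(p, q, _AllParentRng(), cps, 99)
        assert np.array_equal(child.loci, p.loci)

    def test_per_locus_parent_fraction_half(self):
        cps = dummy_cps(n_cp=6, n_layers=2)
        locked = np.zeros(6, dtype=bool)
        p = Chromosome(loci=np.zeros(6, dtype=int), locked=locked)
        q = Chromosome(loci=np.ones(6, dtype=int), locked=locked.copy())
        rng = rng_stream(8, "mating")
        n = 10_000
        frac = np.zeros(6)
        for _ in range(n):
            frac += mate(p, q, rng, cps, 0).loci
        frac /= n
        sigma = np.sqrt(0.25 / n)
        assert np.all(np.abs(frac - 0.5) < 4 * sigma)

    def test_locked_loci_copied_verbatim(self):
        cps = dummy_cps(n_cp=5, n_layers=3)
        locked = np.array([True, False, True, False, False])
        p = Chromosome(loci=np.array([2, 0, 1, 0, 0]), locked=locked)
        q = Chromosome(loci=np.array([0, 1, 0, 1, 1]), locked=locked.copy())
        for seed in range(10):
            child = mate(p, q, rng_stream(seed, "mating"), cps, 0)
            assert child.loci[0] == 2 and child.loci[2] == 1

    def test_mask_mismatch_rejected(self):
        cps = dummy_cps()
        p = Chromosome(loci=np.zeros(4, dtype=int),
                       locked=np.zeros(4, dtype=bool))
        q = Chromosome(loci=np.zeros(4, dtype=int),
                       locked=np.ones(4, dtype=bool))
        with pytest.raises(ValueError):
            mate(p, q, rng_stream(0, "mating"), cps, 0)


class TestWeightOptimization:
    def make_problem(self):
        from protonarc.objective import ObjectiveEvaluator, ObjectiveTerm
        from protonarc.phantom import Phantom
        rsp = np.ones((2, 1, 1))
        body = np.ones((2, 1, 1), dtype=bool)
        ph = Phantom(rsp=rsp, voxel_size=(2, 2, 2),
                     structures={"body": body, "roi": body.copy()})
        terms = [ObjectiveTerm("roi", d_over=50.0, beta_over=1.0,
                               d_under=50.0, beta_under=1.0)]
        return ObjectiveEvaluator(terms, ph)

    def test_recovers_least_squares_solution(self):
        """On a 2x2 influence with a unique positive solution of
        M^T w = 50, the descent reaches it to 1e-4."""
        ev = self.make_problem()
        M = np.array([[3.0, 1.0], [1.0, 2.0]])  # (beamlet, voxel)
        w_star = np.linalg.solve(M.T, np.full(2, 50.0))
        assert np.all(w_star > 0)
        w, f, _ = optimize_weights_dense(M, np.ones(2), ev, 400)
        np.testing.assert_allclose(w, w_star, atol=1e-4)

    def test_objective_never_increases(self):
        ev = self.make_problem()
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 2, (4, 2))
        w = rng.uniform(0, 30, 4)
        f_prev = None
        for _ in range(5):
            dose = w @ M
            f0 = ev.value(dose)
            w, f, _ = optimize_weights_dense(M, w, ev, 10)
            assert f <= f0 + 1e-12
            if f_prev is not None:
                assert f <= f_prev + 1e-12
            f_prev = f

    def test_optimal_point_is_fixed(self):
        ev = self.make_problem()
        M = np.array([[3.0, 1.0], [1.0, 2.0]])
        w_star = np.linalg.solve(M.T, np.full(2, 50.0))
        w, f, _ = optimize_weights_dense(M, w_star, ev, 20)
        np.testing.assert_allclose(w, w_star, atol=1e-9)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_weights_stay_nonnegative(self):
        ev = self.make_problem()
        rng = np.random.default_rng(1)
        M = rng.uniform(0, 2, (6, 2))
        w, _, _ = optimize_weights_dense(M, rng.uniform(0, 100, 6), ev, 50)
        assert np.all(w >= 0)


@pytest.fixture(scope="module")
def small_params():
    return GAParams(population=5, generations=3, runts=1, weight_iters=8,
                    stages=2, final_polish_iters=30)


class TestPipeline:
    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            GAParams(population=2).validate()
        with pytest.raises(ValueError):
            GAParams(population=5, runts=4).validate()
        GAParams(population=5, runts=3).validate()  # boundary: P - 2

    def test_seeded_determinism(self, reference, small_params):
        terms = pa.default_objective_terms()
        p1, t1 = run_dna(reference, terms, seed=5, params=small_params)
        p2, t2 = run_dna(reference, terms, seed=5, params=small_params)
        np.testing.assert_array_equal(p1.ranges, p2.ranges)
        np.testing.assert_array_equal(p1.weights, p2.weights)
        assert t1.rows == t2.rows

    def test_population_size_constant_and_elitism(self, reference,
                                                  small_params):
        terms = pa.default_objective_terms()
        _, trace = run_dna(reference, terms, seed=6, params=small_params)
        best = trace.best_per_stage()
        assert set(best) == {1, 2}
        for fs in best.values():
            assert np.all(np.diff(fs) <= 1e-9)

    def test_gene_locking_across_stages(self, reference):
        """Stage-2 population: 3 locked + 2 unlocked loci, locked values
        equal across all members and to the stage-1 alpha."""
        from protonarc.optimizer import (advance_stage, evaluate_member,
                                         init_population)
        from protonarc.plan import stage_angles
        terms = pa.default_objective_terms()
        prob = ArcOptimizationProblem(reference, terms)
        cps = prob.control_points(stage_angles(-90, -230, 1))
        rng = rng_stream(0, "init")
        pop = init_population(cps, 4, rng)
        for m in pop.members:
            evaluate_member(prob, cps, m, 5, 50.0)
        alpha = rank_members(pop)[0]
        cps2, pop2 = advance_stage(prob, -90, -230, 2, alpha, cps, 4, rng,
                                   pop.n_created)
        locked = np.array([cp.locked for cp in cps2])
        assert locked.sum() == 3 and (~locked).sum() == 2
        for m in pop2.members:
            assert np.array_equal(m.loci[locked], alpha.loci)
            assert np.array_equal(m.locked, locked)

    def test_haploid_one_layer_per_control_point(self, reference,
                                                 small_params):
        terms = pa.default_objective_terms()
        plan, _ = run_dna(reference, terms, seed=7, params=small_params)
        assert len(plan.ranges) == len(plan.angles)
        by_angle = {}
        for b in plan.beamlets:
            by_angle.setdefault(b.gantry_angle, set()).add(b.range_R)
        assert all(len(v) == 1 for v in by_angle.values())
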