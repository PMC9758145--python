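"""Window function, objective F and gradient, DVH curves/metrics,
integral dose, normalization."""

import numpy as np
import pytest

from protonarc.objective import (DVHCurve, ObjectiveEvaluator, ObjectiveTerm,
                                 clamp, compute_dvh, dvh_metric, dvh_window,
                                 integral_dose, normalize_dose, objective_F,
                                 objective_gradient)
from protonarc.phantom import Phantom


def tiny_phantom(n=4, masks=None):
    """Line of n water voxels, the whole body one structure by default."""
    rsp = np.ones((n, 1, 1))
    body = np.ones((n, 1, 1), dtype=bool)
    structures = {"body": body}
    if masks is None:
        masks = {"roi": body.copy()}
    structures.update(masks)
    return Phantom(rsp=rsp, voxel_size=(2.0, 2.0, 2.0), structures=structures)


class TestClamp:
    @pytest.mark.parametrize("x,a,b,out", [
        (5.0, 0.0, np.inf, 5.0),
        (-3.0, 0.0, np.inf, 0.0),
        (-3.0, -np.inf, 0.0, -3.0),
        (7.0, 0.0, 5.0, 0.0),
    ])
    def test_examples(self, x, a, b, out):
        assert clamp(x, a, b) == out

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            clamp(1.0, 2.0, 0.0)


class TestObjectiveF:
    def test_single_voxel_overdose_hand_value(self):
        ph = tiny_phantom(1)
        terms = [ObjectiveTerm("roi", d_over=50.0, beta_over=1.0)]
        assert objective_F(np.array([55.0]), terms, ph) == pytest.approx(25.0)

    def test_zero_residual_gives_zero(self):
        ph = tiny_phantom(6)
        terms = [ObjectiveTerm("roi", d_over=50.0, beta_over=2.0,
                               d_under=50.0, beta_under=3.0)]
        assert objective_F(np.full(6, 50.0), terms, ph) == 0.0

    def test_linear_in_beta(self):
        ph = tiny_phantom(5)
        dose = np.array([40.0, 45.0, 50.0, 58.0, 62.0])
        t1 = [ObjectiveTerm("roi", d_over=50.0, beta_over=1.0,
                            d_under=48.0, beta_under=2.0)]
        t2 = [ObjectiveTerm("roi", d_over=50.0, beta_over=2.0,
                            d_under=48.0, beta_under=4.0)]
        assert objective_F(dose, t2, ph) == pytest.approx(
            2.0 * objective_F(dose, t1, ph))

    def test_nonnegative_and_permutation_invariant(self):
        rng = np.random.default_rng(11)
        ph = tiny_phantom(30)
        dose = rng.uniform(0, 70, 30)
        terms = [ObjectiveTerm("roi", d_over=50.0, beta_over=1.5,
                               d_under=45.0, beta_under=0.7,
                               v_over=20.0, d_v_over=55.0, beta_v_over=1.0)]
        f = objective_F(dose, terms, ph)
        assert f >= 0
        perm = rng.permutation(30)
        ph2 = tiny_phantom(30)
        assert objective_F(dose[perm], terms, ph2) == pytest.approx(f)

    def test_missing_structure_raises(self):
        ph = tiny_phantom(3)
        with pytest.raises(KeyError):
            objective_F(np.zeros(3), [ObjectiveTerm("nope", d_over=1.0,
                                                    beta_over=1.0)], ph)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveTerm("roi", d_over=1.0, beta_over=-1.0)


class TestDvhWindow:
    def test_overdose_window_from_constructed_grid(self):
        # 20% of voxels at 55 Gy, rest at 40: D(V=20%) = 55
        dose = np.array([55.0] * 2 + [40.0] * 8)
        mask = np.ones(10, dtype=bool)
        assert dvh_window(dose, mask, 20.0, 50.0, "over") == pytest.approx(5.0)

    def test_uniform_dose_at_threshold_zero_window(self):
        dose = np.full(10, 50.0)
        mask = np.ones(10, dtype=bool)
        assert dvh_window(dose, mask, 30.0, 50.0, "over") == 0.0

    def test_underdose_met_goal_empty_window(self):
        dose = np.full(10, 55.0)
        mask = np.ones(10, dtype=bool)
        assert dvh_window(dose, mask, 95.0, 50.0, "under") == 0.0

    def test_empty_structure_raises(self):
        with pytest.raises(ValueError):
            dvh_window(np.zeros(4), np.zeros(4, dtype=bool), 50.0, 10.0,
                       "over")


class TestGradient:
    def test_zero_residual_zero_gradient(self):
        ph = tiny_phantom(4)
        ev = ObjectiveEvaluator([ObjectiveTerm("roi", d_over=50.0,
                                               beta_over=1.0)], ph)
        g = ev.dose_gradient(np.full(4, 40.0))
        assert np.all(g == 0)

    def test_overdose_gradient_nonnegative(self):
        ph = tiny_phantom(5)
        ev = ObjectiveEvaluator([ObjectiveTerm("roi", d_over=30.0,
                                               beta_over=2.0)], ph)
        g = ev.dose_gradient(np.array([35.0, 50.0, 31.0, 40.0, 60.0]))
        assert np.all(g >= 0)

    def test_matches_central_finite_differences(self):
        """Analytic weight gradient vs central differences on random small
        instances, away from window boundaries."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_vox, n_b = 12, 5
            ph = tiny_phantom(n_vox, masks={
                "roi": np.arange(n_vox).reshape(n_vox, 1, 1) < 8,
                "oar": np.arange(n_vox).reshape(n_vox, 1, 1) >= 6})
            terms = [
                ObjectiveTerm("roi", d_over=rng.uniform(45, 55),
                              beta_over=rng.uniform(0.5, 2),
                              d_under=rng.uniform(40, 50),
                              beta_under=rng.uniform(0.5, 2)),
                ObjectiveTerm("oar", d_over=rng.uniform(10, 30),
                              beta_over=rng.uniform(0.5, 2)),
            ]

            class _Infl:
                matrix = None

            from scipy import sparse
            M = rng.uniform(0, 3, (n_vox, n_b))
            infl = _Infl()
            infl.matrix = sparse.csc_matrix(M)
            infl.dose = lambda w, M=M: M @ w
            w = rng.uniform(0.5, 2.0, n_b)
            g = objective_gradient(w, infl, terms, ph)
            eps = 1e-6
            for j in range(n_b):
                wp, wm = w.copy(), w.copy()
                wp[j] += eps
                wm[j] -= eps
                fd = (objective_F(M @ wp, terms, ph)
                      - objective_F(M @ wm, terms, ph)) / (2 * eps)
                assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestDvhCurves:
    def test_uniform_dose_steps_at_value(self):
        curve = compute_dvh(np.full(50, 50.0), np.ones(50, dtype=bool))
        assert dvh_metric(curve, "V49.9") == pytest.approx(100.0)
        assert dvh_metric(curve, "V50.2") == pytest.approx(0.0)
        assert curve.volume_pct[0] == 100.0

    def test_half_and_half_mixture(self):
        dose = np.concatenate([np.zeros(30), np.full(30, 10.0)])
        curve = compute_dvh(dose, np.ones(60, dtype=bool))
        assert dvh_metric(curve, "V5") == pytest.approx(50.0)

    def test_metric_read_back_inverts_mixture(self):
        # 40% at 30 Gy, 60% at 60 Gy
        dose = np.concatenate([np.full(40, 30.0), np.full(60, 60.0)])
        curve = compute_dvh(dose, np.ones(100, dtype=bool))
        assert dvh_metric(curve, "D50") == pytest.approx(60.0, abs=0.1)
        assert dvh_metric(curve, "D90") == pytest.approx(30.0, abs=0.1)

    def test_quantile_ordering(self):
        rng = np.random.default_rng(2)
        curve = compute_dvh(rng.uniform(0, 60, 500), np.ones(500, dtype=bool))
        d2 = dvh_metric(curve, "D2")
        d50 = dvh_metric(curve, "D50")
        d95 = dvh_metric(curve, "D95")
        assert d2 >= d50 >= d95

    def test_uniform_dose_metrics_coincide(self):
        curve = compute_dvh(np.full(40, 50.0), np.ones(40, dtype=bool))
        for m in ("D2", "D50", "D95"):
            assert dvh_metric(curve, m) == pytest.approx(50.0, abs=0.1)
        assert dvh_metric(curve, "Dmean") == pytest.approx(50.0)

    def test_non_increasing_enforced(self):
        with pytest.raises(ValueError):
            DVHCurve(edges=np.array([0.0, 1.0]),
                     volume_pct=np.array([50.0, 80.0]), mean_dose=1.0)

    def test_empty_structure_raises(self):
        with pytest.raises(ValueError):
            compute_dvh(np.zeros(5), np.zeros(5, dtype=bool))


class TestIntegralDose:
    def test_zero_dose(self, reference):
        assert integral_dose(np.zeros(reference.grid_shape), reference) == 0.0

    def test_uniform_dose_arithmetic(self, reference):
        """1 Gy over the healthy region: integral = n_voxels * 8e-3 Gy cm3,
        checked against independent mask algebra."""
        region = (reference.body
                  & ~reference.mask("target")
                  & ~reference.mask("ring10mm")
                  & ~reference.mask("skin"))
        dose = np.where(region, 1.0, 0.0)
        expected = region.sum() * 0.008
        assert integral_dose(dose, reference) == pytest.approx(expected)
        # dose outside the region must not contribute
        dose2 = np.where(region, 1.0, 7.0)
        assert integral_dose(dose2, reference) == pytest.approx(expected)


class TestNormalization:
    def test_scale_ratio_for_uniform_plan(self, reference):
        dose = np.where(reference.mask("target"), 25.0, 0.0)
        s = normalize_dose(dose, reference, prescription=50.0, level=95.0)
        assert s == pytest.approx(2.0, abs=0.01)

    def test_post_normalization_d95_within_bin(self, reference):
        rng = np.random.default_rng(9)
        dose = np.where(reference.mask("target"),
                        rng.uniform(40, 60, reference.grid_shape), 0.0)
        s = normalize_dose(dose, reference)
        curve = compute_dvh(s * dose, reference.mask("target"))
        assert dvh_metric(curve, "D95") == pytest.approx(50.0, abs=0.1)

    def test_dvh_shape_invariant(self, reference):
        rng = np.random.default_rng(10)
        dose = np.where(reference.mask("target"),
                        rng.uniform(40, 60, reference.grid_shape), 0.0)
        s = normalize_dose(dose, reference)
        d = dose[reference.mask("target")]
        # relative quantiles are preserved under global scaling
        q = np.quantile(s * d, [0.1, 0.5, 0.9])
        np.testing.assert_allclose(q, s * np.quantile(d, [0.1, 0.5, 0.9]),
                                   rtol=1e-12)

    def test_zero_target_dose_rejected(self, reference):
        with pytest.raises(ValueError):
            normalize_dose(np.zeros(reference.grid_shape), reference)
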