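"""DVH-based quadratic planning objective, its gradient, and plan metrics.

The objective is a sum over structures k of mean squared one-sided penalties

    F = sum_k (1/T_k) sum_{i in tau_k} [
            beta_k^+   c_(0,inf)^2 (d_i - d_k^+)
          + beta_k^-   c_(-inf,0)^2(d_i - d_k^-)
          + beta_k^V+  c_(0, dD^V+)^2 (d_i - d_k^V+)
          + beta_k^V-  c_(dD^V-, 0)^2 (d_i - d_k^V-) ]

where c_(a,b)(x) windows the residual to [a, b] (zero outside), T_k is the
voxel count of structure k, and the dose-volume windows dD^V are the
difference between the current dose at volume level V and the desired
threshold, so only the voxels cheapest to move are penalized.  All
constraints are soft (penalty weights beta >= 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .phantom import Phantom, healthy_region


def clamp(x, a, b):
    """Window function: ``x`` where ``a <= x <= b``, else 0 (elementwise)."""
    if np.any(np.asarray(a) > np.asarray(b)):
        raise ValueError("window requires a <= b")
    x = np.asarray(x, dtype=float)
    out = np.where((x >= a) & (x <= b), x, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Objective terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveTerm:
    """Penalty terms for one structure; any component may be absent.

    Thresholds are in Gy; dose-volume components carry a volume level V in
    percent.  Thresholds may be scalars (constant over the structure) or
    per-voxel arrays matching the structure's voxel count.
    """

    structure: str
    d_over: float | np.ndarray | None = None
    beta_over: float = 0.0
    d_under: float | np.ndarray | None = None
    beta_under: float = 0.0
    v_over: float | None = None       # percent volume level
    d_v_over: float | None = None
    beta_v_over: float = 0.0
    v_under: float | None = None
    d_v_under: float | None = None
    beta_v_under: float = 0.0

    def __post_init__(self):
        for b in (self.beta_over, self.beta_under, self.beta_v_over,
                  self.beta_v_under):
            if b < 0:
                raise ValueError("penalty weights must be >= 0")
        for v in (self.v_over, self.v_under):
            if v is not None and not (0 < v <= 100):
                raise ValueError("volume levels must lie in (0, 100]")


def dose_at_volume(doses: np.ndarray, level: float) -> float:
    """Interpolated dose received by the hottest ``level`` percent of voxels.

    The i-th hottest voxel (1-based) is assigned the volume rank
    ``100 * i / n`` and the dose at ``level`` is linearly interpolated
    between ranks, so D(100%) is the minimum and D(100/n %) the maximum.
    """
    if not (0 < level <= 100):
        raise ValueError("volume level must lie in (0, 100]")
    desc = np.sort(np.asarray(doses, dtype=float).ravel())[::-1]
    ranks = 100.0 * np.arange(1, desc.size + 1) / desc.size
    return float(np.interp(level, ranks, desc))


def dvh_window(dose: np.ndarray, structure: np.ndarray, V: float,
               threshold: float, side: str) -> float:
    """Dose-volume window width dD = D_planned(V) - threshold (Gy).

    For an overdose component, voxels with residual in (0, dD] are
    penalized; for an underdose component, residuals in [dD, 0).  When the
    plan already meets the goal the window is empty and the penalty vanishes.
    """
    m = np.asarray(structure).ravel()
    if not m.any():
        raise ValueError("empty structure")
    dv = dose_at_volume(np.asarray(dose).ravel()[m], V)
    delta = dv - threshold
    if side == "over":
        return max(delta, 0.0)
    if side == "under":
        return min(delta, 0.0)
    raise ValueError("side must be 'over' or 'under'")


class ObjectiveEvaluator:
    """Pre-indexed evaluator of F and its dose gradient on a voxel subset.

    ``subset`` is a flat-voxel index array (or None for the full grid); the
    evaluator resolves every term's structure voxels into positions within
    that subset once, then evaluates F, frozen dose-volume windows, and
    dF/d(dose) with plain vector arithmetic.
    """

    def __init__(self, terms: list[ObjectiveTerm], phantom: Phantom,
                 subset: np.ndarray | None = None):
        n_vox = int(np.prod(phantom.grid_shape))
        if subset is None:
            subset = np.arange(n_vox)
        pos_of = np.full(n_vox, -1, dtype=np.int64)
        pos_of[subset] = np.arange(len(subset))
        self.n_sub = len(subset)
        self._entries = []
        for t in terms:
            mask = phantom.mask(t.structure).ravel()
            idx_full = np.flatnonzero(mask)
            pos = pos_of[idx_full]
            if np.any(pos < 0):
                raise ValueError(
                    f"structure {t.structure!r} has voxels outside the "
                    "evaluation subset")
            self._entries.append((t, pos, float(len(idx_full))))

    # -- frozen dose-volume windows ----------------------------------------

    def freeze_windows(self, dose_sub: np.ndarray) -> list[tuple]:
        """Current dose-volume window widths, one (over, under) per term."""
        wins = []
        for t, pos, _ in self._entries:
            w_over = w_under = None
            if t.beta_v_over > 0 and t.v_over is not None:
                dv = dose_at_volume(dose_sub[pos], t.v_over)
                w_over = max(dv - t.d_v_over, 0.0)
            if t.beta_v_under > 0 and t.v_under is not None:
                dv = dose_at_volume(dose_sub[pos], t.v_under)
                w_under = min(dv - t.d_v_under, 0.0)
            wins.append((w_over, w_under))
        return wins

    # -- F and gradient -----------------------------------------------------

    def value(self, dose_sub: np.ndarray, windows=None) -> float:
        if windows is None:
            windows = self.freeze_windows(dose_sub)
        F = 0.0
        for (t, pos, T_k), (w_over, w_under) in zip(self._entries, windows):
            d = dose_sub[pos]
            acc = 0.0
            if t.beta_over > 0:
                r = d - t.d_over
                acc += t.beta_over * np.sum(np.square(r, where=r > 0,
                                                      out=np.zeros_like(r)))
            if t.beta_under > 0:
                r = d - t.d_under
                acc += t.beta_under * np.sum(np.square(r, where=r < 0,
                                                       out=np.zeros_like(r)))
            if w_over is not None and w_over > 0:
                r = d - t.d_v_over
                sel = (r > 0) & (r <= w_over)
                acc += t.beta_v_over * np.sum(r[sel] ** 2)
            if w_under is not None and w_under < 0:
                r = d - t.d_v_under
                sel = (r < 0) & (r >= w_under)
                acc += t.beta_v_under * np.sum(r[sel] ** 2)
            F += acc / T_k
        return float(F)

    def dose_gradient(self, dose_sub: np.ndarray, windows=None) -> np.ndarray:
        """dF/d(dose) on the subset, with dose-volume windows frozen."""
        if windows is None:
            windows = self.freeze_windows(dose_sub)
        g = np.zeros(self.n_sub)
        for (t, pos, T_k), (w_over, w_under) in zip(self._entries, windows):
            d = dose_sub[pos]
            gk = np.zeros_like(d)
            if t.beta_over > 0:
                r = d - t.d_over
                gk += 2.0 * t.beta_over * np.where(r > 0, r, 0.0)
            if t.beta_under > 0:
                r = d - t.d_under
                gk += 2.0 * t.beta_under * np.where(r < 0, r, 0.0)
            if w_over is not None and w_over > 0:
                r = d - t.d_v_over
                gk += 2.0 * t.beta_v_over * np.where((r > 0) & (r <= w_over),
                                                     r, 0.0)
            if w_under is not None and w_under < 0:
                r = d - t.d_v_under
                gk += 2.0 * t.beta_v_under * np.where((r < 0) & (r >= w_under),
                                                      r, 0.0)
            np.add.at(g, pos, gk / T_k)
        return g


    def directional_curvature(self, dose_sub: np.ndarray,
                              ddose_sub: np.ndarray, windows=None) -> float:
        """Gauss-Newton curvature of F along a dose direction: twice the
        penalty-weighted mean square of the direction over the currently
        active voxels of every term (windows frozen)."""
        if windows is None:
            windows = self.freeze_windows(dose_sub)
        c = 0.0
        for (t, pos, T_k), (w_over, w_under) in zip(self._entries, windows):
            d = dose_sub[pos]
            dd2 = ddose_sub[pos] ** 2
            acc = 0.0
            if t.beta_over > 0:
                acc += t.beta_over * dd2[d - t.d_over > 0].sum()
            if t.beta_under > 0:
                acc += t.beta_under * dd2[d - t.d_under < 0].sum()
            if w_over is not None and w_over > 0:
                r = d - t.d_v_over
                acc += t.beta_v_over * dd2[(r > 0) & (r <= w_over)].sum()
            if w_under is not None and w_under < 0:
                r = d - t.d_v_under
                acc += t.beta_v_under * dd2[(r < 0) & (r >= w_under)].sum()
            c += 2.0 * acc / T_k
        return float(c)


def objective_F(dose, terms: list[ObjectiveTerm], phantom: Phantom) -> float:
    """Objective value on a full dose grid (flat or grid-shaped)."""
    ev = ObjectiveEvaluator(terms, phantom)
    return ev.value(np.asarray(dose, dtype=float).ravel())


def objective_gradient(weights, influence, terms: list[ObjectiveTerm],
                       phantom: Phantom) -> np.ndarray:
    """Gradient of F with respect to beamlet weights (chain rule through the
    dose-influence matrix), dose-volume windows frozen at the current dose."""
    dose = influence.dose(weights)
    ev = ObjectiveEvaluator(terms, phantom)
    g_d = ev.dose_gradient(dose)
    return np.asarray(influence.matrix.T @ g_d).ravel()


# ---------------------------------------------------------------------------
# DVH curves and metrics
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    edges: np.ndarray        # dose bin edges, Gy
    volume_pct: np.ndarray   # percent volume receiving >= edge dose
    mean_dose: float         # mean of the underlying voxel doses, Gy

    def __post_init__(self):
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing")


def compute_dvh(dose, structure, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of ``structure``; V(0) = 100%."""
    m = np.asarray(structure).ravel()
    if not m.any():
        raise ValueError("empty structure")
    d = np.asarray(dose, dtype=float).ravel()[m]
    top = max(d.max(), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    vol = 100.0 * np.mean(d[None, :] >= edges[:, None], axis=1)
    return DVHCurve(edges=edges, volume_pct=vol, mean_dose=float(d.mean()))


def dvh_metric(curve: DVHCurve, metric: str) -> float:
    """Read a named metric off a DVH curve.

    ``D<p>`` is the dose at cumulative volume p% (linear interpolation of
    the curve); ``Dmean`` is the voxel-dose mean; ``V<x>`` the percent
    volume receiving at least x Gy.
    """
    if metric == "Dmean":
        return curve.mean_dose
    if metric.startswith("D"):
        p = float(metric[1:])
        if not (0 < p <= 100):
            raise ValueError("volume level must lie in (0, 100]")
        # volume_pct is non-increasing in dose; interpolate dose at volume p
        v = curve.volume_pct[::-1]
        e = curve.edges[::-1]
        return float(np.interp(p, v, e))
    if metric.startswith("V"):
        x = float(metric[1:])
        return float(np.interp(x, curve.edges, curve.volume_pct))
    raise ValueError(f"unknown metric {metric!r}")


def integral_dose(dose, phantom: Phantom) -> float:
    """Integral dose (Gy cm^3) to healthy tissue inside the skin surface and
    outside the 10 mm ring around the target."""
    region = healthy_region(phantom)
    d = np.asarray(dose, dtype=float).ravel()
    return float(d[region.ravel()].sum() * phantom.voxel_volume_cm3)


def normalize_dose(dose, phantom: Phantom, prescription: float = 50.0,
                   level: float = 95.0, target: str = "target",
                   bin_width: float = 0.1) -> float:
    """Global scale factor s such that the target D{level} of ``s * dose``
    equals the prescription (read off the binned DVH curve)."""
    m = phantom.mask(target).ravel()
    d = np.asarray(dose, dtype=float).ravel()[m]
    base = dose_at_volume(d, level)
    if base <= 0:
        raise ValueError("zero target dose; cannot normalize")
    s0 = prescription / base

    def f(s):
        return dvh_metric(compute_dvh(s * d, np.ones(d.size, dtype=bool),
                                      bin_width), f"D{level:g}") - prescription

    lo, hi = 0.5 * s0, 2.0 * s0
    if f(lo) * f(hi) > 0:       # curve read-back already within a bin
        return s0
    return float(brentq(f, lo, hi, xtol=1e-9))


def normalize_plan(plan, influence, phantom: Phantom,
                   prescription: float = 50.0, level: float = 95.0):
    """Scale a plan's weights so the target D{level} equals the prescription.

    Returns the plan with scaled weights and the factor recorded in
    ``plan.normalization``.
    """
    dose = influence.dose(plan.weights)
    s = normalize_dose(dose, phantom, prescription, level)
    plan.weights = plan.weights * s
    plan.normalization = s
    return plan


def structure_metrics(dose, phantom: Phantom, structure: str,
                      metrics=("D2", "D50", "D90", "D95", "Dmean"),
                      bin_width: float = 0.1) -> dict[str, float]:
    curve = compute_dvh(dose, phantom.mask(structure), bin_width)
    return {m: dvh_metric(curve, m) for m in metrics}


def oar_avoidance_terms(prescription: float = 50.0,
                        oar: str = "brainstem") -> list[ObjectiveTerm]:
    """Soft-constraint scenario prioritizing a maximum OAR dose goal.

    Expresses a highly weighted dose-volume goal of 10 Gy to 2% of the OAR
    together with target coverage goals (D2 within 112% and D50 of at least
    96% of prescription); all constraints remain soft penalties.
    """
    return [
        ObjectiveTerm("target",
                      d_under=prescription, beta_under=100.0,
                      v_over=2.0, d_v_over=1.12 * prescription,
                      beta_v_over=50.0,
                      v_under=50.0, d_v_under=0.96 * prescription,
                      beta_v_under=50.0),
        ObjectiveTerm(oar, v_over=2.0, d_v_over=10.0, beta_v_over=1000.0),
        ObjectiveTerm("ring10mm", d_over=0.5 * prescription, beta_over=10.0),
    ]
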