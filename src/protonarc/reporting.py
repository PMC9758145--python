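"""Plan evaluation reports, plan comparison, stability studies, volume IO."""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .objective import compute_dvh, dvh_metric, integral_dose
from .phantom import Phantom
from .plan import ArcPlan
from .optimizer import Trace, run_dna

_DEFAULT_METRICS = ("D2", "D50", "D90", "D95", "Dmean")


@dataclass
class PlanReport:
    """Per-structure DVH metrics plus integral dose for one dose grid."""

    structure_metrics: dict[str, dict[str, float]]
    integral_dose: float
    normalization: float = 1.0
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"structures": self.structure_metrics,
                           "integral_dose": self.integral_dose,
                           "normalization": self.normalization,
                           "meta": self.meta}, indent=1)


def evaluate_dose(dose, phantom: Phantom, structures=None,
                  metrics=_DEFAULT_METRICS, normalization: float = 1.0,
                  meta: dict | None = None) -> PlanReport:
    """Compute the standard report from a dose grid."""
    if structures is None:
        structures = [s for s in phantom.structures if s != phantom.body_name]
    sm = {}
    for s in structures:
        curve = compute_dvh(dose, phantom.mask(s))
        sm[s] = {m: round(float(dvh_metric(curve, m)), 6) for m in metrics}
    return PlanReport(structure_metrics=sm,
                      integral_dose=float(integral_dose(dose, phantom)),
                      normalization=normalization, meta=meta or {})


def compare_plans(report_a: PlanReport, report_b: PlanReport,
                  dose_a=None, dose_b=None):
    """Per-structure metric deltas (a - b, absolute and percent of b) and,
    when both dose grids are given, the voxelwise dose-difference volume."""
    if set(report_a.structure_metrics) != set(report_b.structure_metrics):
        raise ValueError("reports cover different structures")
    table = {}
    for s, ma in report_a.structure_metrics.items():
        mb = report_b.structure_metrics[s]
        table[s] = {}
        for k in ma:
            d = ma[k] - mb[k]
            table[s][k] = {"delta": d,
                           "pct": 100.0 * d / mb[k] if mb[k] != 0 else np.nan}
    di = report_a.integral_dose - report_b.integral_dose
    table["integral_dose"] = {
        "delta": di,
        "pct": (100.0 * di / report_b.integral_dose
                if report_b.integral_dose else np.nan)}
    diff = None
    if dose_a is not None and dose_b is not None:
        a, b = np.asarray(dose_a), np.asarray(dose_b)
        if a.shape != b.shape:
            raise ValueError("dose grid geometry mismatch")
        diff = a - b
    return table, diff


# ---------------------------------------------------------------------------
# Stability study
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Outcome of repeated genetic optimizations under different seeds."""

    seeds: list[int]
    plans: list[ArcPlan]
    traces: list[Trace]
    reports: list[PlanReport]
    doses: list[np.ndarray]
    angles: np.ndarray
    ranges: np.ndarray              # (n_seeds, n_control_points), cm

    def d95_relative_deviation(self, prescription: float = 50.0,
                               target: str = "target") -> float:
        """Max over seeds of |target D95 - prescription| / prescription."""
        devs = [abs(r.structure_metrics[target]["D95"] - prescription)
                / prescription for r in self.reports]
        return float(max(devs))

    def range_histogram(self) -> dict[float, np.ndarray]:
        """Distinct selected ranges per control-point angle across seeds."""
        return {float(a): np.unique(self.ranges[:, i])
                for i, a in enumerate(self.angles)}

    def adjacent_range_differences(self) -> np.ndarray:
        """Nearest-adjacent-range differences between plans (cm).

        For every plan p and interior control point c, the minimum absolute
        difference between plan p's range at c and the ranges of the other
        plans at the previous and next control points — how closely any
        other plan tracks this plan's energy sequence locally.
        """
        n_seeds, n_cp = self.ranges.shape
        out = []
        for p in range(n_seeds):
            for c in range(1, n_cp - 1):
                others = [q for q in range(n_seeds) if q != p]
                neigh = np.concatenate([self.ranges[others, c - 1],
                                        self.ranges[others, c + 1]])
                out.append(np.min(np.abs(self.ranges[p, c] - neigh)))
        return np.asarray(out)


def run_stability_study(config: RunConfig, n_seeds: int = 10,
                        phantom: Phantom | None = None,
                        seeds=None) -> StabilityResult:
    """Repeat the full genetic optimization with distinct RNG seeds.

    Seeds default to ``config.seed + [0 .. n_seeds-1]``; every run is fully
    deterministic given its seed, so the recorded seed list allows exact
    re-runs.
    """
    if phantom is None:
        phantom = config.build_phantom()
    if seeds is None:
        seeds = [config.seed + k for k in range(n_seeds)]
    seeds = [int(s) for s in seeds]
    from .dose import DoseEngine
    engine = DoseEngine(phantom, config.beam_model)
    plans, traces, reports, doses = [], [], [], []
    ranges = []
    angles = None
    for s in seeds:
        plan, trace = run_dna(
            phantom, config.objectives, seed=s,
            arc_start=config.arc_start, arc_stop=config.arc_stop,
            params=config.ga, collimated=config.collimated,
            prescription=config.prescription,
            normalization_level=config.normalization_level,
            model=config.beam_model, spacing_wet=config.layer_spacing,
            pitch=config.spot_pitch)
        dose = engine.build_influence(plan.beamlets).dose(plan.weights)
        plans.append(plan)
        traces.append(trace)
        doses.append(dose)
        reports.append(evaluate_dose(dose, phantom,
                                     normalization=plan.normalization,
                                     meta={"seed": s}))
        ranges.append(plan.ranges)
        angles = plan.angles
    return StabilityResult(seeds=seeds, plans=plans, traces=traces,
                           reports=reports, doses=doses, angles=angles,
                           ranges=np.asarray(ranges))


# ---------------------------------------------------------------------------
# Volume IO: raw binary + JSON sidecar
# ---------------------------------------------------------------------------

def save_volume(path, array: np.ndarray, voxel_size, origin=(0, 0, 0)) -> None:
    """Write a volume as raw little-endian binary with a JSON header.

    The sidecar ``<path>.json`` records shape, spacing (mm), origin (mm),
    dtype and ordering (x fastest)."""
    path = Path(path)
    arr = np.asarray(array)
    # x fastest: store in Fortran order so x varies first on disk
    arr.astype(arr.dtype.newbyteorder("<")).tofile(path)
    hdr = {"shape": list(arr.shape), "spacing": list(map(float, voxel_size)),
           "origin": list(map(float, origin)), "dtype": str(arr.dtype),
           "ordering": "C (last axis fastest)"}
    Path(str(path) + ".json").write_text(json.dumps(hdr, indent=1))


def load_volume(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    hdr = json.loads(Path(str(path) + ".json").read_text())
    arr = np.fromfile(path, dtype=np.dtype(hdr["dtype"]))
    return arr.reshape(hdr["shape"]), hdr


def save_influence_csv(path, influence) -> None:
    """Persist a dose-influence matrix as sparse triplets (voxel, beamlet,
    value) in CSV."""
    coo = influence.matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("voxel,beamlet,dose_per_weight\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i},{j},{v:.10g}\n")


def load_influence_triplets(path) -> "np.ndarray":
    """Load the (voxel, beamlet, value) triplets written by
    :func:`save_influence_csv` as a structured-free (n, 3) float array."""
    return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
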