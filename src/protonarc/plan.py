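"""Arc plan model: control points, layers, spots, chromosomes, collimation.

An arc delivery is discretized into control points (gantry angles), each
carrying exactly one energy layer (haploid encoding).  The arc resolution is
refined in evolutionary stages: stage ``s`` has ``2**s + 1`` evenly spaced
control points, so each stage inserts a new control point at the midpoint of
every existing pair while the previously optimized angles persist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np
from scipy.spatial import cKDTree

from .dose import Beamlet, BeamModel, DoseEngine, OPEN_EDGES, lateral_sigma
from .phantom import Phantom


# ---------------------------------------------------------------------------
# Stage schedule
# ---------------------------------------------------------------------------

def stage_angles(arc_start: float, arc_stop: float, stage: int) -> np.ndarray:
    """Evenly spaced control-point angles of evolutionary stage ``stage``.

    Stage 1 spans the arc with 3 control points (start, middle, stop);
    every subsequent stage doubles the resolution by midpoint insertion,
    giving ``2**stage + 1`` angles whose set contains all previous stages'.
    """
    if stage < 1:
        raise ValueError("stage must be >= 1")
    if arc_stop == arc_start:
        raise ValueError("arc span must be nonzero")
    return np.linspace(arc_start, arc_stop, 2 ** stage + 1)


# ---------------------------------------------------------------------------
# Energy layers and spots
# ---------------------------------------------------------------------------

def candidate_energy_layers(engine: DoseEngine, gantry_angle: float,
                            spacing_wet: float = 0.5,
                            target: str = "target") -> np.ndarray:
    """Uniformly spaced candidate ranges (cm WET) covering the target.

    The span of water-equivalent depths of target voxels from this gantry
    angle is rounded outward to multiples of ``spacing_wet`` so the whole
    target depth is bracketed.
    """
    mask = engine.phantom.mask(target).ravel()
    if not mask.any():
        raise ValueError("empty target")
    wet = engine.wet_map(gantry_angle)[mask]
    lo = np.floor(wet.min() / spacing_wet + 1e-9) * spacing_wet
    hi = np.ceil(wet.max() / spacing_wet - 1e-9) * spacing_wet
    n = int(round((hi - lo) / spacing_wet)) + 1
    return lo + spacing_wet * np.arange(n)


def target_cross_section(engine: DoseEngine, gantry_angle: float,
                         range_R: float, band: float = 0.25,
                         target: str = "target") -> np.ndarray:
    """BEV (u, v) sample points (mm) of target voxels whose WET lies within
    ``band`` cm of the layer's range — the lateral footprint this energy
    layer is responsible for."""
    mask = engine.phantom.mask(target).ravel()
    wet = engine.wet_map(gantry_angle)
    cu, cv = engine.bev_coords(gantry_angle)
    sel = mask & (np.abs(wet - range_R) <= band + 1e-12)
    return np.column_stack([cu[sel], cv[sel]])


def place_spots(engine: DoseEngine, gantry_angle: float, range_R: float,
                pitch: float = 4.0, band: float = 0.25,
                target: str = "target") -> np.ndarray:
    """Uniform BEV spot grid covering a layer's target cross-section.

    Grid points are aligned to the BEV origin (isocentre projection) at
    ``pitch`` mm spacing and kept when within one pitch of the cross-section
    (a one-pitch lateral margin).  Returned row-major in the BEV (v, then u),
    shape (n, 2); empty when the layer covers no target at this angle.
    """
    xs = target_cross_section(engine, gantry_angle, range_R, band, target)
    if len(xs) == 0:
        return np.zeros((0, 2))
    lo = np.floor((xs.min(axis=0) - pitch) / pitch).astype(int)
    hi = np.ceil((xs.max(axis=0) + pitch) / pitch).astype(int)
    uu = pitch * np.arange(lo[0], hi[0] + 1)
    vv = pitch * np.arange(lo[1], hi[1] + 1)
    gu, gv = np.meshgrid(uu, vv, indexing="xy")  # rows of constant v
    grid = np.column_stack([gu.ravel(), gv.ravel()])
    dist, _ = cKDTree(xs).query(grid)
    return grid[dist <= pitch + 1e-9]


# ---------------------------------------------------------------------------
# Control points and chromosomes
# ---------------------------------------------------------------------------

@dataclass
class ControlPoint:
    """One discretized gantry angle with its candidate layers and spots."""

    gantry_angle: float
    candidate_ranges: np.ndarray
    spots: list[np.ndarray]          # spot grid per candidate layer
    locked: bool = False
    assigned_layer: int | None = None

    def n_layers(self) -> int:
        return len(self.candidate_ranges)


def build_control_points(engine: DoseEngine, angles, spacing_wet: float = 0.5,
                         pitch: float = 4.0,
                         target: str = "target") -> list[ControlPoint]:
    """Candidate layers and per-layer spot grids for each arc angle."""
    cps = []
    for a in np.asarray(angles, dtype=float):
        ranges = candidate_energy_layers(engine, a, spacing_wet, target)
        spots = [place_spots(engine, a, r, pitch, spacing_wet / 2.0, target)
                 for r in ranges]
        cps.append(ControlPoint(gantry_angle=float(a), candidate_ranges=ranges,
                                spots=spots))
    return cps


@dataclass
class Chromosome:
    """Haploid encoding: one energy-layer index per control point."""

    loci: np.ndarray                 # int layer index per control point
    locked: np.ndarray               # bool per control point
    weights: np.ndarray | None = None
    fitness: float | None = None
    creation_index: int = 0

    def copy(self) -> "Chromosome":
        return Chromosome(self.loci.copy(), self.locked.copy(),
                          None if self.weights is None else self.weights.copy(),
                          self.fitness, self.creation_index)


def chromosome_beamlets(cps: list[ControlPoint], chrom: Chromosome,
                        model: BeamModel) -> list[Beamlet]:
    """Beamlet list implied by a chromosome (uncollimated), in control-point
    order then row-major spot order."""
    beamlets = []
    for cp, li in zip(cps, chrom.loci):
        r = float(cp.candidate_ranges[li])
        s0 = float(model.sigma0(r))
        for spot in cp.spots[li]:
            beamlets.append(Beamlet(cp.gantry_angle, r, (spot[0], spot[1]), s0))
    return beamlets


def segment_sizes(cps: list[ControlPoint], chrom: Chromosome) -> np.ndarray:
    """Beamlet count contributed by each control point under ``chrom``."""
    return np.array([len(cp.spots[li]) for cp, li in zip(cps, chrom.loci)],
                    dtype=int)


# ---------------------------------------------------------------------------
# Arc plans
# ---------------------------------------------------------------------------

@dataclass
class ArcPlan:
    """A deliverable plan: one energy layer per control point plus weights."""

    angles: np.ndarray
    ranges: np.ndarray               # assigned range (cm) per control point
    beamlets: list[Beamlet]
    weights: np.ndarray
    collimated: bool = False
    normalization: float = 1.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        cps = []
        k = 0
        for a, r in zip(self.angles, self.ranges):
            spots = []
            while k < len(self.beamlets) and \
                    self.beamlets[k].gantry_angle == a and \
                    self.beamlets[k].range_R == r:
                b = self.beamlets[k]
                spots.append({"x": b.spot_xy[0], "y": b.spot_xy[1],
                              "weight": float(self.weights[k]),
                              "edges": None if b.edges is None else
                              [None if not np.isfinite(e) else float(e)
                               for e in b.edges]})
                k += 1
            cps.append({"angle": float(a), "range": float(r), "spots": spots})
        return json.dumps({"control_points": cps,
                           "collimated": self.collimated,
                           "normalization": self.normalization,
                           "seed": self.seed, "meta": self.meta}, indent=1)


# ---------------------------------------------------------------------------
# Collimation assignment
# ---------------------------------------------------------------------------

def _axis_edges(samples: np.ndarray, spot: float, other: np.ndarray,
                other_spot: float, tol: float, three_sigma: float):
    """Trimmer edge offsets along one BEV axis at the spot's row.

    The target boundary along the axis is taken from the extreme
    cross-section samples in the row |other - other_spot| <= tol; a side is
    trimmed only when its boundary lies within ``three_sigma`` mm of the
    spot centre, otherwise it stays open.
    """
    row = np.abs(other - other_spot) <= tol
    if not row.any():
        return -np.inf, np.inf
    lo_b = samples[row].min() - spot
    hi_b = samples[row].max() - spot
    lo = lo_b if abs(lo_b) <= three_sigma else -np.inf
    hi = hi_b if abs(hi_b) <= three_sigma else np.inf
    if not lo < hi:  # degenerate trim window on a single-sample row
        return -np.inf, np.inf
    return lo, hi


def collimate_beamlet(engine: DoseEngine, beamlet: Beamlet, pitch: float = 4.0,
                      band: float = 0.25, target: str = "target") -> Beamlet:
    """Assign per-beamlet trimmer edges at the BEV target boundary.

    Each lateral side is trimmed at the target cross-section boundary when
    that boundary lies within 3 sigma (lateral sigma at the Bragg peak) of
    the spot centre; sides farther than 3 sigma are left open, so beamlets
    deep inside the target are unchanged.
    """
    xs = target_cross_section(engine, beamlet.gantry_angle, beamlet.range_R,
                              band, target)
    if len(xs) == 0:
        return beamlet
    sig = float(lateral_sigma(beamlet.range_R, beamlet.range_R,
                              beamlet.sigma0, engine.model))
    tol = max(pitch / 2.0, max(engine.phantom.voxel_size) / 2.0)
    su, sv = beamlet.spot_xy
    ulo, uhi = _axis_edges(xs[:, 0], su, xs[:, 1], sv, tol, 3.0 * sig)
    vlo, vhi = _axis_edges(xs[:, 1], sv, xs[:, 0], su, tol, 3.0 * sig)
    edges = (ulo, uhi, vlo, vhi)
    if edges == OPEN_EDGES:
        return beamlet
    return replace(beamlet, edges=edges)


def set_collimation(engine: DoseEngine, beamlets: list[Beamlet], mode: str,
                    pitch: float = 4.0, band: float = 0.25,
                    target: str = "target") -> list[Beamlet]:
    """Apply a collimation mode to a beamlet list.

    ``"none"`` opens every trimmer; ``"per_beamlet_edge"`` trims each beamlet
    individually at the target boundary.  The returned plan must be
    re-optimized (weights) before evaluation.
    """
    if mode == "none":
        return [b.uncollimated() for b in beamlets]
    if mode == "per_beamlet_edge":
        return [collimate_beamlet(engine, b, pitch, band, target)
                for b in beamlets]
    raise ValueError(f"unknown collimation mode {mode!r}")
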