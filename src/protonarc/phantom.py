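"""Synthetic voxel phantoms and derived structures.

A :class:`Phantom` is a 3-D voxel grid of relative stopping powers (RSP,
water = 1) together with named binary structure masks (body, target, organs
at risk, and derived margins).  Phantoms are rasterized from geometric
primitives by voxel-centre containment, which keeps every construction
deterministic and trivially checkable by brute force.

Conventions
-----------
* Axis order is ``(x, y, z)`` with x pointing toward patient-left, y toward
  anterior, z toward superior.  Beams lie in the axial (x, y) plane.
* World coordinates are in millimetres at voxel centres; the grid is centred
  on the world origin and the isocentre defaults to the target centroid.
* Distances (ring margins, skin thickness) are metric and honour anisotropic
  voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """A primitive does not fit the grid or a structure is inconsistent."""


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Primitive:
    """Solid used to rasterize structures.

    Parameters
    ----------
    kind:
        ``"sphere"``, ``"ellipsoid"``, ``"cylinder"`` (axis along z) or
        ``"box"``.
    center:
        World coordinates of the centre, mm.
    radii:
        Semi-axes in mm.  A sphere uses ``radii[0]``; a cylinder uses
        ``radii[0]`` as the radius and ``radii[2]`` as the half-length along
        z (``inf`` for a full-grid cylinder); a box uses half-sizes.
    """

    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean containment test for an (N, 3) array of mm coordinates."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center, dtype=float)
        rx, ry, rz = self.radii
        if self.kind == "sphere":
            return np.einsum("ij,ij->i", p, p) <= rx * rx
        if self.kind == "ellipsoid":
            q = p / np.array([rx, ry, rz])
            return np.einsum("ij,ij->i", q, q) <= 1.0
        if self.kind == "cylinder":
            in_plane = p[:, 0] ** 2 + p[:, 1] ** 2 <= rx * rx
            if np.isinf(rz):
                return in_plane
            return in_plane & (np.abs(p[:, 2]) <= rz)
        if self.kind == "box":
            return (
                (np.abs(p[:, 0]) <= rx)
                & (np.abs(p[:, 1]) <= ry)
                & (np.abs(p[:, 2]) <= rz)
            )
        raise ValueError(f"unknown primitive kind {self.kind!r}")

    def bounding_half_extents(self) -> np.ndarray:
        """Per-axis half-extents of the solid's bounding box (mm)."""
        rx, ry, rz = self.radii
        if self.kind == "sphere":
            return np.array([rx, rx, rx])
        if self.kind == "cylinder":
            return np.array([rx, rx, rz])
        return np.array([rx, ry, rz])


def sphere(center, radius) -> Primitive:
    return Primitive("sphere", tuple(center), (radius, radius, radius))


def cylinder(center, radius, half_length=np.inf) -> Primitive:
    return Primitive("cylinder", tuple(center), (radius, radius, half_length))


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """Voxelized geometry: RSP grid plus named binary structure masks."""

    rsp: np.ndarray
    voxel_size: tuple[float, float, float]
    structures: dict[str, np.ndarray]
    body_name: str = "body"
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rsp = np.asarray(self.rsp, dtype=float)
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        self.validate()

    # -- basic queries ------------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.rsp.shape  # type: ignore[return-value]

    @property
    def body(self) -> np.ndarray:
        return self.structures[self.body_name]

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"unknown structure {name!r}") from None

    def voxel_centers(self) -> np.ndarray:
        """World mm coordinates of all voxel centres, shape (N, 3), C order."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * d
            for n, d in zip(self.grid_shape, self.voxel_size)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def validate(self) -> None:
        if np.any(self.rsp < 0):
            raise GeometryError("negative relative stopping power")
        if self.body_name not in self.structures:
            raise GeometryError(f"missing body structure {self.body_name!r}")
        body = self.structures[self.body_name]
        if np.any(self.rsp[~body] != 0):
            raise GeometryError("nonzero RSP outside the body")
        for name, m in self.structures.items():
            if m.shape != self.rsp.shape:
                raise GeometryError(f"structure {name!r} shape mismatch")
            if name != self.body_name and np.any(m & ~body):
                raise GeometryError(f"structure {name!r} extends outside body")


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Declarative description of a synthetic phantom.

    ``rsp_overrides`` assigns alternative stopping powers inside listed
    primitives (applied in order, clipped to the body), which is how
    heterogeneous slabs are introduced for testing.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    body: Primitive
    target: Primitive | None = None
    oars: dict[str, Primitive] = field(default_factory=dict)
    body_rsp: float = 1.0
    rsp_overrides: list[tuple[Primitive, float]] = field(default_factory=list)


def _check_inside_grid(prim: Primitive, spec: PhantomSpec, label: str) -> None:
    half_extent = np.array(spec.grid_shape) * np.array(spec.voxel_size) / 2.0
    c = np.abs(np.asarray(prim.center))
    r = prim.bounding_half_extents()
    over = c + r > half_extent + 1e-9
    # infinite extents are clipped by the grid by construction, and a
    # single-voxel axis models a thin replicated slab, so neither is an escape
    thin = np.array(spec.grid_shape) == 1
    if np.any(over & np.isfinite(r) & ~thin):
        raise GeometryError(f"{label} primitive extends outside the grid")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a :class:`PhantomSpec` by voxel-centre containment."""
    _check_inside_grid(spec.body, spec, "body")
    if spec.target is not None:
        _check_inside_grid(spec.target, spec, "target")
    for name, prim in spec.oars.items():
        _check_inside_grid(prim, spec, name)

    shape = tuple(spec.grid_shape)
    # build a throwaway phantom only to get voxel centres
    centers_axes = [
        (np.arange(n) - (n - 1) / 2.0) * d
        for n, d in zip(shape, spec.voxel_size)
    ]
    gx, gy, gz = np.meshgrid(*centers_axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    body = spec.body.contains(pts).reshape(shape)
    rsp = np.where(body, spec.body_rsp, 0.0)
    for prim, value in spec.rsp_overrides:
        m = prim.contains(pts).reshape(shape) & body
        rsp[m] = value

    structures: dict[str, np.ndarray] = {"body": body}
    iso = np.zeros(3)
    if spec.target is not None:
        target = spec.target.contains(pts).reshape(shape) & body
        if not target.any():
            raise GeometryError("target rasterized to zero volume")
        structures["target"] = target
        iso = pts[target.ravel()].mean(axis=0)
    for name, prim in spec.oars.items():
        structures[name] = prim.contains(pts).reshape(shape) & body

    return Phantom(rsp=rsp, voxel_size=tuple(spec.voxel_size),
                   structures=structures, isocenter=iso)


# ---------------------------------------------------------------------------
# Derived structures
# ---------------------------------------------------------------------------

def _distance_to_set(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Euclidean mm distance from every voxel centre to the nearest voxel
    centre inside ``mask`` (0 inside the mask)."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=voxel_size)


def expand_ring(phantom: Phantom, structure: str, margin: float) -> np.ndarray:
    """In-body voxels within ``margin`` mm of ``structure``, excluding it.

    Distances are centre-to-centre Euclidean distances to the nearest voxel
    of the structure, honouring anisotropic voxel sizes.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    m = phantom.mask(structure)
    dist = _distance_to_set(m, phantom.voxel_size)
    return (dist > 0) & (dist <= margin) & phantom.body & ~m


def skin_shell(phantom: Phantom, thickness: float) -> np.ndarray:
    """In-body voxels within ``thickness`` mm of the body surface.

    The surface distance of an in-body voxel is the Euclidean distance from
    its centre to the nearest out-of-body voxel centre.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    body = phantom.body
    if not body.any():
        raise GeometryError("empty body")
    depth = ndimage.distance_transform_edt(body, sampling=phantom.voxel_size)
    return body & (depth <= thickness)


def healthy_region(phantom: Phantom, target: str = "target",
                   ring: str = "ring10mm", skin: str = "skin") -> np.ndarray:
    """Healthy tissue inside the skin surface and outside the target margin.

    This is the region over which integral dose is accumulated: body minus
    target, minus the surrounding ring, minus the skin shell.
    """
    return (phantom.body
            & ~phantom.mask(target)
            & ~phantom.mask(ring)
            & ~phantom.mask(skin))


# ---------------------------------------------------------------------------
# Reference phantom for desk-scale studies
# ---------------------------------------------------------------------------

def reference_phantom() -> Phantom:
    """Desk-scale axial-slab analogue of an intracranial planning case.

    A single 2 mm slice of a 64x64 grid (2 mm voxels): water cylinder body
    of radius 60 mm, spherical target of radius 12 mm offset 20 mm toward
    patient-right, and an abutting cylindrical OAR ("brainstem") of radius
    6 mm placed medially.  Derived structures follow the planning-study
    conventions: a 10 mm ring of healthy tissue around the target, a 5 mm
    skin shell, and the remaining healthy brain.
    """
    spec = PhantomSpec(
        grid_shape=(64, 64, 1),
        voxel_size=(2.0, 2.0, 2.0),
        body=cylinder((0.0, 0.0, 0.0), 60.0),
        target=sphere((-20.0, 0.0, 0.0), 12.0),
        oars={"brainstem": cylinder((-2.0, 0.0, 0.0), 6.0)},
    )
    ph = make_phantom(spec)
    ph.structures["ring10mm"] = expand_ring(ph, "target", 10.0)
    ph.structures["skin"] = skin_shell(ph, 5.0)
    ph.structures["brain"] = healthy_region(ph)
    ph.validate()
    return ph
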