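"""Synthetic phantom generation.

Two families of CT surrogates:

* **Slab phantoms** — layered tissue | lung | tissue along the beam axis
  with a box CTV downstream of the lung layer.  These reproduce the
  canonical benchmark geometry (80 mm lung, CTV 34-47 mm beyond it) used to
  study PTV concepts.
* **Patient-like phantoms** — an elliptic-cylinder tissue body containing
  an ellipsoidal lung compartment with a spherical CTV carved into it, so
  that the geometric path through lung voxels along the beam ray to the CTV
  centroid equals a requested depth.  Only the (tumor volume, depth in
  lung, distal-OAR) covariates of real anatomies are emulated, not their
  shapes.

Default mean lung density is 0.26 (ICRU-lung-like, relative to water);
tumors are water-equivalent (density 1.0).
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .beam import BeamGeometry, wepl_trace
from .grids import Phantom, StructureMask, VoxelGrid

LUNG_DENSITY_DEFAULT = 0.26
TISSUE_DENSITY = 1.0

# patient-like body geometry (mm): elliptic cylinder and lung ellipsoid
BODY_HALF_AXES = (130.0, 95.0)
LUNG_CENTER = (-30.0, 0.0, 0.0)
LUNG_HALF_AXES = (72.0, 62.0, 40.0)


def sphere_radius_for_volume(volume_cm3: float) -> float:
    """Radius in mm of a sphere with the given volume: r = (3V/4pi)^(1/3)."""
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def sphere_mask(grid: VoxelGrid, center_mm: Sequence[float], radius_mm: float,
                name: str = "sphere") -> StructureMask:
    """Boolean mask of voxels whose centers lie within ``radius_mm`` of
    ``center_mm``.  A sphere fully outside the grid yields an empty mask
    plus a warning."""
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    c = np.asarray(center_mm, dtype=float)
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    r2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
    mask = r2 <= radius_mm ** 2
    if not mask.any():
        warnings.warn(
            f"sphere at {tuple(c)} r={radius_mm} mm lies outside the grid; "
            "mask is empty", stacklevel=2)
    return StructureMask.from_grid(name, mask, grid)


def build_slab_phantom(entrance_tissue_mm: float = 10.0,
                       lung_mm: float = 80.0,
                       lung_density: float = LUNG_DENSITY_DEFAULT,
                       ctv_span_mm: Tuple[float, float] = (34.0, 47.0),
                       grid_spacing_mm: float = 1.0,
                       lateral_mm: float = 60.0,
                       ctv_lateral_mm: float = 24.0,
                       distal_tissue_mm: float = 40.0) -> Phantom:
    """Layered slab phantom: tissue | lung | tissue along +y (gantry 0 deg).

    ``ctv_span_mm`` is measured downstream from the lung exit; the CTV is a
    box of that depth span and lateral half-width ``ctv_lateral_mm / 2``.
    ``lung_mm = 0`` degenerates to a homogeneous tissue phantom with an
    empty lung mask.  A CTV span that would start inside the lung layer is
    an error (the benchmark CTV sits downstream of the lung).
    """
    if entrance_tissue_mm <= 0 or grid_spacing_mm <= 0:
        raise ValueError("thicknesses and spacing must be > 0")
    if lung_mm < 0:
        raise ValueError("lung thickness must be >= 0")
    if lung_mm > 0 and not (0.0 < lung_density < 1.0):
        raise ValueError("lung_density must lie in (0, 1)")
    if ctv_span_mm[0] >= ctv_span_mm[1]:
        raise ValueError("ctv_span_mm must be an increasing (start, stop) pair")
    if ctv_span_mm[0] < 0:
        raise ValueError(
            "CTV span overlaps the lung layer; the CTV must start downstream "
            "of the lung exit")

    s = grid_spacing_mm
    depth_total = entrance_tissue_mm + lung_mm + ctv_span_mm[1] + distal_tissue_mm
    ny = int(round(depth_total / s))
    nxz = int(round(lateral_mm / s))
    origin = (-lateral_mm / 2.0 + s / 2.0, s / 2.0, -lateral_mm / 2.0 + s / 2.0)
    density = np.full((nxz, ny, nxz), TISSUE_DENSITY)
    grid = VoxelGrid(density, (s, s, s), origin)

    ys = grid.axis_coords(1)
    lung_lo, lung_hi = entrance_tissue_mm, entrance_tissue_mm + lung_mm
    in_lung = (ys >= lung_lo) & (ys < lung_hi)
    density[:, in_lung, :] = lung_density if lung_mm > 0 else TISSUE_DENSITY
    lung = np.zeros(grid.dims, dtype=bool)
    if lung_mm > 0:
        lung[:, in_lung, :] = True

    ctv_lo = lung_hi + ctv_span_mm[0]
    ctv_hi = lung_hi + ctv_span_mm[1]
    xs = grid.axis_coords(0)
    zs = grid.axis_coords(2)
    half = ctv_lateral_mm / 2.0
    ctv = (np.abs(xs)[:, None, None] <= half) \
        & ((ys >= ctv_lo) & (ys < ctv_hi))[None, :, None] \
        & (np.abs(zs)[None, None, :] <= half)
    if not ctv.any():
        raise ValueError("CTV box is empty; check spans and grid extents")
    density[ctv] = TISSUE_DENSITY

    structures = {"CTV": StructureMask.from_grid("CTV", ctv, grid)}
    meta = {
        "kind": "slab",
        "beam_axis": 1,
        "beam_angle_deg": 0.0,
        "entrance_tissue_mm": entrance_tissue_mm,
        "lung_interval_mm": (lung_lo, lung_hi),
        "lung_density": lung_density if lung_mm > 0 else None,
        "ctv_interval_mm": (ctv_lo, ctv_hi),
        "grid_spacing_mm": s,
    }
    return Phantom(grid, StructureMask.from_grid("lung", lung, grid),
                   structures, meta)


def _ellipsoid_ray_interval(origin: np.ndarray, direction: np.ndarray,
                            center: np.ndarray, half_axes: np.ndarray
                            ) -> Optional[Tuple[float, float]]:
    """Ray parameters (t_in, t_out) of the intersection with an ellipsoid."""
    o = (origin - center) / half_axes
    d = direction / half_axes
    a = float(d @ d)
    b = 2.0 * float(o @ d)
    c = float(o @ o) - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:
        return None
    sq = math.sqrt(disc)
    return ((-b - sq) / (2 * a), (-b + sq) / (2 * a))


def _measure_lung_depth(phantom_density_like: VoxelGrid, lung: np.ndarray,
                        origin, direction, point) -> float:
    """Geometric path length through lung voxels along a ray (voxelized)."""
    lung_grid = VoxelGrid(lung.astype(float), phantom_density_like.spacing,
                          phantom_density_like.origin)
    return wepl_trace(lung_grid, origin, direction, point)


def measure_ctv_depth_in_lung(phantom: Phantom, beam_angle_deg: float) -> float:
    """Path length through lung voxels along the beam ray to the CTV centroid."""
    centroid = phantom.ctv.centroid_mm()
    beam = BeamGeometry(beam_angle_deg, tuple(centroid))
    origin = beam.source_point(600.0)
    return _measure_lung_depth(phantom.density, phantom.lung_mask.mask,
                               origin, beam.direction, centroid)


def build_patient_like_phantom(ctv_volume_cm3: float,
                               ctv_depth_in_lung_mm: float,
                               beam_angle_deg: float = 270.0,
                               oar_spec: Optional[List[Dict]] = None,
                               grid_spacing_mm: float = 2.0,
                               seed: int = 0,
                               lung_density: float = LUNG_DENSITY_DEFAULT,
                               z_extent_mm: float = 100.0,
                               jitter_mm: float = 5.0) -> Phantom:
    """Patient-like phantom with a spherical CTV at a prescribed lung depth.

    The CTV sphere is placed on the beam ray so that the measured geometric
    path through lung voxels from the body surface to the CTV centroid
    equals ``ctv_depth_in_lung_mm`` within one voxel (the placement is
    refined against the voxelized lung mask).  ``seed`` controls a small
    random lateral offset of the aim point, giving reproducible anatomical
    variety.  ``oar_spec`` entries (dicts with keys ``name``, ``shape`` in
    {"cylinder", "sphere"}, ``radius_mm``, ``offset_mm``) are placed distal
    to the CTV along the beam axis.
    """
    if not (1.0 <= ctv_volume_cm3 <= 100.0):
        raise ValueError("ctv_volume_cm3 must lie within [1, 100] cm^3")
    if ctv_depth_in_lung_mm <= 0:
        raise ValueError("ctv_depth_in_lung_mm must be > 0")

    rng = np.random.default_rng(seed)
    r_ctv = sphere_radius_for_volume(ctv_volume_cm3)
    s = grid_spacing_mm

    # grid covering the body with one voxel of air margin
    ax, ay = BODY_HALF_AXES
    nx = int(round(2 * (ax + 2 * s) / s))
    ny = int(round(2 * (ay + 2 * s) / s))
    nz = int(round(z_extent_mm / s))
    origin = (-(nx - 1) * s / 2.0, -(ny - 1) * s / 2.0, -(nz - 1) * s / 2.0)
    grid = VoxelGrid(np.zeros((nx, ny, nz)), (s, s, s), origin)
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]

    body = (xs / ax) ** 2 + (ys / ay) ** 2 <= 1.0
    body = np.broadcast_to(body, grid.dims).copy()
    lung_c = np.asarray(LUNG_CENTER)
    lung_h = np.asarray(LUNG_HALF_AXES)
    lung_full = ((xs - lung_c[0]) / lung_h[0]) ** 2 \
        + ((ys - lung_c[1]) / lung_h[1]) ** 2 \
        + ((zs - lung_c[2]) / lung_h[2]) ** 2 <= 1.0

    # analytic placement of the CTV center on the beam ray
    aim = lung_c + rng.uniform(-jitter_mm, jitter_mm, 3) * np.array([0.0, 1.0, 1.0]) \
        if beam_angle_deg % 180 == 90 else \
        lung_c + rng.uniform(-jitter_mm, jitter_mm, 3) * np.array([1.0, 0.0, 1.0]) \
        if beam_angle_deg % 180 == 0 else \
        lung_c + rng.uniform(-jitter_mm, jitter_mm, 3) * np.array([0.5, 0.5, 1.0])
    beam = BeamGeometry(beam_angle_deg, tuple(aim))
    d = beam.direction
    src = beam.source_point(600.0)
    iv = _ellipsoid_ray_interval(src, d, lung_c, lung_h)
    if iv is None:
        raise ValueError("beam ray misses the lung compartment")
    t_in, t_out = iv
    chord = t_out - t_in
    max_depth = chord - 2 * r_ctv - 2 * s
    if ctv_depth_in_lung_mm > max_depth:
        raise ValueError(
            f"requested depth {ctv_depth_in_lung_mm} mm exceeds the lung "
            f"extent; maximum achievable depth for this volume/angle is "
            f"{max_depth:.1f} mm")
    t_c = t_in + ctv_depth_in_lung_mm + r_ctv
    center = src + t_c * d

    # refine against the voxelized lung mask so the measured depth matches
    for _ in range(4):
        ctv = _sphere_bool(xs, ys, zs, center, r_ctv)
        lung = lung_full & ~ctv
        measured = _measure_lung_depth(grid, lung, src, d, center)
        err = ctv_depth_in_lung_mm - measured
        if abs(err) <= 0.3 * s:
            break
        center = center + err * d
    ctv = _sphere_bool(xs, ys, zs, center, r_ctv)
    if not ctv.any():
        raise ValueError("CTV sphere produced an empty mask; check grid spacing")

    structures = {"CTV": StructureMask.from_grid("CTV", ctv, grid)}
    solid = ctv.copy()
    t_ctv_distal = float((center - src) @ d) + r_ctv
    for spec in oar_spec or []:
        oar = _make_oar(grid, xs, ys, zs, spec, src, d, t_ctv_distal)
        structures[oar.name] = oar
        solid |= oar.mask

    lung = lung_full & ~solid
    density = grid.values
    density[body] = TISSUE_DENSITY
    density[lung] = lung_density
    density[solid & body] = TISSUE_DENSITY

    meta = {
        "kind": "patient_like",
        "beam_angle_deg": float(beam_angle_deg),
        "ctv_volume_cm3": ctv_volume_cm3,
        "ctv_radius_mm": r_ctv,
        "requested_depth_mm": ctv_depth_in_lung_mm,
        "ctv_center_mm": tuple(float(c) for c in center),
        "grid_spacing_mm": s,
        "seed": int(seed),
        "lung_density": lung_density,
    }
    phantom = Phantom(grid, StructureMask.from_grid("lung", lung, grid),
                      structures, meta)
    meta["measured_depth_mm"] = measure_ctv_depth_in_lung(phantom, beam_angle_deg)
    return phantom


def _sphere_bool(xs, ys, zs, center, radius) -> np.ndarray:
    return ((xs - center[0]) ** 2 + (ys - center[1]) ** 2
            + (zs - center[2]) ** 2) <= radius ** 2


def _make_oar(grid: VoxelGrid, xs, ys, zs, spec: Dict, src: np.ndarray,
              d: np.ndarray, t_ctv_distal: float) -> StructureMask:
    radius = float(spec.get("radius_mm", 5.0))
    offset = float(spec.get("offset_mm", 10.0))
    name = spec.get("name", "OAR")
    shape = spec.get("shape", "cylinder")
    c = src + (t_ctv_distal + offset + radius) * d
    if shape == "sphere":
        mask = _sphere_bool(xs, ys, zs, c, radius)
    elif shape == "cylinder":  # axis along z (spinal-cord/trachea-like)
        mask = ((xs - c[0]) ** 2 + (ys - c[1]) ** 2 <= radius ** 2) \
            & np.broadcast_to(np.abs(zs - c[2]) <= 30.0, grid.dims)
    else:
        raise ValueError(f"unknown OAR shape '{shape}'")
    if not mask.any():
        warnings.warn(f"OAR '{name}' fell outside the grid; empty mask",
                      stacklevel=2)
    return StructureMask.from_grid(name, mask, grid)
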