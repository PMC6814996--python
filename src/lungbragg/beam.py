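"""Pristine pencil-beam physics.

Depth-dose curves in water, the range-energy relation, lateral spot sizes
calibrated to two measured in-air FWHM points, and exact water-equivalent
path-length (WEPL) ray tracing through a voxel phantom.

Model summary
-------------
* Range-energy: power law ``R(E) = alpha * E**p`` with the widely used
  water constants ``alpha = 0.0022 cm / MeV**p`` and ``p = 1.77``.
* Depth dose: analytic power-law Bragg curve (stopping term plus a linear
  fluence-loss term for nuclear interactions) convolved with a Gaussian
  range spread combining straggling (``0.012 * R**0.935`` cm) and a 1%
  beam energy spread in quadrature.  The sampled curve
  is shifted so its maximum sits exactly at ``R(E)``; dose is normalized to
  a physical peak of 1 per unit spot weight and multiplied by a constant
  RBE of 1.1, so curve values are Gy(RBE)-per-weight up to the plan's
  global calibration through the optimizer.
* Lateral profile: single Gaussian whose FWHM interpolates log-linearly
  between the two calibration points (70 MeV -> 32.5 mm, 221 MeV -> 8.1 mm)
  and is clamped (with a warning) outside that span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .grids import Phantom, VoxelGrid

# --- range-energy power law (water), depths in mm, energies in MeV ---
ALPHA_MM = 0.022            # 0.0022 cm/MeV^p expressed in mm
P_EXPONENT = 1.77
BETA_CM = 0.012             # fluence-loss slope, 1/cm
GAMMA_NUCLEAR = 0.6         # fraction of locally deposited nuclear energy
RBE = 1.1

#: default machine energy window in MeV (slightly wider than the two FWHM
#: calibration energies so shallow proximal layers remain plannable)
MACHINE_WINDOW: Tuple[float, float] = (60.0, 230.0)

#: in-air FWHM calibration points, MeV -> mm
FWHM_CALIBRATION = ((70.0, 32.5), (221.0, 8.1))
GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def range_from_energy(energy_MeV, window: Tuple[float, float] = MACHINE_WINDOW):
    """Proton range in water (mm) from beam energy via ``R = alpha E^p``.

    Strictly increasing in energy.  Energies outside ``window`` raise a
    ``ValueError`` naming the validated window.
    """
    e = np.asarray(energy_MeV, dtype=float)
    if np.any(e < window[0]) or np.any(e > window[1]):
        raise ValueError(
            f"energy {energy_MeV} MeV outside validated window "
            f"[{window[0]}, {window[1]}] MeV"
        )
    r = ALPHA_MM * e ** P_EXPONENT
    return float(r) if np.isscalar(energy_MeV) else r


def energy_from_range(range_mm, window: Tuple[float, float] = MACHINE_WINDOW):
    """Inverse of :func:`range_from_energy` (mm -> MeV)."""
    r = np.asarray(range_mm, dtype=float)
    e = (r / ALPHA_MM) ** (1.0 / P_EXPONENT)
    if np.any(e < window[0]) or np.any(e > window[1]):
        raise ValueError(
            f"range {range_mm} mm needs energy {e} MeV outside window "
            f"[{window[0]}, {window[1]}] MeV"
        )
    return float(e) if np.isscalar(range_mm) else e


#: relative beam momentum/energy spread (synchrotron-like), folded into the
#: Gaussian range spread of the pristine curve
ENERGY_SPREAD_FRAC = 0.01


def straggling_sigma_mm(range_mm: float) -> float:
    """Range-straggling width in water: sigma = 0.012 R^0.935 (cm units)."""
    r_cm = range_mm / 10.0
    return 10.0 * 0.012 * r_cm ** 0.935


def range_spread_sigma_mm(energy_MeV: float,
                          energy_spread_frac: float = ENERGY_SPREAD_FRAC) -> float:
    """Total Gaussian range spread: straggling plus beam energy spread.

    The two contributions add in quadrature; the energy-spread term is
    ``sigma_E * dR/dE`` with ``sigma_E = energy_spread_frac * E``.
    """
    r0 = ALPHA_MM * energy_MeV ** P_EXPONENT
    s_mono = straggling_sigma_mm(r0)
    drde = ALPHA_MM * P_EXPONENT * energy_MeV ** (P_EXPONENT - 1.0)
    s_beam = energy_spread_frac * energy_MeV * drde
    return math.hypot(s_mono, s_beam)


@dataclass
class DepthDoseCurve:
    """1-D dose versus water-equivalent depth for one beam energy.

    ``depths`` is a uniform mm grid starting at 0; ``dose_per_weight`` is the
    RBE-weighted dose per unit spot weight.
    """

    depths: np.ndarray
    dose_per_weight: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.dose_per_weight = np.asarray(self.dose_per_weight, dtype=float)
        if self.depths.shape != self.dose_per_weight.shape:
            raise ValueError("depths and dose arrays must have equal length")
        if np.any(self.dose_per_weight < 0):
            raise ValueError("dose must be non-negative")

    @property
    def step(self) -> float:
        return float(self.depths[1] - self.depths[0])

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.dose_per_weight))

    @property
    def peak_depth(self) -> float:
        return float(self.depths[self.peak_index])

    @property
    def peak_dose(self) -> float:
        return float(self.dose_per_weight.max())

    def integral(self) -> float:
        """Depth-integrated dose (trapezoid)."""
        return float(np.trapezoid(self.dose_per_weight, self.depths))

    def interp(self, depth_mm) -> np.ndarray:
        """Linear interpolation; zero beyond the distal end."""
        return np.interp(depth_mm, self.depths, self.dose_per_weight,
                         left=self.dose_per_weight[0], right=0.0)

    def distal_depth_at_fraction(self, frac: float) -> float:
        """Depth on the distal edge where dose falls to ``frac`` of the peak."""
        level = frac * self.peak_dose
        d = self.dose_per_weight
        post = d[self.peak_index:]
        below = np.nonzero(post < level)[0]
        if below.size == 0:
            raise ValueError(f"distal dose never falls below {frac} of peak")
        j = self.peak_index + below[0]
        # linear interpolation between samples j-1 (>= level) and j (< level)
        d0, d1 = d[j - 1], d[j]
        t = (d0 - level) / (d0 - d1)
        return float(self.depths[j - 1] + t * self.step)

    def distal_falloff_width(self) -> float:
        """d80 -> d20 distal falloff width in mm."""
        return self.distal_depth_at_fraction(0.2) - self.distal_depth_at_fraction(0.8)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.depths, self.dose_per_weight]),
                   delimiter=",", header="depth_mm,dose", comments="")


def _raw_bragg_bin_average(z_lo: np.ndarray, z_hi: np.ndarray, r0: float) -> np.ndarray:
    """Bin averages of the unstraggled analytic Bragg curve.

    The curve ``D(z) ~ (R0-z)^(1/p-1) + c2 (R0-z)^(1/p)`` has an integrable
    singularity at ``z = R0``; averaging the exact antiderivative over each
    bin keeps the discretization well behaved there.
    """
    p = P_EXPONENT
    beta = BETA_CM / 10.0  # per mm
    c2 = beta * (1.0 + GAMMA_NUCLEAR * p)

    def antideriv(z):
        u = np.clip(r0 - z, 0.0, None)
        return -(p * u ** (1.0 / p)) - c2 * u ** (1.0 + 1.0 / p) / (1.0 + 1.0 / p)

    width = z_hi - z_lo
    return (antideriv(z_hi) - antideriv(z_lo)) / width


def pristine_curve(energy_MeV: float, depth_step_mm: float = 0.5,
                   fine_step_mm: float = 0.05,
                   window: Tuple[float, float] = MACHINE_WINDOW,
                   energy_spread_frac: float = ENERGY_SPREAD_FRAC
                   ) -> DepthDoseCurve:
    """Analytic pristine Bragg curve sampled on a uniform depth grid.

    Parameters
    ----------
    energy_MeV : float
        Beam energy within the machine window.
    depth_step_mm : float
        Output sampling step; must be <= 1 mm.
    fine_step_mm : float
        Internal step used for the straggling convolution.

    Returns
    -------
    DepthDoseCurve
        Peak-normalized (physical peak 1.0, RBE 1.1 folded in); the sampled
        peak position equals ``range_from_energy(energy)`` within one step.
    """
    if depth_step_mm > 1.0:
        raise ValueError("depth_step_mm must be <= 1 mm")
    r0 = range_from_energy(energy_MeV, window=window)
    sigma = range_spread_sigma_mm(energy_MeV, energy_spread_frac)

    pad = 5.0 * sigma + 2.0
    n_fine = int(math.ceil((r0 + pad) / fine_step_mm))
    edges = fine_step_mm * np.arange(n_fine + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    raw = np.zeros(n_fine)
    inside = edges[1:] <= r0
    raw[inside] = _raw_bragg_bin_average(edges[:-1][inside], edges[1:][inside], r0)
    # partial bin containing R0
    part = (~inside) & (edges[:-1] < r0)
    if part.any():
        raw[part] = _raw_bragg_bin_average(edges[:-1][part],
                                           np.full(part.sum(), r0), r0) \
            * (r0 - edges[:-1][part]) / fine_step_mm

    # Gaussian range straggling (discrete normalized kernel)
    half = int(math.ceil(4.0 * sigma / fine_step_mm))
    k = np.arange(-half, half + 1) * fine_step_mm
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    # replicate-pad proximally so the plateau is unaffected by the boundary
    padded = np.concatenate([np.full(half, raw[0]), raw, np.zeros(half)])
    smooth = np.convolve(padded, kernel, mode="valid")

    # calibrate the peak onto R(E)
    shift = r0 - centers[int(np.argmax(smooth))]
    depths_fine = centers + shift

    n_out = int(math.floor((r0 + 5.0 * sigma) / depth_step_mm)) + 1
    depths = depth_step_mm * np.arange(n_out)
    dose = np.interp(depths, depths_fine, smooth, left=smooth[0], right=0.0)
    dose = dose / dose.max() * RBE
    return DepthDoseCurve(depths, dose, float(energy_MeV))


def fwhm_air(energy_MeV) -> np.ndarray:
    """In-air spot FWHM (mm): log-linear interpolation between the two
    calibration points, clamped with a warning outside [70, 221] MeV."""
    (e1, f1), (e2, f2) = FWHM_CALIBRATION
    e = np.asarray(energy_MeV, dtype=float)
    if np.any(e < e1) or np.any(e > e2):
        warnings.warn(
            f"energy {energy_MeV} MeV outside FWHM calibration span "
            f"[{e1}, {e2}] MeV; clamping", stacklevel=2)
    ec = np.clip(e, e1, e2)
    logf = np.log(f1) + (ec - e1) * (np.log(f2) - np.log(f1)) / (e2 - e1)
    out = np.exp(logf)
    return float(out) if np.isscalar(energy_MeV) else out


def lateral_sigma(energy_MeV) -> np.ndarray:
    """Gaussian sigma (mm) of the lateral spot profile: FWHM / 2.3548."""
    f = fwhm_air(energy_MeV)
    return f * GAUSS_FWHM_TO_SIGMA


@dataclass
class BeamGeometry:
    """Single-field beam geometry in the axial plane.

    ``gantry_angle`` convention: 0 deg enters from anterior (travels +y),
    270 deg from the patient's right (travels +x); direction is
    ``(-sin(angle), cos(angle), 0)``.
    """

    gantry_angle: float
    isocenter: Tuple[float, float, float]

    def __post_init__(self) -> None:
        a = float(self.gantry_angle) % 360.0
        self.gantry_angle = a
        self.isocenter = tuple(float(c) for c in self.isocenter)

    @property
    def direction(self) -> np.ndarray:
        th = math.radians(self.gantry_angle)
        return np.array([-math.sin(th), math.cos(th), 0.0])

    @property
    def lateral_u(self) -> np.ndarray:
        """In-plane lateral unit vector (beam-eye x)."""
        th = math.radians(self.gantry_angle)
        return np.array([math.cos(th), math.sin(th), 0.0])

    @property
    def lateral_v(self) -> np.ndarray:
        """Out-of-plane lateral unit vector (beam-eye y, patient z)."""
        return np.array([0.0, 0.0, 1.0])

    def source_point(self, phantom_extent_mm: float = 1000.0) -> np.ndarray:
        """A point far upstream of the isocenter along the beam axis."""
        return np.asarray(self.isocenter) - phantom_extent_mm * self.direction


def wepl_trace(phantom_or_grid, ray_origin, ray_direction, point) -> float:
    """Water-equivalent path length along a ray, by exact voxel traversal.

    Integrates relative density from where the ray enters the grid (or from
    ``ray_origin`` if it starts inside) up to ``point``, visiting voxel
    boundary crossings exactly (Siddon-style), so the result is exact for
    piecewise-constant density.  ``point`` must lie on the ray downstream of
    the origin.  A ray that misses the grid returns 0 with a warning.
    """
    grid: VoxelGrid = phantom_or_grid.density if isinstance(phantom_or_grid, Phantom) \
        else phantom_or_grid
    o = np.asarray(ray_origin, dtype=float)
    d = np.asarray(ray_direction, dtype=float)
    d = d / np.linalg.norm(d)
    p = np.asarray(point, dtype=float)
    t_end = float(np.dot(p - o, d))
    if t_end < 0:
        raise ValueError("point lies upstream of the ray origin")
    off = p - (o + t_end * d)
    if np.linalg.norm(off) > 1e-6 * max(1.0, t_end):
        raise ValueError("point does not lie on the ray")

    sp = np.asarray(grid.spacing)
    lo = np.asarray(grid.origin) - 0.5 * sp           # outer face of voxel 0
    hi = lo + sp * np.asarray(grid.dims)

    # entry/exit parameters of the grid bounding box
    t0, t1 = 0.0, t_end
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if not (lo[ax] <= o[ax] <= hi[ax]):
                warnings.warn("ray misses the phantom; WEPL = 0", stacklevel=2)
                return 0.0
            continue
        ta = (lo[ax] - o[ax]) / d[ax]
        tb = (hi[ax] - o[ax]) / d[ax]
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        if t_end > 0 and t0 > t_end:
            return 0.0  # ray would hit the grid beyond the query point
        warnings.warn("ray misses the phantom; WEPL = 0", stacklevel=2)
        return 0.0

    # all boundary-plane crossings in (t0, t1)
    ts = [np.array([t0, t1])]
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        planes = lo[ax] + sp[ax] * np.arange(grid.dims[ax] + 1)
        tc = (planes - o[ax]) / d[ax]
        ts.append(tc[(tc > t0) & (tc < t1)])
    t_all = np.unique(np.concatenate(ts))

    mids = o[None, :] + 0.5 * (t_all[:-1] + t_all[1:])[:, None] * d[None, :]
    idx = np.floor((mids - (np.asarray(grid.origin) - 0.5 * sp)) / sp).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.dims) - 1)
    seg = np.diff(t_all)
    rho = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.sum(rho * seg))
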