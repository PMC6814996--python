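"""Spot-scanning plan engine.

PTV construction (three concepts), energy-layer / lateral spot placement,
non-negative weight optimization against the single planning objective
(>= 95% of the prescription to >= 98% of the PTV, hotspots capped at 115%),
and forward dose calculation for non-modulated and modulated scenarios.

The forward model is a pencil-beam superposition: for each spot the
depth-dose curve is looked up at the voxel's water-equivalent depth along
the beam and multiplied by a normalized lateral Gaussian.  Plans are
always optimized on the *non-modulated* phantom; modulated scenarios
recalculate the same spot weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import nnls

from .beam import (MACHINE_WINDOW, BeamGeometry, DepthDoseCurve,
                   energy_from_range, fwhm_air, lateral_sigma, pristine_curve,
                   range_from_energy)
from .degradation import ModulationModel, degradation_sigma, degraded_family, \
    sample_modulated_density
from .grids import Phantom, StructureMask, VoxelGrid

PRESCRIPTION_GY_RBE = 30.0
HOTSPOT_FACTOR = 1.15
DISTAL_SPACING_MM = 3.0
LATERAL_SPACING_FACTOR = 0.45
OPT_MAX_ITER = 500
OPT_TOL = 1e-6

_CURVE_CACHE: Dict[Tuple[float, float], DepthDoseCurve] = {}


def _cached_curve(energy: float, step: float = 0.5) -> DepthDoseCurve:
    key = (round(energy, 2), step)
    if key not in _CURVE_CACHE:
        _CURVE_CACHE[key] = pristine_curve(key[0], depth_step_mm=step)
    return _CURVE_CACHE[key]


@dataclass
class PencilSpot:
    energy: float          # MeV
    lateral_x: float       # mm, beam-eye (in-plane)
    lateral_y: float       # mm, beam-eye (patient z)
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass
class SpotPlan:
    beam: BeamGeometry
    spots: List[PencilSpot]
    prescription_Gy_RBE: float = PRESCRIPTION_GY_RBE
    ptv_concept: str = "isotropic"
    machine_window: Tuple[float, float] = MACHINE_WINDOW
    optimized: bool = False
    meta: Dict = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return float(sum(s.weight for s in self.spots))

    def layers(self) -> Dict[float, List[int]]:
        """Spot indices grouped by energy, distal layer first."""
        out: Dict[float, List[int]] = {}
        for i, s in enumerate(self.spots):
            out.setdefault(s.energy, []).append(i)
        return dict(sorted(out.items(), key=lambda kv: -kv[0]))


@dataclass
class DoseGrid:
    """RBE-weighted dose (Gy) aligned to the phantom grid."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    scenario: str = "non_modulated"
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("dose must be finite and >= 0")

    def same_geometry(self, other: "DoseGrid") -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))


class BeamFrame:
    """Beam-aligned resampling of a phantom for fast per-voxel line integrals.

    Builds a lattice aligned with (lateral-u, lateral-v, depth-t) axes of the
    beam, trilinearly resamples scalar fields onto it, accumulates them along
    depth (midpoint rule), and samples the result back at voxel centers.
    """

    def __init__(self, phantom: Phantom, beam: BeamGeometry,
                 step_mm: Optional[float] = None):
        self.phantom = phantom
        self.beam = beam
        grid = phantom.density
        self.step = float(step_mm or min(grid.spacing))
        d, u, v = beam.direction, beam.lateral_u, beam.lateral_v
        iso = np.asarray(beam.isocenter)

        xs = grid.axis_coords(0)
        ys = grid.axis_coords(1)
        zs = grid.axis_coords(2)
        # t and u depend only on (x, y); v only on z
        self._T2 = (xs[:, None] - iso[0]) * d[0] + (ys[None, :] - iso[1]) * d[1]
        self._U2 = (xs[:, None] - iso[0]) * u[0] + (ys[None, :] - iso[1]) * u[1]
        self._Vz = zs - iso[2]

        s = self.step
        pad = 2 * s
        self.t_lin = np.arange(self._T2.min() - pad, self._T2.max() + pad, s)
        self.u_lin = np.arange(self._U2.min() - pad, self._U2.max() + pad, s)
        self.v_lin = np.arange(self._Vz.min() - pad, self._Vz.max() + pad, s)

        # world coordinates of lattice nodes -> fractional grid indices
        uu = self.u_lin[:, None, None]
        vv = self.v_lin[None, :, None]
        tt = self.t_lin[None, None, :]
        px = iso[0] + uu * u[0] + tt * d[0] + vv * 0.0
        py = iso[1] + uu * u[1] + tt * d[1] + vv * 0.0
        pz = np.broadcast_to(iso[2] + vv, px.shape)
        org = np.asarray(grid.origin)
        sp = np.asarray(grid.spacing)
        self._lattice_idx = np.stack([
            (np.broadcast_to(px, px.shape) - org[0]) / sp[0],
            (np.broadcast_to(py, px.shape) - org[1]) / sp[1],
            (np.broadcast_to(pz, px.shape) - org[2]) / sp[2],
        ])

        # voxel-center positions in lattice index units
        self._vox_iu = (self._U2 - self.u_lin[0]) / s
        self._vox_it = (self._T2 - self.t_lin[0]) / s
        self._vox_iv = (self._Vz - self.v_lin[0]) / s

    def voxel_uvt(self):
        """Beam-eye coordinates of every voxel center: (U, V, T) arrays
        broadcastable to the phantom shape."""
        nx, ny = self._U2.shape
        nz = self._Vz.size
        U = np.broadcast_to(self._U2[:, :, None], (nx, ny, nz))
        T = np.broadcast_to(self._T2[:, :, None], (nx, ny, nz))
        V = np.broadcast_to(self._Vz[None, None, :], (nx, ny, nz))
        return U, V, T

    def line_integral_volume(self, field: np.ndarray) -> np.ndarray:
        """Per-voxel line integral of ``field`` from upstream of the phantom
        to each voxel center, along the beam direction (mm units)."""
        sampled = ndimage.map_coordinates(np.asarray(field, dtype=np.float64),
                                          self._lattice_idx, order=1, cval=0.0)
        cum = self.step * (np.cumsum(sampled, axis=2) - 0.5 * sampled)
        nx, ny = self._U2.shape
        nz = self._Vz.size
        iu = np.broadcast_to(self._vox_iu[:, :, None], (nx, ny, nz)).ravel()
        it = np.broadcast_to(self._vox_it[:, :, None], (nx, ny, nz)).ravel()
        iv = np.broadcast_to(self._vox_iv[None, None, :], (nx, ny, nz)).ravel()
        out = ndimage.map_coordinates(cum, np.stack([iu, iv, it]), order=1,
                                      cval=0.0)
        return np.clip(out.reshape(nx, ny, nz), 0.0, None)


# ---------------------------------------------------------------------------
# PTV construction
# ---------------------------------------------------------------------------

def _dilation_footprint(spacing, beam: Optional[BeamGeometry], lateral_mm: float,
                        proximal_mm: float, distal_mm: float) -> np.ndarray:
    """Boolean structuring element for (an)isotropic beam-frame dilation."""
    sp = np.asarray(spacing)
    reach = max(lateral_mm, proximal_mm, distal_mm)
    half = np.ceil(reach / sp).astype(int)
    off = [np.arange(-h, h + 1) * s for h, s in zip(half, sp)]
    dx = off[0][:, None, None]
    dy = off[1][None, :, None]
    dz = off[2][None, None, :]
    if beam is None:  # isotropic
        return dx ** 2 + dy ** 2 + dz ** 2 <= lateral_mm ** 2 + 1e-9
    d = beam.direction
    depth = dx * d[0] + dy * d[1] + dz * d[2]
    lat2 = dx ** 2 + dy ** 2 + dz ** 2 - depth ** 2
    return (lat2 <= lateral_mm ** 2 + 1e-9) \
        & (depth >= -proximal_mm - 1e-9) & (depth <= distal_mm + 1e-9)


def build_ptv(ctv: StructureMask, beam: BeamGeometry, concept: str = "isotropic",
              margin_mm: float = 3.0, proximal_mm: float = 5.0,
              distal_mm: float = 7.0, proximal_boost: float = 1.03,
              distal_boost: float = 1.06,
              prescription_Gy_RBE: float = PRESCRIPTION_GY_RBE):
    """PTV mask (and per-voxel prescription map) for one of three concepts.

    * ``isotropic`` — Euclidean dilation of the CTV by ``margin_mm``.
    * ``asymmetric_margin`` — dilation by (``proximal_mm``, ``distal_mm``)
      along the beam axis and ``margin_mm`` laterally.
    * ``boosted_dose`` — isotropic 3 mm mask plus a prescription map of
      ``prescription x (proximal_boost | distal_boost)`` in the proximal /
      distal margin and ``prescription`` in the CTV (and lateral margin).

    Returns ``(ptv_mask, prescription_map)``; the map is ``None`` except for
    the boosted concept.  A PTV reaching the grid boundary raises.
    """
    if ctv.n_voxels == 0:
        raise ValueError("CTV is empty")
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0 and concept == "isotropic":
        return StructureMask(f"PTV[{concept}]", ctv.mask.copy(), ctv.spacing,
                             ctv.origin), None

    if concept == "isotropic" or concept == "boosted_dose":
        fp = _dilation_footprint(ctv.spacing, None, margin_mm, 0, 0)
    elif concept == "asymmetric_margin":
        fp = _dilation_footprint(ctv.spacing, beam, margin_mm, proximal_mm,
                                 distal_mm)
    else:
        raise ValueError(f"unknown PTV concept '{concept}'")
    mask = ndimage.binary_dilation(ctv.mask, structure=fp)
    edge = np.zeros_like(mask)
    edge[[0, -1], :, :] = True
    edge[:, [0, -1], :] = True
    edge[:, :, [0, -1]] = True
    if np.any(mask & edge):
        raise ValueError("PTV exits the grid; enlarge the phantom")
    ptv = StructureMask(f"PTV[{concept}]", mask, ctv.spacing, ctv.origin)

    if concept != "boosted_dose":
        return ptv, None

    # classify margin voxels against the nearest CTV voxel, in the beam frame
    pmap = np.zeros(mask.shape)
    pmap[mask] = prescription_Gy_RBE
    margin = mask & ~ctv.mask
    sp = np.asarray(ctv.spacing)
    _, idx = ndimage.distance_transform_edt(~ctv.mask, sampling=sp,
                                            return_indices=True)
    mi = np.argwhere(margin)
    nearest = idx[:, mi[:, 0], mi[:, 1], mi[:, 2]].T
    delta = (mi - nearest) * sp
    d = beam.direction
    depth = delta @ d
    lat = np.sqrt(np.maximum(np.sum(delta ** 2, axis=1) - depth ** 2, 0.0))
    boost = np.ones(len(mi))
    boost[depth > lat] = distal_boost
    boost[-depth > lat] = proximal_boost
    pmap[mi[:, 0], mi[:, 1], mi[:, 2]] = prescription_Gy_RBE * boost
    return ptv, pmap


# ---------------------------------------------------------------------------
# spot placement
# ---------------------------------------------------------------------------

def place_spots(phantom: Phantom, beam: BeamGeometry, ptv: StructureMask,
                frame: Optional[BeamFrame] = None,
                distal_spacing_mm: float = DISTAL_SPACING_MM,
                lateral_factor: float = LATERAL_SPACING_FACTOR,
                machine_window: Tuple[float, float] = MACHINE_WINDOW
                ) -> List[PencilSpot]:
    """Energy layers and lateral spot grids covering the PTV.

    Energy layers are spaced ``distal_spacing_mm`` apart in water-equivalent
    depth covering the [proximal, distal] WEPL extent of the PTV; each
    layer's lateral grid is spaced ``lateral_factor x FWHM(E)`` and covers
    the PTV's beam-eye projection expanded by one sigma.
    """
    frame = frame or BeamFrame(phantom, beam)
    wepl = frame.line_integral_volume(phantom.density.values)
    m = ptv.mask
    w_ptv = wepl[m]
    wmin, wmax = float(w_ptv.min()), float(w_ptv.max())

    r_max = range_from_energy(machine_window[1], window=machine_window)
    if wmax > r_max:
        raise ValueError(
            f"PTV distal WEPL {wmax:.1f} mm exceeds the maximum-energy range "
            f"{r_max:.1f} mm (deficit {wmax - r_max:.1f} mm)")

    n_layers = int(math.floor((wmax - wmin) / distal_spacing_mm)) + 1
    layer_wepls = wmax - distal_spacing_mm * np.arange(n_layers)
    if layer_wepls[-1] - wmin > 1e-9:
        layer_wepls = np.append(layer_wepls, wmin)

    U, V, _ = frame.voxel_uvt()
    pu, pv = U[m], V[m]
    from scipy.spatial import cKDTree
    tree = cKDTree(np.column_stack([pu, pv]))

    spots: List[PencilSpot] = []
    for w in layer_wepls:
        e = energy_from_range(max(w, range_from_energy(machine_window[0],
                                                       window=machine_window)),
                              window=machine_window)
        spacing = lateral_factor * fwhm_air(e)
        sigma = lateral_sigma(e)
        for (a, b) in _lateral_grid(pu, pv, spacing, sigma):
            if tree.query([a, b])[0] <= sigma:  # projection plus one sigma
                spots.append(PencilSpot(float(e), float(a), float(b)))
    if not spots:
        raise ValueError("no spots placed; check PTV and machine window")
    return spots


def _lateral_grid(pu: np.ndarray, pv: np.ndarray, spacing: float, sigma: float):
    """Centered square lateral grid covering the projection plus one sigma."""
    cu, cv = 0.5 * (pu.min() + pu.max()), 0.5 * (pv.min() + pv.max())
    half_u = 0.5 * (pu.max() - pu.min()) + sigma
    half_v = 0.5 * (pv.max() - pv.min()) + sigma
    nu = int(math.ceil(half_u / spacing))
    nv = int(math.ceil(half_v / spacing))
    for i in range(-nu, nu + 1):
        for j in range(-nv, nv + 1):
            yield cu + i * spacing, cv + j * spacing


# ---------------------------------------------------------------------------
# influence and forward dose
# ---------------------------------------------------------------------------

def _spot_dose_components(plan: SpotPlan, wepl: np.ndarray,
                          sigma_deg: Optional[np.ndarray],
                          curve_step: float = 0.5):
    """Yield (spot_indices, per-voxel depth dose, lateral sigma) per layer."""
    for energy, idxs in plan.layers().items():
        curve = _cached_curve(energy, curve_step)
        if sigma_deg is None:
            dd = np.interp(wepl, curve.depths, curve.dose_per_weight,
                           left=curve.dose_per_weight[0], right=0.0)
        else:
            smax = float(sigma_deg.max())
            sigmas, depths, mat = degraded_family(curve, smax + 0.25,
                                                  sigma_step_mm=0.25)
            rgi = RegularGridInterpolator((sigmas, depths), mat,
                                          bounds_error=False, fill_value=0.0)
            dd = rgi(np.column_stack([sigma_deg.ravel(), wepl.ravel()]))
            dd = dd.reshape(wepl.shape)
        yield idxs, dd, float(lateral_sigma(energy))


def influence_matrix(phantom: Phantom, plan: SpotPlan, voxel_mask: np.ndarray,
                     frame: Optional[BeamFrame] = None) -> np.ndarray:
    """Dense per-spot dose basis on the voxels of ``voxel_mask`` (columns in
    plan spot order), computed on the non-modulated phantom."""
    frame = frame or BeamFrame(phantom, plan.beam)
    wepl = frame.line_integral_volume(phantom.density.values)[voxel_mask]
    U, V, _ = frame.voxel_uvt()
    u, v = U[voxel_mask], V[voxel_mask]
    n_spots = len(plan.spots)
    A = np.zeros((u.size, n_spots))
    for idxs, dd, sig in _spot_dose_components(plan, wepl, None):
        norm = 1.0 / (2.0 * math.pi * sig * sig)
        for i in idxs:
            s = plan.spots[i]
            lat = np.exp(-((u - s.lateral_x) ** 2 + (v - s.lateral_y) ** 2)
                         / (2.0 * sig * sig))
            A[:, i] = dd * lat * norm
    return A


@dataclass
class OptimizationResult:
    weights: np.ndarray
    v95: float
    converged: bool
    achieved_dose: np.ndarray
    n_outer: int
    objective: float


def optimize_weights(influence: np.ndarray, prescription: np.ndarray,
                     hotspot_factor: float = HOTSPOT_FACTOR,
                     overdose_weight: float = 30.0, v95_goal: float = 0.98,
                     max_outer: int = 6,
                     reg_frac: float = 1e-4) -> OptimizationResult:
    """Non-negative penalized least squares against the prescription.

    Minimizes the quadratic deviation from the per-voxel prescription over
    the PTV, with extra penalty rows for voxels exceeding
    ``hotspot_factor`` times their prescription and a small Tikhonov term
    (``reg_frac`` of the mean column norm) that discourages extreme
    single-spot weights.  Reports the achieved V95 (fraction of PTV voxels
    at >= 95% of prescription); ``converged`` is False, never silent, when
    the 98% objective is unreachable.
    """
    A = np.asarray(influence, dtype=float)
    p = np.asarray(prescription, dtype=float)
    if A.ndim != 2 or A.shape[0] != p.size:
        raise ValueError("influence/prescription shape mismatch")
    n = A.shape[1]
    lam = math.sqrt(reg_frac * float(np.mean(np.sum(A ** 2, axis=0))))
    A_reg = np.vstack([A, lam * np.eye(n)])
    b_reg = np.concatenate([p, np.zeros(n)])
    w, _ = nnls(A_reg, b_reg, maxiter=max(OPT_MAX_ITER, 3 * n))
    prev_obj = np.inf
    n_outer = 1
    for it in range(max_outer - 1):
        d = A @ w
        over = d > hotspot_factor * p
        obj = float(np.sum((d - p) ** 2))
        if not over.any() or abs(prev_obj - obj) <= OPT_TOL * max(obj, 1e-12):
            break
        prev_obj = obj
        A2 = np.vstack([A_reg, math.sqrt(overdose_weight) * A[over]])
        b2 = np.concatenate([b_reg, math.sqrt(overdose_weight)
                             * hotspot_factor * p[over]])
        w, _ = nnls(A2, b2, maxiter=max(OPT_MAX_ITER, 3 * n))
        n_outer += 1
    d = A @ w
    v95 = float(np.mean(d >= 0.95 * p - 1e-9))
    return OptimizationResult(w, v95, v95 >= v95_goal, d, n_outer,
                              float(np.sum((d - p) ** 2)))


def make_plan(phantom: Phantom, beam: BeamGeometry, concept: str = "isotropic",
              prescription_Gy_RBE: float = PRESCRIPTION_GY_RBE,
              machine_window: Tuple[float, float] = MACHINE_WINDOW,
              frame: Optional[BeamFrame] = None, **ptv_kwargs):
    """Full planning pass: PTV, spots, influence, optimization.

    Returns ``(plan, ptv, opt_result)``; the plan's meta records the
    achieved V95 and the PTV concept parameters.
    """
    frame = frame or BeamFrame(phantom, beam)
    ptv, pmap = build_ptv(phantom.ctv, beam, concept=concept,
                          prescription_Gy_RBE=prescription_Gy_RBE, **ptv_kwargs)
    spots = place_spots(phantom, beam, ptv, frame=frame,
                        machine_window=machine_window)
    plan = SpotPlan(beam, spots, prescription_Gy_RBE, concept, machine_window)
    A = influence_matrix(phantom, plan, ptv.mask, frame=frame)
    presc = (pmap[ptv.mask] if pmap is not None
             else np.full(ptv.n_voxels, prescription_Gy_RBE))
    res = optimize_weights(A, presc)
    for s, w in zip(plan.spots, res.weights):
        s.weight = float(w)
    plan.optimized = True
    plan.meta.update({"v95": res.v95, "converged": res.converged,
                      "n_spots": len(spots),
                      "n_layers": len(plan.layers()),
                      "prescription_map": pmap})
    return plan, ptv, res


def compute_dose(plan: SpotPlan, phantom: Phantom,
                 modulation: Optional[ModulationModel] = None,
                 frame: Optional[BeamFrame] = None,
                 fluence_cutoff: float = 1e-4) -> DoseGrid:
    """Forward dose on the phantom grid for one scenario.

    ``modulation=None`` (or ``p_mod = 0``) reproduces the planning-system
    prediction.  Convolution mode degrades each voxel's depth dose with
    ``sigma = sqrt(P_mod x lung path to the voxel)``; density-sampling mode
    averages ``n_samples`` independently modulated density realizations
    (pristine curves on randomized WEPL).
    """
    if not plan.optimized:
        raise ValueError("plan must be optimized before dose calculation")
    frame = frame or BeamFrame(phantom, plan.beam)

    if modulation is not None and modulation.mode == "density_sampling" \
            and modulation.p_mod_um > 0:
        acc = None
        for k in range(modulation.n_samples):
            dens = sample_modulated_density(phantom, modulation.p_mod_um,
                                            modulation.seed + k)
            wepl = frame.line_integral_volume(dens.values)
            d = _superpose(plan, frame, wepl, None, fluence_cutoff)
            acc = d if acc is None else acc + d
        values = acc / modulation.n_samples
        return DoseGrid(values, phantom.density.spacing, phantom.density.origin,
                        scenario=modulation.label,
                        meta={"p_mod_um": modulation.p_mod_um,
                              "seed": modulation.seed,
                              "n_samples": modulation.n_samples})

    wepl = frame.line_integral_volume(phantom.density.values)
    sigma_deg = None
    label = "non_modulated"
    meta: Dict = {}
    if modulation is not None and modulation.p_mod_um > 0:
        lpath = frame.line_integral_volume(
            phantom.lung_mask.mask.astype(np.float64))
        sigma_deg = degradation_sigma(modulation.p_mod_um, lpath)
        label = modulation.label
        meta = {"p_mod_um": modulation.p_mod_um}
    values = _superpose(plan, frame, wepl, sigma_deg, fluence_cutoff)
    return DoseGrid(values, phantom.density.spacing, phantom.density.origin,
                    scenario=label, meta=meta)


def _superpose(plan: SpotPlan, frame: BeamFrame, wepl: np.ndarray,
               sigma_deg: Optional[np.ndarray], fluence_cutoff: float
               ) -> np.ndarray:
    U, V, _ = frame.voxel_uvt()
    dose = np.zeros(wepl.shape)
    for energy, idxs in plan.layers().items():
        sig = float(lateral_sigma(energy))
        norm = 1.0 / (2.0 * math.pi * sig * sig)
        fl = np.zeros(wepl.shape)
        for i in idxs:
            s = plan.spots[i]
            if s.weight == 0:
                continue
            fl += s.weight * np.exp(
                -((U - s.lateral_x) ** 2 + (V - s.lateral_y) ** 2)
                / (2.0 * sig * sig))
        if not fl.any():
            continue
        active = fl > fluence_cutoff * fl.max()
        curve = _cached_curve(energy)
        if sigma_deg is None:
            dd = np.interp(wepl[active], curve.depths, curve.dose_per_weight,
                           left=curve.dose_per_weight[0], right=0.0)
        else:
            smax = float(sigma_deg.max())
            sigmas, depths, mat = degraded_family(curve, smax + 0.25,
                                                  sigma_step_mm=0.25)
            rgi = RegularGridInterpolator((sigmas, depths), mat,
                                          bounds_error=False, fill_value=0.0)
            dd = rgi(np.column_stack([sigma_deg[active], wepl[active]]))
        dose[active] += dd * fl[active] * norm
    return dose


def sum_plans(doses: Sequence[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of aligned dose grids of the same scenario type."""
    if not doses:
        raise ValueError("no dose grids to sum")
    first = doses[0]
    for d in doses[1:]:
        if not first.same_geometry(d):
            raise ValueError("dose grids are not aligned")
        if d.scenario != first.scenario:
            raise ValueError(
                f"cannot sum scenarios '{first.scenario}' and '{d.scenario}'")
    values = np.sum([d.values for d in doses], axis=0)
    return DoseGrid(values, first.spacing, first.origin, first.scenario,
                    meta={"n_fields": len(doses)})
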