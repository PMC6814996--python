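"""Independent test oracles.

These deliberately re-derive quantities through routes that share no code
with the package: numeric integration of a Bethe-like stopping power for
the range-energy relation, midpoint-rule line integrals for WEPL, a direct
O(n^2) quadrature for Gaussian depth smearing, a sort-based D_x% rule, and
an exhaustive (no early exit) brute-force gamma search with its own
trilinear interpolation.
"""

from __future__ import annotations

import numpy as np

PROTON_MASS_MEV = 938.272
ELECTRON_MASS_MEV = 0.510999
K_BETHE = 0.307075            # MeV cm^2 / mol
WATER_Z_OVER_A = 0.55509
WATER_I_MEV = 75e-6
WATER_RHO = 1.0               # g/cm^3


def bethe_stopping_power(energy_MeV: np.ndarray) -> np.ndarray:
    """Relativistic Bethe mass stopping power of water, MeV/cm."""
    e = np.asarray(energy_MeV, dtype=float)
    gamma = 1.0 + e / PROTON_MASS_MEV
    beta2 = 1.0 - 1.0 / gamma ** 2
    arg = 2.0 * ELECTRON_MASS_MEV * beta2 * gamma ** 2 / WATER_I_MEV
    return K_BETHE * WATER_Z_OVER_A / beta2 * (np.log(arg) - beta2) * WATER_RHO


def bethe_range_mm(energy_MeV: float, e_min: float = 1.0, n: int = 20000) -> float:
    """CSDA range in water by numeric integration of 1/S(E), in mm."""
    es = np.linspace(e_min, energy_MeV, n)
    integrand = 1.0 / bethe_stopping_power(es)
    return 10.0 * float(np.trapezoid(integrand, es))


def midpoint_wepl(density: np.ndarray, spacing, origin, ray_origin, direction,
                  point, step: float = 0.002) -> float:
    """Dense midpoint-rule line integral of piecewise-constant density."""
    o = np.asarray(ray_origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t_end = float(np.dot(np.asarray(point, float) - o, d))
    ts = np.arange(0.5 * step, t_end, step)
    pts = o[None, :] + ts[:, None] * d[None, :]
    idx = np.floor((pts - (np.asarray(origin) - 0.5 * np.asarray(spacing)))
                   / np.asarray(spacing)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(density.shape)), axis=1)
    vals = np.zeros(len(ts))
    vals[inside] = density[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return float(np.sum(vals) * step)


def smear_quadrature(depths: np.ndarray, dose: np.ndarray, sigma: float,
                     n_sigma: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Direct quadrature of the truncated, normalized Gaussian smearing
    integral over the extended depth axis (replicate proximal padding,
    zeros distally) — an O(n^2) re-derivation of the convolution."""
    step = depths[1] - depths[0]
    half = int(np.ceil(n_sigma * sigma / step))
    out_depths = depths[0] + step * np.arange(len(depths) + half)

    def f(z):
        z = np.asarray(z)
        out = np.interp(z, depths, dose, left=dose[0], right=0.0)
        return out

    ks = np.arange(-half, half + 1) * step
    kern = np.exp(-0.5 * (ks / sigma) ** 2)
    kern = kern / kern.sum()
    out = np.array([np.sum(kern * f(z - ks)) for z in out_depths])
    return out_depths, out


def dx_sorted(doses: np.ndarray, x_pct: float) -> float:
    """Sort-based D_x%: lower-adjacent value on the ascending order."""
    srt = np.sort(np.asarray(doses, float))
    i = int(np.floor((1.0 - x_pct / 100.0) * srt.size))
    return float(srt[min(max(i, 0), srt.size - 1)])


def _trilinear(a: np.ndarray, pos: np.ndarray) -> np.ndarray:
    i0 = np.floor(pos).astype(int)
    i0 = np.minimum(np.maximum(i0, 0), np.asarray(a.shape) - 2)
    f = pos - i0
    out = np.zeros(len(pos))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (f[:, 0] if dx else 1 - f[:, 0]) \
                    * (f[:, 1] if dy else 1 - f[:, 1]) \
                    * (f[:, 2] if dz else 1 - f[:, 2])
                out += w * a[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def brute_gamma_passing(ref: np.ndarray, ev: np.ndarray, spacing,
                        crit_pct: float = 3.0, dta: float = 1.0,
                        thr_pct: float = 20.0, radius_factor: float = 3.0,
                        substep: float = 10.0, chunk: int = 4000) -> float:
    """Exhaustive gamma passing rate: every lattice offset in the search
    ball is evaluated for every included voxel (no early exit, no
    sub-sampling shortcuts)."""
    step = dta / substep
    n = int(np.floor(radius_factor * dta / step))
    ks = np.arange(-n, n + 1) * step
    offs = np.array(np.meshgrid(ks, ks, ks, indexing="ij")).reshape(3, -1).T
    offs = offs[np.sum(offs ** 2, axis=1) <= (radius_factor * dta) ** 2 + 1e-12]

    inc = ref >= thr_pct / 100.0 * ref.max()
    coords = np.argwhere(inc).astype(float)
    dref = ref[inc]
    crit = crit_pct / 100.0 * dref
    best = np.full(dref.size, np.inf)
    dims = np.asarray(ref.shape, float)
    sp = np.asarray(spacing, float)

    for s in range(0, len(offs), chunk):
        block = offs[s:s + chunk]
        pos = coords[None, :, :] + (block / sp)[:, None, :]
        flat = pos.reshape(-1, 3)
        valid = np.all((flat >= 0) & (flat <= dims - 1), axis=1)
        vals = np.full(len(flat), np.nan)
        if valid.any():
            vals[valid] = _trilinear(ev, flat[valid])
        vals = vals.reshape(len(block), dref.size)
        g2 = ((vals - dref[None, :]) / crit[None, :]) ** 2 \
            + (np.sum(block ** 2, axis=1) / dta ** 2)[:, None]
        g2 = np.where(np.isnan(g2), np.inf, g2)
        best = np.minimum(best, g2.min(axis=0))
    return float(np.mean(np.sqrt(best) <= 1.0) * 100.0)
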