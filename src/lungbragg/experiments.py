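"""End-to-end experiment orchestration.

Runs the full pipeline — phantom, single-field plan optimized on the
non-modulated geometry, two-scenario recalculation over a modulation-power
sweep, and the comparison report — over a matrix of beam angles and
phantoms, with deterministic seeding and CSV/JSON outputs that embed the
configuration hash and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import ComparisonReport, cumulative_dvh, scenario_report
from .beam import MACHINE_WINDOW, BeamGeometry, pristine_curve
from .degradation import (PMOD_SWEEP_UM, ModulationModel, degradation_sigma,
                          degrade_curve)
from .grids import Phantom
from .io import config_hash
from .phantoms import build_patient_like_phantom, build_slab_phantom
from .planning import (PRESCRIPTION_GY_RBE, BeamFrame, DoseGrid, compute_dose,
                       make_plan, sum_plans)

log = logging.getLogger("lungbragg")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment matrix."""

    kind: str = "slab"                      # "slab" | "patient_like"
    phantom: Dict = field(default_factory=dict)
    angles: Sequence[float] = (0.0,)
    p_mod_um: Sequence[float] = PMOD_SWEEP_UM
    mode: str = "convolution"
    seed: int = 0
    n_samples: int = 20
    prescription_Gy_RBE: float = PRESCRIPTION_GY_RBE
    ptv_concept: str = "isotropic"
    output_dir: Optional[str] = None
    gamma_thresholds: Sequence[float] = (20.0, 80.0)
    isodose_levels: Sequence[float] = (95.0, 80.0, 20.0)

    def to_dict(self) -> Dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        # output location is run bookkeeping, not part of the experiment
        d = self.to_dict()
        d.pop("output_dir", None)
        return config_hash(d)

    @classmethod
    def from_dict(cls, d: Dict) -> "ExperimentConfig":
        return cls(**d)


def build_phantom(config: ExperimentConfig, angle: Optional[float] = None
                  ) -> Phantom:
    """Phantom described by the config (placement angle may be overridden)."""
    kw = dict(config.phantom)
    if config.kind == "slab":
        return build_slab_phantom(**kw)
    if config.kind == "patient_like":
        if angle is not None:
            kw.setdefault("beam_angle_deg", angle)
        kw.setdefault("seed", config.seed)
        return build_patient_like_phantom(**kw)
    raise ValueError(f"unknown phantom kind '{config.kind}'")


def run_single_field(config: ExperimentConfig, angle: float,
                     phantom: Optional[Phantom] = None,
                     keep_doses: bool = False) -> ComparisonReport:
    """One beam direction end-to-end: optimize on the nominal phantom,
    recalculate for every modulation power, compare.

    The report meta carries the achieved V95, per-stage wall times, the
    config hash and seed; CSVs (metrics/gamma/shifts, DVH curves and a
    central-axis depth-dose profile) are written when the config names an
    output directory.
    """
    stages: Dict[str, float] = {}
    t0 = time.perf_counter()
    try:
        ph = phantom or build_phantom(config, angle)
    except Exception as exc:  # pragma: no cover - error tagging only
        raise RuntimeError(f"[stage=phantom] {exc}") from exc
    stages["phantom_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        iso = tuple(ph.ctv.centroid_mm())
        beam = BeamGeometry(angle, iso)
        frame = BeamFrame(ph, beam)
        plan, ptv, opt = make_plan(ph, beam, concept=config.ptv_concept,
                                   prescription_Gy_RBE=config.prescription_Gy_RBE,
                                   frame=frame)
    except Exception as exc:
        raise RuntimeError(f"[stage=plan] {exc}") from exc
    stages["plan_s"] = time.perf_counter() - t0
    log.info("angle=%g v95=%.3f spots=%d", angle, opt.v95, len(plan.spots))

    t0 = time.perf_counter()
    try:
        nominal = compute_dose(plan, ph, None, frame=frame)
        modulated: List[DoseGrid] = []
        for p in config.p_mod_um:
            model = ModulationModel(p, config.mode,
                                    seed=config.seed if config.mode ==
                                    "density_sampling" else None,
                                    n_samples=config.n_samples)
            modulated.append(compute_dose(plan, ph, model, frame=frame))
    except Exception as exc:
        raise RuntimeError(f"[stage=dose] {exc}") from exc
    stages["dose_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        structures = list(ph.structures.values())
        report = scenario_report(nominal, modulated, structures,
                                 config.prescription_Gy_RBE, beam=beam,
                                 ptv=ptv,
                                 gamma_thresholds=config.gamma_thresholds,
                                 isodose_levels=config.isodose_levels)
    except Exception as exc:
        raise RuntimeError(f"[stage=analyze] {exc}") from exc
    stages["analyze_s"] = time.perf_counter() - t0

    report.meta.update({
        "angle_deg": angle,
        "v95": opt.v95,
        "converged": opt.converged,
        "config_hash": config.hash,
        "seed": config.seed,
        "stages": stages,
        "phantom_meta": {k: v for k, v in ph.meta.items()},
    })
    if keep_doses:
        report.meta["doses"] = {"nominal": nominal, "modulated": modulated,
                                "plan": plan, "ptv": ptv, "phantom": ph,
                                "beam": beam}
    if config.output_dir:
        _write_outputs(config, angle, ph, beam, nominal, modulated, report)
    return report


def _write_outputs(config, angle, ph, beam, nominal, modulated, report):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"angle{angle:g}"
    header = [f"config_hash={config.hash}", f"seed={config.seed}",
              f"angle_deg={angle:g}"]
    report.to_csv(str(out / f"report_{tag}"), header_lines=header)

    # DVH curves per structure and scenario
    rows = {}
    for s in ph.structures.values():
        edges, vol = cumulative_dvh(nominal, s)
        rows[f"{s.name}:non_modulated"] = (edges, vol)
        for dg in modulated:
            e2, v2 = cumulative_dvh(dg, s)
            rows[f"{s.name}:{dg.scenario}"] = (e2, v2)
    with open(out / f"dvh_{tag}.csv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for key, (e, v) in rows.items():
            df = pd.DataFrame({"dose_Gy": e, "volume_pct": v})
            df.insert(0, "curve", key)
            df.to_csv(fh, index=False, header=(fh.tell() < 200),
                      float_format="%.6g")

    # central-axis depth dose (nominal and strongest modulation)
    from .analysis import _ray_profile
    src = beam.source_point(300.0)
    ts, vals_n = _ray_profile(nominal, src, beam.direction, 0.5, 1400)
    prof = {"t_mm": ts, "nominal_Gy": vals_n}
    for dg in modulated:
        _, vals_m = _ray_profile(dg, src, beam.direction, 0.5, 1400)
        prof[f"pmod{dg.meta.get('p_mod_um', 0):g}_Gy"] = vals_m
    with open(out / f"central_axis_{tag}.csv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        pd.DataFrame(prof).to_csv(fh, index=False, float_format="%.6g")


def run_matrix(config: ExperimentConfig) -> Dict:
    """The full angle x modulation-power matrix, plus the summed-field
    comparison and trend summary.

    Partial failures are recorded per cell and the matrix continues.
    Returns ``{"reports": {angle: ComparisonReport}, "summary": DataFrame,
    "sum_report": ComparisonReport | None, "failures": {...}}``.
    """
    if len(config.angles) < 1 or len(config.p_mod_um) < 1:
        raise ValueError("need at least one angle and one modulation power")
    reports: Dict[float, ComparisonReport] = {}
    failures: Dict[float, str] = {}
    doses_by_angle = {}
    phantom = build_phantom(config) if config.kind == "patient_like" else None

    for angle in config.angles:
        try:
            rep = run_single_field(config, angle, phantom=phantom,
                                   keep_doses=True)
            reports[angle] = rep
            doses_by_angle[angle] = rep.meta.pop("doses")
        except Exception as exc:
            failures[angle] = str(exc)
            log.warning("matrix cell angle=%g failed: %s", angle, exc)

    sum_report = None
    if len(doses_by_angle) > 1:
        nominals = [d["nominal"] for d in doses_by_angle.values()]
        nominal_sum = sum_plans(nominals)
        mods = []
        n_p = len(config.p_mod_um)
        for i in range(n_p):
            mods.append(sum_plans([d["modulated"][i]
                                   for d in doses_by_angle.values()]))
        any_d = next(iter(doses_by_angle.values()))
        structures = list(any_d["phantom"].structures.values())
        sum_report = scenario_report(nominal_sum, mods, structures,
                                     config.prescription_Gy_RBE)

    rows = []
    for angle, rep in reports.items():
        pm = rep.meta.get("phantom_meta", {})
        sub = rep.table[rep.table.structure == "CTV"]
        for _, r in sub.iterrows():
            rows.append({
                "angle_deg": angle,
                "p_mod_um": r.p_mod_um,
                "ctv_volume_cm3": pm.get("ctv_volume_cm3"),
                "depth_in_lung_mm": pm.get("measured_depth_mm"),
                "delta_d_mean_pct": r.delta_d_mean_pct,
                "delta_d_98_pct": r.delta_d_98_pct,
                "delta_d_2_pct": r.delta_d_2_pct,
                "v95": rep.meta["v95"],
            })
    summary = pd.DataFrame(rows)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "matrix_summary.csv", "w") as fh:
            fh.write(f"# config_hash={config.hash}\n# seed={config.seed}\n")
            summary.to_csv(fh, index=False, float_format="%.6g")
        (out / "matrix_meta.json").write_text(json.dumps({
            "config_hash": config.hash, "seed": config.seed,
            "failures": failures}, indent=2))
    return {"reports": reports, "summary": summary, "sum_report": sum_report,
            "failures": failures}


def export_fig4_curves(energies: Sequence[float],
                       p_mod_um: Sequence[float] = PMOD_SWEEP_UM,
                       lung_path_mm: float = 80.0,
                       depth_step_mm: float = 0.5) -> pd.DataFrame:
    """Pristine and degraded depth-dose curves in water, as a tidy table.

    For each energy the pristine curve and its degraded variants (sigma from
    each modulation power over ``lung_path_mm`` of lung) are sampled on a
    common depth grid.  Column names: ``E{energy}_pmod{P}``, with ``pmod0``
    the pristine curve.
    """
    frames = {}
    depths_ref = None
    for e in energies:
        curve = pristine_curve(e, depth_step_mm=depth_step_mm)
        all_p = [0.0] + [p for p in p_mod_um if p > 0]
        for p in all_p:
            sig = degradation_sigma(p, lung_path_mm)
            dc = degrade_curve(curve, sig) if sig > 0 else curve
            if depths_ref is None or dc.depths[-1] > depths_ref[-1]:
                depths_ref = dc.depths
            frames[f"E{e:g}_pmod{p:g}"] = dc
    out = {"depth_mm": depths_ref}
    for name, dc in frames.items():
        out[name] = np.interp(depths_ref, dc.depths, dc.dose_per_weight,
                              left=dc.dose_per_weight[0], right=0.0)
    return pd.DataFrame(out)
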