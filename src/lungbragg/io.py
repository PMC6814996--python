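"""File I/O: NIfTI volumes, plan serialization, phantom recipes.

Volumetric grids and masks are written as NIfTI-1 (one file per volume);
spacing and origin round-trip exactly through the affine.  Plans are plain
YAML (energy layers, lateral positions in mm, weights) with a documented
schema version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import nibabel as nib
import numpy as np
import yaml

from .beam import BeamGeometry
from .grids import StructureMask, VoxelGrid
from .planning import DoseGrid, PencilSpot, SpotPlan

PLAN_SCHEMA_VERSION = 1


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_nifti(obj: Union[VoxelGrid, StructureMask, DoseGrid],
                path: Union[str, Path],
                meta: Optional[Dict] = None) -> None:
    """Write a grid, mask or dose to NIfTI-1 with exact spacing/origin."""
    if isinstance(obj, StructureMask):
        data = obj.mask.astype(np.uint8)
    else:
        data = obj.values.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(obj.spacing, obj.origin))
    if meta:
        img.header["descrip"] = json.dumps(meta)[:79].encode()
    nib.save(img, str(path))


def read_nifti_grid(path: Union[str, Path]) -> VoxelGrid:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def read_nifti_mask(path: Union[str, Path], name: str = "structure"
                    ) -> StructureMask:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return StructureMask(name, np.asarray(img.dataobj) > 0, spacing, origin)


def write_plan(plan: SpotPlan, path: Union[str, Path]) -> None:
    """Serialize a spot plan to YAML.

    Schema: ``{schema, gantry_angle_deg, isocenter_mm, prescription_Gy_RBE,
    ptv_concept, machine_window_MeV, spots: [[energy_MeV, x_mm, y_mm,
    weight], ...]}``.
    """
    doc = {
        "schema": PLAN_SCHEMA_VERSION,
        "gantry_angle_deg": plan.beam.gantry_angle,
        "isocenter_mm": list(plan.beam.isocenter),
        "prescription_Gy_RBE": plan.prescription_Gy_RBE,
        "ptv_concept": plan.ptv_concept,
        "machine_window_MeV": list(plan.machine_window),
        "optimized": plan.optimized,
        "spots": [[s.energy, s.lateral_x, s.lateral_y, s.weight]
                  for s in plan.spots],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_plan(path: Union[str, Path]) -> SpotPlan:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema") != PLAN_SCHEMA_VERSION:
        raise ValueError(f"unsupported plan schema {doc.get('schema')}")
    beam = BeamGeometry(doc["gantry_angle_deg"], tuple(doc["isocenter_mm"]))
    spots = [PencilSpot(e, x, y, w) for e, x, y, w in doc["spots"]]
    plan = SpotPlan(beam, spots, doc["prescription_Gy_RBE"],
                    doc["ptv_concept"], tuple(doc["machine_window_MeV"]))
    plan.optimized = bool(doc.get("optimized", False))
    return plan


def config_hash(config: Dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Union[str, Path]) -> Dict:
    return yaml.safe_load(Path(path).read_text())
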