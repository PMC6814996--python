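import warnings

import numpy as np
import pytest

from lungbragg import (BeamFrame, BeamGeometry, ModulationModel,
                       build_slab_phantom, compute_dose, make_plan)

warnings.filterwarnings("ignore", message=".*FWHM calibration span.*")


@pytest.fixture(scope="session")
def slab():
    """The benchmark slab: 10 mm tissue | 80 mm lung | CTV 34-47 mm beyond."""
    return build_slab_phantom()


@pytest.fixture(scope="session")
def slab_case(slab):
    """Planned slab with nominal and modulated (450/800 um) dose grids.

    Computed once per session; plans are optimized on the non-modulated
    phantom and recalculated unchanged under modulation.
    """
    beam = BeamGeometry(0.0, tuple(slab.ctv.centroid_mm()))
    frame = BeamFrame(slab, beam)
    plan, ptv, opt = make_plan(slab, beam, frame=frame)
    nominal = compute_dose(plan, slab, None, frame=frame)
    mod = {p: compute_dose(plan, slab, ModulationModel(p), frame=frame)
           for p in (100.0, 250.0, 450.0, 800.0)}
    return {"phantom": slab, "beam": beam, "frame": frame, "plan": plan,
            "ptv": ptv, "opt": opt, "nominal": nominal, "modulated": mod}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
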