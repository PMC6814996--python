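"""Plan engine: PTV concepts, spot placement, weight optimization and
forward dose calculation."""

import numpy as np
import pytest

from lungbragg import (BeamFrame, BeamGeometry, DoseGrid, ModulationModel,
                       build_ptv, build_slab_phantom, compute_dose,
                       dvh_metrics, fwhm_air, make_plan, optimize_weights,
                       place_spots, sphere_mask, sum_plans)
from lungbragg.grids import VoxelGrid
from lungbragg.planning import SpotPlan, PencilSpot


@pytest.fixture(scope="module")
def sphere_ctv():
    grid = VoxelGrid(np.ones((40, 40, 40)), (1, 1, 1), (-19.5, -19.5, -19.5))
    return grid, sphere_mask(grid, (0.0, 0.0, 0.0), 10.0, name="CTV")


class TestBuildPtv:
    def test_isotropic_dilation_volume(self):
        # 3 mm margin on a 10 mm sphere -> volume ratio ~ (13/10)^3 at fine
        # spacing (0.5 mm)
        n, s = 64, 0.5
        c = (n - 1) * s / 2.0
        grid = VoxelGrid(np.ones((n, n, n)), (s, s, s), (0, 0, 0))
        ctv = sphere_mask(grid, (c, c, c), 10.0, name="CTV")
        beam = BeamGeometry(0.0, (c, c, c))
        ptv, pmap = build_ptv(ctv, beam, "isotropic")
        assert pmap is None
        ratio = ptv.n_voxels / ctv.n_voxels
        assert ratio == pytest.approx((13 / 10) ** 3, rel=0.03)

    def test_zero_margin_identity(self, sphere_ctv):
        grid, ctv = sphere_ctv
        beam = BeamGeometry(0.0, (0.0, 0.0, 0.0))
        ptv, _ = build_ptv(ctv, beam, "isotropic", margin_mm=0.0)
        assert np.array_equal(ptv.mask, ctv.mask)

    def test_asymmetric_margin_extents(self, sphere_ctv):
        grid, ctv = sphere_ctv
        beam = BeamGeometry(0.0, (0.0, 0.0, 0.0))   # beam along +y
        ptv, _ = build_ptv(ctv, beam, "asymmetric_margin")
        idx = np.argwhere(ptv.mask)
        cidx = np.argwhere(ctv.mask)
        # proximal 5 mm, distal 7 mm along y; 3 mm lateral in x/z
        assert cidx[:, 1].min() - idx[:, 1].min() == 5
        assert idx[:, 1].max() - cidx[:, 1].max() == 7
        assert idx[:, 0].max() - cidx[:, 0].max() == 3

    def test_boosted_dose_map_values(self, sphere_ctv):
        # distal margin prescription = 1.06 x 30 Gy(RBE) = 31.8
        grid, ctv = sphere_ctv
        beam = BeamGeometry(0.0, (0.0, 0.0, 0.0))
        ptv, pmap = build_ptv(ctv, beam, "boosted_dose")
        assert pmap is not None
        vals = np.unique(np.round(pmap[ptv.mask], 6))
        assert set(vals) == {30.0, 30.9, 31.8}
        assert np.all(pmap[ctv.mask] == 30.0)
        # distal margin voxels (largest y) carry the 6% boost
        margin = ptv.mask & ~ctv.mask
        iy = np.argwhere(margin)[:, 1]
        distal_vox = np.argwhere(margin)[iy == iy.max()][0]
        assert pmap[tuple(distal_vox)] == pytest.approx(31.8)

    def test_ptv_exiting_grid_errors(self):
        grid = VoxelGrid(np.ones((12, 12, 12)), (1, 1, 1), (0, 0, 0))
        ctv = sphere_mask(grid, (5.5, 5.5, 5.5), 4.0, name="CTV")
        beam = BeamGeometry(0.0, (5.5, 5.5, 5.5))
        with pytest.raises(ValueError, match="exits the grid"):
            build_ptv(ctv, beam, "isotropic")


class TestPlaceSpots:
    def test_layer_count_for_30mm_extent(self):
        # PTV WEPL extent of 30 mm at 3 mm spacing -> >= 11 energy layers
        ph = build_slab_phantom(ctv_span_mm=(34.0, 58.0), distal_tissue_mm=60.0)
        beam = BeamGeometry(0.0, tuple(ph.ctv.centroid_mm()))
        frame = BeamFrame(ph, beam)
        ptv, _ = build_ptv(ph.ctv, beam, "isotropic")
        spots = place_spots(ph, beam, ptv, frame=frame)
        energies = {s.energy for s in spots}
        assert len(energies) >= 11

    def test_lateral_spacing_at_70mev(self):
        assert 0.45 * fwhm_air(70.0) == pytest.approx(14.625)

    def test_every_ptv_voxel_covered_laterally(self, slab_case):
        # covering property: each PTV voxel within one lateral spacing of
        # some spot axis of its (nearest-energy) layer
        frame, ptv = slab_case["frame"], slab_case["ptv"]
        plan = slab_case["plan"]
        U, V, _ = frame.voxel_uvt()
        pu, pv = U[ptv.mask], V[ptv.mask]
        for energy, idxs in plan.layers().items():
            spacing = 0.45 * fwhm_air(energy)
            su = np.array([plan.spots[i].lateral_x for i in idxs])
            sv = np.array([plan.spots[i].lateral_y for i in idxs])
            d2 = (pu[:, None] - su[None, :]) ** 2 + (pv[:, None] - sv[None, :]) ** 2
            assert np.sqrt(d2.min(axis=1)).max() <= spacing + 1e-9

    def test_unreachable_ptv_errors(self):
        ph = build_slab_phantom()
        beam = BeamGeometry(0.0, tuple(ph.ctv.centroid_mm()))
        ptv, _ = build_ptv(ph.ctv, beam, "isotropic")
        with pytest.raises(ValueError, match="deficit"):
            place_spots(ph, beam, ptv, machine_window=(60.0, 70.0))


class TestOptimizeWeights:
    def test_single_spot_single_voxel(self):
        # weight = prescription / unit-weight dose
        A = np.array([[2.0]])
        res = optimize_weights(A, np.array([30.0]))
        assert res.weights[0] == pytest.approx(15.0, rel=1e-3)
        assert res.v95 == 1.0 and res.converged

    def test_linearity_in_prescription(self, rng):
        A = rng.uniform(0.0, 1.0, (50, 8))
        p = np.full(50, 30.0)
        w1 = optimize_weights(A, p).weights
        w2 = optimize_weights(A, 2 * p).weights
        assert np.allclose(w2, 2 * w1, rtol=1e-6, atol=1e-9)

    def test_unreachable_objective_reports_not_silent(self):
        # a spot that cannot dose the second voxel at all
        A = np.array([[1.0], [0.0]])
        res = optimize_weights(A, np.array([30.0, 30.0]))
        assert not res.converged
        assert res.v95 == pytest.approx(0.5)

    def test_planning_objective_met_on_slab(self, slab_case):
        # >= 95% of prescription to >= 98% of the PTV, optimizer converged
        assert slab_case["opt"].v95 >= 0.98
        assert slab_case["opt"].converged

    def test_hotspot_cap_respected(self, slab_case):
        d = slab_case["nominal"].values[slab_case["ptv"].mask]
        assert d.max() <= 1.15 * 30.0 * 1.01  # small numerical slack


class TestComputeDose:
    def test_no_modulation_equals_pmod_zero(self, slab_case):
        d0 = compute_dose(slab_case["plan"], slab_case["phantom"],
                          ModulationModel(0.0), frame=slab_case["frame"])
        assert np.allclose(d0.values, slab_case["nominal"].values)

    def test_linear_in_spot_weights(self, slab_case):
        plan = slab_case["plan"]
        doubled = SpotPlan(plan.beam,
                           [PencilSpot(s.energy, s.lateral_x, s.lateral_y,
                                       2 * s.weight) for s in plan.spots],
                           plan.prescription_Gy_RBE, plan.ptv_concept,
                           plan.machine_window)
        doubled.optimized = True
        d2 = compute_dose(doubled, slab_case["phantom"],
                          frame=slab_case["frame"])
        assert np.allclose(d2.values, 2 * slab_case["nominal"].values,
                           rtol=1e-9)

    def test_unoptimized_plan_rejected(self, slab_case):
        plan = SpotPlan(slab_case["beam"], slab_case["plan"].spots)
        with pytest.raises(ValueError, match="optimized"):
            compute_dose(plan, slab_case["phantom"])

    def test_modulated_lower_in_distal_ctv_higher_beyond_falloff(self, slab_case):
        # smoothing moves dose from the distal target edge past the falloff
        ph = slab_case["phantom"]
        nom, mod = slab_case["nominal"], slab_case["modulated"][800.0]
        ys = ph.density.axis_coords(1)
        ctv_lo, ctv_hi = ph.meta["ctv_interval_mm"]
        i, k = ph.density.dims[0] // 2, ph.density.dims[2] // 2
        distal_ctv = (ys >= ctv_hi - 4) & (ys < ctv_hi)
        assert np.all(mod.values[i, distal_ctv, k]
                      < nom.values[i, distal_ctv, k])
        beyond = (ys > ctv_hi + 12) & (ys < ctv_hi + 25)
        assert np.mean(mod.values[i, beyond, k]) \
            > np.mean(nom.values[i, beyond, k])

    def test_proximal_dose_invariant_under_modulation(self, slab_case):
        # upstream of the lung both scenarios agree exactly
        ph = slab_case["phantom"]
        ys = ph.density.axis_coords(1)
        prox = ys < ph.meta["lung_interval_mm"][0]
        nom = slab_case["nominal"].values[:, prox, :]
        mod = slab_case["modulated"][800.0].values[:, prox, :]
        assert np.allclose(nom, mod, rtol=1e-9, atol=1e-12)

    def test_sampling_mode_mean_close_to_convolution(self, slab_case):
        model = ModulationModel(450.0, "density_sampling", seed=4, n_samples=20)
        ds = compute_dose(slab_case["plan"], slab_case["phantom"], model,
                          frame=slab_case["frame"])
        dc = slab_case["modulated"][450.0]
        m_ctv = slab_case["phantom"].ctv.mask
        assert dvh_metrics(ds, slab_case["phantom"].ctv).d_mean == pytest.approx(
            dvh_metrics(dc, slab_case["phantom"].ctv).d_mean, rel=0.03)
        assert ds.scenario.startswith("modulated")


class TestSumPlans:
    def _mk(self, vals, scen="non_modulated"):
        return DoseGrid(vals, (1, 1, 1), (0, 0, 0), scen)

    def test_single_plan_identity(self, rng):
        d = self._mk(rng.uniform(0, 30, (5, 5, 5)))
        s = sum_plans([d])
        assert np.array_equal(s.values, d.values)

    def test_mean_adds_linearly(self, rng):
        a = self._mk(rng.uniform(0, 30, (5, 5, 5)))
        b = self._mk(rng.uniform(0, 30, (5, 5, 5)))
        s = sum_plans([a, b])
        assert s.values.mean() == pytest.approx(a.values.mean()
                                                + b.values.mean())

    def test_mismatched_scenarios_rejected(self, rng):
        a = self._mk(rng.uniform(0, 1, (4, 4, 4)))
        b = self._mk(rng.uniform(0, 1, (4, 4, 4)), scen="modulated(x)")
        with pytest.raises(ValueError, match="scenario"):
            sum_plans([a, b])
        c = DoseGrid(rng.uniform(0, 1, (5, 4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="aligned"):
            sum_plans([a, c])

    def test_sum_delta_bounded_by_field_deltas(self, rng):
        # relative change of a sum lies between the fields' relative changes
        base1 = rng.uniform(10, 30, (6, 6, 6))
        base2 = rng.uniform(10, 30, (6, 6, 6))
        mod1, mod2 = 0.97 * base1, 0.92 * base2
        rel = lambda m, b: (m.mean() - b.mean()) / b.mean()
        r_sum = rel(mod1 + mod2, base1 + base2)
        lo, hi = sorted([rel(mod1, base1), rel(mod2, base2)])
        assert lo - 1e-12 <= r_sum <= hi + 1e-12
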