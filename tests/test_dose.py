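"""Dose engine: density conversion, plan normalisation, ray tracing, DVH."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cbctdose as cd
from cbctdose.dose import ControlPoint, TreatmentPlan


def _water(shape=(40, 40, 40), spacing=5.0):
    origin = -(np.asarray(shape) - 1) * spacing / 2.0
    grid = cd.ImageGrid(shape, (spacing,) * 3, tuple(origin))
    return cd.ScalarVolume(grid, np.ones(shape), "density")


def _single_beam_plan(prescription=40.0):
    return TreatmentPlan(
        prescription, (0.0, 0.0, 0.0), [ControlPoint(0.0, 1.0, (-50, 50, -50, 50))], scale=1.0
    )


class TestHUDensity:
    @pytest.mark.parametrize(
        "hu,rho",
        [(0.0, 1.0), (-1000.0, 0.00121), (500.0, 1.3), (3000.0, 3.0), (-2000.0, 0.00121)],
    )
    def test_anchor_and_interpolated_values(self, hu, rho):
        table = cd.HUDensityTable()
        assert table(np.array([hu]))[0] == pytest.approx(rho)

    def test_volume_conversion(self, rng):
        grid = cd.ImageGrid((6, 6, 6), (2, 2, 2))
        vol = cd.ScalarVolume(grid, rng.uniform(-1000, 1000, grid.shape), "HU")
        dens = cd.hu_to_density(vol)
        assert dens.quantity == "density"
        assert np.all(dens.values >= 0)


class TestOverrideOutsideFOV:
    def _setup(self):
        grid = cd.ImageGrid((10, 10, 10), (2, 2, 2))
        dens = cd.ScalarVolume(grid, np.full(grid.shape, 0.3), "density")
        body = cd.ROIMask(grid, np.ones(grid.shape, bool), "BODY")
        fov_vals = np.zeros(grid.shape, bool)
        fov_vals[:5] = True
        return dens, body, cd.ROIMask(grid, fov_vals, "FOV")

    def test_body_outside_fov_set_to_water(self):
        dens, body, fov = self._setup()
        out = cd.override_outside_fov(dens, body, fov)
        assert np.all(out.values[5:] == 1.0)
        assert np.all(out.values[:5] == 0.3)

    def test_fov_covering_body_changes_nothing(self):
        dens, body, _ = self._setup()
        fov = cd.ROIMask(dens.grid, np.ones(dens.grid.shape, bool), "FOV")
        out = cd.override_outside_fov(dens, body, fov)
        np.testing.assert_array_equal(out.values, dens.values)

    def test_outside_body_untouched(self):
        dens, _, fov = self._setup()
        body = cd.ROIMask(dens.grid, np.zeros(dens.grid.shape, bool), "BODY")
        out = cd.override_outside_fov(dens, body, fov)
        np.testing.assert_array_equal(out.values, dens.values)


class TestRayTracing:
    def test_siddon_straight_ray_in_uniform_medium(self):
        water = _water()
        # 100 mm straight path through unit density = 10 cm water-equivalent
        assert cd.radiological_path(water, (0, -50, 0), (0, 50, 0)) == pytest.approx(10.0, abs=1e-9)

    def test_siddon_agrees_with_dense_sampling(self, rng):
        grid = cd.ImageGrid((16, 16, 16), (4, 4, 4), (-30, -30, -30))
        dens = cd.ScalarVolume(grid, rng.uniform(0.1, 2.0, grid.shape), "density")
        for _ in range(10):
            p0 = rng.uniform(-40, 40, 3)
            p1 = rng.uniform(-40, 40, 3)
            exact = cd.radiological_path(dens, p0, p1)
            # brute-force dense nearest-neighbour sampling
            ts = np.linspace(0, 1, 4001)
            pts = p0[None] + ts[:, None] * (p1 - p0)[None]
            idx = np.floor(grid.world_to_index(pts) + 0.5).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
            rho = np.where(ok, dens.values[idx[:, 0].clip(0, 15), idx[:, 1].clip(0, 15), idx[:, 2].clip(0, 15)], 0.0)
            approx = rho[:-1].sum() * np.linalg.norm(p1 - p0) / 4000 / 10.0
            if exact > 0.05:
                assert abs(exact - approx) / exact < 0.005

    def test_central_axis_attenuation_law(self):
        # two points on the central axis of a uniform water phantom: the dose
        # ratio follows exp(-mu*dd) with inverse-square correction within 1%
        water = _water()
        plan = _single_beam_plan()
        dose = cd.compute_dose(water, plan, bev_step_mm=2.0)
        ax_y = water.grid.axes()[1]
        i0 = 20
        y1, y2 = ax_y[28], ax_y[12]
        d1, d2 = dose.values[i0, 28, i0], dose.values[i0, 12, i0]
        expect = math.exp(-plan.mu_eff * ((y1 - y2) / 10.0)) * ((plan.sad - y1) / (plan.sad - y2)) ** 2
        assert d2 / d1 == pytest.approx(expect, rel=0.01)

    def test_dose_monotone_in_density(self):
        water = _water()
        half = water.with_values(water.values * 0.5)
        plan = _single_beam_plan()
        d_full = cd.compute_dose(water, plan)
        d_half = cd.compute_dose(half, plan)
        deep = np.s_[20, 5:15, 20]  # beyond the entrance region
        assert np.all(d_half.values[deep] >= d_full.values[deep])


class TestPlanAndNormalisation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TreatmentPlan(40.0, (0, 0, 0), [ControlPoint(0.0, 0.5, (-10, 10, -10, 10))])

    def test_arc_spans_within_range(self, clean_phantom):
        _, structures, _ = clean_phantom
        plan = cd.build_partial_vmat_plan(structures["whole_breast_CTV"], cp_spacing_deg=10.0)
        total = sum(cp.weight for cp in plan.control_points)
        assert total == pytest.approx(1.0)
        # 2 tangential fields + 4 arcs discretised at 10 deg
        assert len(plan.control_points) > 6

    def test_normalisation_contract_and_frozen_scale(self, clean_phantom):
        pct, structures, _ = clean_phantom
        ctv = structures["whole_breast_CTV"]
        dens = cd.hu_to_density(pct)
        plan = cd.build_partial_vmat_plan(ctv, prescription=42.56, cp_spacing_deg=10.0)
        plan = cd.normalize_plan(plan, dens, ctv)
        dose = cd.compute_dose(dens, plan)
        assert dose.values[ctv.values].mean() == pytest.approx(42.56, rel=1e-6)
        # frozen plan: identical input reproduces the dose bit-identically
        dose2 = cd.compute_dose(dens.copy(), plan)
        np.testing.assert_array_equal(dose.values, dose2.values)

    def test_ctv_outside_beams_rejected(self, clean_phantom):
        pct, structures, _ = clean_phantom
        ctv = structures["whole_breast_CTV"]
        dens = cd.hu_to_density(pct)
        plan = cd.build_partial_vmat_plan(ctv, cp_spacing_deg=10.0)
        empty_aperture = [replace(cp, aperture=(900.0, 910.0, 900.0, 910.0)) for cp in plan.control_points]
        bad = replace(plan, control_points=empty_aperture)
        with pytest.raises(ValueError, match="no dose"):
            cd.normalize_plan(bad, dens, ctv)


class TestDVH:
    def test_uniform_dose(self):
        grid = cd.ImageGrid((5, 5, 4), (2, 2, 2))
        dose = cd.ScalarVolume(grid, np.full(grid.shape, 42.56), "dose")
        roi = cd.ROIMask(grid, np.ones(grid.shape, bool))
        s = cd.dvh_stats(dose, roi, 42.56)
        for v in s.as_dict().values():
            assert v == pytest.approx(42.56)
        assert s.as_dict(relative=True)["mean"] == pytest.approx(100.0)

    def test_percentile_estimator_matches_sort_oracle(self):
        # 100 voxels of 1..100 Gy: D95 is the 5th percentile = 5.95 Gy under
        # linear interpolation between order statistics
        grid = cd.ImageGrid((10, 10, 1), (2, 2, 2))
        dose = cd.ScalarVolume(grid, np.arange(1.0, 101.0).reshape(10, 10, 1), "dose")
        roi = cd.ROIMask(grid, np.ones(grid.shape, bool))
        s = cd.dvh_stats(dose, roi, 100.0)
        assert s.d95 == pytest.approx(5.95)
        sorted_d = np.sort(dose.values.ravel())

        def oracle(top_pct):
            q = (100.0 - top_pct) / 100.0 * (len(sorted_d) - 1)
            lo = int(np.floor(q))
            frac = q - lo
            return sorted_d[lo] * (1 - frac) + sorted_d[min(lo + 1, len(sorted_d) - 1)] * frac

        assert s.d1 == pytest.approx(oracle(1))
        assert s.d98 == pytest.approx(oracle(98))

    def test_orderings_on_random_fields(self, rng):
        grid = cd.ImageGrid((8, 8, 8), (2, 2, 2))
        for _ in range(20):
            dose = cd.ScalarVolume(grid, rng.gamma(2.0, 5.0, grid.shape), "dose")
            roi = cd.ROIMask(grid, rng.uniform(size=grid.shape) < 0.5)
            if roi.n_voxels < 5:
                continue
            s = cd.dvh_stats(dose, roi, 42.56)
            assert s.d99 <= s.d98 <= s.d95
            assert s.d2 <= s.d1

    def test_empty_roi_rejected(self):
        grid = cd.ImageGrid((4, 4, 4), (2, 2, 2))
        dose = cd.ScalarVolume(grid, np.ones(grid.shape), "dose")
        with pytest.raises(ValueError, match="empty"):
            cd.dvh_stats(dose, cd.ROIMask(grid, np.zeros(grid.shape, bool)), 42.56)


class TestDoseDifferenceReport:
    def _stats(self, mean, prescription=42.56):
        return cd.DVHStatistics("ctv", prescription, mean + 2, mean + 1.5, mean - 1, mean - 1.5, mean - 2, mean)

    def test_self_difference_is_zero(self):
        ref = self._stats(42.0)
        df = cd.dose_difference_report(ref, {"same": self._stats(42.0)})
        assert np.allclose(df.loc["same"].values, 0.0)

    def test_known_absolute_difference(self):
        # 73 cGy below the reference at 42.56 Gy prescription is -1.7%
        ref = self._stats(42.0)
        low = self._stats(42.0 - 0.73)
        df = cd.dose_difference_report(ref, {"low": low})
        assert df.loc["low", "mean"] == pytest.approx(-1.7, abs=0.02)

    def test_sign_convention(self):
        ref = self._stats(40.0)
        hi = self._stats(41.0)
        df = cd.dose_difference_report(ref, {"hi": hi})
        assert df.loc["hi", "mean"] > 0

    def test_prescription_mismatch_rejected(self):
        ref = self._stats(42.0)
        other = self._stats(42.0, prescription=55.86)
        with pytest.raises(ValueError, match="mismatch"):
            cd.dose_difference_report(ref, {"other": other})
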