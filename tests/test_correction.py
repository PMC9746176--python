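"""Correction methods: HU-override, conversion estimation, analytical, virtual CT."""

import numpy as np
import pytest
from dataclasses import replace

import cbctdose as cd
from cbctdose.correction import multiotsu_thresholds
from cbctdose.phantom import CBCTArtifactModel

from conftest import SEPARATED_HU, small_params


@pytest.fixture(scope="module")
def plateau_case():
    """Noiseless separated-plateau phantom with an air pocket, affine-only CBCT."""
    params = small_params(tissue_hu=dict(SEPARATED_HU), noise_sigma=0.0, air_pocket_cc=3.0)
    pct, structures = cd.generate_phantom(params)
    art = CBCTArtifactModel(gain=0.9, offset=-30.0, shading_amplitude=0.0, noise_sigma=0.0)
    cbct, fov, _ = cd.simulate_cbct(pct, art, seed=0)
    return params, pct, structures, cbct, fov


class TestDensityClassTable:
    def test_defaults_are_the_six_clinical_classes(self):
        t = cd.DensityClassTable()
        assert t.n_classes == 6
        assert t.densities == (0.00121, 0.26, 0.95, 1.05, 1.6, 3.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            cd.DensityClassTable(names=("a", "b"), densities=(1.0, 0.5))


class TestHUOverride:
    def test_noiseless_plateaus_classified_exactly(self, plateau_case):
        params, pct, structures, cbct, fov = plateau_case
        out = cd.correct_hu_override(cbct, structures.body, fov=fov)
        plateaus = np.array(sorted(params.tissue_hu.values()))
        truth = np.argmin(np.abs(pct.values[..., None] - plateaus), axis=-1)
        domain = structures.body.values & fov.values
        assert np.mean(out.class_labels[domain] == truth[domain]) >= 0.999

    def test_lung_class_density(self, plateau_case):
        params, pct, structures, cbct, fov = plateau_case
        out = cd.correct_hu_override(cbct, structures.body, fov=fov)
        dens = out.density_volume()
        lung = structures["lungs"].values & fov.values
        assert np.median(dens.values[lung]) == 0.26

    def test_raw_grey_levels_retained(self, plateau_case):
        _, _, structures, cbct, fov = plateau_case
        out = cd.correct_hu_override(cbct, structures.body, fov=fov)
        np.testing.assert_array_equal(out.hu.values, cbct.values)

    def test_constant_image_rejected(self, plateau_case):
        _, _, structures, cbct, fov = plateau_case
        flat = cbct.with_values(np.zeros_like(cbct.values))
        with pytest.raises(ValueError, match="distinct"):
            cd.correct_hu_override(flat, structures.body, fov=fov)

    def test_multiotsu_exact_on_spikes(self):
        # six well-separated spikes: every threshold separates two spikes
        vals = np.repeat([-1000.0, -700.0, -300.0, 0.0, 300.0, 800.0], 100)
        thr = multiotsu_thresholds(vals, 6)
        labels = np.searchsorted(thr, vals, side="left")
        assert len(np.unique(labels)) == 6
        for spike in np.unique(vals):
            sel = labels[vals == spike]
            assert len(np.unique(sel)) == 1


class TestEstimateConversion:
    def test_identity_pair_recovers_identity(self, standard_case):
        case = standard_case
        mask = case.fov
        conv = cd.estimate_conversion(case.rct, case.rct, mask)
        lo, hi = np.percentile(case.rct.values[mask.values], [1, 99])
        xs = np.linspace(lo, hi, 200)
        bin_width = (np.percentile(case.rct.values[mask.values], 99.95)
                     - np.percentile(case.rct.values[mask.values], 0.05)) / 128
        assert np.max(np.abs(conv(xs) - xs)) <= bin_width

    def test_recovers_affine_distortion_at_plateaus(self, plateau_case):
        params, pct, structures, cbct, fov = plateau_case
        conv = cd.estimate_conversion(cbct, pct, fov)
        spread = np.ptp(cbct.values[fov.values])
        bin_width = spread / 128
        for h in params.tissue_hu.values():
            g = 0.9 * h - 30.0
            assert abs(conv(np.array([g]))[0] - h) <= bin_width + 1e-9

    def test_monotone_by_construction(self, standard_case):
        case = standard_case
        conv = cd.estimate_conversion(case.cbct, case.rct, case.fov)
        assert np.all(np.diff(conv.anchors_out) >= -1e-9)

    def test_empty_mask_rejected(self, standard_case):
        case = standard_case
        empty = cd.ROIMask(case.cbct.grid, np.zeros(case.cbct.grid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            cd.estimate_conversion(case.cbct, case.rct, empty)


class TestAnalyticalCorrection:
    def test_zero_iterations_returns_input(self, standard_case):
        case = standard_case
        out = cd.correct_analytical(case.cbct, case.pct, case.fov, n_iter=0)
        np.testing.assert_array_equal(out.hu.values, case.cbct.values)

    def test_artifact_free_cbct_left_nearly_unchanged(self):
        # nothing to correct: output matches the rCT within twice the CT noise
        params = small_params()
        art = CBCTArtifactModel(gain=1.0, offset=0.0, shading_amplitude=0.0, noise_sigma=0.0)
        case = cd.generate_case(params, artifact=art, seed=3)
        body = case.structures_rct.body
        out = cd.correct_analytical(
            case.cbct, case.pct, case.fov, body=body, ground_truth_field=case.field
        )
        roi = cd.build_cbct_roi(case.fov, body)
        assert cd.mae(case.rct, out.hu, roi) <= 2.0 * params.noise_sigma

    def test_reduces_mae_under_full_corruption(self, separated_case):
        case = separated_case
        body = case.structures_rct.clip_to_body().body
        roi = cd.build_cbct_roi(case.fov, body)
        out = cd.correct_analytical(
            case.cbct, case.pct, case.fov, body=body, ground_truth_field=case.field
        )
        assert cd.mae(case.rct, out.hu, roi) < 0.4 * cd.mae(case.rct, case.cbct, roi)


class TestAirPockets:
    def test_detects_injected_cavity(self, plateau_case):
        params, pct, structures, cbct, fov = plateau_case
        pockets = cd.detect_air_pockets(pct, structures.body, exclude=structures["lungs"])
        X, Y, Z = pct.grid.meshgrid()
        r = (3.0 * params.air_pocket_cc * 1000 / (4 * np.pi)) ** (1 / 3)
        c = params.air_pocket_center
        cavity = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2) & structures.body.values
        assert pockets.values[cavity].mean() >= 0.9

    def test_lungs_not_reported_as_pockets(self, plateau_case):
        _, pct, structures, _, _ = plateau_case
        pockets = cd.detect_air_pockets(pct, structures.body, exclude=structures["lungs"])
        assert pockets.values[structures["lungs"].values].mean() < 0.05

    def test_no_candidates_gives_empty_mask(self, plateau_case):
        _, pct, structures, _, _ = plateau_case
        soft = pct.with_values(np.where(structures.body.values, 40.0, -1000.0))
        assert cd.detect_air_pockets(soft, structures.body).n_voxels == 0

    def test_min_volume_filter(self, plateau_case):
        params, pct, structures, _, _ = plateau_case
        pockets = cd.detect_air_pockets(
            pct, structures.body, min_volume_cc=50.0, exclude=structures["lungs"]
        )
        assert pockets.n_voxels == 0  # 3 cc cavity is below 50 cc


class TestVirtualCT:
    def test_equals_warped_pct_outside_air(self, standard_case):
        case = standard_case
        body = case.structures_rct.body
        lungs = case.structures_rct["lungs"]
        cc = cd.correct_analytical(
            case.cbct, case.pct, case.fov, body=body, ground_truth_field=case.field
        )
        ctv = cd.build_virtual_ct(case.pct, cc, case.field, body, lungs=lungs, fov=case.fov)
        warped = cd.warp_volume(case.pct, case.field)
        # no air pockets in this case: bit-exact equality everywhere
        assert ctv.provenance["replaced_voxels"] == 0
        np.testing.assert_array_equal(ctv.hu.values, warped.values)

    def test_cavity_taken_from_cbct_cc(self):
        params = small_params(air_pocket_cc=3.0, noise_sigma=0.0)
        case = cd.generate_case(params, seed=2)
        body = case.structures_rct.body
        lungs = case.structures_rct["lungs"]
        cc = cd.correct_analytical(
            case.cbct, case.pct, case.fov, body=body, ground_truth_field=case.field
        )
        ctv = cd.build_virtual_ct(case.pct, cc, case.field, body, lungs=lungs, fov=case.fov)
        warped = cd.warp_volume(case.pct, case.field)
        pockets = cd.detect_air_pockets(warped, body, exclude=lungs)
        assert pockets.n_voxels > 0
        np.testing.assert_array_equal(
            ctv.hu.values[pockets.values], cc.hu.values[pockets.values]
        )
        replaced = ctv.hu.values != warped.values
        # replacement confined to detected pockets (in either image)
        fovbody = cd.intersect_masks(body, case.fov)
        cc_pockets = cd.detect_air_pockets(cc.hu, fovbody, exclude=lungs)
        allowed = pockets.values | cc_pockets.values
        assert not np.any(replaced & ~allowed)

    def test_requires_cbct_cc(self, standard_case):
        case = standard_case
        with pytest.raises(ValueError, match="analytically corrected"):
            cd.build_virtual_ct(case.pct, None, case.field, case.structures_rct.body)
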