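"""Core data model: grids, I/O round-trips, resampling, mask algebra."""

import numpy as np
import pytest

import cbctdose as cd
from cbctdose.volumes import GridMismatchError, VolumeIOError


def _ball_mask(grid, center, radius):
    X, Y, Z = grid.meshgrid()
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2
    return cd.ROIMask(grid, inside, "ball")


class TestImageGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            cd.ImageGrid((0, 8, 8), (1, 1, 1))
        with pytest.raises(ValueError):
            cd.ImageGrid((8, 8, 8), (1, -1, 1))

    def test_world_index_round_trip(self, rng):
        g = cd.ImageGrid((8, 9, 10), (1.5, 2.0, 3.0), (-4.0, 0.0, 7.0))
        pts = rng.uniform(-20, 40, (25, 3))
        np.testing.assert_allclose(g.index_to_world(g.world_to_index(pts)), pts, atol=1e-12)


class TestIO:
    @pytest.mark.parametrize("ext", [".nii.gz", ".nii", ".nrrd"])
    def test_volume_round_trip(self, tmp_path, rng, ext):
        grid = cd.ImageGrid((8, 8, 8), (1.0, 1.0, 3.0), (-3.0, 2.0, 0.0))
        vol = cd.ScalarVolume(grid, rng.normal(0, 100, grid.shape), "HU")
        path = tmp_path / f"vol{ext}"
        cd.write_volume(vol, path)
        back = cd.read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        assert back.grid.same_as(grid)

    def test_missing_file(self, tmp_path):
        with pytest.raises(VolumeIOError, match="no_such"):
            cd.read_volume(tmp_path / "no_such.nii.gz")

    def test_truncated_file(self, tmp_path, rng):
        grid = cd.ImageGrid((8, 8, 8), (1, 1, 1))
        path = tmp_path / "trunc.nii.gz"
        cd.write_volume(cd.ScalarVolume(grid, rng.normal(size=grid.shape)), path)
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(VolumeIOError):
            cd.read_volume(path)

    def test_deformation_field_round_trip(self, tmp_path, rng):
        grid = cd.ImageGrid((6, 7, 8), (2, 2, 3), (-5, 0, 4))
        field = cd.DeformationField(grid, rng.normal(0, 3, grid.shape + (3,)))
        cd.write_deformation_field(field, tmp_path / "field.nii.gz")
        back = cd.read_deformation_field(tmp_path / "field.nii.gz")
        np.testing.assert_allclose(back.displacement, field.displacement)
        assert back.grid.same_as(grid)

    def test_structure_set_round_trip(self, tmp_path):
        grid = cd.ImageGrid((10, 10, 6), (2, 2, 2), (-9, -9, -5))
        body = _ball_mask(grid, (0, 0, 0), 8)
        ctv = _ball_mask(grid, (0, 0, 0), 4)
        ctv.name = "ctv"
        sset = cd.StructureSet({"BODY": body, "ctv": ctv}, external="BODY")
        cd.write_structure_set(sset, tmp_path / "structs")
        back = cd.read_structure_set(tmp_path / "structs")
        assert back.external == "BODY"
        np.testing.assert_array_equal(back["ctv"].values, ctv.values)


class TestResample:
    def test_identity_resample(self, rng):
        grid = cd.ImageGrid((9, 9, 9), (2, 2, 2))
        vol = cd.ScalarVolume(grid, rng.normal(0, 50, grid.shape), "HU")
        out = cd.resample_to_grid(vol, grid, "trilinear")
        np.testing.assert_allclose(out.values, vol.values, atol=1e-9)

    def test_constant_preserved(self):
        grid = cd.ImageGrid((9, 9, 9), (2, 2, 2))
        vol = cd.ScalarVolume(grid, np.full(grid.shape, 100.0), "HU")
        target = cd.ImageGrid((5, 5, 5), (3, 3, 3), (1.0, 1.0, 1.0))
        out = cd.resample_to_grid(vol, target, "trilinear")
        np.testing.assert_allclose(out.values, 100.0)

    def test_linear_ramp_exact_on_half_spacing(self):
        # trilinear interpolation reproduces an affine field exactly
        grid = cd.ImageGrid((11, 5, 5), (2, 2, 2))
        X = grid.meshgrid()[0]
        vol = cd.ScalarVolume(grid, X.astype(float), "HU")
        fine = cd.ImageGrid((19, 5, 5), (1, 2, 2), (0.5, 0, 0))
        out = cd.resample_to_grid(vol, fine, "trilinear")
        np.testing.assert_allclose(out.values, fine.meshgrid()[0], atol=1e-6)

    def test_fill_value_by_quantity(self):
        grid = cd.ImageGrid((4, 4, 4), (2, 2, 2))
        vol = cd.ScalarVolume(grid, np.zeros(grid.shape), "HU")
        with pytest.raises(ValueError, match="overlap"):
            cd.resample_to_grid(vol, cd.ImageGrid((4, 4, 4), (2, 2, 2), (500.0, 0.0, 0.0)))
        target = cd.ImageGrid((4, 4, 4), (2, 2, 2), (4.0, 0.0, 0.0))
        out = cd.resample_to_grid(vol, target, "nearest")
        assert out.values[-1, 0, 0] == -1000.0  # beyond source extent -> air
        assert out.values[0, 0, 0] == 0.0

    def test_nearest_idempotent(self, rng):
        grid = cd.ImageGrid((7, 7, 7), (2, 2, 2))
        vol = cd.ScalarVolume(grid, rng.normal(size=grid.shape), "HU")
        once = cd.resample_to_grid(vol, grid, "nearest")
        twice = cd.resample_to_grid(once, grid, "nearest")
        np.testing.assert_array_equal(once.values, twice.values)


class TestMaskOps:
    def setup_method(self):
        self.grid = cd.ImageGrid((40, 40, 40), (2, 2, 2), (-39, -39, -39))

    def test_erode_zero_margin_is_identity(self):
        ball = _ball_mask(self.grid, (0, 0, 0), 30)
        out = cd.erode_mask(ball, 0.0)
        np.testing.assert_array_equal(out.values, ball.values)

    def test_erode_ball_matches_distance_oracle(self):
        # eroding a 30 mm ball by 20 mm leaves a ~10 mm ball
        ball = _ball_mask(self.grid, (0, 0, 0), 30)
        out = cd.erode_mask(ball, 20.0)
        small = _ball_mask(self.grid, (0, 0, 0), 10)
        X, Y, Z = self.grid.meshgrid()
        r = np.sqrt(X**2 + Y**2 + Z**2)
        # agreement everywhere except within one voxel of the 10 mm boundary
        boundary = np.abs(r - 10.0) <= 2.0 * np.sqrt(3)
        np.testing.assert_array_equal(out.values[~boundary], small.values[~boundary])

    def test_over_erosion_empties(self):
        ball = _ball_mask(self.grid, (0, 0, 0), 10)
        assert cd.erode_mask(ball, 20.0).n_voxels == 0

    def test_negative_margin_rejected(self):
        ball = _ball_mask(self.grid, (0, 0, 0), 10)
        with pytest.raises(ValueError):
            cd.erode_mask(ball, -1.0)

    @pytest.mark.parametrize("m1,m2", [(0.0, 5.0), (5.0, 10.0), (10.0, 25.0)])
    def test_erosion_monotone(self, m1, m2):
        ball = _ball_mask(self.grid, (5, -3, 2), 28)
        big = cd.erode_mask(ball, m1)
        small = cd.erode_mask(ball, m2)
        assert not np.any(small.values & ~big.values)

    def test_intersection_properties(self):
        a = _ball_mask(self.grid, (-8, 0, 0), 20)
        b = _ball_mask(self.grid, (8, 0, 0), 20)
        empty = cd.ROIMask(self.grid, np.zeros(self.grid.shape, bool))
        np.testing.assert_array_equal(cd.intersect_masks(a, a).values, a.values)
        assert cd.intersect_masks(a, empty).n_voxels == 0
        inter = cd.intersect_masks(a, b)
        assert inter.n_voxels == int(np.count_nonzero(a.values & b.values))
        assert inter.n_voxels <= min(a.n_voxels, b.n_voxels)

    def test_grid_mismatch_raises(self):
        a = _ball_mask(self.grid, (0, 0, 0), 10)
        other = cd.ImageGrid((40, 40, 40), (2, 2, 2), (0, 0, 0))
        b = _ball_mask(other, (40, 40, 40), 10)
        with pytest.raises(GridMismatchError, match="resample"):
            cd.intersect_masks(a, b)


class TestRigidTransform:
    def test_inverse_round_trip(self, rng):
        t = cd.RigidTransform((3.0, -2.0, 5.0), (4.0, -6.0, 2.0), (10.0, 0.0, -5.0))
        pts = rng.uniform(-100, 100, (50, 3))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_json_round_trip(self):
        t = cd.RigidTransform((1.0, 2.0, 3.0), (-1.0, 0.5, 2.0), (0.0, 0.0, 0.0))
        back = cd.RigidTransform.from_json(t.to_json())
        np.testing.assert_allclose(back.rotation_deg, t.rotation_deg)
        np.testing.assert_allclose(back.translation_mm, t.translation_mm)


class TestDeformationField:
    def test_identity_is_all_zero(self):
        grid = cd.ImageGrid((5, 5, 5), (2, 2, 2))
        f = cd.DeformationField.identity(grid)
        assert np.all(f.displacement == 0)
        np.testing.assert_allclose(f.jacobian_determinant(), 1.0, atol=1e-12)
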