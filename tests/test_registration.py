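"""Template alignment, hemisphere split/mirror, deformable registration, and
affine mask mapping."""
import numpy as np
import pytest
import SimpleITK as sitk

from conftest import small_spec

from nwuct.config import RunConfig
from nwuct.core_io import BinaryMask, CTVolume
from nwuct.errors import RegistrationError
from nwuct.phantom import generate_phantom, _smooth_vector_field
from nwuct.registration import (AffineTransform, DeformationField,
                                HemispherePair, align_to_template,
                                map_mask_affine, mirror, register_hemispheres,
                                split_and_mirror, warp_with_field)


@pytest.fixture(scope="module")
def textured_phantom():
    return generate_phantom(small_spec(seed=21)).ct


def _apply_rigid(vol: CTVolume, angle_deg: float, translation) -> CTVolume:
    """Resample ``vol`` as if the head had been rotated/translated."""
    tx = sitk.Euler3DTransform()
    tx.SetRotation(0.0, 0.0, np.deg2rad(angle_deg))
    tx.SetTranslation(tuple(translation))
    img = vol.to_sitk()
    moved = sitk.Resample(img, img, tx, sitk.sitkLinear, -1000.0)
    return CTVolume.from_sitk(moved)


class TestAffineAlignment:
    def test_self_registration_near_identity(self, textured_phantom):
        aligned, tf, diag = align_to_template(textured_phantom, textured_phantom,
                                              RunConfig(seed=3))
        assert np.abs(tf.matrix - np.eye(3)).max() < 0.01   # < ~0.5 deg
        assert np.abs(tf.translation).max() < 0.5
        assert diag["metric_final"] <= diag["metric_initial"] + 1e-9

    def test_known_rigid_transform_recovered(self, textured_phantom):
        moved = _apply_rigid(textured_phantom, 5.0, (4.0, -2.0, 0.0))
        aligned, tf, _ = align_to_template(moved, textured_phantom, RunConfig(seed=3))
        # resampling by S moves the head by S^{-1}; recovery means the
        # moving->fixed map composed with S^{-1} is identity on head points
        tx = sitk.Euler3DTransform()
        tx.SetRotation(0.0, 0.0, np.deg2rad(5.0))
        tx.SetTranslation((4.0, -2.0, 0.0))
        pts = np.array([[x, y, z] for x in (-15, 0, 15) for y in (-20, 0, 20)
                        for z in (-10, 0, 10)], dtype=float)
        moved_pts = np.array([tx.GetInverse().TransformPoint(tuple(p)) for p in pts])
        recovered = tf.apply(moved_pts)
        err = np.linalg.norm(recovered - pts, axis=1)
        assert err.mean() < 1.0

    def test_non_overlapping_volumes_error(self):
        a = CTVolume(np.full((16, 16, 16), 35.0, dtype=np.float32),
                     origin=(0.0, 0.0, 0.0))
        b = CTVolume(np.full((16, 16, 16), 35.0, dtype=np.float32),
                     origin=(10000.0, 0.0, 0.0))
        with pytest.raises(RegistrationError):
            align_to_template(a, b, RunConfig(affine_metric="mi", seed=3))


class TestAffineTransformAlgebra:
    def test_inverse_round_trip(self, rng):
        m = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        tf = AffineTransform(m, rng.normal(0, 5, 3))
        pts = rng.normal(0, 20, (10, 3))
        back = tf.inverse().apply(tf.apply(pts))
        assert np.abs(back - pts).max() < 1e-6

    def test_save_load_round_trip(self, tmp_path, rng):
        tf = AffineTransform(np.eye(3) * 1.1, rng.normal(0, 3, 3))
        tf.save(tmp_path / "tf.txt")
        back = AffineTransform.load(tmp_path / "tf.txt")
        assert np.allclose(back.to_matrix4(), tf.to_matrix4())

    def test_singular_matrix_rejected(self):
        with pytest.raises(RegistrationError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))


class TestSplitAndMirror:
    def test_symmetric_phantom_halves_match(self):
        ct = generate_phantom(small_spec(texture_amplitude=0.05, seed=4)).ct
        pair = split_and_mirror(ct)
        assert np.array_equal(pair.left.values, pair.right_mirrored.values)

    def test_mirror_is_involution(self, rng):
        arr = rng.normal(0, 1, (9, 6, 5))
        assert np.array_equal(mirror(mirror(arr)), arr)

    @pytest.mark.parametrize("nx", [10, 11])
    def test_voxel_conservation(self, nx):
        arr = np.arange(nx * 8 * 8, dtype=np.float32).reshape(nx, 8, 8)
        pair = split_and_mirror(CTVolume(arr))
        total = pair.left.values.size + pair.right_mirrored.values.size
        lost = arr.size - total
        assert lost == (0 if nx % 2 == 0 else 8 * 8)   # at most the mid slice


class TestDeformableRegistration:
    def test_identical_hemispheres_zero_field(self):
        ct = generate_phantom(small_spec(seed=6)).ct
        pair = split_and_mirror(ct)
        field, diag = register_hemispheres(pair, RunConfig())
        fg = (pair.left.values > 0)
        assert field.magnitude[fg].mean() < 0.2
        assert diag["mse_after"] <= diag["mse_before"]

    def test_known_deformation_recovered(self):
        ct = generate_phantom(small_spec(seed=6)).ct
        pair = split_and_mirror(ct)
        rng = np.random.default_rng(2)
        true = _smooth_vector_field(pair.left.shape, pair.left.spacing, 4.0, 16.0, rng)
        tfield = DeformationField(true, pair.left.spacing, pair.left.origin)
        moved = warp_with_field(pair.right_mirrored, tfield)
        pair2 = HemispherePair(left=moved, right_mirrored=pair.right_mirrored,
                               midplane_index=pair.midplane_index,
                               n_total=pair.n_total)
        rec, diag = register_hemispheres(pair2, RunConfig())
        from scipy import ndimage as ndi

        fg = (moved.values > 0) & (pair.right_mirrored.values > 0)
        fg = ndi.binary_erosion(fg, iterations=5)
        epe = np.linalg.norm(rec.values - true, axis=-1)[fg]
        assert epe.mean() < 1.0
        assert diag["mse_after"] <= diag["mse_before"]
        assert diag["mean_jacobian"] > 0

    def test_field_magnitude_capped(self, rng):
        f = DeformationField(rng.normal(0, 8, (6, 6, 6, 3)), (1, 1, 1))
        capped = f.capped(10.0)
        assert capped.magnitude.max() <= 10.0 + 1e-9


class TestMapMaskAffine:
    def _cuboid(self, shape=(40, 40, 40), lo=10, hi=20):
        m = np.zeros(shape, dtype=np.uint8)
        m[lo:hi, lo:hi, lo:hi] = 1
        return BinaryMask(m, origin=(0.0, 0.0, 0.0))

    def test_identity_same_grid(self):
        mask = self._cuboid()
        out = map_mask_affine(mask, AffineTransform.identity(), mask)
        assert np.array_equal(out.values, mask.values)

    def test_pure_translation_moves_centroid(self):
        mask = self._cuboid()
        tf = AffineTransform(np.eye(3), np.array([10.0, 0.0, 0.0]))
        out = map_mask_affine(mask, tf, mask)
        c_in = np.argwhere(mask.values).mean(axis=0)
        c_out = np.argwhere(out.values).mean(axis=0)
        assert np.abs((c_out - c_in) - [10.0, 0.0, 0.0]).max() <= 0.5

    def test_round_trip_dice(self, rng):
        # double nearest-neighbour resampling erodes a surface shell, so the
        # attainable round-trip Dice is size-dependent: translations are
        # near-lossless, rotations keep >= 0.85 for >= 1000-voxel cuboids
        from nwuct.metrics import dice

        ang = np.deg2rad(5.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        for _ in range(3):
            lo = rng.integers(6, 12, 3)
            hi = lo + rng.integers(10, 16, 3)
            m = np.zeros((40, 40, 40), dtype=np.uint8)
            m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
            mask = BinaryMask(m)
            assert mask.values.sum() >= 1000
            shift = AffineTransform(np.eye(3), rng.uniform(-6, 6, 3))
            fwd = map_mask_affine(mask, shift, mask)
            back = map_mask_affine(fwd, shift.inverse(), mask)
            assert dice(back.values, mask.values) >= 0.95
            tf = AffineTransform(rot, np.array([3.0, -2.0, 1.5]))
            fwd = map_mask_affine(mask, tf, mask)
            back = map_mask_affine(fwd, tf.inverse(), mask)
            assert dice(back.values, mask.values) >= 0.85
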