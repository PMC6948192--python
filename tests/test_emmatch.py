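"""Volume rendering, projection geometry and 2D class matching."""

import numpy as np
import pytest

from saxsemble import (BeadModel, ClassImage, match_classes, project,
                       project_model, render_volume)
from scipy import ndimage


class TestRenderVolume:
    def test_single_bead_centered_symmetric(self):
        vol = render_volume(BeadModel(np.zeros((1, 3))), voxel=6.5,
                            resolution=40.0)
        com = ndimage.center_of_mass(vol.data)
        center = (np.array(vol.data.shape) - 1) / 2.0
        assert np.all(np.abs(np.array(com) - center) < 0.5)
        assert np.all(vol.data >= 0)

    def test_density_linear_in_bead_count(self):
        one = render_volume(BeadModel(np.zeros((1, 3))), box=21)
        two = render_volume(
            BeadModel(np.array([[0, 0, 0], [0, 0, 0.0]])), box=21)
        assert two.data.sum() == pytest.approx(2.0 * one.data.sum(), rel=1e-9)

    def test_two_bead_maxima_separation(self):
        sep = 91.0  # > 40 A resolution: two resolved blobs
        m = BeadModel(np.array([[0, 0, -sep / 2], [0, 0, sep / 2]]))
        vol = render_volume(m, voxel=6.5, resolution=40.0)
        prof = vol.data[:, vol.data.shape[1] // 2, vol.data.shape[2] // 2]
        # density along z: two local maxima separated by ~sep
        peaks = np.where((prof[1:-1] > prof[:-2]) & (prof[1:-1] > prof[2:]))[0] + 1
        assert len(peaks) == 2
        measured = (peaks[1] - peaks[0]) * vol.voxel
        assert abs(measured - sep) <= vol.voxel

    def test_resolution_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            render_volume(BeadModel(np.zeros((1, 3))), voxel=6.5,
                          resolution=10.0)


@pytest.fixture(scope="module")
def two_blob_volume():
    m = BeadModel(np.array([[0, 0, -45.0], [0, 0, 45.0]]))
    return render_volume(m, voxel=6.5, resolution=40.0, box=33)


@pytest.fixture(scope="module")
def two_models():
    rng = np.random.default_rng(0)
    compact = BeadModel(rng.uniform(-25, 25, size=(40, 3)))
    pts = rng.uniform(-10, 10, size=(40, 3))
    pts[:, 2] *= 9.0  # elongated
    extended = BeadModel(pts)
    return [compact, extended]


class TestProject:
    def test_projection_sum_conserved_across_orientations(self, two_blob_volume):
        s1 = project(two_blob_volume, 0, 0, 0).data.sum()
        s2 = project(two_blob_volume, 40, 70, 15).data.sum()
        assert abs(s1 - s2) / s1 < 0.01

    def test_side_view_preserves_in_plane_distance(self, two_blob_volume):
        # view perpendicular to the blob axis: peaks separated by 90 A
        img = project(two_blob_volume, 0, 90, 0).data
        ys, xs = np.unravel_index(np.argsort(img.ravel())[-2:], img.shape)
        dist = np.hypot((ys[0] - ys[1]) * 6.5, (xs[0] - xs[1]) * 6.5)
        assert abs(dist - 90.0) <= 6.5

    def test_viewing_axis_rotation_commutes_with_2d_rotation(self):
        m = BeadModel(np.array([[30.0, 0, 0], [-30.0, 0, 0], [0, 20.0, 0]]))
        vol = render_volume(m, voxel=6.5, resolution=40.0, box=25)
        # the image-rotation sense is opposite to the volume psi because
        # image rows index y downward in array coordinates
        rot3d = project(vol, 0, 0, 90).data
        rot2d = ndimage.rotate(project(vol, 0, 0, 0).data, -90,
                               reshape=False, order=1)
        corr = np.corrcoef(rot3d.ravel(), rot2d.ravel())[0, 1]
        assert corr > 0.995

    def test_matches_analytic_bead_projection(self):
        m = BeadModel(np.array([[20.0, -10, 5], [-15, 25, -10.0]]))
        vol = render_volume(m, voxel=6.5, resolution=40.0, box=25)
        voxel_img = project(vol, 30, 60, 0).data
        bead_img = project_model(m, 30, 60, 0, box=25)
        corr = np.corrcoef(voxel_img.ravel(), bead_img.ravel())[0, 1]
        assert corr > 0.995  # limited by linear interpolation in the rotation


class TestMatchClasses:
    def test_noiseless_self_match(self, two_models):
        box = 40
        classes = [ClassImage(6.5, project_model(two_models[0], 20, 40, 0, box)),
                   ClassImage(6.5, project_model(two_models[1], 80, 110, 0, box))]
        mr = match_classes(classes, two_models, angular_step=10)
        assert mr.best_model[0] == 0 and mr.best_model[1] == 1
        assert mr.scores[0, 0] > 0.999
        assert mr.scores[1, 1] > 0.999

    def test_self_match_against_volume_projection(self, two_models):
        vol = render_volume(two_models[0], voxel=6.5, resolution=40.0, box=40)
        classes = [ClassImage(6.5, project(vol, 20, 40, 0).data)]
        mr = match_classes(classes, two_models, angular_step=10)
        assert mr.best_model[0] == 0
        assert mr.scores[0, 0] > 0.999

    def test_scores_bounded_for_random_images(self, two_models):
        rng = np.random.default_rng(1)
        classes = [ClassImage(6.5, rng.normal(size=(40, 40))) for _ in range(2)]
        mr = match_classes(classes, two_models, angular_step=30)
        assert np.all(mr.scores >= -1.0) and np.all(mr.scores <= 1.0)

    def test_intensity_scale_and_shift_invariance(self, two_models):
        box = 40
        img = project_model(two_models[0], 50, 70, 0, box)
        shifted = np.roll(img, (2, -1), axis=(0, 1))
        classes = [ClassImage(6.5, img), ClassImage(6.5, 10.0 * shifted + 3.0)]
        mr = match_classes(classes, two_models, angular_step=10)
        assert mr.scores[0, 0] == pytest.approx(mr.scores[1, 0], abs=1e-4)

    def test_empty_inputs_rejected(self, two_models):
        with pytest.raises(ValueError):
            match_classes([], two_models)
        with pytest.raises(ValueError):
            match_classes([ClassImage(6.5, np.zeros((10, 10)))], [])
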