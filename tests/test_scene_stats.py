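"""Gaze cropping, steerable orientation estimation and circular statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from oriadapt import (
    FrameStack,
    SceneSpec,
    gaze_patch,
    next_frame_conditional,
    orientation_field,
    sliding_circular_stats,
    synth_frame_stack,
)
from oriadapt.errors import ConfigurationError
from oriadapt.scene_stats import LevelField, OrientationField, SlidingStats, wrap_axial


def grating(n, theta, wavelength=8.0):
    """Test image with contours oriented at ``theta`` (radians)."""
    y, x = np.mgrid[0:n, 0:n].astype(float)
    beta = theta + np.pi / 2.0  # wavevector orthogonal to the contours
    phase = (x * np.cos(beta) + y * np.sin(beta)) * 2 * np.pi / wavelength
    return 0.5 + 0.4 * np.cos(phase)


def make_stack(frames, deg_per_pixel=0.0625):
    frames = np.asarray(frames)
    T, H, W = frames.shape
    gaze = np.tile([[W / 2.0, H / 2.0]], (T, 1))
    return FrameStack(frames=frames, frame_rate=24.0, deg_per_pixel=deg_per_pixel, gaze=gaze)


class TestGazePatch:
    def test_centered_gaze_crops_central_window(self):
        frames = np.random.default_rng(0).random((3, 64, 64))
        stack = make_stack(frames, deg_per_pixel=6.0 / 32.0)
        patches, clamped = gaze_patch(stack, 6.0)
        assert patches.shape == (3, 32, 32)
        assert not clamped.any()
        assert np.array_equal(patches[0], frames[0, 16:48, 16:48])

    def test_corner_gaze_clamped_and_flagged(self):
        frames = np.zeros((2, 64, 64))
        stack = FrameStack(frames=frames, frame_rate=24.0, deg_per_pixel=6.0 / 32.0,
                           gaze=np.array([[1.0, 1.0], [32.0, 32.0]]))
        patches, clamped = gaze_patch(stack, 6.0)
        assert clamped[0] and not clamped[1]
        assert patches.shape[1:] == (32, 32)

    def test_field_recording_geometry(self):
        # 60 deg over 1280 px implies a 6-deg patch of 128 px
        deg_per_pixel = 60.0 / 1280.0
        frames = np.zeros((1, 960, 1280))
        stack = FrameStack(frames=frames, frame_rate=24.0, deg_per_pixel=deg_per_pixel,
                           gaze=np.array([[640.0, 480.0]]))
        patches, _ = gaze_patch(stack, 6.0)
        assert patches.shape == (1, 128, 128)

    def test_patch_larger_than_frame_rejected(self):
        stack = make_stack(np.zeros((1, 16, 16)), deg_per_pixel=6.0 / 64.0)
        with pytest.raises(ConfigurationError):
            gaze_patch(stack, 6.0)


class TestOrientationEstimator:
    @pytest.mark.parametrize("angle_deg", [-60.0, -15.0, 0.0, 30.0, 75.0])
    def test_grating_orientation_recovered(self, angle_deg):
        img = grating(96, np.deg2rad(angle_deg), wavelength=16.0)
        field = orientation_field(img[None], levels=(2,))
        lf = field[2]
        inner = np.s_[0, 12:-12, 12:-12]
        err = np.degrees(wrap_axial(lf.orientation[inner] - np.deg2rad(angle_deg)))
        # orientation is undefined on the grating's zero-gradient extrema lines
        responsive = lf.magnitude[inner] > 0.1 * lf.magnitude[inner].max()
        assert np.max(np.abs(err[responsive])) < 1.0

    def test_rotation_equivariance(self):
        # rotating the image by 90 degrees rotates the estimates by 90 (mod pi)
        img = grating(96, np.deg2rad(30.0), wavelength=16.0)
        f0 = orientation_field(img[None], levels=(2,))[2]
        f90 = orientation_field(np.ascontiguousarray(np.rot90(img))[None], levels=(2,))[2]
        inner = np.s_[0, 12:-12, 12:-12]
        gate0 = f0.magnitude[inner] > 0.1 * f0.magnitude[inner].max()
        gate90 = f90.magnitude[inner] > 0.1 * f90.magnitude[inner].max()
        a = np.median(np.degrees(wrap_axial(f0.orientation[inner][gate0] - np.deg2rad(30.0))))
        b = np.median(np.degrees(wrap_axial(f90.orientation[inner][gate90] - np.deg2rad(120.0))))
        assert abs(a) < 1.0 and abs(b) < 1.0

    def test_contrast_invariance(self):
        img = grating(48, 0.4)
        f1 = orientation_field(img[None], levels=(2,))[2]
        f2 = orientation_field((0.2 * (img - 0.5) + 0.5)[None], levels=(2,))[2]
        d = wrap_axial(f1.orientation - f2.orientation)
        assert np.max(np.abs(d)) < 1e-9

    def test_isotropic_noise_uniform_orientations(self):
        rng = np.random.default_rng(7)
        imgs = rng.random((400, 64, 64))
        field = orientation_field(imgs, levels=(2,))[2]
        # decimate spatially so samples are independent of the filter support
        ori = field.orientation[:, 2::6, 2::6].ravel()[: 10_000]
        counts, _ = np.histogram(ori, bins=16, range=(-np.pi / 2, np.pi / 2))
        stat, p = chisquare(counts)
        assert p > 0.01

    def test_levels_halve_resolution(self):
        imgs = np.random.default_rng(1).random((2, 128, 128))
        field = orientation_field(imgs, levels=(2, 3, 4))
        assert field[2].orientation.shape[1:] == (64, 64)
        assert field[3].orientation.shape[1:] == (32, 32)
        assert field[4].orientation.shape[1:] == (16, 16)


class TestSlidingStats:
    def _field_from_orientations(self, ori):
        ori = np.asarray(ori, dtype=float)
        lf = LevelField(level=2, orientation=ori, magnitude=np.ones_like(ori),
                        valid=np.ones(ori.shape, dtype=bool))
        return OrientationField(levels={2: lf})

    def test_constant_sequence_zero_variance(self):
        ori = np.full((80, 2, 2), 0.3)
        stats = sliding_circular_stats(self._field_from_orientations(ori), 72)
        assert np.allclose(stats.variance[2], 0.0, atol=1e-12)
        assert np.allclose(wrap_axial(stats.mean[2] - 0.3), 0.0, atol=1e-9)

    def test_uniform_sequence_high_variance(self):
        rng = np.random.default_rng(0)
        ori = rng.uniform(-np.pi / 2, np.pi / 2, size=(73, 8, 8))
        stats = sliding_circular_stats(self._field_from_orientations(ori), 72)
        assert np.all(np.abs(stats.variance[2] - 1.0) < 0.45)
        assert np.mean(np.abs(stats.variance[2] - 1.0) < 0.15) > 0.5

    def test_orthogonal_clusters_cancel(self):
        # equal mass at two orientations 90 deg apart: doubled angles antipodal
        ori = np.tile(np.array([0.0, np.pi / 2]), 40)[: 73].reshape(-1, 1, 1)
        stats = sliding_circular_stats(self._field_from_orientations(ori), 72)
        assert stats.variance[2].max() > 0.97

    def test_too_few_frames_rejected(self):
        ori = np.zeros((72, 2, 2))
        with pytest.raises(ConfigurationError):
            sliding_circular_stats(self._field_from_orientations(ori), 72)


class TestConditionalHistogram:
    def test_empty_band_flagged(self):
        rng = np.random.default_rng(2)
        ori = rng.uniform(-np.pi / 2, np.pi / 2, size=(80, 4, 4))
        lf = LevelField(level=2, orientation=ori, magnitude=np.ones_like(ori),
                        valid=np.ones(ori.shape, dtype=bool))
        field = OrientationField(levels={2: lf})
        stats = sliding_circular_stats(field, 72)
        hist = next_frame_conditional(field, stats, (0.0, 0.1))
        assert hist.empty
        assert hist.n_samples == 0

    def test_central_bin_straddles_zero(self):
        ori = np.full((80, 2, 2), 0.2)
        lf = LevelField(level=2, orientation=ori, magnitude=np.ones_like(ori),
                        valid=np.ones(ori.shape, dtype=bool))
        field = OrientationField(levels={2: lf})
        stats = sliding_circular_stats(field, 72)
        hist = next_frame_conditional(field, stats, (0.0, 0.1))
        center = np.argmax(hist.counts)
        assert hist.bin_edges_deg[center] < 0 < hist.bin_edges_deg[center + 1]
        assert hist.counts[center] == hist.counts.sum()

    def test_persistence_orders_concentration(self):
        """Next-frame concentration grows with the generator's persistence."""
        concentrations = []
        for p in (0.0, 0.5, 0.9, 1.0):
            spec = SceneSpec(n_frames=120, persistence=p, stable_fraction=1.0)
            stack, _ = synth_frame_stack(spec, rng_seed=6)
            patches, _ = gaze_patch(stack)
            field = orientation_field(patches, levels=(2,))
            stats = sliding_circular_stats(field, 72)
            hist = next_frame_conditional(field, stats, (0.0, 1.01))
            centers = np.deg2rad(2.0 * hist.bin_centers_deg)
            pmf = hist.counts / hist.counts.sum()
            concentrations.append(np.abs(np.sum(pmf * np.exp(1j * centers))))
        assert np.all(np.diff(concentrations) > -0.02)
        assert concentrations[-1] > concentrations[0] + 0.2

    def test_estimates_track_latent_orientation(self):
        """Estimator vs ground truth on stable regions (magnitude-gated)."""
        from pingouin import circ_corrcc

        stack, truth = synth_frame_stack(SceneSpec(), rng_seed=1)
        patches, _ = gaze_patch(stack)
        field = orientation_field(patches, levels=(2,))[2]
        lat = truth["latent_orientation"]
        reg = truth["region_px"]
        est, ref, mag = [], [], []
        for i, j in itertools.product(*map(range, lat.shape[1:])):
            if not truth["stable_mask"][i, j]:
                continue
            cy, cx = (i * reg + reg // 2) // 2, (j * reg + reg // 2) // 2
            est.append(field.orientation[:, cy, cx])
            ref.append(lat[:, i, j])
            mag.append(field.magnitude[:, cy, cx])
        est, ref, mag = map(np.concatenate, (est, ref, mag))
        sel = mag >= np.median(mag)
        r, _ = circ_corrcc(2 * est[sel], 2 * ref[sel])
        assert abs(r) > 0.9
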