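"""Scalar-wave propagation, hologram simulation and reconstruction."""

import numpy as np
import pytest
import skimage.draw as skd

from holoplankton import (
    Hologram,
    NoiseSpec,
    OpticalConfig,
    angular_spectrum_propagate,
    reconstruct_slice,
    reconstruct_volume,
    remove_background,
    simulate_hologram,
)
from holoplankton.optics import MM
from holoplankton.scenes import Scene, TrueParticle


def _random_field(shape, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=shape) + 1j * rng.normal(size=shape)


def _disc_region(p, config):
    """Boolean frame mask of a centred particle's true footprint."""
    canvas = np.zeros(config.sensor_shape, bool)
    mr, mc = p.mask.shape
    r0 = config.sensor_shape[0] // 2 - mr // 2
    c0 = config.sensor_shape[1] // 2 - mc // 2
    canvas[r0 : r0 + mr, c0 : c0 + mc] = p.mask
    return canvas


def _disc_particle(diameter_um, z_mm, pitch=3.45, x_um=0.0, y_um=0.0):
    r_px = diameter_um / pitch / 2
    n = int(2 * r_px) + 10
    mask = np.zeros((n, n), bool)
    rr, cc = skd.disk((n / 2, n / 2), r_px)
    mask[rr, cc] = True
    return TrueParticle("Suspension", diameter_um, 1.0, False, x_um, y_um, z_mm, mask)


class TestPropagation:
    def test_zero_distance_is_identity(self, small_config):
        f = _random_field(small_config.sensor_shape)
        np.testing.assert_array_equal(angular_spectrum_propagate(f, 0.0, small_config), f)

    def test_plane_wave_is_eigenfunction(self, small_config):
        pw = np.ones(small_config.sensor_shape, complex)
        out = angular_spectrum_propagate(pw, 70 * MM, small_config)
        assert np.abs(np.abs(out) - 1).max() < 1e-12

    @pytest.mark.parametrize("distance_mm", [10.0, 100.0, 338.4])
    def test_round_trip_identity(self, small_config, distance_mm):
        f = _random_field(small_config.sensor_shape, seed=1)
        g = angular_spectrum_propagate(f, distance_mm * MM, small_config)
        h = angular_spectrum_propagate(g, -distance_mm * MM, small_config)
        assert np.abs(h - f).max() < 1e-9

    def test_linearity(self, small_config):
        f = _random_field(small_config.sensor_shape, seed=2)
        g = _random_field(small_config.sensor_shape, seed=3)
        a, b = 1.7, -0.4 + 0.3j
        lhs = angular_spectrum_propagate(a * f + b * g, 42 * MM, small_config)
        rhs = a * angular_spectrum_propagate(f, 42 * MM, small_config) + (
            b * angular_spectrum_propagate(g, 42 * MM, small_config)
        )
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_power_conservation(self, small_config):
        f = _random_field(small_config.sensor_shape, seed=4)
        g = angular_spectrum_propagate(f, 150 * MM, small_config)
        p0 = (np.abs(f) ** 2).sum()
        p1 = (np.abs(g) ** 2).sum()
        assert abs(p1 / p0 - 1) < 1e-6

    def test_rejects_nonfinite_field(self, small_config):
        f = np.ones(small_config.sensor_shape, complex)
        f[0, 0] = np.nan
        with pytest.raises(ValueError):
            angular_spectrum_propagate(f, 10 * MM, small_config)

    def test_rejects_excessive_distance(self, small_config):
        f = np.ones(small_config.sensor_shape, complex)
        with pytest.raises(ValueError):
            angular_spectrum_propagate(f, 11 * small_config.working_length_mm * MM, small_config)


class TestOpticalConfig:
    def test_pupil_area_derived_from_geometry(self):
        cfg = OpticalConfig()
        assert cfg.pupil_area_mm2 == pytest.approx(0.5e6 / 338.4, rel=1e-6)

    def test_inconsistent_pupil_area_rejected(self):
        with pytest.raises(ValueError):
            OpticalConfig(pupil_area_mm2=1600.0)

    @pytest.mark.parametrize("field", ["wavelength_um", "pixel_pitch_um", "working_length_mm"])
    def test_positive_lengths_required(self, field):
        with pytest.raises(ValueError):
            OpticalConfig(**{field: 0.0})


class TestSimulate:
    def test_empty_scene_gives_uniform_intensity(self, small_config):
        holo = simulate_hologram(Scene([], small_config), small_config, noise=None)
        assert np.ptp(holo.intensity) < 1e-12
        assert holo.intensity[0, 0] == pytest.approx(1.0)

    def test_deterministic_for_fixed_seed(self, small_config):
        scene = Scene([_disc_particle(300, 40.0)], small_config)
        h1 = simulate_hologram(scene, small_config, NoiseSpec(0.02), rng_seed=7)
        h2 = simulate_hologram(scene, small_config, NoiseSpec(0.02), rng_seed=7)
        np.testing.assert_array_equal(h1.intensity, h2.intensity)

    def test_fresnel_fringes_around_disc(self, small_config):
        """The first bright Fresnel ring sits near r ~ sqrt(lambda z)."""
        z = 30.0
        scene = Scene([_disc_particle(300, z)], small_config)
        holo = simulate_hologram(scene, small_config, noise=None)
        centre = np.array(holo.intensity.shape) // 2
        prof = holo.intensity[centre[0], centre[1] :]
        # intensity oscillates: there must be a maximum above 1 (constructive
        # fringe) within the first ~60 pixels beyond the disc edge
        edge = int(150 / small_config.pixel_pitch_um)
        assert prof[edge : edge + 60].max() > 1.02

    def test_particle_outside_volume_rejected(self, small_config):
        scene = Scene([_disc_particle(300, 400.0)], small_config)
        with pytest.raises(ValueError):
            simulate_hologram(scene, small_config, noise=None)

    def test_identical_positions_warn(self, small_config):
        p1 = _disc_particle(300, 40.0)
        p2 = _disc_particle(200, 40.0)
        scene = Scene([p1, p2], small_config)
        with pytest.warns(UserWarning):
            simulate_hologram(scene, small_config, noise=None)


class TestBackgroundRemoval:
    def test_uniform_hologram_becomes_ones(self, small_config):
        holo = Hologram(np.full(small_config.sensor_shape, 3.7), small_config)
        out = remove_background(holo, "divide_lowpass")
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_smooth_vignette_removed(self, small_config):
        scene = Scene([_disc_particle(120, 40.0)], small_config)
        holo = simulate_hologram(scene, small_config, noise=None)
        n = small_config.sensor_shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        vignette = 1.2 - 0.4 * ((yy - n / 2) ** 2 + (xx - n / 2) ** 2) / (n / 2) ** 2
        dirty = Hologram(holo.intensity * vignette, small_config)
        clean_dirty = remove_background(dirty, "divide_lowpass").intensity
        clean_ref = remove_background(holo, "divide_lowpass").intensity
        # away from the frame border (filter edge effects) the vignetted
        # hologram normalises to the same field within 2%
        b = n // 10
        assert np.abs(clean_dirty - clean_ref)[b:-b, b:-b].max() < 0.02

    def test_sequence_mean_cancels_static_background(self, small_config):
        rng = np.random.default_rng(0)
        static = 1.0 + 0.3 * rng.random(small_config.sensor_shape)
        scene = Scene([_disc_particle(250, 40.0)], small_config)
        fringe = simulate_hologram(scene, small_config, noise=None).intensity - 1.0
        frames = [Hologram(static + (fringe if i == 0 else 0.0), small_config) for i in range(4)]
        out = remove_background(frames[0], "subtract_sequence_mean", sequence=frames)
        residual = out.intensity - out.intensity.mean() - 0.75 * fringe
        assert np.abs(residual).max() < 0.01 * np.abs(fringe).max() + 0.05

    def test_sequence_mean_needs_multiple_frames(self, small_config):
        holo = Hologram(np.random.default_rng(0).random(small_config.sensor_shape), small_config)
        with pytest.raises(ValueError):
            remove_background(holo, "subtract_sequence_mean", sequence=[holo])


class TestReconstruction:
    def test_disc_support_recovered_at_true_depth(self, small_config):
        z0 = 40.0
        p = _disc_particle(400, z0)
        holo = simulate_hologram(Scene([p], small_config), small_config, noise=None)
        sl = reconstruct_slice(holo, z0)
        dark = sl.amplitude < 0.5
        assert dark.sum() == pytest.approx(p.mask.sum(), rel=0.10)

    def test_contrast_drops_away_from_focus(self, small_config):
        z0 = 40.0
        p = _disc_particle(400, z0)
        holo = simulate_hologram(Scene([p], small_config), small_config, noise=None)
        region = _disc_region(p, small_config)
        at_focus = reconstruct_slice(holo, z0).amplitude[region]
        far = reconstruct_slice(holo, z0 + 60.0).amplitude[region]
        # the silhouette is deepest (mean darkest) in focus
        assert at_focus.mean() < far.mean()

    def test_empty_scene_uniform_amplitude(self, small_config):
        holo = simulate_hologram(Scene([], small_config), small_config, noise=None)
        sl = reconstruct_slice(holo, 50.0)
        assert np.ptp(sl.amplitude) < 1e-9

    def test_z_out_of_range_rejected(self, small_config):
        holo = simulate_hologram(Scene([], small_config), small_config, noise=None)
        with pytest.raises(ValueError):
            reconstruct_slice(holo, 400.0)

    def test_volume_slice_count(self, small_config):
        holo = simulate_hologram(Scene([], small_config), small_config, noise=None)
        stack = reconstruct_volume(holo, (10.0, 20.0), 5.0)
        assert [s.z_mm for s in stack] == [10.0, 15.0, 20.0]

    def test_step_larger_than_range_gives_single_slice(self, small_config):
        holo = simulate_hologram(Scene([], small_config), small_config, noise=None)
        stack = reconstruct_volume(holo, (10.0, 20.0), 50.0)
        assert len(stack) == 1 and stack[0].z_mm == 10.0

    def test_reversed_range_rejected(self, small_config):
        holo = simulate_hologram(Scene([], small_config), small_config, noise=None)
        with pytest.raises(ValueError):
            reconstruct_volume(holo, (20.0, 10.0), 5.0)

    def test_sharpest_slice_near_true_depth(self, small_config):
        from holoplankton.extraction import focus_metric

        z0 = 45.0
        p = _disc_particle(350, z0)
        holo = simulate_hologram(Scene([p], small_config), small_config, noise=None)
        stack = reconstruct_volume(holo, (25.0, 65.0), 5.0)
        c = small_config.sensor_shape[0] // 2
        hw = 70
        sharp = [focus_metric(s.amplitude[c - hw : c + hw, c - hw : c + hw]) for s in stack]
        z_best = stack[int(np.argmax(sharp))].z_mm
        assert abs(z_best - z0) <= 5.0
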