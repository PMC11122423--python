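"""Simulator oracles and invariants."""

import numpy as np
import pytest

from dssmlm import sim
from dssmlm.calibration import pixel_to_wavelength


def test_config_validation():
    with pytest.raises(sim.ConfigError):
        sim.OpticsConfig(split_ratio=1.5)
    with pytest.raises(sim.ConfigError):
        sim.OpticsConfig(psf_sigma=-1)
    with pytest.raises(sim.ConfigError):
        sim.OpticsConfig(background_rate=0.0)


def test_fov_too_small_rejected(af647):
    tiny = sim.OpticsConfig(fov=(0.2, 0.2))  # 2x2 px, PSF does not fit
    with pytest.raises(sim.ConfigError):
        sim.simulate_stack(tiny, [af647], 1, 0.1, seed=0)


def test_dye_spectrum_invariants():
    dye = sim.DyeSpectrum("x", [500.0, 510.0, 520.0], [0.5, 2.0, 1.0])
    assert dye.intensities.max() == 1.0
    assert dye.peak_wavelength == 510.0
    with pytest.raises(ValueError):
        sim.DyeSpectrum("bad", [500.0, 500.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        sim.DyeSpectrum("bad", [500.0, 510.0], [1.0, -0.1])


def test_emitter_truth_validation(af647):
    with pytest.raises(ValueError):
        sim.EmitterTruth(0, 1.0, 1.0, 100.0, af647)
    with pytest.raises(ValueError):
        sim.EmitterTruth(1, 1.0, 1.0, 0.0, af647)


def test_spatial_mass_quadrature_oracle(optics, af647):
    """Noise-free render of one emitter carries (1-split)*photons, checked
    against independent numerical integration of the Gaussian."""
    e = sim.EmitterTruth(1, 3200.0, 3200.0, 1000.0, af647)
    frame = sim.render_frame(optics, [e], 1)
    got = frame.spatial_image.sum()

    # quadrature oracle: integrate the 2-D Gaussian over the pixel grid on
    # a 10x-oversampled lattice
    px = optics.camera_pixel_size
    s = optics.psf_sigma
    n = optics.frame_shape[0]
    grid = (np.arange(n * 10) + 0.5) / 10.0 - 0.5  # px units, pixel centres at ints
    x_nm = grid * px
    g1 = np.exp(-((x_nm - e.x) ** 2) / (2 * s ** 2))
    mass_1d = g1.sum() * (px / 10.0) / (np.sqrt(2 * np.pi) * s)
    expected = 0.25 * 1000.0 * mass_1d ** 2
    assert got == pytest.approx(expected, rel=5e-3)
    assert got == pytest.approx(0.25 * 1000.0, rel=5e-3)


def test_photon_conservation_both_channels(af647):
    """Spatial + spectral expected mass equals the emitted photon budget
    split by the detection fractions (0.5% tolerance)."""
    wide = sim.OpticsConfig(fov=(12.8, 12.8), spectral_width=256)
    e = sim.EmitterTruth(1, 6400.0, 6400.0, 2000.0, af647)
    frame = sim.render_frame(wide, [e], 1)
    assert frame.spatial_image.sum() == pytest.approx(0.25 * 2000, rel=5e-3)
    assert frame.spectral_image.sum() == pytest.approx(0.75 * 2000, rel=5e-3)


def test_background_only_frame(optics, af647):
    """Zero emitters: mean equals background_rate (read noise has mean 0)."""
    frames, truths = sim.simulate_stack(optics, [af647], 30, 1e-9, seed=3)
    assert len(truths) == 0
    mean = np.mean([f.spatial_image.mean() for f in frames])
    assert mean == pytest.approx(optics.background_rate, rel=0.02)


def test_poisson_variance_matches_mean(af647):
    """Per-pixel variance ~ per-pixel mean on constant-background frames."""
    opt = sim.OpticsConfig(fov=(1.6, 1.6), read_noise_sd=0.0)
    frames, _ = sim.simulate_stack(opt, [af647], 1200, 1e-9, seed=5)
    stack = np.stack([f.spatial_image for f in frames])
    mean = stack.mean(axis=0).mean()
    var = stack.var(axis=0).mean()
    assert var == pytest.approx(mean, rel=0.05)


def test_density_calibration(af647):
    """Mean emitters/frame within 3 sd of density x area over 1000 frames."""
    opt = sim.OpticsConfig(fov=(3.2, 3.2))
    density = 0.5
    n_frames = 1000
    _, truths = sim.simulate_stack(opt, [af647], n_frames, density, seed=11)
    lam = density * opt.fov[0] * opt.fov[1]
    sd = np.sqrt(lam / n_frames)
    assert len(truths) / n_frames == pytest.approx(lam, abs=3 * sd)


def test_expected_mean_emitters_at_paper_density(af647):
    """0.1 /um^2 on a 25.6 um square field -> Poisson mean ~65.5."""
    opt = sim.OpticsConfig(fov=(25.6, 25.6))
    assert 0.1 * opt.fov[0] * opt.fov[1] == pytest.approx(65.5, abs=0.1)
    _, truths = sim.simulate_stack(opt, [af647], 60, 0.1, seed=2)
    assert len(truths) / 60 == pytest.approx(65.5, rel=0.1)


def test_determinism(optics, af647):
    a = sim.simulate_stack(optics, [af647], 5, 0.1, seed=99)
    b = sim.simulate_stack(optics, [af647], 5, 0.1, seed=99)
    for fa, fb in zip(a[0], b[0]):
        np.testing.assert_array_equal(fa.spatial_image, fb.spatial_image)
        np.testing.assert_array_equal(fa.spectral_image, fb.spectral_image)
    assert [(t.x, t.y, t.photons) for t in a[1]] == \
        [(t.x, t.y, t.photons) for t in b[1]]


def test_spike_index_rounding_oracle():
    """Continuous (10.3, 20.7) px at 4x -> grid indices (41, 83)."""
    assert sim.spike_index(10.3, 4) == round(10.3 * 4) == 41
    assert sim.spike_index(20.7, 4) == round(20.7 * 4) == 83


def test_spatial_training_set_min_emitters(small_stack):
    frames, truths = small_stack
    pairs = sim.make_spatial_training_set(frames, truths, patch_size=32,
                                          upsampling=4, n_pairs=50, seed=0)
    assert pairs, "expected at least one valid patch"
    for p in pairs:
        assert p.emitter_count >= 3
        assert p.input_patch.shape == (32, 32)
        assert p.target_grid.shape == (128, 128)
        assert np.all(p.target_grid >= 0)
        # unit per-spike mass
        assert p.target_grid.sum() == pytest.approx(p.emitter_count)


def test_spatial_training_set_spike_positions(optics, af647):
    e = sim.EmitterTruth(1, 10.3 * 100.0, 20.7 * 100.0, 1000.0, af647)
    e2 = sim.EmitterTruth(1, 500.0, 700.0, 1000.0, af647)
    e3 = sim.EmitterTruth(1, 2000.0, 2500.0, 1000.0, af647)
    frame = sim.render_frame(optics, [e, e2, e3], 1)
    pairs = sim.make_spatial_training_set([frame], [e, e2, e3], patch_size=64,
                                          upsampling=4, n_pairs=1, seed=0)
    target = pairs[0].target_grid
    assert target[83, 41] == 1.0  # row = y index, col = x index
    assert target[28, 20] == 1.0
    assert pairs[0].emitter_count == 3


def test_spatial_training_set_shortfall_warns(small_stack):
    frames, truths = small_stack
    with pytest.warns(UserWarning, match="only"):
        pairs = sim.make_spatial_training_set(
            frames, truths, patch_size=32, upsampling=4, n_pairs=10 ** 6,
            seed=0)
    assert 0 < len(pairs) < 10 ** 6


def test_spectral_training_set_shapes(spectral_pairs):
    assert spectral_pairs
    for p in spectral_pairs[:50]:
        assert p.roi_shape == (5, 50)
        assert p.noisy_roi.shape == (5, 50)
        assert np.all(p.clean_roi >= 0)


def test_spectral_training_set_zero_noise(wide_optics, af647):
    """With noise disabled, noisy and clean ROIs coincide."""
    frames, clean, truths = sim.simulate_stack(
        wide_optics, [af647], 20, 0.1, seed=4, noise=False, return_clean=True)
    cal = sim.true_calibration(wide_optics)
    pairs = sim.make_spectral_training_set(frames, clean, truths, cal,
                                           mode="labeled", n_pairs=10 ** 9,
                                           seed=0)
    assert pairs
    for p in pairs:
        np.testing.assert_array_equal(p.noisy_roi, p.clean_roi)


def test_clean_roi_peak_matches_convolution_oracle(wide_optics, af647):
    """Clean ROI column profile peaks where the independently recomputed
    (spectrum x dispersion x Gaussian) model peaks."""
    from scipy.special import erf

    opt = wide_optics
    cal = sim.true_calibration(opt)
    e = sim.EmitterTruth(1, 4000.0, 6000.0, 3000.0, af647)
    frame = sim.render_frame(opt, [e], 1)
    from dssmlm.enhancer import crop_spectral_roi
    roi = crop_spectral_roi(frame, (e.x, e.y), cal, "labeled",
                            camera_pixel_size=opt.camera_pixel_size)
    profile = roi.pixels.mean(axis=0)

    # oracle: direct reconvolution on the ROI columns
    cols = roi.roi_origin[1] + np.arange(50)
    cx = e.x / opt.camera_pixel_size
    xk = cx + opt.reference_offset + \
        (af647.wavelengths - opt.calibration_intercept) / opt.spectral_dispersion
    w = af647.intensities * np.gradient(af647.wavelengths)
    w = w / w.sum()
    sig = opt.psf_sigma_px
    edges = np.concatenate([cols - 0.5, [cols[-1] + 0.5]])
    cdf = 0.5 * (1 + erf((edges[None, :] - xk[:, None]) / (sig * np.sqrt(2))))
    oracle = w @ np.diff(cdf, axis=1)
    assert int(np.argmax(profile)) == int(np.argmax(oracle))


def test_clean_roi_peak_wavelength_near_dye_peak(wide_optics, af647):
    """Peak column maps through the calibration to the dye peak within one
    dispersion step."""
    opt = wide_optics
    cal = sim.true_calibration(opt)
    for x_px in (25.0, 40.3, 77.7):
        e = sim.EmitterTruth(1, x_px * 100.0, 6000.0, 3000.0, af647)
        frame = sim.render_frame(opt, [e], 1)
        from dssmlm.enhancer import crop_spectral_roi
        roi = crop_spectral_roi(frame, (e.x, e.y), cal, "labeled")
        profile = roi.pixels.mean(axis=0)
        col = roi.roi_origin[1] + int(np.argmax(profile))
        lam = pixel_to_wavelength(cal, x_px, col)
        assert lam == pytest.approx(af647.peak_wavelength,
                                    abs=opt.spectral_dispersion)
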