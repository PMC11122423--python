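"""Evaluation metrics: matching, JI, RMSE, SSIM, FWHM, FRC."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from dssmlm.metrics import (FWHM_FACTOR, FitError, GaussianFit, MatchResult,
                            evaluate_detection, frc_curve, frc_resolution,
                            fwhm_from_profile, jaccard_index, lateral_rmse,
                            match_localizations, ssim)
from dssmlm.postprocess import render
from dssmlm.spectral import Localization


# ---------------------------------------------------------------- matching

def brute_force_match(pred, truth, radius):
    """Exhaustive optimal assignment: maximize matches, then minimize total
    distance.  Only viable for a handful of points."""
    pred = np.asarray(pred, float).reshape(-1, 2)
    truth = np.asarray(truth, float).reshape(-1, 2)
    d = np.sqrt(((pred[:, None] - truth[None]) ** 2).sum(-1))
    best = (0, 0.0, ())
    np_, nt = len(pred), len(truth)
    for k in range(min(np_, nt), -1, -1):
        found = None
        for ps in itertools.combinations(range(np_), k):
            for ts in itertools.permutations(range(nt), k):
                if all(d[i, j] <= radius for i, j in zip(ps, ts)):
                    tot = sum(d[i, j] for i, j in zip(ps, ts))
                    if found is None or tot < found[0]:
                        found = (tot, tuple(zip(ps, ts)))
        if found:
            best = (k, found[0], found[1])
            break
    return best  # (tp, total distance, pairs)


def test_match_identical_lists(rng):
    pts = rng.uniform(0, 1000, (6, 2))
    m = match_localizations(pts, pts, radius=100.0)
    assert (m.tp, m.fp, m.fn) == (6, 0, 0)
    assert jaccard_index(m) == 1.0
    assert lateral_rmse(m, pts, pts) == 0.0


def test_match_disjoint_far_lists():
    pred = [(0.0, 0.0), (10.0, 0.0)]
    truth = [(5000.0, 5000.0)]
    m = match_localizations(pred, truth, radius=100.0)
    assert (m.tp, m.fp, m.fn) == (0, 2, 1)


def test_match_one_pred_two_truths():
    """One prediction within radius of two truths: tp 1, fn 1, fp 0."""
    pred = [(0.0, 0.0)]
    truth = [(30.0, 0.0), (-30.0, 0.0)]
    m = match_localizations(pred, truth, radius=100.0)
    assert (m.tp, m.fp, m.fn) == (1, 0, 1)
    tp_bf, _, _ = brute_force_match(pred, truth, 100.0)
    assert m.tp == tp_bf


@pytest.mark.parametrize("seed", range(6))
def test_match_agrees_with_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    pred = rng.uniform(0, 400, (int(rng.integers(0, 5)), 2))
    truth = rng.uniform(0, 400, (int(rng.integers(1, 5)), 2))
    radius = 150.0
    m = match_localizations(pred, truth, radius)
    tp_bf, dist_bf, _ = brute_force_match(pred, truth, radius)
    assert m.tp == tp_bf
    if m.tp:
        d = np.sqrt(((pred[:, None] - truth[None]) ** 2).sum(-1))
        tot = sum(d[i, j] for i, j in m.pairs)
        assert tot == pytest.approx(dist_bf, rel=1e-9)


def test_match_greedy_variant():
    pred = [(0.0, 0.0), (60.0, 0.0)]
    truth = [(50.0, 0.0)]
    m = match_localizations(pred, truth, radius=100.0, method="greedy")
    assert m.tp == 1 and m.pairs == ((1, 0),)


def test_match_result_invariants():
    with pytest.raises(ValueError):
        MatchResult(2, 0, 0, ((0, 0),))


def test_jaccard_hand_arithmetic():
    assert jaccard_index(MatchResult(2, 1, 1, ((0, 0), (1, 1)))) == 0.5
    with pytest.raises(ValueError):
        jaccard_index(MatchResult(0, 0, 0, ()))


def test_lateral_rmse_pythagorean():
    pred = [(3.0, 4.0)]
    truth = [(0.0, 0.0)]
    m = match_localizations(pred, truth, radius=100.0)
    assert lateral_rmse(m, pred, truth) == pytest.approx(5.0)


def test_lateral_rmse_translation_invariant(rng):
    pred = rng.uniform(0, 500, (5, 2))
    truth = pred + rng.normal(0, 10, (5, 2))
    m = match_localizations(pred, truth, radius=100.0)
    r1 = lateral_rmse(m, pred, truth)
    r2 = lateral_rmse(m, pred + 777.0, truth + 777.0)
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_evaluate_detection_pools_frames():
    pred = {1: np.array([[0.0, 0.0]]), 2: np.zeros((0, 2))}
    truth = {1: np.array([[10.0, 0.0]]), 2: np.array([[5.0, 5.0]])}
    out = evaluate_detection(pred, truth, radius=100.0)
    assert out["tp"] == 1 and out["fn"] == 1 and out["fp"] == 0
    assert out["ji"] == 0.5
    assert out["rmse_nm"] == pytest.approx(10.0)


# ---------------------------------------------------------------- SSIM

def _reference_ssim(a, b, data_range):
    """Independent SSIM (Wang et al.) with Gaussian weighting, matching the
    stated constants: K1=0.01, K2=0.03, window sd 1.5."""
    fil = lambda x: gaussian_filter(x, 1.5, truncate=3.5)  # noqa: E731
    ua, ub = fil(a), fil(b)
    va = fil(a * a) - ua * ua
    vb = fil(b * b) - ub * ub
    cab = fil(a * b) - ua * ub
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * cab + c2)) / \
        ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2))
    pad = 5  # (win-1)//2 for sigma 1.5, truncate 3.5
    return s[pad:-pad, pad:-pad].mean()


def test_ssim_identity():
    a = np.random.default_rng(0).random((32, 32))
    assert ssim(a, a) == pytest.approx(1.0, abs=1e-9)


def test_ssim_matches_reference_implementation(rng):
    a = rng.random((32, 32))
    b = rng.random((32, 32))
    assert ssim(a, b, data_range=1.0) == \
        pytest.approx(_reference_ssim(a, b, 1.0), abs=1e-6)


def test_ssim_shape_mismatch():
    with pytest.raises(ValueError):
        ssim(np.zeros((4, 4)), np.zeros((5, 5)))


# ---------------------------------------------------------------- FWHM

def test_fwhm_factor_exact():
    assert FWHM_FACTOR == pytest.approx(2 * np.sqrt(2 * np.log(2)), abs=1e-12)
    fit = GaussianFit(1.0, 0.0, 1.0, 0.0)
    assert fit.fwhm == pytest.approx(2.355, abs=1e-3)


def test_fwhm_ratio_on_noise_free_gaussian():
    x = np.arange(-60.0, 60.0, 1.0)
    y = 3.0 * np.exp(-(x ** 2) / (2 * 10.0 ** 2)) + 0.5
    fit = fwhm_from_profile(x, y)
    assert fit.sigma == pytest.approx(10.0, abs=1e-6)
    assert fit.fwhm / fit.sigma == pytest.approx(FWHM_FACTOR, abs=1e-12)
    assert fit.center == pytest.approx(0.0, abs=1e-6)
    assert fit.amplitude == pytest.approx(3.0, abs=1e-6)
    assert fit.offset == pytest.approx(0.5, abs=1e-6)


def test_fwhm_errors():
    with pytest.raises(FitError):
        fwhm_from_profile([0.0, 1.0, 2.0], [1.0, 2.0, 1.0])
    with pytest.raises(FitError):
        fwhm_from_profile([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0])


# ---------------------------------------------------------------- FRC

def _cluster_locs(rng, n_events, sd=50.0, n_clusters=25):
    centers = [(1000.0 + (i % 5) * 1500.0, 1000.0 + (i // 5) * 1500.0)
               for i in range(n_clusters)]
    locs = []
    for k in range(n_events):
        cx, cy = centers[int(rng.integers(n_clusters))]
        locs.append(Localization(frame=k + 1, x=cx + rng.normal(0, sd),
                                 y=cy + rng.normal(0, sd), photons=100.0))
    return locs


def test_frc_uncorrelated_noise_near_zero(rng):
    locs = [Localization(frame=i + 1, x=float(x), y=float(y), photons=1.0)
            for i, (x, y) in enumerate(rng.uniform(0, 5000, (4000, 2)))]
    img1 = render(locs[:2000], 20.0, extent=((0, 5000), (0, 5000)))
    img2 = render(locs[2000:], 20.0, extent=((0, 5000), (0, 5000)))
    freq, frc = frc_curve(img1, img2)
    assert np.abs(frc[5:]).mean() < 0.1


def test_frc_resolution_simulation_oracle(rng):
    """Median FRC resolution over seeds within 30% of the 2.355*sd*sqrt(2)
    expectation for Gaussian-spread clusters."""
    sd = 50.0
    locs = _cluster_locs(rng, 8000, sd=sd)
    res = [frc_resolution(locs, pixel=20.0, seed=s) for s in range(10)]
    expected = FWHM_FACTOR * sd * np.sqrt(2)
    assert np.median(res) == pytest.approx(expected, rel=0.30)


def test_frc_resolution_improves_with_count(rng):
    locs = _cluster_locs(rng, 12000, sd=50.0)
    res_small = np.median([frc_resolution(locs[:1500], pixel=20.0, seed=s)
                           for s in range(5)])
    res_large = np.median([frc_resolution(locs, pixel=20.0, seed=s)
                           for s in range(5)])
    assert res_large < res_small


def test_frc_threshold_never_crossed_reports_nyquist():
    rng = np.random.default_rng(0)
    # heavy duplication makes any random half-split nearly identical, so
    # the FRC stays above 1/7 at every ring
    base = _cluster_locs(rng, 400, sd=30.0, n_clusters=4)
    locs = base * 20
    res = frc_resolution(locs, pixel=50.0, seed=1)
    assert res == pytest.approx(2 * 50.0)  # Nyquist-limited lower bound
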