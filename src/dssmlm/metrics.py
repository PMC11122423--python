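"""Evaluation suite: detection matching, Jaccard index, lateral RMSE,
SSIM, Gaussian-fit FWHM, and Fourier ring correlation resolution."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, linear_sum_assignment
from skimage.metrics import structural_similarity

from .postprocess import render
from .spectral import Localization

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]  # (prediction index, truth index)

    def __post_init__(self):
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of matched pairs")


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    center: float
    sigma: float
    offset: float

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


class FitError(RuntimeError):
    pass


def _as_xy(points) -> np.ndarray:
    a = np.asarray(points, dtype=np.float64)
    if a.size == 0:
        return a.reshape(0, 2)
    return a.reshape(-1, 2)


def match_localizations(pred, truth, radius: float,
                        method: str = "optimal") -> MatchResult:
    """One-to-one matching of predictions to ground truth within ``radius``.

    ``optimal`` minimizes total distance over admissible pairs (Hungarian
    assignment); ``greedy`` matches nearest pairs first.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    p = _as_xy(pred)
    t = _as_xy(truth)
    if p.shape[0] == 0 or t.shape[0] == 0:
        return MatchResult(0, p.shape[0], t.shape[0], ())
    d = np.sqrt(((p[:, None, :] - t[None, :, :]) ** 2).sum(axis=2))
    if method == "optimal":
        big = radius * 1e6
        cost = np.where(d <= radius, d, big)
        ri, ci = linear_sum_assignment(cost)
        pairs = tuple((int(i), int(j)) for i, j in zip(ri, ci)
                      if d[i, j] <= radius)
    elif method == "greedy":
        pairs_l = []
        used_p, used_t = set(), set()
        order = np.argsort(d, axis=None)
        for flat in order:
            i, j = np.unravel_index(flat, d.shape)
            if d[i, j] > radius:
                break
            if i in used_p or j in used_t:
                continue
            used_p.add(int(i))
            used_t.add(int(j))
            pairs_l.append((int(i), int(j)))
        pairs = tuple(pairs_l)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    tp = len(pairs)
    return MatchResult(tp, p.shape[0] - tp, t.shape[0] - tp, pairs)


def jaccard_index(m: MatchResult) -> float:
    """TP / (FN + FP + TP)."""
    denom = m.tp + m.fp + m.fn
    if denom == 0:
        raise ValueError("Jaccard index undefined for an empty problem")
    return m.tp / denom


def lateral_rmse(m: MatchResult, pred, truth) -> float:
    """Root mean square Euclidean distance over matched pairs (nm)."""
    if m.tp < 1:
        raise ValueError("lateral RMSE undefined without matches")
    p = _as_xy(pred)
    t = _as_xy(truth)
    pi = np.array([i for i, _ in m.pairs])
    ti = np.array([j for _, j in m.pairs])
    d2 = ((p[pi] - t[ti]) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Mean SSIM with a Gaussian window (sd 1.5 px, k1=0.01, k2=0.03).

    ``data_range`` defaults to the dynamic range of ``b`` (the reference
    / ground-truth image).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0:
            data_range = 1.0
    kwargs = {}
    # the Gaussian window (sd 1.5) spans 11 px; shrink it for small ROIs
    if min(a.shape) < 11:
        win = min(a.shape)
        kwargs["win_size"] = win if win % 2 else win - 1
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, **kwargs))


def _gauss_offset(x, a, mu, sigma, c):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)) + c


def fwhm_from_profile(positions, intensities) -> GaussianFit:
    """Least-squares Gaussian+offset fit of a line profile.

    FWHM is reported as 2*sqrt(2 ln 2)*sigma of the fitted Gaussian.
    """
    x = np.asarray(positions, dtype=np.float64)
    y = np.asarray(intensities, dtype=np.float64)
    if x.size < 4:
        raise FitError("need at least 4 samples")
    if np.ptp(y) == 0:
        raise FitError("profile is constant")
    c0 = y.min()
    a0 = y.max() - c0
    mu0 = float(x[np.argmax(y)])
    w = np.maximum(y - c0, 0)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w))) or np.ptp(x) / 4
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # a perfect (noise-free) fit has a singular covariance; harmless
            _warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss_offset, x, y, p0=[a0, mu0, sigma0, c0],
                                maxfev=10000)
    except RuntimeError as e:
        raise FitError(f"Gaussian fit did not converge: {e}") from e
    a, mu, sigma, c = popt
    if sigma == 0 or not np.isfinite(sigma):
        raise FitError("degenerate fitted sigma")
    return GaussianFit(float(a), float(mu), float(abs(sigma)), float(c))


def evaluate_detection(pred_by_frame: dict, truth_by_frame: dict,
                       radius: float, method: str = "optimal") -> dict:
    """Frame-wise one-to-one matching, pooled into overall JI and RMSE.

    ``pred_by_frame`` / ``truth_by_frame`` map frame index -> (n, 2)
    arrays of (x, y) positions in nm.
    """
    tp = fp = fn = 0
    sq: list[float] = []
    for f in sorted(set(pred_by_frame) | set(truth_by_frame)):
        p = _as_xy(pred_by_frame.get(f, np.empty((0, 2))))
        t = _as_xy(truth_by_frame.get(f, np.empty((0, 2))))
        m = match_localizations(p, t, radius, method=method)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        for i, j in m.pairs:
            sq.append(float(((p[i] - t[j]) ** 2).sum()))
    ji = tp / (tp + fp + fn) if tp + fp + fn else float("nan")
    rmse = float(np.sqrt(np.mean(sq))) if sq else float("nan")
    return {"ji": ji, "rmse_nm": rmse, "tp": tp, "fp": fp, "fn": fn}


def frc_curve(img1: np.ndarray, img2: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Ring-wise Fourier correlation of two equally shaped images.

    Returns (spatial frequency in 1/px, FRC value) per ring.
    """
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    n = min(img1.shape)
    cy, cx = img1.shape[0] // 2, img1.shape[1] // 2
    yy, xx = np.indices(img1.shape)
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2).astype(int)
    nr = n // 2
    num = np.bincount(r.ravel(), weights=(f1 * np.conj(f2)).real.ravel(),
                      minlength=nr)[:nr]
    d1 = np.bincount(r.ravel(), weights=(np.abs(f1) ** 2).ravel(),
                     minlength=nr)[:nr]
    d2 = np.bincount(r.ravel(), weights=(np.abs(f2) ** 2).ravel(),
                     minlength=nr)[:nr]
    denom = np.sqrt(d1 * d2)
    frc = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    freq = np.arange(nr) / n  # cycles per pixel
    return freq, frc


def frc_resolution(locs: list[Localization], pixel: float, seed: int = 0,
                   threshold: float = 1.0 / 7.0) -> float:
    """FRC resolution (nm): localizations are split randomly in half, the
    two renders are ring-correlated, the 2-bin moving-averaged curve is
    read off at the fixed 1/7 threshold.

    If the curve never drops below the threshold the Nyquist-limited
    lower bound (2 * pixel) is returned.
    """
    if len(locs) < 2:
        raise ValueError("need at least two localizations")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(locs))
    half = len(locs) // 2
    xs = np.array([l.x for l in locs])
    ys = np.array([l.y for l in locs])
    extent = ((xs.min(), xs.max() + pixel), (ys.min(), ys.max() + pixel))
    a = [locs[i] for i in idx[:half]]
    b = [locs[i] for i in idx[half:]]
    img1 = render(a, pixel, blur_sigma=0.0, extent=extent)
    img2 = render(b, pixel, blur_sigma=0.0, extent=extent)
    side = min(img1.shape)
    img1 = img1[:side, :side]
    img2 = img2[:side, :side]
    freq, frc = frc_curve(img1, img2)
    # 2-bin moving average smoothing
    sm = np.convolve(frc, np.ones(2) / 2.0, mode="same")
    below = np.where(sm[1:] < threshold)[0]
    if below.size == 0:
        return 2.0 * pixel
    i = below[0] + 1
    # linear interpolation of the crossing between bins i-1 and i
    f0, f1v = sm[i - 1], sm[i]
    x0, x1 = freq[i - 1], freq[i]
    fc = x0 if f1v == f0 else x0 + (f0 - threshold) * (x1 - x0) / (f0 - f1v)
    if fc <= 0:
        return 2.0 * pixel
    return float(pixel / fc)
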