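"""Post-processing of localization lists: cross-correlation drift
correction, spectral-regression merging of repeated emissions, and
super-resolution rendering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .spectral import Localization


@dataclass
class DriftModel:
    bin_edges: np.ndarray   # frame-index bin edges, len n_bins+1
    dx: np.ndarray          # per-bin lateral shift (nm), first bin (0, 0)
    dy: np.ndarray

    def __post_init__(self):
        if self.dx[0] != 0.0 or self.dy[0] != 0.0:
            raise ValueError("first-bin shift must be (0, 0)")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("shifts must be finite")

    def shift_at(self, frame) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame shift by linear interpolation between bin centres."""
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0
        f = np.asarray(frame, dtype=np.float64)
        return (np.interp(f, centers, self.dx),
                np.interp(f, centers, self.dy))


@dataclass
class MergeGroup:
    member_ids: list[int]
    centroid: tuple[float, float]
    total_photons: float
    wavelength: float | None


def render(locs: list[Localization], pixel: float, blur_sigma: float = 0.0,
           extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
           photon_weighted: bool = False) -> np.ndarray:
    """2-D histogram of positions (rows = y) at ``pixel`` nm, optionally
    Gaussian-blurred with ``blur_sigma`` nm.  Total mass equals the
    localization count (or summed photons when ``photon_weighted``)."""
    if pixel <= 0:
        raise ValueError("pixel must be > 0")
    if extent is None:
        if not locs:
            return np.zeros((1, 1))
        xs = np.array([l.x for l in locs])
        ys = np.array([l.y for l in locs])
        extent = ((xs.min(), xs.max() + pixel), (ys.min(), ys.max() + pixel))
    (x0, x1), (y0, y1) = extent
    nx = max(1, int(np.ceil((x1 - x0) / pixel)))
    ny = max(1, int(np.ceil((y1 - y0) / pixel)))
    if not locs:
        return np.zeros((ny, nx))
    xs = np.array([l.x for l in locs])
    ys = np.array([l.y for l in locs])
    w = np.array([l.photons for l in locs]) if photon_weighted else None
    img, _, _ = np.histogram2d(ys, xs, bins=(ny, nx),
                               range=((y0, y0 + ny * pixel),
                                      (x0, x0 + nx * pixel)), weights=w)
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma / pixel)
    return img


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> tuple[float, float]:
    """Sub-pixel shift s such that ``img`` is ``ref`` translated by s
    (rows, cols), via FFT cross-correlation and per-axis parabolic fit."""
    f_ref = np.fft.fft2(ref)
    f_img = np.fft.fft2(img)
    corr = np.fft.ifft2(f_img * np.conj(f_ref)).real
    ny, nx = corr.shape
    py, px = np.unravel_index(np.argmax(corr), corr.shape)

    def refine(c, p, n, axis):
        idx = [( p - 1) % n, p, (p + 1) % n]
        if axis == 0:
            y0, y1, y2 = c[idx[0], px], c[p, px], c[idx[2], px]
        else:
            y0, y1, y2 = c[py, idx[0]], c[py, p], c[py, idx[2]]
        denom = y0 - 2 * y1 + y2
        d = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        return p + float(np.clip(d, -1, 1))

    sy = refine(corr, py, ny, 0)
    sx = refine(corr, px, nx, 1)
    # unwrap to signed shifts
    sy = (sy + ny / 2) % ny - ny / 2
    sx = (sx + nx / 2) % nx - nx / 2
    return sy, sx


def correct_drift(locs: list[Localization], n_bins: int = 10,
                  render_pixel: float = 10.0, upsample: int = 1
                  ) -> tuple[list[Localization], DriftModel]:
    """Estimate and subtract lateral drift.

    Localizations are split into ``n_bins`` temporal bins; each bin is
    rendered at ``render_pixel / upsample`` nm and cross-correlated
    against the first bin; per-frame shifts are linearly interpolated
    between bin centres and subtracted.
    """
    if n_bins < 2:
        raise ValueError("need at least two temporal bins")
    if not locs:
        raise ValueError("no localizations")
    frames = np.array([l.frame for l in locs])
    f0, f1 = frames.min(), frames.max()
    if f1 == f0:
        raise ValueError("need frames spanning at least two bins")
    edges = np.linspace(f0, f1 + 1, n_bins + 1)
    pe = render_pixel / upsample

    xs = np.array([l.x for l in locs])
    ys = np.array([l.y for l in locs])
    pad = 5 * pe
    extent = ((xs.min() - pad, xs.max() + pad), (ys.min() - pad, ys.max() + pad))

    bins = [[] for _ in range(n_bins)]
    bin_of = np.clip(np.digitize(frames, edges) - 1, 0, n_bins - 1)
    for l, b in zip(locs, bin_of):
        bins[b].append(l)

    ref = None
    dxs = np.full(n_bins, np.nan)
    dys = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if not bins[b]:
            warnings.warn(f"drift bin {b} is empty; interpolating across it",
                          stacklevel=2)
            continue
        img = render(bins[b], pe, blur_sigma=pe, extent=extent)
        if ref is None:
            ref = img
            dxs[b] = dys[b] = 0.0
            continue
        sy, sx = _xcorr_shift(ref, img)
        dxs[b], dys[b] = sx * pe, sy * pe
    if ref is None:
        raise ValueError("all drift bins empty")
    # interpolate across empty bins
    idx = np.arange(n_bins)
    ok = np.isfinite(dxs)
    dxs = np.interp(idx, idx[ok], dxs[ok])
    dys = np.interp(idx, idx[ok], dys[ok])
    dxs[0] = dys[0] = 0.0

    model = DriftModel(edges, dxs, dys)
    sx, sy = model.shift_at(frames)
    corrected = [replace(l, x=l.x - float(dx), y=l.y - float(dy))
                 for l, dx, dy in zip(locs, sx, sy)]
    return corrected, model


def spectral_regression(locs: list[Localization], radius: float = 50.0,
                        spectral_tol: float = 10.0, max_gap: int = 5
                        ) -> list[Localization]:
    """Merge repeated emissions of the same molecule.

    Greedy frame-ordered chaining: an event joins the nearest active
    group whose centroid is within ``radius`` nm, whose wavelength is
    within ``spectral_tol`` nm, and whose last event is at most
    ``max_gap`` frames old.  Merged records carry the photon-weighted
    centroid, summed photons, and photon-weighted mean wavelength.
    """
    order = sorted(range(len(locs)), key=lambda i: locs[i].frame)
    cell = max(radius, 1e-9)

    groups: list[dict] = []
    grid: dict[tuple[int, int], list[int]] = {}

    def cell_of(x, y):
        return (int(np.floor(x / cell)), int(np.floor(y / cell)))

    for i in order:
        l = locs[i]
        w = l.photons if l.photons > 0 else 1.0
        cx, cy = cell_of(l.x, l.y)
        best, best_d2 = None, radius ** 2
        for dx in (-1, 0, 1):
            for dyc in (-1, 0, 1):
                for gi in grid.get((cx + dx, cy + dyc), ()):
                    g = groups[gi]
                    if l.frame - g["last_frame"] > max_gap:
                        continue
                    if (l.wavelength is None) != (g["wl"] is None):
                        continue
                    if l.wavelength is not None and \
                            abs(l.wavelength - g["wl"]) > spectral_tol:
                        continue
                    d2 = (l.x - g["x"]) ** 2 + (l.y - g["y"]) ** 2
                    if d2 <= best_d2:
                        best, best_d2 = gi, d2
        if best is None:
            groups.append({"x": l.x, "y": l.y, "w": w, "wl": l.wavelength,
                           "photons": l.photons, "frame": l.frame,
                           "last_frame": l.frame, "n": l.merged_count,
                           "channel": l.channel})
            grid.setdefault(cell_of(l.x, l.y), []).append(len(groups) - 1)
        else:
            g = groups[best]
            old_cell = cell_of(g["x"], g["y"])
            tw = g["w"] + w
            g["x"] = (g["x"] * g["w"] + l.x * w) / tw
            g["y"] = (g["y"] * g["w"] + l.y * w) / tw
            if g["wl"] is not None:
                g["wl"] = (g["wl"] * g["w"] + l.wavelength * w) / tw
            g["w"] = tw
            g["photons"] += l.photons
            g["last_frame"] = l.frame
            g["n"] += l.merged_count
            new_cell = cell_of(g["x"], g["y"])
            if new_cell != old_cell:
                grid[old_cell].remove(best)
                grid.setdefault(new_cell, []).append(best)

    return [Localization(frame=g["frame"], x=g["x"], y=g["y"],
                         wavelength=g["wl"], photons=g["photons"],
                         merged_count=g["n"], channel=g["channel"])
            for g in groups]
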