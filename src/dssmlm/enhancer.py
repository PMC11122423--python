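"""Spectral-PSF enhancement: ROI cropping and the skip-connection DCNN.

The restorer is a stack of 3x3 convolutions (ReLU on all but the last,
single-filter, layer) with an additive input-to-output skip connection,
trained with plain MSE against noise-free crops.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .calibration import SpectralCalibration, wavelength_to_pixel
from .localizer import TrainingDiverged


class RoiOutOfBounds(ValueError):
    """Signal that a spectral ROI crop falls (partly) outside the image."""


@dataclass(frozen=True)
class ModeParams:
    roi_shape: tuple[int, int]   # (rows, cols)
    lambda_window_start: float   # nm at the left ROI edge


MODES: dict[str, ModeParams] = {
    "label-free": ModeParams((9, 95), 500.0),
    "labeled": ModeParams((5, 50), 620.0),
}


@dataclass(frozen=True)
class EnhancerSpec:
    n_layers: int = 7
    filters: int = 64
    kernel: int = 3

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("need at least an input and an output layer")
        if self.kernel != 3:
            raise ValueError("kernel is fixed at 3")


@dataclass
class SpectralROI:
    pixels: np.ndarray
    anchor: tuple[float, float]        # owning localization (x, y) in nm
    roi_origin: tuple[int, int]        # (row, col) of top-left in spectral image
    mode: str

    def __post_init__(self):
        expected = MODES[self.mode].roi_shape
        if tuple(self.pixels.shape) != expected:
            raise ValueError(f"ROI shape {self.pixels.shape} != {expected} "
                             f"for mode {self.mode!r}")


def crop_spectral_roi(frame, loc: tuple[float, float], cal: SpectralCalibration,
                      mode: str, camera_pixel_size: float = 100.0,
                      lambda_window_start: float | None = None) -> SpectralROI:
    """Crop the spectral-PSF ROI owned by a localization.

    Vertically centred on the localization row; horizontally starting at
    the column the calibration maps to the mode's spectral-window start.
    Raises :class:`RoiOutOfBounds` if the crop does not fit.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    params = MODES[mode]
    lam0 = params.lambda_window_start if lambda_window_start is None \
        else lambda_window_start
    h, w = params.roi_shape
    x_nm, y_nm = loc
    cx = x_nm / camera_pixel_size
    cy = y_nm / camera_pixel_size
    sh, sw = frame.spatial_image.shape
    if not (0 <= cx <= sw - 1 and 0 <= cy <= sh - 1):
        raise RoiOutOfBounds("localization outside spatial image")
    row0 = int(round(cy)) - (h - 1) // 2
    col0 = int(round(wavelength_to_pixel(cal, cx, lam0)))
    gh, gw = frame.spectral_image.shape
    if row0 < 0 or row0 + h > gh or col0 < 0 or col0 + w > gw:
        raise RoiOutOfBounds(
            f"ROI origin ({row0}, {col0}) with shape ({h}, {w}) outside "
            f"spectral image ({gh}, {gw})")
    crop = frame.spectral_image[row0:row0 + h, col0:col0 + w].copy()
    return SpectralROI(crop, (x_nm, y_nm), (row0, col0), mode)


def loss_enh(pred_roi, clean_roi) -> float:
    """Mean squared error over pixels, averaged over the batch."""
    p = np.asarray(pred_roi, dtype=np.float64)
    t = np.asarray(clean_roi, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("prediction and target must share shape")
    return float(np.mean((p - t) ** 2))


class DCNN:
    """n_layers 3x3 convolutions with additive input->output skip."""

    def __init__(self, spec: EnhancerSpec, rng: np.random.Generator):
        self.spec = spec
        layers: list[nn.Layer] = [nn.Conv2D(1, spec.filters, 3, rng), nn.ReLU()]
        for _ in range(spec.n_layers - 2):
            layers += [nn.Conv2D(spec.filters, spec.filters, 3, rng), nn.ReLU()]
        layers.append(nn.Conv2D(spec.filters, 1, 3, rng))
        self.body = nn.Sequential(layers)

    def params(self):
        return self.body.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.body.forward(x) + x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(dy) + dy


class EnhancerModel:
    def __init__(self, net: DCNN, spec: EnhancerSpec, mode: str):
        self.net = net
        self.spec = spec
        self.mode = mode
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    def enhance_batch(self, rois: np.ndarray) -> np.ndarray:
        """(N, H, W) noisy crops -> restored crops, negatives clamped to 0."""
        x = np.asarray(rois, dtype=nn.DTYPE)
        scale = x.reshape(x.shape[0], -1).max(axis=1)
        scale = np.maximum(scale, 1e-6)[:, None, None]
        y = self.net.forward((x / scale)[..., None])[..., 0]
        return np.maximum(y * scale, 0.0).astype(np.float64)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i:04d}": p.value for i, p in enumerate(self.net.params())})
        meta = {"spec": asdict(self.spec), "mode": self.mode}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "EnhancerModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = EnhancerSpec(**meta["spec"])
        net = DCNN(spec, np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as data:
            state = [data[k] for k in sorted(data.files)]
        for p, s in zip(net.params(), state):
            p.value[...] = s
        return cls(net, spec, meta["mode"])


def enhance_roi(model: EnhancerModel, roi: SpectralROI) -> SpectralROI:
    if tuple(roi.pixels.shape) != MODES[model.mode].roi_shape:
        raise ValueError("ROI shape does not match the trained model")
    restored = model.enhance_batch(roi.pixels[None])[0]
    return SpectralROI(restored, roi.anchor, roi.roi_origin, roi.mode)


def train_enhancer(pairs, spec: EnhancerSpec, epochs: int, seed: int = 0,
                   mode: str = "labeled", val_fraction: float = 0.1,
                   lr: float = 1e-3, batch_size: int = 64,
                   verbose: bool = False) -> EnhancerModel:
    """Adam/MSE training with a 90:10 train/validation split; the
    best-validation parameters are retained."""
    if not pairs:
        raise ValueError("at least one training pair is required")
    rng = np.random.default_rng(seed)
    net = DCNN(spec, rng)
    model = EnhancerModel(net, spec, mode)
    if epochs == 0:
        return model

    noisy = np.stack([p.noisy_roi for p in pairs]).astype(nn.DTYPE)
    clean = np.stack([p.clean_roi for p in pairs]).astype(nn.DTYPE)
    scale = np.maximum(noisy.reshape(len(pairs), -1).max(axis=1), 1e-6)
    noisy /= scale[:, None, None]
    clean /= scale[:, None, None]
    noisy = noisy[..., None]
    clean = clean[..., None]

    order = rng.permutation(len(pairs))
    n_val = int(round(len(pairs) * val_fraction))
    va, tr = order[:n_val], order[n_val:]
    if tr.size == 0:
        tr, va = order, order[:0]

    opt = nn.Adam(net.params(), lr=lr)
    best_val = np.inf
    best_state = nn.get_state(net)
    for epoch in range(epochs):
        rng.shuffle(tr)
        losses = []
        for s in range(0, tr.size, batch_size):
            idx = tr[s:s + batch_size]
            xb, tb = noisy[idx], clean[idx]
            pred = net.forward(xb)
            diff = pred - tb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            net.backward((2.0 / (diff.size)) * diff.astype(nn.DTYPE))
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if va.size:
            vl = []
            for s in range(0, va.size, batch_size):
                idx = va[s:s + batch_size]
                vl.append(loss_enh(net.forward(noisy[idx]), clean[idx]))
            val_loss = float(np.mean(vl))
        else:
            val_loss = train_loss
        model.history["train_loss"].append(train_loss)
        model.history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: train {train_loss:.6f} "
                  f"val {val_loss:.6f}")
        if val_loss <= best_val:
            best_val = val_loss
            best_state = nn.get_state(net)
    nn.set_state(net, best_state)
    return model
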