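"""U-Net emitter localizer operating on an upsampled prediction grid.

The encoder applies two 3x3 convolutions (ELU) then a 2x2 max-pool per
level; the decoder mirrors it with 2x2 transposed convolutions and skip
concatenations; a final 1x1 linear layer emits the pixelwise prediction.
The input frame is resampled onto the high-resolution grid before the
network (optionally part of the upsampling can be deferred to learned
transposed-convolution stages after the decoder, which is much cheaper
on CPU at the same total grid factor).

Training minimizes  ||pred (*) g - target (*) g||^2 + ||pred||_1  over
batches, where g is a small Gaussian kernel and the target is a spike
image with one spike per true emitter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import maximum_filter

from . import nn
from .sim import TrainingPairSpatial


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class LocalizerSpec:
    depth: int = 3
    base_filters: int = 16
    conv_kernel: int = 3
    pool_kernel: int = 2
    upsampling: int = 4
    loss_kernel_sigma: float = 1.0  # upsampled px
    head_stages: int = 0            # learned x2 upsampling stages after the decoder
    head_filters: int | None = None  # channels in head stages (None: keep width)
    l1_weight: float = 1.0
    spike_amplitude: float = 100.0  # target-grid scale during optimization

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.upsampling < 1:
            raise ValueError("upsampling must be >= 1")
        if self.conv_kernel != 3 or self.pool_kernel != 2:
            raise ValueError("conv_kernel is fixed at 3 and pool_kernel at 2")
        if self.upsampling % (2 ** self.head_stages) != 0:
            raise ValueError("2**head_stages must divide upsampling")

    @property
    def pre_upsample(self) -> int:
        return self.upsampling // (2 ** self.head_stages)


@dataclass
class PredictionGrid:
    values: np.ndarray
    source_frame: int
    upsampling: int

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("prediction grid must be non-negative")


class UNet:
    def __init__(self, spec: LocalizerSpec, rng: np.random.Generator):
        self.spec = spec
        f, d = spec.base_filters, spec.depth
        filters = [f * 2 ** i for i in range(d)]
        self.enc, self.pools = [], []
        cin = 1
        for fo in filters:
            self.enc.append(nn.Sequential([
                nn.Conv2D(cin, fo, 3, rng), nn.ELU(),
                nn.Conv2D(fo, fo, 3, rng), nn.ELU()]))
            self.pools.append(nn.MaxPool2x2())
            cin = fo
        fb = f * 2 ** d
        self.bottleneck = nn.Sequential([
            nn.Conv2D(cin, fb, 3, rng), nn.ELU(),
            nn.Conv2D(fb, fb, 3, rng), nn.ELU()])
        self.ups, self.dec = [], []
        cin = fb
        for fo in reversed(filters):
            self.ups.append(nn.TransposedConv2x2(cin, fo, rng))
            self.dec.append(nn.Sequential([
                nn.Conv2D(2 * fo, fo, 3, rng), nn.ELU(),
                nn.Conv2D(fo, fo, 3, rng), nn.ELU()]))
            cin = fo
        head: list[nn.Layer] = []
        for _ in range(spec.head_stages):
            cout = spec.head_filters or cin
            head += [nn.TransposedConv2x2(cin, cout, rng), nn.ELU()]
            cin = cout
        head.append(nn.Conv2D(cin, 1, 1, rng))
        self.head = nn.Sequential(head)
        self._skip_channels = [b.layers[-2].cout for b in self.enc]

    def modules(self):
        return [*self.enc, *self.pools, self.bottleneck, *self.ups, *self.dec,
                self.head]

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=3)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        dskips = []
        for up, block, c in zip(reversed(self.ups), reversed(self.dec),
                                self._skip_channels):
            dy = block.backward(dy)
            dskips.append(dy[..., :c])
            dy = up.backward(np.ascontiguousarray(dy[..., c:]))
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(self.spec.depth)):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)
        return dy


def loss_loc(pred_grid, target_grid, g_sigma: float,
             l1_weight: float = 1.0, return_grad: bool = False):
    """Combined localization loss (batch mean):

        sum((pred (*) g - target (*) g)^2)  +  l1_weight * sum(|pred|)
    """
    p = np.asarray(pred_grid, dtype=nn.DTYPE)
    t = np.asarray(target_grid, dtype=nn.DTYPE)
    if p.shape != t.shape:
        raise ValueError("prediction and target grids must share shape")
    squeeze = p.ndim == 2
    if squeeze:
        p, t = p[None, ..., None], t[None, ..., None]
    n = p.shape[0]
    blur = nn.FixedConv(nn.gaussian_kernel2d(g_sigma))
    delta = blur(p - t)
    loss = float((delta ** 2).sum() / n + l1_weight * np.abs(p).sum() / n)
    if not return_grad:
        return loss
    grad = (2.0 * blur(delta) + l1_weight * np.sign(p)) / n
    return loss, grad.astype(nn.DTYPE)


def _nearest_upsample(x: np.ndarray, f: int) -> np.ndarray:
    """Repeat along the spatial axes of an (N, H, W, C) batch."""
    if f == 1:
        return x
    return np.repeat(np.repeat(x, f, axis=1), f, axis=2)


def _normalize(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(nn.DTYPE)
    sd = p.std()
    return (p - p.mean()) / (sd + nn.DTYPE(1e-6))


class LocalizerModel:
    """Trained (or freshly initialized) localizer with its preprocessing."""

    def __init__(self, net: UNet, spec: LocalizerSpec):
        self.net = net
        self.spec = spec
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    def predict_grid(self, frame: np.ndarray, frame_index: int = 1) -> PredictionGrid:
        spec = self.spec
        h, w = frame.shape
        div = 2 ** spec.depth
        ph = (-h) % div
        pw = (-w) % div
        x = _normalize(np.asarray(frame))
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
        x = _nearest_upsample(x[None, :, :, None], spec.pre_upsample)
        y = self.net.forward(x)[0, :, :, 0]
        u = spec.upsampling
        y = y[:h * u, :w * u]
        return PredictionGrid(np.maximum(y, 0.0), frame_index, u)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i:04d}": p.value for i, p in enumerate(self.net.params())})
        path.with_suffix(".json").write_text(json.dumps(asdict(self.spec)))

    @classmethod
    def load(cls, path: str | Path) -> "LocalizerModel":
        path = Path(path)
        spec = LocalizerSpec(**json.loads(path.with_suffix(".json").read_text()))
        net = UNet(spec, np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as data:
            state = [data[k] for k in sorted(data.files)]
        for p, s in zip(net.params(), state):
            p.value[...] = s
        return cls(net, spec)


def train_localizer(pairs: list[TrainingPairSpatial], spec: LocalizerSpec,
                    epochs: int, val_fraction: float = 0.1, seed: int = 0,
                    lr: float = 1e-3, batch_size: int = 16,
                    verbose: bool = False) -> LocalizerModel:
    """Adam training of the U-Net on spatial patch/spike-grid pairs.

    Keeps the parameters of the best validation epoch.  ``epochs=0``
    returns the randomly initialized model.
    """
    if not pairs:
        raise ValueError("at least one training pair is required")
    rng = np.random.default_rng(seed)
    net = UNet(spec, rng)
    model = LocalizerModel(net, spec)
    if epochs == 0:
        return model

    n_val = int(round(len(pairs) * val_fraction))
    order = rng.permutation(len(pairs))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order[:0]

    xs = np.stack([_normalize(pairs[i].input_patch) for i in order])[..., None]
    xs = _nearest_upsample(xs, spec.pre_upsample)
    ts = np.stack([pairs[i].target_grid
                   for i in order]).astype(nn.DTYPE)[..., None]
    ts *= nn.DTYPE(spec.spike_amplitude)
    pos = {int(i): k for k, i in enumerate(order)}
    tr = np.array([pos[int(i)] for i in train_idx])
    va = np.array([pos[int(i)] for i in val_idx])

    opt = nn.Adam(net.params(), lr=lr)
    blur_sigma = spec.loss_kernel_sigma
    best_val = np.inf
    best_state = nn.get_state(net)
    for epoch in range(epochs):
        rng.shuffle(tr)
        losses = []
        for s in range(0, tr.size, batch_size):
            idx = tr[s:s + batch_size]
            xb, tb = xs[idx], ts[idx]
            pred = net.forward(xb)
            loss, grad = loss_loc(pred, tb, blur_sigma,
                                  l1_weight=spec.l1_weight, return_grad=True)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if va.size:
            vlosses = [loss_loc(net.forward(xs[va[s:s + batch_size]]),
                                ts[va[s:s + batch_size]], blur_sigma,
                                l1_weight=spec.l1_weight)
                       for s in range(0, va.size, batch_size)]
            val_loss = float(np.mean(vlosses))
        else:
            val_loss = train_loss
        model.history["train_loss"].append(train_loss)
        model.history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: train {train_loss:.4f} "
                  f"val {val_loss:.4f}")
        if val_loss <= best_val:
            best_val = val_loss
            best_state = nn.get_state(net)
    nn.set_state(net, best_state)
    return model


def local_maxima(grid: np.ndarray, threshold: float,
                 min_separation: float) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) indices and values of thresholded 8-connected local maxima,
    with maxima closer than ``min_separation`` merged to the brighter one."""
    g = np.asarray(grid)
    if g.max() <= 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    mask = (g == maximum_filter(g, size=3)) & (g >= threshold) & (g > 0)
    rc = np.argwhere(mask)
    vals = g[mask]
    order = np.argsort(vals)[::-1]
    rc, vals = rc[order], vals[order]
    kept: list[int] = []
    for i in range(len(rc)):
        ok = True
        for j in kept:
            d2 = float(((rc[i] - rc[j]) ** 2).sum())
            if d2 < min_separation ** 2:
                ok = False
                break
        if ok:
            kept.append(i)
    return rc[kept], vals[kept]


def predict_localizations(model: LocalizerModel, frame: np.ndarray,
                          threshold: float = 0.1,
                          min_separation: float | None = None,
                          camera_pixel_size: float = 100.0,
                          frame_index: int = 1,
                          return_values: bool = False):
    """Extract emitter coordinates (nm) from the prediction grid.

    ``threshold`` is a fraction of the per-frame grid maximum.
    """
    grid = model.predict_grid(frame, frame_index)
    u = grid.upsampling
    if min_separation is None:
        min_separation = float(u)
    g = grid.values
    if g.max() <= 0:
        coords = np.empty((0, 2))
        return (coords, np.empty(0)) if return_values else coords
    rc, vals = local_maxima(g, threshold * g.max(), min_separation)
    coords = np.column_stack([rc[:, 1], rc[:, 0]]).astype(np.float64)
    coords = coords / u * camera_pixel_size  # (x, y) in nm
    return (coords, vals) if return_values else coords
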