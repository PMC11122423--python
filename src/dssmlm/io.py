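"""Readers/writers: TIFF stacks, localization tables, YAML configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile
import yaml

from .sim import EmitterTruth, FramePair, OpticsConfig
from .spectral import ChannelSpec, Localization

FLOAT_FMT = "%.6f"


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- stacks

def write_stack(frames: list[FramePair], path: str | Path,
                layout: str = "side-by-side") -> None:
    """Write a stack as multi-page TIFF.

    ``side-by-side``: one file, each page is ``spatial | spectral``.
    ``two-files``: ``<stem>_spatial.tif`` and ``<stem>_spectral.tif``.
    """
    path = Path(path)
    if layout == "side-by-side":
        pages = [np.hstack([f.spatial_image, f.spectral_image]).astype(np.float32)
                 for f in frames]
        tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    elif layout == "two-files":
        tifffile.imwrite(path.with_name(path.stem + "_spatial.tif"),
                         np.stack([f.spatial_image.astype(np.float32)
                                   for f in frames]),
                         photometric="minisblack")
        tifffile.imwrite(path.with_name(path.stem + "_spectral.tif"),
                         np.stack([f.spectral_image.astype(np.float32)
                                   for f in frames]),
                         photometric="minisblack")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def iter_stack(path: str | Path, layout: str = "side-by-side",
               split_column: int | None = None) -> Iterator[FramePair]:
    """Stream FramePairs from disk one page at a time."""
    path = Path(path)
    if layout == "side-by-side":
        if split_column is None:
            raise ValueError("split_column is required for side-by-side layout")
        with tifffile.TiffFile(path) as tif:
            shape = None
            for i, page in enumerate(tif.pages):
                img = page.asarray().astype(np.float64)
                if shape is None:
                    shape = img.shape
                    if not 0 < split_column < shape[1]:
                        raise FormatError("split_column outside page width")
                elif img.shape != shape:
                    raise FormatError(f"page {i} has inconsistent size")
                yield FramePair(img[:, :split_column], img[:, split_column:],
                                i + 1)
    elif layout == "two-files":
        p_spatial = path.with_name(path.stem + "_spatial.tif")
        p_spectral = path.with_name(path.stem + "_spectral.tif")
        with tifffile.TiffFile(p_spatial) as t1, \
                tifffile.TiffFile(p_spectral) as t2:
            if len(t1.pages) != len(t2.pages):
                raise FormatError("spatial/spectral frame counts differ")
            for i, (a, b) in enumerate(zip(t1.pages, t2.pages)):
                yield FramePair(a.asarray().astype(np.float64),
                                b.asarray().astype(np.float64), i + 1)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_stack(path: str | Path, layout: str = "side-by-side",
               split_column: int | None = None) -> list[FramePair]:
    return list(iter_stack(path, layout, split_column))


# ---------------------------------------------------- localization tables

NATIVE_COLUMNS = ["frame", "x_nm", "y_nm", "wavelength_nm", "photons",
                  "merged_count", "channel"]
THUNDERSTORM_COLUMNS = ["frame", "x [nm]", "y [nm]", "intensity [photon]"]


def write_localizations(locs: list[Localization], path: str | Path,
                        dialect: str = "native") -> None:
    path = Path(path)
    if dialect == "native":
        df = pd.DataFrame({
            "frame": [l.frame for l in locs],
            "x_nm": [l.x for l in locs],
            "y_nm": [l.y for l in locs],
            "wavelength_nm": [np.nan if l.wavelength is None else l.wavelength
                              for l in locs],
            "photons": [l.photons for l in locs],
            "merged_count": [l.merged_count for l in locs],
            "channel": [l.channel or "" for l in locs],
        })
    elif dialect == "thunderstorm":
        df = pd.DataFrame({
            "frame": [l.frame for l in locs],
            "x [nm]": [l.x for l in locs],
            "y [nm]": [l.y for l in locs],
            "intensity [photon]": [l.photons for l in locs],
        })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_localizations(path: str | Path) -> list[Localization]:
    df = pd.read_csv(path)
    if "x [nm]" in df.columns:  # thunderstorm dialect
        return [Localization(frame=int(r["frame"]), x=float(r["x [nm]"]),
                             y=float(r["y [nm]"]),
                             photons=float(r["intensity [photon]"]))
                for _, r in df.iterrows()]
    out = []
    for _, r in df.iterrows():
        wl = r.get("wavelength_nm", np.nan)
        ch = r.get("channel", "")
        out.append(Localization(
            frame=int(r["frame"]), x=float(r["x_nm"]), y=float(r["y_nm"]),
            wavelength=None if pd.isna(wl) else float(wl),
            photons=float(r.get("photons", 0.0)),
            merged_count=int(r.get("merged_count", 1)),
            channel=None if (pd.isna(ch) or ch == "") else str(ch)))
    return out


def write_truths(truths: list[EmitterTruth], path: str | Path) -> None:
    """Ground truth CSV, ThunderSTORM-compatible frame,x,y column order."""
    df = pd.DataFrame({
        "frame": [t.frame_index for t in truths],
        "x_nm": [t.x for t in truths],
        "y_nm": [t.y for t in truths],
        "photons": [t.photons for t in truths],
        "dye": [t.dye.name for t in truths],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_truth_positions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    calibration_path: str | None = None
    mode: str = "labeled"
    channels: list[ChannelSpec] = field(default_factory=list)
    filter_window: tuple[float, float] | None = (640.0, 700.0)
    drift: dict = field(default_factory=lambda: {"n_bins": 10,
                                                 "render_pixel": 10.0,
                                                 "upsample": 1})
    regression: dict = field(default_factory=lambda: {"radius_nm": 50.0,
                                                      "spectral_tol_nm": 10.0,
                                                      "max_gap": 5})
    render: dict = field(default_factory=lambda: {"pixel_nm": 10.0,
                                                  "blur_sigma_nm": 10.0})
    threshold: float = 0.1
    split_column: int | None = None
    seed: int = 0


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["optics"]["fov"] = list(cfg.optics.fov)
    d["channels"] = [{"name": c.name, "window": list(c.window)}
                     for c in cfg.channels]
    if cfg.filter_window is not None:
        d["filter_window"] = list(cfg.filter_window)
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    opt = dict(d.get("optics", {}))
    if "fov" in opt:
        opt["fov"] = tuple(opt["fov"])
    d["optics"] = OpticsConfig(**opt)
    d["channels"] = [ChannelSpec(c["name"], tuple(c["window"]))
                     for c in d.get("channels", [])]
    if d.get("filter_window") is not None:
        d["filter_window"] = tuple(d["filter_window"])
    return PipelineConfig(**d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
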