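"""End-to-end reconstruction: localize -> crop -> enhance -> spectra ->
filter -> drift-correct -> merge -> assign channels -> render."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import tifffile

from . import io as dio
from .calibration import load_calibration
from .enhancer import EnhancerModel, RoiOutOfBounds, crop_spectral_roi
from .localizer import LocalizerModel, predict_localizations
from .postprocess import correct_drift, render, spectral_regression
from .spectral import (Localization, NoPeak, assign_channels, extract_spectrum,
                       filter_by_window, find_peak)

log = logging.getLogger("dssmlm")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: dio.PipelineConfig, stack_path: str | Path,
                 loc_model_path: str | Path, enh_model_path: str | Path | None,
                 out_dir: str | Path, layout: str = "side-by-side") -> dict:
    """Run the full post-processing chain and write the output bundle.

    Returns the run report (also written to ``report.json``): per-stage
    record counts and wall times.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    t_all = time.time()

    def stage(name, n_in, fn):
        t0 = time.time()
        try:
            result, n_out = fn()
        except Exception as e:  # noqa: BLE001
            report["stages"].append({"stage": name, "n_in": n_in,
                                     "error": str(e)})
            (out / "report.json").write_text(json.dumps(report, indent=2))
            raise PipelineStageError(name, e) from e
        dt = time.time() - t0
        report["stages"].append({"stage": name, "n_in": n_in, "n_out": n_out,
                                 "seconds": round(dt, 3)})
        log.info("stage %-18s n_in=%-8s n_out=%-8s %.2fs", name, n_in, n_out, dt)
        return result

    optics = cfg.optics
    px = optics.camera_pixel_size
    cal = load_calibration(cfg.calibration_path) if cfg.calibration_path else None
    loc_model = LocalizerModel.load(loc_model_path)
    enh_model = EnhancerModel.load(enh_model_path) if enh_model_path else None
    split = cfg.split_column or optics.frame_shape[1]

    def do_read():
        fr = dio.read_stack(stack_path, layout=layout, split_column=split)
        return fr, len(fr)

    frames = stage("read_stack", str(stack_path), do_read)

    def do_localize():
        locs = []
        for f in frames:
            coords, vals = predict_localizations(
                loc_model, f.spatial_image, threshold=cfg.threshold,
                camera_pixel_size=px, frame_index=f.frame_index,
                return_values=True)
            for (x, y), v in zip(coords, vals):
                locs.append(Localization(frame=f.frame_index, x=float(x),
                                         y=float(y), photons=float(v)))
        return locs, len(locs)

    locs = stage("localize", len(frames), do_localize)

    if enh_model is not None and cal is not None:
        def do_spectra():
            out_locs = []
            rois, owners = [], []
            for l in locs:
                try:
                    roi = crop_spectral_roi(frames[l.frame - 1], (l.x, l.y),
                                            cal, cfg.mode,
                                            camera_pixel_size=px)
                except RoiOutOfBounds:
                    continue
                rois.append(roi)
                owners.append(l)
            if rois:
                enhanced = enh_model.enhance_batch(
                    np.stack([r.pixels for r in rois]))
            for roi, l, pix in zip(rois, owners,
                                   enhanced if rois else []):
                roi.pixels = pix
                spec = extract_spectrum(roi, cal, camera_pixel_size=px)
                try:
                    wl = find_peak(spec)
                except NoPeak:
                    continue
                out_locs.append(Localization(frame=l.frame, x=l.x, y=l.y,
                                             wavelength=wl, photons=l.photons))
            return out_locs, len(out_locs)

        locs = stage("spectra", len(locs), do_spectra)

        if cfg.filter_window is not None:
            def do_filter():
                kept = filter_by_window(locs, cfg.filter_window)
                return kept, len(kept)

            locs = stage("spectral_filter", len(locs), do_filter)

    if cfg.drift.get("n_bins", 0) >= 2 and len(locs) > 10:
        def do_drift():
            corrected, model = correct_drift(
                locs, n_bins=cfg.drift["n_bins"],
                render_pixel=cfg.drift.get("render_pixel", 10.0),
                upsample=cfg.drift.get("upsample", 1))
            centers = (model.bin_edges[:-1] + model.bin_edges[1:]) / 2
            with open(out / "drift.csv", "w") as fh:
                fh.write("frame,dx_nm,dy_nm\n")
                for c, dx, dy in zip(centers, model.dx, model.dy):
                    fh.write(f"{c:.1f},{dx:.6f},{dy:.6f}\n")
            return corrected, len(corrected)

        locs = stage("drift_correction", len(locs), do_drift)

    if cfg.regression.get("radius_nm", 0) > 0:
        locs = stage("spectral_regression", len(locs), lambda: (
            lambda merged: (merged, len(merged)))(spectral_regression(
                locs, radius=cfg.regression["radius_nm"],
                spectral_tol=cfg.regression.get("spectral_tol_nm", 10.0),
                max_gap=cfg.regression.get("max_gap", 5))))

    channel_map = None
    if cfg.channels:
        channel_map = stage("assign_channels", len(locs), lambda: (
            lambda m: (m, sum(len(v) for k, v in m.items()
                              if k != "unassigned")))(
            assign_channels(locs, cfg.channels)))
        locs = [l for name, ls in channel_map.items()
                if name != "unassigned" for l in ls]

    dio.write_localizations(locs, out / "localizations.csv")

    def do_render():
        pxr = cfg.render["pixel_nm"]
        blur = cfg.render.get("blur_sigma_nm", 0.0)
        if locs:
            xs = np.array([l.x for l in locs])
            ys = np.array([l.y for l in locs])
            extent = ((xs.min(), xs.max() + pxr), (ys.min(), ys.max() + pxr))
        else:
            extent = ((0, pxr), (0, pxr))
        if channel_map:
            imgs = []
            for c in cfg.channels:
                img = render(channel_map[c.name], pxr, blur, extent=extent)
                tifffile.imwrite(out / f"render_{c.name}.tif",
                                 img.astype(np.float32))
                imgs.append(img)
            composite = np.sum(imgs, axis=0)
        else:
            composite = render(locs, pxr, blur, extent=extent)
        tifffile.imwrite(out / "render.tif", composite.astype(np.float32))
        return composite, len(locs)

    stage("render", len(locs), do_render)

    report["total_seconds"] = round(time.time() - t_all, 3)
    report["n_final"] = len(locs)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
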