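# dssmlm

Two-network reconstruction pipeline for spectroscopic single-molecule
localization microscopy (sSMLM).

An sSMLM frame holds two images of the same blinking emitters: a spatial
(zeroth-order) image and a spectrally dispersed (first-order) image.
This package simulates such data, trains two small convolutional
networks on the simulation — a U-Net that localizes emitters on an
upsampled grid, and a skip-connection DCNN that restores low-photon
spectral PSF crops — and runs the full post-processing chain: spectral
calibration, ROI cropping, spectrum/peak extraction, spectral-window
filtering, cross-correlation drift correction, spectral-regression
merging of repeated emissions, multicolor channel assignment, and
super-resolution rendering, plus a quantitative evaluation suite
(Jaccard index, lateral RMSE, SSIM, Gaussian-fit FWHM, FRC resolution).

The networks are implemented in pure NumPy (float32, manual backprop,
Adam) so that training and inference run anywhere NumPy runs — no deep
learning framework is required.

## Layout

| module                | contents |
|-----------------------|----------|
| `dssmlm.sim`          | optics/dye/emitter types, frame simulator, training-set builders |
| `dssmlm.calibration`  | linear pixel↔wavelength calibration (laser-line fitting) |
| `dssmlm.nn`           | NumPy CNN layers (conv, pool, transposed conv, ELU/ReLU, Adam) |
| `dssmlm.localizer`    | U-Net localizer, combined MSE+L1 spike loss, maxima extraction |
| `dssmlm.enhancer`     | spectral ROI crop rule, 7-layer skip DCNN, MSE training |
| `dssmlm.spectral`     | 1-D spectra, peak finding, window filtering, channel assignment |
| `dssmlm.postprocess`  | drift correction, spectral regression, rendering |
| `dssmlm.metrics`      | matching, JI, lateral RMSE, SSIM, FWHM fit, FRC |
| `dssmlm.io` / `cli`   | TIFF stacks, localization tables (native + ThunderSTORM), YAML config, CLI |
| `dssmlm.pipeline`     | end-to-end `run_pipeline` with a per-stage run report |

## CLI

```sh
# simulate a stack (side-by-side TIFF + ground-truth CSV + calibration)
dssmlm simulate --frames 1000 --density 0.1 --dyes AF647 --seed 1 --clean --out data/

# fit the spectral calibration from a laser-line reference image
dssmlm calibrate --ref ref.tif --lines 405,488,532,552,637 --split-column 64 --out cal.json

# train the two networks on simulated data
dssmlm train-loc  --data data/ --epochs 200 --n-pairs 15000 --out loc_model
dssmlm train-spec --data data/ --epochs 30 --mode labeled --out enh_model

# localize a stack / run the full reconstruction chain
dssmlm localize --model loc_model --stack data/stack.tif --split-column 64 --out locs.csv
dssmlm reconstruct --stack data/stack.tif --model-loc loc_model \
    --model-spec enh_model --config pipeline.yaml --out outdir/

# evaluation
dssmlm evaluate --pred locs.csv --truth data/truth.csv --radius 100
dssmlm frc --locs locs.csv --pixel 10
```

`pipeline.yaml` mirrors `dssmlm.io.PipelineConfig` (an `optics:` block
with the `OpticsConfig` field names, spectral `filter_window`,
`channels:` windows for multicolor assignment, drift/regression/render
parameters and the `split_column` separating the two images).

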