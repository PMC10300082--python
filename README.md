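# sted-restore

Gentle STED microscopy through learned denoising. STED (stimulated
emission depletion) microscopy resolves subcellular structure below the
diffraction limit, but the depletion beam bleaches fluorophores and
photodamages live samples. Cutting the pixel dwell time Δt by one or two
orders of magnitude spares the sample, at the price of severe Poisson shot
noise: the expected photon count per pixel scales linearly with Δt. This
package restores such low-dwell STED images with a **two-step UNet-RCAN
network** — a residual U-Net recovers broad context from the noisy frame,
and a residual channel attention network (RCAN), fed the U-Net output
concatenated with the raw input, reconstructs the fine, super-resolved
detail — and ships every computation around it:

- **`sim`** — a synthetic STED image generator (filamentous, punctate and
  hollow-tubular targets) with a Gaussian effective PSF obeying the STED
  scaling law `d = d_conf / sqrt(1 + P/P_sat)` and Poisson photon counting
  `E[counts] = Δt · (brightness · intensity + background)`, so the whole
  pipeline is testable without any microscope data.
- **`noise`** — semi-synthetic training data: scale a high-SNR image by a
  coefficient λ, Poisson-sample each pixel, and fit λ by minimizing the MSE
  between max-normalized count histograms (first bin discarded), averaged
  over 5 repeats.
- **`register`** — rigid xy-drift correction via the maximum of the
  Fourier-domain cross-correlation of each noisy/ground-truth pair.
- **`dataset`** — patch extraction, per-patch max normalization, and an
  L2-norm content filter (patches whose dataset-normalized norm falls below
  a threshold of 0.2–0.4 are discarded).
- **`model` / `train`** — the UNet-RCAN itself (2D and 3D), trained with a
  Charbonnier + edge loss

  L_char(y, ŷ) = mean √((y−ŷ)² + ε²),  L_edge(y, ŷ) = mean √((Δy−Δŷ)² + ε²),
  L = L_char + α·L_edge,  with ε = 10⁻³, α = 0.05,

  using Adam (initial learning rate 10⁻⁴, cosine annealing, batch size 1).
  The networks run on a compact numpy reverse-mode autodiff core bundled
  with the package (`sted_restore._engine`).
- **`evaluation`** — PSNR, NMSE, multi-scale SSIM, Gaussian line-profile
  FWHM fits, image-decorrelation resolution estimation (Radius 0–1,
  Nr = 50, Ng = 10), and photobleaching curves from max-normalized
  per-frame L2 norms.
- **`io` / `pipeline` / `cli`** — TIFF + JSON-sidecar I/O and an
  end-to-end `sted-restore` command-line tool.

## Worked example

```python
import sted_restore as sr

# a synthetic microtubule-like specimen imaged at 60 nm effective FWHM
phantom = sr.make_phantom("filaments", (128, 128), pixel_size=20.0, seed=11)
optics  = sr.OpticsModel(confocal_fwhm=240, sted_power_fraction=15,
                         saturation_power_fraction=1)
print(sr.effective_fwhm(optics))           # 60.0 (nm)

# a fast (0.072 µs) / conventional (2.3 µs) dwell-time pair
pair = sr.simulate_pair(phantom, optics, seed=5)
print(pair.gt.mean() / pair.noisy.mean())  # 32.02 — the >32x exposure contrast

# train a small restoration model on normalized patches
pn, pg, off = sr.extract_patches(pair.noisy, pair.gt, (64, 64),
                                 max_patches=32, seed=0)
patches = sr.filter_patches(pn, pg, threshold=0.3, offsets=off)
config  = sr.NetworkConfig(dims=2, unet_base_filters=8, unet_depth=2,
                           rcan_filters=8, n_residual_groups=1,
                           n_cab_per_group=2, seed=1)
results = sr.RestorationModel.from_patch_set(patches, config).fit(
    sr.TrainConfig(epochs=8, initial_lr=3e-3, seed=0))
print(results.summary())
restored = results.predict(pair.noisy)
```

`summary()` prints the configuration (here 40,538 parameters) and the
loss trajectory; on this demo profile the training loss falls from 2.17
to 0.10 in 8 epochs, and the restored frame gains 4–6 dB PSNR over the
noisy input against the noiseless truth (see
`sted_restore.pipeline.run_pipeline` for the fully scripted version of
this example, which prints `psnr_noisy_db ≈ 18.1`,
`psnr_restored_db ≈ 22.5` at seed 1).

The same flow is available from the shell:

```bash
sted-restore simulate --kind filaments --shape 512x512 --seed 7 --out pair.tif
sted-restore run --seed 1 --out demo/
```

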