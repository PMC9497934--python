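# dqekit

Image-quality characterization of flat-panel radiography detectors:
presampled MTF by the slanted-edge method, normalized noise power spectrum
(NNPS) from flat-field series, detective quantum efficiency (DQE) at IEC RQA
beam qualities, phantom CNR/COV metrics, and Wiener restoration driven by a
measured MTF — together with a simulated imaging chain whose MTF and NNPS
are known in closed form, so every estimator can be verified without
detector hardware.

## Who this is for

Detector physicists and QA engineers who need the standard spatial-frequency
metrics of digital radiography — and anyone who wants a fully synthetic,
ground-truth-known test bench for those estimators.

## The metrics

For a linear, shift-invariant detector sampled at pixel pitch *a*:

- **MTF(f)** — modulation transfer versus spatial frequency (lp/mm),
  normalized to 1 at f = 0.  Measured presampled (aliasing-free) from a
  tungsten edge tilted 1.5–3° from a pixel axis: the edge spread function is
  rebinned at sub-pixel pitch, differentiated into the line spread function,
  and Fourier transformed: `MTF(f) = |F{LSF}|`.
- **NNPS(u, v)** — the noise power spectrum of flat-field frames divided by
  the squared mean signal (units mm²).  Estimated from half-overlapping
  128² or 256² ROIs in a homogeneous central region: each ROI is detrended
  by a least-squares polynomial surface S, and

  `NNPS(u, v) = (a² / N²) · ⟨|F{I − S}|²⟩ / S̄²`.

  The 1-D reduction averages seven off-axis rows/columns per side (axial)
  or seven-bin-wide annuli (radial).
- **DQE(f)** — the fraction of input photon information preserved:

  `DQE(f) = MTF²(f) / (Ka · (SNR²/Ka) · NNPS(f))`,

  where Ka is the air kerma (µGy) and SNR²/Ka the beam quality's squared
  SNR per air kerma (1/(mm²·µGy)), numerically the photon fluence per air
  kerma ratio.  RQA-3 and RQA-5 constants ship in a registry (both the
  current 2015 and the superseded 2003 tabulations).
- **CNR / COV** — `|S_A − S_B| / √(σ_A² + σ_B²)` and `σ/S` over rectangular
  ROIs, for phantom images.
- **Restoration** — the degradation model `h = PSF ⊗⊗ f + n`, an adaptive
  local minimum-mean-square denoiser, a radially symmetric PSF synthesized
  from a measured 1-D MTF, and Wiener deconvolution `H/(H² + nsr)`.

The simulator implements the forward chain Poisson quanta → Gaussian
scintillator blur → pixel-aperture integration → gain → electronic noise,
with closed-form ground truth `MTF(f) = e^{−2π²σ²f²}·|sinc(π a f)|` and the
alias-folded quantum NNPS (see `docs/methods.md`).

## Worked example

```python
from dqekit import (compute_dqe, get_beam_quality, illustrative_chain_config,
                    measure_mtf, measure_nnps, simulate_edge_image,
                    simulate_flat_field)

bq = get_beam_quality("RQA5")      # 70 kV, 21 mm Al, SNR²/Ka = 20673
kerma = 2.5                        # uGy

# illustrative preset for the thick-scintillator, 99 um pitch detector
cfg = illustrative_chain_config("FXRD-4343FAW", beam="RQA5", kerma=kerma,
                                frame_shape=(512, 512), seed=0)

edge = simulate_edge_image(cfg, angle=2.5)
flats = simulate_flat_field(cfg, n_frames=10)

mtf = measure_mtf(edge)
nnps = measure_nnps(flats, roi_side=128)
dqe = compute_dqe(mtf, nnps, bq, kerma)

print(f"MTF at 1.5 lp/mm:  {mtf.interp(1.5):.3f}")
print(f"MTF at Nyquist:    {mtf.values[-1]:.3f}   (f = {mtf.nyquist:.2f} lp/mm)")
print(f"NNPS at 2 lp/mm:   {nnps.interp(2.0):.3e} mm^2   ({nnps.n_rois} ROIs)")
print(f"DQE at 0.5 lp/mm:  {dqe.interp(0.5):.3f}")
print(f"DQE at 2 lp/mm:    {dqe.interp(2.0):.3f}")
```

prints

```
MTF at 1.5 lp/mm:  0.730
MTF at Nyquist:    0.023   (f = 5.05 lp/mm)
NNPS at 2 lp/mm:   7.844e-06 mm^2   (490 ROIs)
DQE at 0.5 lp/mm:  0.780
DQE at 2 lp/mm:    0.789
```

The preset absorbs 75% of the incident quanta, so the measured DQE sits near
0.75–0.8 across the band: blur lowers the MTF and the quantum NNPS together
and largely cancels in the DQE.  The same stages are available from the
shell:

```bash
dqekit simulate --preset FXRD-4343FAW --beam RQA5 --kerma 2.5 \
    --n-frames 10 --angle 2.5 --seed 0 --out-dir sim/
dqekit mtf  --image sim/edge.tif --pitch 0.099 --out mtf.csv
dqekit nnps --frames sim/flat_000.tif --frames sim/flat_001.tif \
    --pitch 0.099 --roi-side 128 --out nnps.csv
dqekit dqe  --mtf mtf.csv --nnps nnps.csv --beam RQA5 --kerma 2.5 --out dqe.csv
```

plus `phantom-metrics`, `restore`, and `run` (full pipeline from a YAML
config, writing CSV curves and a versioned JSON summary).

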