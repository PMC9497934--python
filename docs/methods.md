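# Methods

This note records the models, estimator choices, numerical details and known
limitations of dqekit, in the order data flows through the toolkit.

## Forward model of the imaging chain

The simulator treats an indirect-conversion flat panel as a linear,
shift-invariant chain acting on a Poisson photon field of fluence *q*
(photons/mm², optionally derived from a beam quality and air kerma through
the registry):

1. **Scintillator blur** — an isotropic Gaussian point spread function of
   standard deviation σ (mm).  A 2-D Gaussian blur of a half-plane step is
   an error-function ramp along the edge normal, which is what makes fully
   analytic edge rendering possible.
2. **Pixel aperture** — integration over the square *a* × *a* pixel.
3. **Readout** — linear gain *g* (output units per detected photon) plus
   additive white Gaussian electronic noise of standard deviation σₑ.

Ground truth follows in closed form:

- presampled MTF: `MTF(f) = exp(−2π²σ²f²) · |sinc(π a f)|`;
- flat-field NNPS:
  `NNPS(u,v) = [g² q a⁴ T(u) T(v) + σₑ² a²] / (g q a²)²`,
  where `T` is the per-axis quantum transfer **with sampling aliases folded
  in**.  `T` is computed exactly as the DTFT of the pixel-count
  autocovariance — lag *j* is the overlap integral of two blur-smeared
  apertures, a triangle of base 2*a* convolved with a Gaussian of width
  σ√2 — rather than by truncating the slowly converging replica sum
  `Σ_k |G|² sinc²` (whose tail decays only as 1/k²).  With σ = 0 the
  transfer is exactly 1 at every frequency: sampled white Poisson noise.

**Noise generation.**  Unblurred chains draw exact Poisson counts per pixel
(with a documented normal approximation above mean 1000).  Blurred chains
draw a stationary Gaussian random field synthesized in the frequency domain
with exactly the target spectrum `g² q a⁴ T(u)T(v)`.  This is deliberate: a
discretized blur-and-bin chain on a sub-pixel grid carries a Dirichlet-
kernel aggregation transfer that exceeds the continuous-aperture sinc by
several percent near Nyquist, which would corrupt the oracle the simulator
exists to provide.  At radiographic fluences (tens to thousands of detected
photons per pixel) blurred counts pool many Poisson contributions and the
Gaussian limit is accurate far below the estimators' sampling noise.  For
edge and phantom scenes the stationary field is modulated by the square
root of the local transmitted fraction, preserving the Poisson
variance-to-mean relation; the modulation varies only within a few blur
widths of a contrast boundary, so the correlation structure is essentially
unaffected where it matters.

**Mean fields.**  The edge scene (tilt 1.5–3°, opaque foil by default) is
rendered analytically: the error-function profile is integrated over each
pixel aperture by 16×16 midpoint supersampling (configurable, ≥ 8×
enforced), and pixels farther than 4σ + a from the edge take their plateau
values exactly.  Phantom discs are rendered on a sub-pixel grid and
aggregated, which antialiases the disc boundary; interior pixels are exact.

**Determinism.**  One master seed; every frame draws from a substream keyed
by (seed, scene type, frame index), so identical configurations are
bit-identical and frame sets of any length are reproducible.

**Illustrative detector presets.**  The specification sheet for the three
registered detectors does not include blur, quantum efficiency or
electronic noise.  The presets (σ = 0.050/0.075/0.080 mm, quantum
efficiency 0.45/0.60/0.75, σₑ = 1.0/1.0/0.5) are *illustrative*: blur and
absorbed fraction both grow with scintillator thickness, reproducing the
qualitative trade-off of the thickness series — best MTF for the thin
standard panel, lowest NNPS and highest DQE for the thick high-efficiency
panel.  They are not measured properties of any hardware.

## Slanted-edge MTF estimator

- **Angle fit** — per-row mid-level crossings by linear interpolation,
  least-squares line through the crossings; a warning (not an error) if the
  tilt leaves the recommended 1.5–3° band; an error if more than 10% of
  rows have no crossing.  At least 50 rows are required.
- **ESF binning** — pixel centers projected onto the edge normal, binned at
  `pitch / oversample` (default 10, minimum 4); bins take member means;
  empty interior bins are filled by linear interpolation.
- **Record cropping** — the record is cropped to ±16 pixels around the
  steepest transition by default.  Plateau bins far from the edge carry no
  resolution information, but their noise leaks into every frequency of the
  transform; cropping reduces the standard deviation of the low-frequency
  MTF by more than an order of magnitude on noisy frames while leaving
  noiseless recoveries unchanged (the transition span of any realistic
  blur is a few pixels).  Set `record_halfwidth_px=None` to keep the full
  record, or enlarge it for very wide PSFs.
- **Transform** — LSF by central finite differences; a Hann window centered
  on the LSF peak and spanning the record (switchable off); zero-padded FFT;
  division by **two** transfer corrections: the sub-pixel binning box
  `sinc(f·Δ)` and the central-difference kernel `sinc(2f·Δ)` (Δ = bin
  width).  With oversample 10 the combined bias at Nyquist would otherwise
  be ≈ 2%, which is larger than the estimator's verified accuracy (the
  sharp-edge aperture recovery is exact to ≈ 0.002 at Nyquist with the
  corrections in place).  Output is normalized to exactly 1 at f = 0 and
  resampled on a uniform grid (step ≈ 0.05 lp/mm) ending exactly at the
  detector Nyquist.  The estimate is invariant to image scaling and edge
  polarity.

Verified accuracy on simulated 512² edges: |sinc| recovery within 0.01 at
Nyquist for a sharp edge; Gaussian-blur ground truth within 2% absolute up
to 0.8 × Nyquist (in practice ≤ 0.2% noiseless).

## NNPS estimator

- **ROI tiling** — central 1024² region (or the largest centered square
  compatible with half-overlap tiling, with a warning), square ROIs of side
  256 (default) or 128 at 50% overlap: 49 or 225 ROIs per frame at the full
  region, `(2·1024/side − 1)²`.
- **Detrending** — per-ROI least-squares polynomial surface, default order
  2 (six coefficients).  Order 0 (mean subtraction) and a `mean_frame`
  reference mode (subtract the pixelwise mean of the series, removing fixed
  -pattern structure) are available; the surface interpretation is the
  default because it removes low-frequency shading without requiring many
  frames.  Order-2 detrending absorbs a few percent of genuine noise power
  in the lowest one or two frequency bins (degrees-of-freedom effect);
  white-noise variance is reduced by exactly 6/N on average.
- **Scaling** — mean periodogram × `pitch²/N²`, divided by the squared
  grand mean of the (undetrended) signal.  This satisfies Parseval exactly:
  `Σ NNPS · Δf² = residual variance / mean²`.
- **1-D reduction** — axial: average of the seven off-axis rows/columns on
  each side of both frequency axes (axes themselves excluded), as a
  function of the along-axis frequency; radial: seven-bin-wide annular
  averages.  The zero-frequency bin is excluded in both modes.

Sampling properties worth knowing: half-overlapping ROIs are correlated, so
the effective number of independent periodogram samples is smaller than
ROI count × bins; and the finite ROI convolves the true spectrum with a
Fejér kernel, biasing sharply curved (heavily blurred) spectra upward by a
few percent near Nyquist.  `theoretical_nnps_axial` mirrors the axial
sampling of the estimator for bias-free comparisons in tests.

## DQE

`DQE(f) = MTF²(f) / (Ka · (SNR²/Ka) · NNPS(f))`, NNPS entering to the first
power — the only exponent that renders the quotient dimensionless with NNPS
in mm² and fluence in mm⁻², and the standard definition.  Curves are
resampled by linear interpolation onto the coarser grid over the overlap of
their supports; extrapolation is refused.  Values are reported unclipped
(with a warning when sampling noise pushes a bin above 1) to preserve
estimator statistics.  The registry exposes both the 2015 (default) and
2003 RQA constant tabulations; which one a given historical measurement
used must be chosen by the caller.

Verified: a quantum-limited chain at the RQA-5 fluence returns
DQE(f→0) = 1 within 0.05 (residual deviation dominated by the order-2
detrend dip in the lowest NNPS bin), and the DQE is exactly invariant to
system gain.

## CNR / COV

Sample (n−1) standard deviations by default (population convention
switchable).  ROI coordinates are 0-based, top-left origin, half-open
extents.  CNR is invariant under affine rescaling of the image; COV only
under pure scaling.  Quantum-limited closed forms used as oracles:
COV = 1/√(q a²); CNR grows as √fluence.

## Restoration

- `degrade` — spatial convolution with a unit-sum PSF (reflective
  boundary) plus additive Gaussian noise.
- `denoise_adaptive` — per-pixel local minimum-mean-square filter
  `m + max(0, v − nv)/max(v, nv) · (x − m)` over an odd window (default 5);
  the noise variance defaults to the median of the local variances.
- `psf_from_mtf` — the 1-D curve is swept radially (isotropy assumed — the
  measured MTF is 1-D), its tail continued beyond the last sample by a
  log-quadratic roll-off fitted to the final samples (exact for Gaussian
  transfers), and the spectral replicas are folded before the inverse
  transform so the kernel is the PSF *sampled at pixel centers* rather than
  its ringing-prone band-limited interpolant.  Clipped at zero, truncated
  to the requested odd support, renormalized to unit sum.  A Gaussian
  round trip recovers σ to 0.01%.
- `wiener_deconvolve` — frequency-domain `H/(H² + nsr)` with H the radial
  transfer, symmetric padding (default 32 px) against wrap-around ringing,
  and the zero-frequency gain pinned to 1 so the mean is preserved.  `nsr`
  is a user scalar (default 10⁻²); deconvolution with `nsr = 0` is refused
  if the transfer has zeros.  Deconvolution is high-pass: amplification of
  high-frequency noise is inherent, which is why the denoise-then-
  deconvolve ordering of the restoration workflow measurably outperforms
  deconvolution alone on noisy fixtures.

## Problem sizes

The test suite and acceptance script run on 512² frames (256² for
restoration fixtures), 10-frame flat series, and ROI side 128 — ensembles
of 490 half-overlapping ROIs, large enough that every stochastic tolerance
above is a small multiple of the measured standard error, while the whole
suite completes in well under a minute of compute.

## What the simulator does and does not establish

Passing the suite shows the estimators are correct for a linear,
shift-invariant, Poisson–Gaussian chain with isotropic Gaussian blur and
white electronic noise.  Real panels add effects the forward model omits by
design: depth-dependent scintillator light transport and Swank noise,
detector lag, fixed-pattern (structure) noise, scatter, the heel effect,
and anisotropic or non-Gaussian PSFs.  Estimates on real frames inherit the
usual caveats of the standard methods (gain-map correction and linearity
are the user's responsibility; pixel pitch is required metadata and never
inferred from files).  The detector presets are illustrative orderings,
not measurements; no quantitative curve of any physical detector is claimed
or reproduced here.
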