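# Methods

## Model and assumptions

The network is a population of `N` leaky integrate-and-fire units encoding
standardized image patches (`K` pixels, zero mean, unit variance per patch).
Inference runs in discrete time with the membrane time constant `τ` as the
unit of time: Euler step `Δt = 0.1 τ`, window `5 τ`, hence 50 integration
steps per presentation and a hard ceiling of 50 spikes per unit per patch.
The update per step is

    u ← u + (Δt/τ)(−u + Q x − W y),

with three deliberate conventions, each a literal reading of the model's
event ordering:

* a threshold crossing detected after the update at step `t` produces the
  spike at step `t + 1`; the recurrent term at a step uses the spikes being
  emitted at that step;
* the internal variable is reset to the resting value (0) on the step the
  spike is emitted, and may cross threshold again immediately — there is no
  refractory period and no lower bound on `u`;
* all units update synchronously from the previous step's state; there is no
  sequential tie-breaking.

The dynamics are noise-free, so responses are exactly reproducible; a unit
can in principle spike on consecutive steps without limit (bounded only by
the window).  Inputs are continuous pixel values, not spiking afferents;
inhibition is direct and one-way rather than mediated by interneurons.

## Learning rules

All three rules are synaptically local and are applied once per 100-image
batch using batch means:

* inhibition: `ΔW_im = α⟨n_i n_m − p²⟩`, then negative entries clipped to 0
  and the diagonal forced to 0.  Clipping keeps recurrent weights
  inhibitory; a sign-free variant (`clip_negative_w=False`) is exposed but
  carries no tested claims;
* thresholds: `Δθ_i = γ⟨n_i − p⟩`, unclamped in both directions;
* feed-forward: Oja's rule `ΔQ_ik = β⟨n_i(x_k − n_i Q_ik)⟩`.

The non-local gradient rule `ΔQ_ik = β⟨n_i(x_k − Σ_j Q_jk n_j)⟩` is
implemented alongside as a validation oracle.  The two rules coincide
exactly when at most one unit is active per image; on independent synthetic
counts the relative Frobenius discrepancy of the batch-averaged updates
shrinks roughly linearly with the target rate `p` (the cross-terms scale as
`p²` against signal terms of order `p`), which the test suite and the
reproduction script verify on a grid from `p = 1.0` down to `0.05`.

`LearningConfig` permits zero learning rates (validation is `≥ 0`), because
probing a trained network is defined as inference with all rates at zero.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p` | 0.05 spikes/image | lifetime sparseness target; well below one spike per image so activity is "hard"-sparse |
| `α`, `γ` | 0.01 (library), 0.3 (desk preset) | inhibition / threshold rates |
| `β` | 0.001 (library), 0.03 (desk preset) | feed-forward rate; must be ≪ α, γ (a ratio above 0.5 warns) so activity stays sparse and decorrelated while Q drifts |
| `batch_size` | 100 | images per update |
| `init_theta` | 5.0 (library), 1.0 (desk preset) | initial uniform threshold |
| `init_q_scale` | `1/√K` | SD of the Gaussian feed-forward init, giving unit-variance initial drive |
| schedule | ×1 → ×0.5 (half-way) → ×0.1 (three-quarters) | staged decay of all three rates; only "start large, then reduce" is prescribed, the three-stage geometric form is this package's choice |

### The desk-scale preset

`sailnet.presets` fixes the configuration used by the examples, the test
suite, and `scripts/acceptance.py`: 64 units on 8×8 patches, 200 batches
(2×10⁴ presentations) of patches sampled from ten whitened 128×128 synthetic
1/f images, probed with 10⁴ fresh patches.  Two settings deviate from the
library defaults, for a structural reason rather than tuning: with a tiny
target rate the downward homeostatic step is bounded by `γ·p` per batch, so
annealing a high threshold (5.0) at small `γ` takes thousands of batches —
affordable at the published scale of ~10⁵ batches, not in a 200-batch run.
The preset therefore starts thresholds at 1.0 (units fire densely at first,
and the much faster *upward* homeostatic steps take over) and uses rates
`α = γ = 0.3`, `β = 0.03`, preserving the required ordering `β ≪ α, γ`.
The 10⁴-patch probe size is chosen so that units at the ≥30-spike inclusion
threshold for STA analyses are far from the STA sampling-noise floor (the
cosine between a measured STA and its true direction degrades as
`s/√(s² + K/n_spikes)`), and matches the split-half sufficiency check.

## Stimuli

The synthetic generator produces Gaussian random fields with `1/f^a`
amplitude spectra (default `a = 1`), optionally superposed with sparse
random Gabor elements, normalized to unit pixel variance.  Whitening is the
zero-phase frequency-domain filter `f·exp(−(f/f₀)^4)` with `f₀ = 200`
cycles/image; on desk-scale images (≤128 px) the roll-off is inactive and
the filter is effectively the ramp `|f|`, which exactly flattens `1/f`
inputs.  Patches are standardized per patch (zero mean, unit SD); a switch
disables standardization.  Pixel coordinates are 0-based row-major, patches
stored flattened row-major.

Surrogates reproduce the second-order statistics of natural scenes but not
their higher-order structure (edges, occlusions, textures).  Passing tests
on surrogates therefore validate the machinery — convergence, homeostasis,
decorrelation, STA∝Q, decoding — but make *no* claim that the learned RF
shapes match physiological RF-shape distributions; that comparison requires
real natural images and physiological data, both outside this package.
Gaussian stimuli in particular make STA/Q alignment easier than natural
images would (for Gaussian inputs the STA of any threshold unit points along
its drive vector), so the STA∝Q tests are read as convergence diagnostics,
not as discriminating the learning rule per se.

## Analysis choices

* **STA**: count-weighted mean stimulus `Σ n x / Σ n`; units with zero total
  spikes are *undefined*, never zero.  Downstream analyses include units
  with ≥ 30 probe spikes.
* **Gabor fitting**: best-of-multi-start Levenberg–Marquardt least squares
  on the 8-parameter model, with starts built from the RF's second moments
  (center, envelope) and dominant Fourier component (orientation,
  frequency), four phase offsets, and seeded jitters; envelope widths are
  optimized on a log scale.  The model's exact symmetries
  (`A→−A, φ→φ+π`; `orientation→orientation+π, φ→−φ`; `f→−f, φ→−φ`) are
  collapsed by canonicalization before parameters are compared or reported.
  Shape parameters are `n_x = σ_x f`, `n_y = σ_y f` (envelope SD in cycles
  of the sinusoid; the `σf` convention, not `2σf`).
* **Gabor QC**: a fit is rejected if the optimizer failed, if the residual
  MSE exceeds the cut, if the center lies outside the patch, or if the
  center lies within one envelope SD of any edge, using the rotated
  envelope's extent projected onto each image axis.  The MSE cut is
  calibrated as half the 5th percentile of MSEs from fits to pure-noise RFs
  at matched variance: noise-fit MSEs cluster at 0.75–1.1× the RF variance
  while genuine Gabor fits leave only measurement noise (typically < 0.1×),
  so the cut sits in a wide gap and rejects noise reliably.
* **Histogram fits** are least squares on the binned density (not maximum
  likelihood), matching how such curves are fit to published histograms;
  variance explained is reported per family.  Rate histograms use 20 linear
  bins over the positive rates; degenerate (< 3 occupied bins) histograms
  are flagged and skipped.  The log-weight analysis bins the logs of the
  strictly positive inhibitory weights into 20 uniform log-space bins,
  normalizes to unit area, and fits a Gaussian (lognormality check).
* **Correlations**: Pearson coefficients per unordered pair on spike counts;
  zero-variance pairs are NaN (undefined), never zero.  Two equal-rate,
  never-co-active binary units sit at the analytic floor `−q/(1−q)`.
* **Decoding**: `x̂ = g·Σ n_i RF_i` with one global least-squares gain `g`
  over the probe ensemble (STA ∝ Q only up to a scalar).  Whole-image
  reconstruction standardizes each non-overlapping patch, encodes, decodes,
  then restores the recorded per-patch mean and SD before tiling; images are
  cropped (with a warning) to whole patches.

## Numerical notes

* Training aborts with a diagnostic if any parameter becomes non-finite.
* `run_inference_batch` is defined as (and implemented by) mapping the
  single-patch simulator, so batch and loop results are bit-identical.
* Checkpoints round-trip `Q`, `W`, `θ`, the trace, and the RNG state
  bit-exactly under a versioned HDF5 schema; resuming from a checkpoint
  reproduces an uninterrupted run exactly when fed the same patch sequence.
* Zero-variance patches cannot be standardized and are resampled with a
  retry cap; zero-variance RFs are rejected as degenerate before fitting.

## Known limitations

* The stimulus surrogates limit claims to machinery, not RF-shape realism
  (see above); no difference-of-Gaussians fitting for center–surround RFs.
* Convergence is monitored via the trace, not auto-detected; run length is
  explicit.
* The sign-free recurrent variant is exposed but untested against any
  quantitative claim.
* First-spike-latency readouts and spike-timing-dependent plasticity are out
  of scope.
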