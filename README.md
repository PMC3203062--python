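# sailnet

A spiking sparse-coding network with synaptically local plasticity, plus the
measurement suite used to characterize it.

Primary visual cortex is often modeled as learning a *sparse code* for
natural images: each image patch is represented by a few active units whose
preferred features resemble the receptive fields (RFs) of V1 simple cells.
Classic sparse-coding algorithms achieve this with learning rules that are
biologically implausible — updating one synapse requires knowing the weights
and activities of many other units.  This package implements a network of
spiking leaky integrate-and-fire (LIF) units that learns a sparse code using
only *synaptically local* information (pre-synaptic activity, post-synaptic
activity, and the current strength of that one connection), and the analysis
tools needed to study what it learns.  It is aimed at computational
neuroscientists who want a compact, fully testable reference implementation
of the model and its analyses.

## The model

`N` units encode a standardized image patch `x ∈ R^K` (zero mean, unit
variance).  Each unit `i` has an internal variable `u_i` (membrane analog)
integrated with a forward-Euler step `Δt = 0.1 τ` over a window of `5 τ`
(50 steps):

    u_i ← u_i + (Δt/τ) · ( −u_i + Σ_k Q_ik x_k − Σ_m W_im y_m )

A unit whose `u_i` exceeds its threshold `θ_i` emits a one-step binary spike
`y_i = 1` at the next step and resets `u_i` to 0.  The per-patch spike count
`n_i` is the unit's output.  After every 100-patch batch, three local rules
update the parameters (learning rates `α, β, γ`, sparseness target `p`
spikes/image):

    ΔW_im = α ⟨ n_i n_m − p² ⟩        (anti-Hebbian inhibition; W ≥ 0, W_ii = 0)
    Δθ_i  = γ ⟨ n_i − p ⟩             (homeostasis toward the target rate)
    ΔQ_ik = β ⟨ n_i (x_k − n_i Q_ik) ⟩  (Oja's Hebbian rule)

Together these perform approximate constrained optimization: the network
minimizes the error of the linear generative model `x̂ = Σ_i n_i Q_i·`
subject to fixed mean rates and uncorrelated activity (thresholds and
inhibitory weights play the role of Lagrange multipliers).  In the sparse,
decorrelated limit the batch-averaged Oja rule approximates the non-local
gradient rule `ΔQ_ik = β ⟨ n_i (x_k − Σ_j Q_jk n_j) ⟩` used by classic
sparse coding; the package implements the non-local rule as a validation
oracle and measures the discrepancy.  At convergence the spike-triggered
average (STA) of each unit is proportional to its feed-forward weight row,
so RFs can be read out either way.

The analysis suite covers: STA receptive fields, Gabor-function fits
(`G = A·exp(−x′²/2σ_x² − y′²/2σ_y²)·cos(2πf x′ + φ)`) with quality-control
cuts and the dimensionless shape parameters `n_x = σ_x f`, `n_y = σ_y f`;
firing-rate histograms with least-squares lognormal/exponential fits;
pairwise spike-count Pearson correlations (including the analytic floor
`−q/(1−q)` for never-co-active pairs); the log-weight distribution of the
learned inhibition with a Gaussian fit (lognormality check); RF-overlap vs.
inhibition strength; and linear decoding / whole-image reconstruction.

## Worked example

The desk-scale preset trains 64 units on 8×8 patches sampled from whitened
synthetic 1/f images for 2×10⁴ presentations, then probes the frozen network
with 10⁴ fresh patches:

```python
import numpy as np
from sailnet.presets import train_toy_network, toy_probe_patches
from sailnet.dynamics import run_inference
from sailnet.analysis import spike_triggered_average, pairwise_correlations

run = train_toy_network(seed=1)          # 64 units, 8x8 patches, 2e4 presentations
probe = toy_probe_patches(seed=1, n=10_000)
responses = [run_inference(run.params, q, run.dynamics) for q in probe]
counts = np.stack([r.counts for r in responses])

print(f"mean firing rate : {counts.mean():.3f} spikes/image (target p = {run.learn_cfg.p})")
print(f"reconstruction E : {run.trace.recon_error[0]:.2f} -> {run.trace.recon_error[-1]:.2f}")
r = pairwise_correlations(counts)
print(f"mean |pairwise r|: {np.nanmean(np.abs(r)):.3f}")

rfs = spike_triggered_average(responses, probe)
cos = [float(rf.map @ q / (np.linalg.norm(rf.map) * np.linalg.norm(q)))
       for rf, q in zip(rfs, run.params.Q) if rf.n_spikes_used >= 30]
print(f"STA ~ Q cosine   : min {min(cos):.3f} over {len(cos)} active units")
```

Output (about 10 s on one CPU):

```
mean firing rate : 0.052 spikes/image (target p = 0.05)
reconstruction E : 3.62 -> 0.89
mean |pairwise r|: 0.013
STA ~ Q cosine   : min 0.961 over 64 active units
```

Homeostasis pins the mean rate at the sparseness target, the linear
reconstruction error of the generative model falls during training, lateral
inhibition decorrelates the units, and every unit's measured RF (STA) aligns
with its learned feed-forward weights.

There is also a command line for file-based runs:

```sh
sailnet train --config run.yaml --out run.h5 --trace-csv trace.csv
sailnet probe --model run.h5 --out rates.csv --contrast-divisor 3
sailnet analyze --model run.h5 --report report/ --figures
sailnet decode --model run.h5 --image img.npy --out recon.npy
```

A minimal `run.yaml` needs only `n_neurons` and `patch_side`; everything
else has documented defaults (see `sailnet.io.RunConfig`).

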