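"""Measurement suite for trained networks.

Implements the analyses a physiologist would run on the model: receptive
fields by spike-triggered averaging (which, at convergence of the Oja rule,
are proportional to the feed-forward weights), firing-rate distributions
with lognormal/exponential fits, pairwise spike-count correlations,
the log-weight distribution of the learned inhibitory connections, the
relationship between receptive-field overlap and mutual inhibition, and
linear decoding of the population spike counts back into images.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .dynamics import (
    DynamicsConfig,
    NetworkParams,
    SpikeResponse,
    StimulusPatch,
    run_inference,
)
from .errors import ShapeError, ValidationError

__all__ = [
    "ReceptiveField",
    "DistributionFit",
    "RateDistribution",
    "OverlapInhibition",
    "spike_triggered_average",
    "fit_rate_distribution",
    "firing_rate_distribution",
    "pairwise_correlations",
    "weight_distribution",
    "overlap_vs_inhibition",
    "linear_decode",
    "fit_decoder_gain",
    "reconstruct_image",
]


@dataclasses.dataclass
class ReceptiveField:
    """A spike-triggered-average receptive field for one unit.

    ``map`` is the flat pixel vector (None when the unit never spiked, in
    which case the RF is undefined rather than zero).
    """

    map: np.ndarray | None
    n_spikes_used: int

    @property
    def defined(self) -> bool:
        return self.map is not None and self.n_spikes_used > 0

    def image(self) -> np.ndarray:
        if not self.defined:
            raise ValidationError("RF undefined: unit emitted no spikes")
        side = int(round(math.sqrt(self.map.size)))
        return self.map.reshape(side, side)


@dataclasses.dataclass
class DistributionFit:
    """A least-squares fit of a density family to a binned histogram."""

    family: str
    params: dict[str, float]
    variance_explained: float


@dataclasses.dataclass
class RateDistribution:
    """Per-unit mean firing rates with histogram fits and a sufficiency check."""

    rates: np.ndarray
    lognormal: DistributionFit | None
    exponential: DistributionFit | None
    degenerate: bool
    n_silent: int
    split_half_variance_ratio: float | None = None


@dataclasses.dataclass
class OverlapInhibition:
    """RF overlap vs. inhibitory strength for sampled unit pairs."""

    overlaps: np.ndarray
    strengths: np.ndarray
    rank_correlation: float
    p_value: float
    defined: bool


def _counts_matrix(responses) -> np.ndarray:
    if isinstance(responses, np.ndarray):
        counts = np.asarray(responses, dtype=np.float64)
        if counts.ndim != 2:
            raise ShapeError("counts must be a 2-D (B, N) array")
        return counts
    rows = []
    for r in responses:
        rows.append(r.counts if isinstance(r, SpikeResponse) else np.asarray(r))
    if not rows:
        raise ValidationError("no responses supplied")
    return np.stack(rows).astype(np.float64)


def _stimulus_matrix(stimuli) -> np.ndarray:
    if isinstance(stimuli, np.ndarray):
        X = np.asarray(stimuli, dtype=np.float64)
        if X.ndim != 2:
            raise ShapeError("stimuli must be a 2-D (B, K) array")
        return X
    rows = [
        s.pixels if isinstance(s, StimulusPatch) else np.asarray(s, dtype=np.float64).ravel()
        for s in stimuli
    ]
    if not rows:
        raise ValidationError("no stimuli supplied")
    return np.stack(rows)


def spike_triggered_average(responses, stimuli) -> list[ReceptiveField]:
    """Count-weighted mean stimulus per unit: ``RF_i = sum_b n_i x / sum_b n_i``.

    When probe statistics match the training ensemble and the Oja rule has
    converged, the STA is proportional to the unit's feed-forward weight
    vector.  Units with zero total spikes get an undefined RF.  If the whole
    population is silent an empty list is returned with a warning.
    """
    counts = _counts_matrix(responses)
    X = _stimulus_matrix(stimuli)
    if counts.shape[0] != X.shape[0]:
        raise ShapeError(
            f"{counts.shape[0]} responses but {X.shape[0]} stimuli"
        )
    totals = counts.sum(axis=0)
    if np.all(totals == 0):
        warnings.warn("all units silent over the probe set; no RFs defined")
        return []
    weighted = counts.T @ X
    out: list[ReceptiveField] = []
    for i, total in enumerate(totals):
        if total > 0:
            out.append(ReceptiveField(weighted[i] / total, int(total)))
        else:
            out.append(ReceptiveField(None, 0))
    return out


def _lognormal_pdf(r, mu, sigma):
    return stats.lognorm.pdf(r, abs(sigma), scale=np.exp(mu))


def _exponential_pdf(r, scale):
    return stats.expon.pdf(r, scale=abs(scale))


def _variance_explained(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((observed - fitted) ** 2)) / ss_tot


def fit_rate_distribution(
    rates: np.ndarray, n_bins: int = 20
) -> tuple[DistributionFit | None, DistributionFit | None, bool]:
    """Least-squares lognormal and exponential fits to a binned rate histogram.

    Fits the densities to the histogram values (not by maximum likelihood),
    mirroring how reported curves are fit to published histograms, and
    reports the variance in the binned density explained by each family.
    Returns ``(lognormal, exponential, degenerate)``; fits are skipped (None)
    when the positive rates fall into fewer than three occupied bins.
    """
    rates = np.asarray(rates, dtype=np.float64).ravel()
    positive = rates[rates > 0]
    if positive.size < 4:
        return None, None, True
    density, edges = np.histogram(positive, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(density) < 3:
        return None, None, True

    logs = np.log(positive)
    lognormal = exponential = None
    try:
        popt, _ = optimize.curve_fit(
            _lognormal_pdf, centers, density,
            p0=(float(logs.mean()), float(max(logs.std(), 1e-3))), maxfev=20000,
        )
        ve = _variance_explained(density, _lognormal_pdf(centers, *popt))
        lognormal = DistributionFit(
            "lognormal", {"mu": float(popt[0]), "sigma": float(abs(popt[1]))}, ve
        )
    except RuntimeError:
        pass
    try:
        popt, _ = optimize.curve_fit(
            _exponential_pdf, centers, density, p0=(float(positive.mean()),),
            maxfev=20000,
        )
        ve = _variance_explained(density, _exponential_pdf(centers, *popt))
        exponential = DistributionFit(
            "exponential", {"scale": float(abs(popt[0]))}, ve
        )
    except RuntimeError:
        pass
    return lognormal, exponential, False


def firing_rate_distribution(
    params: NetworkParams,
    probe_patches: Sequence,
    config: DynamicsConfig | None = None,
    n_bins: int = 20,
) -> RateDistribution:
    """Mean spike count per unit over a probe set, with histogram fits.

    Learning is implicitly off: inference only.  Also reports a split-half
    sample-size sufficiency check -- the ratio of the across-unit variance
    of rates estimated from each half of the probe set; values near 1 mean
    the probe is large enough that the measured spread is not dominated by
    sampling noise.
    """
    probe_patches = list(probe_patches)
    if not probe_patches:
        raise ValidationError("probe set is empty")
    counts = _counts_matrix(
        [run_inference(params, patch, config) for patch in probe_patches]
    )
    rates = counts.mean(axis=0)
    lognormal, exponential, degenerate = fit_rate_distribution(rates, n_bins=n_bins)
    half = counts.shape[0] // 2
    ratio = None
    if half >= 2:
        v1 = float(counts[:half].mean(axis=0).var())
        v2 = float(counts[half:].mean(axis=0).var())
        if v2 > 0:
            ratio = v1 / v2
    return RateDistribution(
        rates=rates,
        lognormal=lognormal,
        exponential=exponential,
        degenerate=degenerate,
        n_silent=int(np.sum(counts.sum(axis=0) == 0)),
        split_half_variance_ratio=ratio,
    )


def pairwise_correlations(responses) -> np.ndarray:
    """Pearson correlation of spike counts for every unordered unit pair.

    Returns a flat array over pairs ``i < m``.  Pairs involving a unit with
    zero count variance are NaN (undefined), never zero.
    """
    counts = _counts_matrix(responses)
    b, n = counts.shape
    if n < 2:
        raise ShapeError("need at least two units")
    if b < 2:
        raise ShapeError("need at least two images")
    sd = counts.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(counts.T)
    iu, im = np.triu_indices(n, k=1)
    r = corr[iu, im]
    undefined = (sd[iu] == 0) | (sd[im] == 0)
    r = r.astype(np.float64)
    r[undefined] = np.nan
    return r


def _gaussian_pdf(x, mu, sigma):
    sigma = abs(sigma)
    return np.exp(-((x - mu) ** 2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))


def weight_distribution(
    W: np.ndarray, n_bins: int = 20, min_nonzero: int = 10
) -> DistributionFit:
    """Gaussian fit to the log-weight histogram of the inhibitory matrix.

    Strictly positive entries only.  Their logarithms are binned into
    ``n_bins`` uniform bins in log space (so the bins are log-spaced on the
    weight axis), normalized to unit area, and a Gaussian density is fit by
    least squares.  A high variance explained indicates an approximately
    lognormal weight distribution.
    """
    W = np.asarray(W, dtype=np.float64)
    w = W[W > 0]
    if w.size < min_nonzero:
        raise ValidationError(
            f"need at least {min_nonzero} positive weights, found {w.size}"
        )
    logs = np.log(w)
    density, edges = np.histogram(logs, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    popt, _ = optimize.curve_fit(
        _gaussian_pdf, centers, density,
        p0=(float(logs.mean()), float(max(logs.std(), 1e-6))), maxfev=20000,
    )
    ve = _variance_explained(density, _gaussian_pdf(centers, *popt))
    return DistributionFit(
        "gaussian-on-log",
        {"mu": float(popt[0]), "sigma": float(abs(popt[1]))},
        ve,
    )


def overlap_vs_inhibition(
    params: NetworkParams, n_pairs: int = 5000, seed: int | None = 0
) -> OverlapInhibition:
    """RF overlap (dot product of feed-forward rows) vs. inhibitory strength.

    Samples unit pairs without replacement (all pairs if fewer exist than
    requested) and reports the Spearman rank correlation between overlap and
    the symmetrized connection strength.  On converged networks the
    correlation is positive: units with similar receptive fields need strong
    mutual inhibition to stay decorrelated.  Degenerate strength sets (e.g.
    an untrained all-zero ``W``) are flagged undefined.
    """
    n = params.n_neurons
    if n < 2:
        raise ShapeError("need at least two units")
    iu, im = np.triu_indices(n, k=1)
    total = iu.size
    if n_pairs < total:
        rng = np.random.default_rng(seed)
        pick = rng.choice(total, size=n_pairs, replace=False)
        iu, im = iu[pick], im[pick]
    overlaps = np.einsum("ij,ij->i", params.Q[iu], params.Q[im])
    strengths = 0.5 * (params.W[iu, im] + params.W[im, iu])
    if np.all(strengths == strengths[0]) or np.all(overlaps == overlaps[0]):
        return OverlapInhibition(overlaps, strengths, np.nan, np.nan, False)
    rho, pval = stats.spearmanr(overlaps, strengths)
    return OverlapInhibition(overlaps, strengths, float(rho), float(pval), True)


def _rf_matrix(rfs, counts: np.ndarray) -> np.ndarray:
    if isinstance(rfs, NetworkParams):
        return rfs.Q
    if isinstance(rfs, np.ndarray):
        if rfs.ndim != 2:
            raise ShapeError("RF matrix must be 2-D (N, K)")
        return rfs
    maps = []
    active = counts.sum(axis=0) > 0
    for i, rf in enumerate(rfs):
        if isinstance(rf, ReceptiveField):
            if rf.defined:
                maps.append(rf.map)
            elif active[i]:
                raise ValidationError(
                    f"unit {i} spikes in the responses but its RF is undefined"
                )
            else:
                maps.append(None)
        else:
            maps.append(np.asarray(rf, dtype=np.float64).ravel())
    k = next(m.size for m in maps if m is not None)
    return np.stack([m if m is not None else np.zeros(k) for m in maps])


def linear_decode(rfs, responses, gain: float = 1.0) -> np.ndarray:
    """Linear generative read-out ``x_hat = gain * sum_i n_i RF_i`` per patch.

    ``rfs`` may be a :class:`NetworkParams` (uses the feed-forward rows), an
    ``(N, K)`` array, or a list of :class:`ReceptiveField` (STA maps; units
    that spike must have defined RFs).  Linear in the counts by construction.
    """
    counts = _counts_matrix(responses)
    rf = _rf_matrix(rfs, counts)
    if rf.shape[0] != counts.shape[1]:
        raise ShapeError(
            f"{counts.shape[1]} units in responses but {rf.shape[0]} RFs"
        )
    return gain * (counts @ rf)


def fit_decoder_gain(rfs, responses, stimuli) -> float:
    """Global least-squares gain for the linear decoder over a probe ensemble.

    The STA is proportional to the feed-forward weights only up to a scalar,
    so one shared gain ``g = <x . x_hat> / <x_hat . x_hat>`` is fit across
    all probe patches.  Returns 1.0 (with a warning) if the raw decode is
    identically zero.
    """
    xhat = linear_decode(rfs, responses, gain=1.0)
    X = _stimulus_matrix(stimuli)
    if X.shape != xhat.shape:
        raise ShapeError("stimuli and decoded patches have different shapes")
    denom = float(np.sum(xhat * xhat))
    if denom == 0.0:
        warnings.warn("decoded output is identically zero; gain undefined, using 1.0")
        return 1.0
    return float(np.sum(X * xhat) / denom)


def reconstruct_image(
    image: np.ndarray,
    params: NetworkParams | None,
    patch_side: int,
    config: DynamicsConfig | None = None,
    rfs=None,
    gain: float | str = "lsq",
    codec: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Encode and linearly decode a whole image patch by patch.

    The image is divided into non-overlapping ``patch_side`` squares
    (cropped, with a warning, if the dimensions do not divide evenly).  Each
    patch is standardized, encoded by the network, linearly decoded, and the
    standardization inverted (each patch's recorded mean and standard
    deviation restored) before tiling the reconstruction back together.

    ``gain="lsq"`` fits one global decoder gain over all patches of this
    image; a float fixes it.  ``codec`` substitutes an arbitrary
    patch-to-patch map for the encode/decode step (identity gives a pure
    plumbing check).  Zero-variance patches are passed through as their own
    mean.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {image.shape}")
    if min(image.shape) < patch_side:
        raise ShapeError("image smaller than one patch")
    ny = (image.shape[0] // patch_side) * patch_side
    nx = (image.shape[1] // patch_side) * patch_side
    if (ny, nx) != image.shape:
        warnings.warn(
            f"cropping image from {image.shape} to ({ny}, {nx}) "
            f"to fit whole {patch_side}px patches"
        )
        image = image[:ny, :nx]

    tiles = []
    stats_list = []
    for r in range(0, ny, patch_side):
        for c in range(0, nx, patch_side):
            p = image[r : r + patch_side, c : c + patch_side].ravel()
            mu, sd = float(p.mean()), float(p.std())
            z = (p - mu) / sd if sd > 0 else np.zeros_like(p)
            tiles.append(z)
            stats_list.append((r, c, mu, sd))

    if codec is not None:
        decoded = [np.asarray(codec(z), dtype=np.float64).ravel() for z in tiles]
    else:
        if params is None:
            raise ValidationError("params required when no codec is supplied")
        rf = params.Q if rfs is None else _rf_matrix(rfs, np.zeros((1, params.n_neurons)))
        responses = [run_inference(params, z, config) for z in tiles]
        if gain == "lsq":
            g = fit_decoder_gain(rf, responses, np.stack(tiles))
        else:
            g = float(gain)
        decoded = list(linear_decode(rf, responses, gain=g))

    out = np.empty_like(image)
    for z_hat, (r, c, mu, sd) in zip(decoded, stats_list):
        out[r : r + patch_side, c : c + patch_side] = (
            z_hat.reshape(patch_side, patch_side) * sd + mu
        )
    return out
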