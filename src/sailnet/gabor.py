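"""Gabor receptive-field model: forward model, fitting, quality control.

A Gabor function is a two-dimensional Gaussian envelope multiplied by a
sinusoid:

    G(x, y) = A * exp(-x'^2 / (2 sx^2) - y'^2 / (2 sy^2)) * cos(2 pi f x' + phi)

where ``(x', y')`` are pixel coordinates relative to the center ``(x0, y0)``
rotated by the orientation angle, ``x'`` pointing along the direction in
which the sinusoid oscillates (frequency ``f`` in cycles/pixel) and ``y'``
perpendicular to it.  The envelope has standard deviations ``sigma_x`` along
the oscillation and ``sigma_y`` across it.

The dimensionless shape parameters used to classify receptive fields are
``n_x = sigma_x * f`` and ``n_y = sigma_y * f``: the envelope size measured
in cycles of the sinusoid along and across the oscillation.

The parameterization has exact symmetries, which fitting can land on:
``A -> -A`` with ``phi -> phi + pi``, and ``orientation -> orientation + pi``
with ``phi -> -phi``.  :func:`canonical_parameters` maps any parameter set
to a canonical representative (``A >= 0``, orientation in ``[0, pi)``,
``phi`` in ``(-pi, pi]``) so fits can be compared to ground truth.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize

from .errors import ShapeError, ValidationError

__all__ = [
    "GaborFit",
    "gabor_image",
    "fit_gabor",
    "gabor_quality_control",
    "canonical_parameters",
    "calibrate_mse_threshold",
]

_PARAM_NAMES = (
    "amplitude",
    "x0",
    "y0",
    "orientation",
    "phase",
    "frequency",
    "sigma_x",
    "sigma_y",
)


@dataclasses.dataclass
class GaborFit:
    """Result of fitting one receptive field.

    Pixel coordinates are 0-based with ``x`` along columns and ``y`` along
    rows.  ``mse`` is the mean squared residual between the receptive field
    and the best-fit Gabor.  ``qc_pass`` is set by
    :func:`gabor_quality_control`; ``qc_reason`` records why a fit was
    rejected.
    """

    amplitude: float
    x0: float
    y0: float
    orientation: float
    phase: float
    frequency: float
    sigma_x: float
    sigma_y: float
    mse: float
    converged: bool = True
    qc_pass: bool | None = None
    qc_reason: str | None = None

    def __post_init__(self) -> None:
        if self.converged:
            if self.sigma_x <= 0 or self.sigma_y <= 0:
                raise ValidationError("envelope widths must be positive")
            if self.frequency < 0:
                raise ValidationError("frequency must be non-negative")

    @property
    def n_x(self) -> float:
        """Envelope size along the oscillation, in sinusoid cycles."""
        return self.sigma_x * self.frequency

    @property
    def n_y(self) -> float:
        """Envelope size across the oscillation, in sinusoid cycles."""
        return self.sigma_y * self.frequency

    def parameters(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_NAMES}


def gabor_image(
    side: int,
    amplitude: float,
    x0: float,
    y0: float,
    orientation: float,
    phase: float,
    frequency: float,
    sigma_x: float,
    sigma_y: float,
) -> np.ndarray:
    """Evaluate the Gabor function on a ``side x side`` pixel grid."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dx = xx - x0
    dy = yy - y0
    c, s = math.cos(orientation), math.sin(orientation)
    xr = dx * c + dy * s
    yr = -dx * s + dy * c
    envelope = np.exp(-(xr**2) / (2 * sigma_x**2) - (yr**2) / (2 * sigma_y**2))
    return amplitude * envelope * np.cos(2 * np.pi * frequency * xr + phase)


def _gabor_from_vector(vec: np.ndarray, side: int) -> np.ndarray:
    a, x0, y0, ori, phi, f, log_sx, log_sy = vec
    # Clamp so optimizer excursions cannot under/overflow the envelope.
    sx = math.exp(min(max(log_sx, -10.0), 10.0))
    sy = math.exp(min(max(log_sy, -10.0), 10.0))
    return gabor_image(side, a, x0, y0, ori, phi, f, sx, sy)


def _initial_guesses(
    rf: np.ndarray, side: int, n_starts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Moment- and spectrum-based starting points plus random jitters."""
    weights = rf**2
    total = weights.sum()
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    x0 = float((weights * xx).sum() / total)
    y0 = float((weights * yy).sum() / total)

    # Dominant Fourier component gives orientation and frequency.
    spectrum = np.abs(np.fft.fft2(rf))
    spectrum[0, 0] = 0.0
    ky, kx = np.unravel_index(np.argmax(spectrum), spectrum.shape)
    fy = np.fft.fftfreq(side)[ky]
    fx = np.fft.fftfreq(side)[kx]
    f0 = float(np.hypot(fx, fy))
    if f0 < 1e-3:
        f0 = 1.0 / side
        ori0 = 0.0
    else:
        ori0 = float(np.arctan2(fy, fx)) % np.pi

    # Envelope widths from second moments of rf^2 (whose envelope has
    # standard deviation sigma / sqrt(2)).
    c, s = math.cos(ori0), math.sin(ori0)
    xr = (xx - x0) * c + (yy - y0) * s
    yr = -(xx - x0) * s + (yy - y0) * c
    sx0 = math.sqrt(max(float((weights * xr**2).sum() / total), 0.25)) * math.sqrt(2)
    sy0 = math.sqrt(max(float((weights * yr**2).sum() / total), 0.25)) * math.sqrt(2)
    a0 = float(np.abs(rf).max())

    starts = [
        np.array([a0, x0, y0, ori0, phi, f0, math.log(sx0), math.log(sy0)])
        for phi in (0.0, 0.5 * np.pi, np.pi, -0.5 * np.pi)
    ]
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    a0 * rng.uniform(0.5, 1.5),
                    x0 + rng.normal(0, side / 10),
                    y0 + rng.normal(0, side / 10),
                    (ori0 + rng.normal(0, 0.4)) % np.pi,
                    rng.uniform(-np.pi, np.pi),
                    f0 * rng.uniform(0.6, 1.6),
                    math.log(sx0) + rng.normal(0, 0.4),
                    math.log(sy0) + rng.normal(0, 0.4),
                ]
            )
        )
    return starts[:n_starts]


def fit_gabor(rf, n_starts: int = 6, seed: int | None = 0) -> GaborFit:
    """Best-of-multi-start least-squares Gabor fit to a receptive field.

    ``rf`` may be a flat length-``K`` vector (``K`` a perfect square), a
    square 2-D array, or a :class:`~sailnet.analysis.ReceptiveField`.
    Starting points combine a moment/spectrum-based guess (four phase
    offsets) with seeded random jitters; the fit with the smallest residual
    wins.  Envelope widths are optimized on a log scale so they stay
    positive.  Deterministic for a given seed.  If no start converges the
    returned fit is flagged ``converged=False`` (and fails QC downstream).
    """
    map_attr = getattr(rf, "map", None)
    if map_attr is not None:
        rf = map_attr
    if rf is None:
        raise ValidationError("receptive field is undefined (no spikes)")
    rf = np.asarray(rf, dtype=np.float64)
    if rf.ndim == 1:
        side = int(round(math.sqrt(rf.size)))
        if side * side != rf.size:
            raise ShapeError(f"flat RF length {rf.size} is not a perfect square")
        rf = rf.reshape(side, side)
    elif rf.ndim == 2 and rf.shape[0] == rf.shape[1]:
        side = rf.shape[0]
    else:
        raise ShapeError(f"RF must be square, got shape {rf.shape}")
    if not np.all(np.isfinite(rf)):
        raise ValidationError("RF contains non-finite values")
    if rf.std() < 1e-12:
        raise ValidationError("degenerate RF: zero variance")

    flat = rf.ravel()
    rng = np.random.default_rng(seed)
    best_vec = None
    best_sse = np.inf
    for start in _initial_guesses(rf, side, n_starts, rng):
        try:
            res = optimize.least_squares(
                lambda v: _gabor_from_vector(v, side).ravel() - flat,
                start,
                method="lm",
                max_nfev=4000,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(2 * res.cost)
        if sse < best_sse:
            best_sse = sse
            best_vec = res.x

    if best_vec is None:
        return GaborFit(
            amplitude=np.nan, x0=np.nan, y0=np.nan, orientation=np.nan,
            phase=np.nan, frequency=np.nan, sigma_x=np.nan, sigma_y=np.nan,
            mse=np.inf, converged=False, qc_pass=False, qc_reason="fit_failed",
        )

    a, x0, y0, ori, phi, f, log_sx, log_sy = best_vec
    params = canonical_parameters(
        {
            "amplitude": float(a),
            "x0": float(x0),
            "y0": float(y0),
            "orientation": float(ori),
            "phase": float(phi),
            "frequency": float(f),
            "sigma_x": math.exp(log_sx),
            "sigma_y": math.exp(log_sy),
        }
    )
    return GaborFit(mse=best_sse / flat.size, **params)


def canonical_parameters(params: dict[str, float]) -> dict[str, float]:
    """Map Gabor parameters to a canonical representative of their orbit.

    Applies the exact symmetries of the model: ``f -> -f`` with
    ``phi -> -phi``; ``orientation -> orientation - pi`` with
    ``phi -> -phi``; ``A -> -A`` with ``phi -> phi + pi``.  The canonical
    form has ``A >= 0``, ``f >= 0``, orientation in ``[0, pi)``, and phase
    in ``(-pi, pi]``.
    """
    p = dict(params)
    if p["frequency"] < 0:
        p["frequency"] = -p["frequency"]
        p["phase"] = -p["phase"]
    # Bring orientation into [0, pi): a pi shift flips x' -> -x', which
    # negates the sinusoid argument, so the phase flips sign.
    ori = p["orientation"] % (2 * np.pi)
    if ori >= np.pi:
        ori -= np.pi
        p["phase"] = -p["phase"]
    p["orientation"] = ori
    if p["amplitude"] < 0:
        p["amplitude"] = -p["amplitude"]
        p["phase"] = p["phase"] + np.pi
    p["phase"] = float((p["phase"] + np.pi) % (2 * np.pi) - np.pi)
    if p["phase"] == -np.pi:
        p["phase"] = np.pi
    return p


def gabor_quality_control(
    fit: GaborFit, patch_side: int, mse_threshold: float
) -> GaborFit:
    """Classify a fit as a usable Gabor description of the RF.

    A fit is rejected when (in order): the optimizer never converged; the
    residual ``mse`` exceeds ``mse_threshold`` (a signal-to-noise cut); the
    fitted center lies outside the patch; or the center lies within one
    envelope standard deviation of any patch edge.  The edge margin uses the
    rotated envelope's extent projected onto each image axis, so elongated
    oblique envelopes are cut symmetrically.  Returns a copy with
    ``qc_pass`` / ``qc_reason`` set.
    """
    fit = dataclasses.replace(fit)
    if not fit.converged:
        fit.qc_pass, fit.qc_reason = False, "fit_failed"
        return fit
    if not np.isfinite(fit.mse) or fit.mse > mse_threshold:
        fit.qc_pass, fit.qc_reason = False, "mse"
        return fit
    hi = patch_side - 1
    if not (0 <= fit.x0 <= hi and 0 <= fit.y0 <= hi):
        fit.qc_pass, fit.qc_reason = False, "center_outside"
        return fit
    c, s = math.cos(fit.orientation), math.sin(fit.orientation)
    extent_x = math.hypot(fit.sigma_x * c, fit.sigma_y * s)
    extent_y = math.hypot(fit.sigma_x * s, fit.sigma_y * c)
    if (
        fit.x0 < extent_x
        or fit.x0 > hi - extent_x
        or fit.y0 < extent_y
        or fit.y0 > hi - extent_y
    ):
        fit.qc_pass, fit.qc_reason = False, "edge_margin"
        return fit
    fit.qc_pass, fit.qc_reason = True, None
    return fit


def calibrate_mse_threshold(
    patch_side: int,
    rf_variance: float = 1.0,
    n_noise: int = 50,
    quantile: float = 0.05,
    margin: float = 0.5,
    seed: int = 0,
    n_starts: int = 4,
) -> float:
    """MSE cut calibrated on pure-noise receptive fields.

    Fits Gabors to ``n_noise`` white-noise RFs with the given pixel variance
    and places the cut at ``margin`` times a low quantile of their residual
    MSEs.  Fits to structureless RFs leave most of the variance unexplained,
    so their MSEs cluster just below the RF variance; a cut safely under the
    low tail of that distribution rejects essentially all noise RFs, while
    genuine Gabor-like RFs -- whose residual is only measurement noise --
    fall far below it.
    """
    rng = np.random.default_rng(seed)
    sd = math.sqrt(rf_variance)
    mses = []
    for i in range(n_noise):
        noise = rng.normal(0.0, sd, size=(patch_side, patch_side))
        fit = fit_gabor(noise, n_starts=n_starts, seed=int(rng.integers(2**31)))
        if np.isfinite(fit.mse):
            mses.append(fit.mse)
    if not mses:
        raise ValidationError("no noise fit converged; cannot calibrate")
    return float(margin * np.quantile(mses, quantile))
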