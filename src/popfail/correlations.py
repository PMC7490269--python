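"""Shift-predictor-corrected noise cross-correlograms and their metrics.

Repeated-trial spike rasters mix stimulus-locked ("signal") and trial-to-
trial ("noise") correlation.  The shift predictor isolates the stimulus-
locked part: cross-correlating cell A's response on repeat i with cell B's
response on a *different* repeat j destroys shared trial-to-trial noise but
keeps everything locked to the common stimulus.  Subtracting the shift
predictor (averaged over all ordered repeat pairs) from the raw CCF leaves
the noise CCF.  Correlation strength is quantified by the positive area,
width and zero-lag height of the central positive lobe, and the spatial
footprint of correlations over a population by fitting a * exp(-d / scale)
to positive area vs pair distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress
from scipy.stats import t as student_t

from .glm import SpikeRaster

__all__ = [
    "CCFResult",
    "CCFMetrics",
    "ccf_raw",
    "ccf_shuffled",
    "noise_ccf",
    "ccf_metrics",
    "fit_spatial_scale",
]


@dataclass
class CCFResult:
    lags: np.ndarray  # seconds, symmetric around 0
    raw: np.ndarray
    shuffled: np.ndarray
    pair_distance: float | None = None

    @property
    def noise(self) -> np.ndarray:
        return self.raw - self.shuffled


@dataclass
class CCFMetrics:
    positive_area: float
    full_width: float
    peak_height_0lag: float


def _prep(raster: SpikeRaster, bin_width: float) -> np.ndarray:
    rb = raster if abs(raster.dt - bin_width) < 1e-12 else raster.rebin(bin_width)
    return rb.counts.astype(float)


def _xcov_sum(a: np.ndarray, b: np.ndarray, max_bins: int) -> np.ndarray:
    """sum_t a(t) b(t+lag) for lag in [-max_bins, max_bins], via FFT."""
    n = a.shape[-1]
    full = np.fft.irfft(
        np.conj(np.fft.rfft(a, 2 * n)) * np.fft.rfft(b, 2 * n), 2 * n
    )
    # full[lag] for lag >= 0; full[2n - m] holds lag -m, so the last max_bins
    # entries are lags -max_bins..-1 in increasing order
    pos = full[..., : max_bins + 1]
    neg = full[..., -max_bins:]
    return np.concatenate([neg, pos], axis=-1)


def _ccf_parts(counts: np.ndarray, cell_a: int, cell_b: int, max_bins: int):
    """Trial-mean-subtracted per-trial traces and the shared normalizer."""
    xa = counts[:, cell_a, :]
    xb = counts[:, cell_b, :]
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    n_bins = xa.shape[1]
    var_a = (xa ** 2).sum(axis=1).mean() / n_bins
    var_b = (xb ** 2).sum(axis=1).mean() / n_bins
    if var_a == 0 or var_b == 0:
        raise ValueError("silent cell: zero variance, CCF undefined")
    norm = n_bins * np.sqrt(var_a * var_b)
    return xa, xb, norm


def ccf_raw(
    raster: SpikeRaster,
    cell_a: int,
    cell_b: int,
    max_lag: float = 0.2,
    bin_width: float = 0.005,
) -> np.ndarray:
    """Trial-averaged cross-covariance, normalized by the geometric mean of the
    zero-lag autocovariances (coefficient normalization)."""
    counts = _prep(raster, bin_width)
    if counts.shape[0] < 1:
        raise ValueError("need at least one trial")
    max_bins = int(round(max_lag / bin_width))
    xa, xb, norm = _ccf_parts(counts, cell_a, cell_b, max_bins)
    cc = _xcov_sum(xa, xb, max_bins).mean(axis=0)
    return cc / norm


def ccf_shuffled(
    raster: SpikeRaster,
    cell_a: int,
    cell_b: int,
    max_lag: float = 0.2,
    bin_width: float = 0.005,
) -> np.ndarray:
    """Shift predictor: cross-trial CCF averaged over ALL ordered repeat pairs.

    Uses the identity sum_{i != j} x_i * y_j = (sum_i x_i) * (sum_j y_j)
    - sum_i x_i * y_i, so every ordered pair is included exactly at O(n) cost.
    """
    counts = _prep(raster, bin_width)
    n_trials = counts.shape[0]
    if n_trials < 2:
        raise ValueError("shift predictor needs at least two repeats")
    max_bins = int(round(max_lag / bin_width))
    xa, xb, norm = _ccf_parts(counts, cell_a, cell_b, max_bins)
    total = _xcov_sum(xa.sum(axis=0), xb.sum(axis=0), max_bins)
    same = _xcov_sum(xa, xb, max_bins).sum(axis=0)
    cc = (total - same) / (n_trials * (n_trials - 1))
    return cc / norm


def noise_ccf(
    raster: SpikeRaster,
    cell_a: int,
    cell_b: int,
    max_lag: float = 0.2,
    bin_width: float = 0.005,
    pair_distance: float | None = None,
) -> CCFResult:
    """Raw minus shift predictor, bundled with its lag axis."""
    raw = ccf_raw(raster, cell_a, cell_b, max_lag, bin_width)
    shuf = ccf_shuffled(raster, cell_a, cell_b, max_lag, bin_width)
    max_bins = int(round(max_lag / bin_width))
    lags = np.arange(-max_bins, max_bins + 1) * bin_width
    if pair_distance is None and raster.cell_positions is not None:
        pair_distance = float(
            np.linalg.norm(
                raster.cell_positions[cell_a] - raster.cell_positions[cell_b]
            )
        )
    return CCFResult(lags=lags, raw=raw, shuffled=shuf, pair_distance=pair_distance)


def ccf_metrics(noise: np.ndarray, lags: np.ndarray) -> CCFMetrics:
    """Central positive lobe of a noise CCF: area, width, zero-lag height.

    The lobe is the contiguous run of positive values containing lag zero;
    if the zero-lag value is not positive, area and width are zero (negative
    lobes are not quantified).
    """
    noise = np.asarray(noise, dtype=float)
    bin_width = float(lags[1] - lags[0])
    i0 = int(np.argmin(np.abs(lags)))
    peak = float(noise[i0])
    if peak <= 0:
        return CCFMetrics(0.0, 0.0, peak)
    lo = i0
    while lo > 0 and noise[lo - 1] > 0:
        lo -= 1
    hi = i0
    while hi < len(noise) - 1 and noise[hi + 1] > 0:
        hi += 1
    area = float(noise[lo : hi + 1].sum() * bin_width)
    width = float((hi - lo + 1) * bin_width)
    return CCFMetrics(positive_area=area, full_width=width, peak_height_0lag=peak)


def fit_spatial_scale(
    pair_distances: np.ndarray, positive_areas: np.ndarray, confidence: float = 0.95
):
    """Fit a*exp(-d/scale) to pair areas; returns (scale, (ci_lo, ci_hi)).

    The fit is a log-linear regression log(area) = log(a) - d/scale on the
    positive areas.  CCF-area noise is approximately multiplicative, so the
    log model is homoscedastic and the standard t-based CI on the slope is
    well calibrated; the slope interval maps monotonically onto the scale
    interval.  Requires >= 5 pairs at >= 2 distinct distances.  If the data
    do not decay significantly with distance, a warning is issued and the
    interval is unbounded above.
    """
    d = np.asarray(pair_distances, dtype=float)
    y = np.asarray(positive_areas, dtype=float)
    if len(d) < 5 or len(np.unique(d)) < 2:
        raise ValueError("need >= 5 pairs spanning >= 2 distinct distances")

    pos = y > 0
    if pos.sum() < 5 or len(np.unique(d[pos])) < 2:
        warnings.warn(
            "too few positive areas; spatial-scale fit poorly constrained"
        )
        return np.inf, (0.0, np.inf)

    res = linregress(d[pos], np.log(y[pos]))
    dof = max(int(pos.sum()) - 2, 1)
    tcrit = student_t.ppf(0.5 + confidence / 2.0, dof)
    s_lo = res.slope - tcrit * res.stderr
    s_hi = res.slope + tcrit * res.stderr
    if res.slope >= 0 or s_hi >= 0:
        warnings.warn(
            "spatial-scale fit poorly constrained (non-decaying data?)"
        )
        scale = float(-1.0 / res.slope) if res.slope < 0 else np.inf
        lo = float(-1.0 / s_lo) if s_lo < 0 else 0.0
        return scale, (min(lo, 0.0) if not np.isfinite(scale) else lo, np.inf)
    scale = float(-1.0 / res.slope)
    return scale, (float(-1.0 / s_lo), float(-1.0 / s_hi))
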