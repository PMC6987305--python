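"""Spike-train and astrocyte-activity analysis.

Provides the cumulative-moving-average (CMA) burst detector, pooled
activity spectra with border-corrected Gaussian smoothing, normalized
cross-correlation between smoothed neuronal and astrocytic activities,
and the astrocyte activation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "Burst",
    "BurstFeatures",
    "SpectrumResult",
    "CrossCorrResult",
    "cma_isi_threshold",
    "detect_bursts_cma",
    "burst_features",
    "gaussian_smooth",
    "smooth_activity",
    "pooled_spectrum",
    "band_ratio",
    "cross_correlation",
    "activation_ratio",
]

# Skewness -> alpha1 lookup of the CMA burst detector: the more skewed the
# CMA curve of the ISI histogram, the further below its maximum the burst
# threshold is placed.  Entries are (skewness upper bound, alpha1).
DEFAULT_SKEW_ALPHA = ((1.0, 1.0), (4.0, 0.7), (9.0, 0.5), (np.inf, 0.3))


@dataclass(frozen=True)
class Burst:
    start: float      # s, time of first spike
    end: float        # s, time of last spike
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BurstFeatures:
    """Network-averaged spike/burst features (per-neuron means)."""

    spike_rate: float        # spikes/min
    burst_rate: float        # bursts/min
    spikes_per_burst: float  # mean spikes per burst (0 when no bursts)
    burst_duration_ms: float  # mean burst duration (0 when no bursts)


def cma_isi_threshold(isi, bin_width: float = 0.005,
                      skew_alpha=DEFAULT_SKEW_ALPHA,
                      alpha1: float | None = None) -> float:
    """Burst ISI threshold from the CMA curve of the ISI histogram.

    The interspike-interval histogram is summarised by its cumulative
    moving average curve CMA(k) = mean(h[0..k]).  The threshold is the
    upper edge of the first bin past the CMA maximum where the curve has
    fallen below alpha1 * max(CMA); alpha1 is selected from the skewness
    of the CMA curve via ``skew_alpha`` (or fixed explicitly).
    """
    isi = np.asarray(isi, dtype=float)
    if len(isi) == 0:
        raise ValueError("at least one interspike interval is required")
    n_bins = max(int(np.ceil(isi.max() / bin_width)), 1)
    hist, _ = np.histogram(isi, bins=n_bins, range=(0.0, n_bins * bin_width))
    cma = np.cumsum(hist) / np.arange(1, n_bins + 1)
    if alpha1 is None:
        skew = stats.skew(cma) if len(cma) > 1 else 0.0
        for bound, a in skew_alpha:
            if skew < bound:
                alpha1 = a
                break
    peak = int(np.argmax(cma))
    below = np.nonzero(cma[peak + 1:] < alpha1 * cma[peak])[0]
    threshold_bin = peak + 1 + below[0] if len(below) else n_bins - 1
    return (threshold_bin + 1) * bin_width


def detect_bursts_cma(spike_times, bin_width: float = 0.005,
                      min_spikes: int = 3,
                      skew_alpha=DEFAULT_SKEW_ALPHA,
                      alpha1: float | None = None) -> list[Burst]:
    """CMA burst detection on a single spike train.

    Runs of consecutive spikes with ISI below the CMA threshold (see
    :func:`cma_isi_threshold`) and at least ``min_spikes`` spikes form
    bursts.  An empty or too-short train yields no bursts.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if len(t) < min_spikes:
        return []
    isi = np.diff(t)
    threshold = cma_isi_threshold(isi, bin_width, skew_alpha, alpha1)

    in_burst = isi <= threshold
    bursts: list[Burst] = []
    start = 0
    for i in range(len(isi) + 1):
        if i == len(isi) or not in_burst[i]:
            count = i - start + 1
            if count >= min_spikes:
                bursts.append(Burst(t[start], t[i], count))
            start = i + 1
    return bursts


def burst_features(trains, t_total: float,
                   bursts: list[list[Burst]] | None = None,
                   **detector_kwargs) -> BurstFeatures:
    """Per-neuron spike/burst features averaged over the network.

    ``trains`` is a sequence of spike-time arrays (one per neuron);
    ``bursts`` may hold pre-detected bursts per train, otherwise the CMA
    detector is run with ``detector_kwargs``.
    """
    if bursts is None:
        bursts = [detect_bursts_cma(t, **detector_kwargs) for t in trains]
    n = len(trains)
    if n == 0:
        return BurstFeatures(0.0, 0.0, 0.0, 0.0)
    spike_rate = 60.0 * np.mean([len(t) for t in trains]) / t_total
    burst_rate = 60.0 * np.mean([len(b) for b in bursts]) / t_total
    all_bursts = [b for bl in bursts for b in bl]
    if all_bursts:
        spb = float(np.mean([b.n_spikes for b in all_bursts]))
        dur = 1000.0 * float(np.mean([b.duration for b in all_bursts]))
    else:
        spb = dur = 0.0
    return BurstFeatures(spike_rate, burst_rate, spb, dur)


# ---------------------------------------------------------------------------
# smoothing, spectra, cross-correlation
# ---------------------------------------------------------------------------

def gaussian_smooth(values, step: float, width: float) -> np.ndarray:
    """Gaussian kernel smoothing with border correction.

    The kernel is renormalised at every point by its mass falling inside
    the observed grid (normalized convolution), so constants are preserved
    exactly, including at the borders.
    """
    values = np.asarray(values, dtype=float)
    half = max(int(np.ceil(4.0 * width / step)), 1)
    kernel = np.exp(-(np.arange(-half, half + 1) * step) ** 2
                    / (2.0 * width ** 2))
    num = signal.fftconvolve(values, kernel, mode="same")
    den = signal.fftconvolve(np.ones_like(values), kernel, mode="same")
    return num / den


def smooth_activity(series, dt: float, rho: float = 3.0) -> np.ndarray:
    """Smooth a pooled activity series with a Gaussian of width rho (s)."""
    return gaussian_smooth(series, dt, rho)


@dataclass(frozen=True)
class SpectrumResult:
    frequencies: np.ndarray   # Hz
    raw: np.ndarray           # run-averaged DFT moduli
    smoothed: np.ndarray      # border-corrected Gaussian smoothing
    sigma: float              # smoothing width, Hz
    bands: tuple = ((0.01, 0.1), (1.0, 10.0))
    band_averages: tuple[float, float] = (0.0, 0.0)


def pooled_spectrum(pooled_runs, dt: float, sigma: float = 0.025,
                    bands=((0.01, 0.1), (1.0, 10.0))) -> SpectrumResult:
    """Run-averaged, smoothed amplitude spectrum of pooled spike counts.

    Each run's pooled count series is mean-centred, Fourier transformed,
    and reduced to DFT moduli; moduli are averaged across runs and then
    smoothed with a border-corrected Gaussian kernel of width ``sigma``.
    """
    pooled_runs = [np.asarray(p, dtype=float) for p in pooled_runs]
    if not pooled_runs:
        raise ValueError("at least one run is required")
    n = len(pooled_runs[0])
    if any(len(p) != n for p in pooled_runs):
        raise ValueError("all runs must have equal length")
    moduli = [np.abs(np.fft.rfft(p - p.mean())) for p in pooled_runs]
    raw = np.mean(moduli, axis=0)
    freqs = np.fft.rfftfreq(n, dt)
    df = freqs[1] - freqs[0]
    smoothed = gaussian_smooth(raw, df, sigma)
    averages = []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs <= hi)
        if not np.any(mask):
            raise ValueError(f"band ({lo}, {hi}) Hz outside the frequency grid")
        averages.append(float(smoothed[mask].mean()))
    return SpectrumResult(freqs, raw, smoothed, sigma, tuple(bands),
                          tuple(averages))


def band_ratio(spectrum: SpectrumResult) -> float:
    """Ratio of the second band average to the first (1-10 Hz over
    0.01-0.1 Hz with the default bands)."""
    low, high = spectrum.band_averages
    if low == 0:
        raise ValueError("low band average is zero")
    return high / low


@dataclass(frozen=True)
class CrossCorrResult:
    lags: np.ndarray     # s; positive lag = second series delayed
    values: np.ndarray   # correlation coefficients in [-1, 1]


def cross_correlation(x, y, dt: float, max_lag: float) -> CrossCorrResult:
    """Normalized cross-correlation r(k) = corr(x_t, y_{t+k}).

    A maximum at positive lag means features of ``y`` follow features of
    ``x`` by that delay.  Normalization uses the full-sample standard
    deviations, so |r| <= 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    x0 = x - x.mean()
    y0 = y - y.mean()
    denom = n * x0.std() * y0.std()
    if denom == 0:
        raise ValueError("cross-correlation undefined for constant series")
    full = signal.correlate(y0, x0, mode="full", method="fft")
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= int(round(max_lag / dt))
    return CrossCorrResult(lags[keep] * dt, full[keep] / denom)


def run_averaged_cross_correlation(pairs, dt: float,
                                   max_lag: float) -> CrossCorrResult:
    """Average the normalized cross-correlation over (neuronal, astro)
    series pairs from repeated runs."""
    results = [cross_correlation(x, y, dt, max_lag) for x, y in pairs]
    return CrossCorrResult(results[0].lags,
                           np.mean([r.values for r in results], axis=0))


def activation_ratio(active_counts, n_astrocytes: int, tau_a: float = 1.5,
                     tau_r: float = 7.0, tau_u: float = 5.0) -> float:
    """Mean fraction of active astrocytes, normalized so that continuous
    U -> A -> R cycling yields 1.

    The mean dwell time in the active state is tau_R (the A -> R transition
    fires with probability dt/tau_R per bin), so an always-cycling astrocyte
    is active for a fraction tau_R / (tau_A + tau_R + tau_U) of the time and

        AR = (<B> / n_A) * (tau_A + tau_R + tau_U) / tau_R.
    """
    if n_astrocytes <= 0:
        raise ValueError("n_astrocytes must be positive")
    mean_active = float(np.mean(active_counts))
    return (mean_active / n_astrocytes) * (tau_a + tau_r + tau_u) / tau_r
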