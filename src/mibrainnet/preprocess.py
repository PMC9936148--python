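"""Band selection via R-squared maps, zero-phase bandpass filtering, and
wavelet soft-threshold denoising.

The R² map scores every (channel, frequency band) cell by the squared
Pearson correlation between log band power and the class label, maximized
over one-vs-rest dichotomies; the band whose cells concentrate the
discriminative mass is then used for band-pass filtering. Denoising follows
the VisuShrink recipe: multilevel DWT, soft-threshold the detail
coefficients at the universal threshold, reconstruct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._wavelets import dwt_max_level, soft_threshold, wavedec, waverec, _filters_for
from .epochs import EpochSet

__all__ = ["R2Map", "compute_r2_map", "suggest_band", "bandpass", "wavelet_denoise", "default_band_edges"]


@dataclass
class R2Map:
    """Channel x band table of squared label/band-power correlations."""

    values: np.ndarray  # (n_channels, n_bands), each in [0, 1]
    band_edges: list[tuple[float, float]]
    channel_names: list[str]


def default_band_edges(fs: float, width: float = 4.0) -> list[tuple[float, float]]:
    """Contiguous bands of ``width`` Hz from 0.5 Hz up to Nyquist."""
    edges = []
    low = 0.5
    while low + width <= fs / 2:
        edges.append((low, low + width))
        low += width
    return edges


def _band_log_power(epochs: EpochSet, band_edges: list[tuple[float, float]]) -> np.ndarray:
    """Per (trial, channel, band) log band power from a Welch PSD.

    Welch with 1-second windows and 50% overlap; band power is the PSD
    integrated over the band's frequency bins.
    """
    nperseg = min(int(epochs.fs), epochs.n_samples)
    freqs, psd = sps.welch(
        epochs.data, fs=epochs.fs, nperseg=nperseg, noverlap=nperseg // 2, axis=2
    )
    power = np.empty(epochs.data.shape[:2] + (len(band_edges),))
    for b, (lo, hi) in enumerate(band_edges):
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"empty band ({lo}, {hi}) Hz at fs={epochs.fs}")
        power[:, :, b] = np.trapezoid(psd[:, :, mask], freqs[mask], axis=2)
    return np.log(power + np.finfo(float).tiny)


def compute_r2_map(epochs: EpochSet, band_edges: list[tuple[float, float]] | None = None) -> R2Map:
    """Score every channel/band cell by label-discriminative power.

    For each cell the per-trial log band power is correlated with each
    one-vs-rest binary labeling; the cell value is the maximum squared
    Pearson correlation over those dichotomies, in [0, 1].
    """
    classes = epochs.classes
    if classes.size < 2:
        raise ValueError("compute_r2_map needs at least two classes")
    if band_edges is None:
        band_edges = default_band_edges(epochs.fs)
    if not band_edges:
        raise ValueError("no frequency bands given")
    for lo, hi in band_edges:
        if not 0 < lo < hi < epochs.fs / 2:
            raise ValueError(f"band ({lo}, {hi}) outside (0, fs/2)")
    logp = _band_log_power(epochs, band_edges)  # (trials, channels, bands)
    x = logp - logp.mean(axis=0)
    x_sd = x.std(axis=0)
    values = np.zeros(logp.shape[1:])
    for c in classes:
        y = (epochs.labels == c).astype(float)
        y = y - y.mean()
        y_sd = y.std()
        if y_sd == 0:
            continue
        r = (x * y[:, None, None]).mean(axis=0) / np.where(x_sd > 0, x_sd * y_sd, np.inf)
        values = np.maximum(values, r**2)
    return R2Map(values, list(band_edges), list(epochs.channel_names))


def suggest_band(r2map: R2Map, coverage: float = 0.8) -> tuple[float, float]:
    """Smallest contiguous run of bands holding >= ``coverage`` of the r² mass.

    Deterministic: among runs of equal length the leftmost wins. Returns the
    (low, high) Hz endpoints of the run.
    """
    mass = r2map.values.sum(axis=0)
    total = mass.sum()
    n = mass.size
    if total <= 0:  # featureless map: return the full range
        return r2map.band_edges[0][0], r2map.band_edges[-1][1]
    target = coverage * total
    best: tuple[int, int] | None = None
    for width in range(1, n + 1):
        for start in range(0, n - width + 1):
            if mass[start:start + width].sum() >= target - 1e-12:
                best = (start, start + width - 1)
                break
        if best is not None:
            break
    assert best is not None
    return r2map.band_edges[best[0]][0], r2map.band_edges[best[1]][1]


def bandpass(epochs: EpochSet, low: float, high: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass applied per channel per trial."""
    nyq = epochs.fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for fs={epochs.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=epochs.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, epochs.data, axis=2)
    return epochs.with_data(filtered, f"bandpass({low}-{high} Hz)")


def wavelet_denoise(epochs: EpochSet, wavelet_name: str = "db10", level: int = 3) -> EpochSet:
    """Soft-threshold wavelet denoising, channel by channel.

    Details below the universal threshold sigma * sqrt(2 ln N) are zeroed
    and larger ones shrunk toward zero; sigma is the robust MAD estimate
    median(|D1|)/0.6745 from the finest detail level.
    """
    h, _ = _filters_for(wavelet_name)
    max_lvl = dwt_max_level(epochs.n_samples, h.size)
    if level < 1 or level > max_lvl:
        raise ValueError(
            f"denoise level {level} infeasible for {epochs.n_samples} samples "
            f"with {wavelet_name}; maximum feasible level is {max_lvl}"
        )
    out = np.empty_like(epochs.data)
    n = epochs.n_samples
    for t in range(epochs.n_trials):
        for ch in range(epochs.n_channels):
            coeffs = wavedec(epochs.data[t, ch], wavelet_name, level)
            sigma = np.median(np.abs(coeffs[-1])) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(n))
            coeffs = [coeffs[0]] + [soft_threshold(d, thr) for d in coeffs[1:]]
            out[t, ch] = waverec(coeffs, wavelet_name)[:n]
    return epochs.with_data(out, f"wavelet_denoise({wavelet_name}, level={level})")
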