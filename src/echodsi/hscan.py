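"""H-scan matched-filter analysis.

A bank of Gaussian bandpass filters (default 256, peak frequencies equally
spaced from 5.2 to 12.4 MHz) is applied to each scanline in the frequency
domain. Each RF sample is assigned the index of the filter whose output
envelope is largest there; that index (the "color level" C, 1..n_filters)
encodes the local spectral content: low C = low-frequency, large-scatterer
echoes; high C = high-frequency content.

Filters are normalized to unit spectral energy so that the argmax is a
matched-filter comparison and not biased by bandwidth, and the comparison
uses the magnitude of the filtered analytic signal (the raw filtered RF
oscillates through zero, which would make a per-sample argmax ill-defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import RFFrame


@dataclass
class GaussianFilterBank:
    peak_freqs: np.ndarray  # MHz, strictly increasing
    sigma_f: float  # MHz, common spectral std

    def __post_init__(self):
        self.peak_freqs = np.asarray(self.peak_freqs, dtype=float)
        if self.peak_freqs.size < 2 or np.any(np.diff(self.peak_freqs) <= 0):
            raise ValueError("peak frequencies must be strictly increasing, n >= 2")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")

    @property
    def n_filters(self) -> int:
        return self.peak_freqs.size

    @property
    def spacing(self) -> float:
        return float(self.peak_freqs[1] - self.peak_freqs[0])

    def spectral_windows(self, freqs: np.ndarray) -> np.ndarray:
        """Unit-energy Gaussian windows evaluated on ``freqs``, [n_filters, n_freqs].

        Energy is normalized discretely on the given frequency grid so that
        ``sum |H|^2 df = 1`` for every filter.
        """
        freqs = np.asarray(freqs, dtype=float)
        df = freqs[1] - freqs[0]
        h = np.exp(-((freqs[None, :] - self.peak_freqs[:, None]) ** 2) / (2 * self.sigma_f**2))
        energy = np.sum(h**2, axis=1) * df
        return h / np.sqrt(energy[:, None])


def build_filter_bank(
    f_lo: float = 5.2, f_hi: float = 12.4, n: int = 256, sigma_f: float = 1.0
) -> GaussianFilterBank:
    """Build the Gaussian matched-filter bank with equally spaced peaks."""
    if not (f_hi > f_lo > 0):
        raise ValueError("need f_hi > f_lo > 0")
    if n < 2:
        raise ValueError("need at least two filters")
    return GaussianFilterBank(peak_freqs=np.linspace(f_lo, f_hi, n), sigma_f=sigma_f)


@dataclass
class HScanMap:
    """Per-pixel color level C in {1, ..., n_filters}."""

    color_level: np.ndarray  # int array [n_samples, n_lines]
    n_filters: int

    def __post_init__(self):
        c = np.asarray(self.color_level)
        if c.size and (c.min() < 1 or c.max() > self.n_filters):
            raise ValueError("color levels out of range")


def hscan_color_map(
    frame: RFFrame, bank: GaussianFilterBank, chunk: int = 32
) -> HScanMap:
    """Assign each pixel the index of the best-matching Gaussian filter.

    The frame should already be attenuation-corrected by the caller. Ties at
    the argmax break toward the lower filter index. Filters are applied in
    chunks to bound memory.
    """
    nyquist = frame.fs / 2.0
    if bank.peak_freqs[-1] >= nyquist:
        raise ValueError(
            f"filter peak {bank.peak_freqs[-1]:.2f} MHz at or above Nyquist {nyquist:.2f} MHz"
        )
    x = frame.samples
    n = x.shape[0]
    spec = np.fft.fft(x, axis=0)
    freqs = np.fft.fftfreq(n, d=1.0 / frame.fs)
    # analytic-signal construction: keep positive frequencies, doubled
    analytic_weight = np.zeros(n)
    analytic_weight[0] = 1.0
    if n % 2 == 0:
        analytic_weight[1 : n // 2] = 2.0
        analytic_weight[n // 2] = 1.0
    else:
        analytic_weight[1 : (n + 1) // 2] = 2.0
    pos = freqs >= 0
    # Gaussian windows on the positive-frequency half, unit energy there
    grid = np.abs(freqs)
    best_val = np.full(x.shape, -np.inf)
    best_idx = np.zeros(x.shape, dtype=np.int32)
    df = frame.fs / n
    for start in range(0, bank.n_filters, chunk):
        peaks = bank.peak_freqs[start : start + chunk]
        h = np.exp(-((grid[None, :] - peaks[:, None]) ** 2) / (2 * bank.sigma_f**2))
        h[:, ~pos] = 0.0
        energy = np.sum(h**2, axis=1) * df
        h /= np.sqrt(energy[:, None])
        for j in range(h.shape[0]):
            filt_spec = spec * (h[j] * analytic_weight)[:, None]
            mag = np.abs(np.fft.ifft(filt_spec, axis=0))
            better = mag > best_val  # strict: ties keep the lower index
            best_val[better] = mag[better]
            best_idx[better] = start + j
    return HScanMap(color_level=best_idx + 1, n_filters=bank.n_filters)


def hscan_features(hmap: HScanMap, mask: np.ndarray) -> dict:
    """Mean and standard deviation of the color level over lesion pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hmap.color_level.shape:
        raise ValueError("mask shape does not match the color map")
    if not mask.any():
        raise ValueError("empty lesion mask")
    vals = hmap.color_level[mask].astype(float)
    return {
        "hscan_color_level": float(vals.mean()),
        "hscan_std": float(vals.std()),
    }
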