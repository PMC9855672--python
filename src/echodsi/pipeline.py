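"""RF -> envelope -> log-compressed B-mode, and zone-wise attenuation compensation.

The compensation multiplies the spectrum of each of ``n_zones`` contiguous
axial blocks by a scalar gain ``exp(alpha' * f0 * x_z)``, where ``x_z`` is the
mean depth of zone ``z`` in cm, ``f0`` the center frequency in MHz, and
``alpha'`` the attenuation coefficient converted from dB.MHz^-1.cm^-1 to
nepers via ``alpha * ln(10)/20``. An optional frequency-dependent mode
replaces the scalar ``f0`` by the spectral frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .frames import BModeImage, EnvelopeFrame, RFFrame

DB_TO_NEPER = np.log(10.0) / 20.0


def rf_to_envelope(frame: RFFrame) -> EnvelopeFrame:
    """Detect the echo envelope as the per-scanline analytic-signal magnitude.

    IQ demodulation followed by magnitude detection is equivalent, up to the
    demodulation carrier, to the Hilbert-transform analytic signal used here.
    """
    if not np.all(np.isfinite(frame.samples)):
        raise ValueError("RF frame contains non-finite samples")
    env = np.abs(hilbert(frame.samples, axis=0))
    return EnvelopeFrame(
        amplitudes=env,
        fs=frame.fs,
        f0=frame.f0,
        axial_pitch=frame.axial_pitch,
        lateral_pitch=frame.lateral_pitch,
    )


def log_compress(env: EnvelopeFrame, dynamic_range: float = 60.0) -> BModeImage:
    """Log-compress an envelope to an 8-bit B-mode image.

    ``20 log10(A / A_max)`` is clipped to ``[-dynamic_range, 0]`` dB and
    mapped linearly onto ``[0, 255]``; the frame maximum always maps to 255.
    """
    a = np.asarray(env.amplitudes, dtype=float)
    a_max = a.max()
    if a_max <= 0:
        raise ValueError("cannot log-compress an all-zero envelope")
    if dynamic_range <= 0:
        raise ValueError("dynamic range must be positive")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(a / a_max)
    db = np.clip(db, -dynamic_range, 0.0)
    intensity = 255.0 * (1.0 + db / dynamic_range)
    return BModeImage(
        intensity=intensity,
        dynamic_range=dynamic_range,
        axial_pitch=env.axial_pitch,
        lateral_pitch=env.lateral_pitch,
    )


@dataclass
class AttenuationConfig:
    """Zone model for depth attenuation compensation.

    alpha : dB per MHz per cm; f0 : MHz; n_zones : contiguous axial blocks.
    """

    alpha: float = 1.0
    f0: float = 9.4
    n_zones: int = 10
    frequency_dependent: bool = False

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("attenuation coefficient must be nonnegative")
        if self.n_zones < 1:
            raise ValueError("need at least one depth zone")


def _zone_slices(n_samples: int, n_zones: int):
    """Equal-length contiguous blocks; remainder samples go to the deepest zone."""
    size = n_samples // n_zones
    if size < 1:
        raise ValueError(f"{n_samples} samples cannot be split into {n_zones} zones")
    slices = []
    for z in range(n_zones):
        lo = z * size
        hi = (z + 1) * size if z < n_zones - 1 else n_samples
        slices.append(slice(lo, hi))
    return slices


def attenuation_correct(frame: RFFrame, cfg: AttenuationConfig | None = None) -> RFFrame:
    """Apply the zone-wise exponential gain compensating depth attenuation.

    With ``alpha = 0`` the input is returned unchanged (to machine precision).
    """
    if cfg is None:
        cfg = AttenuationConfig()
    if cfg.alpha == 0:
        return frame.with_samples(frame.samples.copy())
    out = np.empty_like(frame.samples)
    slices = _zone_slices(frame.n_samples, cfg.n_zones)
    depth_cm = frame.depth_mm() / 10.0
    for sl in slices:
        x_z = depth_cm[sl].mean()
        block = frame.samples[sl]
        spec = np.fft.rfft(block, axis=0)
        if cfg.frequency_dependent:
            freqs = np.fft.rfftfreq(block.shape[0], d=1.0 / frame.fs)
            gain = np.exp(DB_TO_NEPER * cfg.alpha * freqs * x_z)[:, None]
        else:
            gain = np.exp(DB_TO_NEPER * cfg.alpha * cfg.f0 * x_z)
        out[sl] = np.fft.irfft(spec * gain, n=block.shape[0], axis=0)
    return frame.with_samples(out)


def zone_gains(frame: RFFrame, cfg: AttenuationConfig) -> np.ndarray:
    """Scalar amplitude gain applied to each zone (diagnostic helper)."""
    slices = _zone_slices(frame.n_samples, cfg.n_zones)
    depth_cm = frame.depth_mm() / 10.0
    return np.array(
        [np.exp(DB_TO_NEPER * cfg.alpha * cfg.f0 * depth_cm[sl].mean()) for sl in slices]
    )
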