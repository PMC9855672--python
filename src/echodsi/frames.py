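"""Core image containers: RF frames, envelope frames, B-mode images.

Coordinate convention used throughout the package: arrays are indexed
``[axial_sample, scanline]`` (row = depth, column = lateral position),
0-based. Contours and masks share this convention with ``x`` = column
(scanline index) and ``y`` = row (axial sample index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

#: Speed of sound used for all depth <-> time conversions, mm/us.
SOUND_SPEED_MM_US = 1.540


@dataclass
class RFFrame:
    """Raw beamformed echo samples with acquisition metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_lines)
        Real-valued RF echo samples, rows are depth.
    fs : float
        Sampling frequency in MHz.
    f0 : float
        Transmit center frequency in MHz.
    axial_pitch : float
        Depth increment per sample in mm (``c / (2 fs)`` for pulse-echo).
    lateral_pitch : float
        Lateral spacing between scanlines in mm.
    """

    samples: np.ndarray
    fs: float
    f0: float
    axial_pitch: float
    lateral_pitch: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D array [n_samples, n_lines]")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def depth_mm(self) -> np.ndarray:
        """Depth of each axial sample in mm."""
        return np.arange(self.n_samples) * self.axial_pitch

    def with_samples(self, samples: np.ndarray) -> "RFFrame":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class EnvelopeFrame:
    """Nonnegative echo-amplitude (envelope) frame, same grid as its RF source."""

    amplitudes: np.ndarray
    fs: float
    f0: float
    axial_pitch: float
    lateral_pitch: float

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("envelope amplitudes must be nonnegative")


@dataclass
class BModeImage:
    """Log-compressed envelope mapped to 8-bit display range [0, 255]."""

    intensity: np.ndarray
    dynamic_range: float
    axial_pitch: float = 1.0
    lateral_pitch: float = 1.0

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.min() < 0 or self.intensity.max() > 255:
            raise ValueError("B-mode intensities must lie in [0, 255]")


def save_rf_hdf5(frame: RFFrame, path: str | Path, seed: int | None = None) -> None:
    """Write RF samples to HDF5 (`/rf`, float32) with a JSON metadata sidecar."""
    path = Path(path)
    # on disk lines are rows ([n_lines, n_samples]); in memory rows are depth
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=frame.samples.T.astype(np.float32))
    sidecar = {
        "fs_MHz": frame.fs,
        "f0_MHz": frame.f0,
        "axial_pitch_mm": frame.axial_pitch,
        "lateral_pitch_mm": frame.lateral_pitch,
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_rf_hdf5(path: str | Path) -> RFFrame:
    """Read an RF frame written by :func:`save_rf_hdf5`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        samples = np.asarray(f["rf"], dtype=float).T
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RFFrame(
        samples=samples,
        fs=meta["fs_MHz"],
        f0=meta["f0_MHz"],
        axial_pitch=meta["axial_pitch_mm"],
        lateral_pitch=meta["lateral_pitch_mm"],
        meta={k: v for k, v in meta.items() if k == "seed"},
    )
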