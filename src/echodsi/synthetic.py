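"""Seeded synthetic RF cohorts with controllable biophysical structure.

The simulator is deliberately simple — a 1-D per-scanline convolution of a
Gaussian-modulated cosine pulse with a random scatterer train, followed by
zone-wise frequency-dependent attenuation and additive noise — but it
reproduces the statistical structure the downstream feature extractors
assume:

* dense random scatterers give fully developed speckle (Rayleigh envelope);
* the lesion interior carries its own pulse spectrum (spectral content),
  echogenicity ratio, and heavy-tailed Burr-distributed reflectivities;
* the lesion boundary is an ellipse radially perturbed by smoothed noise
  whose amplitude directly controls the convex-hull roughness dA/A;
* depth attenuation follows exp(-alpha * f * x) with alpha in dB/MHz/cm.

No diffraction, beamforming or transducer model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import fftconvolve, gausspulse
from shapely import contains_xy
from shapely.geometry import Polygon

from .burr import burr_sample
from .frames import SOUND_SPEED_MM_US, RFFrame
from .morphology import LesionContour
from .pipeline import DB_TO_NEPER, _zone_slices

_MAX_CONTOUR_RETRIES = 25


@dataclass
class ScattererField:
    """Point scatterers inside a rectangular region.

    positions : [n, 2] array of (axial_mm, lateral_mm); amplitudes unitless.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    region_size: tuple[float, float]  # (depth_mm, width_mm)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("scatterer amplitudes must be finite")
        d, w = self.region_size
        if self.positions.size and (
            self.positions[:, 0].min() < 0
            or self.positions[:, 0].max() > d
            or self.positions[:, 1].min() < 0
            or self.positions[:, 1].max() > w
        ):
            raise ValueError("scatterer positions outside the region")


@dataclass
class Pulse:
    """Gaussian-modulated cosine excitation pulse."""

    f0: float = 9.4  # MHz
    fractional_bandwidth: float = 0.6
    fs: float = 36.0  # MHz

    def waveform(self) -> np.ndarray:
        """Odd-length symmetric waveform sampled at fs, peak at the center."""
        t_cut = gausspulse("cutoff", fc=self.f0 * 1e6, bw=self.fractional_bandwidth, tpr=-60)
        n_half = int(np.ceil(t_cut * self.fs * 1e6))
        t = np.arange(-n_half, n_half + 1) / (self.fs * 1e6)
        return gausspulse(t, fc=self.f0 * 1e6, bw=self.fractional_bandwidth)


def generate_lesion_contour(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    roughness: float,
    n_vertices: int = 64,
    seed: int | np.random.Generator = 0,
) -> LesionContour:
    """Ellipse boundary radially perturbed by smoothed Gaussian noise.

    Coordinates are millimetres, ``(x, y) = (lateral, axial)``. The
    perturbation amplitude is ``roughness x mean radius``, so the expected
    convex-hull roughness dA/A grows monotonically with ``roughness``;
    ``roughness = 0`` returns the inscribed (convex) ellipse polygon.
    """
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if n_vertices < 16:
        raise ValueError("need at least 16 vertices")
    if roughness < 0:
        raise ValueError("roughness must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    base = np.stack([a * np.cos(theta), b * np.sin(theta)], axis=1)
    base_r = np.hypot(base[:, 0], base[:, 1])
    mean_r = base_r.mean()
    for _ in range(_MAX_CONTOUR_RETRIES):
        if roughness == 0:
            perturbed_r = base_r
        else:
            g = rng.standard_normal(n_vertices)
            # circular moving-average smoothing keeps the boundary coherent
            win = max(3, n_vertices // 16)
            kernel = np.ones(win) / win
            g = np.convolve(np.concatenate([g, g, g]), kernel, mode="same")[
                n_vertices : 2 * n_vertices
            ]
            g = g / g.std() if g.std() > 0 else g
            perturbed_r = base_r + roughness * mean_r * g
            perturbed_r = np.maximum(perturbed_r, 0.05 * mean_r)
        xy = np.stack(
            [
                center[0] + perturbed_r * np.cos(theta) * (a / base_r),
                center[1] + perturbed_r * np.sin(theta) * (b / base_r),
            ],
            axis=1,
        )
        poly = Polygon(xy)
        if poly.is_valid and poly.area > 0:
            return LesionContour(vertices=xy)
        if roughness == 0:  # pragma: no cover - ellipse is always valid
            break
    raise RuntimeError("could not generate a simple contour at this roughness")


def simulate_rf_frame(
    field: ScattererField,
    pulse: Pulse | None = None,
    attenuation_coeff: float = 0.0,
    noise_floor: float = 0.0,
    seed: int | np.random.Generator = 0,
    lateral_pitch: float = 0.30,
    n_zones: int = 10,
    extra: list[tuple[ScattererField, Pulse]] | None = None,
) -> RFFrame:
    """Simulate one RF frame from scatterer trains by 1-D convolution.

    Each scatterer is binned onto its nearest scanline and pulse-echo delay
    sample (``2 d / c``); each line is convolved with the pulse. ``extra``
    allows additional scatterer populations carrying their own pulse (used
    for class-conditional lesion spectral content); attenuation and noise
    are applied to the summed frame.
    """
    if pulse is None:
        pulse = Pulse()
    if attenuation_coeff < 0:
        raise ValueError("attenuation coefficient must be nonnegative")
    f_max = pulse.f0 * (1.0 + pulse.fractional_bandwidth)
    if pulse.fs <= 2.0 * f_max:
        raise ValueError(
            f"fs = {pulse.fs} MHz aliases the pulse; need fs > {2 * f_max:.1f} MHz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth_mm, width_mm = field.region_size
    axial_pitch = SOUND_SPEED_MM_US / (2.0 * pulse.fs)  # mm per sample
    n_samples = int(round(depth_mm / axial_pitch)) + 1
    n_lines = max(int(round(width_mm / lateral_pitch)), 1)

    rf = np.zeros((n_samples, n_lines))
    populations = [(field, pulse)] + list(extra or [])
    for fld, pls in populations:
        if fld.positions.size == 0:
            continue
        train = np.zeros((n_samples, n_lines))
        rows = np.clip(np.round(fld.positions[:, 0] / axial_pitch).astype(int), 0, n_samples - 1)
        cols = np.clip(np.round(fld.positions[:, 1] / lateral_pitch).astype(int), 0, n_lines - 1)
        np.add.at(train, (rows, cols), fld.amplitudes)
        wave = pls.waveform()
        half = len(wave) // 2
        full = fftconvolve(train, wave[:, None], mode="full", axes=0)
        rf += full[half : half + n_samples]

    if attenuation_coeff > 0:
        depth_cm = np.arange(n_samples) * axial_pitch / 10.0
        for sl in _zone_slices(n_samples, n_zones):
            x_z = depth_cm[sl].mean()
            block = rf[sl]
            spec = np.fft.rfft(block, axis=0)
            freqs = np.fft.rfftfreq(block.shape[0], d=1.0 / pulse.fs)
            loss = np.exp(-DB_TO_NEPER * attenuation_coeff * freqs * x_z)[:, None]
            rf[sl] = np.fft.irfft(spec * loss, n=block.shape[0], axis=0)

    if noise_floor > 0:
        ref = np.sqrt(np.mean(rf**2))
        ref = ref if ref > 0 else 1.0
        rf += noise_floor * ref * rng.standard_normal(rf.shape)

    return RFFrame(
        samples=rf,
        fs=pulse.fs,
        f0=pulse.f0,
        axial_pitch=axial_pitch,
        lateral_pitch=lateral_pitch,
    )


@dataclass
class ClassParams:
    """Class-conditional lesion properties."""

    pulse_center_freq: float  # MHz content of lesion echoes
    scatterer_density: float  # per mm^2
    echogenicity_ratio: float  # lesion/background envelope amplitude ratio
    boundary_roughness: float  # radial perturbation fraction, >= 0
    burr_b: float  # reflectivity power-law exponent, > 1
    burr_lambda: float = 1.0

    def __post_init__(self):
        if self.burr_b <= 1:
            raise ValueError("burr_b must exceed 1")
        if self.burr_lambda <= 0:
            raise ValueError("burr_lambda must be positive")
        if self.boundary_roughness < 0:
            raise ValueError("roughness must be nonnegative")


#: Strong-effect class conditions used as the default study cohort.
BENIGN_DEFAULT = ClassParams(
    pulse_center_freq=8.5,
    scatterer_density=100.0,
    echogenicity_ratio=1.0,
    boundary_roughness=0.05,
    burr_b=3.5,
)
MALIGNANT_DEFAULT = ClassParams(
    pulse_center_freq=10.5,
    scatterer_density=100.0,
    echogenicity_ratio=0.5,
    boundary_roughness=0.5,
    burr_b=2.0,
)


@dataclass
class CohortSpec:
    """Recipe for a labeled synthetic cohort (benign = -1, malignant = +1)."""

    n_benign: int = 40
    n_malignant: int = 40
    benign_params: ClassParams = dc_field(default_factory=lambda: BENIGN_DEFAULT)
    malignant_params: ClassParams = dc_field(default_factory=lambda: MALIGNANT_DEFAULT)
    attenuation_coeff: float = 1.0  # dB/MHz/cm
    seed: int = 0
    # acquisition geometry (a package convention, not a clinical fact)
    depth_mm: float = 30.0
    width_mm: float = 19.2
    fs: float = 36.0
    f0_background: float = 9.4
    fractional_bandwidth: float = 0.6
    lateral_pitch: float = 0.30
    background_density: float = 100.0  # per mm^2; >= 10 per resolution cell
    noise_floor: float = 1e-3
    n_contour_vertices: int = 64

    def __post_init__(self):
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("case counts must be nonnegative")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation coefficient must be nonnegative")


@dataclass
class LabeledCase:
    """One synthetic case: frame + lesion contour (mm) + biopsy-style label."""

    case_id: str
    frame: RFFrame
    contour_mm: LesionContour  # (x=lateral mm, y=axial mm)
    label: int  # -1 benign, +1 malignant
    lesion_area_cm2: float

    def __post_init__(self):
        if self.label not in (-1, 1):
            raise ValueError("label must be -1 (benign) or +1 (malignant)")
        if self.lesion_area_cm2 <= 0:
            raise ValueError("lesion area must be positive")


def _uniform_scatterers(region, density, rng) -> np.ndarray:
    depth, width = region
    n = rng.poisson(density * depth * width)
    return np.column_stack([rng.uniform(0, depth, n), rng.uniform(0, width, n)])


def _make_case(spec: CohortSpec, params: ClassParams, label: int, case_id: str,
               rng: np.random.Generator) -> LabeledCase:
    region = (spec.depth_mm, spec.width_mm)
    # lesion placed centrally with room for the outer margin band
    cx = rng.uniform(0.40 * spec.width_mm, 0.60 * spec.width_mm)
    cy = rng.uniform(0.40 * spec.depth_mm, 0.60 * spec.depth_mm)
    ax = rng.uniform(3.5, 6.0)
    ay = rng.uniform(3.5, 6.0)
    contour = generate_lesion_contour(
        (cx, cy), (ax, ay), params.boundary_roughness, spec.n_contour_vertices, rng
    )
    poly = contour.polygon()

    bg_pos = _uniform_scatterers(region, spec.background_density, rng)
    inside_bg = contains_xy(poly, bg_pos[:, 1], bg_pos[:, 0])
    bg_pos = bg_pos[~inside_bg]
    bg_amp = rng.standard_normal(len(bg_pos))
    background = ScattererField(bg_pos, bg_amp, region)

    # rejection-sample lesion scatterers inside the contour
    minx, miny, maxx, maxy = poly.bounds
    box_area = (maxx - minx) * (maxy - miny)
    n_target = rng.poisson(params.scatterer_density * poly.area)
    n_draw = max(int(2.5 * n_target * box_area / max(poly.area, 1e-9)), 10)
    cand = np.column_stack(
        [rng.uniform(miny, maxy, n_draw), rng.uniform(minx, maxx, n_draw)]
    )  # (axial, lateral)
    keep = contains_xy(poly, cand[:, 1], cand[:, 0])
    # a rough contour may poke outside the frame; scatterers stay inside it
    keep &= (
        (cand[:, 0] >= 0)
        & (cand[:, 0] <= spec.depth_mm)
        & (cand[:, 1] >= 0)
        & (cand[:, 1] <= spec.width_mm)
    )
    les_pos = cand[keep][:n_target]
    amps = burr_sample(max(len(les_pos), 1), params.burr_lambda, params.burr_b, rng)
    amps = amps[: len(les_pos)] * rng.choice([-1.0, 1.0], len(les_pos))
    # scale so lesion mean echo intensity / background = echogenicity_ratio^2
    if len(les_pos):
        target = (
            params.echogenicity_ratio**2
            * spec.background_density
            / max(params.scatterer_density, 1e-9)
        )
        amps *= np.sqrt(target / max(np.mean(amps**2), 1e-12))
    lesion = ScattererField(les_pos, amps, region)

    frame = simulate_rf_frame(
        background,
        Pulse(spec.f0_background, spec.fractional_bandwidth, spec.fs),
        attenuation_coeff=spec.attenuation_coeff,
        noise_floor=spec.noise_floor,
        seed=rng,
        lateral_pitch=spec.lateral_pitch,
        extra=[
            (lesion, Pulse(params.pulse_center_freq, spec.fractional_bandwidth, spec.fs))
        ],
    )
    return LabeledCase(
        case_id=case_id,
        frame=frame,
        contour_mm=contour,
        label=label,
        lesion_area_cm2=poly.area / 100.0,  # mm^2 -> cm^2
    )


def generate_cohort(spec: CohortSpec) -> list[LabeledCase]:
    """Generate the labeled cohort; reproducible bit-for-bit for a fixed seed."""
    n_total = spec.n_benign + spec.n_malignant
    if n_total == 0:
        return []
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    cases = []
    for i in range(n_total):
        rng = np.random.default_rng(streams[i])
        if i < spec.n_benign:
            cases.append(_make_case(spec, spec.benign_params, -1, f"benign_{i:03d}", rng))
        else:
            j = i - spec.n_benign
            cases.append(
                _make_case(spec, spec.malignant_params, +1, f"malignant_{j:03d}", rng)
            )
    return cases
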