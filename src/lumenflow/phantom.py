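"""Synthetic carotid M-mode phantom with exact ground truth.

Emulates single-scanline A-mode recordings of the common carotid artery:
a hypoechoic lumen bounded by two strong wall echoes, pulsatile distension
over the cardiac cycle, paced-breathing diameter modulation, an optional
hand-grip diameter trend, diffuse tissue speckle, static high-contrast
artifact bands, and additive electronic noise.

The rendering model is a fixed per-subject scatterer reflectivity train
(weak inside the lumen, stronger outside), unit-amplitude impulses at the
two wall positions, and static artifact impulses; the train is convolved
along depth with a Gabor pulse (Gaussian envelope, carrier at the
transducer's normalized center frequency) and white noise is added. Every
frame carries exact real-valued wall positions, so the generator doubles
as a ground-truth oracle for training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .errors import ConfigError

__all__ = [
    "AcquisitionSpec",
    "PhantomSubjectConfig",
    "GroundTruthAnnotation",
    "MModeRecord",
    "SubjectRecording",
    "Cohort",
    "cardiac_pulse_shape",
    "diameter_waveform",
    "render_recording",
    "make_cohort",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and sampling constants of the ultrasound system.

    Defaults describe a 7.8 MHz linear-array transducer sampled at
    31.25 MHz RF, frames at 500 Hz, 1020 depth samples of 24.65 µm each.
    """

    depth_samples: int = 1020
    depth_scale_um: float = 24.65
    frame_rate_hz: float = 500.0
    rf_sampling_hz: float = 31.25e6
    center_frequency_hz: float = 7.8e6
    sound_speed_m_s: float = 1540.0

    def __post_init__(self) -> None:
        expected_um = self.sound_speed_m_s / (2.0 * self.rf_sampling_hz) * 1e6
        if abs(expected_um - self.depth_scale_um) > 0.1:
            raise ConfigError(
                f"depth_scale_um={self.depth_scale_um} inconsistent with pulse-echo "
                f"sampling (expected ~{expected_um:.3f} um = c / (2 f_rf))"
            )
        f_norm = self.center_frequency_hz / self.rf_sampling_hz
        if not 0.0 < f_norm < 0.5:
            raise ConfigError(
                f"normalized carrier frequency {f_norm:.3f} outside (0, 0.5)"
            )

    @property
    def carrier_cycles_per_sample(self) -> float:
        return self.center_frequency_hz / self.rf_sampling_hz

    @property
    def wavelength_m(self) -> float:
        return self.sound_speed_m_s / self.center_frequency_hz

    def mm_to_samples(self, x_mm: float | np.ndarray) -> float | np.ndarray:
        return x_mm * 1000.0 / self.depth_scale_um


@dataclass(frozen=True)
class PhantomSubjectConfig:
    """Per-subject physiology and imaging-noise parameters.

    Amplitude fields are in mm of diameter change; positions and widths in
    depth samples. ``artifact_bands`` is a sequence of (depth_sample,
    relative_amplitude <= 0.8) static high-contrast reflectors.
    """

    mean_diameter_mm: float = 7.5
    pulse_amplitude_mm: float = 0.5
    heart_rate_bpm: float = 60.0
    resp_amplitude_mm: float = 0.2
    resp_rate_cpm: float = 7.5
    trend_amplitude_mm: float = 0.0
    lumen_center_baseline: float = 500.0
    center_drift_sigma: float = 0.02
    wall_pulse_sigma: float = 4.0
    artifact_bands: tuple[tuple[float, float], ...] = ()
    speckle_sigma: float = 0.1
    lumen_echo_sigma: float = 0.02
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self, spec: AcquisitionSpec) -> None:
        if self.mean_diameter_mm - self.pulse_amplitude_mm - self.resp_amplitude_mm <= 0:
            raise ConfigError(
                "mean_diameter_mm must exceed pulse_amplitude_mm + resp_amplitude_mm "
                f"(got {self.mean_diameter_mm}, {self.pulse_amplitude_mm}, "
                f"{self.resp_amplitude_mm})"
            )
        max_d_mm = (self.mean_diameter_mm + self.pulse_amplitude_mm
                    + self.resp_amplitude_mm + abs(self.trend_amplitude_mm))
        half = spec.mm_to_samples(max_d_mm) / 2.0
        margin = 5.0 * self.wall_pulse_sigma
        if (self.lumen_center_baseline - half - margin < 0
                or self.lumen_center_baseline + half + margin >= spec.depth_samples):
            raise ConfigError(
                f"lumen_center_baseline={self.lumen_center_baseline} puts wall "
                "excursions outside the depth range"
            )
        lo = self.lumen_center_baseline - half - margin
        hi = self.lumen_center_baseline + half + margin
        for depth, amp in self.artifact_bands:
            if lo <= depth <= hi:
                raise ConfigError(
                    f"artifact_bands: depth {depth} lies inside the lumen excursion "
                    f"range [{lo:.0f}, {hi:.0f}]"
                )
            if not 0 <= depth < spec.depth_samples:
                raise ConfigError(f"artifact_bands: depth {depth} outside frame")
            if amp > 0.8:
                raise ConfigError(
                    f"artifact_bands: relative amplitude {amp} exceeds 0.8"
                )


@dataclass
class GroundTruthAnnotation:
    """Exact per-frame wall geometry, all in (real-valued) depth samples."""

    anterior: np.ndarray
    posterior: np.ndarray
    center: np.ndarray
    diameter: np.ndarray

    @classmethod
    def from_walls(cls, anterior: np.ndarray, posterior: np.ndarray) -> "GroundTruthAnnotation":
        anterior = np.asarray(anterior, dtype=np.float64)
        posterior = np.asarray(posterior, dtype=np.float64)
        if np.any(posterior <= anterior):
            raise ConfigError("posterior wall must lie deeper than anterior wall")
        return cls(
            anterior=anterior,
            posterior=posterior,
            center=(anterior + posterior) / 2.0,
            diameter=posterior - anterior,
        )

    @property
    def n_frames(self) -> int:
        return len(self.anterior)


@dataclass
class MModeRecord:
    """Depth x time stack of A-mode frames (RF or envelope)."""

    samples: np.ndarray  # (depth, n_frames)
    spec: AcquisitionSpec
    kind: str = "rf"  # {"rf", "envelope"}

    @property
    def n_frames(self) -> int:
        return self.samples.shape[1]


def cardiac_pulse_shape(phase: np.ndarray) -> np.ndarray:
    """Normalized diameter pulse over one cardiac cycle, range [0, 1].

    Raised-cosine upstroke over the first 15% of the cycle (sharp systolic
    foot) followed by exponential relaxation with a time constant of 25%
    of the cycle.
    """
    phase = np.asarray(phase, dtype=np.float64) % 1.0
    up = 0.15
    tau = 0.25
    rising = phase < up
    out = np.empty_like(phase)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / up))
    out[~rising] = np.exp(-(phase[~rising] - up) / tau)
    return out


def diameter_waveform(subject: PhantomSubjectConfig, n_frames: int,
                      spec: AcquisitionSpec | None = None) -> np.ndarray:
    """Per-frame arterial diameter in mm: baseline + cardiac pulse +
    respiratory modulation + hand-grip trend. Deterministic (no noise)."""
    spec = spec or AcquisitionSpec()
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    subject.validate(spec)
    t = np.arange(n_frames, dtype=np.float64) / spec.frame_rate_hz
    cardiac = cardiac_pulse_shape(t * subject.heart_rate_bpm / 60.0)
    resp = np.sin(2.0 * np.pi * subject.resp_rate_cpm / 60.0 * t)
    trend = subject.trend_amplitude_mm * (t / t[-1] if n_frames > 1 else 0.0)
    d = (subject.mean_diameter_mm
         + subject.pulse_amplitude_mm * cardiac
         + subject.resp_amplitude_mm * resp
         + trend)
    if np.min(d) <= 0:
        raise ConfigError("diameter waveform reaches zero; reduce modulation amplitudes")
    return d


def _gabor_kernel(sigma: float, cycles_per_sample: float) -> np.ndarray:
    half = int(np.ceil(4.0 * sigma))
    n = np.arange(-half, half + 1, dtype=np.float64)
    return np.exp(-0.5 * (n / sigma) ** 2) * np.cos(2.0 * np.pi * cycles_per_sample * n)


def _deposit(train: np.ndarray, depths: np.ndarray, amps: np.ndarray,
             frame_idx: np.ndarray) -> None:
    """Add impulses at real-valued depths by linear splitting between bins."""
    lo = np.floor(depths).astype(np.intp)
    w = depths - lo
    np.add.at(train, (lo, frame_idx), amps * (1.0 - w))
    np.add.at(train, (lo + 1, frame_idx), amps * w)


def render_recording(subject: PhantomSubjectConfig, n_frames: int,
                     spec: AcquisitionSpec | None = None
                     ) -> tuple[MModeRecord, GroundTruthAnnotation]:
    """Render an RF M-mode stack plus its exact ground-truth annotation."""
    spec = spec or AcquisitionSpec()
    d_mm = diameter_waveform(subject, n_frames, spec)
    d_samples = np.asarray(spec.mm_to_samples(d_mm))

    rng = np.random.default_rng(subject.seed)
    drift = np.cumsum(rng.normal(0.0, subject.center_drift_sigma, n_frames))
    center = subject.lumen_center_baseline + drift
    annotation = GroundTruthAnnotation.from_walls(center - d_samples / 2.0,
                                                  center + d_samples / 2.0)
    depth = spec.depth_samples
    if np.min(annotation.anterior) < 1 or np.max(annotation.posterior) >= depth - 1:
        raise ConfigError("wall excursion beyond depth range; adjust baseline or amplitudes")

    tissue = rng.normal(0.0, 1.0, depth) * subject.speckle_sigma
    lumen = rng.normal(0.0, 1.0, depth) * subject.lumen_echo_sigma

    idx = np.arange(depth, dtype=np.float64)[:, None]
    inside = (idx > annotation.anterior) & (idx < annotation.posterior)
    train = np.where(inside, lumen[:, None], tissue[:, None]).astype(np.float64)

    frames = np.arange(n_frames, dtype=np.intp)
    _deposit(train, annotation.anterior, np.ones(n_frames), frames)
    _deposit(train, annotation.posterior, np.ones(n_frames), frames)
    for band_depth, band_amp in subject.artifact_bands:
        train[int(round(band_depth)), :] += band_amp

    kernel = _gabor_kernel(subject.wall_pulse_sigma, spec.carrier_cycles_per_sample)
    rf = fftconvolve(train, kernel[:, None], mode="same", axes=0)
    if subject.noise_sigma > 0:
        rf = rf + rng.normal(0.0, subject.noise_sigma, rf.shape)
    record = MModeRecord(samples=rf.astype(np.float32), spec=spec, kind="rf")
    return record, annotation


@dataclass
class SubjectRecording:
    """One subject's rendered recording with provenance."""

    config: PhantomSubjectConfig
    rf: MModeRecord
    annotation: GroundTruthAnnotation
    envelope: np.ndarray | None = None  # (depth, frames), filled by preprocessing
    extras: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """A multi-subject phantom dataset, reproducible from ``master_seed``."""

    spec: AcquisitionSpec
    master_seed: int
    subjects: list[SubjectRecording]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _draw_subject_config(rng: np.random.Generator, spec: AcquisitionSpec,
                         seed: int) -> PhantomSubjectConfig:
    baseline = float(rng.uniform(350.0, 650.0))
    heart_rate = float(rng.uniform(55.0, 75.0))
    base = PhantomSubjectConfig(lumen_center_baseline=baseline,
                                heart_rate_bpm=heart_rate, seed=seed)
    # static artifact bands well clear of the lumen excursion range
    max_d = spec.mm_to_samples(base.mean_diameter_mm + base.pulse_amplitude_mm
                               + base.resp_amplitude_mm)
    margin = 5.0 * base.wall_pulse_sigma + 10.0
    lo, hi = baseline - max_d / 2.0 - margin, baseline + max_d / 2.0 + margin
    bands: list[tuple[float, float]] = []
    for _ in range(int(rng.integers(2, 5))):
        for _attempt in range(20):
            depth = float(rng.uniform(30.0, spec.depth_samples - 30.0))
            if not lo <= depth <= hi:
                bands.append((depth, float(rng.uniform(0.3, 0.8))))
                break
    return replace(base, artifact_bands=tuple(bands))


def make_cohort(n_subjects: int, frames_per_subject: int, master_seed: int,
                spec: AcquisitionSpec | None = None) -> Cohort:
    """Render a cohort of phantom subjects with per-subject sub-seeds.

    At least two subjects are required so the cohort supports
    leave-one-subject-out evaluation.
    """
    spec = spec or AcquisitionSpec()
    if n_subjects < 2:
        raise ConfigError(
            "n_subjects must be >= 2: leave-one-subject-out evaluation needs at "
            "least two subjects"
        )
    subjects = []
    for k in range(n_subjects):
        sub_seed = master_seed * 100003 + k
        rng = np.random.default_rng(sub_seed)
        config = _draw_subject_config(rng, spec, seed=sub_seed)
        rf, annotation = render_recording(config, frames_per_subject, spec)
        subjects.append(SubjectRecording(config=config, rf=rf, annotation=annotation))
    return Cohort(spec=spec, master_seed=master_seed, subjects=subjects)
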