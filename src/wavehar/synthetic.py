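"""Seeded generator of labelled tri-axial accelerometer recordings.

The generator emulates the structure that body-worn accelerometer data
shows at the scale of a few-second window:

* a gravity offset along the (slightly uncertain, slowly drifting) device
  orientation — orientation is a property of how the sensor is worn, so
  upright activities share one orientation distribution rather than each
  class getting a tell-tale tilt;
* activity-specific periodic content: a fundamental stride/step frequency
  with per-axis harmonic amplitude profiles, slow amplitude modulation and
  stride-to-stride frequency jitter;
* per-recording ("subject") variation of cadence, movement amplitude and
  orientation, so classes overlap the way multi-subject collections do;
* optional impulsive bursts (jump landings) and additive Gaussian noise.

Static activities (sitting, standing) have no periodic component.  The
dynamic classes deliberately overlap in cadence and amplitude and differ
mainly in *which sub-bands* their harmonics occupy — so recognising them
hinges on cleanly resolved sub-band content, the property along which
mother wavelets genuinely differ.

It also builds *matched-wavelet* signals: sparse wavelet-packet synthesis
under a chosen mother wavelet, which by construction concentrate their
energy in few coefficients under that wavelet — the test harness for the
premise that the best mother wavelet is the one resembling the signal.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .preprocess import GRAVITY_M_PER_S2, Segment, SensorRecording, segment as _segment
from .wavelets import (
    PacketCoefficients,
    WaveletSpec,
    get_wavelet,
    padded_length_for,
    wpt_reconstruct,
)

__all__ = [
    "ActivityModel",
    "DEFAULT_ACTIVITIES",
    "simulate_activity",
    "make_benchmark",
    "make_recordings",
    "write_benchmark",
    "matched_wavelet_signals",
]

#: depth of the slow common amplitude envelope shared by all harmonics
_COMMON_AM_LOG_SD = 0.4
#: burst decay time constant, seconds
_BURST_TAU = 0.08


@dataclass(frozen=True)
class ActivityModel:
    """Generative description of one activity class.

    Parameters
    ----------
    name : str
        Activity label.
    fundamental_hz : float
        Stride/step fundamental frequency; 0 marks a static activity.
    harmonic_amplitudes : tuple
        (3, n_harmonics) nested tuple, row = axis (x, y, z), column =
        harmonic of the fundamental, amplitudes in signal units
        (m/s² at the default unit setting).
    gravity_vector : tuple
        Base gravity offset per axis before orientation perturbations.
    noise_sd : float
        Additive white sensor/artefact noise, signal units.
    burst_rate_hz, burst_amplitude : float
        Poisson rate and peak amplitude of exponentially decaying
        randomly oriented impulsive bursts (0 disables).
    amplitude_jitter : float in [0, 1)
        Depth of the slow per-harmonic amplitude modulation.
    freq_jitter : float
        Relative sd of the slow instantaneous-frequency modulation.
    subject_f0_sd : float
        Relative sd of the per-recording cadence draw (between-subject
        variation).
    subject_amp_sd : float
        Log-sd of the per-recording overall amplitude scale.
    tilt_deg, tilt_sd_deg : float
        Mean and sd of the device tilt from vertical drawn per recording
        (azimuth uniform).
    drift_deg : float
        Amplitude of the slow within-recording orientation drift.
    """

    name: str
    fundamental_hz: float
    harmonic_amplitudes: tuple = ()
    gravity_vector: tuple = (0.0, 0.0, GRAVITY_M_PER_S2)
    noise_sd: float = 0.1
    burst_rate_hz: float = 0.0
    burst_amplitude: float = 0.0
    amplitude_jitter: float = 0.0
    freq_jitter: float = 0.0
    subject_f0_sd: float = 0.0
    subject_amp_sd: float = 0.0
    tilt_deg: float = 0.0
    tilt_sd_deg: float = 0.0
    drift_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.amplitude_jitter < 1.0:
            raise ValueError("amplitude_jitter must be in [0, 1)")
        if self.fundamental_hz < 0:
            raise ValueError("fundamental_hz must be >= 0")


def _gait(name: str, f0: float, amps: tuple, noise: float, **kw) -> ActivityModel:
    return ActivityModel(
        name=name, fundamental_hz=f0, harmonic_amplitudes=amps, noise_sd=noise,
        amplitude_jitter=0.45, freq_jitter=0.04, subject_f0_sd=0.06,
        subject_amp_sd=0.3, tilt_deg=8.0, tilt_sd_deg=2.0, drift_deg=2.0, **kw,
    )


#: Six default activity classes.  The three gait classes overlap in
#: cadence and amplitude on purpose: walking carries its power in the 2nd
#: harmonic (~3.7 Hz), stair climbing in the 4th (~7.2 Hz), jogging in the
#: 2nd/3rd of a faster fundamental — profiles that land in different
#: 3.125 Hz-wide sub-bands of a 3-level, 50 Hz packet decomposition.
DEFAULT_ACTIVITIES: tuple[ActivityModel, ...] = (
    ActivityModel(
        name="sitting", fundamental_hz=0.0, noise_sd=0.06,
        tilt_deg=60.0, tilt_sd_deg=10.0, drift_deg=2.0,
    ),
    ActivityModel(
        name="standing", fundamental_hz=0.0, noise_sd=0.09,
        tilt_deg=8.0, tilt_sd_deg=2.0, drift_deg=2.0,
    ),
    _gait(
        "walking", 1.85,
        ((2.5, 0.7, 0.0, 0.0), (1.5, 0.42, 0.0, 0.0), (1.0, 0.28, 0.0, 0.0)),
        0.45,
    ),
    _gait(
        "stairs", 1.80,
        ((2.5, 0.15, 0.15, 0.7), (1.5, 0.1, 0.1, 0.42), (1.0, 0.05, 0.05, 0.28)),
        0.45,
    ),
    _gait(
        "jogging", 2.60,
        ((3.25, 0.49, 0.49, 0.0), (2.0, 0.28, 0.28, 0.0), (1.25, 0.21, 0.21, 0.0)),
        0.54,
    ),
    _gait(
        "jumping", 1.20,
        ((2.0, 0.3, 0.15, 0.1), (1.0, 0.15, 0.1, 0.05), (2.5, 0.4, 0.2, 0.1)),
        0.45, burst_rate_hz=1.0, burst_amplitude=6.0,
    ),
)


def _smooth_noise(rng: np.random.Generator, n: int, rate: float, cutoff_hz: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise (slow modulation)."""
    pad = 200
    raw = rng.normal(size=n + 2 * pad)
    b, a = butter(2, min(cutoff_hz / (rate / 2), 0.99))
    out = filtfilt(b, a, raw)[pad:-pad]
    sd = np.std(out)
    return out / sd if sd > 0 else out


def _oriented_gravity(model: ActivityModel, rng: np.random.Generator) -> np.ndarray:
    base = np.asarray(model.gravity_vector, dtype=float)
    if model.tilt_deg == 0.0 and model.tilt_sd_deg == 0.0:
        return base
    magnitude = np.linalg.norm(base)
    theta = np.deg2rad(model.tilt_deg + rng.normal(0.0, model.tilt_sd_deg))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return magnitude * np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def simulate_activity(model: ActivityModel, duration_s: float, rate: float,
                      seed: int | np.random.Generator, *,
                      subject_id: str = "sim", units: str = "m_per_s2") -> SensorRecording:
    """Simulate one constant-label recording of ``duration_s`` seconds.

    Per axis: (tilted, slowly drifting) gravity + harmonics of a jittered
    fundamental with seeded random phases and slow amplitude modulation +
    Gaussian noise + Poisson-timed decaying bursts.  Per-recording
    ("subject") cadence, amplitude and tilt draws happen once per call.
    Bit-identical output for a given seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if model.fundamental_hz >= rate / 2:
        raise ValueError(
            f"fundamental {model.fundamental_hz} Hz is at or above the "
            f"Nyquist frequency {rate / 2} Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    samples = np.tile(_oriented_gravity(model, rng), (n, 1))
    if model.drift_deg > 0.0:
        drift = GRAVITY_M_PER_S2 * np.deg2rad(model.drift_deg)
        for axis in range(2):
            samples[:, axis] += drift * _smooth_noise(rng, n, rate, 0.03)
    if model.fundamental_hz > 0.0 and len(model.harmonic_amplitudes):
        f0 = model.fundamental_hz * (1.0 + rng.normal(0.0, model.subject_f0_sd))
        if model.freq_jitter > 0.0:
            inst = f0 * (1.0 + model.freq_jitter * _smooth_noise(rng, n, rate, 0.3))
        else:
            inst = np.full(n, f0)
        phase = 2.0 * np.pi * np.cumsum(inst) / rate
        amps = np.atleast_2d(np.asarray(model.harmonic_amplitudes, dtype=float))
        if amps.shape[0] == 1:  # one shared row -> same profile on every axis
            amps = np.repeat(amps, 3, axis=0)
        amps = amps * np.exp(rng.normal(0.0, model.subject_amp_sd))
        common = (
            np.exp(_COMMON_AM_LOG_SD * _smooth_noise(rng, n, rate, 0.08))
            if model.amplitude_jitter > 0.0
            else np.ones(n)
        )
        for axis in range(3):
            for h, amp in enumerate(amps[axis], start=1):
                if amp == 0.0:
                    continue
                if model.amplitude_jitter > 0.0:
                    env = common * np.clip(
                        1.0 + model.amplitude_jitter * _smooth_noise(rng, n, rate, 0.2),
                        0.05, None,
                    )
                else:
                    env = 1.0
                phi = rng.uniform(0.0, 2.0 * np.pi)
                samples[:, axis] += amp * env * np.sin(h * phase + phi)
    if model.burst_rate_hz > 0.0 and model.burst_amplitude > 0.0:
        n_bursts = rng.poisson(model.burst_rate_hz * duration_s)
        for _ in range(n_bursts):
            start = rng.uniform(0.0, duration_s)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            mask = t >= start
            envelope = np.exp(-(t[mask] - start) / _BURST_TAU)
            samples[mask] += model.burst_amplitude * envelope[:, None] * direction
    if model.noise_sd > 0.0:
        samples += rng.normal(0.0, model.noise_sd, size=samples.shape)
    return SensorRecording(
        subject_id=subject_id,
        placement="simulated",
        sampling_rate=float(rate),
        units=units,  # type: ignore[arg-type]
        samples=samples,
        labels=np.full(n, model.name, dtype=object),
    )


def make_recordings(seed: int, *, activities: tuple[ActivityModel, ...] = DEFAULT_ACTIVITIES,
                    n_segments_per_class: int = 120, n_subjects: int = 6,
                    rate: float = 50.0, window_seconds: float = 2.5,
                    units: str = "m_per_s2") -> list[SensorRecording]:
    """One recording per (activity, simulated subject).

    Each subject's recording is long enough to yield its share of the
    per-class segment quota; subject-level cadence/amplitude/orientation
    draws are what make classes overlap realistically.
    """
    rng = np.random.default_rng(seed)
    per_subject = int(np.ceil(n_segments_per_class / n_subjects))
    duration = (per_subject + 1) * window_seconds
    scale = 1.0 if units == "m_per_s2" else 1.0 / GRAVITY_M_PER_S2
    out = []
    for model in activities:
        for subj in range(n_subjects):
            rec = simulate_activity(
                model, duration, rate, rng, subject_id=f"subj{subj:02d}", units=units,
            )
            if scale != 1.0:
                rec = SensorRecording(
                    subject_id=rec.subject_id, placement=rec.placement,
                    sampling_rate=rec.sampling_rate, units="g",
                    samples=rec.samples * scale, labels=rec.labels,
                )
            out.append(rec)
    return out


def make_benchmark(seed: int, *, activities: tuple[ActivityModel, ...] = DEFAULT_ACTIVITIES,
                   n_segments_per_class: int = 120, n_subjects: int = 6,
                   rate: float = 50.0, window_seconds: float = 2.5,
                   units: str = "m_per_s2") -> list[Segment]:
    """Class-balanced labelled segment collection (default 6 x 120).

    Simulates ``n_subjects`` recordings per activity and windows them;
    every class contributes exactly ``n_segments_per_class`` segments of
    ``round(window_seconds * rate)`` samples.
    """
    per_subject = int(np.ceil(n_segments_per_class / n_subjects))
    by_class: dict[str, list[Segment]] = {}
    for rec in make_recordings(
        seed, activities=activities, n_segments_per_class=n_segments_per_class,
        n_subjects=n_subjects, rate=rate, window_seconds=window_seconds, units=units,
    ):
        label = str(rec.labels[0])
        by_class.setdefault(label, []).extend(_segment(rec, window_seconds)[:per_subject])
    segments: list[Segment] = []
    for model in activities:
        segments.extend(by_class[model.name][:n_segments_per_class])
    return segments


def write_benchmark(out_dir, seed: int, **kwargs) -> Path:
    """Write a synthetic benchmark as per-recording CSV files + manifest.

    Files use the ``"synthetic"`` schema layout (t, x, y, z, label,
    subject), so the full read -> resample -> segment path can be
    exercised on them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = make_recordings(seed, **kwargs)
    manifest = []
    for rec in recordings:
        label = str(rec.labels[0])
        name = f"{label}_{rec.subject_id}.csv"
        pd.DataFrame(
            {
                "t": np.arange(rec.n_samples) / rec.sampling_rate,
                "x": rec.samples[:, 0],
                "y": rec.samples[:, 1],
                "z": rec.samples[:, 2],
                "label": rec.labels,
                "subject": rec.subject_id,
            }
        ).to_csv(out_dir / name, index=False)
        manifest.append(
            {"file": name, "label": label, "subject": rec.subject_id,
             "sampling_rate": rec.sampling_rate, "units": rec.units,
             "n_samples": rec.n_samples}
        )
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def matched_wavelet_signals(wavelet: WaveletSpec | str, n_signals: int, sparsity: int,
                            noise_sd: float, seed: int, *, level: int = 3,
                            length: int = 125, label: str | None = None) -> list[Segment]:
    """Segments synthesized from sparse packets of the given wavelet.

    Each axis of each segment is the inverse packet transform of a level-
    ``level`` coefficient set with exactly ``sparsity`` nonzero entries at
    seeded random positions, plus Gaussian noise.  Under the generating
    wavelet the (noise-free) signal's energy sits in ``sparsity``
    coefficients — minimal entropy — so that wavelet wins the fitness
    ranking on these signals.
    """
    if sparsity < 1:
        raise ValueError("sparsity must be >= 1")
    if isinstance(wavelet, str):
        wavelet = get_wavelet(wavelet)
    rng = np.random.default_rng(seed)
    padded = padded_length_for(length, level)
    node_len = padded // 2 ** level
    out = []
    for _ in range(n_signals):
        axes = []
        for _axis in range(3):
            coeffs = np.zeros(padded)
            pos = rng.choice(padded, size=sparsity, replace=False)
            coeffs[pos] = rng.choice([-1.0, 1.0], size=sparsity) * rng.uniform(
                0.8, 1.2, size=sparsity
            )
            packet = PacketCoefficients(
                wavelet_name=wavelet.name,
                level=level,
                nodes=tuple(
                    coeffs[j * node_len: (j + 1) * node_len] for j in range(2 ** level)
                ),
                original_length=padded,
                padded_length=padded,
            )
            sig = wpt_reconstruct(packet, wavelet)[:length]
            if noise_sd > 0.0:
                sig = sig + rng.normal(0.0, noise_sd, size=length)
            axes.append(sig)
        out.append(
            Segment(
                samples=np.column_stack(axes),
                label=label or f"matched_{wavelet.name}",
                subject_id="sim",
                placement="simulated",
            )
        )
    return out
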