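"""Trial audio for 2IFC signal-in-noise detection, and the visualizer envelope.

Each 2IFC trial comprises two sound intervals sharing one Gaussian
white-noise sample; one interval additionally carries the acoustic signal,
RMS-scaled to a target dB SNR relative to the noise, linearly faded in and
out (to blunt attack/release cues) and placed at a uniformly jittered
onset.  SNR follows the RMS-power convention: snr_db = 20 log10(rms_signal
/ rms_noise), so 0 dB SNR means signal and noise have equal RMS.

The "visualizer" time series — the amplitude envelope that drove the
on-screen circle in the crossmodal experiments — is the full-wave
rectified waveform passed through a zero-phase (forward-backward)
fifth-order 60 Hz low-pass Butterworth filter.  Rendering is out of scope;
the envelope is emitted as a sample series (optionally normalised to
[0, 1]).

WAV I/O uses scipy (PCM 16/32-bit and float32/64; 24-bit PCM is not
supported for writing).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, filtfilt

__all__ = [
    "AudioBuffer",
    "TrialSpec",
    "STUDY1_TRIAL",
    "STUDY2_TRIAL",
    "NOISE_SIGMA",
    "rms",
    "mono_mix",
    "scale_to_snr",
    "apply_linear_fade",
    "build_trial_pair",
    "amplitude_envelope",
    "normalized_envelope",
    "read_wav",
    "write_wav",
    "write_envelope_csv",
]

# Gaussian-noise amplitude: P(|x| > 1 full scale) < 1e-6 per sample
# requires 1/sigma > Phi^{-1}(1 - 5e-7) = 4.8916.
NOISE_SIGMA = 0.2044


@dataclass
class AudioBuffer:
    """A mono waveform: dimensionless samples (nominal +-1) at a sample rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not (self.rate > 0):
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class TrialSpec:
    """Timing and SNR parameters of one 2IFC trial.

    ``onset_window_s`` is the (min, max) signal-onset time after noise
    onset; the signal must fit inside the noise interval and the fades
    inside the signal.
    """

    noise_duration_s: float
    signal_duration_s: float
    onset_window_s: Tuple[float, float]
    fade_s: float
    snr_db: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.onset_window_s
        if not (0 <= lo <= hi):
            raise ValueError("onset window must satisfy 0 <= min <= max")
        if hi + self.signal_duration_s > self.noise_duration_s + 1e-12:
            raise ValueError("signal at max onset must fit inside the noise")
        if self.fade_s > self.signal_duration_s / 2 + 1e-12:
            raise ValueError("fade longer than half the signal")


# Published trial geometries: 4 s noise / 2 s signal / onset 1-2 s / 500 ms
# fades, and the shorter 2 s / 1 s / 0.5-1 s / 200 ms variant.
STUDY1_TRIAL = TrialSpec(4.0, 2.0, (1.0, 2.0), 0.5)
STUDY2_TRIAL = TrialSpec(2.0, 1.0, (0.5, 1.0), 0.2)


def rms(buf: AudioBuffer) -> float:
    """Root-mean-square amplitude."""
    return float(np.sqrt(np.mean(buf.samples**2)))


def mono_mix(left: AudioBuffer, right: AudioBuffer) -> AudioBuffer:
    """Average L/R channels into one mono buffer."""
    if left.samples.size != right.samples.size or left.rate != right.rate:
        raise ValueError("channels must share length and rate")
    return AudioBuffer(0.5 * (left.samples + right.samples), left.rate)


def scale_to_snr(signal: AudioBuffer, noise: AudioBuffer, snr_db: float) -> AudioBuffer:
    """Scale ``signal`` so its RMS sits ``snr_db`` dB relative to the noise RMS."""
    rs, rn = rms(signal), rms(noise)
    if rs == 0 or rn == 0:
        raise ValueError("cannot set SNR with a silent signal or noise")
    gain = rn * 10.0 ** (snr_db / 20.0) / rs
    return AudioBuffer(signal.samples * gain, signal.rate)


def apply_linear_fade(signal: AudioBuffer, fade_s: float) -> AudioBuffer:
    """Linear fade-in over the first ``fade_s`` and fade-out over the last."""
    n = signal.samples.size
    n_fade = int(round(fade_s * signal.rate))
    if 2 * n_fade > n:
        raise ValueError("fade longer than half the signal")
    out = signal.samples.copy()
    if n_fade > 0:
        ramp = np.linspace(0.0, 1.0, n_fade)
        out[:n_fade] *= ramp
        out[n - n_fade :] *= ramp[::-1]
    return AudioBuffer(out, signal.rate)


def build_trial_pair(
    signal: AudioBuffer, spec: TrialSpec, rng: np.random.Generator
) -> Tuple[AudioBuffer, AudioBuffer, float]:
    """Construct the two intervals of one trial.

    Draws a single Gaussian white-noise buffer of ``spec.noise_duration_s``;
    the noise interval is that buffer, the signal interval is the same
    buffer plus the SNR-scaled, faded signal starting at an onset drawn
    uniformly from ``spec.onset_window_s``.  SNR is set on the un-faded
    signal; the fade is applied afterwards.  Returns
    ``(signal_interval, noise_interval, onset_s)``.
    """
    n_expected = int(round(spec.signal_duration_s * signal.rate))
    if abs(signal.samples.size - n_expected) > 1:
        raise ValueError(
            f"signal length {signal.samples.size} does not match the spec's "
            f"{spec.signal_duration_s} s at {signal.rate} Hz"
        )
    n_noise = int(round(spec.noise_duration_s * signal.rate))
    noise = AudioBuffer(rng.normal(0.0, NOISE_SIGMA, n_noise), signal.rate)
    onset_s = float(rng.uniform(*spec.onset_window_s))
    scaled = scale_to_snr(signal, noise, spec.snr_db)
    faded = apply_linear_fade(scaled, spec.fade_s)
    start = int(round(onset_s * signal.rate))
    mixed = noise.samples.copy()
    mixed[start : start + faded.samples.size] += faded.samples
    return AudioBuffer(mixed, signal.rate), noise, onset_s


def amplitude_envelope(
    signal: AudioBuffer,
    cutoff_hz: float = 60.0,
    order: int = 5,
    rectify: bool = True,
) -> AudioBuffer:
    """Amplitude envelope: rectify, then zero-phase Butterworth low-pass.

    The designed filter is ``order``-th order at ``cutoff_hz``; the
    forward-backward pass makes it zero-lag (and doubles the effective
    roll-off).  Full-wave rectification is the (configurable) pre-step —
    without it, low-passing a zero-mean carrier returns ~0 rather than an
    envelope.  Output is clamped at 0 and has the input's length.
    """
    if signal.rate <= 2 * cutoff_hz:
        raise ValueError("sample rate too low for the requested cutoff")
    x = np.abs(signal.samples) if rectify else signal.samples
    b, a = butter(order, cutoff_hz, btype="low", fs=signal.rate)
    env = filtfilt(b, a, x)
    return AudioBuffer(np.maximum(env, 0.0), signal.rate)


def normalized_envelope(signal: AudioBuffer, **kwargs) -> AudioBuffer:
    """Envelope scaled to [0, 1] — the series that drives the visualizer."""
    env = amplitude_envelope(signal, **kwargs)
    peak = env.samples.max()
    if peak == 0:
        return env
    return AudioBuffer(env.samples / peak, env.rate)


def read_wav(path) -> AudioBuffer:
    """Read a WAV file; integer PCM is rescaled to float in [-1, 1].

    Stereo input is averaged across channels (mono mix).
    """
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit PCM is unsigned
        data = (data.astype(float) - 128.0) / 127.0
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioBuffer(data, float(rate))


def write_wav(path, buf: AudioBuffer, subtype: str = "float32") -> None:
    """Write a mono WAV file (``subtype``: 'float32', 'float64' or 'pcm16')."""
    rate = int(round(buf.rate))
    if subtype == "float32":
        wavfile.write(path, rate, buf.samples.astype(np.float32))
    elif subtype == "float64":
        wavfile.write(path, rate, buf.samples.astype(np.float64))
    elif subtype == "pcm16":
        clipped = np.clip(buf.samples, -1.0, 1.0)
        wavfile.write(path, rate, (clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def write_envelope_csv(env: AudioBuffer, path) -> None:
    """Export an envelope series as CSV columns (time_s, value)."""
    t = np.arange(env.samples.size) / env.rate
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for ti, vi in zip(t, env.samples):
            w.writerow([f"{ti:.6f}", f"{vi:.8g}"])
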