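"""Build the audio of one 2IFC trial and extract the visualizer envelope.

Constructs the two intervals of a trial (shared white-noise sample, one
with an added -10 dB SNR signal, 500 ms fades, onset jittered in 1-2 s)
and computes the amplitude envelope that drives the on-screen visualizer
(rectification + zero-phase 5th-order 60 Hz Butterworth low-pass).
"""

import numpy as np

from crossmodal import audio

rate = 8000.0
rng = np.random.default_rng(2)

# a percussive-like test signal: decaying 1 kHz tone, 2 s
t = np.arange(int(2.0 * rate)) / rate
signal = audio.AudioBuffer(np.sin(2 * np.pi * 1000 * t) * np.exp(-2 * t), rate)

spec = audio.TrialSpec(4.0, 2.0, (1.0, 2.0), 0.5, snr_db=-10.0)
signal_iv, noise_iv, onset = audio.build_trial_pair(signal, spec, rng)

measured = 20 * np.log10(
    audio.rms(audio.scale_to_snr(signal, noise_iv, spec.snr_db))
    / audio.rms(noise_iv)
)
print(f"noise interval: {noise_iv.duration_s:.1f} s, rms {audio.rms(noise_iv):.4f}")
print(f"signal onset:   {onset:.3f} s after noise onset")
print(f"target SNR {spec.snr_db:.1f} dB, measured {measured:.6f} dB")

env = audio.normalized_envelope(signal)
peak_t = np.argmax(env.samples) / rate
print(f"envelope peak at {peak_t:.3f} s (signal attack), range "
      f"[{env.samples.min():.3f}, {env.samples.max():.3f}]")
# The envelope is the [0, 1] series that would modulate the visualizer
# circle's radius; the SNR round-trip confirms the RMS-power convention.
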