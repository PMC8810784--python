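"""Front-end walkthrough: filter -> baseline -> ADM spike encoding.

Generates 20 s of 1/f scalp-EEG-like background with one 120 Hz ripple,
band-passes it to the 80-250 Hz ripple band, estimates the noise-floor
baseline, and encodes the trace into UP/DN spikes with the threshold at 30%
of the baseline amplitude.
"""

from eegsnn.preprocess import (
    AdmConfig,
    FilterSpec,
    RIPPLE_BAND,
    adm_encode,
    bandpass_filter,
    estimate_baseline,
    spike_threshold_from_baseline,
)
from eegsnn.synth import SynthConfig, SynthEvent, gen_background, inject_ripple

cfg = SynthConfig(duration=20.0, seed=0)
ripple = SynthEvent(kind="ripple", start=10.0, duration=0.08,
                    center_freq=120.0, amplitude=5 * cfg.noise_sigma)
signal = inject_ripple(gen_background(cfg), ripple)

filtered = bandpass_filter(signal, FilterSpec(*RIPPLE_BAND))
baseline = estimate_baseline(filtered)
threshold = spike_threshold_from_baseline(baseline)
up, dn = adm_encode(filtered, AdmConfig(threshold=threshold))

in_ripple = [t for t in up.times if ripple.start <= t < ripple.end]
print(f"baseline amplitude (quiet-window peak-to-peak): {baseline.amplitude:.2f} uV")
print(f"ADM threshold (30% of baseline):                {threshold:.2f} uV")
print(f"UP spikes total / within the ripple:            {up.n} / {len(in_ripple)}")
print(f"DN spikes total:                                {dn.n}")
print(
    "\nReading: the encoder is event-driven -- spikes cluster where the\n"
    "signal swings fast (the ripple), while quiet background produces only\n"
    "sparse spikes near the threshold."
)
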