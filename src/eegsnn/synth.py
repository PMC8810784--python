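"""Ground-truth-annotated synthetic scalp EEG.

Emulates the signal classes the detector must separate: 1/f background
noise, Gaussian-windowed ripple-band oscillations (the standard simulated-HFO
morphology), broadband biphasic sharp transients, and high-frequency
(500-900 Hz) artifact bursts with deliberate ripple-band leakage so the core
network fires and the artifact-rejection path is exercised.  Recordings are
generated as a bilateral pair of homologous channels with ripples only on the
"affected" channel and a configurable fraction of artifacts placed
simultaneously on both, which exercises contralateral rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording, TimeSeries

__all__ = [
    "SynthEvent",
    "SynthConfig",
    "gen_background",
    "inject_ripple",
    "inject_hf_artifact",
    "inject_sharp_transient",
    "make_synthetic_recording",
    "write_text_recording",
]


@dataclass(frozen=True)
class SynthEvent:
    """One injected event with exact ground-truth timing."""

    kind: str  # ripple | sharp_transient | hf_artifact
    start: float
    duration: float
    center_freq: float = 0.0
    amplitude: float = 0.0  # µV (peak of the envelope)
    channel: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ripple", "sharp_transient", "hf_artifact"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.kind == "ripple" and not (80 <= self.center_freq <= 250):
            raise ValueError("ripple center_freq must lie in the 80-250 Hz band")
        if self.kind == "hf_artifact" and not (500 <= self.center_freq <= 900):
            raise ValueError("hf_artifact center_freq must lie in 500-900 Hz")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class SynthConfig:
    """Synthetic-recording study conditions.

    Background is 1/f^alpha Gaussian noise with total standard deviation
    ``noise_sigma`` µV; event amplitudes are drawn uniformly from
    ``amplitude_range`` in units of ``noise_sigma``.  Rates are events/min.
    """

    fs: float = 2000.0
    duration: float = 300.0
    noise_alpha: float = 1.0
    noise_sigma: float = 10.0  # µV, scalp-EEG background scale
    ripple_rate: float = 2.0
    transient_rate: float = 2.0
    artifact_rate: float = 2.0
    amplitude_range: tuple = (3.0, 6.0)  # multiples of noise_sigma
    ripple_freq_range: tuple = (90.0, 200.0)
    ripple_duration_range: tuple = (0.04, 0.12)
    bilateral_artifact_fraction: float = 0.5
    bilateral: bool = True
    deterministic_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 2 * 900:
            raise ValueError("fs must exceed twice the artifact band top (1800 Hz)")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


def gen_background(cfg: SynthConfig) -> TimeSeries:
    """1/f^alpha colored Gaussian noise at the configured sigma (µV)."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    white = rng.standard_normal(n)
    if cfg.noise_sigma == 0:
        return TimeSeries(np.zeros(n), fs=cfg.fs, label="synth")
    if cfg.noise_alpha == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
        shape = np.ones_like(freqs)
        nz = freqs > 0
        shape[nz] = freqs[nz] ** (-cfg.noise_alpha / 2.0)
        shape[0] = 0.0  # no DC
        x = np.fft.irfft(spec * shape, n=n)
    x *= cfg.noise_sigma / x.std()
    return TimeSeries(x, fs=cfg.fs, label="synth")


def _check_range(ts: TimeSeries, event: SynthEvent) -> None:
    if event.start < 0 or event.end > ts.duration + 1e-9:
        raise ValueError(
            f"event [{event.start:.3f}, {event.end:.3f}) outside signal "
            f"duration {ts.duration:.3f}s"
        )


def inject_ripple(ts: TimeSeries, event: SynthEvent) -> TimeSeries:
    """Add a Gaussian-windowed sinusoid at the event's center frequency.

    The envelope peaks at the event midpoint with sigma = duration/6, so the
    oscillation is effectively confined to the event interval.
    """
    if event.kind != "ripple":
        raise ValueError("event kind must be 'ripple'")
    _check_range(ts, event)
    t = np.arange(ts.n) / ts.fs
    mid = event.start + event.duration / 2
    env = np.exp(-0.5 * ((t - mid) / (event.duration / 6.0)) ** 2)
    wave = event.amplitude * env * np.sin(2 * np.pi * event.center_freq * (t - event.start))
    out = TimeSeries(ts.samples + wave, fs=ts.fs, t0=ts.t0, label=ts.label)
    return out


def inject_hf_artifact(ts: TimeSeries, event: SynthEvent) -> TimeSeries:
    """Add a fast transient artifact burst.

    The burst combines a Gaussian-windowed oscillation in the 500-900 Hz band
    with a sharp biphasic deflection, giving it both substantial >500 Hz
    energy and ripple-band leakage — the signature that must drive the core
    network yet be rejected by the artifact path.
    """
    if event.kind != "hf_artifact":
        raise ValueError("event kind must be 'hf_artifact'")
    _check_range(ts, event)
    t = np.arange(ts.n) / ts.fs
    mid = event.start + event.duration / 2
    env = np.exp(-0.5 * ((t - mid) / (event.duration / 6.0)) ** 2)
    hf = env * np.sin(2 * np.pi * event.center_freq * (t - mid))
    # broadband biphasic kick: derivative-of-Gaussian with ~5 ms half-width
    sig = 0.0025
    kick = -(t - mid) / sig * np.exp(0.5 - 0.5 * ((t - mid) / sig) ** 2)
    wave = event.amplitude * (hf + 1.0 * kick)
    return TimeSeries(ts.samples + wave, fs=ts.fs, t0=ts.t0, label=ts.label)


def inject_sharp_transient(ts: TimeSeries, event: SynthEvent) -> TimeSeries:
    """Add a single biphasic spike-like deflection (broadband, ~10-30 ms).

    Modeled as a derivative-of-Gaussian whose half-width is set by the event
    duration; its spectrum leaks into the ripple band, challenging the core
    network's dis-inhibition motif.
    """
    if event.kind != "sharp_transient":
        raise ValueError("event kind must be 'sharp_transient'")
    _check_range(ts, event)
    t = np.arange(ts.n) / ts.fs
    mid = event.start + event.duration / 2
    sig = event.duration / 5.0
    wave = event.amplitude * (-(t - mid) / sig) * np.exp(0.5 - 0.5 * ((t - mid) / sig) ** 2)
    return TimeSeries(ts.samples + wave, fs=ts.fs, t0=ts.t0, label=ts.label)


_INJECTORS = {
    "ripple": inject_ripple,
    "sharp_transient": inject_sharp_transient,
    "hf_artifact": inject_hf_artifact,
}


def _event_count(rate_per_min: float, duration: float, rng, deterministic: bool) -> int:
    expected = rate_per_min * duration / 60.0
    if deterministic:
        return int(round(expected))
    return int(rng.poisson(expected))


def _draw_events(
    cfg: SynthConfig, rng: np.random.Generator, kind: str, rate: float, channel: str
) -> list[SynthEvent]:
    n = _event_count(rate, cfg.duration, rng, cfg.deterministic_counts)
    lo_a, hi_a = cfg.amplitude_range
    events = []
    margin = 0.5  # keep events clear of the edges
    for _ in range(n):
        if kind == "ripple":
            dur = rng.uniform(*cfg.ripple_duration_range)
            freq = rng.uniform(*cfg.ripple_freq_range)
        elif kind == "hf_artifact":
            dur = rng.uniform(0.02, 0.05)
            freq = rng.uniform(550.0, 850.0)
        else:
            dur = rng.uniform(0.01, 0.03)
            freq = 0.0
        start = rng.uniform(margin, cfg.duration - margin - dur)
        amp = rng.uniform(lo_a, hi_a) * cfg.noise_sigma
        events.append(
            SynthEvent(kind=kind, start=start, duration=dur, center_freq=freq,
                       amplitude=amp, channel=channel)
        )
    return sorted(events, key=lambda e: e.start)


def make_synthetic_recording(cfg: SynthConfig) -> tuple[Recording, list[SynthEvent]]:
    """Generate a bilateral homologous channel pair with exact ground truth.

    Ripples are placed only on the affected channel ("T3-T5"); sharp
    transients are drawn independently per channel; a configurable fraction
    of hf artifacts is placed simultaneously on both channels.  Returns the
    recording and the full ground-truth event list (channel-tagged).
    """
    rng = np.random.default_rng(cfg.seed)
    aff_label, contra_label = "T3-T5", "T4-T6"
    noise_a = gen_background(
        SynthConfig(**{**vars(cfg), "seed": int(rng.integers(2**31))})
    )
    noise_b = gen_background(
        SynthConfig(**{**vars(cfg), "seed": int(rng.integers(2**31))})
    )
    chan_a = TimeSeries(noise_a.samples, fs=cfg.fs, label=aff_label)
    chan_b = TimeSeries(noise_b.samples, fs=cfg.fs, label=contra_label)

    truth: list[SynthEvent] = []
    for ev in _draw_events(cfg, rng, "ripple", cfg.ripple_rate, aff_label):
        chan_a = inject_ripple(chan_a, ev)
        truth.append(ev)
    for label in (aff_label, contra_label) if cfg.bilateral else (aff_label,):
        for ev in _draw_events(cfg, rng, "sharp_transient", cfg.transient_rate, label):
            ch = chan_a if label == aff_label else chan_b
            ch = inject_sharp_transient(ch, ev)
            if label == aff_label:
                chan_a = ch
            else:
                chan_b = ch
            truth.append(ev)
    for ev in _draw_events(cfg, rng, "hf_artifact", cfg.artifact_rate, aff_label):
        chan_a = inject_hf_artifact(chan_a, ev)
        truth.append(ev)
        if cfg.bilateral and rng.uniform() < cfg.bilateral_artifact_fraction:
            twin = SynthEvent(
                kind=ev.kind, start=ev.start, duration=ev.duration,
                center_freq=ev.center_freq, amplitude=ev.amplitude,
                channel=contra_label,
            )
            chan_b = inject_hf_artifact(chan_b, twin)
            truth.append(twin)

    channels = [chan_a, chan_b] if cfg.bilateral else [chan_a]
    hmap = {aff_label: contra_label, contra_label: aff_label} if cfg.bilateral else {}
    rec = Recording(channels=channels, homolog_map=hmap, recording_id="synthetic")
    return rec, sorted(truth, key=lambda e: (e.channel, e.start))


def write_text_recording(rec: Recording, path) -> None:
    """Write a recording in the package's delimited-text format."""
    data = np.column_stack([ts.samples for ts in rec.channels])
    header = f"# fs={rec.fs:g}\n" + ",".join(rec.labels)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.6f")
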