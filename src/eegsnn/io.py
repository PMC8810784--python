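"""EEG input/output: reading, bipolar montage, resampling, segmentation.

Recordings are held as lists of :class:`TimeSeries` in microvolts.  Two input
formats are supported: EDF (the de-facto clinical standard for scalp EEG, read
through MNE) and a delimited numeric text format used for synthetic fixtures.
Time coordinates are seconds from recording start; intervals are half-open
``[start, end)`` throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "Recording",
    "AnnotationRecord",
    "read_recording",
    "make_bipolar",
    "resample_to",
    "segment_intervals",
    "write_annotations",
    "read_annotations",
    "write_rate_table",
]

ANNOTATION_KINDS = ("EoI", "artifact", "HFO", "HFO_rejected_contralateral")


@dataclass
class TimeSeries:
    """A uniformly sampled single-channel signal in microvolts.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in µV.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Start offset in seconds from the recording origin.
    label : str
        Channel name (e.g. ``"T3"`` or bipolar ``"T3-T5"``).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite amplitudes in channel {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class Recording:
    """A multichannel EEG recording with montage metadata.

    ``montage`` lists (anode, cathode) label pairs for the bipolar derivation;
    ``homolog_map`` maps each channel label to its homologous channel on the
    contralateral hemisphere (symmetric).
    """

    channels: list[TimeSeries]
    montage: list[tuple[str, str]] = field(default_factory=list)
    homolog_map: dict[str, str] = field(default_factory=dict)
    recording_id: str = ""
    patient_id: str = ""
    phase: str = "presurgical"

    def __post_init__(self) -> None:
        rates = {ts.fs for ts in self.channels}
        if len(rates) > 1:
            raise ValueError(f"channels have mixed sampling rates: {sorted(rates)}")
        for a, b in self.homolog_map.items():
            if self.homolog_map.get(b) != a:
                raise ValueError(f"homolog_map is not symmetric at {a!r}<->{b!r}")
        labels = {ts.label for ts in self.channels}
        for anode, cathode in self.montage:
            for lab in (anode, cathode):
                if lab not in labels:
                    raise KeyError(f"montage label {lab!r} not found among channels")

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    def channel(self, label: str) -> TimeSeries:
        for ts in self.channels:
            if ts.label == label:
                return ts
        raise KeyError(f"no channel labelled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [ts.label for ts in self.channels]


@dataclass(frozen=True)
class AnnotationRecord:
    """A timestamped event annotation on one channel."""

    channel: str
    start: float
    end: float
    kind: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must precede end ({self.start} >= {self.end})")
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")


def _read_text_recording(path: Path) -> tuple[list[str], np.ndarray, float]:
    """Delimited-text format: ``# fs=<Hz>`` line, header of labels, rows."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs=" not in first:
            raise ValueError(f"{path}: first line must declare '# fs=<Hz>'")
        fs = float(first.split("fs=")[1].split()[0])
        header = fh.readline().strip()
        delim = "\t" if "\t" in header else ","
        labels = [h.strip() for h in header.split(delim)]
        data = np.loadtxt(fh, delimiter=delim, ndmin=2)
    if data.size and data.shape[1] != len(labels):
        raise ValueError(f"{path}: {data.shape[1]} columns but {len(labels)} labels")
    return labels, data, fs


def _read_edf_recording(path: Path) -> tuple[list[str], np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts
    return list(raw.ch_names), (data * 1e6).T, float(raw.info["sfreq"])


def read_recording(
    path: str | Path,
    montage: list[tuple[str, str]] | None = None,
    homolog_map: dict[str, str] | None = None,
    recording_id: str = "",
    patient_id: str = "",
    phase: str = "presurgical",
) -> Recording:
    """Read an EDF or delimited-text EEG file into a :class:`Recording`.

    Channel order in the file is preserved.  Raises ``FileNotFoundError`` /
    ``OSError`` for unreadable files and ``KeyError`` if a montage label is
    absent from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        labels, data, fs = _read_edf_recording(path)
    else:
        labels, data, fs = _read_text_recording(path)
    channels = [TimeSeries(data[:, i], fs=fs, label=lab) for i, lab in enumerate(labels)]
    return Recording(
        channels=channels,
        montage=list(montage or []),
        homolog_map=dict(homolog_map or {}),
        recording_id=recording_id or path.stem,
        patient_id=patient_id,
        phase=phase,
    )


def make_bipolar(recording: Recording) -> Recording:
    """Derive the bipolar montage: each output channel is anode − cathode.

    Output labels are ``"ANODE-CATHODE"``; the homolog map is rewritten so
    that homologous bipolar channels pair up (anode homolog − cathode
    homolog).
    """
    if not recording.montage:
        raise ValueError("recording has no montage pairs")
    out: list[TimeSeries] = []
    for anode, cathode in recording.montage:
        a = recording.channel(anode)
        c = recording.channel(cathode)
        if a.n != c.n:
            raise ValueError(f"channel length mismatch {anode!r} vs {cathode!r}")
        out.append(TimeSeries(a.samples - c.samples, fs=a.fs, t0=a.t0, label=f"{anode}-{cathode}"))

    hmap: dict[str, str] = {}
    pair_labels = {f"{a}-{c}" for a, c in recording.montage}
    for anode, cathode in recording.montage:
        ha = recording.homolog_map.get(anode)
        hc = recording.homolog_map.get(cathode)
        if ha and hc and f"{ha}-{hc}" in pair_labels:
            hmap[f"{anode}-{cathode}"] = f"{ha}-{hc}"
    return replace(recording, channels=out, montage=[], homolog_map=hmap)


def resample_to(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Anti-alias low-pass (cutoff 0.45·target_fs) and decimate to target_fs.

    The polyphase resampler accepts non-integer rate ratios; the common use is
    the factor-5 decimation 10 kHz → 2 kHz.  Duration is preserved to within
    one output sample.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if target_fs > ts.fs:
        raise ValueError(f"target_fs {target_fs} exceeds source rate {ts.fs}")
    if target_fs == ts.fs:
        return replace(ts, samples=ts.samples.copy())
    frac = Fraction(target_fs / ts.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    # FIR designed at the upsampled rate; transition band 0.45..0.5·target_fs.
    fs_up = ts.fs * up
    cutoff = 0.45 * target_fs
    numtaps = int(20 * fs_up / target_fs) | 1
    h = sps.firwin(numtaps, cutoff, fs=fs_up)
    y = sps.resample_poly(ts.samples, up, down, window=h)
    return replace(ts, samples=y, fs=float(target_fs))


def segment_intervals(ts: TimeSeries, length: float = 300.0) -> list[TimeSeries]:
    """Split into consecutive non-overlapping intervals of ``length`` seconds.

    The trailing partial interval is retained; its true duration is carried by
    its sample count so downstream rate denominators stay correct.
    """
    if not length > 0:
        raise ValueError("segment length must be > 0")
    step = int(round(length * ts.fs))
    out = []
    for i0 in range(0, ts.n, step):
        chunk = ts.samples[i0 : i0 + step]
        if chunk.size:
            out.append(replace(ts, samples=chunk, t0=ts.t0 + i0 / ts.fs))
    return out


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    """Write annotations as CSV, rows sorted by (channel, start)."""
    rows = sorted(records, key=lambda r: (r.channel, r.start, r.end))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "start_s", "end_s", "kind"])
        for r in rows:
            w.writerow([r.channel, f"{r.start:.6f}", f"{r.end:.6f}", r.kind])


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AnnotationRecord(
                    channel=row["channel"],
                    start=float(row["start_s"]),
                    end=float(row["end_s"]),
                    kind=row["kind"],
                )
            )
    return out


def write_rate_table(rows: list[dict], path: str | Path) -> None:
    """Write per-channel rates: recording_id, channel, n_hfo, minutes, rate_per_min."""
    cols = ["recording_id", "channel", "n_hfo", "minutes", "rate_per_min"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in sorted(rows, key=lambda r: (str(r["recording_id"]), str(r["channel"]))):
            w.writerow([r["recording_id"], r["channel"], r["n_hfo"], f"{r['minutes']:.4f}", f"{r['rate_per_min']:.6f}"])
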