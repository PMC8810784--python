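"""Shared fixtures: programmatic EDF fixture writer and small networks."""

from __future__ import annotations

import numpy as np
import pytest

from eegsnn.snn import JitterModel, build_artifact_snn, build_core_snn


def write_edf(path, data: np.ndarray, fs: float, labels: list[str],
              phys_range: float = 1000.0) -> None:
    """Write a minimal 16-bit EDF file (1-second data records).

    ``data`` is (n_samples, n_channels) in µV; amplitudes are quantized to
    the ±``phys_range`` µV physical range.
    """
    n_samples, n_ch = data.shape
    fs_i = int(fs)
    assert fs == fs_i and n_samples % fs_i == 0, "EDF fixture needs whole-second data"
    n_records = n_samples // fs_i

    def pad(text, width):
        b = str(text).encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    hdr = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2020 X X X", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(256 * (n_ch + 1), 8),
        pad("", 44),
        pad(n_records, 8),
        pad(1, 8),
        pad(n_ch, 4),
    ])
    fields = [
        (16, lambda i: labels[i]),
        (80, lambda i: ""),
        (8, lambda i: "uV"),
        (8, lambda i: -phys_range),
        (8, lambda i: phys_range),
        (8, lambda i: -32768),
        (8, lambda i: 32767),
        (80, lambda i: ""),
        (8, lambda i: fs_i),
        (32, lambda i: ""),
    ]
    for width, value in fields:
        for i in range(n_ch):
            hdr += pad(value(i), width)

    scale = 32767.0 / phys_range
    dig = np.clip(np.round(data * scale), -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = dig[r * fs_i : (r + 1) * fs_i]
            for c in range(n_ch):
                fh.write(block[:, c].tobytes())


@pytest.fixture(scope="session")
def edf_writer():
    return write_edf


@pytest.fixture(scope="session")
def small_core_net():
    """16-neuron core network without mismatch (fast to simulate)."""
    return build_core_snn(16, JitterModel(cv=0.0))


@pytest.fixture(scope="session")
def small_artifact_net():
    return build_artifact_snn(16, JitterModel(cv=0.0))
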