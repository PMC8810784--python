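"""Pipeline configuration: all detector defaults in one flat, serializable record.

The defaults are the detector's published operating point: ripple band
80-250 Hz, artifact band 500-900 Hz, 2nd-order Butterworth filters, ADM
threshold at 30% of the baseline amplitude, 15 ms event windows, 0.25 HFO/min
rate threshold, 5-min processing intervals, 256-neuron second layers and a
0.1 ms simulation step.  ``input_gain`` maps the synapse table's
current-like weight magnitudes onto normalized LIF currents; its value is the
output of :func:`eegsnn.snn.calibrate_input_gain` (geometric mean of the
largest background-silent gain and the smallest reference-ripple-detecting
gain at cv = 0), stored here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["PipelineConfig", "DEFAULT_INPUT_GAIN", "DEFAULT_ARTIFACT_ADM_FRACTION"]

#: Calibrated global input gain (see module docstring).
DEFAULT_INPUT_GAIN = 0.0361
#: ADM threshold fraction for the 500-900 Hz artifact path.  The artifact
#: network lacks inhibitory control, so its encoder uses a higher fraction of
#: its band's baseline than the ripple path's 30%; the value is the output of
#: :func:`eegsnn.snn.calibrate_artifact_fraction` at the calibrated gain.
DEFAULT_ARTIFACT_ADM_FRACTION = 0.70


@dataclass
class PipelineConfig:
    """Flat key-value configuration for the end-to-end detector."""

    # signal path
    working_fs: float = 2000.0
    ripple_low: float = 80.0
    ripple_high: float = 250.0
    artifact_low: float = 500.0
    artifact_high: float = 900.0
    filter_order: int = 2
    zero_phase: bool = False
    # baseline / ADM
    baseline_window_s: float = 1.0
    baseline_percentile: float = 25.0
    adm_fraction: float = 0.30
    artifact_adm_fraction: float = DEFAULT_ARTIFACT_ADM_FRACTION
    adm_refractory_s: float = 0.0
    # networks
    n_core: int = 256
    n_artifact: int = 256
    cv: float = 0.1
    gi_rate_hz: float = 100.0
    input_gain: float = DEFAULT_INPUT_GAIN
    dt_ms: float = 0.1
    # event logic
    eoi_window_s: float = 0.015
    artifact_window_s: float = 0.015
    min_spikes: int = 1
    rate_threshold: float = 0.25
    interval_s: float = 300.0
    # run control
    seed: int = 0
    input: str = ""
    montage: str = ""
    out: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.ripple_low < self.ripple_high < self.working_fs / 2:
            raise ValueError("ripple band must satisfy 0 < low < high < fs/2")
        if not 0 < self.artifact_low < self.artifact_high < self.working_fs / 2:
            raise ValueError("artifact band must satisfy 0 < low < high < fs/2")
        if not 0 < self.adm_fraction:
            raise ValueError("adm_fraction must be > 0")
        if not 0 < self.dt_ms <= 1.0:
            raise ValueError("dt_ms must be in (0, 1]")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")
        if not self.interval_s > 0:
            raise ValueError("interval_s must be > 0")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        """Read a flat ``key=value`` file; unknown keys are an error."""
        raw: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        raw.update(overrides or {})
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in types:
                raise KeyError(f"unknown config key {k!r}")
            if isinstance(v, str):
                t = types[k]
                if t == "bool":
                    v = v.lower() in ("1", "true", "yes")
                elif t == "int":
                    v = int(v)
                elif t == "float":
                    v = float(v)
            kwargs[k] = v
        return cls(**kwargs)
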