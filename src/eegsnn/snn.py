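"""Leaky integrate-and-fire network construction and fixed-step simulation.

Two networks are built from the published synapse table:

* the **core SNN** — UP/DN input ports projecting to a grid of second-layer
  neurons (excitatory from UP, matched-strength short-tau inhibitory from DN)
  plus a dis-inhibition motif: a dis-inhibitory neuron driven by both ports
  inhibits a tonically firing global-inhibitory neuron, which continuously
  inhibits the second layer.  The motif suppresses responses to isolated
  sharp transients while sustained ripple input releases the layer.
* the **artifact SNN** — the same input-to-layer projection pattern with no
  inhibitory-control neurons, fed from the 500-900 Hz band.

Neuron dynamics use normalized units (v_reset = 0, v_th = 1); a single global
input gain maps the table's current-like weight magnitudes onto normalized
currents.  Circuit mismatch is emulated by jittering every synaptic weight and
time constant with a truncated normal of given coefficient of variation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._kernels import lif_membrane_trace, lif_step_loop
from .preprocess import SpikeTrain

__all__ = [
    "NeuronParams",
    "SynapseSpec",
    "NetworkSpec",
    "JitterModel",
    "SpikeRaster",
    "sample_jittered",
    "build_core_snn",
    "build_artifact_snn",
    "simulate",
    "membrane_trace",
    "bias_for_tonic_rate",
    "calibrate_input_gain",
    "calibrate_artifact_fraction",
]

# Synapse table of the EEG SNN (weights in circuit-current units, taus in ms).
W_LAYER_RANGE = (7.0, 14.0)     # UP -> second layer, excitatory
TAU_EXC_RANGE_MS = (3.0, 6.0)   # excitatory synaptic time constants
TAU_INH_RANGE_MS = (0.1, 1.0)   # DN -> second layer inhibition (fast)
W_DI = 21.0                     # UP/DN -> dis-inhibitory neuron, excitatory
TAU_DI_MS = 5.0
W_DI_GI = 7.5                   # dis-inhibitory -> global-inhibitory, inhibitory
TAU_DI_GI_MS = 20.0
W_GI = 21.0                     # global-inhibitory -> second layer, inhibitory
TAU_GI_MS = 5.0

# Normalized LIF constants shared by all neurons.
TAU_M_MS = 10.0
V_TH = 1.0
V_RESET = 0.0
T_REF_MS = 3.0
GI_TONIC_RATE_HZ = 100.0


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron constants: times in ms, voltages in normalized units."""

    tau_m: float = TAU_M_MS
    v_th: float = V_TH
    v_reset: float = V_RESET
    t_ref: float = T_REF_MS
    i_bias: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError("tau_m must be > 0")
        if not self.v_th > self.v_reset:
            raise ValueError("v_th must exceed v_reset")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")


@dataclass(frozen=True)
class SynapseSpec:
    """A connection: positive weight, polarity gives the sign, tau_s in ms."""

    pre: str
    post: str
    weight: float
    polarity: str  # "exc" | "inh"
    tau_s: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("synapse weight must be > 0")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be > 0")
        if self.polarity not in ("exc", "inh"):
            raise ValueError(f"polarity must be exc or inh, got {self.polarity!r}")

    @property
    def signed_weight(self) -> float:
        return self.weight if self.polarity == "exc" else -self.weight


@dataclass
class NetworkSpec:
    """A complete network: neurons, synapses, input ports, readout set."""

    neurons: list[tuple[str, NeuronParams]]
    synapses: list[SynapseSpec]
    inputs: tuple[str, ...] = ("UP", "DN")
    readout: frozenset = frozenset()

    def __post_init__(self) -> None:
        ids = {nid for nid, _ in self.neurons}
        for s in self.synapses:
            if s.pre not in ids and s.pre not in self.inputs:
                raise ValueError(f"synapse source {s.pre!r} unresolved")
            if s.post not in ids:
                raise ValueError(f"synapse target {s.post!r} unresolved")
        if not self.readout:
            raise ValueError("readout set must be non-empty")
        if not self.readout <= ids:
            raise ValueError("readout ids must be network neurons")

    def to_json(self) -> str:
        return json.dumps(
            {
                "neurons": [
                    {"id": nid, **vars(p)} for nid, p in self.neurons
                ],
                "synapses": [vars(s) for s in self.synapses],
                "inputs": list(self.inputs),
                "readout": sorted(self.readout),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            neurons=[(n.pop("id"), NeuronParams(**n)) for n in d["neurons"]],
            synapses=[SynapseSpec(**s) for s in d["synapses"]],
            inputs=tuple(d["inputs"]),
            readout=frozenset(d["readout"]),
        )


@dataclass
class JitterModel:
    """Parameter mismatch model: truncated Normal(value, cv*value).

    ``cv`` may be a scalar or a mapping per parameter class
    (``{"weight": ..., "tau": ...}``).
    """

    cv: float | dict = 0.0
    seed: int = 0

    def cv_for(self, kind: str) -> float:
        c = self.cv[kind] if isinstance(self.cv, dict) else self.cv
        if c < 0:
            raise ValueError("cv must be >= 0")
        return float(c)


@dataclass
class SpikeRaster:
    """Per-neuron spike times (s) over a simulation window."""

    trains: dict
    duration: float

    def pooled_times(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate([t for t in self.trains.values()]))

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def to_csv(self, path) -> None:
        """Export the raster as CSV (neuron_id, time_s), sorted."""
        with open(path, "w") as fh:
            fh.write("neuron_id,time_s\n")
            for nid in sorted(self.trains):
                for t in self.trains[nid]:
                    fh.write(f"{nid},{t:.6f}\n")


def sample_jittered(
    value: float,
    jitter: JitterModel,
    rng: np.random.Generator | None = None,
    kind: str = "weight",
) -> float:
    """Draw a mismatched parameter value: Normal(value, cv*value), floored at
    5% of the nominal value to preserve positivity."""
    cv = jitter.cv_for(kind)
    if cv == 0:
        return float(value)
    if rng is None:
        rng = np.random.default_rng(jitter.seed)
    draw = rng.normal(value, cv * value)
    return float(max(draw, 0.05 * value))


def bias_for_tonic_rate(rate_hz: float, p: NeuronParams = NeuronParams()) -> float:
    """Constant bias current giving a LIF neuron the requested tonic rate.

    Inverts the noiseless LIF f-I curve
    ``T = t_ref + tau_m * ln(I / (I - v_th))`` (with v_reset = 0).
    """
    t_int = 1000.0 / rate_hz - p.t_ref  # ms of integration per cycle
    if t_int <= 0:
        raise ValueError("requested rate exceeds 1/t_ref")
    span = p.v_th - p.v_reset
    return p.v_reset + span / (1.0 - math.exp(-t_int / p.tau_m))


def _grid(n: int, lo: float, hi: float) -> np.ndarray:
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n)


def _layer_synapses(
    n_second_layer: int, jitter: JitterModel, rng: np.random.Generator, suffix: str
) -> tuple[list[str], list[SynapseSpec]]:
    """The shared input→layer tiling: a k×k grid over excitatory weight and
    tau, with matched-strength fast DN inhibition aligned on the tau axis."""
    k = math.isqrt(n_second_layer)
    if k * k != n_second_layer:
        raise ValueError(
            f"n_second_layer must be a perfect square to tile the "
            f"weight x tau grid, got {n_second_layer}"
        )
    weights = _grid(k, *W_LAYER_RANGE)
    taus_exc = _grid(k, *TAU_EXC_RANGE_MS)
    taus_inh = _grid(k, *TAU_INH_RANGE_MS)
    ids: list[str] = []
    syns: list[SynapseSpec] = []
    idx = 0
    for iw in range(k):
        for it in range(k):
            nid = f"L{suffix}{idx:03d}"
            ids.append(nid)
            w = sample_jittered(weights[iw], jitter, rng, "weight")
            te = sample_jittered(taus_exc[it], jitter, rng, "tau")
            ti = sample_jittered(taus_inh[it], jitter, rng, "tau")
            syns.append(SynapseSpec("UP", nid, w, "exc", te))
            # DN inhibition strength references the paired UP weight
            syns.append(SynapseSpec("DN", nid, w, "inh", ti))
            idx += 1
    return ids, syns


def build_core_snn(
    n_second_layer: int = 256,
    jitter: JitterModel = JitterModel(),
    gi_rate_hz: float = GI_TONIC_RATE_HZ,
) -> NetworkSpec:
    """Core HFO-detection network with the dis-inhibition motif.

    The second layer tiles the published parameter ranges (weight 7-14,
    excitatory tau 3-6 ms, inhibitory tau 0.1-1 ms) as a uniform grid; both
    ports drive the dis-inhibitory neuron (weight 21, tau 5 ms), which
    inhibits the global-inhibitory neuron (weight 7.5, tau 20 ms); the
    global-inhibitory neuron fires tonically from a constant bias and
    inhibits every layer neuron (weight 21, tau 5 ms).
    """
    if n_second_layer < 1:
        raise ValueError("need at least one second-layer neuron")
    rng = np.random.default_rng(jitter.seed)
    ids, syns = _layer_synapses(n_second_layer, jitter, rng, "")
    neurons = [(nid, NeuronParams()) for nid in ids]
    neurons.append(("di", NeuronParams()))
    neurons.append(("gi", NeuronParams(i_bias=bias_for_tonic_rate(gi_rate_hz))))
    for port in ("UP", "DN"):
        syns.append(
            SynapseSpec(
                port, "di",
                sample_jittered(W_DI, jitter, rng, "weight"),
                "exc",
                sample_jittered(TAU_DI_MS, jitter, rng, "tau"),
            )
        )
    syns.append(
        SynapseSpec(
            "di", "gi",
            sample_jittered(W_DI_GI, jitter, rng, "weight"),
            "inh",
            sample_jittered(TAU_DI_GI_MS, jitter, rng, "tau"),
        )
    )
    for nid in ids:
        syns.append(
            SynapseSpec(
                "gi", nid,
                sample_jittered(W_GI, jitter, rng, "weight"),
                "inh",
                sample_jittered(TAU_GI_MS, jitter, rng, "tau"),
            )
        )
    return NetworkSpec(neurons=neurons, synapses=syns, readout=frozenset(ids))


def build_artifact_snn(
    n_second_layer: int = 256, jitter: JitterModel = JitterModel()
) -> NetworkSpec:
    """Artifact-detection network: input ports to second layer only."""
    if n_second_layer < 1:
        raise ValueError("need at least one second-layer neuron")
    rng = np.random.default_rng(jitter.seed)
    ids, syns = _layer_synapses(n_second_layer, jitter, rng, "a")
    neurons = [(nid, NeuronParams()) for nid in ids]
    return NetworkSpec(neurons=neurons, synapses=syns, readout=frozenset(ids))


def _compile(network: NetworkSpec, dt_s: float, gain: float):
    index = {nid: i for i, (nid, _) in enumerate(network.neurons)}
    n = len(network.neurons)
    tau_m = np.empty(n)
    alpha = np.empty(n)
    v_th = np.empty(n)
    v_reset = np.empty(n)
    ref_steps = np.empty(n, dtype=np.int64)
    i_bias = np.empty(n)
    for i, (_, p) in enumerate(network.neurons):
        tau_m[i] = p.tau_m * 1e-3
        alpha[i] = math.exp(-dt_s / tau_m[i])
        v_th[i] = p.v_th
        v_reset[i] = p.v_reset
        ref_steps[i] = int(round(p.t_ref * 1e-3 / dt_s))
        i_bias[i] = p.i_bias

    n_syn = len(network.synapses)
    s_post = np.empty(n_syn, dtype=np.int64)
    s_w = np.empty(n_syn)
    s_decay = np.empty(n_syn)
    s_gamma = np.empty(n_syn)
    up_syn, dn_syn = [], []
    by_neuron: list[list[int]] = [[] for _ in range(n)]
    for s_i, s in enumerate(network.synapses):
        post = index[s.post]
        s_post[s_i] = post
        tau_s = s.tau_s * 1e-3
        if abs(tau_s - tau_m[post]) < 1e-9:  # avoid the degenerate equal-tau pole
            tau_s *= 1.0 + 1e-6
        s_w[s_i] = s.signed_weight * gain
        s_decay[s_i] = math.exp(-dt_s / tau_s)
        s_gamma[s_i] = tau_s / (tau_s - tau_m[post])
        if s.pre == "UP":
            up_syn.append(s_i)
        elif s.pre == "DN":
            dn_syn.append(s_i)
        else:
            by_neuron[index[s.pre]].append(s_i)
    start = np.zeros(n + 1, dtype=np.int64)
    flat: list[int] = []
    for j in range(n):
        start[j + 1] = start[j] + len(by_neuron[j])
        flat.extend(by_neuron[j])
    return (
        index,
        (alpha, v_th, v_reset, ref_steps, i_bias),
        (s_post, s_w, s_decay, s_gamma),
        (np.array(up_syn, dtype=np.int64), np.array(dn_syn, dtype=np.int64)),
        (start, np.array(flat, dtype=np.int64)),
    )


def _input_steps(train, duration: float, dt_s: float) -> np.ndarray:
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size and times.max() >= duration:
        raise ValueError("input spike times must be < duration")
    return np.sort((times / dt_s).astype(np.int64))


def simulate(
    network: NetworkSpec,
    inputs: dict,
    duration: float,
    dt_ms: float = 0.1,
    gain: float = 1.0,
    record: set | None = None,
) -> SpikeRaster:
    """Run the clock-driven LIF simulation and return the readout raster.

    ``inputs`` maps port names ("UP", "DN") to :class:`SpikeTrain` (or plain
    time arrays, seconds).  ``gain`` scales every synaptic weight, mapping
    table weight magnitudes onto normalized currents.  ``record`` widens the
    returned raster beyond ``network.readout`` (e.g. to inspect the
    inhibitory-control neurons).  Deterministic given inputs and network.
    """
    if not (0 < dt_ms <= 1.0):
        raise ValueError(f"dt must be in (0, 1] ms for stability, got {dt_ms}")
    dt_s = dt_ms * 1e-3
    n_steps = int(round(duration / dt_s))
    index, neuron_arrays, syn_arrays, port_syn, csr = _compile(network, dt_s, gain)
    up_steps = _input_steps(inputs.get("UP", np.empty(0)), duration, dt_s)
    dn_steps = _input_steps(inputs.get("DN", np.empty(0)), duration, dt_s)
    spk_n, spk_t = lif_step_loop(
        n_steps, *neuron_arrays, *syn_arrays, *port_syn, *csr, up_steps, dn_steps
    )
    wanted = set(network.readout) if record is None else set(record)
    trains: dict[str, np.ndarray] = {nid: np.empty(0) for nid in wanted}
    times = (spk_t + 1) * dt_s
    rev = {i: nid for nid, i in index.items()}
    for i in np.unique(spk_n):
        nid = rev[int(i)]
        if nid in wanted:
            trains[nid] = times[spk_n == i]
    return SpikeRaster(trains=trains, duration=duration)


def membrane_trace(
    network: NetworkSpec,
    inputs: dict,
    duration: float,
    neuron: str,
    dt_ms: float = 0.1,
    gain: float = 1.0,
) -> np.ndarray:
    """Membrane-potential trace of one neuron (same dynamics as simulate)."""
    if not (0 < dt_ms <= 1.0):
        raise ValueError(f"dt must be in (0, 1] ms, got {dt_ms}")
    dt_s = dt_ms * 1e-3
    n_steps = int(round(duration / dt_s))
    index, neuron_arrays, syn_arrays, port_syn, csr = _compile(network, dt_s, gain)
    up_steps = _input_steps(inputs.get("UP", np.empty(0)), duration, dt_s)
    dn_steps = _input_steps(inputs.get("DN", np.empty(0)), duration, dt_s)
    return lif_membrane_trace(
        n_steps, *neuron_arrays, *syn_arrays, *port_syn, *csr,
        up_steps, dn_steps, index[neuron],
    )


def calibrate_input_gain(
    fs: float = 2000.0,
    n_second_layer: int = 256,
    noise_duration: float = 20.0,
    ripple_snr: float = 3.0,
    seed: int = 12345,
    n_iter: int = 12,
) -> dict:
    """Calibrate the global input gain on synthetic reference signals.

    Finds, by bisection, the largest gain at which stationary 1/f background
    noise elicits no second-layer spike (``gain_silent``) and the smallest
    gain at which a 120 Hz ripple at ``ripple_snr`` times the baseline
    amplitude drives at least one second-layer neuron (``gain_fire``), both
    at cv = 0.  The recommended operating gain is their geometric mean.
    """
    from .io import TimeSeries
    from .preprocess import (
        AdmConfig, FilterSpec, RIPPLE_BAND, adm_encode, bandpass_filter,
        estimate_baseline, spike_threshold_from_baseline,
    )
    from .synth import SynthConfig, SynthEvent, gen_background, inject_ripple

    cfg = SynthConfig(fs=fs, duration=noise_duration, seed=seed)
    noise = gen_background(cfg)
    band = FilterSpec(*RIPPLE_BAND)
    filt_noise = bandpass_filter(noise, band)
    baseline = estimate_baseline(filt_noise)
    thr = spike_threshold_from_baseline(baseline)

    ripple = SynthEvent(
        kind="ripple", start=noise_duration / 2, duration=0.08,
        center_freq=120.0, amplitude=ripple_snr * baseline.amplitude,
    )
    with_ripple = bandpass_filter(inject_ripple(noise, ripple), band)

    net = build_core_snn(n_second_layer, JitterModel(cv=0.0))
    adm = AdmConfig(threshold=thr)

    def layer_spikes(ts: TimeSeries, gain: float) -> int:
        up, dn = adm_encode(ts, adm)
        raster = simulate(net, {"UP": up, "DN": dn}, ts.duration, gain=gain)
        return raster.n_spikes

    lo, hi = 1e-4, 1.0
    # largest gain with silent background
    a, b = lo, hi
    for _ in range(n_iter):
        mid = math.sqrt(a * b)
        if layer_spikes(filt_noise, mid) == 0:
            a = mid
        else:
            b = mid
    gain_silent = a
    # smallest gain detecting the reference ripple
    a, b = lo, hi
    for _ in range(n_iter):
        mid = math.sqrt(a * b)
        if layer_spikes(with_ripple, mid) >= 1:
            b = mid
        else:
            a = mid
    gain_fire = b
    return {
        "gain_silent": gain_silent,
        "gain_fire": gain_fire,
        "gain": math.sqrt(gain_silent * gain_fire),
        "adm_threshold_uv": thr,
        "baseline_uv": baseline.amplitude,
    }


def calibrate_artifact_fraction(
    gain: float,
    fs: float = 2000.0,
    n_second_layer: int = 256,
    noise_duration: float = 20.0,
    burst_snr: float = 3.0,
    seed: int = 12345,
    n_iter: int = 12,
) -> dict:
    """Calibrate the ADM threshold fraction for the 500-900 Hz artifact path.

    The artifact network has no inhibitory control, so its encoder must be
    less eager than the ripple-band one: at the ripple band's 30% fraction
    the high-frequency noise floor alone drives the layer.  Bisection finds
    the smallest fraction at which 1/f background elicits no artifact-layer
    spike (``fraction_silent``) and the largest fraction at which a reference
    high-frequency burst (amplitude ``burst_snr`` times the background
    standard deviation) is still detected (``fraction_fire``); the
    recommended operating point is their geometric mean.
    """
    from .preprocess import (
        AdmConfig, ARTIFACT_BAND, FilterSpec, adm_encode, bandpass_filter,
        estimate_baseline, spike_threshold_from_baseline,
    )
    from .synth import SynthConfig, SynthEvent, gen_background, inject_hf_artifact

    cfg = SynthConfig(fs=fs, duration=noise_duration, seed=seed)
    noise = gen_background(cfg)
    band = FilterSpec(*ARTIFACT_BAND)
    filt_noise = bandpass_filter(noise, band)
    baseline = estimate_baseline(filt_noise)

    burst = SynthEvent(
        kind="hf_artifact", start=noise_duration / 2, duration=0.03,
        center_freq=700.0, amplitude=burst_snr * cfg.noise_sigma,
    )
    with_burst = bandpass_filter(inject_hf_artifact(noise, burst), band)

    net = build_artifact_snn(n_second_layer, JitterModel(cv=0.0))

    def layer_spikes(ts, fraction: float) -> int:
        thr = spike_threshold_from_baseline(baseline, fraction)
        up, dn = adm_encode(ts, AdmConfig(threshold=thr))
        raster = simulate(net, {"UP": up, "DN": dn}, ts.duration, gain=gain)
        return raster.n_spikes

    lo, hi = 0.05, 20.0
    a, b = lo, hi
    for _ in range(n_iter):  # smallest fraction silencing the background
        mid = math.sqrt(a * b)
        if layer_spikes(filt_noise, mid) == 0:
            b = mid
        else:
            a = mid
    fraction_silent = b
    a, b = lo, hi
    for _ in range(n_iter):  # largest fraction still detecting the burst
        mid = math.sqrt(a * b)
        if layer_spikes(with_burst, mid) >= 1:
            a = mid
        else:
            b = mid
    fraction_fire = a
    return {
        "fraction_silent": fraction_silent,
        "fraction_fire": fraction_fire,
        "fraction": math.sqrt(fraction_silent * fraction_fire),
        "baseline_uv": baseline.amplitude,
    }
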