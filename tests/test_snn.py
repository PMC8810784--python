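"""Network construction from the parameter table and LIF simulation dynamics."""

import math

import numpy as np
import pytest

from eegsnn.snn import (
    JitterModel,
    NetworkSpec,
    NeuronParams,
    SynapseSpec,
    bias_for_tonic_rate,
    build_artifact_snn,
    build_core_snn,
    membrane_trace,
    sample_jittered,
    simulate,
)


def _single_neuron_net(weight=1.0, tau_s=5.0, v_th=1.0, i_bias=0.0):
    return NetworkSpec(
        neurons=[("n0", NeuronParams(v_th=v_th, i_bias=i_bias))],
        synapses=[SynapseSpec("UP", "n0", weight, "exc", tau_s)],
        readout=frozenset({"n0"}),
    )


class TestSampleJittered:
    def test_cv_zero_returns_nominal(self):
        assert sample_jittered(5.0, JitterModel(cv=0.0)) == 5.0

    def test_sample_statistics(self):
        rng = np.random.default_rng(0)
        jit = JitterModel(cv=0.1)
        draws = np.array([sample_jittered(5.0, jit, rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(5.0, rel=0.01)
        assert draws.std() / draws.mean() == pytest.approx(0.1, rel=0.10)

    def test_truncation_floor(self):
        rng = np.random.default_rng(1)
        jit = JitterModel(cv=2.0)
        draws = [sample_jittered(5.0, jit, rng) for _ in range(2000)]
        assert min(draws) >= 0.25  # 5% of nominal

    def test_per_class_cv(self):
        jit = JitterModel(cv={"weight": 0.0, "tau": 0.5})
        assert sample_jittered(7.0, jit, kind="weight") == 7.0
        assert jit.cv_for("tau") == 0.5


class TestBuildCoreSnn:
    def test_structure_and_table_values(self):
        net = build_core_snn(256, JitterModel(cv=0.0))
        layer = [nid for nid, _ in net.neurons if nid.startswith("L")]
        assert len(layer) == 256
        assert net.readout == frozenset(layer)
        by_edge = {(s.pre, s.post): s for s in net.synapses}
        up_di = by_edge[("UP", "di")]
        assert (up_di.weight, up_di.polarity, up_di.tau_s) == (21.0, "exc", 5.0)
        dn_di = by_edge[("DN", "di")]
        assert (dn_di.weight, dn_di.polarity) == (21.0, "exc")
        di_gi = by_edge[("di", "gi")]
        assert (di_gi.weight, di_gi.polarity, di_gi.tau_s) == (7.5, "inh", 20.0)
        gi_l0 = by_edge[("gi", layer[0])]
        assert (gi_l0.weight, gi_l0.polarity, gi_l0.tau_s) == (21.0, "inh", 5.0)
        # grid spans the printed ranges
        ws = sorted({s.weight for s in net.synapses if s.pre == "UP" and s.post in layer})
        assert ws[0] == 7.0 and ws[-1] == 14.0 and len(ws) == 16
        taus_e = sorted({s.tau_s for s in net.synapses if s.pre == "UP" and s.post in layer})
        assert taus_e[0] == 3.0 and taus_e[-1] == 6.0
        taus_i = sorted({s.tau_s for s in net.synapses if s.pre == "DN" and s.post in layer})
        assert taus_i[0] == 0.1 and taus_i[-1] == 1.0
        # DN inhibition strength mirrors the paired UP weight
        for nid in layer:
            assert by_edge[("DN", nid)].weight == by_edge[("UP", nid)].weight

    def test_single_neuron_grid_midpoint(self):
        net = build_core_snn(1, JitterModel(cv=0.0))
        up = next(s for s in net.synapses if s.pre == "UP" and s.post.startswith("L"))
        assert up.weight == pytest.approx(10.5)
        assert up.tau_s == pytest.approx(4.5)

    def test_same_seed_reproducible(self):
        a = build_core_snn(16, JitterModel(cv=0.2, seed=7))
        b = build_core_snn(16, JitterModel(cv=0.2, seed=7))
        assert a.synapses == b.synapses
        c = build_core_snn(16, JitterModel(cv=0.2, seed=8))
        assert a.synapses != c.synapses

    def test_non_square_layer_rejected(self):
        with pytest.raises(ValueError, match="perfect square"):
            build_core_snn(12, JitterModel(cv=0.0))

    def test_raster_csv_export(self, tmp_path):
        net = _single_neuron_net(weight=8.0, tau_s=5.0, v_th=1.0)
        raster = simulate(net, {"UP": np.array([0.05, 0.25])}, duration=0.5)
        p = tmp_path / "raster.csv"
        raster.to_csv(p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "neuron_id,time_s"
        assert len(lines) == 1 + raster.n_spikes
        assert all(line.startswith("n0,") for line in lines[1:])

    def test_json_round_trip(self):
        net = build_core_snn(4, JitterModel(cv=0.1, seed=3))
        back = NetworkSpec.from_json(net.to_json())
        assert back.neurons == net.neurons
        assert back.synapses == net.synapses
        assert back.readout == net.readout


class TestBuildArtifactSnn:
    def test_no_inhibitory_control_neurons(self):
        net = build_artifact_snn(256, JitterModel(cv=0.0))
        ids = {nid for nid, _ in net.neurons}
        assert "di" not in ids and "gi" not in ids
        assert len(ids) == 256
        assert all(p.i_bias == 0.0 for _, p in net.neurons)

    def test_zero_input_empty_raster(self, small_artifact_net):
        raster = simulate(small_artifact_net, {}, duration=0.5, gain=0.05)
        assert raster.n_spikes == 0

    def test_same_seed_identical(self):
        a = build_artifact_snn(16, JitterModel(cv=0.3, seed=5))
        b = build_artifact_snn(16, JitterModel(cv=0.3, seed=5))
        assert a.synapses == b.synapses


class TestSimulate:
    def test_no_input_no_bias_empty(self, small_artifact_net):
        raster = simulate(small_artifact_net, {"UP": np.empty(0)}, duration=1.0)
        assert raster.n_spikes == 0

    def test_subthreshold_matches_difference_of_exponentials(self):
        w, tau_s, tau_m = 1.0, 5.0, 10.0
        net = _single_neuron_net(weight=w, tau_s=tau_s, v_th=10.0)
        dt_ms = 0.05
        trace = membrane_trace(net, {"UP": np.array([0.01])}, 0.1, "n0", dt_ms=dt_ms)
        t = (np.arange(trace.size) + 1) * dt_ms * 1e-3
        td = np.clip(t - 0.01, 0, None)
        ts_, tm_ = tau_s * 1e-3, tau_m * 1e-3
        analytic = np.where(
            td > 0,
            w * ts_ / (tm_ - ts_) * (np.exp(-td / tm_) - np.exp(-td / ts_)),
            0.0,
        )
        peak = analytic.max()
        assert np.max(np.abs(trace - analytic)) < 0.01 * peak

    def test_ten_suprathreshold_inputs_ten_spikes(self):
        # single UP spike is suprathreshold (peak 2 v_th); inputs 100 ms apart
        net = _single_neuron_net(weight=8.0, tau_s=5.0, v_th=1.0)
        times = 0.05 + 0.1 * np.arange(10)
        raster = simulate(net, {"UP": times}, duration=1.05)
        assert raster.trains["n0"].size == 10

    def test_refractory_interval_enforced(self):
        # strong tonic drive: spikes must stay >= t_ref apart
        net = NetworkSpec(
            neurons=[("n0", NeuronParams(i_bias=50.0))],
            synapses=[SynapseSpec("UP", "n0", 1.0, "exc", 5.0)],
            readout=frozenset({"n0"}),
        )
        raster = simulate(net, {}, duration=0.5)
        gaps = np.diff(raster.trains["n0"])
        assert gaps.size > 10
        assert gaps.min() >= NeuronParams().t_ref * 1e-3 - 1e-9

    def test_tonic_rate_matches_bias_inversion(self):
        rate = 100.0
        net = NetworkSpec(
            neurons=[("gi", NeuronParams(i_bias=bias_for_tonic_rate(rate)))],
            synapses=[SynapseSpec("UP", "gi", 1.0, "exc", 5.0)],
            readout=frozenset({"gi"}),
        )
        raster = simulate(net, {}, duration=2.0)
        assert raster.trains["gi"].size == pytest.approx(2 * rate, rel=0.03)

    def test_dt_bounds_enforced(self, small_artifact_net):
        with pytest.raises(ValueError, match="dt"):
            simulate(small_artifact_net, {}, 0.1, dt_ms=0.0)
        with pytest.raises(ValueError, match="dt"):
            simulate(small_artifact_net, {}, 0.1, dt_ms=2.0)

    def test_late_input_spike_rejected(self, small_artifact_net):
        with pytest.raises(ValueError, match="duration"):
            simulate(small_artifact_net, {"UP": np.array([0.2])}, duration=0.1)


def _barrage(duration=0.3, rate=1000.0):
    times = np.arange(0, duration - 3e-3, 1.0 / rate) + 1e-3
    return {"UP": times, "DN": times + 0.4e-3}


class TestDisinhibitionMotif:
    def test_barrage_silences_global_inhibitor_and_releases_layer(self, small_core_net):
        gain = 0.05
        raster = simulate(
            small_core_net, _barrage(), 0.3, gain=gain,
            record=set(small_core_net.readout) | {"gi"},
        )
        gi = raster.trains["gi"]
        quiet = simulate(small_core_net, {}, 0.3, gain=gain, record={"gi"})
        assert quiet.trains["gi"].size == pytest.approx(0.3 * 100, rel=0.1)
        # dis-inhibition: gi stops firing shortly after the barrage starts
        assert gi[gi > 0.1].size == 0
        layer_spikes = sum(
            raster.trains[n].size for n in small_core_net.readout
        )
        assert layer_spikes > 0

    def test_removing_disinhibitory_neuron_reduces_layer_output(self, small_core_net):
        gain = 0.05
        no_di = NetworkSpec(
            neurons=[(n, p) for n, p in small_core_net.neurons if n != "di"],
            synapses=[s for s in small_core_net.synapses
                      if s.pre != "di" and s.post != "di"],
            readout=small_core_net.readout,
        )
        full = simulate(small_core_net, _barrage(), 0.3, gain=gain)
        ablated = simulate(no_di, _barrage(), 0.3, gain=gain)
        assert ablated.n_spikes < full.n_spikes

    def test_layer_output_monotone_in_input_density(self, small_core_net):
        gain = 0.05
        rng = np.random.default_rng(5)
        base = np.sort(rng.uniform(0.0, 0.3, 150))
        extra = np.sort(np.concatenate([base, rng.uniform(0.0, 0.3, 150)]))
        extra += np.arange(extra.size) * 1e-9  # keep strictly increasing
        sparse = simulate(small_core_net, {"UP": base}, 0.31, gain=gain)
        dense = simulate(small_core_net, {"UP": extra}, 0.31, gain=gain)
        assert dense.n_spikes >= sparse.n_spikes


class TestSpecValidation:
    def test_unresolved_synapse_rejected(self):
        with pytest.raises(ValueError, match="unresolved"):
            NetworkSpec(
                neurons=[("a", NeuronParams())],
                synapses=[SynapseSpec("a", "missing", 1.0, "exc", 5.0)],
                readout=frozenset({"a"}),
            )

    def test_empty_readout_rejected(self):
        with pytest.raises(ValueError, match="readout"):
            NetworkSpec(neurons=[("a", NeuronParams())], synapses=[], readout=frozenset())

    def test_neuron_param_invariants(self):
        with pytest.raises(ValueError):
            NeuronParams(tau_m=0.0)
        with pytest.raises(ValueError):
            NeuronParams(v_th=0.0, v_reset=0.0)
        with pytest.raises(ValueError):
            SynapseSpec("UP", "a", -1.0, "exc", 5.0)
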