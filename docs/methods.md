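# Methods

## Scope and model

`eegsnn` detects interictal high-frequency oscillations (HFO) in the ripple
band (80–250 Hz) of scalp EEG with a fixed, untrained two-layer spiking
neural network, screens the candidates with a parallel artifact-detection
network operating on the 500–900 Hz band, rejects events co-occurring on the
homologous contralateral channel, and relates the resulting per-recording HFO
rates to epilepsy state and seizure frequency.  Detection runs independently
per bipolar channel and per 5-minute interval; rates use the true analyzed
duration, including partial trailing intervals.

## Signal path

1. **Band-pass filtering.** 2nd-order Butterworth band-passes (80–250 Hz for
   the detection path, 500–900 Hz for the artifact path), applied causally
   (forward-only) to mirror an analog filter stage; a `zero_phase` switch
   enables forward–backward filtering for exploratory use.  The >500 Hz
   artifact band deliberately avoids the 250–500 Hz fast-ripple band so fast
   ripples are never consumed as artifacts.
2. **Baseline (noise-floor) estimation.** The filtered interval is cut into
   non-overlapping 1-s windows; the baseline amplitude is the mean
   peak-to-peak value of the windows at or below the 25th percentile of all
   window peak-to-peak values.  Sparse large events land in the upper
   quartiles and are excluded, so the estimate tracks the stationary
   background.  The estimator is deterministic; window length and percentile
   are config keys.  This quiet-window quartile definition is this package's
   own concrete choice of noise-floor estimator.
3. **ADM spike encoding.** An asynchronous delta modulator holds a reference
   equal to the last encoded value (initialised to the first sample); a rise
   (fall) of at least the threshold emits an UP (DN) spike and moves the
   reference to the current value.  The threshold is 30 % of the baseline
   amplitude for the ripple path.  Encoding is at sample resolution (the
   input is already discrete at 2 kHz); the optional refractory dead time
   defaults to 0 s.

### Artifact-path threshold fraction

The artifact network has no inhibitory control, so any sustained
spike-train activity in its input fires it.  At the ripple path's 30 %
fraction the 500–900 Hz noise floor alone produces enough level crossings to
keep the artifact layer active, which would veto a large fraction of the
recording.  The artifact path therefore uses its own ADM threshold fraction
(default 0.70 of that band's baseline), chosen by the packaged calibration
(below) as the geometric mean of the smallest fraction that silences pure
background and the largest fraction that still detects a reference
high-frequency burst at 3× the background standard deviation.

## Networks

All neurons are leaky integrate-and-fire in normalized units: `v_reset = 0`,
`v_th = 1`, `tau_m = 10 ms`, refractory `3 ms`.  Synapses are exponential
current synapses: a presynaptic event adds the (signed) weight to the synapse
current, which decays with its time constant; the membrane obeys
`tau_m dV/dt = −V + i_bias + Σ currents`.

* **Core network.**  UP/DN input ports project to a second layer of 256
  neurons tiling a 16×16 grid over excitatory weight ∈ [7, 14] and
  excitatory tau ∈ [3, 6] ms; each neuron's DN inhibition has the same
  strength as its UP excitation with fast tau ∈ [0.1, 1] ms aligned with the
  tau grid axis.  Both ports drive a dis-inhibitory neuron (weight 21, tau
  5 ms, excitatory) which inhibits a global-inhibitory neuron (weight 7.5,
  tau 20 ms); the global-inhibitory neuron inhibits every layer neuron
  (weight 21, tau 5 ms) and fires tonically at 100 Hz from a constant bias
  current obtained by inverting the noiseless LIF f–I curve.  The motif
  suppresses responses to isolated sharp transients: a transient's brief
  input burst ends before the global inhibition is lifted, while a ripple's
  sustained volleys dis-inhibit the layer.
* **Artifact network.**  The same input-to-layer tiling (256 neurons) with
  no inhibitory-control neurons; any second-layer spike marks an artifact.
* **Mismatch model.**  Every synaptic weight and time constant is drawn from
  `Normal(nominal, cv·nominal)` floored at 5 % of nominal, emulating analog
  circuit mismatch.  The default cv = 0.1 is a generic mismatch magnitude
  for subthreshold analog arrays; cv may be set per parameter class.

The second-layer size (256 = 16×16) and the LIF constants are this package's
choices; rasters of real detections show tens of responding neurons, which
implies a tiled population of this order.  Weight numbers carry the
magnitude conventions of the current-mode circuits they describe; the
millisecond time constants are authoritative, and the circuit's
current-to-time-constant conversion is deliberately not used as a formula
because it is not consistent across connections.

## Simulation

Clock-driven, fixed step `dt = 0.1 ms` (at 2 kHz input, five steps per
sample).  Each step: input-port events and previous-step neuron spikes add
their weights to the synapse currents; the membrane then advances by the
**exact per-step solution** of the linear membrane/exponential-current
system,

    V ← (V − i_bias − Σ β_s) α + i_bias + Σ β_s d_s,
    α = e^(−dt/tau_m),  d_s = e^(−dt/tau_s),  β_s = c_s·tau_s/(tau_s − tau_m),

with threshold checked at step ends.  The exact map (rather than explicit
Euler) removes integration error from the fast 0.1–1 ms inhibitory
synapses, leaving step-quantisation of threshold crossings as the only
discretisation; halving dt changes second-layer spike counts on a reference
ripple by ~3 %.  dt is bounded to (0, 1] ms.  A global input gain maps the
weight magnitudes onto normalized currents (below).  Simulation is
deterministic given the network and inputs.

## Gain calibration

The packaged routine `calibrate_input_gain` fixes the single free scale of
the network: at cv = 0, background 1/f noise (20 s) must elicit no
second-layer spike, and a 120 Hz ripple at 3× the baseline amplitude must
drive at least one.  Bisection brackets the silent and firing gains
(0.065 and 0.020 here) and the default is their geometric mean, 0.0361,
stored in `eegsnn.config.DEFAULT_INPUT_GAIN`.  The artifact-path threshold
fraction is calibrated analogously at that gain
(`calibrate_artifact_fraction`, default 0.70).  Both constants live in the
config for provenance and can be re-derived.

## Event logic

Second-layer spikes are pooled across neurons and binned into tumbling 15 ms
windows from the interval start; windows holding at least `min_spikes`
(default 1) spikes are active, and maximal runs of active windows form one
Event of Interest spanning `[first bin start, last bin end)`.  Each
artifact-layer spike opens a 15 ms artifact interval; overlapping intervals
merge.  An EoI intersecting any artifact interval is rejected; survivors are
HFO.  HFO overlapping in time with an HFO on the homologous contralateral
channel are removed from both channels.  All intervals are half-open;
touching intervals do not overlap.  The per-channel rate is the pooled HFO
count divided by the total analyzed minutes; the per-hemisphere figure is
the maximum of the channel means.

## Clinical validation

A recording *shows HFO* if its affected-hemisphere rate is ≥ 0.25 HFO/min
(the boundary is included; the packaged cohort contains no rate at exactly
the threshold).  *Active epilepsy* is any presurgical recording, or a
postsurgical recording with ILAE class 2–5.  The module reports the
confusion table and PPV/NPV/sensitivity/specificity/accuracy; Spearman rank
correlation and log10–log10 OLS of seizure frequency on HFO rate (seizure
freedom coded 10⁻³ seizures/month for log-scale analyses only — outcome
classification always uses ILAE); pre/post concordance over pairs matched on
(patient, surgery) with a 1-df equal-probability χ² on the
concordant/discordant split; and Wilcoxon rank-sum / signed-rank tests via
standard library routines.

Concordance tie rule: when the seizure frequency is unchanged, the pair
counts as concordant iff the showing-HFO state (at the 0.25 HFO/min
threshold) is also unchanged; a strict raw-sign rule is available as
`tie_rule="sign"`.  On the packaged cohort the default rule yields 8/8
concordant pairs and χ² = 8.

The packaged cohort CSV carries 20 recordings from 11 pediatric focal
lesional epilepsy patients (one with two surgeries), with rates printed at
two decimals.  Recomputed association statistics from those printed values
are rho = 0.892 and slope = 2.287 (intercept 0.675, R² = 0.762); analyses
from the full-precision rates round to 0.90 and 2.27, so results computed
from the packaged table can differ from full-precision values in the last
printed digit.

## Synthetic data

The generator emulates the signal classes the detector must separate, on a
bilateral homologous channel pair at 2 kHz:

* background: 1/f^α Gaussian noise (α = 1, σ = 10 µV);
* ripples: Gaussian-windowed sinusoids, 90–200 Hz, 40–120 ms, only on the
  affected channel (the standard simulated-HFO morphology);
* sharp transients: derivative-of-Gaussian biphasic deflections, 10–30 ms,
  broadband with ripple-band leakage;
* high-frequency artifacts: 550–850 Hz Gaussian-windowed bursts plus a
  biphasic kick, giving substantial energy both above 500 Hz and in the
  ripple band; a configurable fraction (default 0.5) appears simultaneously
  on both channels.

Event amplitudes are drawn from 3–6× the background σ; default event rates
are 2/min per class; counts are deterministic (`rate × duration`) by
default so ground truth is exactly sized.  Ground truth uses the same
half-open convention; a detection hits a truth event if their intervals
overlap.

What the generator does **not** emulate: real electrode/muscle artifact
morphologies, non-stationary sleep architecture, line noise, inter-channel
correlation of background activity, and physiological field spread.
Passing the synthetic suite therefore demonstrates the pipeline's internal
correctness and its separation of the modeled event classes, not clinical
performance on recorded EEG.

## Problem sizes and determinism

The shipped test-suite and acceptance runs use 2-channel recordings of 20 s
to 5 min and 1000-signal/200-set oracle sweeps — sizes chosen so the whole
synthetic programme runs in minutes on one CPU while every pipeline stage is
exercised at its default 256+256-neuron, dt = 0.1 ms operating point.
All randomness flows through explicit integer seeds (generator, mismatch,
pipeline); identical config and seed reproduce byte-identical annotation and
report files.

## Known limitations

* Real-EEG performance figures (total HFO counts, per-recording rates,
  detector-to-detector rate correlations) require the clinical recordings
  and are out of scope here; the clinical layer operates on the packaged
  rate table.
* The baseline estimator and the artifact-path threshold fraction are this
  package's definitions; other implementations of the same detector family
  may use different noise-floor estimators and thresholds.
* The cohort is small (20 recordings) and heterogeneous; the validation
  layer reports association statistics without confidence intervals.
* EDF files are read, not written; synthetic recordings are exported in a
  delimited-text format.
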