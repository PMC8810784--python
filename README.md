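# eegsnn — spiking-network HFO detection in scalp EEG

`eegsnn` detects interictal **high-frequency oscillations (HFO)** — brief
ripple-band (80–250 Hz) events that mark epileptogenic brain tissue — in
multichannel scalp EEG, and relates the resulting HFO rates to epilepsy
severity.  It is written for epilepsy researchers and neuromorphic-signal-
processing engineers who want a fully automated, trainless detector whose
every stage maps onto low-power analog hardware: no event scoring, no
learned weights, no post-hoc visual review.

## The detector

For each bipolar channel and 5-minute interval:

1. **Filter** into the ripple band (80–250 Hz) and, in parallel, into a
   500–900 Hz artifact band (above the fast-ripple band, so fast ripples are
   never consumed as artifacts), with causal 2nd-order Butterworth filters.
2. **Baseline**: the noise floor of each filtered trace is the mean
   peak-to-peak amplitude of its quietest quartile of 1-s windows.
3. **Encode**: an asynchronous delta modulator (ADM) emits an UP (DN) spike
   whenever the trace rises (falls) by a threshold — 30 % of the baseline
   amplitude — from the last encoded value.
4. **Detect**: the UP/DN trains drive a two-layer leaky integrate-and-fire
   network (grid of 256 second-layer neurons over synaptic weight ∈ [7, 14]
   and tau ∈ [3, 6] ms, with matched fast DN inhibition).  A tonically
   firing global-inhibitory neuron suppresses the layer; sustained ripple
   input silences it via a dis-inhibitory neuron, while isolated sharp
   transients end before the suppression lifts.  Pooled layer spikes are
   binned into 15 ms windows; runs of active windows are Events of Interest.
5. **Reject**: a parallel inhibition-free network fed from the 500–900 Hz
   band marks artifacts (15 ms per spike); EoI overlapping an artifact are
   dropped, and HFO co-occurring on the homologous contralateral channel are
   removed from both sides.  Rates are HFO counts over analyzed minutes.

The clinical layer classifies a recording as *showing HFO* at ≥ 0.25 HFO/min
over the affected hemisphere, cross-tabulates this against *active epilepsy*
(presurgical, or postsurgical ILAE 2–5), and fits
`log10(seizure_frequency) = a·log10(HFO_rate) + b` alongside a Spearman rank
correlation and pre/post-surgery concordance counts.

See `docs/methods.md` for assumptions, parameter tables, calibration, and
limitations.

## Worked example

`examples/` holds one short script per capability.  Clinical validation on
the packaged 20-recording pediatric cohort
(`python examples/clinical_validation.py`):

```
Recordings analyzed: 20
Confusion (showing-HFO vs active epilepsy): TP=10 FP=0 TN=6 FN=4
Accuracy 80%  Sensitivity 71%  Specificity 100%  PPV 100%  NPV 60%
Spearman rho (HFO rate vs seizure frequency): 0.89
log10(seizure_freq) = 2.29 * log10(HFO_rate) + 0.7   (R^2 = 0.76)
Predicted seizure frequency at 1 HFO/min: 5 /month
Pre/post concordant pairs: 8/8 (chi2 = 8.00)
Higher affected-hemisphere rate in 9 of 14 active-epilepsy recordings
```

Every recording with a suprathreshold HFO rate came from a patient with
active epilepsy (PPV 100 %), no seizure-free patient exceeded the threshold
(specificity 100 %), and the log-log fit says an HFO rate of 1/min predicts
about 5 seizures/month.

End-to-end detection on synthetic ground truth
(`python examples/detect_synthetic.py`):

```
T3-T5: 6 HFO in 2.0 min -> 3.00 HFO/min
T4-T6: 0 HFO in 2.0 min -> 0.00 HFO/min
injected ripples on T3-T5: 6, detected: 6
```

`examples/encode_spikes.py` walks through the ADM front end and
`examples/network_motif.py` shows the dis-inhibition motif rejecting a sharp
transient while passing a ripple.

## Command line

```bash
eegsnn detect --input rec.edf --montage montage.csv --out results/ --seed 1
eegsnn validate --cohort cohort.csv --out results/
eegsnn synth --out fixtures/ --seed 1 --duration 300
```

`detect` accepts EDF or delimited-text EEG, a montage file of
`pair,ANODE,CATHODE` and `homolog,A,B` lines, and writes annotations and
rate tables as CSV; any config key can be overridden with `--set key=value`.

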