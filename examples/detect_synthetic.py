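"""End-to-end detection on a ground-truth-annotated synthetic recording.

Builds a bilateral pair of channels (2 min, ripples only on the affected
side, high-frequency artifacts on both), runs the full pipeline -- ripple
path, artifact path, artifact rejection, contralateral rejection -- and
scores the detections against the exact injected ground truth.
"""

from eegsnn.config import PipelineConfig
from eegsnn.pipeline import run_detection
from eegsnn.synth import SynthConfig, make_synthetic_recording

scfg = SynthConfig(duration=120.0, ripple_rate=3.0, seed=7)
recording, truth = make_synthetic_recording(scfg)
result = run_detection(PipelineConfig(seed=1), recording=recording)

ripples = [e for e in truth if e.kind == "ripple"]
for label, r in sorted(result["results"].items()):
    n_hfo = sum(1 for e in r.events if e.kind == "HFO")
    print(f"{label}: {n_hfo} HFO in {r.analyzed_minutes:.1f} min "
          f"-> {r.rate:.2f} HFO/min")

hfos = [e for e in result["results"]["T3-T5"].events if e.kind == "HFO"]
hits = sum(
    1 for t in ripples
    if any(h.start < t.end and t.start < h.end for h in hfos)
)
print(f"injected ripples on T3-T5: {len(ripples)}, detected: {hits}")
for entry in result["log"]:
    print(f"  {entry['channel']}: {entry['n_eoi']} EoI, "
          f"{entry['n_artifact']} artifact intervals")
print(
    "\nReading: the affected channel carries the ripple rate; the homologous\n"
    "contralateral channel stays near zero because bilateral events are\n"
    "rejected as non-epileptic and its background drives no detections."
)
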