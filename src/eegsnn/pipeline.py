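"""End-to-end orchestration: recording → per-channel HFO rates and reports.

``run_detection`` drives the full detector over each bipolar channel and
5-min interval: ripple-band path (filter → baseline → ADM → core network →
EoI) and artifact path (500-900 Hz filter → ADM → artifact network →
artifact intervals), artifact rejection, contralateral rejection across
homologous channels, and duration-correct rate aggregation.
``run_validation`` produces the clinical report from a cohort table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, detect, snn
from .config import PipelineConfig
from .io import (
    AnnotationRecord,
    Recording,
    make_bipolar,
    read_recording,
    resample_to,
    segment_intervals,
    write_annotations,
    write_rate_table,
)
from .preprocess import (
    AdmConfig,
    FilterSpec,
    adm_encode,
    bandpass_filter,
    estimate_baseline,
    spike_threshold_from_baseline,
)

__all__ = ["PipelineConfig", "run_detection", "run_validation", "read_montage_file"]


def read_montage_file(path: str | Path) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Read montage metadata: ``pair,ANODE,CATHODE`` and ``homolog,A,B`` lines."""
    pairs: list[tuple[str, str]] = []
    hmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == "pair" and len(parts) == 3:
                pairs.append((parts[1], parts[2]))
            elif parts[0] == "homolog" and len(parts) == 3:
                hmap[parts[1]] = parts[2]
                hmap[parts[2]] = parts[1]
            else:
                raise ValueError(f"malformed montage line: {line!r}")
    return pairs, hmap


def _config_hash(cfg: PipelineConfig) -> str:
    """Hash of the scientific configuration (I/O paths excluded)."""
    d = {k: v for k, v in asdict(cfg).items() if k not in ("input", "montage", "out")}
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _detect_channel_interval(ts, band, n_layer_net, cfg, window_s, min_spikes, fraction):
    """One channel-interval through one band's path; returns event intervals
    in recording time and the interval's event/spike accounting."""
    filt = bandpass_filter(
        ts, FilterSpec(*band, order=cfg.filter_order), zero_phase=cfg.zero_phase
    )
    baseline = estimate_baseline(
        filt, window=cfg.baseline_window_s, percentile=cfg.baseline_percentile
    )
    thr = spike_threshold_from_baseline(baseline, fraction)
    if thr <= 0:  # silent segment: nothing to encode
        return [], 0
    up, dn = adm_encode(filt, AdmConfig(threshold=thr, refractory=cfg.adm_refractory_s))
    raster = snn.simulate(
        n_layer_net,
        {"UP": up, "DN": dn},
        duration=ts.duration,
        dt_ms=cfg.dt_ms,
        gain=cfg.input_gain,
    )
    if window_s == cfg.eoi_window_s:
        events = detect.extract_eoi(raster, window=window_s, min_spikes=min_spikes,
                                    channel=ts.label)
    else:
        events = detect.artifact_intervals(raster, window=window_s, channel=ts.label)
    # shift from interval-local to recording time
    shifted = [
        detect.EventInterval(e.start + ts.t0, e.end + ts.t0, e.kind, e.channel)
        for e in events
    ]
    return shifted, raster.n_spikes


def run_detection(cfg: PipelineConfig, recording: Recording | None = None) -> dict:
    """Run the detector; returns results and optionally writes output files.

    When ``recording`` is omitted it is read from ``cfg.input`` (EDF or
    delimited text) with the montage file named by ``cfg.montage``.  Returns
    a dict with per-channel :class:`ChannelDetectionResult`, the full
    annotation list, an interval-level log, and the config hash.
    """
    if recording is None:
        if not cfg.input:
            raise ValueError("no recording given and cfg.input is empty")
        montage, hmap = ([], {})
        if cfg.montage:
            montage, hmap = read_montage_file(cfg.montage)
        recording = read_recording(cfg.input, montage=montage, homolog_map=hmap)

    if recording.fs != cfg.working_fs:
        recording = Recording(
            channels=[resample_to(ch, cfg.working_fs) for ch in recording.channels],
            montage=recording.montage,
            homolog_map=recording.homolog_map,
            recording_id=recording.recording_id,
            patient_id=recording.patient_id,
            phase=recording.phase,
        )
    if recording.montage:
        recording = make_bipolar(recording)

    jit_core = snn.JitterModel(cv=cfg.cv, seed=cfg.seed)
    jit_art = snn.JitterModel(cv=cfg.cv, seed=cfg.seed + 1)
    core = snn.build_core_snn(cfg.n_core, jit_core, gi_rate_hz=cfg.gi_rate_hz)
    art = snn.build_artifact_snn(cfg.n_artifact, jit_art)
    ripple_band = (cfg.ripple_low, cfg.ripple_high)
    artifact_band = (cfg.artifact_low, cfg.artifact_high)

    log: list[dict] = []
    per_channel_eoi: dict[str, list] = {}
    per_channel_art: dict[str, list] = {}
    minutes: dict[str, float] = {}
    min_dur = 3 * cfg.baseline_window_s
    for ch in recording.channels:
        eois: list = []
        arts: list = []
        analyzed = 0.0
        for seg in segment_intervals(ch, cfg.interval_s):
            if seg.duration < min_dur:  # too short for a baseline estimate
                continue
            seg_eoi, n_core_spk = _detect_channel_interval(
                seg, ripple_band, core, cfg, cfg.eoi_window_s, cfg.min_spikes,
                cfg.adm_fraction,
            )
            seg_art, n_art_spk = _detect_channel_interval(
                seg, artifact_band, art, cfg, cfg.artifact_window_s, 1,
                cfg.artifact_adm_fraction,
            )
            eois.extend(seg_eoi)
            arts.extend(seg_art)
            analyzed += seg.duration
            log.append(
                {
                    "channel": ch.label,
                    "interval_start_s": seg.t0,
                    "interval_s": seg.duration,
                    "n_eoi": len(seg_eoi),
                    "n_artifact": len(seg_art),
                    "n_core_spikes": n_core_spk,
                    "n_artifact_spikes": n_art_spk,
                }
            )
        per_channel_eoi[ch.label] = eois
        per_channel_art[ch.label] = arts
        minutes[ch.label] = analyzed / 60.0

    hfos = {
        lab: detect.reject_artifact_overlaps(per_channel_eoi[lab], per_channel_art[lab])
        for lab in per_channel_eoi
    }
    # contralateral rejection over each homologous pair (once per pair)
    done = set()
    rejected: dict[str, list] = {lab: [] for lab in hfos}
    for a, b in recording.homolog_map.items():
        key = frozenset((a, b))
        if key in done or a not in hfos or b not in hfos:
            continue
        done.add(key)
        fa, fb = detect.reject_contralateral(hfos[a], hfos[b])
        hfos[a] = [e for e in fa if e.kind == "HFO"]
        hfos[b] = [e for e in fb if e.kind == "HFO"]
        rejected[a] = [e for e in fa if e.kind != "HFO"]
        rejected[b] = [e for e in fb if e.kind != "HFO"]

    results = {}
    annotations: list[AnnotationRecord] = []
    rate_rows = []
    for lab in per_channel_eoi:
        if minutes[lab] <= 0:
            continue
        results[lab] = detect.channel_rate(hfos[lab], minutes[lab], channel=lab)
        for ev in per_channel_eoi[lab]:
            annotations.append(AnnotationRecord(lab, ev.start, ev.end, "EoI"))
        for ev in per_channel_art[lab]:
            annotations.append(AnnotationRecord(lab, ev.start, ev.end, "artifact"))
        for ev in hfos[lab]:
            annotations.append(AnnotationRecord(lab, ev.start, ev.end, "HFO"))
        for ev in rejected[lab]:
            annotations.append(
                AnnotationRecord(lab, ev.start, ev.end, "HFO_rejected_contralateral")
            )
        rate_rows.append(
            {
                "recording_id": recording.recording_id,
                "channel": lab,
                "n_hfo": len(hfos[lab]),
                "minutes": minutes[lab],
                "rate_per_min": results[lab].rate,
            }
        )

    out = {
        "results": results,
        "annotations": annotations,
        "log": log,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
    }
    if cfg.out:
        outdir = Path(cfg.out)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotations(annotations, outdir / "annotations.csv")
        write_rate_table(rate_rows, outdir / "rates.csv")
        with open(outdir / "run.json", "w") as fh:
            json.dump(
                {"config_hash": out["config_hash"], "seed": cfg.seed, "log": log},
                fh, indent=1, sort_keys=True,
            )
    return out


def _pct(x):
    return None if x is None else round(100 * x)


def run_validation(cohort: str | Path | list, out: str | Path | None = None) -> dict:
    """Clinical report from a cohort table (path, DataFrame rows, or summaries).

    Emits the confusion table, percentage metrics, Spearman rho, the log-log
    regression with its 1-HFO/min prediction, pre/post concordance and the
    rank tests, as JSON plus a human-readable text block.
    """
    if isinstance(cohort, (str, Path)):
        summaries = clinical.summaries_from_frame(pd.read_csv(cohort))
    elif cohort and isinstance(cohort[0], clinical.RecordingSummary):
        summaries = list(cohort)
    else:
        summaries = clinical.summaries_from_frame(pd.DataFrame(cohort))

    c = clinical.confusion(summaries)
    m = clinical.metrics(c)
    degenerate = len(summaries) < 3
    report: dict = {
        "n_recordings": len(summaries),
        "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
        "metrics_pct": {k: _pct(v) for k, v in m.items()},
        "metrics": m,
    }
    if degenerate:
        report["warning"] = "fewer than 3 recordings: association stats not computed"
    else:
        rho = clinical.spearman_rate_vs_seizures(summaries)
        slope, intercept, r2 = clinical.fit_loglog(summaries)
        try:
            conc, total, chi2 = clinical.concordant_pre_post_pairs(summaries)
        except ValueError:
            conc = total = 0
            chi2 = float("nan")
        n_higher = sum(
            1
            for s in summaries
            if clinical.is_active_epilepsy(s)
            and s.hfo_rate_nonaffected is not None
            and s.hfo_rate_affected > s.hfo_rate_nonaffected
        )
        n_active_paired = sum(
            1 for s in summaries
            if clinical.is_active_epilepsy(s) and s.hfo_rate_nonaffected is not None
        )
        report.update(
            {
                "spearman_rho": rho,
                "regression": {
                    "slope": slope,
                    "intercept": intercept,
                    "r2": r2,
                    "predicted_sf_at_1hfo_min": clinical.predict_seizure_freq(
                        (slope, intercept), 1.0
                    ),
                },
                "pre_post_pairs": {"concordant": conc, "total": total, "chi2": chi2},
                "higher_affected_rate": {"n": n_higher, "of": n_active_paired},
                "rank_tests": clinical.rank_tests(summaries),
            }
        )

    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "clinical_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, allow_nan=True)
        with open(out / "clinical_report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    c = report["confusion"]
    m = report["metrics_pct"]
    lines = [
        f"Recordings analyzed: {report['n_recordings']}",
        f"Confusion (showing-HFO vs active epilepsy): "
        f"TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']}",
        f"Accuracy {m['accuracy']}%  Sensitivity {m['sensitivity']}%  "
        f"Specificity {m['specificity']}%  PPV {m['ppv']}%  NPV {m['npv']}%",
    ]
    if "spearman_rho" in report:
        r = report["regression"]
        p = report["pre_post_pairs"]
        lines += [
            f"Spearman rho (HFO rate vs seizure frequency): {report['spearman_rho']:.2f}",
            f"log10(seizure_freq) = {r['slope']:.2f} * log10(HFO_rate) + "
            f"{r['intercept']:.1f}   (R^2 = {r['r2']:.2f})",
            f"Predicted seizure frequency at 1 HFO/min: "
            f"{r['predicted_sf_at_1hfo_min']:.0f} /month",
            f"Pre/post concordant pairs: {p['concordant']}/{p['total']} "
            f"(chi2 = {p['chi2']:.2f})",
            f"Higher affected-hemisphere rate in "
            f"{report['higher_affected_rate']['n']} of "
            f"{report['higher_affected_rate']['of']} active-epilepsy recordings",
        ]
    return "\n".join(lines) + "\n"
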