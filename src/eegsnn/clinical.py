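"""Clinical validation: HFO rates versus epilepsy state and seizure frequency.

A recording "shows HFO" if its affected-hemisphere rate reaches the 0.25
HFO/min threshold.  Active epilepsy is every presurgical recording and every
postsurgical recording with ILAE outcome class 2-5; ILAE 1 is seizure-free.
The module cross-tabulates these two labels, computes the usual confusion
metrics, relates rate to seizure frequency by Spearman correlation and
log10-log10 ordinary least squares, and scores pre/post concordance of rate
and seizure-frequency changes.  The packaged 20-recording pediatric cohort
(11 focal lesional epilepsy patients, one with two surgeries) ships as a CSV
fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "RecordingSummary",
    "ConfusionCounts",
    "AssociationStats",
    "RATE_THRESHOLD",
    "ZERO_SEIZURE_CODE",
    "load_cohort",
    "classify_showing_hfo",
    "is_active_epilepsy",
    "confusion",
    "metrics",
    "spearman_rate_vs_seizures",
    "fit_loglog",
    "predict_seizure_freq",
    "concordant_pre_post_pairs",
    "rank_tests",
]

#: Rate threshold (HFO/min) above which a recording is defined as showing HFO.
RATE_THRESHOLD = 0.25
#: Seizure freedom is coded as this frequency for log-scale analyses.
ZERO_SEIZURE_CODE = 1e-3


@dataclass(frozen=True)
class RecordingSummary:
    """One EEG recording's clinical row.

    ``ilae`` is the postsurgical outcome class (1 = seizure-free, 2-5 =
    recurrence) and is ``None`` for presurgical recordings.
    """

    patient_id: str
    surgery_index: int
    phase: str  # "pre" | "post"
    seizure_freq: float  # seizures/month
    ilae: int | None = None
    hfo_rate_affected: float | None = None
    hfo_rate_nonaffected: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be pre or post, got {self.phase!r}")
        if self.seizure_freq < 0:
            raise ValueError("seizure_freq must be >= 0")
        for r in (self.hfo_rate_affected, self.hfo_rate_nonaffected):
            if r is not None and r < 0:
                raise ValueError("HFO rates must be >= 0")
        if self.ilae is not None and not (1 <= self.ilae <= 5):
            raise ValueError("ILAE class must be 1-5")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AssociationStats:
    """Bundle of rate-vs-severity association results."""

    rho: float
    slope: float
    intercept: float
    r2: float
    concordant_pairs: int
    total_pairs: int
    chi2: float


def load_cohort() -> list[RecordingSummary]:
    """The packaged 20-recording cohort (rates in HFO/min, frequency /month)."""
    with resources.files("eegsnn.data").joinpath("cohort_scalp_hfo.csv").open() as fh:
        df = pd.read_csv(fh)
    return summaries_from_frame(df)


def summaries_from_frame(df: pd.DataFrame) -> list[RecordingSummary]:
    """Build summaries from a cohort table; raises on malformed rows."""
    required = {"patient_id", "surgery_index", "phase", "seizure_freq",
                "ilae", "hfo_rate_affected", "hfo_rate_nonaffected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    out = []
    bad = []
    for i, row in df.iterrows():
        try:
            out.append(
                RecordingSummary(
                    patient_id=str(row["patient_id"]),
                    surgery_index=int(row["surgery_index"]),
                    phase=str(row["phase"]),
                    seizure_freq=float(row["seizure_freq"]),
                    ilae=None if pd.isna(row["ilae"]) else int(row["ilae"]),
                    hfo_rate_affected=None if pd.isna(row["hfo_rate_affected"])
                    else float(row["hfo_rate_affected"]),
                    hfo_rate_nonaffected=None if pd.isna(row["hfo_rate_nonaffected"])
                    else float(row["hfo_rate_nonaffected"]),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        raise ValueError(f"malformed cohort rows: {bad}")
    return out


def classify_showing_hfo(rate: float, threshold: float = RATE_THRESHOLD) -> bool:
    """True iff the rate reaches the threshold.

    The boundary is included (>=); the packaged cohort contains no rate at
    exactly the threshold, so the convention does not affect its results.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return rate >= threshold


def is_active_epilepsy(summary: RecordingSummary) -> bool:
    """Active epilepsy: any presurgical recording, or postsurgical ILAE 2-5."""
    if summary.phase == "pre":
        return True
    if summary.ilae is None:
        raise ValueError(
            f"postsurgical recording of patient {summary.patient_id} lacks an "
            "ILAE outcome class"
        )
    return summary.ilae >= 2


def confusion(summaries: list[RecordingSummary], threshold: float = RATE_THRESHOLD) -> ConfusionCounts:
    """Cross-tabulate showing-HFO against active epilepsy."""
    tp = fp = tn = fn = 0
    for s in summaries:
        if s.hfo_rate_affected is None:
            raise ValueError(f"recording of patient {s.patient_id} lacks an affected-hemisphere rate")
        show = classify_showing_hfo(s.hfo_rate_affected, threshold)
        active = is_active_epilepsy(s)
        if show and active:
            tp += 1
        elif show:
            fp += 1
        elif active:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict:
    """PPV, NPV, sensitivity, specificity, accuracy as fractions.

    A metric whose denominator is zero is reported as ``None`` (undefined).
    Display rounding to integer percent is left to the caller; full precision
    is retained here.
    """
    if c.n == 0:
        raise ValueError("empty confusion table")

    def frac(num, den):
        return num / den if den > 0 else None

    return {
        "ppv": frac(c.tp, c.tp + c.fp),
        "npv": frac(c.tn, c.tn + c.fn),
        "sensitivity": frac(c.tp, c.tp + c.fn),
        "specificity": frac(c.tn, c.tn + c.fp),
        "accuracy": (c.tp + c.tn) / c.n,
    }


def _coded_freqs(summaries, zero_code):
    return np.array(
        [s.seizure_freq if s.seizure_freq > 0 else zero_code for s in summaries]
    )


def _affected_rates(summaries):
    rates = [s.hfo_rate_affected for s in summaries]
    if any(r is None for r in rates):
        raise ValueError("every summary needs an affected-hemisphere rate")
    return np.array(rates, dtype=float)


def spearman_rate_vs_seizures(
    summaries: list[RecordingSummary], zero_code: float = ZERO_SEIZURE_CODE
) -> float:
    """Spearman rank correlation of affected-hemisphere rate vs seizure
    frequency (seizure freedom coded as ``zero_code``; average ranks on
    ties).  The result does not depend on the code's value as long as it lies
    below the smallest positive frequency."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 recordings")
    rates = _affected_rates(summaries)
    freqs = _coded_freqs(summaries, zero_code)
    return float(sstats.spearmanr(rates, freqs).statistic)


def fit_loglog(
    summaries: list[RecordingSummary], zero_code: float = ZERO_SEIZURE_CODE
) -> tuple[float, float, float]:
    """OLS of log10(seizure frequency) on log10(affected HFO rate).

    Returns (slope, intercept, r2).  Zero seizure frequencies are coded as
    ``zero_code``; a zero HFO rate is a data error (log undefined).
    """
    rates = _affected_rates(summaries)
    if np.any(rates <= 0):
        raise ValueError("all affected-hemisphere rates must be > 0 for the log fit")
    freqs = _coded_freqs(summaries, zero_code)
    res = sstats.linregress(np.log10(rates), np.log10(freqs))
    r2 = float(res.rvalue**2)
    if not math.isfinite(r2):  # constant response: no variance to explain
        r2 = 0.0
    return float(res.slope), float(res.intercept), r2


def predict_seizure_freq(model: tuple[float, float, float] | tuple[float, float], rate: float) -> float:
    """Seizures/month predicted by the log-log model at the given HFO rate."""
    if not rate > 0:
        raise ValueError("rate must be > 0")
    slope, intercept = model[0], model[1]
    return float(10 ** (slope * math.log10(rate) + intercept))


def concordant_pre_post_pairs(
    summaries: list[RecordingSummary],
    threshold: float = RATE_THRESHOLD,
    tie_rule: str = "classification",
) -> tuple[int, int, float]:
    """Concordance of pre/post changes in HFO rate and seizure frequency.

    Pairs are matched on (patient_id, surgery_index) and require affected
    rates on both sides.  A pair is concordant when the direction of the HFO
    rate change agrees with the direction of the seizure-frequency change.
    When the seizure frequency is unchanged, the default ``classification``
    tie rule counts the pair as concordant iff the showing-HFO state at the
    rate threshold is also unchanged; ``sign`` demands an exactly unchanged
    rate.  Returns (concordant, total, chi2) where chi2 is the 1-df
    goodness-of-fit statistic of the concordant/discordant split against an
    equal-probability null.
    """
    pre = {}
    post = {}
    for s in summaries:
        if s.hfo_rate_affected is None:
            continue
        (pre if s.phase == "pre" else post)[(s.patient_id, s.surgery_index)] = s
    keys = sorted(set(pre) & set(post))
    if not keys:
        raise ValueError("no matched pre/post pairs with affected rates")
    concordant = 0
    for k in keys:
        a, b = pre[k], post[k]
        d_rate = np.sign(b.hfo_rate_affected - a.hfo_rate_affected)
        d_sf = np.sign(b.seizure_freq - a.seizure_freq)
        if d_sf == 0:
            if tie_rule == "classification":
                ok = classify_showing_hfo(a.hfo_rate_affected, threshold) == \
                     classify_showing_hfo(b.hfo_rate_affected, threshold)
            else:
                ok = d_rate == 0
        else:
            ok = d_rate == d_sf
        concordant += int(ok)
    total = len(keys)
    exp = total / 2.0
    chi2 = (concordant - exp) ** 2 / exp + ((total - concordant) - exp) ** 2 / exp
    return concordant, total, float(chi2)


def rank_tests(summaries: list[RecordingSummary]) -> dict:
    """Standard rank tests on the cohort's rates.

    * Wilcoxon rank-sum: affected-hemisphere rates, active vs seizure-free
      recordings.
    * Wilcoxon matched-pairs signed-rank: affected vs non-affected hemisphere
      rates within recordings of patients with active epilepsy.

    Degenerate groups are reported as not computable (``None`` p-value).
    """
    active_rates, free_rates = [], []
    paired = []
    for s in summaries:
        if s.hfo_rate_affected is None:
            continue
        if is_active_epilepsy(s):
            active_rates.append(s.hfo_rate_affected)
            if s.hfo_rate_nonaffected is not None:
                paired.append((s.hfo_rate_affected, s.hfo_rate_nonaffected))
        else:
            free_rates.append(s.hfo_rate_affected)

    out: dict = {}
    if active_rates and free_rates:
        res = sstats.ranksums(active_rates, free_rates)
        out["ranksum_active_vs_free"] = {
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "n_active": len(active_rates), "n_free": len(free_rates),
        }
    else:
        out["ranksum_active_vs_free"] = {"statistic": None, "p": None}
    diffs = [a - b for a, b in paired]
    if paired and any(d != 0 for d in diffs):
        res = sstats.wilcoxon([a for a, _ in paired], [b for _, b in paired])
        out["signedrank_affected_vs_nonaffected"] = {
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "n_pairs": len(paired),
        }
    else:
        out["signedrank_affected_vs_nonaffected"] = {"statistic": None, "p": None,
                                                     "n_pairs": len(paired)}
    return out
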