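"""Event extraction and rejection: rasters → EoI → artifact-screened HFO.

Second-layer spikes of the core network are pooled and binned into tumbling
15 ms windows; runs of active windows form Events of Interest (EoI).  Each
artifact-network spike opens a 15 ms artifact interval.  An EoI overlapping
any artifact interval is rejected; survivors are HFO.  HFO co-occurring on
the homologous contralateral channel are rejected as non-epileptic.  All
intervals are half-open ``[start, end)``; overlap means nonempty
intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .snn import SpikeRaster

__all__ = [
    "EventInterval",
    "ChannelDetectionResult",
    "extract_eoi",
    "artifact_intervals",
    "reject_artifact_overlaps",
    "reject_contralateral",
    "channel_rate",
    "hemisphere_rate",
]


@dataclass(frozen=True)
class EventInterval:
    """A half-open [start, end) event on one channel (times in seconds)."""

    start: float
    end: float
    kind: str = "EoI"
    channel: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must precede end ({self.start} >= {self.end})")

    def overlaps(self, other: "EventInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class ChannelDetectionResult:
    """Per-channel detection outcome with the analyzed duration and HFO rate."""

    channel: str
    events: list
    analyzed_minutes: float
    rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.analyzed_minutes > 0:
            raise ValueError("analyzed_minutes must be > 0")
        n_hfo = sum(1 for e in self.events if e.kind == "HFO")
        self.rate = n_hfo / self.analyzed_minutes


def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals (touching intervals merge)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def extract_eoi(
    raster: SpikeRaster,
    window: float = 0.015,
    min_spikes: int = 1,
    channel: str = "",
) -> list[EventInterval]:
    """Mark Events of Interest from the pooled second-layer raster.

    Time is tiled into consecutive ``window``-long bins from t = 0; a bin
    holding at least ``min_spikes`` pooled spikes is active, and maximal runs
    of active bins merge into one EoI spanning [first bin start, last bin
    end).
    """
    if not window > 0:
        raise ValueError("window must be > 0")
    times = raster.pooled_times()
    if times.size == 0:
        return []
    bins = np.floor(times / window).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)
    active = uniq[counts >= min_spikes]
    if active.size == 0:
        return []
    merged = _merge([(b * window, (b + 1) * window) for b in active])
    return [EventInterval(s, e, "EoI", channel) for s, e in merged]


def artifact_intervals(
    raster: SpikeRaster, window: float = 0.015, channel: str = ""
) -> list[EventInterval]:
    """Each artifact-layer spike at t opens an interval [t, t + window);
    overlapping intervals are merged."""
    if not window > 0:
        raise ValueError("window must be > 0")
    times = raster.pooled_times()
    if times.size == 0:
        return []
    merged = _merge([(t, t + window) for t in times])
    return [EventInterval(s, e, "artifact", channel) for s, e in merged]


def reject_artifact_overlaps(
    eois: list[EventInterval], artifacts: list[EventInterval]
) -> list[EventInterval]:
    """Drop every EoI intersecting an artifact interval; relabel survivors HFO.

    Touching half-open intervals ([a,b) and [b,c)) do not overlap.
    Rejection never reshapes events: each output HFO has the time span of an
    input EoI.
    """
    out = []
    for e in eois:
        if not any(e.overlaps(a) for a in artifacts):
            out.append(replace(e, kind="HFO"))
    return out


def reject_contralateral(
    hfos_a: list[EventInterval], hfos_b: list[EventInterval]
) -> tuple[list[EventInterval], list[EventInterval]]:
    """Remove HFO co-occurring on homologous channels of the two hemispheres.

    Any HFO in one list that overlaps in time with any HFO in the other is
    removed from both (relabelled ``HFO_rejected_contralateral``); the
    operation is symmetric in its arguments.
    """

    def screen(events, others):
        kept = []
        for e in events:
            if any(e.overlaps(o) for o in others):
                kept.append(replace(e, kind="HFO_rejected_contralateral"))
            else:
                kept.append(e)
        return kept

    return screen(hfos_a, hfos_b), screen(hfos_b, hfos_a)


def channel_rate(
    events: list[EventInterval], analyzed_minutes: float, channel: str = ""
) -> ChannelDetectionResult:
    """HFO rate of one channel: count of kind=HFO events / analyzed minutes."""
    if not analyzed_minutes > 0:
        raise ValueError("analyzed_minutes must be > 0")
    if not channel and events:
        channel = events[0].channel
    return ChannelDetectionResult(
        channel=channel, events=list(events), analyzed_minutes=analyzed_minutes
    )


def hemisphere_rate(results: list[ChannelDetectionResult]) -> float:
    """Maximum of the per-channel mean HFO rates over a hemisphere."""
    if not results:
        raise ValueError("need at least one channel result")
    return max(r.rate for r in results)
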