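"""Detection and summarization of spontaneous cytosolic calcium transients.

Input is a per-ROI Fluo-4 fluorescence time series sampled at one frame
every ``dt`` seconds (default 2 s).  The trace is normalized to F/F0 with
F0 the 10th percentile of the raw trace (a robust baseline under sparse
transients); events are contiguous excursions of F/F0 above
1 + k_sigma * sigma_noise, where sigma_noise is the SD of sub-threshold
residuals estimated by a two-pass exclusion scheme.  Amplitude is the peak
F/F0 of the excursion, frequency is events per minute of recording, and a
cell is classified as oscillating when it shows at least ``min_events``
events.  Group statistics (amplitude and frequency mean +- SEM) follow the
screening convention of being computed over oscillating cells only, while
the percent-oscillating figure is over all cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "CalciumEvent",
    "TraceSummary",
    "GroupSummary",
    "baseline_f0",
    "detect_events",
    "summarize_trace",
    "summarize_group",
    "analyze_traces",
    "read_traces_csv",
]

DEFAULT_DT_S = 2.0
DEFAULT_K_SIGMA = 3.0
DEFAULT_MIN_SEPARATION_S = 4.0
DEFAULT_MIN_EVENTS = 2
DEFAULT_MIN_WIDTH = 2  # frames an excursion must persist; rejects 1-frame noise spikes
BASELINE_PERCENTILE = 10.0


class InvalidTraceError(ValueError):
    pass


@dataclass
class FluorescenceTrace:
    cell_id: str
    values: np.ndarray
    dt: float = DEFAULT_DT_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 10:
            raise InvalidTraceError(
                f"{self.cell_id}: need a 1-D trace of >= 10 frames"
            )
        if not (self.values > 0).all():
            raise InvalidTraceError(f"{self.cell_id}: fluorescence must be > 0")
        if self.dt <= 0:
            raise InvalidTraceError(f"{self.cell_id}: dt must be > 0")

    @property
    def duration(self) -> float:
        """Recording span in seconds, dt * (n - 1)."""
        return self.dt * (self.values.size - 1)


@dataclass(frozen=True)
class CalciumEvent:
    onset_index: int
    peak_index: int
    amplitude: float  # peak F/F0


@dataclass
class TraceSummary:
    cell_id: str
    n_events: int
    mean_amplitude: float | None
    frequency: float  # events per minute
    oscillating: bool


@dataclass
class GroupSummary:
    label: str
    n_cells: int
    n_oscillating: int
    pct_oscillating: float
    amplitude_mean: float | None
    amplitude_sem: float | None
    frequency_mean: float | None
    frequency_sem: float | None


def baseline_f0(trace: FluorescenceTrace, percentile: float = BASELINE_PERCENTILE) -> float:
    """Baseline fluorescence: the 10th percentile of the raw trace."""
    f0 = float(np.percentile(trace.values, percentile))
    if f0 <= 0:
        raise InvalidTraceError(f"{trace.cell_id}: non-positive baseline {f0}")
    return f0


def _noise_center_sigma(f_norm: np.ndarray, k_sigma: float) -> tuple[float, float]:
    """Robust center and SD of the sub-threshold F/F0 noise, by two-pass
    exclusion.

    The 10th-percentile baseline puts the quiescent level of F/F0 slightly
    above 1, so the noise center is estimated (median, then mean of
    sub-threshold frames) rather than assumed to be 1.  First pass uses a
    MAD-based robust SD (insensitive to transients); frames above the
    provisional threshold are excluded and both statistics re-estimated
    once on the remainder.
    """
    c0 = float(np.median(f_norm))
    resid = f_norm - c0
    sigma0 = 1.4826 * float(np.median(np.abs(resid)))
    if sigma0 == 0:
        sigma0 = float(np.std(resid))
    if sigma0 == 0:
        return c0, 0.0
    sub = f_norm[resid <= k_sigma * sigma0]
    if sub.size < 2:
        return c0, sigma0
    return float(np.mean(sub)), float(np.std(sub, ddof=1))


def detect_events(
    trace: FluorescenceTrace,
    k_sigma: float = DEFAULT_K_SIGMA,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_width: int = DEFAULT_MIN_WIDTH,
) -> list[CalciumEvent]:
    """Detect transient events as supra-threshold excursions of F/F0.

    Threshold = 1 + k_sigma * sigma_noise.  An excursion must persist for
    ``min_width`` consecutive frames; excursions whose peaks are closer
    than ``min_separation_s`` are merged (the larger peak is kept).
    Detection is invariant to a positive rescaling of the raw trace.
    """
    f0 = baseline_f0(trace)
    f = trace.values / f0
    center, sigma = _noise_center_sigma(f, k_sigma)
    if sigma == 0:
        return []
    thr = max(center, 1.0) + k_sigma * sigma

    above = f > thr
    if not above.any():
        return []
    # contiguous runs above threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    events: list[CalciumEvent] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_width:
            continue
        peak = int(start + np.argmax(f[start:stop]))
        events.append(CalciumEvent(int(start), peak, float(f[peak])))

    # merge events with peaks closer than min_separation_s
    min_gap = min_separation_s / trace.dt
    merged: list[CalciumEvent] = []
    for ev in events:
        if merged and ev.peak_index - merged[-1].peak_index < min_gap:
            if ev.amplitude > merged[-1].amplitude:
                merged[-1] = CalciumEvent(
                    merged[-1].onset_index, ev.peak_index, ev.amplitude
                )
        else:
            merged.append(ev)
    return merged


def summarize_trace(
    trace: FluorescenceTrace,
    events: Sequence[CalciumEvent],
    min_events: int = DEFAULT_MIN_EVENTS,
) -> TraceSummary:
    n = len(events)
    return TraceSummary(
        cell_id=trace.cell_id,
        n_events=n,
        mean_amplitude=float(np.mean([e.amplitude for e in events])) if n else None,
        frequency=n / (trace.duration / 60.0),
        oscillating=n >= min_events,
    )


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, sem


def summarize_group(summaries: Sequence[TraceSummary], label: str) -> GroupSummary:
    """Group statistics: % oscillating over all cells; amplitude and
    frequency mean +- SEM over oscillating cells only."""
    if not summaries:
        raise ValueError("no trace summaries to aggregate")
    osc = [s for s in summaries if s.oscillating]
    pct = 100.0 * len(osc) / len(summaries)
    if not osc:
        return GroupSummary(label, len(summaries), 0, pct, None, None, None, None)
    amp = np.array([s.mean_amplitude for s in osc if s.mean_amplitude is not None])
    freq = np.array([s.frequency for s in osc])
    amp_mean, amp_sem = _mean_sem(amp)
    freq_mean, freq_sem = _mean_sem(freq)
    return GroupSummary(
        label=label,
        n_cells=len(summaries),
        n_oscillating=len(osc),
        pct_oscillating=pct,
        amplitude_mean=amp_mean,
        amplitude_sem=amp_sem,
        frequency_mean=freq_mean,
        frequency_sem=freq_sem,
    )


def analyze_traces(
    traces: Sequence[FluorescenceTrace],
    label: str = "group",
    k_sigma: float = DEFAULT_K_SIGMA,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> tuple[list[TraceSummary], GroupSummary]:
    """Run detection and per-cell/group summarization over a population."""
    summaries = [
        summarize_trace(t, detect_events(t, k_sigma, min_separation_s), min_events)
        for t in traces
    ]
    return summaries, summarize_group(summaries, label)


def read_traces_csv(path, dt: float = DEFAULT_DT_S) -> list[FluorescenceTrace]:
    """Read traces from CSV: long format (cell_id, frame, fluorescence) or
    wide format (one column per cell)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if {"cell_id", "frame", "fluorescence"} <= set(cols):
        traces = []
        for cid, grp in df.groupby(cols["cell_id"], sort=True):
            grp = grp.sort_values(cols["frame"])
            traces.append(
                FluorescenceTrace(str(cid), grp[cols["fluorescence"]].to_numpy(), dt)
            )
        return traces
    return [FluorescenceTrace(str(c), df[c].to_numpy(), dt) for c in df.columns]


def group_summary_json(summary: GroupSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.__dict__, fh, indent=2)
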