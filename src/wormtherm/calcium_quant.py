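"""Quantification of GCaMP fluorescence time series.

The analysis chain mirrors standard practice for slow temperature-ramp
imaging of C. elegans sensory neurons:

1. :func:`dff` — percent fluorescence change relative to the mean of the
   first 10 frames (the baseline window), after background subtraction.
2. :func:`detect_events` — a *response* is a bout of dF/F exceeding 10%;
   maximal suprathreshold intervals are extracted, short gaps merged and
   sub-minimum bouts discarded.
3. :func:`t_star` — the stimulus temperature at the onset of the earliest
   response on a rising ramp: the neuron's response threshold temperature
   (written T* for the AFD neuron).
4. :func:`bin_response_fraction` — the fraction of neurons responding in
   successive 15-s stimulus bins.
5. :func:`compare_distributions` — two-sample KS or Mann-Whitney U
   comparisons of response-duration distributions, with the cumulative
   distribution fraction curves used for plotting.

Events are half-open ``[onset, offset)`` in frame space; onset is the first
frame *strictly* above threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import TemperatureRamp

__all__ = [
    "CalciumTrace",
    "DffTrace",
    "ResponseEvent",
    "NeuronSummary",
    "CompareResult",
    "dff",
    "detrend_peri_tc",
    "detect_events",
    "t_star",
    "bin_response_fraction",
    "compare_distributions",
    "summarize_neuron",
]


@dataclass
class CalciumTrace:
    """Background-subtracted fluorescence time series of one neuron."""

    neuron_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    temperature: Optional[np.ndarray] = None
    frame_rate: float = 2.0
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.times) != len(self.fluorescence):
            raise ValueError("times and fluorescence must have equal length")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if len(self.temperature) != len(self.times):
                raise ValueError("temperature channel length mismatch")
        if len(self.times) < 10:
            raise ValueError(
                f"trace {self.neuron_id!r} too short ({len(self.times)} frames); "
                "a baseline window of 10 frames must exist"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DffTrace:
    """Percent fluorescence change relative to a stored baseline."""

    times: np.ndarray
    dff: np.ndarray
    baseline_value: float
    frame_rate: float = 2.0
    temperature: Optional[np.ndarray] = None
    neuron_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.times) != len(self.dff):
            raise ValueError("times and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff trace contains non-finite values")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ResponseEvent:
    """One suprathreshold calcium bout, half-open in time."""

    onset_time: float
    offset_time: float
    peak_dff: float
    onset_temperature: Optional[float] = None

    def __post_init__(self):
        if self.offset_time <= self.onset_time:
            raise ValueError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass
class NeuronSummary:
    """Per-neuron response summary: total and mean bout durations and T*."""

    neuron_id: str
    n_events: int
    total_response_duration: float
    mean_event_duration: float
    responded: bool
    t_star: Optional[float] = None


@dataclass
class CompareResult:
    """Two-sample comparison plus the ECDF curves for plotting."""

    test: str
    statistic: float
    p_value: float
    ecdf_a: Tuple[np.ndarray, np.ndarray]
    ecdf_b: Tuple[np.ndarray, np.ndarray]

    def __iter__(self):
        # allows `stat, p = compare_distributions(...)`
        return iter((self.statistic, self.p_value))


def dff(trace: CalciumTrace, baseline_frames: int = 10) -> DffTrace:
    """Percent change from the mean of the first ``baseline_frames`` frames.

    The baseline mean must be positive (a non-positive value signals failed
    background subtraction).  By construction the output's own baseline
    window averages ~0.
    """
    if len(trace) <= baseline_frames:
        raise ValueError(
            f"trace length {len(trace)} must exceed baseline window {baseline_frames}"
        )
    baseline = float(np.mean(trace.fluorescence[:baseline_frames]))
    if baseline <= 0:
        raise ValueError(
            f"non-positive baseline ({baseline:.4g}); check background subtraction"
        )
    values = 100.0 * (trace.fluorescence - baseline) / baseline
    return DffTrace(
        times=trace.times.copy(),
        dff=values,
        baseline_value=baseline,
        frame_rate=trace.frame_rate,
        temperature=None if trace.temperature is None else trace.temperature.copy(),
        neuron_id=trace.neuron_id,
    )


def detrend_peri_tc(trace: DffTrace, window: Tuple[float, float] = (18.0, 22.0)) -> DffTrace:
    """Restrict to a temperature window and remove the best-fit linear trend.

    Used for scoring responses around the cultivation temperature
    ("peri-Tc", 18-22 degC by default), where slow drift would otherwise
    swamp small transients.  The output has ~zero mean by construction.
    """
    if trace.temperature is None:
        raise ValueError("detrending requires a temperature channel")
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"empty temperature window {window}")
    mask = (trace.temperature >= lo) & (trace.temperature <= hi)
    if not mask.any():
        raise ValueError(
            f"window [{lo}, {hi}] degC outside recorded temperatures "
            f"[{trace.temperature.min():.3g}, {trace.temperature.max():.3g}]"
        )
    t = trace.times[mask]
    y = trace.dff[mask]
    coeffs = np.polyfit(t, y, 1)
    detrended = y - np.polyval(coeffs, t)
    return DffTrace(
        times=t.copy(),
        dff=detrended,
        baseline_value=trace.baseline_value,
        frame_rate=trace.frame_rate,
        temperature=trace.temperature[mask].copy(),
        neuron_id=trace.neuron_id,
    )


def _suprathreshold_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def detect_events(
    trace: DffTrace,
    threshold: float = 10.0,
    min_duration: int = 2,
    merge_gap: int = 1,
) -> List[ResponseEvent]:
    """Detect suprathreshold calcium response bouts.

    A response is a maximal contiguous interval of frames with dF/F
    strictly above ``threshold`` percent.  Intervals separated by at most
    ``merge_gap`` subthreshold frames are merged; merged intervals shorter
    than ``min_duration`` frames are discarded.  Durations are frame counts
    divided by the frame rate.
    """
    mask = trace.dff > threshold
    runs = _suprathreshold_runs(mask)
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for a, b in runs[1:]:
            pa, pb = merged[-1]
            if a - pb <= merge_gap:
                merged[-1] = (pa, b)
            else:
                merged.append((a, b))
        runs = merged
    runs = [(a, b) for a, b in runs if b - a >= min_duration]

    fr = trace.frame_rate
    events = []
    for a, b in runs:
        onset_t = float(trace.times[a])
        events.append(
            ResponseEvent(
                onset_time=onset_t,
                offset_time=onset_t + (b - a) / fr,
                peak_dff=float(trace.dff[a:b].max()),
                onset_temperature=(
                    None if trace.temperature is None else float(trace.temperature[a])
                ),
            )
        )
    return events


def t_star(events: Sequence[ResponseEvent], ramp: TemperatureRamp) -> Optional[float]:
    """Response threshold temperature: ramp temperature at the earliest onset.

    Returns None when there are no events (the neuron is classified as
    non-responding).  Requires a rising ramp.
    """
    if ramp.rate <= 0:
        raise ValueError("T* is defined only on a rising temperature ramp")
    if not events:
        return None
    onset = min(ev.onset_time for ev in events)
    temp = ramp.temperature(onset)
    lo, hi = ramp.start_temp, ramp.end_temp
    return float(min(max(temp, lo), hi))


def bin_response_fraction(
    traces_events: Sequence[Tuple[DffTrace, Sequence[ResponseEvent]]],
    bin_width: float = 15.0,
) -> pd.DataFrame:
    """Fraction of neurons responding within successive time bins.

    Each bin ``[k*w, (k+1)*w)`` scores the fraction of neurons having at
    least one suprathreshold frame inside it (an event interval
    overlapping the bin).  All traces must share the stimulus time base.
    """
    if not traces_events:
        raise ValueError("no traces supplied")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_frames = len(traces_events[0][0])
    fr = traces_events[0][0].frame_rate
    t0 = traces_events[0][0].times[0]
    for tr, _ in traces_events:
        if len(tr) != n_frames or abs(tr.times[0] - t0) > 1e-9:
            raise ValueError("traces do not share a common stimulus time base")
    total_duration = n_frames / fr
    n_bins = int(np.ceil(total_duration / bin_width - 1e-9))
    starts = t0 + bin_width * np.arange(n_bins)
    fractions = np.zeros(n_bins)
    for tr, events in traces_events:
        for b in range(n_bins):
            lo = starts[b]
            hi = lo + bin_width
            if any(ev.onset_time < hi and ev.offset_time > lo for ev in events):
                fractions[b] += 1
    fractions /= len(traces_events)
    return pd.DataFrame(
        {
            "bin_start_s": starts,
            "bin_end_s": starts + bin_width,
            "fraction_responding": fractions,
        }
    )


def _ecdf(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    xs = np.sort(values)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def compare_distributions(
    a: Sequence[float], b: Sequence[float], test: str = "ks"
) -> CompareResult:
    """Two-sided two-sample comparison of duration distributions.

    ``test='ks'`` runs the Kolmogorov-Smirnov test on the cumulative
    distribution fractions; ``test='mwu'`` the Mann-Whitney U test (exact
    when sample sizes permit).  The returned object also carries both ECDF
    curves for plotting.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if test == "ks":
        res = stats.ks_2samp(a, b, alternative="two-sided")
    elif test == "mwu":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}; use 'ks' or 'mwu'")
    return CompareResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ecdf_a=_ecdf(a),
        ecdf_b=_ecdf(b),
    )


def summarize_neuron(
    neuron_id: str,
    events: Sequence[ResponseEvent],
    ramp: Optional[TemperatureRamp] = None,
) -> NeuronSummary:
    """Collapse a neuron's events into total/mean durations and T*."""
    n = len(events)
    total = float(sum(ev.duration for ev in events))
    if n and not np.isclose(total, sum(ev.duration for ev in events), atol=1e-9 * n):
        warnings.warn("duration summation drift", stacklevel=2)
    star = None
    if ramp is not None and ramp.rate > 0:
        star = t_star(events, ramp)
    return NeuronSummary(
        neuron_id=neuron_id,
        n_events=n,
        total_response_duration=total,
        mean_event_duration=total / n if n else 0.0,
        responded=n > 0,
        t_star=star,
    )
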