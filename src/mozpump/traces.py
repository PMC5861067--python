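"""Pump-cycle kinematics from ROI-intensity time series.

X-ray absorption is linear in the mass of contrast-laden food, so the mean
grayscale intensity over a region of interest covering a pump tracks that
pump's volume.  The pipeline mirrors how such recordings are analyzed:
smooth with a 3-point moving average, normalize per bout, locate stroke
start/peak/end from local minima and maxima, derive the cycle-timing table,
and label each stroke continuous or burst by its amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "IntensityTrace",
    "CycleEvent",
    "smooth_trace",
    "normalize_trace",
    "robust_amplitude",
    "detect_cycles",
    "classify_mode",
    "timing_table",
    "summarize_timing",
    "analyze_trace",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityTrace:
    """Two-channel ROI-intensity recording at a fixed frame rate.

    ``bouts`` are [start, end) sample-index ranges of drinking bouts; when
    absent the whole recording is one bout.
    """

    time_s: np.ndarray
    cp: np.ndarray
    pp: np.ndarray
    fps: float = 30.0
    specimen: str = "s1"
    bouts: Optional[List[Tuple[int, int]]] = None

    def __post_init__(self):
        n = len(self.time_s)
        if len(self.cp) != n or len(self.pp) != n:
            raise ValueError("channels must have the same length as the time axis")

    def channel(self, pump: str) -> np.ndarray:
        return self.cp if pump == "cp" else self.pp

    def bout_ranges(self) -> List[Tuple[int, int]]:
        return self.bouts if self.bouts else [(0, len(self.time_s))]


@dataclass
class CycleEvent:
    """One pump stroke: flanking minima and the peak between them."""

    pump: str
    start_s: float
    peak_s: float
    end_s: float
    amplitude: float
    start_idx: int
    peak_idx: int
    end_idx: int
    mode: str = "continuous"

    def __post_init__(self):
        if not (self.start_s < self.peak_s < self.end_s):
            raise ValueError("event requires start < peak < end")


def smooth_trace(values: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average; the endpoints use the shrunken
    2-point windows."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to smooth")
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def normalize_trace(
    values: np.ndarray, bouts: Optional[Sequence[Tuple[int, int]]] = None
) -> np.ndarray:
    """Min/max normalization to [0, 1] within each bout."""
    x = np.asarray(values, dtype=float)
    out = np.empty_like(x)
    for lo, hi in bouts if bouts else [(0, x.size)]:
        seg = x[lo:hi]
        span = float(np.max(seg) - np.min(seg))
        if span == 0.0:
            raise ValueError(f"flat bout [{lo}, {hi}) cannot be normalized")
        out[lo:hi] = (seg - np.min(seg)) / span
    return out


def robust_amplitude(values: np.ndarray) -> float:
    """Robust peak-to-peak amplitude of the oscillatory component.

    Uses the median absolute deviation: a raised cosine has
    MAD = (peak-to-peak)/(2*sqrt(2)), so amplitude = 2*sqrt(2)*MAD.  Unlike
    the raw range, this barely moves when rare large bursts are embedded in
    a continuous recording, so the stroke-detection threshold keeps tracking
    the continuous strokes.
    """
    x = np.asarray(values, dtype=float)
    mad = float(np.median(np.abs(x - np.median(x))))
    return 2.0 * np.sqrt(2.0) * mad


def _refine_onset(x: np.ndarray, lo: int, m: int, fraction: float) -> int:
    """Last sample at or before the peak still within ``fraction`` of the
    stroke height above the flanking-minimum baseline.

    When the pump rests between strokes the raw minimum sits anywhere on
    the flat gap (noise decides); the stroke boundary is where the signal
    actually leaves the baseline, so the flanking minimum is refined toward
    the peak until the signal starts to rise.
    """
    thr = x[lo] + fraction * (x[m] - x[lo])
    below = np.flatnonzero(x[lo : m + 1] <= thr)
    return lo + int(below[-1]) if below.size else lo


def detect_cycles(
    values: np.ndarray,
    time_s: np.ndarray,
    pump: str = "cp",
    prominence: float = 0.1,
    raw: Optional[np.ndarray] = None,
    onset_fraction: float = 0.05,
) -> List[CycleEvent]:
    """Locate pump strokes as prominence-filtered maxima flanked by minima.

    ``prominence`` is a fraction of the robust continuous-stroke amplitude
    (for a pure normalized continuous trace this is the plain 0.1-of-range
    threshold).  The first and last samples are admitted as candidate
    flanking minima so strokes at the recording edges are kept.  Stroke
    start/end are refined from the flanking minima to the last/first sample
    within ``onset_fraction`` of the stroke height above the minimum, which
    pins the boundary to the onset of wall motion rather than to a
    noise-selected point on a rest plateau.  Event amplitudes are read from
    ``raw`` (un-normalized values) when given.

    Returns an empty list when the trace has no oscillatory content.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(time_s, dtype=float)
    amp_ref = robust_amplitude(x)
    if amp_ref == 0.0:
        return []
    threshold = prominence * amp_ref
    maxima, _ = find_peaks(x, prominence=threshold)
    if maxima.size == 0:
        return []
    minima, _ = find_peaks(-x, prominence=threshold)
    # boundary samples may serve as flanking minima
    minima = np.unique(np.concatenate([[0, x.size - 1], minima]))

    amp_src = np.asarray(raw, dtype=float) if raw is not None else x
    events: List[CycleEvent] = []
    for m in maxima:
        left = minima[minima < m]
        right = minima[minima > m]
        if left.size == 0 or right.size == 0:
            continue
        lo, hi = int(left[-1]), int(right[0])
        amplitude = float(amp_src[m] - 0.5 * (amp_src[lo] + amp_src[hi]))
        lo = _refine_onset(x, lo, int(m), onset_fraction)
        hi_rev = _refine_onset(x[::-1], x.size - 1 - hi, x.size - 1 - int(m),
                               onset_fraction)
        hi = x.size - 1 - hi_rev
        events.append(
            CycleEvent(
                pump=pump,
                start_s=float(t[lo]),
                peak_s=float(t[m]),
                end_s=float(t[hi]),
                amplitude=amplitude,
                start_idx=lo,
                peak_idx=int(m),
                end_idx=hi,
            )
        )
    return events


def classify_mode(
    events: List[CycleEvent],
    ratio: float = 3.0,
    min_context: int = 3,
    absolute_fallback: Optional[float] = None,
    reference_amplitude: Optional[float] = None,
) -> List[str]:
    """Label each stroke ``"continuous"`` or ``"burst"`` by amplitude.

    A stroke is a burst when its (un-normalized) amplitude exceeds ``ratio``
    times the median stroke amplitude of the recording.  With fewer than
    ``min_context`` strokes there is no continuous context to take a median
    over; then the threshold falls back to ``absolute_fallback`` if given,
    else to ``ratio`` times ``reference_amplitude`` (e.g. the robust
    baseline amplitude of the raw trace), so an isolated large event is
    still recognized as a burst.  Labels are also written onto the events.
    """
    if not events:
        return []
    amps = np.array([e.amplitude for e in events])
    if len(events) >= min_context:
        threshold = ratio * float(np.median(amps))
    elif absolute_fallback is not None:
        threshold = absolute_fallback
    elif reference_amplitude is not None:
        threshold = ratio * reference_amplitude
    else:
        raise ValueError(
            "too few events for a median threshold; provide absolute_fallback "
            "or reference_amplitude"
        )
    labels = []
    for e in events:
        e.mode = "burst" if e.amplitude > threshold else "continuous"
        labels.append(e.mode)
    return labels


_ABS_VARS = [
    "cp_start_ms", "pp_start_ms", "cp_peak_ms", "pp_peak_ms",
    "cp_end_ms", "pp_end_ms", "total_cycle_ms", "cp_cycle_ms", "pp_cycle_ms",
    "between_starts_ms", "between_peaks_ms", "between_ends_ms",
    "time_to_next_ms",
]


def timing_table(
    cp_events: List[CycleEvent],
    pp_events: List[CycleEvent],
    specimen: str = "s1",
) -> pd.DataFrame:
    """Per-cycle timing variables from paired cibarial/pharyngeal strokes.

    Each cibarial stroke is paired with the next-starting pharyngeal stroke;
    unpaired strokes are skipped with a log entry.  Times are reported in ms
    relative to the cycle origin (the cibarial start); the total cycle runs
    from the cibarial start to the pharyngeal end, and relative (%) values
    are per-cycle fractions of that total.  ``time_to_next_ms`` is the gap
    from the pharyngeal end to the next cycle's cibarial start (negative
    when cycles overlap), and the cycle frequency is the reciprocal of the
    cibarial start-to-start interval.
    """
    cp_sorted = sorted(cp_events, key=lambda e: e.start_s)
    pp_sorted = sorted(pp_events, key=lambda e: e.start_s)
    rows = []
    for i, cpe in enumerate(cp_sorted):
        next_cp_start = (
            cp_sorted[i + 1].start_s if i + 1 < len(cp_sorted) else np.nan
        )
        candidates = [
            p for p in pp_sorted
            if p.start_s >= cpe.start_s
            and (np.isnan(next_cp_start) or p.start_s < next_cp_start)
        ]
        if not candidates:
            logger.info(
                "specimen %s: cibarial stroke at %.3f s has no paired "
                "pharyngeal stroke; cycle skipped", specimen, cpe.start_s,
            )
            continue
        ppe = candidates[0]
        t0 = cpe.start_s
        total = ppe.end_s - t0
        row = {
            "specimen": specimen,
            "cycle_origin_s": t0,
            "cp_start_ms": 0.0,
            "pp_start_ms": (ppe.start_s - t0) * 1e3,
            "cp_peak_ms": (cpe.peak_s - t0) * 1e3,
            "pp_peak_ms": (ppe.peak_s - t0) * 1e3,
            "cp_end_ms": (cpe.end_s - t0) * 1e3,
            "pp_end_ms": (ppe.end_s - t0) * 1e3,
            "total_cycle_ms": total * 1e3,
            "cp_cycle_ms": (cpe.end_s - cpe.start_s) * 1e3,
            "pp_cycle_ms": (ppe.end_s - ppe.start_s) * 1e3,
            "between_starts_ms": (ppe.start_s - cpe.start_s) * 1e3,
            "between_peaks_ms": (ppe.peak_s - cpe.peak_s) * 1e3,
            "between_ends_ms": (ppe.end_s - cpe.end_s) * 1e3,
            "time_to_next_ms": (next_cp_start - ppe.end_s) * 1e3,
            "cycle_frequency_hz": (
                1.0 / (next_cp_start - t0) if next_cp_start > t0 else np.nan
            ),
            "cp_pp_ratio": (cpe.end_s - cpe.start_s) / (ppe.end_s - ppe.start_s),
            "mode": (
                "burst" if "burst" in (cpe.mode, ppe.mode) else "continuous"
            ),
        }
        for var in _ABS_VARS:
            row[var.replace("_ms", "_rel_pct")] = 100.0 * row[var] / row["total_cycle_ms"]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_timing(per_cycle: pd.DataFrame) -> pd.DataFrame:
    """Grand mean ± SD of every timing variable, averaging per specimen
    first.

    With several specimens the SD is across specimen means; with a single
    specimen it is the SD across that specimen's cycles.
    """
    numeric = [c for c in per_cycle.columns if per_cycle[c].dtype.kind == "f"]
    numeric = [c for c in numeric if c != "cycle_origin_s"]
    by_spec = per_cycle.groupby("specimen")[numeric].mean()
    if len(by_spec) > 1:
        mean, sd = by_spec.mean(), by_spec.std(ddof=1)
    else:
        mean = by_spec.iloc[0]
        sd = per_cycle[numeric].std(ddof=1)
    return pd.DataFrame({"mean": mean, "sd": sd})


def analyze_trace(
    trace: IntensityTrace,
    prominence: float = 0.1,
    burst_ratio: float = 3.0,
) -> dict:
    """Full pipeline: smooth, normalize per bout, detect strokes on the
    normalized signal, classify modes on raw amplitudes, build the timing
    table from continuous cycles.

    Returns a dict with per-pump events, the per-cycle table, its summary,
    and per-pump burst counts.
    """
    out = {"events": {}, "n_bursts": {}}
    smoothed = {}
    for pump in ("cp", "pp"):
        sm = smooth_trace(trace.channel(pump))
        smoothed[pump] = sm
        norm = normalize_trace(sm, trace.bouts)
        events = detect_cycles(
            norm, trace.time_s, pump=pump, prominence=prominence, raw=sm
        )
        classify_mode(
            events,
            ratio=burst_ratio,
            reference_amplitude=robust_amplitude(sm),
        )
        out["events"][pump] = events
        out["n_bursts"][pump] = sum(e.mode == "burst" for e in events)
    continuous = {
        pump: [e for e in out["events"][pump] if e.mode == "continuous"]
        for pump in ("cp", "pp")
    }
    per_cycle = timing_table(
        continuous["cp"], continuous["pp"], specimen=trace.specimen
    )
    out["per_cycle"] = per_cycle
    out["summary"] = summarize_timing(per_cycle) if len(per_cycle) else None
    return out
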