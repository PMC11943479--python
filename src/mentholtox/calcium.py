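"""Quantification of agonist-evoked calcium transients from plate-reader traces.

A trace is relative fluorescence (RFU) sampled over time in one well; the
agonist is added after a ~20 s baseline window. Quantities extracted per
trace: baseline (mean pre-addition RFU), peak height (max of the smoothed,
baseline-subtracted post-addition signal within a 4-minute window), time to
peak, and whether the signal returned to baseline by the end of the window.
Percent block by a channel inhibitor compares peak heights with and without
the inhibitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "PeakSummary",
    "baseline_subtract",
    "peak_height",
    "percent_block",
    "summarize_conditions",
    "area_under_curve",
    "traces_from_wide",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Timestamped RFU series for one well."""

    timestamps: np.ndarray          # seconds
    rfu: np.ndarray
    addition_time: float            # seconds; agonist added at this time
    well_label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        y = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "rfu", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("timestamps and rfu must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("rfu must be finite")
        if np.sum(t < self.addition_time) < 2:
            raise ValueError("need >= 2 samples before addition_time")


@dataclass(frozen=True)
class PeakSummary:
    baseline: float
    peak_height: float              # baseline-subtracted RFU
    time_to_peak: float             # seconds (absolute time)
    returns_to_baseline: bool
    well_label: str = ""
    condition: str = ""


def baseline_subtract(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Subtract the mean pre-addition RFU; pre-addition mean becomes 0."""
    pre = trace.timestamps < trace.addition_time
    baseline = float(trace.rfu[pre].mean())
    return replace(trace, rfu=trace.rfu - baseline)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    # centered, edges shrink to the available samples
    kernel = np.ones(window) / window
    padded = np.pad(y, window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    return out[window // 2: window // 2 + y.size]


def peak_height(
    trace: FluorescenceTrace,
    smooth_window: int = 3,
    window_s: float = 240.0,
    tail_fraction: float = 0.10,
    return_threshold: float = 0.20,
) -> PeakSummary:
    """Peak of the smoothed baseline-subtracted signal after addition.

    The measurement window runs from addition to ``window_s`` seconds later.
    ``returns_to_baseline`` is true when the mean over the final
    ``tail_fraction`` of the window is below ``return_threshold`` × peak
    (a flat or non-responding trace trivially returns).
    """
    pre = trace.timestamps < trace.addition_time
    baseline = float(trace.rfu[pre].mean())
    post = (trace.timestamps >= trace.addition_time) & (
        trace.timestamps <= trace.addition_time + window_s
    )
    if not post.any():
        raise ValueError("empty post-addition window")
    t_post = trace.timestamps[post]
    y_post = _moving_average(trace.rfu[post] - baseline, smooth_window)
    i_peak = int(np.argmax(y_post))
    peak = float(y_post[i_peak])
    if peak <= 0:
        peak = 0.0
    tail_start = trace.addition_time + (1.0 - tail_fraction) * window_s
    tail = y_post[t_post >= tail_start]
    if peak == 0.0:
        returns = True
    else:
        returns = bool(tail.size and float(tail.mean()) < return_threshold * peak)
    return PeakSummary(
        baseline=baseline,
        peak_height=peak,
        time_to_peak=float(t_post[i_peak]),
        returns_to_baseline=returns,
        well_label=trace.well_label,
        condition=trace.condition,
    )


def percent_block(peak_agonist: float, peak_with_inhibitor: float) -> float:
    """Percent reduction of the agonist peak by an inhibitor, in [0, 100].

    Values outside [0, 100] (inhibitor peak exceeding the agonist peak, or
    negative peaks) are clipped with a warning.
    """
    if not peak_agonist > 0:
        raise ValueError(f"peak_agonist must be positive, got {peak_agonist!r}")
    raw = 100.0 * (1.0 - peak_with_inhibitor / peak_agonist)
    if raw < 0 or raw > 100:
        warnings.warn(f"percent block {raw:.1f} outside [0, 100]; clipped", stacklevel=2)
    return float(np.clip(raw, 0.0, 100.0))


def area_under_curve(trace: FluorescenceTrace, window_s: float = 240.0) -> float:
    """Trapezoidal AUC of the baseline-subtracted post-addition signal."""
    sub = baseline_subtract(trace)
    post = (sub.timestamps >= sub.addition_time) & (
        sub.timestamps <= sub.addition_time + window_s
    )
    return float(np.trapezoid(sub.rfu[post], sub.timestamps[post]))


def summarize_conditions(
    traces: list[FluorescenceTrace], smooth_window: int = 3, window_s: float = 240.0
) -> pd.DataFrame:
    """Per-condition mean peak height ± SEM over replicate wells.

    SEM is reported as NaN for single-replicate conditions.
    """
    if not traces:
        raise ValueError("no traces supplied")
    rows = [
        {"condition": s.condition, "well": s.well_label, "peak_height": s.peak_height}
        for s in (peak_height(t, smooth_window, window_s) for t in traces)
    ]
    df = pd.DataFrame(rows)
    out = df.groupby("condition", sort=False)["peak_height"].agg(
        n="count", mean_peak="mean", sd=lambda v: v.std(ddof=1)
    ).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, ["sd", "sem"]] = np.nan
    return out.drop(columns="sd")


def traces_from_wide(
    trace_table: pd.DataFrame, well_map: pd.DataFrame
) -> list[FluorescenceTrace]:
    """Build traces from a wide CSV (time + one RFU column per well).

    ``well_map`` has columns ``well``, ``condition`` and ``addition_time``.
    """
    if "time" not in trace_table.columns:
        raise ValueError("trace table needs a 'time' column")
    required = {"well", "condition", "addition_time"}
    if not required.issubset(well_map.columns):
        raise ValueError(f"well map needs columns {sorted(required)}")
    t = trace_table["time"].to_numpy(dtype=float)
    traces = []
    for row in well_map.itertuples(index=False):
        if row.well not in trace_table.columns:
            raise ValueError(f"well {row.well!r} missing from trace table")
        traces.append(FluorescenceTrace(
            timestamps=t,
            rfu=trace_table[row.well].to_numpy(dtype=float),
            addition_time=float(row.addition_time),
            well_label=str(row.well),
            condition=str(row.condition),
        ))
    return traces
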