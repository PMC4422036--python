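"""Evoked field-potential metrics and plasticity time courses.

A dentate-gyrus evoked response to perforant-path stimulation is a positive
field EPSP with a sharp negative population spike (PS) superimposed near its
peak.  Synaptic strength is indexed by the maximal rising slope of the fEPSP
(the steepest least-squares slope through five consecutive samples on the
positive deflection) and granule-cell output by the PS amplitude (depth of
the first negative deflection).  Long-term potentiation is expressed as
percent of the mean of the first six baseline time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "EvokedResponse",
    "PlasticityTimeSeries",
    "default_schedule",
    "average_sweeps",
    "fepsp_slope",
    "ps_amplitude",
    "io_select_intensity",
    "measure_time_points",
    "percent_of_baseline",
    "summarize_group",
]


@dataclass
class EvokedResponse:
    """One evoked sweep: sample times in ms (stimulus at t=0), values in mV."""

    time_ms: np.ndarray
    values_mv: np.ndarray
    time_point_min: float | None = None
    intensity_ua: float | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, float)
        self.values_mv = np.asarray(self.values_mv, float)
        if self.time_ms.shape != self.values_mv.shape:
            raise ValueError("time and value arrays must align")


def default_schedule() -> tuple[np.ndarray, list[str]]:
    """Standard recording schedule (minutes) with phase labels.

    Six baseline points at 5 min intervals, i.c.v. injection after 30 min,
    six post-injection points, HFS after 60 min, three post-HFS points at
    5 min intervals then 15 min intervals out to 4 h, and a 24-25 h block.
    """
    times: list[float] = []
    phases: list[str] = []
    for t in range(0, 30, 5):                      # 0..25
        times.append(float(t)); phases.append("baseline")
    for t in range(35, 65, 5):                     # 35..60
        times.append(float(t)); phases.append("post_injection")
    for t in (65, 70, 75):
        times.append(float(t)); phases.append("post_hfs")
    for t in range(90, 301, 15):                   # out to 4 h after HFS
        times.append(float(t)); phases.append("post_hfs")
    for t in range(1500, 1561, 15):                # 24-25 h after HFS
        times.append(float(t)); phases.append("24h")
    return np.asarray(times), phases


def average_sweeps(sweeps: list[EvokedResponse]) -> EvokedResponse:
    """Pointwise average of sweeps sharing one time base."""
    if not sweeps:
        raise ValueError("no sweeps to average")
    t0 = sweeps[0].time_ms
    for s in sweeps[1:]:
        if not np.array_equal(s.time_ms, t0):
            raise ValueError("sweeps have mismatched time bases")
    mean = np.mean([s.values_mv for s in sweeps], axis=0)
    return EvokedResponse(time_ms=t0.copy(), values_mv=mean,
                          time_point_min=sweeps[0].time_point_min,
                          intensity_ua=sweeps[0].intensity_ua)


# --------------------------------------------------------------------------
# sweep metrics
# --------------------------------------------------------------------------

def _rolling_slopes(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Least-squares slope of every window of ``n`` consecutive samples
    (uniform spacing assumed)."""
    if len(y) < n:
        return np.empty(0)
    dt = float(t[1] - t[0])
    w = (np.arange(n) - (n - 1) / 2.0) * dt
    denom = float(np.sum(w * w))
    return np.convolve(y, w[::-1], mode="valid") / denom


def fepsp_slope(sweep: EvokedResponse, window_ms: tuple[float, float] = (1.0, 10.0),
                n_points: int = 5, min_slope: float = 0.0) -> float:
    """Maximal 5-point least-squares slope on the rising (positive)
    deflection, restricted to ``window_ms`` after the stimulus (mV/ms).

    The search stops at the first prominent local maximum inside the
    window (the fEPSP peak), so the steep recovery edge of a superimposed
    population spike is never mistaken for the synaptic rising phase.
    Returns NaN with a warning when no slope exceeds ``min_slope`` (no
    positive deflection above the noise gate).  Invariant to DC offset.
    """
    lo, hi = window_ms
    sel = (sweep.time_ms >= lo) & (sweep.time_ms <= hi)
    t, y = sweep.time_ms[sel], sweep.values_mv[sel]
    gate = 0.05 * float(np.ptp(y))
    if gate > 0:
        peaks, _ = find_peaks(y, prominence=gate)
        if peaks.size:
            t, y = t[:peaks[0] + 1], y[:peaks[0] + 1]
    slopes = _rolling_slopes(t, y, n_points)
    if slopes.size == 0:
        raise ValueError("sweep too short for the slope window")
    best = float(np.max(slopes))
    if best <= min_slope:
        warnings.warn("no positive deflection above the noise gate",
                      stacklevel=2)
        return np.nan
    return best


def ps_amplitude(sweep: EvokedResponse, method: str = "tangent",
                 window_ms: tuple[float, float] = (1.0, 20.0),
                 n_points: int = 5, min_prominence_frac: float = 0.05
                 ) -> float:
    """Amplitude of the first negative deflection (population spike), mV.

    The PS trough is the first prominent local minimum after the fEPSP
    positive peak (prominence gate: ``min_prominence_frac`` of the sweep's
    peak-to-peak range).  Two amplitude conventions:

    ``tangent`` (default)
        depth of the trough below the line joining the local maxima that
        flank the spike (recovers the injected spike depth on a smooth
        fEPSP envelope).
    ``peak_to_trough``
        preceding local maximum minus trough value.

    Both are invariant to DC offset and scale linearly with the sweep.
    Returns NaN when no negative deflection is found.
    """
    if method not in ("tangent", "peak_to_trough"):
        raise ValueError(f"unknown method {method!r}")
    lo, hi = window_ms
    sel = (sweep.time_ms >= lo) & (sweep.time_ms <= hi)
    t, y = sweep.time_ms[sel], sweep.values_mv[sel]
    if len(y) < 2 * n_points:
        raise ValueError("sweep too short for PS analysis")
    gate = min_prominence_frac * float(np.ptp(y))
    if gate == 0.0:
        warnings.warn("flat sweep: no negative deflection", stacklevel=2)
        return np.nan
    peaks0, _ = find_peaks(y, prominence=gate)
    p = int(peaks0[0]) if peaks0.size else int(np.argmax(y))
    troughs, _ = find_peaks(-y[p:], prominence=gate)
    if troughs.size == 0:
        warnings.warn("no negative deflection found", stacklevel=2)
        return np.nan
    tr = p + int(troughs[0])

    # steepest 5-point descending window on the falling edge (kept for the
    # record of how the deflection was localized; its sign gates validity)
    edge_slopes = _rolling_slopes(t[p:tr + 1], y[p:tr + 1], n_points) \
        if tr - p + 1 >= n_points else np.array([-np.inf])
    if edge_slopes.size and float(np.min(edge_slopes)) >= 0.0:
        warnings.warn("no descending edge before the trough", stacklevel=2)
        return np.nan

    maxima, _ = find_peaks(y, prominence=gate)
    pre_candidates = maxima[maxima < tr]
    pre = int(pre_candidates[-1]) if pre_candidates.size else p
    post_candidates = maxima[maxima > tr]
    if method == "tangent":
        if post_candidates.size:
            post = int(post_candidates[0])
        else:
            # no recovery maximum (monotone terrain after the spike):
            # mirror the deflection width to anchor the far support
            post = min(2 * tr - pre, len(y) - 1)
            if post <= tr:
                return float(y[pre] - y[tr])
        # interpolate the fEPSP envelope across the spike: quadratic fit
        # through short support windows just outside the flanking maxima
        # (second-order accurate on a smooth envelope), linear fallback
        k = max(n_points, 3)
        sup = np.r_[np.arange(max(pre - k, 0), pre + 1),
                    np.arange(post, min(post + k + 1, len(y)))]
        if len(sup) >= 6:
            coef = np.polyfit(t[sup], y[sup], 2)
            interp = float(np.polyval(coef, t[tr]))
        else:
            frac = (t[tr] - t[pre]) / (t[post] - t[pre])
            interp = float(y[pre] + frac * (y[post] - y[pre]))
        return float(interp - y[tr])
    # fall back to peak-to-trough when no recovery maximum exists
    return float(y[pre] - y[tr])


def io_select_intensity(intensities: np.ndarray | list[float],
                        responses: np.ndarray | list[float]) -> float:
    """Choose the stimulation intensity whose response is nearest 40% of the
    maximum response over the input/output curve; ties break to the lower
    intensity."""
    intensities = np.asarray(intensities, float)
    responses = np.asarray(responses, float)
    if intensities.size < 2:
        raise ValueError("need responses at >= 2 intensities")
    if intensities.shape != responses.shape:
        raise ValueError("intensity/response arrays must align")
    order = np.argsort(intensities, kind="stable")
    intensities, responses = intensities[order], responses[order]
    max_resp = float(np.max(responses))
    if max_resp <= 0:
        raise ValueError("non-positive maximum response")
    target = 0.4 * max_resp
    return float(intensities[int(np.argmin(np.abs(responses - target)))])


# --------------------------------------------------------------------------
# plasticity time series
# --------------------------------------------------------------------------

@dataclass
class PlasticityTimeSeries:
    """Percent-of-baseline time course for one subject and metric."""

    time_min: np.ndarray
    pct: np.ndarray
    phases: list[str]
    baseline_mean: float
    metric: str = ""

    def phase_means(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for ph in dict.fromkeys(self.phases):        # preserves order
            sel = [i for i, p in enumerate(self.phases) if p == ph]
            out[ph] = float(np.nanmean(self.pct[sel]))
        return out


def measure_time_points(sweeps: list[EvokedResponse],
                        ps_method: str = "tangent") -> pd.DataFrame:
    """Average the sweeps at each scheduled time point and measure both
    metrics; returns columns time_point_min, fepsp_slope, ps_amplitude."""
    by_tp: dict[float, list[EvokedResponse]] = {}
    for s in sweeps:
        by_tp.setdefault(float(s.time_point_min), []).append(s)
    rows = []
    for tp in sorted(by_tp):
        avg = average_sweeps(by_tp[tp])
        rows.append({"time_point_min": tp,
                     "fepsp_slope": fepsp_slope(avg),
                     "ps_amplitude": ps_amplitude(avg, method=ps_method)})
    return pd.DataFrame(rows)


def percent_of_baseline(time_min: np.ndarray | list[float],
                        values: np.ndarray | list[float],
                        phases: list[str] | None = None,
                        n_baseline: int = 6,
                        metric: str = "") -> PlasticityTimeSeries:
    """Express per-time-point means as percent of the mean of the first
    ``n_baseline`` points."""
    time_min = np.asarray(time_min, float)
    values = np.asarray(values, float)
    if time_min.size != values.size:
        raise ValueError("time/value arrays must align")
    if time_min.size < n_baseline:
        raise ValueError(f"need >= {n_baseline} baseline time points")
    base = values[:n_baseline]
    if np.any(~np.isfinite(base)):
        raise ValueError("missing values in the baseline period")
    baseline_mean = float(np.mean(base))
    if baseline_mean == 0:
        raise ValueError("zero baseline mean")
    if phases is None:
        phases = (["baseline"] * n_baseline
                  + ["post"] * (time_min.size - n_baseline))
    return PlasticityTimeSeries(time_min=time_min,
                                pct=100.0 * values / baseline_mean,
                                phases=list(phases),
                                baseline_mean=baseline_mean, metric=metric)


def summarize_group(series: list[PlasticityTimeSeries]) -> pd.DataFrame:
    """Group mean +/- SEM per time point over subjects (columns time_min,
    phase, mean_pct, sem, n)."""
    if not series:
        return pd.DataFrame(columns=["time_min", "phase", "mean_pct",
                                     "sem", "n"])
    t0 = series[0].time_min
    for s in series[1:]:
        if not np.array_equal(s.time_min, t0):
            raise ValueError("series have mismatched schedules")
    mat = np.vstack([s.pct for s in series])
    n = mat.shape[0]
    sem = (np.nanstd(mat, axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
        else np.zeros(mat.shape[1])
    return pd.DataFrame({"time_min": t0, "phase": series[0].phases,
                         "mean_pct": np.nanmean(mat, axis=0),
                         "sem": sem, "n": n})
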