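"""Hilbert cycle-by-cycle amplitude and frequency analysis.

A band-filtered oscillation is turned into an analytic signal (Hilbert
transform); individual cycles are excised between successive upward
crossings of phase -pi (trough to trough in the cosine convention, phase 0
at the waveform maximum).  Each cycle yields a recalculated frequency
(analysis rate / cycle length) and a trough-to-peak amplitude (signal
maximum minus minimum within the cycle; the term "peak-to-slope
amplitude" sometimes used for theta cycles denotes the same quantity).  For theta cycles the
mean trough-to-peak amplitude of the gamma cycles nested inside is attached
(a gamma cycle belongs to the theta cycle containing its start).

Relative amplitudes are pooled into frequency-binned maps (integer bins
5-10 Hz by timeline window, percent of baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

__all__ = [
    "CycleRecord",
    "analytic_phase",
    "excise_cycles",
    "nested_gamma_amplitude",
    "frequency_binned_map",
]


@dataclass
class CycleRecord:
    """One excised oscillation cycle (half-open sample interval)."""

    start: int
    end: int
    rate: float
    frequency: float                     # rate / length, Hz
    amplitude: float                     # trough-to-peak, signal units
    nested_gamma: float = np.nan         # mean nested gamma amplitude

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_time(self) -> float:
        return self.start / self.rate


def analytic_phase(x: np.ndarray, envelope_mode: str = "trough_to_peak"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (cosine convention, (-pi, pi], zero at the
    waveform maximum) and analytic amplitude of a band-filtered signal.

    ``envelope_mode`` is accepted for symmetry with :func:`excise_cycles`
    but does not alter the analytic amplitude.  Raises on a constant signal
    (undefined phase).
    """
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise ValueError("constant signal: instantaneous phase undefined")
    z = hilbert(x)
    return np.angle(z), np.abs(z)


def excise_cycles(x: np.ndarray, phase: np.ndarray, rate: float,
                  amplitude_mode: str = "trough_to_peak"
                  ) -> list[CycleRecord]:
    """Cut a filtered epoch into complete phase cycles.

    Cycle boundaries sit at successive upward crossings of phase -pi
    (phase wraps); partial cycles at the epoch edges are discarded.  The
    "maximum elongation" of a cycle is its trough-to-peak amplitude
    (max - min of the signal within the cycle); ``amplitude_mode
    "analytic_peak"`` uses the maximum analytic amplitude instead.
    """
    if amplitude_mode not in ("trough_to_peak", "analytic_peak"):
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
    x = np.asarray(x, float)
    wraps = np.flatnonzero(np.diff(phase) < -np.pi) + 1
    if wraps.size < 2:
        return []
    env = np.abs(hilbert(x)) if amplitude_mode == "analytic_peak" else None
    records: list[CycleRecord] = []
    for a, b in zip(wraps[:-1], wraps[1:]):
        if amplitude_mode == "trough_to_peak":
            amp = float(np.max(x[a:b]) - np.min(x[a:b]))
        else:
            amp = float(np.max(env[a:b]))
        records.append(CycleRecord(start=int(a), end=int(b), rate=rate,
                                   frequency=rate / (b - a), amplitude=amp))
    return records


def nested_gamma_amplitude(theta_cycles: list[CycleRecord],
                           gamma_filtered: np.ndarray,
                           gamma_rate: float) -> list[CycleRecord]:
    """Attach the mean gamma trough-to-peak amplitude nested in each theta
    cycle.

    The gamma epoch is cycle-analyzed at its own rate; theta cycle
    boundaries are mapped to gamma time, and each gamma cycle is attributed
    to the theta cycle containing its start.  Theta cycles hosting no gamma
    cycle keep a missing (NaN) nested amplitude.
    """
    if not theta_cycles:
        return []
    g_phase, _ = analytic_phase(gamma_filtered)
    g_cycles = excise_cycles(gamma_filtered, g_phase, gamma_rate)
    g_starts = np.array([c.start_time for c in g_cycles])
    g_amps = np.array([c.amplitude for c in g_cycles])
    out: list[CycleRecord] = []
    for c in theta_cycles:
        t0, t1 = c.start_time, c.end / c.rate
        inside = (g_starts >= t0) & (g_starts < t1)
        nested = float(np.mean(g_amps[inside])) if inside.any() else np.nan
        out.append(CycleRecord(start=c.start, end=c.end, rate=c.rate,
                               frequency=c.frequency, amplitude=c.amplitude,
                               nested_gamma=nested))
    return out


def frequency_binned_map(records: pd.DataFrame,
                         value_col: str = "amplitude",
                         baseline_window: str = "baseline",
                         freq_bins: tuple[int, int] = (5, 10),
                         window_order: tuple[str, ...] | None = None
                         ) -> pd.DataFrame:
    """Frequency x window map of mean relative amplitude (percent of
    baseline).

    ``records`` is a long table with columns subject, window, frequency and
    ``value_col`` (cycle amplitude or nested gamma amplitude).  Cycle
    frequencies are rounded to the nearest integer Hz; cycles outside the
    displayed 5-10 Hz range are discarded.  Values are normalized per
    subject and frequency bin to that bin's baseline mean, then averaged
    over subjects and epochs.  Empty cells are NaN.
    """
    df = records.copy()
    df["freq_bin"] = np.rint(df["frequency"]).astype(int)
    lo, hi = freq_bins
    df = df[(df["freq_bin"] >= lo) & (df["freq_bin"] <= hi)]
    df = df.dropna(subset=[value_col])
    base = (df[df["window"] == baseline_window]
            .groupby(["subject", "freq_bin"])[value_col].mean()
            .rename("baseline_mean"))
    df = df.merge(base, how="left", left_on=["subject", "freq_bin"],
                  right_index=True)
    df["relative_pct"] = 100.0 * df[value_col] / df["baseline_mean"]
    table = df.pivot_table(index="freq_bin", columns="window",
                           values="relative_pct", aggfunc="mean")
    table = table.reindex(range(lo, hi + 1))
    if window_order is not None:
        table = table.reindex(columns=list(window_order))
    return table
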