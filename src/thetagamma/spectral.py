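"""Band filtering, down-sampling and mean-square-spectrum band power.

Five linear-phase FIR band-pass filters (-3 dB edges: delta 2-4, theta
4.5-10, alpha 10-12, beta 12.5-28, gamma 29.5-99.5 Hz) plus a 48.5-55 Hz
mains band-stop are applied to 4.096 s epochs after down-sampling to a
band-specific analysis rate (delta/theta/alpha 125 Hz, beta 250 Hz, gamma
500 Hz), so one epoch is exactly one FFT block (512/1024/2048 samples).
Per-epoch power is the mean of the mean square spectrum (MSS): the squared
magnitude of the Hamming-windowed FFT.  Power is normalized per subject and
band to the 100 s baseline window mean (taken as 100%).

Filters are designed with scipy's windowed-sinc method and their cutoffs
calibrated numerically so the measured -3 dB points land on the stated
edges (within 0.25 Hz).  Zero phase is achieved by compensated delay
(odd-length symmetric taps, centered convolution), not forward-backward
filtering, so the -3 dB contract holds for a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin, freqz

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "NOTCH_BAND",
    "FilterBank",
    "design_filterbank",
    "design_fir",
    "apply_fir",
    "downsample",
    "epoch_band_power",
    "relative_power",
]


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band: -3 dB passband edges, transition width, analysis
    rate and FFT size (= epoch sample count at that rate)."""

    name: str
    low: float
    high: float
    transition: float
    rate: float
    fft_size: int
    kind: str = "bandpass"               # or "bandstop"
    notch: bool = False                  # apply the mains notch first

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high < self.rate / 2:
            raise ValueError(f"{self.name}: passband must lie in "
                             f"(0, rate/2)")
        if self.transition <= 0:
            raise ValueError("transition width must be > 0")
        if self.transition > (self.high - self.low):
            raise ValueError(f"{self.name}: transition wider than passband "
                             "is unrealizable")


# transition widths: 1 Hz (delta, alpha), 1.5 Hz (theta, beta),
# 2.5 Hz (gamma, notch); narrower bands get narrower transitions.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0, 1.0, 125.0, 512),
    BandDefinition("theta", 4.5, 10.0, 1.5, 125.0, 512),
    BandDefinition("alpha", 10.0, 12.0, 1.0, 125.0, 512),
    BandDefinition("beta", 12.5, 28.0, 1.5, 250.0, 1024, notch=True),
    BandDefinition("gamma", 29.5, 99.5, 2.5, 500.0, 2048, notch=True),
)

NOTCH_BAND = BandDefinition("notch", 48.5, 55.0, 2.5, 500.0, 2048,
                            kind="bandstop")


# --------------------------------------------------------------------------
# FIR design with calibrated -3 dB edges
# --------------------------------------------------------------------------

def _numtaps(rate: float, transition: float) -> int:
    n = int(np.ceil(3.3 * rate / transition))
    return n + 1 if n % 2 == 0 else n

def _measured_edges(taps: np.ndarray, rate: float, lo: float, hi: float
                    ) -> tuple[float, float]:
    """Frequencies where |H| crosses 1/sqrt(2) nearest the two edges."""
    w, h = freqz(taps, worN=1 << 15, fs=rate)
    mag = np.abs(h)
    thr = 1.0 / np.sqrt(2.0)
    cross = np.flatnonzero(np.diff(np.signbit(mag - thr)))

    def crossing(target: float) -> float:
        if cross.size == 0:
            return target
        k = cross[int(np.argmin(np.abs(w[cross] - target)))]
        f0, f1 = w[k], w[k + 1]
        m0, m1 = mag[k], mag[k + 1]
        if m1 == m0:
            return float(f0)
        return float(f0 + (thr - m0) * (f1 - f0) / (m1 - m0))

    return crossing(lo), crossing(hi)


def design_fir(band: BandDefinition) -> np.ndarray:
    """Linear-phase FIR (Hamming windowed sinc) whose measured -3 dB points
    land on the band's stated edges within 0.25 Hz."""
    numtaps = _numtaps(band.rate, band.transition)
    pass_zero = band.kind == "bandstop"
    c_lo, c_hi = band.low, band.high
    for _ in range(6):
        c_lo = min(max(c_lo, 0.05), band.rate / 2 - 0.05)
        c_hi = min(max(c_hi, c_lo + 0.1), band.rate / 2 - 0.01)
        taps = firwin(numtaps, [c_lo, c_hi], pass_zero=pass_zero,
                      fs=band.rate)
        m_lo, m_hi = _measured_edges(taps, band.rate, band.low, band.high)
        err_lo, err_hi = m_lo - band.low, m_hi - band.high
        if abs(err_lo) < 0.02 and abs(err_hi) < 0.02:
            break
        c_lo -= err_lo
        c_hi -= err_hi
    return taps


def apply_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application by compensated delay (odd symmetric taps,
    centered convolution)."""
    return fftconvolve(x, taps, mode="same")


# --------------------------------------------------------------------------
# down-sampling
# --------------------------------------------------------------------------

def downsample(x: np.ndarray, orig_rate: float, target_rate: float
               ) -> np.ndarray:
    """Anti-alias filter and decimate; the factor must be an integer.
    Output length is ceil(n / factor)."""
    ratio = orig_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"non-integer down-sampling factor {ratio}")
    if factor == 1:
        return np.asarray(x, float).copy()
    numtaps = 30 * factor + 1
    aa = firwin(numtaps, 0.9 * (target_rate / 2.0), fs=orig_rate)
    return apply_fir(np.asarray(x, float), aa)[::factor]


# --------------------------------------------------------------------------
# band power
# --------------------------------------------------------------------------

def _mean_mss(x: np.ndarray, band: BandDefinition,
              spectrum: str = "full") -> float:
    w = np.hamming(len(x))
    spec = np.abs(np.fft.rfft(x * w)) ** 2 / len(x)
    if spectrum == "passband":
        freqs = np.fft.rfftfreq(len(x), d=1.0 / band.rate)
        sel = (freqs >= band.low) & (freqs <= band.high)
        spec = spec[sel]
    elif spectrum != "full":
        raise ValueError("spectrum must be 'full' or 'passband'")
    return float(np.mean(spec))


class FilterBank:
    """Designed filters for all bands plus the mains notch at every
    analysis rate that needs it."""

    def __init__(self, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                 notch: BandDefinition = NOTCH_BAND,
                 spectrum: str = "full"):
        self.bands = {b.name: b for b in bands}
        self.taps = {b.name: design_fir(b) for b in bands}
        self.spectrum = spectrum
        self.notch_taps: dict[float, np.ndarray] = {}
        for b in bands:
            if b.notch and b.rate not in self.notch_taps:
                nb = BandDefinition("notch", notch.low, notch.high,
                                    notch.transition, b.rate, b.fft_size,
                                    kind="bandstop")
                self.notch_taps[b.rate] = design_fir(nb)

    def filtered_epoch(self, samples: np.ndarray, band_name: str,
                       raw_rate: float) -> np.ndarray:
        """Down-sample to the band's analysis rate, notch if configured,
        band-filter.  Length must come out at the band's FFT size."""
        band = self.bands[band_name]
        x = downsample(samples, raw_rate, band.rate)
        if len(x) != band.fft_size:
            raise ValueError(
                f"epoch length {len(x)} does not match FFT size "
                f"{band.fft_size} for band {band_name!r}")
        if band.notch:
            x = apply_fir(x, self.notch_taps[band.rate])
        return apply_fir(x, self.taps[band_name])

    def band_power(self, samples: np.ndarray, band_name: str,
                   raw_rate: float) -> float:
        x = self.filtered_epoch(samples, band_name, raw_rate)
        return _mean_mss(x, self.bands[band_name], self.spectrum)

    def parameters(self) -> pd.DataFrame:
        """Filter-bank parameter dump for the run log."""
        rows = [{"band": b.name, "low": b.low, "high": b.high,
                 "transition": b.transition, "rate": b.rate,
                 "fft_size": b.fft_size, "numtaps": len(self.taps[b.name]),
                 "notch": b.notch} for b in self.bands.values()]
        return pd.DataFrame(rows)


def design_filterbank(bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                      **kw) -> FilterBank:
    return FilterBank(bands, **kw)


def epoch_band_power(samples: np.ndarray, band: BandDefinition,
                     raw_rate: float, bank: FilterBank | None = None,
                     spectrum: str = "full") -> float:
    """Mean MSS value for one epoch and band (arbitrary microvolts squared).

    Convenience wrapper around :class:`FilterBank`; pass a shared bank to
    avoid re-designing filters.
    """
    bank = bank or FilterBank((band,), spectrum=spectrum)
    return bank.band_power(samples, band.name, raw_rate)


# --------------------------------------------------------------------------
# baseline normalization
# --------------------------------------------------------------------------

def relative_power(records: pd.DataFrame,
                   baseline_window: str = "baseline",
                   value_col: str = "mss",
                   keys: tuple[str, ...] = ("subject", "band")
                   ) -> pd.DataFrame:
    """Append ``relative_pct`` = 100 * value / mean(baseline values), with
    the baseline mean computed per subject and band.  Groups without a
    valid baseline propagate NaN."""
    records = records.copy()
    base = (records[records["window"] == baseline_window]
            .groupby(list(keys))[value_col].mean()
            .rename("baseline_mean"))
    records = records.merge(base, how="left", left_on=list(keys),
                            right_index=True)
    records["relative_pct"] = 100.0 * records[value_col] \
        / records["baseline_mean"]
    return records.drop(columns=["baseline_mean"])
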