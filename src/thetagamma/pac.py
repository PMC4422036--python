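"""Envelope-to-signal correlation (ESC) phase-amplitude coupling.

ESC quantifies cross-frequency coupling as the linear correlation between a
slow oscillation's band-filtered signal and a fast oscillation's amplitude
envelope.  Envelopes come from complex Morlet wavelet filtering (width 7);
the slow signal from an FIR band-pass at the bin's center +/- 2 Hz.  Raw
epochs are analyzed at 500 Hz.  Center frequencies run 3-98 Hz in 5 Hz
steps (20 bins); cells with signal frequency >= envelope frequency are
undefined (the envelope of a slower rhythm against a faster signal is not
meaningful) and reported missing.

Significance is referenced to a shuffling surrogate: the envelope is cut
into contiguous segments (default 200 windows) whose order is permuted,
destroying coupling while preserving both marginal spectra; the surrogate
ESC distribution's mean/SD per cell forms the null.

The theta-gamma score pools the cells with signal frequency in the theta
band and envelope frequency in the gamma band, normalized to the baseline
window (=100%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

__all__ = [
    "CENTERS",
    "PACMatrix",
    "SurrogateNull",
    "wavelet_envelope",
    "esc",
    "pac_matrix",
    "surrogate_null",
    "esc_surrogates",
    "theta_gamma_pool",
]

# center frequencies 3-98 Hz in 5 Hz steps, each +/- 2 Hz -> 20 bins
CENTERS: np.ndarray = np.arange(3, 99, 5, dtype=float)
HALF_WIDTH = 2.0
PAC_RATE = 500.0


# --------------------------------------------------------------------------
# component filters
# --------------------------------------------------------------------------

def _morlet_kernel(fc: float, rate: float, width: float) -> np.ndarray:
    """Complex Morlet wavelet, unit passband gain for a cosine at ``fc``
    (a unit-amplitude on-center tone yields a unit envelope)."""
    sigma_t = width / (2.0 * np.pi * fc)
    half = int(np.ceil(4.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    gauss = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    kernel = gauss * np.exp(2j * np.pi * fc * t)
    return kernel * (2.0 / gauss.sum())


@lru_cache(maxsize=64)
def _low_taps(fc: float, rate: float) -> np.ndarray:
    lo = max(fc - HALF_WIDTH, 0.25)
    hi = fc + HALF_WIDTH
    numtaps = int(np.ceil(3.3 * rate / 1.5))
    numtaps += 1 - numtaps % 2
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=rate)


def lowband_signal(x: np.ndarray, fc: float, rate: float = PAC_RATE
                   ) -> np.ndarray:
    """FIR band-pass at ``fc`` +/- 2 Hz, zero phase by compensated delay."""
    return fftconvolve(np.asarray(x, float), _low_taps(float(fc), rate),
                       mode="same")


def wavelet_envelope(x: np.ndarray, center_freq: float,
                     rate: float = PAC_RATE, width: float = 7.0,
                     block_size: int | None = 200) -> np.ndarray:
    """Amplitude envelope: modulus of the complex Morlet response.

    ``block_size`` sets the overlap-add convolution block length (the
    stated processing setting); the result is block-size invariant.  Same
    length as the input; non-negative.
    """
    x = np.asarray(x, float)
    if center_freq >= rate / 2.0:
        raise ValueError("center frequency must lie below Nyquist")
    if center_freq <= 0:
        raise ValueError("center frequency must be > 0")
    kernel = _morlet_kernel(center_freq, rate, width)
    n, m = len(x), len(kernel)
    if block_size is None:
        full = fftconvolve(x, kernel, mode="full")
    else:
        block = max(int(block_size), 1)
        full = np.zeros(n + m - 1, dtype=complex)
        for start in range(0, n, block):
            seg = x[start:start + block]
            full[start:start + len(seg) + m - 1] += fftconvolve(seg, kernel,
                                                                mode="full")
    lo = (m - 1) // 2
    return np.abs(full[lo:lo + n])


def esc(low_signal: np.ndarray, high_envelope: np.ndarray) -> float:
    """Envelope-to-signal correlation: Pearson correlation between the
    band-filtered slow signal and the fast amplitude envelope.  NaN on
    zero-variance input."""
    low_signal = np.asarray(low_signal, float)
    high_envelope = np.asarray(high_envelope, float)
    if low_signal.shape != high_envelope.shape:
        raise ValueError("inputs must have equal length")
    if np.std(low_signal) == 0 or np.std(high_envelope) == 0:
        return np.nan
    return float(np.corrcoef(low_signal, high_envelope)[0, 1])


# --------------------------------------------------------------------------
# PAC matrices
# --------------------------------------------------------------------------

@dataclass
class PACMatrix:
    """ESC scores over (signal frequency) x (envelope frequency) bins."""

    low_centers: np.ndarray
    high_centers: np.ndarray
    values: np.ndarray                   # [i_low, j_high], NaN where undefined
    surrogate_mean: np.ndarray | None = None
    surrogate_sd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.low_centers, name="f_low"),
                            columns=pd.Index(self.high_centers,
                                             name="f_high"))


def _components(x: np.ndarray, rate: float, low_centers: np.ndarray,
                high_centers: np.ndarray, width: float,
                block_size: int | None
                ) -> tuple[dict[float, np.ndarray], dict[float, np.ndarray]]:
    lows = {fc: lowband_signal(x, fc, rate) for fc in low_centers}
    highs = {fc: wavelet_envelope(x, fc, rate, width, block_size)
             for fc in high_centers}
    return lows, highs


def pac_matrix(epoch: np.ndarray, rate: float = PAC_RATE,
               low_centers: np.ndarray | None = None,
               high_centers: np.ndarray | None = None,
               width: float = 7.0, block_size: int | None = 200
               ) -> PACMatrix:
    """Full comodulogram for one artifact-free epoch at 500 Hz.

    Cell (f_low, f_high) is the ESC between the signal filtered at
    f_low +/- 2 Hz and the wavelet envelope at f_high; cells with
    f_low >= f_high are missing.
    """
    low_centers = CENTERS.copy() if low_centers is None \
        else np.asarray(low_centers, float)
    high_centers = CENTERS.copy() if high_centers is None \
        else np.asarray(high_centers, float)
    lows, highs = _components(np.asarray(epoch, float), rate, low_centers,
                              high_centers, width, block_size)
    values = np.full((len(low_centers), len(high_centers)), np.nan)
    for i, fl in enumerate(low_centers):
        for j, fh in enumerate(high_centers):
            if fl >= fh:
                continue
            values[i, j] = esc(lows[fl], highs[fh])
    return PACMatrix(low_centers=low_centers, high_centers=high_centers,
                     values=values)


# --------------------------------------------------------------------------
# shuffling surrogates
# --------------------------------------------------------------------------

@dataclass
class SurrogateNull:
    """Per-cell surrogate mean/SD under envelope segment shuffling."""

    low_centers: np.ndarray
    high_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_surrogates: int
    n_windows: int


def _surrogate_escs(low: np.ndarray, env: np.ndarray,
                    perms: np.ndarray) -> np.ndarray:
    """Exact ESC values for envelope segment-order permutations.

    The envelope is cut into ``nseg`` equal contiguous segments (tail
    samples beyond ``nseg * seg_len`` are dropped); each row of ``perms``
    is a segment order.  Uses the identity that the correlation numerator
    decomposes into per-(slot, segment) dot products.
    """
    nseg = perms.shape[1]
    s = len(low) // nseg
    m = s * nseg
    x, e = low[:m], env[:m]
    sx, se = x.std(), e.std()
    if sx == 0 or se == 0:
        return np.full(perms.shape[0], np.nan)
    xs = x.reshape(nseg, s)
    es = e.reshape(nseg, s)
    dots = xs @ es.T                     # [dest slot, source segment]
    sums = dots[np.arange(nseg)[None, :], perms].sum(axis=1)
    return (sums / m - x.mean() * e.mean()) / (sx * se)


def esc_surrogates(low_signal: np.ndarray, high_envelope: np.ndarray,
                   n_windows: int = 200, n_surrogates: int = 200,
                   rng: np.random.Generator | int | None = None
                   ) -> np.ndarray:
    """Surrogate ESC distribution for one (signal, envelope) pair."""
    rng = np.random.default_rng(rng)
    n = len(low_signal)
    if n // n_windows < 1:
        warnings.warn(f"epoch too short for {n_windows} shuffling windows; "
                      f"reduced to {n}", stacklevel=2)
        n_windows = n
    perms = np.array([rng.permutation(n_windows)
                      for _ in range(n_surrogates)])
    return _surrogate_escs(np.asarray(low_signal, float),
                           np.asarray(high_envelope, float), perms)


def surrogate_null(epoch: np.ndarray, n_windows: int = 200,
                   n_surrogates: int = 200, rate: float = PAC_RATE,
                   low_centers: np.ndarray | None = None,
                   high_centers: np.ndarray | None = None,
                   width: float = 7.0, block_size: int | None = 200,
                   rng: np.random.Generator | int | None = None
                   ) -> SurrogateNull:
    """Per-cell surrogate mean/SD for a full comodulogram.

    One shared set of segment permutations is drawn per epoch and applied
    to every cell's envelope; seeded via ``rng`` for exact
    reproducibility."""
    rng = np.random.default_rng(rng)
    epoch = np.asarray(epoch, float)
    low_centers = CENTERS.copy() if low_centers is None \
        else np.asarray(low_centers, float)
    high_centers = CENTERS.copy() if high_centers is None \
        else np.asarray(high_centers, float)
    n = len(epoch)
    if n // n_windows < 1:
        warnings.warn(f"epoch too short for {n_windows} shuffling windows; "
                      f"reduced to {n}", stacklevel=2)
        n_windows = n
    perms = np.array([rng.permutation(n_windows)
                      for _ in range(n_surrogates)])
    lows, highs = _components(epoch, rate, low_centers, high_centers,
                              width, block_size)
    mean = np.full((len(low_centers), len(high_centers)), np.nan)
    sd = np.full_like(mean, np.nan)
    for i, fl in enumerate(low_centers):
        for j, fh in enumerate(high_centers):
            if fl >= fh:
                continue
            vals = _surrogate_escs(lows[fl], highs[fh], perms)
            mean[i, j] = np.mean(vals)
            sd[i, j] = np.std(vals, ddof=1)
    return SurrogateNull(low_centers=low_centers, high_centers=high_centers,
                         mean=mean, sd=sd, n_surrogates=n_surrogates,
                         n_windows=n_windows)


# --------------------------------------------------------------------------
# theta-gamma pooling
# --------------------------------------------------------------------------

def theta_gamma_pool(matrices: dict[str, PACMatrix],
                     baseline_window: str = "baseline",
                     theta_band: tuple[float, float] = (4.0, 10.0),
                     gamma_band: tuple[float, float] = (30.0, 100.0)
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool theta-signal x gamma-envelope cells per timeline window.

    ``matrices`` maps window name to a (mean) comodulogram.  The pooled
    score is the mean over cells whose signal center frequency lies in the
    theta band and whose envelope center frequency lies in the gamma band;
    pooled scores are normalized to the baseline window (=100%).  Also
    returns a per-envelope-center-frequency series for bin-resolved
    comparisons.  Missing baseline propagates NaN relative values.
    """
    if not matrices:
        raise ValueError("no matrices to pool")
    first = next(iter(matrices.values()))
    low_sel = np.array([(theta_band[0] <= c <= theta_band[1])
                        for c in first.low_centers])
    high_sel = np.array([(gamma_band[0] <= c <= gamma_band[1])
                         for c in first.high_centers])
    if not low_sel.any() or not high_sel.any():
        raise ValueError("no cells inside the requested bands")

    pooled_rows, center_rows = [], []
    for window, mat in matrices.items():
        block = mat.values[np.ix_(low_sel, high_sel)]
        pooled_rows.append({"window": window,
                            "pooled_esc": float(np.nanmean(block))})
        for j, fh in enumerate(np.asarray(first.high_centers)[high_sel]):
            center_rows.append({"window": window, "f_high": float(fh),
                                "esc": float(np.nanmean(block[:, j]))})
    pooled = pd.DataFrame(pooled_rows)
    per_center = pd.DataFrame(center_rows)

    base = pooled.loc[pooled["window"] == baseline_window, "pooled_esc"]
    base_val = float(base.iloc[0]) if len(base) else np.nan
    pooled["rel_pct"] = 100.0 * pooled["pooled_esc"] / base_val
    cbase = (per_center[per_center["window"] == baseline_window]
             .set_index("f_high")["esc"])
    per_center["rel_pct"] = per_center.apply(
        lambda r: 100.0 * r["esc"] / cbase.get(r["f_high"], np.nan), axis=1)
    return pooled, per_center
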