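"""Timeline construction, artifact masking and epoch extraction.

The analysis timeline around HFS comprises five contiguous windows: a 100 s
baseline ending at HFS onset, the HFS window (protocol span rounded up to
whole 10 s inter-stimulus slots), and three 100 s post-HFS windows.  From
every 10 s slot one artifact-free epoch of nominally 4.1 s is extracted;
the realized epoch length is an exact power of two at the analysis rates
(512/1024/2048 samples at 125/250/500 Hz = 4.096 s) so one epoch equals one
FFT block downstream.

Artifact samples are flagged by a robust amplitude criterion (z > 6 in
median/MAD units) or by proximity to any stimulus event (guard margin
0.25 s on both sides); contaminated spans are excluded, never repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import RecordingSession, StimulationProtocol

__all__ = [
    "Window",
    "AnalysisTimeline",
    "Epoch",
    "EpochSet",
    "epoch_samples",
    "build_timeline",
    "detect_artifacts",
    "extract_epochs",
]

WINDOW_NAMES = ("baseline", "hfs", "post1", "post2", "post3")


@dataclass(frozen=True)
class Window:
    name: str
    start: float
    end: float                           # half-open [start, end)

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class AnalysisTimeline:
    """Five contiguous analysis windows around HFS onset."""

    windows: tuple[Window, ...]
    hfs_onset: float
    slot_len: float = 10.0

    def __getitem__(self, name: str) -> Window:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(name)

    @property
    def start(self) -> float:
        return self.windows[0].start

    @property
    def end(self) -> float:
        return self.windows[-1].end


def build_timeline(hfs_onset: float, protocol: StimulationProtocol,
                   trace_duration: float | None = None,
                   baseline_len: float = 100.0, post_len: float = 100.0,
                   n_post: int = 3, slot_len: float = 10.0
                   ) -> AnalysisTimeline:
    """Lay out baseline/HFS/post windows around ``hfs_onset`` (seconds).

    The HFS window length is the protocol's first-to-last pulse span rounded
    up to a whole number of 10 s slots (90.7 s -> 100 s, ten slots).
    """
    if hfs_onset < baseline_len:
        raise ValueError("trace too short before HFS onset: no baseline")
    span = protocol.hfs_span
    hfs_len = max(np.ceil(span / slot_len) * slot_len, slot_len)
    windows = [Window("baseline", hfs_onset - baseline_len, hfs_onset),
               Window("hfs", hfs_onset, hfs_onset + hfs_len)]
    cursor = hfs_onset + hfs_len
    for i in range(n_post):
        windows.append(Window(f"post{i + 1}", cursor, cursor + post_len))
        cursor += post_len
    if trace_duration is not None and cursor > trace_duration:
        raise ValueError("trace too short to host all analysis windows")
    return AnalysisTimeline(windows=tuple(windows), hfs_onset=hfs_onset,
                            slot_len=slot_len)


# --------------------------------------------------------------------------
# artifact detection
# --------------------------------------------------------------------------

@dataclass
class ArtifactMask:
    flags: np.ndarray                    # boolean, one per sample
    guard: float                         # seconds

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _dilate(flags: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0 or not flags.any():
        return flags
    idx = np.flatnonzero(flags)
    out = np.zeros_like(flags)
    for i in idx:                        # runs are rare; loop over flags only
        out[max(i - margin, 0): i + margin + 1] = True
    return out


def detect_artifacts(session: RecordingSession, z_threshold: float = 6.0,
                     guard: float = 0.25) -> ArtifactMask:
    """Flag samples exceeding ``z_threshold`` robust z-units (median/MAD) or
    lying within ``guard`` seconds of any stimulus event."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    x = session.signal
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    margin = int(round(guard * session.rate))
    if mad == 0:
        amp_flags = np.zeros(len(x), bool)
    else:
        z = 0.6744897501960817 * np.abs(x - med) / mad
        amp_flags = _dilate(z > z_threshold, margin)

    flags = amp_flags
    if len(session.events):
        ev = np.asarray(session.events["time_s"], float)
        ev_flags = np.zeros(len(x), bool)
        for t0 in ev:
            i = int(round(t0 * session.rate))
            ev_flags[max(i - margin, 0): i + margin + 1] = True
        flags = flags | ev_flags

    if flags.all():
        warnings.warn("every sample is flagged as artifact", stacklevel=2)
    return ArtifactMask(flags=flags, guard=guard)


# --------------------------------------------------------------------------
# epoch extraction
# --------------------------------------------------------------------------

@dataclass
class Epoch:
    samples: np.ndarray
    rate: float
    start_s: float
    window: str
    slot: int

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class EpochSet:
    epochs: list[Epoch] = field(default_factory=list)
    invalid_windows: set[str] = field(default_factory=set)

    def by_window(self, name: str) -> list[Epoch]:
        return [e for e in self.epochs if e.window == name]

    def __len__(self) -> int:
        return len(self.epochs)


def epoch_samples(rate: float, nominal: float = 4.1) -> int:
    """Realized epoch length in samples: the nearest power of two to
    ``nominal * rate`` when that lies within 2% (4.096 s at the analysis
    rates), otherwise the plain rounding."""
    target = nominal * rate
    p = 2 ** int(round(np.log2(target)))
    if abs(p / target - 1.0) < 0.02:
        return p
    return int(round(target))


def extract_epochs(session: RecordingSession, timeline: AnalysisTimeline,
                   mask: ArtifactMask, epoch_len: float = 4.1,
                   slot_len: float | None = None) -> EpochSet:
    """Extract one artifact-free epoch per 10 s inter-stimulus slot.

    Within each slot the epoch is centered in the longest run of clean
    samples (ties toward the slot start) and dropped if no run can host it.
    Epochs never straddle window boundaries and contain no flagged sample.
    Windows yielding zero epochs are marked invalid for normalization.
    """
    slot_len = timeline.slot_len if slot_len is None else slot_len
    if slot_len < epoch_len:
        raise ValueError("slot length must be >= epoch length")
    rate = session.rate
    n_epoch = epoch_samples(rate, epoch_len)
    flags = mask.flags
    n = len(flags)
    out = EpochSet()
    for w in timeline.windows:
        found = 0
        n_slots = int(round(w.length / slot_len))
        for s in range(n_slots):
            lo = int(round((w.start + s * slot_len) * rate))
            hi = min(int(round((w.start + (s + 1) * slot_len) * rate)), n)
            if hi - lo < n_epoch:
                continue
            clean = ~flags[lo:hi]
            # maximal clean runs
            edges = np.diff(np.concatenate(([0], clean.view(np.int8), [0])))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            best = None
            for a, b in zip(starts, ends):
                if b - a >= n_epoch and (best is None
                                         or b - a > best[1] - best[0]):
                    best = (a, b)
            if best is None:
                continue
            a, b = best
            off = a + (b - a - n_epoch) // 2          # centered, tie to start
            i0 = lo + off
            out.epochs.append(Epoch(samples=session.signal[i0:i0 + n_epoch]
                                    .copy(), rate=rate, start_s=i0 / rate,
                                    window=w.name, slot=s))
            found += 1
        if found == 0:
            out.invalid_windows.add(w.name)
            warnings.warn(f"window {w.name!r} yielded no artifact-free "
                          "epochs; marked invalid for normalization",
                          stacklevel=2)
    return out
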