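"""Seeded synthetic LFP / evoked-potential generator.

Emulates intrahippocampal dentate-gyrus recordings around an LTP-inducing
high-frequency stimulation (HFS) session: five phenomenological band
oscillators (delta 2-4, theta 4-10, alpha 10-12, beta 12-28, gamma 30-100 Hz),
theta-phase-modulated gamma amplitude, stimulus artifacts (test pulses and
HFS pulse trains), and stereotyped evoked field potentials (fEPSP + population
spike) with condition-specific potentiation profiles.

Two conditions are built in:

``control``
    theta (and gamma) power suppressed to ~50% of baseline early in HFS and
    recovering in its second half; gamma power peaking in the first 100 s
    after HFS; theta-gamma coupling rising during HFS; robust LTP (>24 h).

``abeta``
    elevated power in all five bands during HFS, no early theta suppression,
    reduced theta-gamma coupling during HFS, impaired potentiation.

Band gain curves are expressed in percent of baseline band *power* (the
amplitude multiplier is the square root), so the injected curves can be read
directly against baseline-normalized spectral output.  All generation is
deterministic under a fixed seed.  Amplitudes are arbitrary microvolts for
the LFP and millivolts for evoked sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .evoked import EvokedResponse, default_schedule

__all__ = [
    "StepCurve",
    "StimulationProtocol",
    "BandProfile",
    "SyntheticConfig",
    "EvokedShapeConfig",
    "RecordingSession",
    "SubjectData",
    "generate_lfp",
    "inject_stimulus_artifacts",
    "generate_evoked_series",
    "generate_cohort",
    "default_config",
    "default_evoked_config",
]


# --------------------------------------------------------------------------
# step curves (zero-order-hold gain profiles over the analysis timeline)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StepCurve:
    """Piecewise-constant curve: value ``values[i]`` holds on
    ``[times[i], times[i+1])``; ``values[0]`` also holds before ``times[0]``
    and ``values[-1]`` after ``times[-1]``."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty StepCurve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("StepCurve times must be strictly increasing")

    @classmethod
    def constant(cls, value: float) -> "StepCurve":
        return cls((0.0,), (float(value),))

    def at(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.times), np.asarray(t, float),
                              side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        return np.asarray(self.values, float)[idx]


# --------------------------------------------------------------------------
# stimulation protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulationProtocol:
    """HFS tetanus and test-pulse schedule.

    Defaults encode the standard dentate-gyrus LTP protocol: 10 trains of
    15 pulses at 200 Hz, 10 s between trains, 0.2 ms biphasic pulses, and
    0.025 Hz test pulses.  The elapsed time from the first to the last HFS
    pulse is ``trains*(pulses-1)/rate + (trains-1)*gap`` = 90.7 s with the
    defaults.
    """

    trains: int = 10
    pulses_per_train: int = 15
    intra_train_rate: float = 200.0
    inter_train_gap: float = 10.0
    pulse_width: float = 2e-4
    test_pulse_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.trains < 0:
            raise ValueError("trains must be >= 0")
        if self.trains and self.pulses_per_train < 1:
            raise ValueError("pulses_per_train must be >= 1")
        if self.intra_train_rate <= 0 or self.test_pulse_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.inter_train_gap < 0:
            raise ValueError("inter_train_gap must be >= 0")

    @property
    def train_duration(self) -> float:
        """First-to-last pulse time within one train (seconds)."""
        return (self.pulses_per_train - 1) / self.intra_train_rate

    @property
    def hfs_span(self) -> float:
        """First-to-last HFS pulse time across all trains (seconds)."""
        if self.trains == 0:
            return 0.0
        return (self.trains * self.train_duration
                + (self.trains - 1) * self.inter_train_gap)

    def hfs_pulse_times(self, onset: float) -> np.ndarray:
        """Absolute times of every HFS pulse for a tetanus starting at
        ``onset`` seconds."""
        if self.trains == 0:
            return np.empty(0)
        starts = onset + np.arange(self.trains) * (self.train_duration
                                                   + self.inter_train_gap)
        within = np.arange(self.pulses_per_train) / self.intra_train_rate
        return (starts[:, None] + within[None, :]).ravel()

    def test_pulse_times(self, duration: float,
                         exclude: tuple[float, float] | None = None
                         ) -> np.ndarray:
        """Test-pulse times on [0, duration), optionally excluding the HFS
        interval."""
        n = int(np.floor(duration * self.test_pulse_rate))
        times = np.arange(n) / self.test_pulse_rate
        times = times[times < duration]
        if exclude is not None:
            lo, hi = exclude
            times = times[(times < lo) | (times > hi)]
        return times


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandProfile:
    """One band oscillator: a cosine at ``center_hz`` with slow Ornstein-
    Uhlenbeck frequency jitter (SD ``freq_jitter_hz``), base amplitude in
    arbitrary microvolts, and a time-varying gain curve in percent of
    baseline band power (amplitude scales with the square root)."""

    name: str
    center_hz: float
    base_amplitude: float
    gain: StepCurve = field(default_factory=lambda: StepCurve.constant(100.0))
    freq_jitter_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.center_hz <= 0:
            raise ValueError("center_hz must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if np.any(np.asarray(self.gain.values) <= 0):
            raise ValueError("gain curve values must be > 0 (percent)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one synthetic recording session."""

    rate: float = 1000.0
    bands: tuple[BandProfile, ...] = ()
    m: float = 0.4                       # theta-gamma modulation index, [0, 1]
    m_curve: StepCurve = field(default_factory=lambda: StepCurve.constant(1.0))
    noise_sd: float = 10.0
    artifact_amplitude: float = 400.0
    artifact_width: float = 5e-3
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("modulation index m must lie in [0, 1]")
        carrier = self.gamma_carrier
        if carrier is not None and self.rate < 2.0 * carrier:
            raise ValueError(
                f"sampling rate {self.rate} Hz is below the Nyquist rate for "
                f"the gamma carrier at {carrier} Hz")

    @property
    def gamma_carrier(self) -> float | None:
        for b in self.bands:
            if b.name == "gamma":
                return b.center_hz
        return None

    def band(self, name: str) -> BandProfile:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass(frozen=True)
class EvokedShapeConfig:
    """Shape of one stereotyped evoked field potential and its potentiation
    profile over the recording schedule.

    The sweep is a positive alpha-function fEPSP (maximal 5-point rising
    slope ``fepsp_slope`` mV/ms) with a superimposed narrow negative Gaussian
    population spike of depth ``ps_depth`` mV.  ``potentiation`` holds one
    multiplicative factor per scheduled time point.
    """

    fepsp_slope: float = 5.0             # peak instantaneous slope, mV/ms
    ps_depth: float = 3.0                # mV
    fepsp_latency_ms: float = 2.0
    fepsp_tau_ms: float = 3.0
    ps_latency_ms: float = 5.5
    ps_sigma_ms: float = 0.2
    potentiation: tuple[float, ...] = ()
    noise_sd: float = 0.05               # mV
    sweep_duration_ms: float = 40.0
    sample_interval_ms: float = 0.1
    sweeps_per_point: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fepsp_latency_ms < self.ps_latency_ms:
            raise ValueError("latencies must be ordered: fEPSP before PS")
        if any(f <= 0 for f in self.potentiation):
            raise ValueError("potentiation factors must be > 0")


# --------------------------------------------------------------------------
# session containers
# --------------------------------------------------------------------------

EVENT_KINDS = ("test_pulse", "hfs_pulse", "injection")


@dataclass
class RecordingSession:
    """Continuous single-channel LFP trace with its stimulus-event schedule."""

    signal: np.ndarray                   # microvolts
    rate: float                          # Hz
    events: pd.DataFrame                 # columns: time_s, kind
    condition: str = "control"
    subject: str = "s0"
    components: dict[str, np.ndarray] | None = None

    @property
    def duration(self) -> float:
        return len(self.signal) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.signal)) / self.rate


@dataclass
class SubjectData:
    """One synthetic animal: LFP session plus evoked-potential series."""

    subject: str
    condition: str
    session: RecordingSession
    sweeps: list[EvokedResponse]
    schedule_min: np.ndarray
    phases: list[str]
    hfs_onset: float
    protocol: StimulationProtocol


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({"time_s": pd.Series(dtype=float),
                         "kind": pd.Series(dtype=object)})


# --------------------------------------------------------------------------
# condition profiles (gain curves in percent of baseline band power)
# --------------------------------------------------------------------------

def _slot_curve(hfs_onset: float, baseline: float, hfs_slots: list[float],
                post: list[float]) -> StepCurve:
    """Build a step curve with one knot per 10 s HFS slot and one per 100 s
    post window."""
    times = [0.0]
    values = [baseline]
    for i, v in enumerate(hfs_slots):
        times.append(hfs_onset + 10.0 * i)
        values.append(v)
    for i, v in enumerate(post):
        times.append(hfs_onset + 100.0 + 100.0 * i)
        values.append(v)
    return StepCurve(tuple(times), tuple(values))


def control_band_profiles(hfs_onset: float = 100.0) -> tuple[BandProfile, ...]:
    """Healthy-animal profile: broadband suppression during HFS; theta (and
    gamma) at ~50% of baseline power in the first half of HFS, recovering in
    the second half; gamma power peaking in the first post-HFS window."""
    return (
        BandProfile("delta", 3.0, 15.0, _slot_curve(
            hfs_onset, 100, [70] * 10, [100, 100, 100]), 0.3),
        BandProfile("theta", 8.0, 30.0, _slot_curve(
            hfs_onset, 100, [50] * 5 + [60, 70, 80, 90, 100], [100, 95, 95]),
            0.6),
        BandProfile("alpha", 11.0, 10.0, _slot_curve(
            hfs_onset, 100, [70] * 10, [100, 100, 100]), 0.3),
        BandProfile("beta", 20.0, 10.0, _slot_curve(
            hfs_onset, 100, [65] * 10, [90, 95, 100]), 1.5),
        BandProfile("gamma", 60.0, 20.0, _slot_curve(
            hfs_onset, 100, [60] * 5 + [70, 80, 90, 100, 110],
            [150, 120, 100]), 3.0),
    )


def abeta_band_profiles(hfs_onset: float = 100.0) -> tuple[BandProfile, ...]:
    """Amyloid-beta profile: elevated power in all five bands during HFS, no
    early theta suppression, unstable delta, power drifting upward after
    HFS."""
    return (
        BandProfile("delta", 3.0, 15.0, _slot_curve(
            hfs_onset, 100, [170, 130, 160, 140, 170, 130, 160, 140, 170, 130],
            [120, 130, 140]), 0.3),
        BandProfile("theta", 8.0, 30.0, _slot_curve(
            hfs_onset, 100, [140] * 10, [120, 130, 140]), 0.6),
        BandProfile("alpha", 11.0, 10.0, _slot_curve(
            hfs_onset, 100, [160] * 10, [130, 140, 150]), 0.3),
        BandProfile("beta", 20.0, 10.0, _slot_curve(
            hfs_onset, 100, [150] * 10, [130, 130, 130]), 1.5),
        BandProfile("gamma", 60.0, 20.0, _slot_curve(
            hfs_onset, 100, [120, 130, 140, 150, 160, 160, 170, 170, 180, 180],
            [180, 140, 120]), 3.0),
    )


def control_m_curve(hfs_onset: float = 100.0) -> StepCurve:
    """Coupling multiplier: rises during HFS in controls."""
    return _slot_curve(hfs_onset, 1.0, [1.5] * 10, [1.2, 1.1, 1.0])


def abeta_m_curve(hfs_onset: float = 100.0) -> StepCurve:
    """Coupling multiplier: collapses during HFS after amyloid-beta."""
    return _slot_curve(hfs_onset, 1.0, [0.4] * 10, [0.7, 0.8, 0.9])


def default_config(condition: str = "control", hfs_onset: float = 100.0,
                   seed: int = 0, **overrides) -> SyntheticConfig:
    """Study-condition configuration for one session."""
    if condition == "control":
        bands = control_band_profiles(hfs_onset)
        m_curve = control_m_curve(hfs_onset)
    elif condition == "abeta":
        bands = abeta_band_profiles(hfs_onset)
        m_curve = abeta_m_curve(hfs_onset)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = SyntheticConfig(bands=bands, m_curve=m_curve, condition=condition,
                          seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def default_evoked_config(condition: str = "control", seed: int = 0
                          ) -> tuple[EvokedShapeConfig, np.ndarray, list[str]]:
    """Evoked-shape configuration plus the recording schedule for one
    condition.  Control: robust potentiation sustained past 24 h.  Abeta:
    slightly depressed transmission after injection and only transient
    potentiation."""
    times, phases = default_schedule()
    factors = np.ones(len(times))
    for i, (t, ph) in enumerate(zip(times, phases)):
        if condition == "control":
            if ph == "post_injection":
                factors[i] = 1.0
            elif ph == "post_hfs":
                # decays from 1.9 toward a sustained 1.6 over 4 h
                factors[i] = 1.6 + 0.3 * np.exp(-(t - 65.0) / 90.0)
            elif ph == "24h":
                factors[i] = 1.55
        elif condition == "abeta":
            if ph == "post_injection":
                factors[i] = 0.85
            elif ph == "post_hfs":
                # short-term potentiation only: decays back to ~0.9
                factors[i] = 0.9 + 0.5 * np.exp(-(t - 65.0) / 30.0)
            elif ph == "24h":
                factors[i] = 0.9
        else:
            raise ValueError(f"unknown condition {condition!r}")
    shape = EvokedShapeConfig(potentiation=tuple(factors), seed=seed)
    return shape, times, phases


# --------------------------------------------------------------------------
# LFP generation
# --------------------------------------------------------------------------

def _ou_jitter(n: int, sd: float, rate: float, rng: np.random.Generator,
               tau: float = 1.0) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sequence (frequency wander, Hz)."""
    if sd == 0.0:
        return np.zeros(n)
    a = np.exp(-1.0 / (tau * rate))
    w = rng.standard_normal(n) * (sd * np.sqrt(1.0 - a * a))
    x = lfilter([1.0], [1.0, -a], w)
    return x


def generate_lfp(config: SyntheticConfig, duration: float) -> RecordingSession:
    """Generate one continuous LFP trace.

    The trace is the sum of the five band oscillators plus white noise.  The
    gamma oscillator's instantaneous amplitude is
    ``A_gamma(t) * (1 + m(t) * cos(theta_phase))`` where ``theta_phase`` is
    the exact phase of the generated theta oscillator (an analytic ground
    truth for coupling estimators).  Deterministic under a fixed seed.

    The returned session's ``components`` dict carries each band component,
    the theta phase and the exact gamma envelope for oracle checks.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rate = config.rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(config.seed)

    components: dict[str, np.ndarray] = {}
    signal = np.zeros(n)
    theta_phase: np.ndarray | None = None

    # theta first so its phase is available to the gamma oscillator
    ordered = sorted(config.bands, key=lambda b: b.name != "theta")
    for prof in ordered:
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        f_inst = prof.center_hz + _ou_jitter(n, prof.freq_jitter_hz, rate, rng)
        phase = phase0 + 2.0 * np.pi * np.cumsum(f_inst) / rate
        amp = prof.base_amplitude * np.sqrt(prof.gain.at(t) / 100.0)
        if prof.name == "theta":
            theta_phase = phase
            components["theta_phase"] = phase
        if prof.name == "gamma":
            m_t = np.clip(config.m * config.m_curve.at(t), 0.0, 1.0)
            envelope = amp * (1.0 + m_t * np.cos(theta_phase)) \
                if theta_phase is not None else amp * np.ones(n)
            comp = envelope * np.cos(phase)
            components["gamma_envelope"] = envelope
        else:
            comp = amp * np.cos(phase)
        components[prof.name] = comp
        signal = signal + comp

    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, n)

    return RecordingSession(signal=signal, rate=rate, events=_empty_events(),
                            condition=config.condition,
                            components=components)


# --------------------------------------------------------------------------
# stimulus artifacts
# --------------------------------------------------------------------------

def _biphasic(width_samples: int, amplitude: float) -> np.ndarray:
    """One-cycle biphasic spike (positive then negative lobe)."""
    k = max(width_samples, 2)
    return amplitude * np.sin(2.0 * np.pi * np.arange(k) / k)


def inject_stimulus_artifacts(session: RecordingSession,
                              protocol: StimulationProtocol,
                              hfs_onset: float,
                              amplitude: float | None = None,
                              width: float = 5e-3) -> RecordingSession:
    """Add test-pulse and HFS stimulus artifacts to a session.

    Every event time enters the event list; the trace carries an additive
    biphasic spike (default width 5 ms, default amplitude 20x the signal SD)
    at each event.  Events that would fall beyond the trace end are
    truncated with a warning.  Test pulses are suspended during the HFS
    interval.
    """
    if not 0.0 <= hfs_onset < session.duration:
        raise ValueError("hfs_onset must lie within the trace")
    duration = session.duration
    hfs_times = protocol.hfs_pulse_times(hfs_onset)
    test_times = protocol.test_pulse_times(
        duration, exclude=(hfs_onset, hfs_onset + protocol.hfs_span))

    all_times = np.concatenate([test_times, hfs_times])
    kinds = np.array(["test_pulse"] * len(test_times)
                     + ["hfs_pulse"] * len(hfs_times), dtype=object)
    keep = all_times < duration
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} stimulus events beyond the "
                      "trace end were truncated", stacklevel=2)
        all_times, kinds = all_times[keep], kinds[keep]
    order = np.argsort(all_times, kind="stable")
    all_times, kinds = all_times[order], kinds[order]

    signal = session.signal.copy()
    return _add_artifacts(session, signal, all_times, kinds,
                          amplitude=amplitude, width=width)


def _add_artifacts(session: RecordingSession, signal: np.ndarray,
                   times: np.ndarray, kinds: np.ndarray,
                   amplitude: float | None = None,
                   width: float = 5e-3) -> RecordingSession:
    if amplitude is None:
        sd = float(np.std(session.signal))
        amplitude = 20.0 * sd if sd > 0 else 1.0
    spike = _biphasic(int(round(width * session.rate)), amplitude)
    n = len(signal)
    for t0 in times:
        i = int(round(t0 * session.rate))
        j = min(i + len(spike), n)
        if i < n:
            signal[i:j] += spike[: j - i]
    events = pd.DataFrame({"time_s": times, "kind": kinds})
    if len(session.events):
        events = pd.concat([session.events, events], ignore_index=True)
        events = events.sort_values("time_s", ignore_index=True)
    return RecordingSession(signal=signal, rate=session.rate, events=events,
                            condition=session.condition,
                            subject=session.subject,
                            components=session.components)


# --------------------------------------------------------------------------
# evoked sweeps
# --------------------------------------------------------------------------

def _sweep_template(shape: EvokedShapeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free unit-factor sweep (time in ms, value in mV)."""
    t = np.arange(0.0, shape.sweep_duration_ms, shape.sample_interval_ms)
    y = np.zeros_like(t)
    s = t - shape.fepsp_latency_ms
    rising = s > 0
    tau = shape.fepsp_tau_ms
    peak = shape.fepsp_slope * tau / np.e      # amplitude giving the set slope
    y[rising] = peak * (s[rising] / tau) * np.exp(1.0 - s[rising] / tau)
    y -= shape.ps_depth * np.exp(-((t - shape.ps_latency_ms) ** 2)
                                 / (2.0 * shape.ps_sigma_ms ** 2))
    return t, y


def generate_evoked_series(shape: EvokedShapeConfig,
                           schedule: np.ndarray | list[float]
                           ) -> list[EvokedResponse]:
    """Generate the evoked-potential sweeps for a recording schedule.

    ``schedule`` is a strictly increasing list of time points (minutes);
    ``shape.sweeps_per_point`` sweeps are produced per point, each the
    stereotyped field potential scaled by the potentiation factor at that
    point, plus independent Gaussian noise.
    """
    schedule = np.asarray(schedule, float)
    if schedule.size == 0:
        return []
    if np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be strictly increasing")
    if len(shape.potentiation) != len(schedule):
        raise ValueError("need one potentiation factor per scheduled point")
    rng = np.random.default_rng(shape.seed)
    t, template = _sweep_template(shape)
    sweeps: list[EvokedResponse] = []
    for tp, factor in zip(schedule, shape.potentiation):
        for _ in range(shape.sweeps_per_point):
            y = factor * template
            if shape.noise_sd > 0:
                y = y + rng.normal(0.0, shape.noise_sd, len(y))
            sweeps.append(EvokedResponse(time_ms=t.copy(), values_mv=y,
                                         time_point_min=float(tp)))
    return sweeps


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def generate_cohort(n_control: int, n_abeta: int, master_seed: int,
                    duration: float = 610.0, hfs_onset: float = 100.0,
                    protocol: StimulationProtocol | None = None,
                    keep_components: bool = False) -> list[SubjectData]:
    """Generate a full two-condition cohort.

    Per-subject seeds are derived deterministically from ``master_seed``;
    subjects differ in their noise realizations and in a +/-10% uniform
    jitter on band amplitudes.  Defaults give 6 + 5 subjects at the study's
    timeline (100 s baseline, ~100 s HFS, 300 s post).
    """
    if n_control < 0 or n_abeta < 0:
        raise ValueError("cohort counts must be >= 0")
    protocol = protocol or StimulationProtocol()
    if duration < hfs_onset + 400.0 + protocol.hfs_span - 90.7:
        # needs the full 500 s analysis timeline after the baseline start
        raise ValueError("duration too short for the analysis timeline")

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_control + n_abeta)
    conditions = ["control"] * n_control + ["abeta"] * n_abeta
    subjects: list[SubjectData] = []
    for i, (child, cond) in enumerate(zip(children, conditions)):
        state = child.generate_state(2)
        seed_lfp = int(state[0]) & 0x7FFFFFFF
        seed_ev = int(state[1]) & 0x7FFFFFFF
        rng = np.random.default_rng(child)
        cfg = default_config(cond, hfs_onset=hfs_onset, seed=seed_lfp)
        jittered = tuple(
            replace(b, base_amplitude=b.base_amplitude
                    * rng.uniform(0.9, 1.1)) for b in cfg.bands)
        cfg = replace(cfg, bands=jittered)
        session = generate_lfp(cfg, duration)
        session = inject_stimulus_artifacts(session, protocol, hfs_onset)
        session.subject = f"{cond}_{i:02d}"
        session.condition = cond
        if not keep_components:
            session.components = None
        shape, times, phases = default_evoked_config(cond, seed=seed_ev)
        sweeps = generate_evoked_series(shape, times)
        subjects.append(SubjectData(
            subject=session.subject, condition=cond, session=session,
            sweeps=sweeps, schedule_min=times, phases=phases,
            hfs_onset=hfs_onset, protocol=protocol))
    return subjects
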