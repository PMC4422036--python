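"""End-to-end orchestration: generate/load -> segment -> spectral -> cycles
-> PAC -> evoked -> stats, emitting figure-style result tables.

A run is fully reproducible from its :class:`RunConfig` plus seed: all
randomness flows from one master seed, with per-stage seeds derived by
stable hashing of stage names.  Missing values propagate as NaN and are
never silently dropped from group means (counts are reported alongside).
"""

from __future__ import annotations

import tomllib
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import evoked as evk
from . import pac as pacmod
from . import stats as stm
from .segmentation import build_timeline, detect_artifacts, extract_epochs
from .spectral import FilterBank, downsample, relative_power
from .synthetic import (RecordingSession, StimulationProtocol, SubjectData,
                        generate_cohort)

__all__ = ["RunConfig", "ResultBundle", "run_analysis",
            "write_sessions", "load_sessions"]

WINDOW_ORDER = ("baseline", "hfs", "post1", "post2", "post3")


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the master seed and the
    stage name."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF,
                                   zlib.crc32(stage.encode())])


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full analysis run."""

    n_control: int = 6
    n_abeta: int = 5
    seed: int = 42
    duration: float = 610.0
    hfs_onset: float = 100.0
    trains: int = 10
    pulses_per_train: int = 15
    intra_train_rate: float = 200.0
    inter_train_gap: float = 10.0
    pac_cells: str = "full"              # or "theta_gamma"
    pac_surrogates: int = 0
    alpha: float = 0.05
    ps_method: str = "tangent"
    spectrum: str = "full"               # MSS mean: full spectrum / passband

    @property
    def protocol(self) -> StimulationProtocol:
        return StimulationProtocol(trains=self.trains,
                                   pulses_per_train=self.pulses_per_train,
                                   intra_train_rate=self.intra_train_rate,
                                   inter_train_gap=self.inter_train_gap)

    def to_toml(self) -> str:
        lines = ["[run]"]
        for k, v in asdict(self).items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            else:
                lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data.get("run", data))


# --------------------------------------------------------------------------
# result bundle
# --------------------------------------------------------------------------

@dataclass
class ResultBundle:
    """All result tables of one run; every table carries subject, condition
    and window provenance columns where applicable."""

    config: RunConfig
    band_power: pd.DataFrame             # per epoch x band
    band_power_summary: pd.DataFrame     # mean relative power per window
    hfs_series: pd.DataFrame             # slot-resolved relative power in HFS
    theta_map: pd.DataFrame              # freq bin x window x condition
    gamma_map: pd.DataFrame              # nested gamma map, same layout
    pac_pooled: pd.DataFrame             # theta-gamma score per subject/window
    pac_per_center: pd.DataFrame         # per envelope center frequency
    pac_matrices: pd.DataFrame           # mean comodulogram cells (long)
    plasticity: pd.DataFrame             # per-subject percent-of-baseline
    plasticity_summary: pd.DataFrame     # group mean +/- SEM per time point
    stats: pd.DataFrame                  # test battery results
    filter_parameters: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "band_power.tsv": self.band_power,
            "band_power_summary.tsv": self.band_power_summary,
            "hfs_series.tsv": self.hfs_series,
            "theta_amplitude_map.tsv": self.theta_map,
            "nested_gamma_map.tsv": self.gamma_map,
            "pac_pooled.tsv": self.pac_pooled,
            "pac_per_center.tsv": self.pac_per_center,
            "pac_matrices.tsv": self.pac_matrices,
            "plasticity.tsv": self.plasticity,
            "plasticity_summary.tsv": self.plasticity_summary,
            "stats.tsv": self.stats,
        }
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False)
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"seed: {self.config.seed}\n")
            fh.write(f"numpy: {np.__version__}\n")
            fh.write("config:\n")
            fh.write(self.config.to_toml())
            fh.write("filter bank:\n")
            fh.write(self.filter_parameters.to_string(index=False))
            fh.write("\n")


# --------------------------------------------------------------------------
# per-subject stages
# --------------------------------------------------------------------------

def _pac_centers(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.pac_cells == "theta_gamma":
        low = np.array([c for c in pacmod.CENTERS if 4.0 <= c <= 10.0])
        high = np.array([c for c in pacmod.CENTERS if 30.0 <= c <= 100.0])
        return low, high
    if config.pac_cells == "full":
        return pacmod.CENTERS.copy(), pacmod.CENTERS.copy()
    raise ValueError(f"unknown pac_cells {config.pac_cells!r}")


def _analyze_subject(subj: SubjectData, config: RunConfig, bank: FilterBank
                     ) -> dict[str, pd.DataFrame]:
    session = subj.session
    raw_rate = session.rate
    timeline = build_timeline(subj.hfs_onset, subj.protocol,
                              trace_duration=session.duration)
    mask = detect_artifacts(session)
    epochs = extract_epochs(session, timeline, mask)

    power_rows, cycle_rows, pac_rows = [], [], []
    low_c, high_c = _pac_centers(config)
    epoch_mats: dict[str, list[np.ndarray]] = {}
    for ep in epochs.epochs:
        for band in bank.bands.values():
            power_rows.append({
                "subject": subj.subject, "condition": subj.condition,
                "window": ep.window, "slot": ep.slot, "band": band.name,
                "mss": bank.band_power(ep.samples, band.name, raw_rate)})
        theta = bank.filtered_epoch(ep.samples, "theta", raw_rate)
        gamma = bank.filtered_epoch(ep.samples, "gamma", raw_rate)
        phase, _ = cyc.analytic_phase(theta)
        tcycles = cyc.excise_cycles(theta, phase, bank.bands["theta"].rate)
        tcycles = cyc.nested_gamma_amplitude(tcycles, gamma,
                                             bank.bands["gamma"].rate)
        for c in tcycles:
            cycle_rows.append({
                "subject": subj.subject, "condition": subj.condition,
                "window": ep.window, "slot": ep.slot,
                "frequency": c.frequency, "amplitude": c.amplitude,
                "nested_gamma": c.nested_gamma})
        x500 = downsample(ep.samples, raw_rate, pacmod.PAC_RATE)
        mat = pacmod.pac_matrix(x500, low_centers=low_c, high_centers=high_c)
        epoch_mats.setdefault(ep.window, []).append(mat.values)
        pooled_sel = mat.values[np.ix_(
            (low_c >= 4.0) & (low_c <= 10.0),
            (high_c >= 30.0) & (high_c <= 100.0))]
        pac_rows.append({
            "subject": subj.subject, "condition": subj.condition,
            "window": ep.window, "slot": ep.slot,
            "pooled_esc": float(np.nanmean(pooled_sel))})

    window_mats = {w: pacmod.PACMatrix(low_c, high_c,
                                       np.nanmean(np.stack(v), axis=0))
                   for w, v in epoch_mats.items()}
    ordered = {w: window_mats[w] for w in WINDOW_ORDER if w in window_mats}
    pooled_df, per_center_df = pacmod.theta_gamma_pool(ordered)
    for df in (pooled_df, per_center_df):
        df.insert(0, "subject", subj.subject)
        df.insert(1, "condition", subj.condition)

    mat_rows = []
    for w, mat in ordered.items():
        frame = mat.to_frame().stack(future_stack=True).rename("esc") \
            .reset_index()
        frame.insert(0, "subject", subj.subject)
        frame.insert(1, "condition", subj.condition)
        frame.insert(2, "window", w)
        mat_rows.append(frame)

    # evoked potentials
    measures = evk.measure_time_points(subj.sweeps, ps_method=config.ps_method)
    plast_rows = []
    for metric in ("fepsp_slope", "ps_amplitude"):
        series = evk.percent_of_baseline(
            measures["time_point_min"], measures[metric],
            phases=subj.phases, metric=metric)
        plast_rows.append(pd.DataFrame({
            "subject": subj.subject, "condition": subj.condition,
            "metric": metric, "time_min": series.time_min,
            "phase": series.phases, "pct": series.pct}))

    return {"power": pd.DataFrame(power_rows),
            "cycles": pd.DataFrame(cycle_rows),
            "pac_epoch": pd.DataFrame(pac_rows),
            "pac_pooled": pooled_df,
            "pac_per_center": per_center_df,
            "pac_matrices": pd.concat(mat_rows, ignore_index=True),
            "plasticity": pd.concat(plast_rows, ignore_index=True)}


# --------------------------------------------------------------------------
# statistics battery over the cohort tables
# --------------------------------------------------------------------------

def _subject_window_means(df: pd.DataFrame, value: str) -> pd.DataFrame:
    return (df.groupby(["subject", "condition", "window", "band"],
                       as_index=False)[value].mean()
            if "band" in df.columns else
            df.groupby(["subject", "condition", "window"],
                       as_index=False)[value].mean())


def _battery(power: pd.DataFrame, pac_pooled: pd.DataFrame,
             pac_epoch: pd.DataFrame, plasticity: pd.DataFrame,
             alpha: float) -> pd.DataFrame:
    rows = []
    bands = sorted(power["band"].unique())
    sw = _subject_window_means(power, "relative_pct")

    def add(comp_id, res):
        rows.append({"comparison_id": comp_id, "test": res.test,
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "alpha_corrected": res.alpha_corrected,
                     "significant": res.significant,
                     "effect_r": res.effect_r})

    for window in ("baseline", "hfs"):
        for band in bands:
            sel = sw[(sw["window"] == window) & (sw["band"] == band)]
            a = sel.loc[sel["condition"] == "control", "relative_pct"].values
            b = sel.loc[sel["condition"] == "abeta", "relative_pct"].values
            if len(a) == 0 or len(b) == 0:
                continue
            add(f"{band}_{window}_control_vs_abeta",
                stm.rank_between(a, b, alpha, m_comparisons=len(bands)))

    # early-HFS theta suppression within controls (first 5 slots vs baseline)
    ctrl = power[(power["condition"] == "control")
                 & (power["band"] == "theta")]
    early = ctrl[(ctrl["window"] == "hfs")
                 & (ctrl["slot"] <= 4)]["relative_pct"].values
    base = ctrl[ctrl["window"] == "baseline"]["relative_pct"].values
    if len(early) and len(base):
        add("theta_early_hfs_vs_baseline_control",
            stm.rank_between(early, base, alpha))

    sel = pac_pooled[pac_pooled["window"] == "hfs"]
    a = sel.loc[sel["condition"] == "control", "rel_pct"].values
    b = sel.loc[sel["condition"] == "abeta", "rel_pct"].values
    if len(a) and len(b):
        add("theta_gamma_esc_hfs_control_vs_abeta",
            stm.rank_between(a, b, alpha))

    for metric in ("fepsp_slope", "ps_amplitude"):
        pm = plasticity[plasticity["metric"] == metric]
        for phase, label in (("post_hfs", "4h"), ("24h", "24h")):
            sub = pm[pm["phase"] == phase]
            if phase == "post_hfs":      # last hour of the 4 h follow-up
                sub = sub[sub["time_min"] >= 240]
            means = sub.groupby(["subject", "condition"],
                                as_index=False)["pct"].mean()
            a = means.loc[means["condition"] == "control", "pct"].values
            b = means.loc[means["condition"] == "abeta", "pct"].values
            if len(a) and len(b):
                add(f"{metric}_{label}_control_vs_abeta",
                    stm.rank_between(a, b, alpha))

    # relationship between relative theta/gamma power and coupling over the
    # 10 HFS epochs, per condition
    for cond in ("control", "abeta"):
        series = []
        for band in ("theta", "gamma"):
            s = (power[(power["condition"] == cond)
                       & (power["window"] == "hfs")
                       & (power["band"] == band)]
                 .groupby("slot")["relative_pct"].mean())
            series.append(s)
        esc_s = (pac_epoch[(pac_epoch["condition"] == cond)
                           & (pac_epoch["window"] == "hfs")]
                 .groupby("slot")["pooled_esc"].mean())
        slots = sorted(set(series[0].index) & set(series[1].index)
                       & set(esc_s.index))
        if len(slots) >= 3:
            aligned = [s.loc[slots].values for s in series] \
                + [esc_s.loc[slots].values]
            add(f"friedman_theta_gamma_esc_hfs_{cond}",
                stm.friedman_relationship(aligned))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# top-level run
# --------------------------------------------------------------------------

def run_analysis(config: RunConfig,
                 subjects: list[SubjectData] | None = None) -> ResultBundle:
    """Execute the full pipeline.

    When ``subjects`` is None a synthetic cohort is generated from the
    config (counts, protocol, master seed).  Idempotent for a fixed config:
    repeated runs yield identical tables.
    """
    if subjects is None:
        subjects = generate_cohort(
            config.n_control, config.n_abeta,
            int(stage_seed(config.seed, "cohort").generate_state(1)[0])
            & 0x7FFFFFFF,
            duration=config.duration, hfs_onset=config.hfs_onset,
            protocol=config.protocol)
    if not subjects:
        raise ValueError("no subjects to analyze")

    bank = FilterBank(spectrum=config.spectrum)
    per_subject = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subj in subjects:
            per_subject.append(_analyze_subject(subj, config, bank))

    def cat(key: str) -> pd.DataFrame:
        return pd.concat([p[key] for p in per_subject], ignore_index=True)

    power = relative_power(cat("power"))
    cycle_records = cat("cycles")
    pac_epoch = cat("pac_epoch")
    pac_pooled = cat("pac_pooled")
    pac_per_center = cat("pac_per_center")
    pac_matrices = cat("pac_matrices")
    plasticity = cat("plasticity")

    summary = (power.groupby(["condition", "window", "band"], as_index=False)
               .agg(relative_pct=("relative_pct", "mean"),
                    n_epochs=("relative_pct", "size")))
    hfs_series = (power[power["window"] == "hfs"]
                  .groupby(["condition", "band", "slot"], as_index=False)
                  .agg(relative_pct=("relative_pct", "mean"),
                       n_epochs=("relative_pct", "size")))

    def cond_map(value_col: str) -> pd.DataFrame:
        frames = []
        for cond, group in cycle_records.groupby("condition"):
            table = cyc.frequency_binned_map(group, value_col=value_col,
                                             window_order=WINDOW_ORDER)
            table = table.reset_index()
            table.insert(0, "condition", cond)
            frames.append(table)
        return pd.concat(frames, ignore_index=True)

    theta_map = cond_map("amplitude")
    gamma_map = cond_map("nested_gamma")

    mat_mean = (pac_matrices.groupby(["condition", "window",
                                      "f_low", "f_high"], as_index=False)
                .agg(esc=("esc", "mean"), n=("esc", "size")))

    plast_summary_frames = []
    for (cond, metric), group in plasticity.groupby(["condition", "metric"]):
        series_list = []
        for _, sub in group.groupby("subject"):
            series_list.append(evk.PlasticityTimeSeries(
                time_min=sub["time_min"].values, pct=sub["pct"].values,
                phases=list(sub["phase"]), baseline_mean=np.nan,
                metric=metric))
        s = evk.summarize_group(series_list)
        s.insert(0, "condition", cond)
        s.insert(1, "metric", metric)
        plast_summary_frames.append(s)
    plast_summary = pd.concat(plast_summary_frames, ignore_index=True)

    stats_df = _battery(power, pac_pooled, pac_epoch, plasticity,
                        config.alpha)

    return ResultBundle(config=config, band_power=power,
                        band_power_summary=summary, hfs_series=hfs_series,
                        theta_map=theta_map, gamma_map=gamma_map,
                        pac_pooled=pac_pooled,
                        pac_per_center=pac_per_center,
                        pac_matrices=mat_mean, plasticity=plasticity,
                        plasticity_summary=plast_summary, stats=stats_df,
                        filter_parameters=bank.parameters())


# --------------------------------------------------------------------------
# session file I/O (signal/event/sweep TSVs with a manifest)
# --------------------------------------------------------------------------

def write_sessions(subjects: list[SubjectData], outdir: str | Path) -> None:
    """Write each subject's LFP trace, event schedule and evoked sweeps as
    TSV files plus a cohort manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for subj in subjects:
        sess = subj.session
        sig = pd.DataFrame({"time_s": sess.times, "value_uV": sess.signal})
        sig.to_csv(out / f"{subj.subject}_signal.tsv", sep="\t", index=False)
        sess.events.to_csv(out / f"{subj.subject}_events.tsv", sep="\t",
                           index=False)
        sweep_rows = []
        for i, sw in enumerate(subj.sweeps):
            sweep_rows.append(pd.DataFrame({
                "sweep": i, "time_point_min": sw.time_point_min,
                "time_ms": sw.time_ms, "value_mV": sw.values_mv}))
        pd.concat(sweep_rows, ignore_index=True).to_csv(
            out / f"{subj.subject}_sweeps.tsv", sep="\t", index=False)
        manifest.append({"subject": subj.subject,
                         "condition": subj.condition,
                         "rate_hz": sess.rate,
                         "hfs_onset_s": subj.hfs_onset,
                         "trains": subj.protocol.trains,
                         "pulses_per_train": subj.protocol.pulses_per_train,
                         "intra_train_rate": subj.protocol.intra_train_rate,
                         "inter_train_gap": subj.protocol.inter_train_gap})
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t",
                                  index=False)


def load_sessions(indir: str | Path) -> list[SubjectData]:
    """Load a cohort previously written by :func:`write_sessions`."""
    indir = Path(indir)
    mpath = indir / "manifest.tsv"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.tsv in {indir}")
    manifest = pd.read_csv(mpath, sep="\t")
    subjects = []
    for _, row in manifest.iterrows():
        name = row["subject"]
        sig = pd.read_csv(indir / f"{name}_signal.tsv", sep="\t")
        events = pd.read_csv(indir / f"{name}_events.tsv", sep="\t")
        session = RecordingSession(signal=sig["value_uV"].values,
                                   rate=float(row["rate_hz"]),
                                   events=events,
                                   condition=row["condition"], subject=name)
        sweeps_df = pd.read_csv(indir / f"{name}_sweeps.tsv", sep="\t")
        sweeps = []
        for (_, tp), grp in sweeps_df.groupby(["sweep", "time_point_min"]):
            sweeps.append(evk.EvokedResponse(
                time_ms=grp["time_ms"].values,
                values_mv=grp["value_mV"].values, time_point_min=float(tp)))
        times, phases = evk.default_schedule()
        protocol = StimulationProtocol(
            trains=int(row["trains"]),
            pulses_per_train=int(row["pulses_per_train"]),
            intra_train_rate=float(row["intra_train_rate"]),
            inter_train_gap=float(row["inter_train_gap"]))
        subjects.append(SubjectData(
            subject=name, condition=row["condition"], session=session,
            sweeps=sweeps, schedule_min=times, phases=phases,
            hfs_onset=float(row["hfs_onset_s"]), protocol=protocol))
    return subjects
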