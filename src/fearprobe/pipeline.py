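"""End-to-end runs: synthetic cohort -> preprocessing -> markers -> group
statistics -> heart rate -> volume regressions.

:func:`run_subject` takes one subject from raw (simulated) recording to
markers; :func:`run_cohort` loops subjects and runs the group-level
analyses; :func:`compare_experiments` contrasts the TMS and no-TMS
cohorts. Everything is deterministic under the configuration seed; each
subject gets an independent child seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fearprobe import cardiac, evoked, preprocess, stats, synth
from fearprobe.core import EpochSet, InvalidParameterError, RawRecording

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SubjectResult", "CohortReport", "run_subject", "run_cohort",
           "compare_experiments"]


@dataclass
class RunConfig:
    """All knobs of a cohort run; round-trips through JSON unchanged."""

    # paradigm / simulator
    n_channels: int = 64
    fs_hz: float = 250.0
    n_trials: int = 90
    frac_csplus: float = 54 / 90
    frac_us: float = 0.33
    iti_range_s: tuple[float, float] = (5.0, 10.0)
    cue_duration_s: float = 5.0
    tms_offset_s: float = 1.0
    mode: str = "tms"  # "tms" | "no_tms"
    # injected truth
    lpp_effect_uV: float = 12.0
    erp152_effect_uV: float = 0.0
    tep_effect_uV: float = 0.0
    evoked_amp_scale: float = 1.0  # global scale on all injected components
    subject_effect_sd_uV: float = 4.0
    heart_rate_baseline_bpm: float = 70.0
    heart_rate_T_bpm: float = 75.0
    heart_rate_NT_bpm: float = 67.0
    cardiac_amp_uV: float = 30.0
    line_noise_amp_uV: float = 5.0
    background_amp_uV: float = 10.0
    background_exponent: float = 1.0
    tms_artifact_amp_uV: float = 2000.0
    trial_amp_jitter: float = 0.1
    # preprocessing
    line_freq_hz: float = 50.0
    lowpass_hz: float = 35.0
    bad_channel_z: float = 5.0
    epoch_window_ms: tuple[float, float] = (-500.0, 2000.0)
    baseline_ms: tuple[float, float] = (-500.0, 0.0)
    # evoked / markers
    min_flank_points: int = 3
    tep_blank_ms: float = 25.0  # skip the interpolated artifact window
    snr_signal_window_ms: tuple[float, float] = (100.0, 600.0)
    cluster_window_ms: tuple[float, float] = (300.0, 800.0)
    # statistics
    n_perm: int = 1000
    cluster_p_thresh: float = 0.05
    alpha: float = 0.05
    marker_alternative: str = "greater"  # contrast tested: threat > no-threat
    alpha_remove: float = 0.10
    # cardiac
    with_heart_rate: bool = True
    ica_components: int | None = 20
    # cohort / volumes
    n_subjects: int = 20
    volume_marker: str = "LPP"
    volume_betas: dict[str, float] = field(
        default_factory=lambda: {"rh_dmPFC": 100.0, "rh_amygdala": 60.0}
    )
    volume_noise_sd: float = 150.0
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        if isinstance(source, Path):
            source = source.read_text()
        elif "{" not in source and Path(source).exists():
            source = Path(source).read_text()
        payload = json.loads(source)
        cfg = cls(**payload)
        # JSON turns tuples into lists; normalize back
        for name in ("iti_range_s", "epoch_window_ms", "baseline_ms",
                     "snr_signal_window_ms", "cluster_window_ms"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class SubjectResult:
    """Everything one subject contributes to the group analysis."""

    seed: int
    markers: pd.DataFrame  # amplitude markers (per labelled component)
    peak_to_peak: pd.DataFrame  # peak-to-peak markers (per pair)
    snr_db: float
    diff_map: np.ndarray  # per-channel T-NT mean amplitude in the cluster window
    marker_channels: dict
    heart_rate: dict[str, float] = field(default_factory=dict)
    n_epochs: dict[str, int] = field(default_factory=dict)


@dataclass
class CohortReport:
    """Group-level tables mirroring the marker/regression table structure."""

    config: RunConfig
    marker_tests: pd.DataFrame
    cluster: stats.ClusterResult | None
    heart_rate_test: stats.TestResult | None
    heart_rates: pd.DataFrame
    regressions: pd.DataFrame
    snr_summary: dict[str, float]
    subjects: list[SubjectResult]

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out / "config.json")
        self.marker_tests.to_csv(out / "marker_tests.tsv", sep="\t", index=False)
        self.regressions.to_csv(out / "regressions.tsv", sep="\t", index=False)
        self.heart_rates.to_csv(out / "heart_rates.tsv", sep="\t", index=False)
        payload = {
            "seed": self.config.seed,
            "snr_summary": self.snr_summary,
            "clusters": None
            if self.cluster is None
            else {
                "n_permutations": self.cluster.n_permutations,
                "threshold_p": self.cluster.threshold_p,
                "seed": self.cluster.seed,
                "clusters": [
                    {"channels": c.channels, "mass": c.mass, "p": c.p}
                    for c in self.cluster.clusters
                ],
            },
            "heart_rate_test": None
            if self.heart_rate_test is None
            else dataclasses.asdict(self.heart_rate_test),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=1))
        return out


def _build_truth(config: RunConfig, layout, rng: np.random.Generator):
    """Per-subject ground truth: config effects plus individual variation."""
    lpp = config.lpp_effect_uV + config.subject_effect_sd_uV * rng.standard_normal()
    erp = config.erp152_effect_uV + config.subject_effect_sd_uV * rng.standard_normal()
    truth = synth.default_ground_truth(
        layout,
        lpp_effect_uV=lpp,
        erp152_effect_uV=erp,
        tep_effect_uV=config.tep_effect_uV,
        heart_rate_bpm={
            "baseline": config.heart_rate_baseline_bpm,
            "CSplus": config.heart_rate_T_bpm,
            "CSminus": config.heart_rate_NT_bpm,
        },
        cardiac_amp_uV=config.cardiac_amp_uV,
        line_noise_amp_uV=config.line_noise_amp_uV,
        background_amp_uV=config.background_amp_uV,
        background_exponent=config.background_exponent,
        tms_artifact_amp_uV=config.tms_artifact_amp_uV,
        noise_sd=config.trial_amp_jitter,
    )
    if config.evoked_amp_scale != 1.0:
        for comp in truth.components:
            comp.amplitude_uV = {
                k: v * config.evoked_amp_scale for k, v in comp.amplitude_uV.items()
            }
    return truth


def simulate_subject(config: RunConfig, seed: int) -> RawRecording:
    """One subject's raw recording under the configured study conditions."""
    ss = np.random.SeedSequence(seed).spawn(3)
    sched_seed, truth_rng, rec_seed = (
        int(ss[0].generate_state(1)[0] % 2**31),
        np.random.default_rng(ss[1]),
        int(ss[2].generate_state(1)[0] % 2**31),
    )
    schedule = synth.generate_trial_schedule(
        n_trials=config.n_trials,
        frac_csplus=config.frac_csplus,
        frac_us=config.frac_us,
        iti_range_s=config.iti_range_s,
        tms_offset_s=config.tms_offset_s if config.mode == "tms" else None,
        cue_duration_s=config.cue_duration_s,
        seed=sched_seed,
    )
    layout = synth.generate_sensor_layout(config.n_channels, seed=0)
    truth = _build_truth(config, layout, truth_rng)
    return synth.simulate_recording(
        schedule, layout, truth, mode=config.mode, seed=rec_seed, fs_hz=config.fs_hz
    )


def _marker_threshold(wave: evoked.EvokedWaveform, channel: str,
                      floor_uV: float = 1.0) -> float:
    """Noise-adaptive labelling threshold from the evoked baseline.

    3x the robust SD of the pre-cue evoked trace, with an absolute floor
    so that sub-microvolt filter ripple is never labelled when the
    recording is nearly noise-free.
    """
    r = wave.row_labels.index(channel)
    base = wave.values[r, wave.times_ms < 0]
    mad = np.median(np.abs(base - np.median(base)))
    return max(float(3.0 * 1.4826 * mad), floor_uV)


def extract_markers(analysis: EpochSet, config: RunConfig) -> dict:
    """Average, detect, label and difference the evoked components.

    Shared by :func:`run_subject` and the command-line ``evoked`` stage.
    Returns a dict with the T-NT amplitude markers, peak-to-peak
    markers, the per-component sensor choices and both evoked averages.
    """
    ev_t = evoked.average_evoked(analysis, "T")
    ev_nt = evoked.average_evoked(analysis, "NT")
    tms_ms = config.tms_offset_s * 1000.0 if config.mode == "tms" else None

    # evoked components have distinct scalp topographies, so each is
    # measured at the sensor with the largest absolute T-NT difference
    # inside its own latency window
    channels = {
        "ERP152": evoked.select_marker_channel(ev_t, ev_nt, evoked.ERP152_WINDOW_MS),
        "LPP": evoked.select_marker_channel(ev_t, ev_nt, evoked.LPP_WINDOW_MS),
    }
    if tms_ms is not None:
        channels["TEP"] = evoked.select_marker_channel(
            ev_t, ev_nt, (tms_ms + config.tep_blank_ms, tms_ms + 1000.0)
        )

    def peaks_for(wave):
        picked: list[evoked.Peak] = []
        for part in ("ERP152", "LPP"):
            ch = channels[part]
            thr = _marker_threshold(wave, ch)
            labelled = evoked.label_peaks(
                evoked.detect_peaks(wave, (0.0, 1000.0), config.min_flank_points,
                                    channels=[ch]),
                "erp", min_amplitude_uV=thr,
            )
            picked.extend(p for p in labelled if p.label == part)
        if tms_ms is not None:
            ch = channels["TEP"]
            thr = _marker_threshold(wave, ch)
            # peaks inside the excised-and-interpolated artifact window are
            # reconstruction artefacts, not evoked activity
            tep_labelled = evoked.label_peaks(
                evoked.detect_peaks(
                    wave, (tms_ms + config.tep_blank_ms, tms_ms + 1000.0),
                    config.min_flank_points, channels=[ch],
                ),
                "tep", tms_time_ms=tms_ms, min_amplitude_uV=thr,
            )
            picked.extend(p for p in tep_labelled if p.label != "unlabelled")
        merged = evoked.PeakSet(
            peaks=sorted(picked, key=lambda p: p.latency_ms),
            condition=wave.condition,
        )
        return evoked.add_anchor_points(
            merged, wave, channels["ERP152"], tms_time_ms=tms_ms
        )

    peaks_t, peaks_nt = peaks_for(ev_t), peaks_for(ev_nt)
    markers = evoked.tnt_markers(peaks_t, peaks_nt)
    if markers.empty or set(markers["label"]) <= {"Cue", "TMS"}:
        logger.warning("no labelled evoked components found; marker table is empty")
    pp = evoked.tnt_peak_to_peak(
        evoked.peak_to_peak(peaks_t, tms_time_ms=tms_ms or 1000.0),
        evoked.peak_to_peak(peaks_nt, tms_time_ms=tms_ms or 1000.0),
    )
    return {"markers": markers, "peak_to_peak": pp, "channels": channels,
            "ev_t": ev_t, "ev_nt": ev_nt}


def run_subject(config: RunConfig, seed: int | None = None,
                rec: RawRecording | None = None) -> SubjectResult:
    """Simulate (or take) one recording, clean it, and extract markers.

    Returns the subject's threat-minus-no-threat amplitude markers per
    labelled component, peak-to-peak markers, evoked SNR, per-channel
    difference map (input to the sensor cluster statistics), and heart
    rates per condition when enabled.
    """
    seed = config.seed if seed is None else seed
    if rec is None:
        rec = simulate_subject(config, seed)

    cleaned = preprocess.clean(
        rec,
        line_freq_hz=config.line_freq_hz,
        z_thresh=config.bad_channel_z,
        cutoff_hz=config.lowpass_hz,
    )
    epochs = preprocess.epoch_and_baseline(
        cleaned, window_ms=config.epoch_window_ms, baseline_ms=config.baseline_ms
    )
    analysis = preprocess.select_analysis_trials(epochs)

    extracted = extract_markers(analysis, config)
    markers, pp = extracted["markers"], extracted["peak_to_peak"]
    channels = extracted["channels"]
    ev_t, ev_nt = extracted["ev_t"], extracted["ev_nt"]
    try:
        snr_db = evoked.compute_snr(
            analysis, config.snr_signal_window_ms, config.baseline_ms
        ).snr_db
    except InvalidParameterError as err:  # degenerate (e.g. all-zero) data
        logger.warning("SNR unavailable: %s", err)
        snr_db = float("nan")

    # per-channel T-NT mean amplitude in the cluster window
    lo, hi = config.cluster_window_ms
    w = (analysis.times_ms >= lo) & (analysis.times_ms <= hi)
    diff_map = (
        ev_t.values[:, w].mean(axis=1) - ev_nt.values[:, w].mean(axis=1)
    )

    heart = {}
    if config.with_heart_rate:
        cardiac_epochs = preprocess.epoch_and_baseline(
            preprocess.clean(rec, cutoff_hz=config.lowpass_hz, lowpass=False,
                             line_freq_hz=config.line_freq_hz,
                             z_thresh=config.bad_channel_z),
            window_ms=(0.0, config.cue_duration_s * 1000.0),
            baseline_ms=(0.0, 0.0),
        )
        cardiac_analysis = preprocess.select_analysis_trials(cardiac_epochs)
        for cond in ("T", "NT"):
            try:
                est = cardiac.estimate_heart_rate(
                    cardiac_analysis, cond,
                    n_components=config.ica_components,
                    seed=seed,
                    segment_s=config.cue_duration_s,
                )
                heart[cond] = est.bpm
            except cardiac.NoCardiacComponentError as err:
                logger.warning("heart rate unavailable for %s: %s", cond, err)

    return SubjectResult(
        seed=seed,
        markers=markers,
        peak_to_peak=pp,
        snr_db=snr_db,
        diff_map=diff_map,
        marker_channels=channels,
        heart_rate=heart,
        n_epochs={
            "T": int(np.sum(analysis.conditions == "T")),
            "NT": int(np.sum(analysis.conditions == "NT")),
        },
    )


def _group_marker_tests(subjects: list[SubjectResult], alternative: str) -> pd.DataFrame:
    """Paired t per marker across subjects, FDR-adjusted (BH)."""
    rows = []
    amp = pd.concat(
        [s.markers.assign(subject=i) for i, s in enumerate(subjects)],
        ignore_index=True,
    )
    # group on canonical labels; subjects' latency-derived display names
    # (e.g. TEP40 vs TEP41) vary with measured latency
    for label, grp in amp.groupby("label", sort=False):
        if len(grp) < 2:
            logger.warning("component %s present in fewer than 2 subjects; skipped",
                           label)
            continue
        res = stats.paired_t(
            grp["amplitude_T_uV"].to_numpy(), grp["amplitude_NT_uV"].to_numpy(),
            alternative=alternative,
        )
        name = grp["component"].mode().iloc[0]
        rows.append({"marker": name, "label": label, "kind": "amplitude",
                     "t": res.t, "p": res.p,
                     "mean_difference": res.mean_difference,
                     "se_difference": res.se_difference,
                     "cohens_d": res.cohens_d, "n": res.n})
    pp = pd.concat(
        [s.peak_to_peak.assign(subject=i) for i, s in enumerate(subjects)],
        ignore_index=True,
    )
    for pair, grp in pp.groupby("pair_labels", sort=False):
        if len(grp) < 2:
            continue
        res = stats.paired_t(
            grp["value_uV_T"].to_numpy(), grp["value_uV_NT"].to_numpy(),
            alternative=alternative,
        )
        name = grp["pair"].mode().iloc[0]
        rows.append({"marker": name, "label": pair, "kind": "peak_to_peak",
                     "t": res.t, "p": res.p,
                     "mean_difference": res.mean_difference,
                     "se_difference": res.se_difference,
                     "cohens_d": res.cohens_d, "n": res.n})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = stats.fdr_adjust(table["p"].to_numpy())
        table["adjustment"] = "BH-FDR"
        table["alternative"] = alternative
    return table


def run_cohort(config: RunConfig) -> CohortReport:
    """Loop subjects, then group statistics, heart rate and regressions."""
    if config.n_subjects < 2:
        raise InvalidParameterError("group statistics need at least 2 subjects")
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects + 2)
    subject_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children[:-2]]
    cluster_seed = int(children[-2].generate_state(1)[0] % 2**31)
    volume_seed = int(children[-1].generate_state(1)[0] % 2**31)

    subjects = [run_subject(config, seed=s) for s in subject_seeds]

    marker_tests = _group_marker_tests(subjects, config.marker_alternative)

    layout = synth.generate_sensor_layout(config.n_channels, seed=0)
    diffs = np.vstack([s.diff_map for s in subjects])
    cluster = stats.cluster_permutation(
        diffs, layout, n_perm=config.n_perm, p_thresh=config.cluster_p_thresh,
        seed=cluster_seed,
    )

    hr_rows = [
        {"subject": i, "condition": cond, "bpm": bpm}
        for i, s in enumerate(subjects)
        for cond, bpm in s.heart_rate.items()
    ]
    heart_rates = pd.DataFrame(hr_rows, columns=["subject", "condition", "bpm"])
    heart_rate_test = None
    if len(heart_rates):
        wide = heart_rates.pivot(index="subject", columns="condition", values="bpm")
        if {"T", "NT"} <= set(wide.columns):
            paired = wide.dropna()
            if len(paired) >= 2:
                heart_rate_test = stats.paired_t(
                    paired["T"].to_numpy(), paired["NT"].to_numpy(),
                    alternative=config.marker_alternative,
                )

    # volume table coupled to the designated marker, regressions per marker
    amp = pd.concat(
        [s.markers.assign(subject=i) for i, s in enumerate(subjects)],
        ignore_index=True,
    )
    wide_amp = amp.pivot(index="subject", columns="label", values="marker_uV")
    regress_rows = []
    volumes = None
    if config.volume_marker in wide_amp.columns and len(
        wide_amp[config.volume_marker].dropna()
    ) >= 3:
        coupled = wide_amp[config.volume_marker]
        full = coupled.dropna()
        volumes = synth.simulate_cohort_volumes(
            n_subjects=len(full),
            betas=config.volume_betas,
            noise_sd=config.volume_noise_sd,
            marker_values=full.to_numpy(),
            seed=volume_seed,
        )
        from fearprobe.core import VOLUME_COLUMNS

        pos = {subj: k for k, subj in enumerate(full.index)}
        for comp in wide_amp.columns:
            y = wide_amp.loc[full.index, comp].dropna()
            if len(y) < 8:
                continue
            X = volumes.iloc[[pos[i] for i in y.index]][
                list(VOLUME_COLUMNS)
            ].reset_index(drop=True)
            try:
                res = stats.backward_elimination(
                    y.to_numpy(), X, alpha_remove=config.alpha_remove
                )
            except InvalidParameterError as err:
                logger.warning("regression for %s failed: %s", comp, err)
                continue
            regress_rows.append(
                {"marker": comp, "predicted_by": "/".join(res.selected) or "-",
                 "r2": res.r2, "adjusted_r2": res.adjusted_r2,
                 "F": res.f_statistic, "p": res.p_value, "n": res.n}
            )
    regressions = pd.DataFrame(
        regress_rows,
        columns=["marker", "predicted_by", "r2", "adjusted_r2", "F", "p", "n"],
    )
    if len(regressions):
        regressions["p_adjusted"] = stats.fdr_adjust(regressions["p"].to_numpy())
        regressions["adjustment"] = "BH-FDR"

    snrs = np.array([s.snr_db for s in subjects])
    snr_summary = {
        "p25_db": float(np.percentile(snrs, 25)),
        "median_db": float(np.percentile(snrs, 50)),
        "p75_db": float(np.percentile(snrs, 75)),
    }
    return CohortReport(
        config=config,
        marker_tests=marker_tests,
        cluster=cluster,
        heart_rate_test=heart_rate_test,
        heart_rates=heart_rates,
        regressions=regressions,
        snr_summary=snr_summary,
        subjects=subjects,
    )


def compare_experiments(
    report_tms: CohortReport, report_no_tms: CohortReport
) -> pd.DataFrame:
    """Welch comparison of markers between the TMS and no-TMS cohorts."""

    def marker_matrix(report: CohortReport) -> pd.DataFrame:
        amp = pd.concat(
            [s.markers.assign(subject=i) for i, s in enumerate(report.subjects)],
            ignore_index=True,
        )
        return amp.pivot(index="subject", columns="component", values="marker_uV")

    a, b = marker_matrix(report_tms), marker_matrix(report_no_tms)
    common = [c for c in a.columns if c in b.columns]
    missing = set(a.columns) ^ set(b.columns)
    if missing:
        logger.warning("marker sets differ; comparing intersection (missing: %s)",
                       sorted(missing))
    rows = []
    for comp in common:
        x, y = a[comp].dropna(), b[comp].dropna()
        if len(x) < 2 or len(y) < 2:
            continue
        res = stats.two_sample_t(x.to_numpy(), y.to_numpy())
        rows.append({"marker": comp, "t": res.t, "p": res.p,
                     "mean_difference": res.mean_difference,
                     "cohens_d": res.cohens_d, "n": res.n})
    table = pd.DataFrame(rows, columns=["marker", "t", "p", "mean_difference",
                                        "cohens_d", "n"])
    if len(table):
        table["p_adjusted"] = stats.fdr_adjust(table["p"].to_numpy())
        table["adjustment"] = "BH-FDR"
    return table
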