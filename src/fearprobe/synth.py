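"""Synthetic instructed-fear TMS-EEG data with retrievable ground truth.

The generator emulates the study conditions of the paradigm the package
analyses: 250 Hz multichannel EEG, 5 s visual cues separated by 5-10 s
inter-stimulus intervals, 90 trials of which 54 are threat cues (CS+)
with 33% US pairing, a TMS pulse 1000 ms after each cue in TMS mode,
evoked deflections at configurable latencies/topographies, a cardiac
source mixed into all channels, 50 Hz line noise and 1/f background.
Everything injected is recorded on the returned objects so downstream
stages can be tested against known truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fearprobe.core import (
    CONDITIONS,
    REGIONS,
    VOLUME_COLUMNS,
    EvokedComponent,
    GroundTruth,
    InvalidParameterError,
    RawRecording,
    SensorLayout,
    Trial,
    TrialSchedule,
)

__all__ = [
    "generate_trial_schedule",
    "generate_sensor_layout",
    "default_ground_truth",
    "simulate_recording",
    "simulate_cohort_volumes",
]

#: Nominal TEP latencies (ms after the TMS pulse) used by the default truth.
TEP_LATENCIES_MS = (41.0, 57.0, 81.0, 117.0, 197.0, 317.0)

#: Typical head-size-corrected region volumes (mm^3) for the cohort table.
_TYPICAL_VOLUME_MM3 = {
    "lh_dmPFC": 9500.0, "rh_dmPFC": 9500.0,
    "lh_insula": 6800.0, "rh_insula": 6800.0,
    "lh_amygdala": 1600.0, "rh_amygdala": 1600.0,
    "lh_hippocampus": 4200.0, "rh_hippocampus": 4200.0,
}


def generate_trial_schedule(
    n_trials: int = 90,
    frac_csplus: float = 54 / 90,
    frac_us: float = 0.33,
    iti_range_s: tuple[float, float] = (5.0, 10.0),
    tms_offset_s: float | None = 1.0,
    cue_duration_s: float = 5.0,
    lead_in_s: float = 2.0,
    fs_hint_hz: float | None = 250.0,
    seed: int = 0,
) -> TrialSchedule:
    """Pseudorandomized cue schedule.

    ``round(frac_csplus * n_trials)`` trials are CS+ and
    ``round(frac_us * n_csplus)`` of those are paired with the US; which
    CS+ trials carry the US is uniform without replacement under the
    seed. ITIs are drawn uniformly from ``iti_range_s``. In TMS mode
    (``tms_offset_s`` not None) every trial gets a pulse at
    ``cue_onset + tms_offset_s``. When ``fs_hint_hz`` is given, ITIs are
    quantized to the sample grid so cue onsets and pulse times fall
    exactly on recorded samples.
    """
    if n_trials <= 0:
        raise InvalidParameterError("n_trials must be positive")
    if not (0.0 <= frac_csplus <= 1.0 and 0.0 <= frac_us <= 1.0):
        raise InvalidParameterError("fractions must lie in [0, 1]")
    lo, hi = iti_range_s
    if lo > hi or lo < 0:
        raise InvalidParameterError("invalid ITI range")

    rng = np.random.default_rng(seed)
    n_csplus = int(np.rint(frac_csplus * n_trials))
    n_us = int(np.rint(frac_us * n_csplus))

    conditions = np.array(["CSplus"] * n_csplus + ["CSminus"] * (n_trials - n_csplus))
    rng.shuffle(conditions)
    us = np.zeros(n_trials, dtype=bool)
    plus_idx = np.flatnonzero(conditions == "CSplus")
    us[rng.choice(plus_idx, size=n_us, replace=False)] = True

    itis = rng.uniform(lo, hi, size=n_trials)
    if fs_hint_hz is not None:
        itis = np.clip(np.round(itis * fs_hint_hz) / fs_hint_hz, lo, hi)
    trials: list[Trial] = []
    onset = lead_in_s
    for cond, flag, iti in zip(conditions, us, itis):
        trials.append(
            Trial(
                condition=str(cond),
                us_paired=bool(flag),
                cue_onset_s=float(onset),
                cue_duration_s=cue_duration_s,
                iti_s=float(iti),
                tms_time_s=None if tms_offset_s is None else float(onset + tms_offset_s),
            )
        )
        onset += cue_duration_s + iti
    schedule = TrialSchedule(trials)
    schedule.validate()
    return schedule


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper unit hemisphere (z >= 0)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n  # uniform in z over (0, 1)
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


# Unit anchor directions per region; +x = front, +y = left, +z = vertex.
_REGION_ANCHORS = {
    "frontal": np.array([0.95, 0.0, 0.31]),
    "dmPFC": np.array([0.55, 0.0, 0.84]),
    "central": np.array([0.0, 0.0, 1.0]),
    "parietal": np.array([-0.55, 0.0, 0.84]),
    "occipital": np.array([-0.95, 0.0, 0.31]),
    "temporal": np.array([0.0, 1.0, 0.1]),  # both sides, |y| handled below
}


def generate_sensor_layout(n_channels: int = 64, seed: int = 0) -> SensorLayout:
    """Electrodes on an upper hemisphere, assigned to six scalp regions.

    Channels are placed quasi-uniformly (Fibonacci lattice plus a small
    seeded jitter) and assigned to the nearest of six angular-sector
    anchors (frontal, dmPFC, central, parietal, occipital, temporal);
    any region left empty steals the best-fitting channel from the most
    populated region, so all six regions are always populated.
    """
    if n_channels < 6:
        raise InvalidParameterError("need at least 6 channels to populate all regions")
    rng = np.random.default_rng(seed)
    pos = _fibonacci_hemisphere(n_channels)
    jitter = rng.normal(scale=0.02, size=pos.shape)
    pos = pos + jitter
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos[:, 2] = np.abs(pos[:, 2])  # stay on the upper hemisphere

    # mirror-symmetric temporal anchor: score against |y|
    scores = np.empty((n_channels, len(REGIONS)))
    for j, region in enumerate(REGIONS):
        anchor = _REGION_ANCHORS[region]
        p = pos.copy()
        if region == "temporal":
            p[:, 1] = np.abs(p[:, 1])
        scores[:, j] = p @ anchor
    assignment = np.argmax(scores, axis=1)

    # repair: guarantee every region non-empty
    counts = np.bincount(assignment, minlength=len(REGIONS))
    while np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        donor = int(np.argmax(counts))
        donor_idx = np.flatnonzero(assignment == donor)
        best = donor_idx[np.argmax(scores[donor_idx, empty])]
        assignment[best] = empty
        counts = np.bincount(assignment, minlength=len(REGIONS))

    labels = [f"E{i + 1:03d}" for i in range(n_channels)]
    regions = [REGIONS[a] for a in assignment]
    return SensorLayout(labels=labels, positions=pos, regions=regions)


def _gaussian_topography(
    layout: SensorLayout, center_region: str, spread: float = 0.9
) -> np.ndarray:
    """Per-channel weights peaking over a region's centroid (max 1)."""
    idx = layout.region_channels(center_region)
    center = layout.positions[idx].mean(axis=0)
    center /= np.linalg.norm(center)
    d = np.linalg.norm(layout.positions - center, axis=1)
    w = np.exp(-(d**2) / (2 * spread**2))
    return w / w.max()


def default_ground_truth(
    layout: SensorLayout,
    lpp_effect_uV: float = 12.0,
    erp152_effect_uV: float = 0.0,
    tep_effect_uV: float = 0.0,
    heart_rate_bpm: dict[str, float] | float = 70.0,
    **overrides,
) -> GroundTruth:
    """Ground truth emulating the evoked structure the paradigm reports.

    Two cue-locked components (an early deflection at 152 ms and a
    sustained late positivity at 500 ms) plus six TMS-locked components
    at 41/57/81/117/197/317 ms after the pulse. ``*_effect_uV`` set the
    threat-minus-no-threat amplitude difference injected at the LPP,
    ERP152, and all TEP components respectively (default: an LPP-only
    effect, the pattern reported for this paradigm).
    """
    if not isinstance(heart_rate_bpm, dict):
        heart_rate_bpm = {
            "baseline": float(heart_rate_bpm),
            "CSplus": float(heart_rate_bpm),
            "CSminus": float(heart_rate_bpm),
        }
    frontal = _gaussian_topography(layout, "frontal")
    dmpfc = _gaussian_topography(layout, "dmPFC")
    central = _gaussian_topography(layout, "central")
    components = [
        EvokedComponent(
            name="ERP152", latency_ms=152.0, reference="cue", width_ms=60.0,
            amplitude_uV={"CSplus": 12.0 + erp152_effect_uV, "CSminus": 12.0},
            topography=frontal,
        ),
        EvokedComponent(
            name="LPP", latency_ms=500.0, reference="cue", width_ms=600.0,
            amplitude_uV={"CSplus": 10.0 + lpp_effect_uV, "CSminus": 10.0},
            topography=central,
        ),
    ]
    # successive TEPs alternate polarity, as TMS-evoked deflections do;
    # condition effects act along each component's own polarity. The
    # magnitude profile (strong first response, weak first trough,
    # partial recovery) keeps neighbouring extrema well separated after
    # low-pass filtering.
    tep_base = (16.0, 6.0, 12.0, 12.0, 12.0, 14.0)
    for k, (lat, base) in enumerate(zip(TEP_LATENCIES_MS, tep_base)):
        sign = 1.0 if k % 2 == 0 else -1.0
        components.append(
            EvokedComponent(
                name=f"TEP{k + 1}", latency_ms=lat, reference="tms",
                width_ms=16.0 if lat < 100 else 48.0,
                amplitude_uV={
                    "CSplus": sign * (base + tep_effect_uV),
                    "CSminus": sign * base,
                },
                topography=dmpfc,
            )
        )
    return GroundTruth(components=components, heart_rate_bpm=heart_rate_bpm, **overrides)


def _tep_complex(
    times_s: np.ndarray,
    t0_s: float,
    latencies_ms: np.ndarray,
    amplitudes_uV: np.ndarray,
    tail_ms: float = 120.0,
) -> np.ndarray:
    """One phase-continuous TMS-evoked complex with extrema at the given
    latencies.

    Successive TMS-evoked deflections are half-cycles of a single
    decelerating oscillation, so the complex is rendered as
    ``E(t) * cos(phi(t))`` with the phase piecewise linear (``phi`` hits
    k*pi exactly at latency k) and the envelope a shape-preserving
    (PCHIP) interpolant through the absolute amplitudes. Extrema
    therefore sit exactly at the injected latencies with the injected
    amplitudes, and the waveform is narrowband enough to pass a 35 Hz
    zero-phase low-pass essentially unchanged. Requires alternating
    amplitude signs.
    """
    lat = np.asarray(latencies_ms, float)
    amp = np.asarray(amplitudes_uV, float)
    signs = np.sign(amp)
    if np.any(signs[:-1] * signs[1:] >= 0):
        raise InvalidParameterError("complex rendering needs alternating signs")
    first_sign = signs[0]
    from scipy.interpolate import PchipInterpolator

    # phase nodes: k*pi at extremum k (phase 0 at the first extremum when
    # its sign is positive, pi when negated); the complex fades in over a
    # full half-cycle before the first extremum and out over a quarter
    # cycle after the last
    phase_at = np.arange(len(lat)) * np.pi + (0.0 if first_sign > 0 else np.pi)
    onset = lat[0] - (lat[1] - lat[0])
    end = lat[-1] + tail_ms
    t_ms = (times_s - t0_s) * 1000.0
    m = (t_ms >= onset) & (t_ms <= end)
    if not m.any():
        return np.zeros_like(times_s)
    x = t_ms[m]
    nodes = np.concatenate([[onset], lat, [end]])
    phase = PchipInterpolator(
        nodes,
        np.concatenate([[phase_at[0] - np.pi], phase_at, [phase_at[-1] + np.pi / 2]]),
    )(x)
    envelope = PchipInterpolator(
        nodes, np.concatenate([[0.0], np.abs(amp), [0.0]])
    )(x)
    out = np.zeros_like(times_s)
    out[m] = envelope * np.cos(phase)
    return out


def _hann_bump(times_s: np.ndarray, center_s: float, width_s: float) -> np.ndarray:
    """Monophasic Hann-windowed deflection, unit peak at ``center_s``."""
    x = (times_s - center_s) / width_s  # in [-0.5, 0.5] inside the bump
    out = np.zeros_like(times_s)
    inside = np.abs(x) <= 0.5
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * x[inside]))
    return out


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs_hz: float, exponent: float
) -> np.ndarray:
    """Per-channel 1/f^exponent background, unit standard deviation."""
    from scipy.fft import next_fast_len

    n_ch, n_t = shape
    n_fft = next_fast_len(n_t)
    white = rng.standard_normal((n_ch, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs_hz)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=n_fft, axis=1)[:, :n_t]
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _cardiac_template(fs_hz: float) -> np.ndarray:
    """One synthetic beat: narrow spiky QRS-like impulse plus a T wave."""
    t = np.arange(int(round(0.45 * fs_hz))) / fs_hz
    qrs = np.exp(-((t - 0.04) ** 2) / (2 * 0.008**2))
    qrs -= 0.35 * np.exp(-((t - 0.06) ** 2) / (2 * 0.012**2))
    t_wave = 0.3 * np.exp(-((t - 0.28) ** 2) / (2 * 0.04**2))
    return qrs + t_wave


def _beat_times(
    rng: np.random.Generator,
    duration_s: float,
    schedule: TrialSchedule,
    heart_rate_bpm: dict[str, float],
    jitter_frac: float = 0.02,
) -> np.ndarray:
    """Sequential beat times; the instantaneous rate follows the condition
    of the cue window the beat falls in (baseline rate elsewhere)."""
    cue_windows = [
        (t.cue_onset_s, t.cue_onset_s + t.cue_duration_s, t.condition)
        for t in schedule.trials
    ]

    def bpm_at(t: float) -> float:
        for a, b, cond in cue_windows:
            if a <= t < b:
                return heart_rate_bpm[cond]
        return heart_rate_bpm["baseline"]

    beats = []
    t = float(rng.uniform(0, 60.0 / heart_rate_bpm["baseline"]))
    while t < duration_s:
        beats.append(t)
        period = 60.0 / bpm_at(t)
        t += period * (1.0 + jitter_frac * rng.standard_normal())
    return np.asarray(beats)


def simulate_recording(
    schedule: TrialSchedule,
    layout: SensorLayout,
    truth: GroundTruth,
    mode: str = "tms",
    seed: int = 0,
    fs_hz: float = 250.0,
    duration_s: float | None = None,
    lead_out_s: float = 2.0,
) -> RawRecording:
    """Render a continuous recording from a schedule, layout and truth.

    data = 1/f background + per-trial evoked components + cardiac source
    mixed into all channels + 50 Hz line noise + (TMS mode) a large
    biphasic transient of <= 10 ms at every pulse time. Bitwise
    reproducible for a fixed seed and parameter set.
    """
    if mode not in ("tms", "no_tms"):
        raise InvalidParameterError("mode must be 'tms' or 'no_tms'")
    if mode == "tms" and not schedule.has_tms:
        raise InvalidParameterError("TMS mode requires tms_time_s on every trial")
    needed = schedule.duration_s + lead_out_s
    if duration_s is None:
        duration_s = needed
    elif duration_s < schedule.duration_s:
        raise InvalidParameterError(
            f"schedule extends to {schedule.duration_s:.1f} s beyond the "
            f"requested duration {duration_s:.1f} s"
        )
    n_ch = layout.n_channels
    n_t = int(round(duration_s * fs_hz))
    times = np.arange(n_t) / fs_hz

    # independent streams so toggling one source never shifts another
    seeds = np.random.SeedSequence(seed).spawn(4)
    rng_bg, rng_card, rng_mix, rng_trial = (np.random.default_rng(s) for s in seeds)

    data = np.zeros((n_ch, n_t))
    if truth.background_amp_uV > 0:
        # shared 1/f sources mixed into all channels: volume conduction
        # makes real background spatially correlated (limited rank)
        rank = truth.background_rank
        if rank is None:
            rank = max(4, n_ch // 2)
        rank = min(rank, n_ch)
        sources = _one_over_f_noise(rng_bg, (rank, n_t), fs_hz,
                                    truth.background_exponent)
        mix = rng_bg.standard_normal((n_ch, rank)) / np.sqrt(rank)
        bg = mix @ sources
        bg /= bg.std(axis=1, keepdims=True)
        data += truth.background_amp_uV * bg

    # evoked components, trial by trial
    cue_comps = [c for c in truth.components if c.reference == "cue"]
    tms_comps = sorted(
        (c for c in truth.components if c.reference == "tms"),
        key=lambda c: c.latency_ms,
    )

    def add_bump(trial, comp, center):
        amp = comp.amplitude_uV.get(trial.condition, 0.0)
        if truth.noise_sd > 0:
            amp *= 1.0 + truth.noise_sd * rng_trial.standard_normal()
        if amp == 0.0:
            return
        topo = comp.topography if comp.topography is not None else np.ones(n_ch)
        lo = center - comp.width_ms / 2000.0
        hi = center + comp.width_ms / 2000.0
        i0 = max(0, int(np.floor(lo * fs_hz)))
        i1 = min(n_t, int(np.ceil(hi * fs_hz)) + 1)
        if i0 >= i1:
            return
        bump = _hann_bump(times[i0:i1], center, comp.width_ms / 1000.0)
        data[:, i0:i1] += amp * np.outer(topo, bump)

    def tms_amps(trial):
        return np.array(
            [c.amplitude_uV.get(trial.condition, 0.0) for c in tms_comps]
        )

    def render_joint_complex(trial):
        """Successive alternating-sign deflections form one oscillatory
        complex (extrema land exactly on the injected latencies); mixed
        or same-sign components fall back to independent bumps."""
        amps = tms_amps(trial)
        if np.all(amps == 0.0):
            return True
        signs = np.sign(amps)
        if len(tms_comps) < 2 or np.any(signs == 0) or np.any(
            signs[:-1] * signs[1:] >= 0
        ):
            return False
        if truth.noise_sd > 0:
            amps = amps * (1.0 + truth.noise_sd * rng_trial.standard_normal())
        topo = tms_comps[0].topography
        if topo is None:
            topo = np.ones(n_ch)
        i0 = max(0, int(trial.tms_time_s * fs_hz))
        i1 = min(n_t, int((trial.tms_time_s + 0.02 + tms_comps[-1].latency_ms / 1000.0
                           + 0.15) * fs_hz) + 1)
        wave = _tep_complex(
            times[i0:i1], trial.tms_time_s,
            np.array([c.latency_ms for c in tms_comps]), amps,
        )
        data[:, i0:i1] += np.outer(topo, wave)
        return True

    for trial in schedule.trials:
        for comp in cue_comps:
            add_bump(trial, comp, trial.cue_onset_s + comp.latency_ms / 1000.0)
        if trial.tms_time_s is None:
            continue
        if not render_joint_complex(trial):
            for comp in tms_comps:
                add_bump(trial, comp, trial.tms_time_s + comp.latency_ms / 1000.0)

    # cardiac source: template train at the configured rate, fixed mixing
    beat_times = None
    if truth.cardiac_amp_uV > 0:
        template = _cardiac_template(fs_hz)
        source = np.zeros(n_t)
        beat_times = _beat_times(rng_card, duration_s, schedule, truth.heart_rate_bpm)
        for bt in beat_times:
            i0 = int(round(bt * fs_hz))
            seg = template[: max(0, min(len(template), n_t - i0))]
            source[i0 : i0 + len(seg)] += seg
        mixing_col = rng_mix.uniform(0.2, 1.0, size=n_ch) * rng_mix.choice(
            [-1.0, 1.0], size=n_ch
        )
        data += truth.cardiac_amp_uV * np.outer(mixing_col, source)

    # 50 Hz mains: common phase, per-channel gain
    if truth.line_noise_amp_uV > 0:
        gains = rng_mix.uniform(0.5, 1.0, size=n_ch)
        line = np.sin(2 * np.pi * 50.0 * times)
        data += truth.line_noise_amp_uV * np.outer(gains, line)

    # TMS pulse artifact: one-cycle biphasic transient, 8 ms
    if mode == "tms" and truth.tms_artifact_amp_uV > 0:
        art_len = int(round(0.008 * fs_hz)) + 1
        t_art = np.arange(art_len) / fs_hz
        artifact = np.sin(2 * np.pi * t_art / 0.008)
        gains = rng_mix.uniform(0.5, 1.5, size=n_ch)
        for pt in schedule.tms_times_s:
            i0 = int(round(pt * fs_hz))
            seg = artifact[: max(0, min(art_len, n_t - i0))]
            data[:, i0 : i0 + len(seg)] += truth.tms_artifact_amp_uV * np.outer(
                gains, seg
            )

    return RawRecording(data=data, fs_hz=fs_hz, schedule=schedule, layout=layout,
                        truth=truth, beat_times_s=beat_times)


def simulate_cohort_volumes(
    n_subjects: int,
    betas: dict[str, float],
    noise_sd: float,
    marker_values: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Structural volume table linearly coupled to a per-subject marker.

    Regions named in ``betas`` get ``typical + beta * marker + N(0, sd)``;
    all other regions are independent Gaussian noise around their typical
    volume. Returns one row per subject with the eight region columns
    plus a head-size scalar.
    """
    if n_subjects < 3:
        raise InvalidParameterError("need at least 3 subjects")
    marker_values = np.asarray(marker_values, dtype=float)
    if marker_values.shape != (n_subjects,):
        raise InvalidParameterError("one marker value per subject required")
    unknown = set(betas) - set(VOLUME_COLUMNS)
    if unknown:
        raise InvalidParameterError(f"unknown volume columns {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    table = {}
    for col in VOLUME_COLUMNS:
        base = _TYPICAL_VOLUME_MM3[col]
        vals = np.full(n_subjects, base, dtype=float)
        if col in betas:
            vals = vals + betas[col] * marker_values
        vals = vals + noise_sd * rng.standard_normal(n_subjects)
        table[col] = np.maximum(vals, 1.0)  # volumes are positive
    table["head_size"] = rng.normal(1500.0, 80.0, size=n_subjects)
    frame = pd.DataFrame(table)
    frame.index.name = "subject"
    return frame
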