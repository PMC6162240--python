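"""Continuous-EEG cleaning: TMS-artifact excision, line-noise and trend
removal, bad-channel handling, low-pass filtering, epoching and baseline
correction, and selection of the analysable trials.

The canonical order is excision -> line noise -> detrend -> bad channels
-> interpolation -> low-pass -> epoching; :func:`clean` applies it in one
call. Every operation preserves sampling rate, channel labels and event
times, and is deterministic for identical input and configuration.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from fearprobe.core import (
    EpochSet,
    InvalidParameterError,
    RawRecording,
    TrialSchedule,
)

logger = logging.getLogger(__name__)

__all__ = [
    "excise_tms_artifact",
    "remove_line_noise",
    "detrend",
    "detect_bad_channels",
    "interpolate_channels",
    "filter_lowpass",
    "epoch_and_baseline",
    "select_analysis_trials",
    "clean",
]


def excise_tms_artifact(
    rec: RawRecording,
    pre_ms: float = 5.0,
    post_ms: float = 20.0,
    method: str = "cubic",
    context_ms: float = 40.0,
) -> RawRecording:
    """Replace the pulse artifact window around every TMS event.

    Samples in ``[t - pre_ms, t + post_ms]`` (window edges rounded
    outward to whole samples, so the stated interval is always fully
    covered) are replaced by interpolated values: a least-squares cubic
    fitted through ``context_ms`` (default 40 ms, i.e. 10 samples at
    250 Hz) of data on each side of the gap, or a
    straight line between the gap endpoints (``method='linear'``).
    Output length and everything outside the windows are unchanged.
    """
    pulses = rec.schedule.tms_times_s
    if pulses.size == 0:
        return rec.copy_with(rec.data.copy())
    if method not in ("cubic", "linear"):
        raise InvalidParameterError("method must be 'cubic' or 'linear'")
    fs = rec.fs_hz
    gaps = np.diff(np.sort(pulses))
    window_s = (pre_ms + post_ms) / 1000.0
    if gaps.size and gaps.min() <= window_s:
        k = int(np.argmin(gaps))
        raise InvalidParameterError(
            f"excision window {window_s * 1000:.0f} ms exceeds the gap between "
            f"pulses {k} and {k + 1} ({gaps.min():.3f} s)"
        )
    data = rec.data.copy()
    n_t = data.shape[1]
    n_ctx = max(2, int(round(context_ms / 1000.0 * fs)))
    excised: list[tuple[int, int]] = []
    for t in pulses:
        i0 = int(np.floor((t - pre_ms / 1000.0) * fs))
        i1 = int(np.ceil((t + post_ms / 1000.0) * fs))
        i0, i1 = max(i0, 0), min(i1, n_t - 1)
        left = np.arange(max(0, i0 - n_ctx), i0)
        right = np.arange(i1 + 1, min(n_t, i1 + 1 + n_ctx))
        if left.size == 0 or right.size == 0:
            raise InvalidParameterError("pulse too close to recording edge")
        gap = np.arange(i0, i1 + 1)
        if method == "linear":
            x = np.array([i0 - 1, i1 + 1])
            y = data[:, x]
            frac = (gap - x[0]) / (x[1] - x[0])
            data[:, gap] = y[:, [0]] + (y[:, [1]] - y[:, [0]]) * frac
        else:
            # least-squares cubic through the context: smooth fill that
            # does not chase context noise (an interpolating spline
            # overshoots on noisy data)
            x = np.concatenate([left, right])
            x0 = x.mean()
            design = np.vander(x - x0, 4)
            coef, *_ = np.linalg.lstsq(design, data[:, x].T, rcond=None)
            data[:, gap] = (np.vander(gap - x0, 4) @ coef).T
        excised.append((int(i0), int(i1)))
    out = rec.copy_with(data)
    return out


def remove_line_noise(rec: RawRecording, freq_hz: float = 50.0, q: float = 30.0) -> RawRecording:
    """Zero-phase IIR notch at the mains frequency (default 50 Hz)."""
    if freq_hz >= rec.fs_hz / 2:
        raise InvalidParameterError("notch frequency must be below Nyquist")
    b, a = sps.iirnotch(freq_hz, Q=q, fs=rec.fs_hz)
    return rec.copy_with(sps.filtfilt(b, a, rec.data, axis=1))


def detrend(rec: RawRecording) -> RawRecording:
    """Remove each channel's linear trend (least-squares line)."""
    x = rec.data
    n = x.shape[1]
    t = np.arange(n) - (n - 1) / 2
    slope = (x @ t) / (t @ t)
    return rec.copy_with(x - x.mean(axis=1, keepdims=True) - np.outer(slope, t))


def _envelope(data: np.ndarray, fs_hz: float, window_s: float = 0.1) -> np.ndarray:
    """Rectified-signal amplitude envelope (moving average of |x|)."""
    n_win = max(1, int(round(window_s * fs_hz)))
    kernel = np.ones(n_win) / n_win
    pad = np.pad(np.abs(data), ((0, 0), (n_win // 2, n_win - 1 - n_win // 2)), "edge")
    csum = np.cumsum(pad, axis=1)
    out = (csum[:, n_win:] - csum[:, :-n_win]) / n_win
    lead = csum[:, n_win - 1 : n_win] / n_win
    return np.concatenate([lead, out], axis=1)


def detect_bad_channels(rec: RawRecording, z_thresh: float = 5.0) -> list[int]:
    """Channels with abnormally high sustained amplitude.

    An automated surrogate for visual inspection: each channel is scored
    by the median absolute deviation of its amplitude envelope
    (100 ms moving average of the rectified signal) across time, the
    scores are robustly z-scored across channels, and channels above
    ``z_thresh`` are flagged.
    """
    if rec.n_channels < 8:
        raise InvalidParameterError("need at least 8 channels")
    env = _envelope(rec.data, rec.fs_hz)[:, ::4]  # decimated: scores only
    med = np.median(env, axis=1, keepdims=True)
    score = np.median(np.abs(env - med), axis=1)
    center = np.median(score)
    mad = np.median(np.abs(score - center))
    scale = 1.4826 * mad if mad > 0 else 1.0
    z = (score - center) / scale
    bad = [int(i) for i in np.flatnonzero(z > z_thresh)]
    if len(bad) == rec.n_channels:
        raise InvalidParameterError("all channels flagged bad; data unusable")
    return bad


def interpolate_channels(rec: RawRecording, bad: list[int], k: int = 4) -> RawRecording:
    """Replace bad channels by inverse-distance-weighted neighbour means.

    Each bad channel becomes the weighted average of its ``k`` nearest
    good channels (weights 1/distance in 3D sensor space). Good channels
    are untouched; an empty list is the identity.
    """
    data = rec.data.copy()
    if not bad:
        return rec.copy_with(data)
    bad_set = set(bad)
    good = [i for i in range(rec.n_channels) if i not in bad_set]
    if not good:
        raise InvalidParameterError("no good channels left to interpolate from")
    pos = rec.layout.positions
    for b in bad:
        d = np.linalg.norm(pos[good] - pos[b], axis=1)
        order = np.argsort(d)[: min(k, len(good))]
        w = 1.0 / np.maximum(d[order], 1e-12)
        w /= w.sum()
        data[b] = w @ rec.data[np.asarray(good)[order]]
    return rec.copy_with(data)


def filter_lowpass(rec: RawRecording, cutoff_hz: float = 35.0, numtaps: int = 101) -> RawRecording:
    """Zero-phase low-pass (linear-phase FIR applied forward-backward).

    Default 35 Hz cut-off; a 1-30 Hz band-pass variant for TMS-EEG data
    is available via :func:`filter_bandpass`.
    """
    if cutoff_hz >= rec.fs_hz / 2:
        raise InvalidParameterError("cutoff must be below Nyquist")
    taps = sps.firwin(numtaps, cutoff_hz, fs=rec.fs_hz)
    return rec.copy_with(sps.filtfilt(taps, [1.0], rec.data, axis=1))


def filter_bandpass(
    rec: RawRecording, low_hz: float = 1.0, high_hz: float = 30.0, numtaps: int = 401
) -> RawRecording:
    """Zero-phase FIR band-pass (default 1-30 Hz)."""
    if not 0 < low_hz < high_hz < rec.fs_hz / 2:
        raise InvalidParameterError("band edges must satisfy 0 < low < high < Nyquist")
    taps = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=rec.fs_hz)
    return rec.copy_with(sps.filtfilt(taps, [1.0], rec.data, axis=1))


def epoch_and_baseline(
    rec: RawRecording,
    schedule: TrialSchedule | None = None,
    window_ms: tuple[float, float] = (-500.0, 2000.0),
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
) -> EpochSet:
    """Cut cue-locked epochs and subtract the pre-cue baseline mean.

    The baseline interval is half-open ``[-500, 0)`` ms relative to cue
    onset. Trials whose window does not fit inside the recording are
    dropped with a warning.
    """
    schedule = schedule or rec.schedule
    fs = rec.fs_hz
    lo, hi = window_ms
    if hi <= lo:
        raise InvalidParameterError("empty epoch window")
    i_lo = int(np.round(lo / 1000.0 * fs))
    i_hi = int(np.round(hi / 1000.0 * fs))
    times_ms = np.arange(i_lo, i_hi + 1) / fs * 1000.0
    b_mask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])

    epochs, conds, us = [], [], []
    for k, trial in enumerate(schedule.trials):
        onset = int(np.round(trial.cue_onset_s * fs))
        a, b = onset + i_lo, onset + i_hi
        if a < 0 or b >= rec.n_samples:
            logger.warning("trial %d at %.2f s too close to recording edge; dropped",
                           k, trial.cue_onset_s)
            continue
        ep = rec.data[:, a : b + 1].copy()
        if b_mask.any():
            ep -= ep[:, b_mask].mean(axis=1, keepdims=True)
        epochs.append(ep)
        conds.append(trial.condition)
        us.append(trial.us_paired)
    if not epochs:
        raise InvalidParameterError("no trial fits inside the recording")
    return EpochSet(
        data=np.stack(epochs),
        times_ms=times_ms,
        conditions=np.array(conds),
        us_paired=np.array(us, dtype=bool),
        fs_hz=fs,
        layout=rec.layout,
        provenance={"window_ms": list(window_ms), "baseline_ms": list(baseline_ms)},
    )


def select_analysis_trials(epochs: EpochSet) -> EpochSet:
    """Drop US-paired CS+ epochs; relabel CS+ -> T and CS- -> NT.

    The shocked CS+ trials are contaminated by the electrodermal
    stimulus and are excluded, leaving the threat (T) epochs as CS+
    without US and the no-threat (NT) epochs as all CS-.
    """
    keep = ~epochs.us_paired
    out = epochs.select(keep, us_removed=int((~keep).sum()))
    mapping = {"CSplus": "T", "CSminus": "NT"}
    out.conditions = np.array([mapping.get(c, c) for c in out.conditions])
    if not np.any(out.conditions == "T"):
        logger.warning("no threat epochs remain after US removal")
    return out


def clean(
    rec: RawRecording,
    excise: bool = True,
    line_freq_hz: float = 50.0,
    z_thresh: float = 5.0,
    cutoff_hz: float = 35.0,
    lowpass: bool = True,
) -> RawRecording:
    """Full continuous-data cleaning chain in the canonical order."""
    out = rec
    if excise and rec.schedule.has_tms:
        out = excise_tms_artifact(out)
    out = remove_line_noise(out, line_freq_hz)
    out = detrend(out)
    bad = detect_bad_channels(out, z_thresh) if out.n_channels >= 8 else []
    out = interpolate_channels(out, bad)
    if lowpass:
        out = filter_lowpass(out, cutoff_hz)
    return out
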