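"""Evoked-potential averaging, peak detection/labelling and excitability
markers.

Peaks are local extrema of the averaged waveform in which a configurable
number of samples on *both* sides (default 3 samples = 12 ms at 250 Hz)
have strictly smaller values (positive peaks) or strictly larger values
(negative deflections, reported with signed amplitude). Cue-locked
components are detected in the 0-1000 ms window (ERP152, LPP) and
TMS-locked components in the 1000-2000 ms window (TEP1..TEP6).

The excitability-to-threat marker of a labelled component is the
threat-minus-no-threat (T-NT) amplitude difference; peak-to-peak
measures difference the amplitudes of consecutive labelled components.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fearprobe.core import (
    EpochSet,
    EvokedWaveform,
    InvalidParameterError,
    Peak,
    PeakSet,
    SensorLayout,
    SnrResult,
    REGIONS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "average_evoked",
    "detect_peaks",
    "label_peaks",
    "add_anchor_points",
    "tnt_markers",
    "peak_to_peak",
    "tnt_peak_to_peak",
    "regional_average",
    "compute_snr",
    "select_marker_channel",
]

#: Default labelling windows (ms post-cue): first candidate window for the
#: early component, and the sustained late-positivity window.
ERP152_WINDOW_MS = (100.0, 250.0)
LPP_WINDOW_MS = (300.0, 1000.0)


def average_evoked(epochs: EpochSet, condition: str) -> EvokedWaveform:
    """Arithmetic mean of one condition's epochs (channels x time)."""
    mask = epochs.conditions == condition
    n = int(mask.sum())
    if n == 0:
        raise InvalidParameterError(f"no epochs with condition {condition!r}")
    return EvokedWaveform(
        condition=condition,
        values=epochs.data[mask].mean(axis=0),
        times_ms=epochs.times_ms,
        n_trials=n,
        row_labels=list(epochs.layout.labels),
        kind="channels",
    )


def _parabolic_refine(v: np.ndarray, i: int, times: np.ndarray) -> tuple[float, float]:
    """Sub-sample apex estimate from a 3-point parabola around sample i."""
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(times[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = times[i + 1] - times[i] if delta >= 0 else times[i] - times[i - 1]
    lat = float(times[i] + delta * dt)
    amp = float(y1 - 0.25 * (y0 - y2) * delta)
    return lat, amp


def detect_peaks(
    wave: EvokedWaveform,
    window_ms: tuple[float, float],
    min_flank_points: int = 3,
    channels: list[str] | None = None,
    refine: bool = True,
) -> PeakSet:
    """All local extrema in the window satisfying the flank criterion.

    A sample is a positive peak when the ``min_flank_points`` samples on
    each side all have strictly smaller values, and a negative peak when
    they all have strictly larger values; negative peaks are reported
    with their signed (negative) amplitude. Ties (plateaus) do not
    qualify (strict inequality); flank samples are taken from the full
    waveform, so candidates must have full flanks available.

    With ``refine=True`` latency and amplitude are refined by a 3-point
    parabolic fit around the apex (sub-sample resolution); ``refine=
    False`` reports the sample grid values.
    """
    lo, hi = window_ms
    t = wave.times_ms
    in_win = (t >= lo) & (t <= hi)
    dt = np.median(np.diff(t))
    if in_win.sum() < 2 * min_flank_points + 1:
        raise InvalidParameterError(
            f"window [{lo}, {hi}] ms holds {int(in_win.sum())} samples; "
            f"need at least {2 * min_flank_points + 1}"
        )
    rows = range(len(wave.row_labels)) if channels is None else [
        wave.row_labels.index(c) for c in channels
    ]
    peaks: list[Peak] = []
    f = min_flank_points
    n = len(t)
    for r in rows:
        v = wave.values[r]
        for i in np.flatnonzero(in_win):
            if i < f or i > n - 1 - f:
                continue
            left, right = v[i - f : i], v[i + 1 : i + 1 + f]
            is_max = np.all(left < v[i]) and np.all(right < v[i])
            is_min = np.all(left > v[i]) and np.all(right > v[i])
            if not (is_max or is_min):
                continue
            if refine:
                lat, amp = _parabolic_refine(v, i, t)
            else:
                lat, amp = float(t[i]), float(v[i])
            peaks.append(
                Peak(label="unlabelled", latency_ms=lat, amplitude_uV=amp,
                     channel=wave.row_labels[r])
            )
    peaks.sort(key=lambda p: p.latency_ms)
    return PeakSet(peaks=peaks, condition=wave.condition)


def label_peaks(
    peaks: PeakSet,
    scheme: str,
    tms_time_ms: float = 1000.0,
    min_amplitude_uV: float = 0.0,
    erp152_window_ms: tuple[float, float] = ERP152_WINDOW_MS,
    lpp_window_ms: tuple[float, float] = LPP_WINDOW_MS,
    n_tep: int = 6,
) -> PeakSet:
    """Assign component labels; unmatched peaks stay unlabelled.

    ERP scheme: the first positive peak above ``min_amplitude_uV`` in the
    early candidate window becomes ``ERP152``, and the largest positive
    peak in the late window becomes ``LPP``. TEP scheme: up to ``n_tep``
    successive supra-threshold peaks after ``tms_time_ms`` become
    ``TEP1``..``TEP6`` in latency order (their latency relative to the
    pulse is ``latency_ms - tms_time_ms``).
    """
    if scheme not in ("erp", "tep"):
        raise InvalidParameterError("scheme must be 'erp' or 'tep'")
    labels = {}
    if scheme == "erp":
        early = [
            p for p in peaks
            if erp152_window_ms[0] <= p.latency_ms <= erp152_window_ms[1]
            and p.amplitude_uV > min_amplitude_uV
        ]
        if early:
            labels[min(early, key=lambda p: p.latency_ms)] = "ERP152"
        late = [
            p for p in peaks
            if lpp_window_ms[0] <= p.latency_ms <= lpp_window_ms[1]
            and p.amplitude_uV > min_amplitude_uV
        ]
        if late:
            labels[max(late, key=lambda p: p.amplitude_uV)] = "LPP"
    else:
        post = sorted(
            (
                p for p in peaks
                if p.latency_ms > tms_time_ms
                and abs(p.amplitude_uV) > min_amplitude_uV
            ),
            key=lambda p: p.latency_ms,
        )
        for k, p in enumerate(post[:n_tep]):
            labels[p] = f"TEP{k + 1}"
    out = [
        Peak(label=labels.get(p, p.label), latency_ms=p.latency_ms,
             amplitude_uV=p.amplitude_uV, channel=p.channel)
        for p in peaks
    ]
    return PeakSet(peaks=out, condition=peaks.condition)


def add_anchor_points(
    peaks: PeakSet, wave: EvokedWaveform, channel: str, tms_time_ms: float | None = 1000.0
) -> PeakSet:
    """Append 'Cue' (0 ms) and 'TMS' (pulse time) waveform samples.

    The peak-to-peak sequence starts at cue onset and passes through the
    pulse time; neither is a detected peak, so their waveform amplitudes
    are added as pseudo-peaks.
    """
    r = wave.row_labels.index(channel)
    anchors = [("Cue", 0.0)]
    if tms_time_ms is not None:
        anchors.append(("TMS", float(tms_time_ms)))
    extra = []
    for label, t0 in anchors:
        i = int(np.argmin(np.abs(wave.times_ms - t0)))
        extra.append(
            Peak(label=label, latency_ms=float(wave.times_ms[i]),
                 amplitude_uV=float(wave.values[r, i]), channel=channel)
        )
    merged = sorted(peaks.peaks + extra, key=lambda p: p.latency_ms)
    return PeakSet(peaks=merged, condition=peaks.condition)


def _display_name(peak: Peak, tms_time_ms: float = 1000.0) -> str:
    """Table-style component name: Cue -> '0', TEPk -> 'TEP<latency>'."""
    if peak.label == "Cue":
        return "0"
    if peak.label.startswith("TEP"):
        return f"TEP{int(round(peak.latency_ms - tms_time_ms))}"
    return peak.label


#: Canonical component order for marker tables and peak-to-peak pairs.
COMPONENT_ORDER = ("Cue", "ERP152", "LPP", "TMS",
                   "TEP1", "TEP2", "TEP3", "TEP4", "TEP5", "TEP6")


def tnt_markers(peaks_t: PeakSet, peaks_nt: PeakSet) -> pd.DataFrame:
    """Threat-minus-no-threat amplitude per matched labelled component."""
    lab_t, lab_nt = peaks_t.labelled(), peaks_nt.labelled()
    rows = []
    for label in COMPONENT_ORDER:
        if label in lab_t and label in lab_nt:
            pt, pn = lab_t[label], lab_nt[label]
            rows.append(
                {
                    "label": label,
                    "component": _display_name(pt),
                    "amplitude_T_uV": pt.amplitude_uV,
                    "amplitude_NT_uV": pn.amplitude_uV,
                    "marker_uV": pt.amplitude_uV - pn.amplitude_uV,
                    "latency_T_ms": pt.latency_ms,
                    "latency_NT_ms": pn.latency_ms,
                }
            )
        elif label in lab_t or label in lab_nt:
            logger.warning("component %s present in only one condition; marker skipped",
                           label)
    return pd.DataFrame(rows)


def peak_to_peak(
    peaks: PeakSet, pairs: list[tuple[str, str]] | None = None,
    tms_time_ms: float = 1000.0,
) -> pd.DataFrame:
    """Signed amplitude difference between consecutive labelled components.

    Default pairs are the consecutive present members of the canonical
    sequence 0 -> ERP152 -> LPP -> TMS -> TEP1 -> ... -> TEP6, named in
    table style ('ERP152-to-LPP', 'TMS-to-TEP41', ...).
    """
    lab = peaks.labelled()
    if pairs is None:
        present = [c for c in COMPONENT_ORDER if c in lab]
        pairs = list(zip(present, present[1:]))
    rows = []
    for a, b in pairs:
        if a not in lab or b not in lab:
            logger.warning("pair (%s, %s) incomplete; skipped", a, b)
            continue
        pa, pb = lab[a], lab[b]
        rows.append(
            {
                "pair": f"{_display_name(pa, tms_time_ms)}-to-"
                        f"{_display_name(pb, tms_time_ms)}",
                "pair_labels": f"{a}-to-{b}",
                "value_uV": pb.amplitude_uV - pa.amplitude_uV,
            }
        )
    return pd.DataFrame(rows)


def tnt_peak_to_peak(pp_t: pd.DataFrame, pp_nt: pd.DataFrame) -> pd.DataFrame:
    """T-NT difference of matching peak-to-peak measures.

    Pairs are matched on their canonical labels (``TMS-to-TEP1``), not on
    the latency-derived display names, which vary with measured latency.
    """
    merged = pp_t.merge(pp_nt, on="pair_labels", suffixes=("_T", "_NT"))
    merged["marker_uV"] = merged["value_uV_T"] - merged["value_uV_NT"]
    merged = merged.rename(columns={"pair_T": "pair"})
    return merged


def regional_average(wave: EvokedWaveform, layout: SensorLayout) -> EvokedWaveform:
    """Unweighted mean of each scalp region's member channels."""
    if wave.kind != "channels":
        raise InvalidParameterError("regional_average expects a channel waveform")
    values = np.vstack(
        [wave.values[layout.region_channels(region)].mean(axis=0) for region in REGIONS]
    )
    return EvokedWaveform(
        condition=wave.condition, values=values, times_ms=wave.times_ms,
        n_trials=wave.n_trials, row_labels=list(REGIONS), kind="regions",
    )


def compute_snr(
    obj: EvokedWaveform | EpochSet,
    signal_window_ms: tuple[float, float],
    baseline_window_ms: tuple[float, float],
    method: str = "mean_abs",
) -> SnrResult:
    """Evoked SNR in dB: ``20 * log10(TL_signal / TL_noise)``.

    ``TL_signal`` is the mean activity in a 500 ms window containing the
    evoked waves and ``TL_noise`` the mean activity at baseline; "mean
    activity" is the mean absolute amplitude over channels and samples
    (``method='rms'`` uses the root mean square instead). The ratio is
    invariant to global positive rescaling and may be negative in dB
    when the evoked activity sits below the baseline level.
    """
    if method not in ("mean_abs", "rms"):
        raise InvalidParameterError("method must be 'mean_abs' or 'rms'")
    if isinstance(obj, EpochSet):
        values, times = obj.data.mean(axis=0), obj.times_ms
    else:
        values, times = obj.values, obj.times_ms
    lo, hi = signal_window_ms
    if not np.isclose(hi - lo, 500.0):
        raise InvalidParameterError("signal window must be 500 ms long")
    sig = values[:, (times >= lo) & (times <= hi)]
    base = values[:, (times >= baseline_window_ms[0]) & (times < baseline_window_ms[1])]
    if sig.size == 0 or base.size == 0:
        raise InvalidParameterError("empty SNR window")
    if method == "mean_abs":
        tl_signal, tl_noise = float(np.mean(np.abs(sig))), float(np.mean(np.abs(base)))
    else:
        tl_signal = float(np.sqrt(np.mean(sig**2)))
        tl_noise = float(np.sqrt(np.mean(base**2)))
    if tl_noise == 0:
        raise InvalidParameterError("zero baseline activity; SNR undefined")
    return SnrResult(
        snr_db=float(20.0 * np.log10(tl_signal / tl_noise)),
        tl_signal=tl_signal, tl_noise=tl_noise,
        signal_window_ms=(lo, hi), baseline_window_ms=tuple(baseline_window_ms),
    )


def select_marker_channel(
    wave_t: EvokedWaveform, wave_nt: EvokedWaveform,
    window_ms: tuple[float, float] | None = None,
    mode: str = "grand_average",
) -> str:
    """Sensor at which marker amplitudes are measured.

    ``grand_average`` (default) picks the channel where the
    condition-average waveform is largest in the window — the standard
    electrode-of-interest choice, stable even for components without a
    condition effect. ``difference`` picks the channel with the largest
    absolute T-NT difference instead (meaningful only where an effect
    exists; with a null effect it follows noise).
    """
    if mode == "difference":
        target = wave_t.values - wave_nt.values
    elif mode == "grand_average":
        target = 0.5 * (wave_t.values + wave_nt.values)
    else:
        raise InvalidParameterError("mode must be 'grand_average' or 'difference'")
    t = wave_t.times_ms
    if window_ms is not None:
        target = target[:, (t >= window_ms[0]) & (t <= window_ms[1])]
    r = int(np.argmax(np.max(np.abs(target), axis=1)))
    return wave_t.row_labels[r]
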