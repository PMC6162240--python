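"""Core data containers shared across the analysis chain.

All amplitudes are in microvolts, all times in seconds (continuous data)
or milliseconds (epoch/evoked time axes, relative to cue onset with
negative values pre-cue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Scalp regions used for regional averaging.
REGIONS = ("frontal", "dmPFC", "occipital", "central", "parietal", "temporal")

#: Condition labels on the trial schedule.
CONDITIONS = ("CSplus", "CSminus")

#: Analysis labels after US-trial removal: threat / no-threat.
THREAT, NO_THREAT = "T", "NT"


class InvalidParameterError(ValueError):
    """A caller-supplied parameter is outside its valid domain."""


@dataclass(frozen=True)
class Trial:
    """One cue presentation.

    ``iti_s`` is the inter-stimulus gap *following* this trial's cue
    offset. ``tms_time_s`` is absent (None) in no-TMS recordings.
    """

    condition: str
    us_paired: bool
    cue_onset_s: float
    cue_duration_s: float
    iti_s: float
    tms_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(f"unknown condition {self.condition!r}")
        if self.us_paired and self.condition != "CSplus":
            raise InvalidParameterError("us_paired requires condition CSplus")


@dataclass
class TrialSchedule:
    """Ordered trial list for one experimental session."""

    trials: list[Trial]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_csplus(self) -> int:
        return sum(t.condition == "CSplus" for t in self.trials)

    @property
    def n_csminus(self) -> int:
        return sum(t.condition == "CSminus" for t in self.trials)

    @property
    def n_us(self) -> int:
        return sum(t.us_paired for t in self.trials)

    @property
    def has_tms(self) -> bool:
        return all(t.tms_time_s is not None for t in self.trials)

    @property
    def tms_times_s(self) -> np.ndarray:
        return np.array([t.tms_time_s for t in self.trials if t.tms_time_s is not None])

    @property
    def duration_s(self) -> float:
        """End of the last trial's ITI, i.e. minimum recording length."""
        last = self.trials[-1]
        return last.cue_onset_s + last.cue_duration_s + last.iti_s

    def validate(self) -> None:
        onsets = [t.cue_onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidParameterError("cue onsets must be strictly increasing")
        for a, b in zip(self.trials, self.trials[1:]):
            gap = b.cue_onset_s - (a.cue_onset_s + a.cue_duration_s)
            if not np.isclose(gap, a.iti_s):
                raise InvalidParameterError("gap between trials must equal iti_s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [t.cue_onset_s for t in self.trials],
                "duration_s": [t.cue_duration_s for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "us_paired": [t.us_paired for t in self.trials],
                "iti_s": [t.iti_s for t in self.trials],
                "tms_time_s": [
                    np.nan if t.tms_time_s is None else t.tms_time_s for t in self.trials
                ],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSchedule":
        trials = [
            Trial(
                condition=row.condition,
                us_paired=bool(row.us_paired),
                cue_onset_s=float(row.onset_s),
                cue_duration_s=float(row.duration_s),
                iti_s=float(row.iti_s),
                tms_time_s=None if pd.isna(row.tms_time_s) else float(row.tms_time_s),
            )
            for row in frame.itertuples()
        ]
        return cls(trials)


@dataclass
class SensorLayout:
    """Electrode labels, 3D positions (head units) and scalp regions."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3)
    regions: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise InvalidParameterError("channel labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise InvalidParameterError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        bad = set(self.regions) - set(REGIONS)
        if bad:
            raise InvalidParameterError(f"unknown regions {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def region_channels(self, region: str) -> np.ndarray:
        """Indices of the channels belonging to ``region``."""
        return np.flatnonzero(np.asarray(self.regions) == region)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "region": self.regions,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SensorLayout":
        return cls(
            labels=list(frame["label"]),
            positions=frame[["x", "y", "z"]].to_numpy(float),
            regions=list(frame["region"]),
        )


@dataclass
class EvokedComponent:
    """One injected evoked deflection (ground truth for the simulator).

    ``latency_ms`` is relative to cue onset for ``reference='cue'`` and
    relative to the TMS pulse for ``reference='tms'``. ``amplitude_uV``
    maps condition -> peak amplitude. ``topography`` holds per-channel
    projection weights (max 1); None means "fill in from layout".
    """

    name: str
    latency_ms: float
    reference: str  # "cue" | "tms"
    width_ms: float
    amplitude_uV: dict[str, float]
    topography: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.reference not in ("cue", "tms"):
            raise InvalidParameterError("reference must be 'cue' or 'tms'")
        if not all(np.isfinite(list(self.amplitude_uV.values()))):
            raise InvalidParameterError("amplitudes must be finite")


@dataclass
class GroundTruth:
    """Everything the simulator injects, kept retrievable for testing."""

    components: list[EvokedComponent]
    heart_rate_bpm: dict[str, float]  # keys: baseline, CSplus, CSminus
    cardiac_amp_uV: float = 30.0
    line_noise_amp_uV: float = 5.0
    background_amp_uV: float = 10.0
    background_exponent: float = 1.0
    background_rank: int | None = None  # shared 1/f sources; None = n_channels // 2
    tms_artifact_amp_uV: float = 2000.0
    noise_sd: float = 0.0  # trial-to-trial amplitude jitter (fraction)

    def __post_init__(self) -> None:
        for bpm in self.heart_rate_bpm.values():
            if not 40.0 <= bpm <= 140.0:
                raise InvalidParameterError("heart_rate_bpm must lie in [40, 140]")
        for comp in self.components:
            lo, hi = (0.0, 1000.0) if comp.reference == "cue" else (0.0, 1000.0)
            if not lo <= comp.latency_ms <= hi:
                raise InvalidParameterError(
                    f"component {comp.name}: latency {comp.latency_ms} ms outside "
                    f"its detection window [{lo}, {hi}] ms"
                )


@dataclass
class RawRecording:
    """Continuous multichannel EEG with events and sensor layout."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs_hz: float
    schedule: TrialSchedule
    layout: SensorLayout
    truth: GroundTruth | None = None
    beat_times_s: np.ndarray | None = None  # injected cardiac beats (simulations)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != self.layout.n_channels:
            raise InvalidParameterError("data rows must match layout channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        return RawRecording(
            data=data, fs_hz=self.fs_hz, schedule=self.schedule,
            layout=self.layout, truth=self.truth, beat_times_s=self.beat_times_s,
        )


@dataclass
class EpochSet:
    """Trials x channels x samples, on a shared time axis relative to cue.

    ``conditions`` holds CSplus/CSminus straight after epoching and the
    analysis labels T/NT after US-trial removal.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_times)
    times_ms: np.ndarray
    conditions: np.ndarray  # str per epoch
    us_paired: np.ndarray  # bool per epoch
    fs_hz: float
    layout: SensorLayout
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.conditions = np.asarray(self.conditions)
        self.us_paired = np.asarray(self.us_paired, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray, **provenance) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            times_ms=self.times_ms,
            conditions=self.conditions[mask],
            us_paired=self.us_paired[mask],
            fs_hz=self.fs_hz,
            layout=self.layout,
            provenance={**self.provenance, **provenance},
        )


@dataclass
class EvokedWaveform:
    """Per-condition averaged waveform, channels (or regions) x time."""

    condition: str
    values: np.ndarray  # (n_rows, n_times), microvolts
    times_ms: np.ndarray
    n_trials: int
    row_labels: list[str]
    kind: str = "channels"  # "channels" | "regions"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")
        if self.values.shape != (len(self.row_labels), len(self.times_ms)):
            raise InvalidParameterError("values shape must match labels x times")


@dataclass(frozen=True)
class Peak:
    """One detected deflection: signed amplitude at a local extremum."""

    label: str  # "ERP152", "LPP", "TEP1".."TEP6", "Cue", "TMS" or "unlabelled"
    latency_ms: float
    amplitude_uV: float
    channel: str


@dataclass
class PeakSet:
    """Peaks detected on one evoked waveform."""

    peaks: list[Peak]
    condition: str

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def labelled(self) -> dict[str, Peak]:
        return {p.label: p for p in self.peaks if p.label != "unlabelled"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "label": [p.label for p in self.peaks],
                "latency_ms": [p.latency_ms for p in self.peaks],
                "amplitude_uV": [p.amplitude_uV for p in self.peaks],
                "channel": [p.channel for p in self.peaks],
            }
        )


@dataclass
class SnrResult:
    """Evoked-potential SNR, 20*log10(TL_signal / TL_noise) in dB."""

    snr_db: float
    tl_signal: float
    tl_noise: float
    signal_window_ms: tuple[float, float]
    baseline_window_ms: tuple[float, float]


@dataclass
class ICADecomposition:
    """Result of extended-infomax ICA on channels x time data.

    ``unmixing`` maps (centred) channel data to component activations,
    v = unmixing @ (y - mean); ``mixing`` is its (pseudo)inverse, whose
    columns give each component's projection onto the sensors.
    """

    unmixing: np.ndarray  # (n_components, n_channels)
    mixing: np.ndarray  # (n_channels, n_components)
    mean: np.ndarray  # (n_channels,)
    activations: np.ndarray  # (n_components, n_times)
    cardiac_rows: list[int] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    final_delta: float = np.nan

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


@dataclass
class HeartRateEstimate:
    """Heart rate recovered from concatenated condition trials."""

    condition: str
    bpm: float
    n_beats: int
    duration_s: float
    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.n_beats >= 2:
            span = self.beat_times_s[-1] - self.beat_times_s[0]
            implied = 60.0 * (self.n_beats - 1) / span
            if not np.isclose(implied, self.bpm, rtol=1e-6):
                raise InvalidParameterError("bpm inconsistent with beat times")


#: Column order of the structural volume table (mm^3, head-size corrected).
VOLUME_COLUMNS = (
    "lh_dmPFC", "rh_dmPFC",
    "lh_insula", "rh_insula",
    "lh_amygdala", "rh_amygdala",
    "lh_hippocampus", "rh_hippocampus",
)
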