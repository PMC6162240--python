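"""Reading and writing the package's on-disk formats.

Continuous recordings go to EDF (16-bit European Data Format, one data
record per second), written by a small built-in writer and read back
through :func:`mne.io.read_raw_edf`. Trial schedules, sensor layouts,
volume tables and marker tables are tab-separated text; ground truth and
epoch metadata are JSON; epoch arrays are stored as ``.npy`` with a JSON
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fearprobe.core import (
    EpochSet,
    EvokedComponent,
    GroundTruth,
    InvalidParameterError,
    RawRecording,
    SensorLayout,
    TrialSchedule,
)

__all__ = [
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
    "write_layout_tsv",
    "read_layout_tsv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "save_epochs",
    "load_epochs",
]


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1 s data records.

    The sampling rate must be a whole number of samples per second. The
    last record is zero-padded; physical scaling is per channel from the
    data range.
    """
    path = Path(path)
    fs = rec.fs_hz
    spr = int(round(fs))
    if not np.isclose(fs, spr):
        raise InvalidParameterError("EDF writer needs an integer sampling rate")
    n_ch, n_t = rec.data.shape
    n_rec = int(np.ceil(n_t / spr))

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min < 1e-9
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    header = bytearray()
    header += _pad_ascii("0", 8)
    header += _pad_ascii("X X X X", 80)
    header += _pad_ascii("Startdate X X X X", 80)
    header += _pad_ascii("01.01.00", 8)
    header += _pad_ascii("00.00.00", 8)
    header += _pad_ascii(str(256 + 256 * n_ch), 8)
    header += _pad_ascii("", 44)
    header += _pad_ascii(str(n_rec), 8)
    header += _pad_ascii("1", 8)
    header += _pad_ascii(str(n_ch), 4)

    def field(values, width):
        return b"".join(_pad_ascii(str(v), width) for v in values)

    header += field(rec.layout.labels, 16)
    header += field([""] * n_ch, 80)
    header += field(["uV"] * n_ch, 8)
    header += field([f"{v:.7g}"[:8] for v in phys_min], 8)
    header += field([f"{v:.7g}"[:8] for v in phys_max], 8)
    header += field([dig_min] * n_ch, 8)
    header += field([dig_max] * n_ch, 8)
    header += field([""] * n_ch, 80)
    header += field([spr] * n_ch, 8)
    header += field([""] * n_ch, 32)

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_t] = rec.data
    digital = np.round(
        (padded - phys_min[:, None]) / scale[:, None] + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(
    path: str | Path,
    schedule: TrialSchedule | None = None,
    layout: SensorLayout | None = None,
) -> RawRecording:
    """Read an EDF file into a RawRecording (via mne).

    EDF does not carry the trial schedule or 3D sensor layout, so these
    are supplied separately (typically from the events/layout TSVs).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    fs = float(raw.info["sfreq"])
    if layout is None:
        # minimal layout: labels from the file, positions unknown
        n = data.shape[0]
        from fearprobe.synth import generate_sensor_layout

        layout = generate_sensor_layout(max(n, 6), seed=0)
        layout = SensorLayout(
            labels=list(raw.ch_names), positions=layout.positions[:n],
            regions=layout.regions[:n],
        )
    if schedule is None:
        schedule = TrialSchedule(trials=[])
    return RawRecording(data=data, fs_hz=fs, schedule=schedule, layout=layout)


def write_events_tsv(schedule: TrialSchedule, path: str | Path) -> Path:
    path = Path(path)
    schedule.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> TrialSchedule:
    return TrialSchedule.from_frame(pd.read_csv(path, sep="\t"))


def write_layout_tsv(layout: SensorLayout, path: str | Path) -> Path:
    path = Path(path)
    layout.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_layout_tsv(path: str | Path) -> SensorLayout:
    return SensorLayout.from_frame(pd.read_csv(path, sep="\t"))


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "components": [
            {
                "name": c.name,
                "latency_ms": c.latency_ms,
                "reference": c.reference,
                "width_ms": c.width_ms,
                "amplitude_uV": c.amplitude_uV,
                "topography": None if c.topography is None else list(
                    np.asarray(c.topography, float)
                ),
            }
            for c in truth.components
        ],
        "heart_rate_bpm": truth.heart_rate_bpm,
        "cardiac_amp_uV": truth.cardiac_amp_uV,
        "line_noise_amp_uV": truth.line_noise_amp_uV,
        "background_amp_uV": truth.background_amp_uV,
        "background_exponent": truth.background_exponent,
        "tms_artifact_amp_uV": truth.tms_artifact_amp_uV,
        "noise_sd": truth.noise_sd,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    components = [
        EvokedComponent(
            name=c["name"], latency_ms=c["latency_ms"], reference=c["reference"],
            width_ms=c["width_ms"], amplitude_uV=c["amplitude_uV"],
            topography=None if c["topography"] is None else np.asarray(c["topography"]),
        )
        for c in payload.pop("components")
    ]
    return GroundTruth(components=components, **payload)


def save_epochs(epochs: EpochSet, directory: str | Path, stem: str = "epochs") -> Path:
    """Epoch array as .npy plus a JSON sidecar with axes and labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{stem}.npy", epochs.data)
    sidecar = {
        "times_ms": list(epochs.times_ms),
        "conditions": list(map(str, epochs.conditions)),
        "us_paired": list(map(bool, epochs.us_paired)),
        "fs_hz": epochs.fs_hz,
        "provenance": epochs.provenance,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar))
    write_layout_tsv(epochs.layout, directory / f"{stem}_layout.tsv")
    return directory / f"{stem}.npy"


def load_epochs(directory: str | Path, stem: str = "epochs") -> EpochSet:
    directory = Path(directory)
    data = np.load(directory / f"{stem}.npy")
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    layout = read_layout_tsv(directory / f"{stem}_layout.tsv")
    return EpochSet(
        data=data,
        times_ms=np.asarray(sidecar["times_ms"]),
        conditions=np.asarray(sidecar["conditions"]),
        us_paired=np.asarray(sidecar["us_paired"], dtype=bool),
        fs_hz=sidecar["fs_hz"],
        layout=layout,
        provenance=sidecar.get("provenance", {}),
    )
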