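"""File I/O: EDF signals, CSV sidecars and the plain-text pipeline config.

EDF is the open interchange format for the one-channel 512-Hz traces (the
acquisition software used in vivo writes a proprietary format, so EDF is
the portable stand-in); CSV is the escape hatch for tests and for all
tabular artifacts (ground truth, stimulation logs, events, pairs,
features, reports).

The EDF writer is a minimal single-channel implementation of the EDF
specification (16-bit samples, 1-s data records); reading goes through
:mod:`mne`, which serves as an independent check of the writer in the
round-trip tests.  Recordings are padded with zeros to a whole number of
1-s records on write.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    EcogRecording,
    GroundTruth,
    SeizureEvent,
    StateLabel,
    StimulationEvent,
)

__all__ = [
    "read_ecog",
    "write_ecog",
    "write_edf",
    "read_edf",
    "write_csv_recording",
    "read_csv_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_stim_log",
    "read_stim_log",
    "write_events",
    "read_events",
    "PipelineConfig",
]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EcogRecording, path) -> None:
    """Write a single-channel EDF file (physical dimension uV).

    The sampling rate must be a whole number of samples per 1-s record;
    the trace is zero-padded to complete the final record.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    fs = int(round(fs))
    x = recording.samples
    n_records = int(np.ceil(len(x) / fs)) if len(x) else 1
    padded = np.zeros(n_records * fs)
    padded[: len(x)] = x
    phys_min = float(min(padded.min(), -1.0))
    phys_max = float(max(padded.max(), 1.0))
    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    dig = np.round((padded - phys_min) * gain + _EDF_DIG_MIN).astype("<i2")

    hdr = _io.BytesIO()
    hdr.write(_pad_ascii("0", 8))
    hdr.write(_pad_ascii(recording.animal_id, 80))
    hdr.write(_pad_ascii("ictaloop synthetic ECoG", 80))
    hdr.write(_pad_ascii("01.01.00", 8))
    hdr.write(_pad_ascii("00.00.00", 8))
    hdr.write(_pad_ascii(256 * 2, 8))
    hdr.write(_pad_ascii("", 44))
    hdr.write(_pad_ascii(n_records, 8))
    hdr.write(_pad_ascii(1, 8))
    hdr.write(_pad_ascii(1, 4))
    hdr.write(_pad_ascii("ECoG", 16))
    hdr.write(_pad_ascii("synthetic", 80))
    hdr.write(_pad_ascii("uV", 8))
    hdr.write(_pad_ascii(f"{phys_min:.6g}"[:8], 8))
    hdr.write(_pad_ascii(f"{phys_max:.6g}"[:8], 8))
    hdr.write(_pad_ascii(_EDF_DIG_MIN, 8))
    hdr.write(_pad_ascii(_EDF_DIG_MAX, 8))
    hdr.write(_pad_ascii("", 80))
    hdr.write(_pad_ascii(fs, 8))
    hdr.write(_pad_ascii("", 32))
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        fh.write(dig.tobytes())


def read_edf(path) -> EcogRecording:
    """Read a single-channel EDF file into microvolts."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) != 1:
        raise ValueError(
            f"expected a single-channel EDF, found {len(raw.ch_names)} channels"
        )
    data = raw.get_data()[0] * 1e6  # mne returns volts
    with open(path, "rb") as fh:
        animal = fh.read(88)[8:].decode("ascii", "replace").strip()
    return EcogRecording(
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
        animal_id=animal or "animal-00",
    )


def write_csv_recording(recording: EcogRecording, path) -> None:
    """CSV escape hatch: header (time_s, uV), one row per sample."""
    t = np.arange(len(recording.samples)) / recording.sampling_rate
    pd.DataFrame({"time_s": t, "uV": recording.samples}).to_csv(path, index=False)


def read_csv_recording(path) -> EcogRecording:
    """Read a (time_s, uV) CSV; the sampling rate is inferred and must be uniform."""
    df = pd.read_csv(path)
    if not {"time_s", "uV"} <= set(df.columns):
        raise ValueError("CSV recording requires columns time_s and uV")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * max(dt[0], 1e-12)) or dt[0] <= 0:
        raise ValueError("nonuniform timestamps; cannot infer a sampling rate")
    return EcogRecording(samples=df["uV"].to_numpy(float), sampling_rate=1.0 / dt[0])


def read_ecog(path, format: Optional[str] = None) -> EcogRecording:
    """Read a recording from EDF or CSV (by extension unless ``format`` given)."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_edf(path)
    if fmt == "csv":
        return read_csv_recording(path)
    raise ValueError(f"unsupported recording format {fmt!r}")


def write_ecog(recording: EcogRecording, path, format: Optional[str] = None) -> None:
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "edf":
        write_edf(recording, path)
    elif fmt == "csv":
        write_csv_recording(recording, path)
    else:
        raise ValueError(f"unsupported recording format {fmt!r}")


# ---------------------------------------------------------------------------
# tabular sidecars
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    return f"{v:.6f}"


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground-truth sidecar CSV: columns (kind, start_s, end_s, label, extra)."""
    rows = []
    for s, e, lab in truth.state_intervals:
        rows.append(("state", _fmt(s), _fmt(e), lab.value, ""))
    for s, e in truth.burst_intervals:
        rows.append(("burst", _fmt(s), _fmt(e), "", ""))
    for ev in truth.seizure_events:
        extra = (
            f"stimulated={int(ev.stimulated)}|"
            f"control_duration={_fmt(ev.control_duration if ev.control_duration is not None else ev.duration)}|"
            f"animal={ev.animal_id}"
        )
        rows.append(("seizure", _fmt(ev.onset), _fmt(ev.offset), "", extra))
    for st in truth.stim_events:
        extra = (
            f"delay={_fmt(st.delay)}|class={st.delay_class or ''}|"
            f"triggered={int(st.triggered)}|condition={st.condition}|"
            f"animal={st.animal_id}"
        )
        end = st.light_on + st.light_duration if st.light_on is not None else st.detection_time
        rows.append(("stim", _fmt(st.detection_time), _fmt(end), "", extra))
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "label", "extra"]).to_csv(
        path, index=False
    )


def _parse_extra(extra: str) -> dict:
    out = {}
    for part in str(extra).split("|"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, keep_default_na=False)
    states, events, stims, bursts = [], [], [], []
    for _, row in df.iterrows():
        kind = row["kind"]
        s, e = float(row["start_s"]), float(row["end_s"])
        if kind == "state":
            states.append((s, e, StateLabel(row["label"])))
        elif kind == "burst":
            bursts.append((s, e))
        elif kind == "seizure":
            x = _parse_extra(row["extra"])
            events.append(
                SeizureEvent(
                    onset=s,
                    offset=e,
                    animal_id=x.get("animal", "animal-00"),
                    stimulated=bool(int(x.get("stimulated", "0"))),
                    control_duration=float(x["control_duration"])
                    if "control_duration" in x
                    else None,
                )
            )
        elif kind == "stim":
            x = _parse_extra(row["extra"])
            triggered = bool(int(x.get("triggered", "0")))
            delay = float(x.get("delay", "0"))
            stims.append(
                StimulationEvent(
                    detection_time=s,
                    delay=delay,
                    delay_class=x.get("class") or None,
                    light_on=s + delay if triggered else None,
                    triggered=triggered,
                    condition=x.get("condition", "NO_OPSIN"),
                    animal_id=x.get("animal", "animal-00"),
                )
            )
    return GroundTruth(
        state_intervals=states,
        seizure_events=events,
        stim_events=stims,
        burst_intervals=bursts,
    )


def write_stim_log(stims, path) -> None:
    """Stimulation log CSV (one row per accepted trial)."""
    rows = [
        {
            "detection_time_s": _fmt(st.detection_time),
            "delay_s": _fmt(st.delay),
            "delay_class": st.delay_class or "",
            "light_on_s": _fmt(st.light_on) if st.light_on is not None else "",
            "light_duration_s": _fmt(st.light_duration),
            "triggered": int(st.triggered),
            "condition": st.condition,
            "animal_id": st.animal_id,
        }
        for st in stims
    ]
    pd.DataFrame(
        rows,
        columns=[
            "detection_time_s",
            "delay_s",
            "delay_class",
            "light_on_s",
            "light_duration_s",
            "triggered",
            "condition",
            "animal_id",
        ],
    ).to_csv(path, index=False)


def read_stim_log(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        triggered = bool(int(r["triggered"]))
        out.append(
            StimulationEvent(
                detection_time=float(r["detection_time_s"]),
                delay=float(r["delay_s"]),
                delay_class=str(r["delay_class"]) or None,
                light_on=float(r["light_on_s"]) if triggered else None,
                triggered=triggered,
                condition=str(r["condition"]),
                light_duration=float(r["light_duration_s"]),
                animal_id=str(r["animal_id"]),
            )
        )
    return out


def write_events(events, path) -> None:
    """Measured-events CSV."""
    rows = [
        {
            "onset_s": _fmt(ev.onset),
            "offset_s": _fmt(ev.offset),
            "duration_s": _fmt(ev.duration),
            "animal_id": ev.animal_id,
            "peak_negative_amplitude": _fmt(ev.peak_negative_amplitude)
            if np.isfinite(ev.peak_negative_amplitude)
            else "",
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=["onset_s", "offset_s", "duration_s", "animal_id", "peak_negative_amplitude"],
    ).to_csv(path, index=False)


def read_events(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        SeizureEvent(
            onset=float(r["onset_s"]),
            offset=float(r["offset_s"]),
            animal_id=str(r["animal_id"]),
            peak_negative_amplitude=float(r["peak_negative_amplitude"])
            if str(r["peak_negative_amplitude"])
            else float("nan"),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat, plain-text pipeline configuration (lossless round-trip)."""

    schema_version: int = 1
    sampling_rate: float = 512.0
    event_threshold_uv: float = -60.0
    detector_k: float = 6.0
    detector_refractory: float = 1.0
    min_interval: float = 20.0
    warmup: float = 30.0
    prominence: float = 0.05
    baseline_band: float = 0.02
    min_gap: float = 0.3
    min_duration: float = 0.5
    reshuffle_eligible_min: float = 2.5
    reshuffle_qualify_min: float = 3.0
    seed: int = 0

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = int(value) if types[key] == "int" else float(value)
        cfg = cls(**kwargs)
        if cfg.schema_version != 1:
            raise ValueError(f"unsupported config schema version {cfg.schema_version}")
        return cfg

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    def as_dict(self) -> dict:
        return asdict(self)
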