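"""Readers/writers for recordings and behavioral logs.

Native on-disk format (transparent, diffable text):

``<stem>.data.tsv``
    channels x samples matrix, tab-delimited floats.
``<stem>.meta.yaml``
    sampling rate, chromophore, subject id and per-channel metadata.
``<stem>.events.tsv``
    stimulus table with columns onset_s, location_deg, intensity_db,
    duration_s.

SNIRF (HDF5) import/export is supported as an optional interchange route;
only the subset needed for processed concentration time series plus stimulus
markers is written.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .core import BehavioralSession, ChannelInfo, Event, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_behavioral",
    "write_behavioral",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk file is missing a required field."""


_EVENT_COLS = ("onset_s", "location_deg", "intensity_db", "duration_s")


def _stem(path: str | os.PathLike) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".data.tsv", ".meta.yaml", ".events.tsv"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def write_recording(rec: Recording, path: str | os.PathLike, format: str = "delimited") -> None:
    """Write a recording; ``path`` is the file stem (native) or .snirf file."""
    if format == "snirf":
        _write_snirf(rec, Path(path))
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(stem.with_suffix(".data.tsv"), rec.data, fmt="%.12g", delimiter="\t")
    meta = {
        "fs_hz": float(rec.fs_hz),
        "chromophore": rec.chromophore,
        "subject_id": rec.subject_id,
        "channels": [
            {
                "channel_id": c.channel_id,
                "hemisphere": c.hemisphere,
                "roi_id": c.roi_id,
                "brodmann_area": c.brodmann_area,
                "mni_xyz": list(c.mni_xyz),
                "proportion": c.proportion,
                "cortical_area": c.cortical_area,
            }
            for c in rec.channels
        ],
    }
    stem.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    lines = ["\t".join(_EVENT_COLS)]
    for ev in rec.events:
        lines.append(f"{ev.onset_s:.6f}\t{ev.location_deg}\t{ev.intensity_db}\t{ev.duration_s:.6f}")
    stem.with_suffix(".events.tsv").write_text("\n".join(lines) + "\n")


def read_recording(path: str | os.PathLike, format: str = "delimited") -> Recording:
    """Read a recording written by :func:`write_recording`."""
    if format == "snirf":
        return _read_snirf(Path(path))
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    stem = _stem(path)
    meta_path = stem.with_suffix(".meta.yaml")
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = yaml.safe_load(meta_path.read_text())
    for key in ("fs_hz", "chromophore", "channels"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing required field {key!r}")
    channels = [
        ChannelInfo(
            channel_id=c["channel_id"],
            hemisphere=c["hemisphere"],
            roi_id=c["roi_id"],
            brodmann_area=c["brodmann_area"],
            mni_xyz=tuple(c["mni_xyz"]),
            proportion=c["proportion"],
            cortical_area=c.get("cortical_area", ""),
        )
        for c in meta["channels"]
    ]
    data = np.loadtxt(stem.with_suffix(".data.tsv"), delimiter="\t", ndmin=2)
    events = _read_events(stem.with_suffix(".events.tsv"))
    return Recording(
        data=data,
        fs_hz=float(meta["fs_hz"]),
        chromophore=meta["chromophore"],
        channels=channels,
        events=events,
        subject_id=meta.get("subject_id", ""),
    )


def _read_events(path: Path) -> list[Event]:
    if not path.exists():
        return []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return []
    header = tuple(lines[0].split("\t"))
    if header != _EVENT_COLS:
        raise FormatError(f"{path}: expected columns {_EVENT_COLS}, got {header}")
    events = []
    for ln in lines[1:]:
        onset, loc, level, dur = ln.split("\t")
        events.append(
            Event(
                onset_s=float(onset),
                location_deg=int(loc),
                intensity_db=int(level),
                duration_s=float(dur),
            )
        )
    return events


# ---------------------------------------------------------------------------
# behavioral logs


def write_behavioral(session: BehavioralSession, path: str | os.PathLike) -> None:
    lines = ["trial\ttarget_speaker\tresponse_speaker\tintensity_db"]
    for i, (tgt, resp, level) in enumerate(session.trials, start=1):
        lines.append(f"{i}\t{tgt}\t{resp}\t{level}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_behavioral(path: str | os.PathLike) -> BehavioralSession:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header != ["trial", "target_speaker", "response_speaker", "intensity_db"]:
        raise FormatError(f"{path}: unexpected header {header}")
    trials = []
    for ln in lines[1:]:
        _, tgt, resp, level = ln.split("\t")
        trials.append((int(tgt), int(resp), int(level)))
    return BehavioralSession(trials=trials)


# ---------------------------------------------------------------------------
# SNIRF (optional HDF5 interchange)

_CHROMO_LABEL = {"oxy": "HbO", "deoxy": "HbR", "total": "HbT"}
_LABEL_CHROMO = {v: k for k, v in _CHROMO_LABEL.items()}


def _write_snirf(rec: Recording, path: Path) -> None:
    import h5py

    label = _CHROMO_LABEL[rec.chromophore]
    n = rec.n_samples
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id or "unknown")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=rec.data.T)
        d1.create_dataset("time", data=np.arange(n) / rec.fs_hz)
        for j, ch in enumerate(rec.channels, start=1):
            ml = d1.create_group(f"measurementList{j}")
            ml.create_dataset("sourceIndex", data=ch.channel_id)
            ml.create_dataset("detectorIndex", data=ch.channel_id)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=99999)  # processed
            ml.create_dataset("dataTypeLabel", data=label)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([780.0, 805.0, 830.0]))
        pos = np.array([c.mni_xyz for c in rec.channels])
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos)
        for k, ev in enumerate(rec.events, start=1):
            st = nirs.create_group(f"stim{k}")
            st.create_dataset("name", data=f"loc{ev.location_deg:+d}_db{ev.intensity_db}")
            st.create_dataset(
                "data", data=np.array([[ev.onset_s, ev.duration_s, 1.0]])
            )


def _read_snirf(path: Path) -> Recording:
    import h5py

    from .probe import load_probe_map

    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"]).T
        time = np.asarray(d1["time"])
        if len(time) < 2:
            raise FormatError(f"{path}: time vector too short to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(time)))
        label = d1["measurementList1/dataTypeLabel"][()]
        if isinstance(label, bytes):
            label = label.decode()
        chromo = _LABEL_CHROMO.get(label)
        if chromo is None:
            raise FormatError(f"{path}: unsupported dataTypeLabel {label!r}")
        subject = f["nirs/metaDataTags/SubjectID"][()]
        if isinstance(subject, bytes):
            subject = subject.decode()
        events = []
        for key in sorted(k for k in f["nirs"] if k.startswith("stim")):
            st = f["nirs"][key]
            name = st["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            try:
                loc_part, db_part = name.split("_")
                loc = int(loc_part.removeprefix("loc"))
                level = int(db_part.removeprefix("db"))
            except ValueError as exc:
                raise FormatError(f"{path}: cannot parse stim name {name!r}") from exc
            for onset, dur, _ in np.atleast_2d(np.asarray(st["data"])):
                events.append(
                    Event(onset_s=float(onset), location_deg=loc,
                          intensity_db=level, duration_s=float(dur))
                )
    pm = load_probe_map()
    if data.shape[0] == pm.n_channels:
        channels = list(pm.channels)
    else:
        channels = [
            ChannelInfo(i + 1, "left" if i < data.shape[0] / 2 else "right",
                        1, 6, (0.0, 0.0, 0.0), 0.5)
            for i in range(data.shape[0])
        ]
    return Recording(
        data=data, fs_hz=fs, chromophore=chromo, channels=channels,
        events=events, subject_id=str(subject) if subject != "unknown" else "",
    )
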