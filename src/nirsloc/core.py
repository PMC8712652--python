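"""Core domain containers for a single-subject fNIRS sound-localization session.

The package represents one recording session as a :class:`Recording`
(channels x samples concentration-change matrix plus channel metadata and a
stimulus event list) and the behavioral half of the session as a
:class:`BehavioralSession` (target/response loudspeaker pairs).  Epoched data
live in :class:`TrialTensor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ChannelInfo",
    "Event",
    "Recording",
    "BehavioralSession",
    "TrialTensor",
    "SPEAKER_ANGLES_DEG",
    "LOCATIONS_DEG",
    "INTENSITIES_DB",
    "ValidationError",
]

#: loudspeaker index -> azimuth in degrees (7 speakers, 30 degree spacing)
SPEAKER_ANGLES_DEG: dict[int, int] = {i: -90 + 30 * (i - 1) for i in range(1, 8)}

#: the five active source azimuths used for stimulation
LOCATIONS_DEG: tuple[int, ...] = (-90, -30, 0, 30, 90)

#: the two presentation levels (dB SPL)
INTENSITIES_DB: tuple[int, ...] = (48, 58)


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one source-detector channel.

    ``proportion`` is the probabilistic anatomical-assignment weight of the
    channel's cortical projection point to its Brodmann area.
    """

    channel_id: int
    hemisphere: Literal["left", "right"]
    roi_id: int
    brodmann_area: int
    mni_xyz: tuple[float, float, float]
    proportion: float
    cortical_area: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.channel_id <= 20:
            raise ValidationError(f"channel_id must be 1-20, got {self.channel_id}")
        if not 1 <= self.roi_id <= 10:
            raise ValidationError(f"roi_id must be 1-10, got {self.roi_id}")
        if self.hemisphere not in ("left", "right"):
            raise ValidationError(f"hemisphere must be left/right, got {self.hemisphere}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValidationError(f"proportion must be in [0, 1], got {self.proportion}")


@dataclass(frozen=True)
class Event:
    """One stimulus presentation: onset, source azimuth, level and duration."""

    onset_s: float
    location_deg: int
    intensity_db: int
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.location_deg not in LOCATIONS_DEG:
            raise ValidationError(
                f"location_deg must be one of {LOCATIONS_DEG}, got {self.location_deg}"
            )
        if self.intensity_db not in INTENSITIES_DB:
            raise ValidationError(
                f"intensity_db must be one of {INTENSITIES_DB}, got {self.intensity_db}"
            )
        if self.onset_s < 0:
            raise ValidationError(f"onset_s must be >= 0, got {self.onset_s}")


@dataclass
class Recording:
    """A multichannel concentration-change time series.

    Parameters
    ----------
    data
        channels x samples array of concentration change (mM*mm, i.e.
        pathlength-scaled concentration as reported by continuous-wave
        instruments that do not resolve the differential pathlength factor).
    fs_hz
        Sampling rate in Hz.
    chromophore
        Which hemoglobin species the rows measure.
    channels
        Per-row channel metadata; ``len(channels) == data.shape[0]``.
    events
        Stimulus events, sorted by onset.
    """

    data: np.ndarray
    fs_hz: float
    chromophore: Literal["oxy", "deoxy", "total"]
    channels: list[ChannelInfo]
    events: list[Event] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D, got shape {self.data.shape}")
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.chromophore not in ("oxy", "deoxy", "total"):
            raise ValidationError(f"unknown chromophore {self.chromophore!r}")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel entries for {self.data.shape[0]} data rows"
            )
        if np.isnan(self.data).any():
            raise ValidationError("data contains missing samples (NaN)")
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("event onsets must be strictly increasing")
        for ev in self.events:
            if ev.onset_s > self.duration_s:
                raise ValidationError(
                    f"event at {ev.onset_s} s lies beyond recording end "
                    f"({self.duration_s:.2f} s)"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced (data is copied)."""
        out = replace(self, **changes)
        out.data = np.array(out.data, dtype=float, copy=True)
        return out

    def sample_index(self, t_s: float) -> int:
        """Time (s) -> 0-based sample index, round-to-nearest convention."""
        return int(round(t_s * self.fs_hz))


@dataclass
class BehavioralSession:
    """Target/response loudspeaker pairs from the pointing task.

    Responses are loudspeaker indices 1-7 (the listener does not know that
    only five speakers are active), targets are restricted to the active
    speakers {1, 3, 4, 5, 7}.
    """

    trials: list[tuple[int, int, int]]  # (target_speaker, response_speaker, intensity_db)
    speaker_angles_deg: dict[int, int] = field(
        default_factory=lambda: dict(SPEAKER_ANGLES_DEG)
    )
    subject_id: str = ""

    def __post_init__(self) -> None:
        for i, (tgt, resp, level) in enumerate(self.trials):
            if not 1 <= tgt <= 7:
                raise ValidationError(f"trial {i}: target speaker {tgt} outside 1-7")
            if not 1 <= resp <= 7:
                raise ValidationError(f"trial {i}: response speaker {resp} outside 1-7")
            if level not in INTENSITIES_DB:
                raise ValidationError(f"trial {i}: intensity {level} dB not in {INTENSITIES_DB}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class TrialTensor:
    """Epoched data: trials x units x samples with per-trial condition labels.

    ``unit_kind`` says whether the middle axis indexes the 20 measurement
    channels or the 10 regions of interest obtained by channel averaging.
    """

    data: np.ndarray
    labels: list[tuple[int, int]]  # (location_deg, intensity_db)
    fs_hz: float
    unit_kind: Literal["channel", "roi"]
    unit_ids: list[int]
    window_s: float = 10.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"trial tensor must be 3-D, got shape {self.data.shape}")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        if len(self.unit_ids) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.unit_ids)} unit ids for {self.data.shape[1]} units"
            )
        if self.unit_kind not in ("channel", "roi"):
            raise ValidationError(f"unknown unit_kind {self.unit_kind!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, idx: Sequence[int] | np.ndarray) -> "TrialTensor":
        idx = np.asarray(idx, dtype=int)
        return TrialTensor(
            data=self.data[idx],
            labels=[self.labels[i] for i in idx],
            fs_hz=self.fs_hz,
            unit_kind=self.unit_kind,
            unit_ids=list(self.unit_ids),
            window_s=self.window_s,
        )
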