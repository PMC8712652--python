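"""Static probe montage: 20 channels over bilateral auditory/prefrontal cortex.

The montage covers premotor cortex (BA6), the supramarginal gyrus (BA40),
dorsolateral prefrontal cortex (BA9), superior temporal gyrus (BA22) and
auditory association cortex (BA42) on both hemispheres, grouped into 10
regions of interest (ROIs 1-5 left, 6-10 right; ROI ``k`` and ``k+5`` are
anatomically mirrored).  Channels 1-10 sit on the left hemisphere, 11-20 on
the right.

MNI coordinates and anatomical-assignment proportions are shipped as static
data.  Two printed coordinates are anatomically implausible (channel 6 at
x = -6 and channel 17 nearly duplicating channel 18); they are reproduced
as published and flagged here rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import ChannelInfo, ValidationError

__all__ = ["ProbeMap", "load_probe_map", "ROI_CHANNELS", "ROI_PAIRS", "BA_NAMES"]

BA_NAMES: dict[int, str] = {
    6: "Pre-motor and supplementary motor cortex",
    40: "Supramarginal gyrus part of Wernicke's area",
    9: "dlPFC",
    22: "Superior temporal gyrus",
    42: "Auditory association cortex",
}

#: ROI id -> member channel ids
ROI_CHANNELS: dict[int, tuple[int, ...]] = {
    1: (1, 2, 5, 8),
    2: (3, 6),
    3: (4,),
    4: (7, 10),
    5: (9,),
    6: (11, 12, 15, 18),
    7: (13, 16),
    8: (14,),
    9: (17, 20),
    10: (19,),
}

#: left/right mirrored ROI pairs (same Brodmann area on opposite hemispheres)
ROI_PAIRS: tuple[tuple[int, int], ...] = ((1, 6), (2, 7), (3, 8), (4, 9), (5, 10))

# channel_id: (hemisphere, roi, (x, y, z), BA, proportion)
_CHANNEL_TABLE: dict[int, tuple[str, int, tuple[float, float, float], int, float]] = {
    1: ("left", 1, (-60.0, 3.0, 39.0), 6, 0.7964),
    2: ("left", 1, (-65.0, -18.0, 39.0), 6, 0.3576),
    5: ("left", 1, (-66.0, -6.0, 29.0), 6, 0.6310),
    8: ("left", 1, (-64.0, 6.0, 17.0), 6, 0.5016),
    3: ("left", 2, (-68.0, -39.0, 30.0), 40, 0.9527),
    6: ("left", 2, (-6.0, -29.0, 25.0), 40, 0.6075),  # as published; x likely -66
    4: ("left", 3, (-69.0, -16.0, 27.0), 9, 0.5610),
    7: ("left", 4, (-68.0, -50.0, 7.0), 22, 0.5290),
    10: ("left", 4, (-71.0, -39.0, 2.0), 22, 0.5092),
    9: ("left", 5, (-68.0, -16.0, 14.0), 42, 0.4658),
    11: ("right", 6, (62.0, 2.0, 40.0), 6, 0.8272),
    12: ("right", 6, (67.0, -18.0, 41.0), 6, 0.3588),
    15: ("right", 6, (68.0, -5.0, 31.0), 6, 0.7785),
    18: ("right", 6, (67.0, 4.0, 18.0), 6, 0.5342),
    13: ("right", 7, (69.0, -40.0, 31.0), 40, 0.9968),
    16: ("right", 7, (71.0, -29.0, 27.0), 40, 0.7037),
    14: ("right", 8, (63.0, 14.0, 27.0), 9, 0.6111),
    17: ("right", 9, (69.0, 4.0, 18.0), 22, 0.4618),  # as published; near-duplicate of ch 18
    20: ("right", 9, (72.0, -41.0, 1.0), 22, 0.5140),
    19: ("right", 10, (71.0, -17.0, 14.0), 42, 0.4969),
}


@dataclass(frozen=True)
class ProbeMap:
    """The channel -> (hemisphere, ROI, anatomy) assignment of the montage."""

    channels: tuple[ChannelInfo, ...]

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValidationError("channel ids must be 1..n with no gaps")

    def channel(self, channel_id: int) -> ChannelInfo:
        return self.channels[channel_id - 1]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def roi_ids(self) -> list[int]:
        return sorted({c.roi_id for c in self.channels})

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def roi_members(self, roi_id: int) -> tuple[int, ...]:
        """Channel ids belonging to one ROI, in ascending order."""
        return tuple(c.channel_id for c in self.channels if c.roi_id == roi_id)

    def roi_hemisphere(self, roi_id: int) -> str:
        hems = {c.hemisphere for c in self.channels if c.roi_id == roi_id}
        if len(hems) != 1:
            raise ValidationError(f"ROI {roi_id} spans hemispheres: {hems}")
        return hems.pop()

    def roi_brodmann(self, roi_id: int) -> int:
        bas = {c.brodmann_area for c in self.channels if c.roi_id == roi_id}
        if len(bas) != 1:
            raise ValidationError(f"ROI {roi_id} spans Brodmann areas: {bas}")
        return bas.pop()


def load_probe_map() -> ProbeMap:
    """Return the standard 20-channel / 10-ROI montage."""
    channels = []
    for ch_id in range(1, 21):
        hem, roi, xyz, ba, prop = _CHANNEL_TABLE[ch_id]
        channels.append(
            ChannelInfo(
                channel_id=ch_id,
                hemisphere=hem,  # type: ignore[arg-type]
                roi_id=roi,
                brodmann_area=ba,
                mni_xyz=xyz,
                proportion=prop,
                cortical_area=BA_NAMES[ba],
            )
        )
    return ProbeMap(channels=tuple(channels))
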