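"""Electrode layout of the 64-channel motor/imagery montage.

The reference recordings use the international 10-10 system with the
mastoid/outer ring electrodes (Nz, F9, F10, FT9, FT10, A1, A2, TP9, TP10,
P9, P10) excluded, leaving 64 channels numbered 1..64 with FC5 first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Channel labels in record order (1-based index = position + 1).
CHANNELS_64: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Electrodes of the 10-10 system deliberately absent from the montage.
EXCLUDED_ELECTRODES: frozenset[str] = frozenset(
    {"Nz", "F9", "F10", "FT9", "FT10", "A1", "A2", "TP9", "TP10", "P9", "P10"}
)


@dataclass(frozen=True)
class ChannelMap:
    """Ordered 64-electrode labelling with 1-based lookup.

    Parameters
    ----------
    names
        Ordered electrode labels; defaults to the reference montage order.
    """

    names: tuple[str, ...] = field(default=CHANNELS_64)

    def __post_init__(self) -> None:
        if len(self.names) != 64:
            raise ValueError(f"channel map must have 64 labels, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel labels must be unique")
        banned = EXCLUDED_ELECTRODES.intersection(self.names)
        if banned:
            raise ValueError(f"excluded electrodes present: {sorted(banned)}")

    def index(self, label: str) -> int:
        """Return the 1-based channel number of ``label``."""
        try:
            return self.names.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    def label(self, number: int) -> str:
        """Return the label of 1-based channel ``number``."""
        if not 1 <= number <= len(self.names):
            raise IndexError(f"channel number out of range 1..64: {number}")
        return self.names[number - 1]

    def __len__(self) -> int:
        return len(self.names)


class RelaxedChannelMap(ChannelMap):
    """Channel map without the 64-electrode montage invariant.

    Used for relaxed reads of non-standard files and for reduced-size
    synthetic cohorts; labels must still be unique.
    """

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel labels must be unique")


def generic_channel_map(n: int) -> ChannelMap:
    """The reference montage for n = 64, otherwise numbered placeholder labels."""
    if n == 64:
        return ChannelMap()
    return RelaxedChannelMap(tuple(f"ch{i}" for i in range(1, n + 1)))
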