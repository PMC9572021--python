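"""Fixed 8-channel montage over four scalp regions.

Channel order is canonical everywhere in the package: frontal, central,
parietal, occipital, left hemisphere before right.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

REGIONS: tuple[str, ...] = ("F", "C", "P", "O")

#: region code -> its two channels, in montage order
REGION_CHANNELS: dict[str, tuple[str, str]] = {
    "F": ("F3", "F4"),
    "C": ("C3", "C4"),
    "P": ("P3", "P4"),
    "O": ("O1", "O2"),
}

#: channel label -> region code
CHANNEL_REGION: dict[str, str] = {
    ch: region for region, pair in REGION_CHANNELS.items() for ch in pair
}


def channels_for_regions(regions: tuple[str, ...] | list[str] | set[str]) -> list[str]:
    """Resolve a set of region codes to channel labels in montage order."""
    wanted = set(regions)
    return [ch for ch in CHANNELS if CHANNEL_REGION[ch] in wanted]
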