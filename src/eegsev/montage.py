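"""Canonical 16-channel 10-20 montage, anatomical regions, and pair ordering.

Every matrix, feature vector, and index map in the package uses the channel
order defined here.  Pair ordering is row-major over the upper triangle
(i < j), which fixes the 120-pair layout per frequency band.
"""

from __future__ import annotations

import itertools

CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

N_CHANNELS = len(CHANNELS)

#: Anatomical lobe grouping used for attribution rollups.  The five regions
#: partition the montage.
REGIONS: dict[str, frozenset[str]] = {
    "frontal": frozenset({"FP1", "FP2", "F3", "F4", "F7", "F8"}),
    "central": frozenset({"C3", "C4"}),
    "parietal": frozenset({"P3", "P4"}),
    "occipital": frozenset({"O1", "O2"}),
    "temporal": frozenset({"T3", "T4", "T5", "T6"}),
}


def channel_index(name: str) -> int:
    """Index of ``name`` in the canonical montage (case-insensitive)."""
    try:
        return CHANNELS.index(name.upper())
    except ValueError:
        raise KeyError(f"unknown electrode name: {name!r}") from None


def region_of(name: str) -> str:
    up = name.upper()
    for region, members in REGIONS.items():
        if up in members:
            return region
    raise KeyError(f"electrode {name!r} not in any region")


def electrode_pairs(n_channels: int = N_CHANNELS) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) channel-index pairs."""
    return list(itertools.combinations(range(n_channels), 2))


def n_pairs(n_channels: int = N_CHANNELS) -> int:
    return n_channels * (n_channels - 1) // 2
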