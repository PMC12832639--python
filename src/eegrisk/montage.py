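"""Standard 19-channel 10-20 scalp montage.

Electrode positions are unit-sphere coordinates in a head frame with
+x to the subject's right, +y anterior, +z through the vertex (Cz).
The montage also carries the anatomical region partition used for
regional band-power aggregation and the left-right mirror pairing used
to construct and test asymmetric microstate topographies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel order used throughout the package.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "O2", "O1", "T6",
)

# Idealised spherical angles (theta = inclination from vertex, phi =
# azimuth from +x, degrees) for the 10-20 positions.
_ANGLES = {
    "Fp1": (92, 108), "Fp2": (92, 72),
    "F7": (92, 144), "F3": (60, 129), "Fz": (46, 90), "F4": (60, 51), "F8": (92, 36),
    "T3": (92, 180), "C3": (46, 180), "Cz": (0, 0), "C4": (46, 0), "T4": (92, 0),
    "T5": (92, 216), "P3": (60, 231), "Pz": (46, 270), "P4": (60, 309),
    "O2": (92, 288), "O1": (92, 252), "T6": (92, 324),
}

_REGIONS = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("T3", "C3", "Cz", "C4", "T4"),
    "posterior": ("T5", "P3", "Pz", "P4", "T6", "O1", "O2"),
}

# Left-right homologue pairs; midline channels map to themselves.
_MIRROR_PAIRS = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"),
    ("T3", "T4"), ("C3", "C4"), ("T5", "T6"),
    ("P3", "P4"), ("O1", "O2"),
)


@dataclass(frozen=True)
class Montage:
    """A named electrode set with positions and a region partition.

    Attributes
    ----------
    channel_names : tuple of str
        Channel labels, defining the canonical channel order.
    positions : ndarray, shape (n_channels, 3)
        Unit-sphere electrode coordinates (x right, y anterior, z up).
    region_map : dict
        Region name -> tuple of member channel names.  Regions are
        disjoint and together cover all channels; ``global`` (the full
        set) is implicit.
    """

    channel_names: tuple
    positions: np.ndarray
    region_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.channel_names) != self.positions.shape[0]:
            raise ValueError("one position required per channel")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        seen = set()
        for region, members in self.region_map.items():
            if not members:
                raise ValueError(f"region {region!r} is empty")
            for ch in members:
                if ch in seen:
                    raise ValueError(f"channel {ch!r} in two regions")
                if ch not in self.channel_names:
                    raise ValueError(f"region channel {ch!r} not in montage")
                seen.add(ch)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def region_indices(self, region: str) -> np.ndarray:
        """Channel indices of ``region`` ('global' = all channels)."""
        if region == "global":
            return np.arange(self.n_channels)
        members = self.region_map[region]
        return np.array([self.index(ch) for ch in members])

    def mirror_indices(self) -> np.ndarray:
        """Permutation mapping each channel to its left-right homologue."""
        perm = np.arange(self.n_channels)
        for a, b in _MIRROR_PAIRS:
            if a in self.channel_names and b in self.channel_names:
                ia, ib = self.index(a), self.index(b)
                perm[ia], perm[ib] = ib, ia
        return perm


def _sph_to_xyz(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def standard_1020() -> Montage:
    """The 19-channel international 10-20 montage used by the pipeline."""
    pos = np.vstack([_sph_to_xyz(*_ANGLES[ch]) for ch in CHANNELS_1020])
    return Montage(channel_names=CHANNELS_1020, positions=pos,
                   region_map=dict(_REGIONS))


REGION_NAMES = ("global", "frontal", "central", "posterior")
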