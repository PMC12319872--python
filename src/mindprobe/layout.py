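"""32-channel 10-20 scalp layout.

The montage is the standard 32-electrode extension of the international
10-20 system (the arrangement used by common 32-channel caps). Three-
dimensional template positions come from MNE's ``standard_1020`` montage
and are projected onto the unit-circle head by an azimuthal-equidistant
projection: the 2-D radius of an electrode is its polar angle from the
vertex divided by pi, so the vertex maps to the origin and electrodes
below the equatorial ring land outside radius 0.5 but inside the unit
circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Channel order used throughout the package (standard 32-channel cap).
CHANNELS_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode labels plus 2-D scalp-projected positions.

    Attributes
    ----------
    labels : tuple of str
        Unique electrode names in recording order.
    positions : ndarray, shape (n_channels, 2)
        Unitless coordinates on the unit-circle head (vertex at origin,
        nose along +y).
    """

    labels: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r > 1.0 + 1e-9):
            raise ValueError("all positions must lie within the unit circle")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


_LAYOUT_CACHE: ChannelLayout | None = None


def _project_azimuthal(pos3d: np.ndarray) -> np.ndarray:
    """Map 3-D head-frame positions to 2-D, vertex at the origin."""
    p = pos3d / np.linalg.norm(pos3d, axis=1, keepdims=True)
    polar = np.arccos(np.clip(p[:, 2], -1.0, 1.0))  # angle from vertex
    azim = np.arctan2(p[:, 1], p[:, 0])
    r2 = polar / np.pi
    return np.column_stack([r2 * np.cos(azim), r2 * np.sin(azim)])


def make_layout() -> ChannelLayout:
    """Return the packaged 32-channel 10-20 template layout.

    Deterministic: repeated calls return identical labels and positions.
    """
    global _LAYOUT_CACHE
    if _LAYOUT_CACHE is None:
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            montage = mne.channels.make_standard_montage("standard_1020")
        ch_pos = montage.get_positions()["ch_pos"]
        pos3d = np.array([ch_pos[name] for name in CHANNELS_32])
        _LAYOUT_CACHE = ChannelLayout(CHANNELS_32, _project_azimuthal(pos3d))
    return _LAYOUT_CACHE
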