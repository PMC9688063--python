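"""Electrode montages on a normalized 2-D head circle.

Positions use the conventional schematic layout: the head is a unit circle,
the nose points toward +y and the right ear toward +x. Coordinates are
unitless; only the qualitative geometry (left/right, anterior/posterior,
midline/lateral) matters for template construction and labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "standard_1020"]

_DEG = np.pi / 180.0

# Outer 10% ring electrodes at radius 0.8, angle in degrees (mathematical
# convention, nose at 90 deg); inner electrodes placed on the 20%/40% arcs.
_RING = {
    "Fp1": 108.0, "Fp2": 72.0, "F7": 144.0, "F8": 36.0, "T3": 180.0,
    "T4": 0.0, "T5": 216.0, "T6": 324.0, "O1": 252.0, "O2": 288.0,
}
_INNER = {
    "F3": (-0.35, 0.42), "F4": (0.35, 0.42),
    "C3": (-0.40, 0.00), "C4": (0.40, 0.00),
    "P3": (-0.35, -0.42), "P4": (0.35, -0.42),
    "Fz": (0.0, 0.40), "Cz": (0.0, 0.0), "Pz": (0.0, -0.40),
}

#: Channel order used throughout for the 19-channel reference montage.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]


@dataclass(frozen=True)
class Montage:
    """A named set of electrodes with 2-D scalp-schematic positions.

    Parameters
    ----------
    channel_names
        Unique electrode labels, e.g. ``"Fp1"``.
    positions
        ``(n_channels, 2)`` array of (x, y) coordinates inside the unit
        circle; +x is the subject's right, +y anterior.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions must be ({len(names)}, 2), got {pos.shape}"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.0 + 1e-9):
            raise ValueError("positions must lie within the unit head circle")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


def standard_1020() -> Montage:
    """The 19-channel international 10/20 montage used as reference."""
    pos = []
    for name in CHANNELS_1020:
        if name in _RING:
            a = _RING[name] * _DEG
            pos.append((0.8 * np.cos(a), 0.8 * np.sin(a)))
        else:
            pos.append(_INNER[name])
    return Montage(tuple(CHANNELS_1020), np.array(pos))
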