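"""Sensor layouts and canonical microstate map geometry.

The package works with an idealised spherical-cap electrode layout: unit
vectors on the upper part of a sphere in a head-centred frame (x to the
right ear, y to the nasion, z to the vertex).  Real electrode coordinates
are never needed for any computation here -- only relative geometry enters
the template construction and the canonical A-D labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MontageSpec", "spherical_montage", "canonical_maps", "CLASS_NAMES"]

#: Canonical microstate class names, in canonical order.
CLASS_NAMES = ("A", "B", "C", "D")

# Dipole axes of the four canonical topographies (head frame, see module
# docstring).  A: left-anterior positive vs right-posterior; B its mirror
# image; C anterior vs posterior; D fronto-central vertex vs
# occipito-temporal rim.
_CANONICAL_AXES = {
    "A": (-1.0, 0.7, 0.1),
    "B": (1.0, 0.7, 0.1),
    "C": (0.0, 1.0, 0.0),
    "D": (0.0, 0.2, 1.0),
}


@dataclass(frozen=True)
class MontageSpec:
    """An electrode layout: unit-sphere positions plus channel names."""

    positions: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if pos.shape[0] < 4:
            raise ValueError("a montage needs at least 4 channels")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if len(self.channel_names) != pos.shape[0]:
            raise ValueError("channel names do not match positions")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def spherical_montage(n_channels: int = 62) -> MontageSpec:
    """Deterministic 10-10-like layout on a spherical cap.

    Channels are placed on a Fibonacci spiral covering polar angles from the
    vertex down to slightly below the equator, mimicking the coverage of a
    62-channel extended 10-10 cap.
    """
    if n_channels < 4:
        raise ValueError("n_channels must be >= 4")
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    k = np.arange(n_channels)
    z_min = -0.25  # just below the equator, like inferior temporal rows
    z = 1.0 - (k + 0.5) / n_channels * (1.0 - z_min)
    azimuth = 2.0 * np.pi * k / golden**2
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    positions = np.column_stack([r * np.cos(azimuth), r * np.sin(azimuth), z])
    positions /= np.linalg.norm(positions, axis=1, keepdims=True)
    names = tuple(f"E{i + 1:02d}" for i in range(n_channels))
    return MontageSpec(positions=positions, channel_names=names)


def canonical_maps(positions: np.ndarray) -> np.ndarray:
    """Average-referenced, unit-norm canonical A-D topographies.

    Each map is the smooth dipolar field ``v_j = p_j . a`` evaluated at the
    electrode positions ``p_j`` for the class axis ``a``, then centred across
    channels (consistent with a common average reference) and normalised.

    Returns an array of shape ``(4, n_channels)`` in canonical A-D order.
    """
    positions = np.asarray(positions, dtype=float)
    maps = []
    for name in CLASS_NAMES:
        axis = np.asarray(_CANONICAL_AXES[name])
        axis = axis / np.linalg.norm(axis)
        v = positions @ axis
        v = v - v.mean()
        v = v / np.linalg.norm(v)
        maps.append(v)
    return np.asarray(maps)
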