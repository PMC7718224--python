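"""Volumetric image container shared by the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class ImageStack:
    """3D (+ optional channel) fluorescence voxel grid.

    ``voxels`` is ordered (z, y, x) or (z, y, x, c); intensities are
    arbitrary fluorescence units and must be non-negative. ``voxel_size_um``
    is (dz, dy, dx). z increases into the gel along the migration axis,
    with z = 0 at the microwell-bearing gel face (plus ``z0_offset_um`` if
    the acquisition started above it).
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    z0_offset_um: float = 0.0
    channels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.voxels.ndim not in (3, 4):
            raise ValueError("voxels must be (z, y, x) or (z, y, x, c)")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.voxels.size and float(np.min(self.voxels)) < 0:
            raise ValueError("intensities must be non-negative")
        if self.voxels.ndim == 4 and self.channels:
            if len(self.channels) != self.voxels.shape[-1]:
                raise ValueError("channel labels do not match channel axis")
        if self.voxels.ndim == 4 and not self.channels:
            self.channels = [f"ch{i}" for i in range(self.voxels.shape[-1])]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[-1] if self.voxels.ndim == 4 else 1

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """One channel as a (z, y, x) array (a view where possible)."""
        if self.voxels.ndim == 3:
            if name_or_index in (0, "0") or name_or_index in self.channels:
                return self.voxels
            raise KeyError(f"no channel {name_or_index!r} in single-channel stack")
        if isinstance(name_or_index, int):
            return self.voxels[..., name_or_index]
        try:
            return self.voxels[..., list(self.channels).index(name_or_index)]
        except ValueError:
            raise KeyError(f"unknown channel {name_or_index!r}") from None

    def summed_channels(self) -> np.ndarray:
        """Sum over channels, the working image for segmentation."""
        return self.voxels.sum(axis=-1) if self.voxels.ndim == 4 else self.voxels

    def z_coords_um(self) -> np.ndarray:
        """Voxel-center z positions in um."""
        dz = self.voxel_size_um[0]
        return self.z0_offset_um + dz * (np.arange(self.shape_zyx[0]) + 0.5)
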