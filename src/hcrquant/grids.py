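"""Core voxel containers shared by every stage of the pipeline.

Axis convention (used everywhere in this package): arrays are ordered
``(z, y, x)`` where z is the dorsoventral (DV) axis, y the mediolateral
(ML) axis, and x the anteroposterior (AP) axis with the anterior at
``x = 0`` (images are acquired "anterior left").  ``spacing`` is the
physical voxel pitch in µm per axis, in the same ``(z, y, x)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: anatomical meaning of the three array axes, in array order
DEFAULT_AXIS_MAP = ("dv", "ml", "ap")


@dataclass
class VoxelGrid:
    """One channel's 3D intensity stack with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array of non-negative intensities in arbitrary units (a.u.),
        ordered ``(z, y, x)``.
    spacing:
        Voxel pitch in µm per axis, ``(z, y, x)``.  Strictly positive.
    channel:
        Probe / fluorophore name (e.g. ``"tbx6"``).
    axis_map:
        Anatomical assignment of the array axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""
    axis_map: tuple[str, str, str] = DEFAULT_AXIS_MAP

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of a single voxel in µm³."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "VoxelGrid":
        """Copy of this grid with new intensity data, preserving metadata."""
        return VoxelGrid(
            data=data,
            spacing=self.spacing,
            channel=self.channel if channel is None else channel,
            axis_map=self.axis_map,
        )

    def coords_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (µm) of voxel centres."""
        return tuple(
            np.arange(n, dtype=np.float64) * s
            for n, s in zip(self.data.shape, self.spacing)
        )


@dataclass
class Mask3D:
    """Boolean volumetric mask with its physical volume in µm³.

    ``volume_um3`` is always ``count(True) × voxel volume`` exactly.
    ``provenance`` records how the mask was built (``auto_threshold``,
    ``fixed_threshold`` or ``roi_interpolation``) plus the parameters used.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def volume_um3(self) -> float:
        """Mask volume in µm³ (true-voxel count × voxel volume)."""
        return self.n_voxels * self.voxel_volume_um3

    def is_empty(self) -> bool:
        return not bool(self.data.any())


def require_same_geometry(grid: VoxelGrid, mask: Mask3D) -> None:
    """Raise if a grid and mask do not share shape and spacing."""
    if grid.data.shape != mask.data.shape:
        raise ValueError(
            f"shape mismatch: grid {grid.data.shape} vs mask {mask.data.shape}"
        )
    if not np.allclose(grid.spacing, mask.spacing):
        raise ValueError(
            f"spacing mismatch: grid {grid.spacing} vs mask {mask.spacing}"
        )
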