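"""Shared spatial containers: voxel grids, multi-channel volumes, nuclear masks.

All physical quantities are in micrometres.  Arrays are ordered (z, y, x),
matching the axis order of confocal / SIM z-stacks, and voxel spacing may be
anisotropic (axial steps are typically coarser than lateral ones, e.g. 0.5 µm
z-intervals against 0.25 µm pixels).

The voxel-centre convention is used throughout: voxel (k, j, i) occupies the
physical point ((k + 0.5)·dz, (j + 0.5)·dy, (i + 0.5)·dx).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GridSpec:
    """Voxel geometry of an image stack.

    Parameters
    ----------
    shape
        Voxel counts per axis, ordered (z, y, x).
    spacing
        Physical voxel size per axis in micrometres, ordered (dz, dy, dx).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("GridSpec requires 3 axes (z, y, x)")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(n < 1 for n in self.shape):
            raise ValueError(f"all voxel counts must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def voxel_diagonal(self) -> float:
        """Length of the voxel body diagonal in µm."""
        return math.sqrt(sum(s * s for s in self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres, one 1-D array per axis."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.spacing)
        )

    def coordinate_grid(self) -> np.ndarray:
        """Dense (3, z, y, x) array of voxel-centre physical coordinates."""
        axes = self.voxel_centers()
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


@dataclass
class MultiChannelVolume:
    """A 3-D multi-channel intensity image on a shared grid.

    ``channels`` maps channel name to a (z, y, x) array; insertion order is
    the channel order.
    """

    channels: dict[str, np.ndarray]
    grid: GridSpec

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, "
                    f"grid expects {self.grid.shape}"
                )
            if np.issubdtype(arr.dtype, np.floating) and np.nanmin(arr) < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None


# 26-connectivity structuring element, the component rule used throughout.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NuclearMask:
    """Binary 3-D mask of a single nucleus.

    Invariant: nonempty and (when produced by the segmentation or the
    generator) a single 26-connected component.
    """

    mask: np.ndarray
    grid: GridSpec
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )
        if not self.mask.any():
            raise ValueError("nuclear mask is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """Voxel-coverage volume in µm³ (count × voxel volume)."""
        return self.voxel_count * self.grid.voxel_volume

    def centroid(self) -> np.ndarray:
        """Geometric centroid of the mask in physical (z, y, x) µm."""
        idx = np.argwhere(self.mask)
        return (idx.mean(axis=0) + 0.5) * np.asarray(self.grid.spacing)

    def is_connected(self) -> bool:
        _, n = ndimage.label(self.mask, structure=CONNECTIVITY_26)
        return n == 1


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 26-connected component of a binary array.

    Ties are broken by the component whose centroid has the lowest
    (z, y, x) coordinate tuple.
    """
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    if n == 1:
        return labels == 1
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    candidates = np.flatnonzero(counts == best) + 1
    if len(candidates) == 1:
        return labels == candidates[0]
    centroids = ndimage.center_of_mass(mask, labels, candidates)
    order = sorted(range(len(candidates)), key=lambda i: tuple(centroids[i]))
    return labels == candidates[order[0]]
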