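"""Spatial containers shared by every stage of the pipeline.

All maps (dose, radio-sensitivity, probability, reliability) live on a common
:class:`GridSpec`: a fixed 2D or 3D voxel grid with physical spacing and a
boolean region-of-interest (ROI) mask.  Spatial normalization / registration
of clinical dose maps to this common grid is assumed done upstream.

Internally the model code works on ROI-flattened vectors (length ``M`` =
number of ROI voxels, C-order); the helpers here convert between full-grid
arrays and ROI vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["GridSpec", "DoseMap", "RSMap", "stack_roi_values"]


@dataclass(frozen=True)
class GridSpec:
    """A fixed voxel grid with physical spacing and an ROI mask.

    Parameters
    ----------
    shape
        Integer extents per axis (>= 2 each); 2D or 3D.
    spacing
        Physical voxel size per axis (> 0), arbitrary length units.
    roi_mask
        Boolean array of ``shape`` selecting the region of interest.
        ``None`` selects every voxel.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...] = ()
    roi_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got shape {shape}")
        if any(s < 2 for s in shape):
            raise ValueError(f"all grid extents must be >= 2, got {shape}")
        spacing = self.spacing or (1.0,) * len(shape)
        if np.isscalar(spacing):
            spacing = (float(spacing),) * len(shape)
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != len(shape):
            raise ValueError("spacing must have one entry per axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "spacing", spacing)
        mask = self.roi_mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("roi_mask shape does not match grid shape")
            if not mask.any():
                raise ValueError("roi_mask must select at least one voxel")
        mask.setflags(write=False)
        object.__setattr__(self, "roi_mask", mask)

    # -- derived geometry ---------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_roi(self) -> int:
        """Number of ROI voxels (the M of the voxelwise backbone)."""
        return int(self.roi_mask.sum())

    @property
    def roi_size(self) -> float:
        """Linear size L of the ROI: longest side of its physical bounding box."""
        idx = np.nonzero(self.roi_mask)
        extents = [
            (ax.max() - ax.min() + 1) * sp for ax, sp in zip(idx, self.spacing)
        ]
        return float(max(extents))

    def roi_coords(self) -> np.ndarray:
        """Physical coordinates (voxel centers) of ROI voxels, shape (M, ndim)."""
        idx = np.nonzero(self.roi_mask)
        return np.stack(
            [ax * sp for ax, sp in zip(idx, self.spacing)], axis=-1
        ).astype(float)

    def roi_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (lo, hi) corners of the ROI bounding box (voxel centers)."""
        idx = np.nonzero(self.roi_mask)
        lo = np.array([ax.min() * sp for ax, sp in zip(idx, self.spacing)])
        hi = np.array([ax.max() * sp for ax, sp in zip(idx, self.spacing)])
        return lo, hi

    # -- ROI <-> full grid --------------------------------------------------

    def to_roi(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("array shape does not match grid shape")
        return values[self.roi_mask]

    def from_roi(self, roi_values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        roi_values = np.asarray(roi_values, dtype=float)
        if roi_values.shape != (self.n_roi,):
            raise ValueError("ROI vector has wrong length")
        out = np.full(self.shape, fill, dtype=float)
        out[self.roi_mask] = roi_values
        return out

    def compatible(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and bool(np.array_equal(self.roi_mask, other.roi_mask))
        )


def _check_map(grid: GridSpec, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} != grid shape {grid.shape}")
    roi = values[grid.roi_mask]
    if not np.all(np.isfinite(roi)):
        raise ValueError(f"{name} has non-finite values inside the ROI")
    if (roi < 0).any():
        raise ValueError(f"{name} has negative values inside the ROI")
    return values


@dataclass(frozen=True)
class DoseMap:
    """Nonnegative scalar dose per voxel (arbitrary units or Gy) on a grid."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_map(self.grid, self.values, "dose"))

    def roi_values(self) -> np.ndarray:
        return self.grid.to_roi(self.values)


@dataclass(frozen=True)
class RSMap:
    """Nonnegative radio-sensitivity weight per voxel (arbitrary units)."""

    grid: GridSpec
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = _check_map(self.grid, self.weights, "radio-sensitivity")
        if w[self.grid.roi_mask].sum() <= 0:
            raise ValueError("radio-sensitivity weights sum to zero over the ROI")
        object.__setattr__(self, "weights", w)

    def roi_values(self) -> np.ndarray:
        return self.grid.to_roi(self.weights)


def stack_roi_values(maps: Sequence[DoseMap]) -> np.ndarray:
    """Stack a cohort of dose maps into an (N, M) matrix of ROI voxel doses.

    All maps must share one grid (shape, spacing and ROI mask).
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    grid = maps[0].grid
    for i, m in enumerate(maps):
        if not grid.compatible(m.grid):
            raise ValueError(f"map {i} is not on the common grid")
    return np.stack([m.roi_values() for m in maps], axis=0)
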