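"""Grid geometry shared by every pipeline stage.

All rasters are 2-D float64 :class:`numpy.ndarray` in row-major order with
row 0 at the top. Cells outside ``GridSpec.valid_mask`` carry no data; on
disk they are stored as the nodata value, in memory they are NaN (or
ignored through the mask, depending on the operation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Abstract raster grid: shape, cell size and the analysable-cell mask.

    Parameters
    ----------
    nrows, ncols:
        Grid dimensions; their product must be at least 4.
    cell_size:
        Side length of a square cell in arbitrary map units (> 0).
    valid_mask:
        Boolean array of shape ``(nrows, ncols)`` marking analysable cells;
        at least one cell must be valid. ``None`` means all cells valid.
    """

    nrows: int
    ncols: int
    cell_size: float = 1.0
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1 or self.nrows * self.ncols < 4:
            raise ValueError(
                f"grid must have nrows*ncols >= 4, got {self.nrows}x{self.ncols}"
            )
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.valid_mask is None:
            mask = np.ones((self.nrows, self.ncols), dtype=bool)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
            if mask.shape != (self.nrows, self.ncols):
                raise ValueError(
                    f"valid_mask shape {mask.shape} != grid {(self.nrows, self.ncols)}"
                )
            if not mask.any():
                raise ValueError("valid_mask has no valid cells")
        mask.setflags(write=False)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area(self) -> float:
        return float(self.cell_size) ** 2

    def valid_indices(self) -> np.ndarray:
        """Flat (row-major) indices of valid cells, ascending."""
        return np.flatnonzero(self.valid_mask.ravel())

    def new_raster(self, fill: float = np.nan) -> np.ndarray:
        """Allocate a float64 raster with invalid cells set to NaN."""
        out = np.full(self.shape, fill, dtype=np.float64)
        out[~self.valid_mask] = np.nan
        return out

    def same_grid(self, other: "GridSpec") -> bool:
        return self.shape == other.shape and np.array_equal(
            self.valid_mask, other.valid_mask
        )
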