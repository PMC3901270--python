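"""Region-merging peak detection.

Three steps: (1) every cell is assigned to the class *peak* or
*non-peak* by a one-dimensional 2-means clustering of all intensities
(centers initialised at the minimum and maximum, Lloyd iterations, so
the result is deterministic); (2) neighboring peak cells are linked into
8-connected regions, discarding regions below a minimum size; (3) each
region is summarised by its centroid point — the member cell with the
smallest mean Euclidean distance (in index space) to all other member
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .model import MeasurementGrid, Peak, PeakList

Region = List[Tuple[int, int]]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class RegionMergeConfig:
    max_kmeans_iter: int = 100
    kmeans_tol: float = 1e-6
    min_region_size: int = 5  # cells

    def validate(self) -> None:
        if self.max_kmeans_iter <= 0 or self.kmeans_tol <= 0 or self.min_region_size <= 0:
            raise ValueError("all RegionMergeConfig fields must be positive")


def binarize_intensities(
    grid: MeasurementGrid, config: RegionMergeConfig | None = None
) -> np.ndarray:
    """2-means over all cell intensities; True where a cell belongs to
    the higher-center class."""
    config = config or RegionMergeConfig()
    x = grid.S.ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("constant grid has no peak/non-peak structure")
    c_lo, c_hi = lo, hi
    for _ in range(config.max_kmeans_iter):
        mid = (c_lo + c_hi) / 2.0
        high = x > mid
        new_lo = float(x[~high].mean()) if np.any(~high) else c_lo
        new_hi = float(x[high].mean()) if np.any(high) else c_hi
        if abs(new_lo - c_lo) < config.kmeans_tol and abs(new_hi - c_hi) < config.kmeans_tol:
            c_lo, c_hi = new_lo, new_hi
            break
        c_lo, c_hi = new_lo, new_hi
    return (grid.S > (c_lo + c_hi) / 2.0)


def link_regions(
    mask: np.ndarray, config: RegionMergeConfig | None = None
) -> List[Region]:
    """8-connected components of True cells; components smaller than
    min_region_size are discarded.  Regions are returned in label order
    (first-encounter row-major)."""
    config = config or RegionMergeConfig()
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    regions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labeled == lab)
        if len(rows) >= config.min_region_size:
            regions.append([(int(r), int(c)) for r, c in zip(rows, cols)])
    return regions


def region_centroid(region: Region, grid: MeasurementGrid) -> Peak:
    """Member cell minimising the mean Euclidean distance (index space)
    to all other members; ties broken by higher intensity then by
    lexicographic index."""
    if not region:
        raise ValueError("region must be non-empty")
    pts = np.array(region, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    mean_dist = np.sqrt((diff ** 2).sum(-1)).sum(1) / max(len(region) - 1, 1)
    intens = np.array([grid.S[r, c] for r, c in region])
    best = min(
        range(len(region)),
        key=lambda k: (mean_dist[k], -intens[k], region[k]),
    )
    row, col = region[best]
    return Peak(
        i=grid.metadata.measurement_id,
        r=float(grid.R[row]),
        t=float(grid.T[col]),
        s=float(grid.S[row, col]),
    )


def detect(grid: MeasurementGrid, config: RegionMergeConfig | None = None) -> PeakList:
    """Binarize → link regions → one centroid peak per region."""
    config = config or RegionMergeConfig()
    config.validate()
    mask = binarize_intensities(grid, config)
    regions = link_regions(mask, config)
    return PeakList(
        detector="regionmerge",
        peaks=[region_centroid(reg, grid) for reg in regions],
    )
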