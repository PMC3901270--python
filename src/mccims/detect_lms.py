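"""Local maxima search with a "significant neighborhood" rule.

A cell is a local maximum if all 8 neighbors have strictly lower
intensity.  A maximum is reported as a peak only if its neighborhood is
*significant*: its own intensity and all 8 neighbors exceed the
threshold ``I``, and at least ``A`` additional adjacent cells — cells on
the 16-cell perimeter of the 5×5 window around it — exceed ``I`` as
well.  Defaults are ``I = 10`` and ``A = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .model import MeasurementGrid, Peak, PeakList


@dataclass
class LMSConfig:
    intensity_threshold: float = 10.0  # I, signal units
    additional_points: int = 2         # A

    def validate(self) -> None:
        if self.additional_points < 0:
            raise ValueError("additional_points must be >= 0")


def local_maxima(grid: MeasurementGrid) -> List[Tuple[int, int]]:
    """All interior cells strictly greater than each of their 8
    neighbors, in row-major order.  Border cells are never returned."""
    S = grid.S
    if S.shape[0] < 3 or S.shape[1] < 3:
        raise ValueError("grid must be at least 3x3 for local maxima search")
    C = S[1:-1, 1:-1]
    higher = np.ones_like(C, dtype=bool)
    for dr in (-1, 0, 1):
        for dt in (-1, 0, 1):
            if dr == 0 and dt == 0:
                continue
            higher &= C > S[1 + dr : S.shape[0] - 1 + dr, 1 + dt : S.shape[1] - 1 + dt]
    rows, cols = np.nonzero(higher)
    return [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]


def is_significant(
    grid: MeasurementGrid, pos: Tuple[int, int], config: LMSConfig | None = None
) -> bool:
    """Significant-neighborhood test at an interior cell.

    Perimeter cells of the 5×5 window that fall outside the grid count
    as failing the threshold.
    """
    config = config or LMSConfig()
    row, col = pos
    S = grid.S
    I = config.intensity_threshold
    if not (1 <= row < S.shape[0] - 1 and 1 <= col < S.shape[1] - 1):
        raise ValueError(f"position {pos} is not interior")
    block = S[row - 1 : row + 2, col - 1 : col + 2]
    if not np.all(block > I):
        return False
    n_extra = 0
    for dr in range(-2, 3):
        for dt in range(-2, 3):
            if max(abs(dr), abs(dt)) != 2:
                continue  # only the 5x5 perimeter
            rr, tt = row + dr, col + dt
            if 0 <= rr < S.shape[0] and 0 <= tt < S.shape[1] and S[rr, tt] > I:
                n_extra += 1
    return n_extra >= config.additional_points


def detect(grid: MeasurementGrid, config: LMSConfig | None = None) -> PeakList:
    """One peak per significant local maximum."""
    config = config or LMSConfig()
    config.validate()
    peaks = []
    for row, col in local_maxima(grid):
        if is_significant(grid, (row, col), config):
            peaks.append(
                Peak(
                    i=grid.metadata.measurement_id,
                    r=float(grid.R[row]),
                    t=float(grid.T[col]),
                    s=float(grid.S[row, col]),
                )
            )
    return PeakList(detector="lms", peaks=peaks)
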