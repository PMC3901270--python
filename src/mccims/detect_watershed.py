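"""Water-level (watershed) peak detection.

The grid is treated as a landscape of hills; an imaginary water level
is lowered continuously.  In the deterministic limit this is a sweep
over cells in strictly descending intensity order: a newly uncovered
cell that touches an already-labeled cell (8-connectivity) inherits the
label of its highest-intensity labeled neighbor; a cell with no labeled
neighbor founds a new label — a new peak at that cell.  The sweep stops
once the level drops below ``min_level``.

Ties are broken deterministically: equal intensities are processed in
(row, column) lexicographic order, and a tie among labeled neighbors is
resolved toward the lowest label id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MeasurementGrid, Peak, PeakList


@dataclass
class WatershedConfig:
    min_level: float = 10.0  # stop once the water level drops below this

    def validate(self) -> None:
        if not np.isfinite(self.min_level):
            raise ValueError("min_level must be finite")


def watershed_detect(
    grid: MeasurementGrid, config: WatershedConfig | None = None
) -> PeakList:
    config = config or WatershedConfig()
    config.validate()
    S = grid.S
    n_r, n_t = S.shape
    flat = S.ravel()
    # descending intensity, ties by (row, col): stable sort on -intensity
    order = np.argsort(-flat, kind="stable")
    labels = np.full(S.shape, -1, dtype=int)
    founders = []  # (row, col) per label
    for idx in order:
        row, col = divmod(int(idx), n_t)
        if S[row, col] < config.min_level:
            break
        best_label = -1
        best_s = -np.inf
        for dr in (-1, 0, 1):
            for dt in (-1, 0, 1):
                if dr == 0 and dt == 0:
                    continue
                rr, tt = row + dr, col + dt
                if 0 <= rr < n_r and 0 <= tt < n_t and labels[rr, tt] >= 0:
                    s_n = S[rr, tt]
                    lab = labels[rr, tt]
                    if s_n > best_s or (s_n == best_s and lab < best_label):
                        best_s = s_n
                        best_label = lab
        if best_label >= 0:
            labels[row, col] = best_label
        else:
            labels[row, col] = len(founders)
            founders.append((row, col))
    peaks = [
        Peak(
            i=grid.metadata.measurement_id,
            r=float(grid.R[row]),
            t=float(grid.T[col]),
            s=float(S[row, col]),
        )
        for row, col in founders
    ]
    return PeakList(detector="watershed", peaks=peaks)


def detect(grid: MeasurementGrid, config: WatershedConfig | None = None) -> PeakList:
    return watershed_detect(grid, config)
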