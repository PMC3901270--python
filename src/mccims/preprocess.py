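"""Four-stage denoising of a measurement grid.

The stages run in a fixed order:

1. RIP compensation — subtract the median of each contour line (matrix
   column), removing the reactant-ion-peak band present in every
   spectrum.
2. Low-pass filter — 2-D discrete Fourier transform, discard high
   spatial frequencies, inverse transform.
3. 2-D Gaussian blur.
4. Savitzky–Golay smoothing of every spectrum (row) along the drift
   axis, window 9 points.

All stages preserve the grid's dimensions and axes.  Negative values
after RIP compensation are kept; thresholding is the detectors' job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .model import MeasurementGrid


@dataclass
class PreprocessConfig:
    """Stage parameters.

    dft_keep_fraction : fraction of the Nyquist band kept per axis.
    blur_sigma_t, blur_sigma_r : Gaussian SDs in grid cells.
    savgol_window : odd window length (cells) along the drift axis.
    savgol_order : polynomial degree of the Savitzky–Golay fit.
    """

    dft_keep_fraction: float = 0.25
    blur_sigma_t: float = 2.0
    blur_sigma_r: float = 2.0
    savgol_window: int = 9
    savgol_order: int = 2

    def validate(self) -> None:
        if not 0 < self.dft_keep_fraction <= 1:
            raise ValueError("dft_keep_fraction must lie in (0, 1]")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        if self.blur_sigma_t <= 0 or self.blur_sigma_r <= 0:
            raise ValueError("blur sigmas must be positive")


def rip_compensation(grid: MeasurementGrid) -> MeasurementGrid:
    """Subtract the per-column median from every column of S."""
    medians = np.median(grid.S, axis=0, keepdims=True)
    return grid.copy_with(S=grid.S - medians)


def dft_lowpass(grid: MeasurementGrid, keep_fraction: float = 0.25) -> MeasurementGrid:
    """Zero every 2-D DFT coefficient whose frequency index exceeds
    ``keep_fraction`` of the Nyquist band on either axis; DC is always
    kept, so constant grids pass unchanged."""
    S = grid.S
    F = np.fft.fft2(S)
    mask = np.outer(
        _axis_keep(S.shape[0], keep_fraction), _axis_keep(S.shape[1], keep_fraction)
    )
    return grid.copy_with(S=np.real(np.fft.ifft2(F * mask)))


def _axis_keep(n: int, keep_fraction: float) -> np.ndarray:
    # symmetric band: index k has frequency min(k, n-k) of Nyquist n//2
    k = np.arange(n)
    freq = np.minimum(k, n - k)
    return (freq <= keep_fraction * (n // 2)).astype(float)


def gaussian_blur(
    grid: MeasurementGrid, sigma_t: float = 2.0, sigma_r: float = 2.0
) -> MeasurementGrid:
    """Separable Gaussian convolution (kernel truncated at 4σ, edge
    replication at the boundary)."""
    if sigma_t <= 0 or sigma_r <= 0:
        raise ValueError("blur sigmas must be positive")
    S = ndimage.gaussian_filter(
        grid.S, sigma=(sigma_r, sigma_t), mode="nearest", truncate=4.0
    )
    return grid.copy_with(S=S)


def savitzky_golay_rows(
    grid: MeasurementGrid, window: int = 9, order: int = 2
) -> MeasurementGrid:
    """Savitzky–Golay smoothing of every spectrum along the drift axis.

    Edge cells are filled by evaluating the polynomial fitted to the
    terminal window.
    """
    if grid.n_t < window:
        raise ValueError(
            f"drift axis has {grid.n_t} points, fewer than window {window}"
        )
    S = signal.savgol_filter(grid.S, window, order, axis=1, mode="interp")
    return grid.copy_with(S=S)


def preprocess_pipeline(
    grid: MeasurementGrid, config: PreprocessConfig | None = None
) -> MeasurementGrid:
    """RIP compensation → DFT low-pass → Gaussian blur → Savitzky–Golay."""
    config = config or PreprocessConfig()
    config.validate()
    grid = rip_compensation(grid)
    grid = dft_lowpass(grid, config.dft_keep_fraction)
    grid = gaussian_blur(grid, config.blur_sigma_t, config.blur_sigma_r)
    grid = savitzky_golay_rows(grid, config.savgol_window, config.savgol_order)
    return grid
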