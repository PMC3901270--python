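"""Peak model estimation (PME).

Each peak is modelled as a product of two shifted inverse Gaussian
densities — one along the drift axis, one along the retention axis —
weighted by a volume parameter; a uniform noise component over the grid
rectangle absorbs the background.  Normalised cell intensities are
treated as a weighted sample over ``(t, r)`` and the mixture is fitted
by expectation maximisation.  Seeds (one component per seed) come from
sign changes of the discrete first derivative along both axes.

The shifted inverse Gaussian is right-skewed, matching the tailing of
chromatographic peaks, and has closed-form maximum-likelihood updates
for its mean and shape parameters when the offset is held fixed —
offsets are pinned a few cells below each seed.  Unlike the discrete
detectors, the fitted component modes are continuous positions that
need not lie on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .model import MeasurementGrid, Peak, PeakList, PMEComponent, PMEModel


@dataclass
class PMEConfig:
    seed_min_intensity: float = 10.0  # signal units
    max_em_iter: int = 200
    loglik_tol: float = 1e-6          # relative log-likelihood change
    # each offset is pinned this many left half-widths (at half maximum,
    # measured from the seed along its axis) below the seed position; a
    # width-scaled margin keeps the whole left flank inside the
    # component's support regardless of grid resolution
    offset_halfwidths: float = 5.0

    def validate(self) -> None:
        if (
            self.seed_min_intensity <= 0
            or self.max_em_iter <= 0
            or self.loglik_tol <= 0
            or self.offset_halfwidths <= 0
        ):
            raise ValueError("all PMEConfig fields must be positive")


# ---------------------------------------------------------------- seeding

def seed_detect(
    grid: MeasurementGrid, config: PMEConfig | None = None
) -> List[Tuple[int, int]]:
    """Cells where the first derivative changes sign + to − along both
    the row (spectrum) and the column (chromatogram), with intensity at
    least ``seed_min_intensity``."""
    config = config or PMEConfig()
    S = grid.S
    seeds = []
    for row in range(1, S.shape[0] - 1):
        for col in range(1, S.shape[1] - 1):
            if S[row, col] < config.seed_min_intensity:
                continue
            row_up = S[row, col] - S[row, col - 1] > 0
            row_down = S[row, col + 1] - S[row, col] < 0
            col_up = S[row, col] - S[row - 1, col] > 0
            col_down = S[row + 1, col] - S[row, col] < 0
            if row_up and row_down and col_up and col_down:
                seeds.append((row, col))
    return seeds


# ------------------------------------------- shifted inverse Gaussian

def sig_pdf(x, mu: float, lam: float, o: float = 0.0):
    """Density of the shifted inverse Gaussian IG(mu, lam) + o.

    Zero for x <= o; integrates to 1 over (o, inf).
    """
    x = np.asarray(x, dtype=float)
    y = x - o
    out = np.zeros_like(y)
    pos = y > 0
    yp = y[pos]
    out[pos] = np.sqrt(lam / (2.0 * np.pi * yp ** 3)) * np.exp(
        -lam * (yp - mu) ** 2 / (2.0 * mu ** 2 * yp)
    )
    return out if out.shape else float(out)


def sig_mode(mu: float, lam: float, o: float = 0.0) -> float:
    """Closed-form mode of the shifted inverse Gaussian."""
    return mu * (math.sqrt(1.0 + 9.0 * mu ** 2 / (4.0 * lam ** 2)) - 3.0 * mu / (2.0 * lam)) + o


# ------------------------------------------------------------------ EM

def _axis_step(axis: np.ndarray) -> float:
    return float(np.mean(np.diff(axis))) if len(axis) > 1 else 1.0


def _left_halfwidths(S: np.ndarray, row: int, col: int) -> Tuple[int, int]:
    """Cells from the seed to the half-maximum point, walking toward
    smaller drift / retention values (minimum 1)."""
    half = 0.5 * S[row, col]
    j = col
    while j > 0 and S[row, j - 1] > half:
        j -= 1
    i = row
    while i > 0 and S[i - 1, col] > half:
        i -= 1
    return max(col - j, 1), max(row - i, 1)


def em_fit(
    grid: MeasurementGrid,
    seeds: Sequence[Tuple[int, int]],
    config: PMEConfig | None = None,
) -> PMEModel:
    """Fit the mixture of shifted-inverse-Gaussian products plus a
    uniform noise component by EM.

    Cell intensities (clipped at 0) are normalised to weights; offsets
    are fixed at the seed position minus ``offset_halfwidths`` left
    half-widths per axis, which gives closed-form M-steps for the IG
    mean and shape per axis.
    Mixture weights sum to 1 after every M-step and the weighted
    log-likelihood is non-decreasing.
    """
    config = config or PMEConfig()
    config.validate()
    if not seeds:
        raise ValueError("em_fit requires at least one seed")
    S = np.clip(grid.S, 0.0, None)
    total_mass = float(S.sum())
    if total_mass <= 0:
        raise ValueError("grid carries no positive mass")
    w = (S / total_mass).ravel()
    keep = w > 0
    w = w[keep]
    tt, rr = np.meshgrid(grid.T, grid.R)
    t_cells = tt.ravel()[keep]
    r_cells = rr.ravel()[keep]

    dt = _axis_step(grid.T)
    dr = _axis_step(grid.R)
    span_t = max(grid.T[-1] - grid.T[0], dt)
    span_r = max(grid.R[-1] - grid.R[0], dr)
    u_noise = 1.0 / (span_t * span_r)

    k = len(seeds)
    o_t = np.empty(k)
    o_r = np.empty(k)
    mu_t = np.empty(k)
    mu_r = np.empty(k)
    for c, (row, col) in enumerate(seeds):
        h_t, h_r = _left_halfwidths(S, row, col)
        o_t[c] = grid.T[col] - config.offset_halfwidths * h_t * dt
        o_r[c] = grid.R[row] - config.offset_halfwidths * h_r * dr
        mu_t[c] = grid.T[col] - o_t[c]
        mu_r[c] = grid.R[row] - o_r[c]
    lam_t = 10.0 * mu_t
    lam_r = 10.0 * mu_r
    noise_w = 0.05
    comp_w = np.full(k, (1.0 - noise_w) / k)

    loglik_history: List[float] = []
    prev_ll = -np.inf
    for iteration in range(config.max_em_iter):
        dens = np.empty((k + 1, len(w)))
        for c in range(k):
            dens[c] = sig_pdf(t_cells, mu_t[c], lam_t[c], o_t[c]) * sig_pdf(
                r_cells, mu_r[c], lam_r[c], o_r[c]
            )
        dens[k] = u_noise
        weights_all = np.concatenate([comp_w, [noise_w]])
        mix = weights_all[:, None] * dens
        totals = mix.sum(axis=0)
        ll = float(np.sum(w * np.log(totals)))
        if not np.isfinite(ll):
            raise ValueError(f"non-finite log-likelihood at EM iteration {iteration}")
        loglik_history.append(ll)
        resp = mix / totals[None, :]

        # M-step: responsibility-weighted mass fractions and IG updates
        mass = resp @ w  # length k+1
        comp_w = mass[:k].copy()
        noise_w = float(mass[k])
        if abs(comp_w.sum() + noise_w - 1.0) > 1e-9:
            raise ValueError(
                f"mixture weights sum to {comp_w.sum() + noise_w} at EM "
                f"iteration {iteration}"
            )
        for c in range(k):
            if mass[c] <= 1e-300:
                continue  # starved component keeps its parameters
            rw = resp[c] * w / mass[c]
            yt = t_cells - o_t[c]
            yr = r_cells - o_r[c]
            # responsibilities vanish outside the support (y <= 0); mask
            # those cells so 0 * inf does not poison the update
            sup = (yt > 0) & (yr > 0)
            rw = np.where(sup, rw, 0.0)
            yt = np.where(sup, yt, 1.0)
            yr = np.where(sup, yr, 1.0)
            mu_t[c] = float(rw @ yt)
            mu_r[c] = float(rw @ yr)
            inv_lt = float(rw @ (1.0 / yt)) - 1.0 / mu_t[c]
            inv_lr = float(rw @ (1.0 / yr)) - 1.0 / mu_r[c]
            lam_t[c] = 1.0 / max(inv_lt, 1e-12)
            lam_r[c] = 1.0 / max(inv_lr, 1e-12)

        if prev_ll > -np.inf and abs(ll - prev_ll) < config.loglik_tol * abs(prev_ll):
            break
        prev_ll = ll

    components = [
        PMEComponent(
            mu_t=float(mu_t[c]),
            lam_t=float(lam_t[c]),
            o_t=float(o_t[c]),
            mu_r=float(mu_r[c]),
            lam_r=float(lam_r[c]),
            o_r=float(o_r[c]),
            weight=float(comp_w[c]),
        )
        for c in range(k)
    ]
    model = PMEModel(
        components=components,
        noise_weight=float(noise_w),
        total_mass=total_mass,
        loglik_history=loglik_history,
    )
    model.validate()
    return model


def detect(
    grid: MeasurementGrid,
    config: PMEConfig | None = None,
    seeds: Sequence[Tuple[int, int]] | None = None,
) -> PeakList:
    """Seed, fit, and report one peak per surviving mixture component.

    Peak positions are the continuous marginal modes of each component;
    peak intensity is the component's share of the total grid mass.
    Components with weight below 1e-4 are dropped.
    """
    config = config or PMEConfig()
    clipped = grid.copy_with(S=np.clip(grid.S, 0.0, None))
    if seeds is None:
        seeds = seed_detect(clipped, config)
    if not seeds:
        return PeakList(detector="pme", peaks=[])
    model = em_fit(clipped, seeds, config)
    peaks = []
    for comp in model.components:
        if comp.weight < 1e-4:
            continue
        peaks.append(
            Peak(
                i=grid.metadata.measurement_id,
                r=max(sig_mode(comp.mu_r, comp.lam_r, comp.o_r), 0.0),
                t=sig_mode(comp.mu_t, comp.lam_t, comp.o_t),
                s=comp.weight * model.total_mass,
            )
        )
    return PeakList(detector="pme", peaks=peaks)


def peaks_to_seeds(grid: MeasurementGrid, peak_list: PeakList) -> List[Tuple[int, int]]:
    """Map a peak list onto nearest grid cells for use as EM seeds."""
    seeds = []
    for p in peak_list:
        row = int(np.argmin(np.abs(grid.R - p.r)))
        col = int(np.argmin(np.abs(grid.T - p.t)))
        seeds.append((row, col))
    return seeds
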