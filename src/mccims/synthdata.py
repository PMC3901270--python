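"""Synthetic MCC/IMS cohort simulator with known ground truth.

Clinical breath measurements are confidential, so the benchmark runs on
simulated measurements that emulate their salient structure: a
reactant-ion-peak (RIP) contour — a high-intensity band at a fixed
inverse reduced mobility present at every retention time — plus
additively superposed compound peaks shaped as volume-weighted products
of shifted inverse Gaussian densities (right-skewed tailing on both
axes), a small positive baseline, i.i.d. Gaussian noise, bounded
per-measurement positional jitter, and a two-class cohort (30 control
K, 39 diseased D) in which a subset of peaks carries a multiplicative
class effect on intensity.

Because the RIP band is constant over retention time, per-column median
subtraction removes it almost exactly — the same reason the real
preprocessing chain starts with a median filter per contour line.

The default grid is desk-scale (300 retention × 500 drift cells) rather
than instrument resolution (12,500 points per spectrum); it is
configurable upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detect_pme import sig_mode, sig_pdf
from .model import MeasurementGrid, MeasurementMetadata, Peak, PeakList

# jitter draws are clipped at this many SDs so that, with the default
# jitter magnitudes, peaks of one compound always stay within the merge
# tolerances of each other (bounded instrument drift)
_JITTER_CLIP_SD = 1.8


@dataclass
class SyntheticPeakSpec:
    """One simulated compound peak (parameters in physical units)."""

    mu_t: float
    lam_t: float
    o_t: float
    mu_r: float
    lam_r: float
    o_r: float
    volume: float = 50.0
    jitter_t: float = 0.0005  # SD, Vs/cm²; keep < 0.003/2
    jitter_r: float = 1.0     # SD, s; keep < 3.0/2
    presence_prob: float = 1.0
    class_effect: float = 1.0  # multiplies intensity for class D

    @property
    def t_mode(self) -> float:
        return sig_mode(self.mu_t, self.lam_t, self.o_t)

    @property
    def r_mode(self) -> float:
        return sig_mode(self.mu_r, self.lam_r, self.o_r)


def peak_at(
    t_mode: float,
    r_mode: float,
    volume: float = 50.0,
    mu_t: float = 0.04,
    lam_t: float = 1.0,
    mu_r: float = 20.0,
    lam_r: float = 222.0,
    **kwargs,
) -> SyntheticPeakSpec:
    """Build a peak spec whose density mode lands at (t_mode, r_mode)."""
    return SyntheticPeakSpec(
        mu_t=mu_t,
        lam_t=lam_t,
        o_t=t_mode - sig_mode(mu_t, lam_t, 0.0),
        mu_r=mu_r,
        lam_r=lam_r,
        o_r=r_mode - sig_mode(mu_r, lam_r, 0.0),
        volume=volume,
        **kwargs,
    )


def default_peaks() -> List[SyntheticPeakSpec]:
    """Eight compound peaks, three of them differential between classes."""
    return [
        peak_at(0.52, 40.0, volume=60.0),
        peak_at(0.56, 120.0, volume=50.0, class_effect=1.8),
        peak_at(0.61, 250.0, volume=45.0),
        peak_at(0.66, 80.0, volume=55.0, class_effect=0.55),
        peak_at(0.71, 320.0, volume=40.0),
        peak_at(0.76, 150.0, volume=50.0, class_effect=2.2),
        peak_at(0.82, 450.0, volume=65.0),
        peak_at(0.88, 60.0, volume=35.0),
    ]


@dataclass
class CohortSpec:
    n_K: int = 30
    n_D: int = 39
    peaks: List[SyntheticPeakSpec] = field(default_factory=default_peaks)
    rip_t: float = 0.46        # Vs/cm²
    rip_height: float = 400.0  # signal units
    rip_sigma_t: float = 0.008
    baseline: float = 2.0
    noise_sd: float = 1.0
    n_t: int = 500
    n_r: int = 300
    t_range: Tuple[float, float] = (0.4, 0.9)
    r_range: Tuple[float, float] = (0.0, 600.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_K < 1 or self.n_D < 1:
            raise ValueError("class counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def axes(self) -> Tuple[np.ndarray, np.ndarray]:
        T = np.linspace(*self.t_range, self.n_t)
        R = np.linspace(*self.r_range, self.n_r)
        return T, R


@dataclass
class SyntheticCohort:
    measurements: List[MeasurementGrid]
    labels: Dict[str, str]
    ground_truth: Dict[str, PeakList]

    def all_truth_peaks(self) -> PeakList:
        peaks = [p for pl in self.ground_truth.values() for p in pl]
        return PeakList(detector="truth", peaks=peaks)


def _clipped_normal(rng: np.random.Generator, sd: float) -> float:
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -_JITTER_CLIP_SD * sd, _JITTER_CLIP_SD * sd))


def simulate_measurement(
    spec: CohortSpec,
    label: str,
    measurement_id: str,
    seed: int,
) -> Tuple[MeasurementGrid, PeakList]:
    """Simulate one measurement and its ground-truth peak list.

    The ground truth records each realised (present) peak at its
    jittered mode position with its realised mass (summed contribution
    over the grid).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    T, R = spec.axes()
    S = np.full((spec.n_r, spec.n_t), spec.baseline, dtype=float)
    # RIP: a Gaussian band in t, constant over retention time
    S += spec.rip_height * np.exp(-0.5 * ((T - spec.rip_t) / spec.rip_sigma_t) ** 2)[None, :]

    truth: List[Peak] = []
    for pk in spec.peaks:
        present = rng.random() < pk.presence_prob
        jt = _clipped_normal(rng, pk.jitter_t)
        jr = _clipped_normal(rng, pk.jitter_r)
        if not present:
            continue
        volume = pk.volume * (pk.class_effect if label == "D" else 1.0)
        contribution = volume * np.outer(
            sig_pdf(R, pk.mu_r, pk.lam_r, pk.o_r + jr),
            sig_pdf(T, pk.mu_t, pk.lam_t, pk.o_t + jt),
        )
        S += contribution
        truth.append(
            Peak(
                i=measurement_id,
                r=sig_mode(pk.mu_r, pk.lam_r, pk.o_r + jr),
                t=sig_mode(pk.mu_t, pk.lam_t, pk.o_t + jt),
                s=float(contribution.sum()),
            )
        )
    if spec.noise_sd > 0:
        S += rng.normal(0.0, spec.noise_sd, size=S.shape)

    meta = MeasurementMetadata(
        measurement_id=measurement_id,
        drift_gas_flow=float(rng.uniform(97.0, 103.0)),
        sample_gas_flow=float(rng.uniform(97.0, 103.0)),
        carrier_gas_flow=float(rng.uniform(147.0, 153.0)),
        mcc_temperature=float(rng.uniform(38.5, 41.5)),
    )
    grid = MeasurementGrid(T=T, R=R, S=S, metadata=meta)
    grid.validate()
    return grid, PeakList(detector="truth", peaks=truth)


def simulate_cohort(spec: Optional[CohortSpec] = None) -> SyntheticCohort:
    """Simulate the full two-class cohort; deterministic in the master
    seed (per-measurement seeds are derived from it)."""
    spec = spec or CohortSpec()
    spec.validate()
    ids = [f"K{i + 1:02d}" for i in range(spec.n_K)] + [
        f"D{i + 1:02d}" for i in range(spec.n_D)
    ]
    labels = {m: m[0] for m in ids}
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(ids)) % (2 ** 31)
    measurements = []
    ground_truth = {}
    for mid, mseed in zip(ids, seeds):
        grid, truth = simulate_measurement(spec, labels[mid], mid, int(mseed))
        measurements.append(grid)
        ground_truth[mid] = truth
    return SyntheticCohort(
        measurements=measurements, labels=labels, ground_truth=ground_truth
    )
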