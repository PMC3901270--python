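"""Domain types for MCC/IMS measurements, peaks and peak clusters.

An MCC/IMS measurement is an ``|R| x |T|`` matrix of signal intensities:
rows are *spectra* (signal versus inverse reduced mobility at a fixed
retention time), columns are *contour lines* (signal versus retention
time at a fixed inverse reduced mobility).  A peak is summarised by the
measurement it came from, its position ``(r, t)`` on the two time axes
and its intensity ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List

import numpy as np

__all__ = [
    "MeasurementMetadata",
    "MeasurementGrid",
    "Peak",
    "PeakList",
    "PeakCluster",
    "FeatureMatrix",
    "PMEComponent",
    "PMEModel",
    "ValidationError",
]


class ValidationError(ValueError):
    """An object violates a domain-type invariant."""


@dataclass
class MeasurementMetadata:
    """Device settings recorded with a measurement.

    Flows are in mL/min, the column temperature in °C.  ``polarity`` is
    the ionisation polarity of the spectrometer ("positive"/"negative").
    """

    measurement_id: str
    drift_gas_flow: float = 100.0
    sample_gas_flow: float = 100.0
    carrier_gas_flow: float = 150.0
    mcc_temperature: float = 40.0
    drift_gas: str = "nitrogen"
    polarity: str = "positive"

    def validate(self) -> None:
        if not self.measurement_id:
            raise ValidationError("measurement_id must be non-empty")
        for name in ("drift_gas_flow", "sample_gas_flow", "carrier_gas_flow"):
            value = getattr(self, name)
            if value is None or value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value!r}")


@dataclass
class MeasurementGrid:
    """One measurement: axes ``T`` (inverse reduced mobility, Vs/cm²),
    ``R`` (retention time, s) and the ``|R| x |T|`` signal matrix ``S``."""

    T: np.ndarray
    R: np.ndarray
    S: np.ndarray
    metadata: MeasurementMetadata

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.S = np.asarray(self.S, dtype=float)

    @property
    def n_r(self) -> int:
        return len(self.R)

    @property
    def n_t(self) -> int:
        return len(self.T)

    def validate(self) -> None:
        self.metadata.validate()
        if self.T.ndim != 1 or self.R.ndim != 1:
            raise ValidationError("T and R must be one-dimensional")
        if len(self.T) == 0 or len(self.R) == 0:
            raise ValidationError("axes must be non-empty")
        if np.any(np.diff(self.T) <= 0):
            raise ValidationError("T axis must be strictly increasing")
        if np.any(np.diff(self.R) <= 0):
            raise ValidationError("R axis must be strictly increasing")
        if self.S.shape != (len(self.R), len(self.T)):
            raise ValidationError(
                f"S shape {self.S.shape} does not match |R|x|T| "
                f"({len(self.R)}, {len(self.T)})"
            )
        for name, arr in (("T", self.T), ("R", self.R), ("S", self.S)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")

    def copy_with(self, **kwargs) -> "MeasurementGrid":
        data = {"T": self.T, "R": self.R, "S": self.S, "metadata": self.metadata}
        data.update(kwargs)
        return MeasurementGrid(**data)


@dataclass(frozen=True)
class Peak:
    """A detected peak: measurement id ``i``, retention time ``r`` (s),
    inverse reduced mobility ``t`` (Vs/cm²) and intensity ``s``."""

    i: str
    r: float
    t: float
    s: float

    def validate(self) -> None:
        if self.r < 0:
            raise ValidationError(f"retention time must be >= 0, got {self.r}")
        if self.t <= 0:
            raise ValidationError(f"inverse reduced mobility must be > 0, got {self.t}")
        if not np.isfinite(self.s):
            raise ValidationError("peak intensity must be finite")


@dataclass
class PeakList:
    """An ordered collection of peaks with a provenance label."""

    detector: str
    peaks: List[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, idx):
        return self.peaks[idx]


@dataclass
class PeakCluster:
    """A cross-measurement group of peaks mapped to one putative compound.

    The representative position ``(r, t)`` is the position of the
    highest-intensity member.  ``intensity_by_measurement`` keeps one
    intensity per measurement (the maximum if several members of a
    measurement fell into the cluster).
    """

    cluster_id: str
    r: float
    t: float
    members: List[Peak] = field(default_factory=list)
    intensity_by_measurement: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.members:
            raise ValidationError("cluster must have at least one member")
        best = max(self.members, key=lambda p: p.s)
        if not (best.r == self.r and best.t == self.t):
            raise ValidationError(
                "representative position must equal the highest-intensity member"
            )


@dataclass
class FeatureMatrix:
    """Measurements × peak clusters intensity table with class labels.

    Labels use the two-class alphabet ``K`` (control) and ``D``
    (diseased).  A measurement without a peak in a cluster carries 0.
    """

    measurement_ids: List[str]
    cluster_ids: List[str]
    values: np.ndarray
    labels: Dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        if self.values.shape != (len(self.measurement_ids), len(self.cluster_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.measurement_ids)}, {len(self.cluster_ids)})"
            )
        if self.values.size and np.any(self.values < 0):
            raise ValidationError("feature intensities must be non-negative")
        for mid in self.measurement_ids:
            if mid not in self.labels:
                raise ValidationError(f"measurement {mid!r} has no class label")
            if self.labels[mid] not in ("K", "D"):
                raise ValidationError(
                    f"label for {mid!r} must be 'K' or 'D', got {self.labels[mid]!r}"
                )

    @property
    def y(self) -> np.ndarray:
        """Labels in measurement order."""
        return np.array([self.labels[m] for m in self.measurement_ids])


@dataclass
class PMEComponent:
    """One mixture component: a volume-weighted product of two shifted
    inverse Gaussian densities, one per axis."""

    mu_t: float
    lam_t: float
    o_t: float
    mu_r: float
    lam_r: float
    o_r: float
    weight: float

    def validate(self) -> None:
        for name in ("mu_t", "lam_t", "mu_r", "lam_r"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError("weight must lie in [0, 1]")


@dataclass
class PMEModel:
    """A fitted peak-model mixture: components plus a uniform noise part."""

    components: List[PMEComponent]
    noise_weight: float
    total_mass: float
    loglik_history: List[float] = field(default_factory=list)

    def validate(self) -> None:
        for c in self.components:
            c.validate()
        total = self.noise_weight + sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights sum to {total}, expected 1")
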