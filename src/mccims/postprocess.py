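"""Peak merging within measurements and clustering across measurements.

Two peaks P and Q with s(P) >= s(Q) are close enough to describe the
same compound if

    |t(P) - t(Q)| < 0.003  Vs/cm²   and
    |r(P) - r(Q)| < 3.0 + 0.1 * r(P)  s,

the retention tolerance widening with retention time because
chromatographic peaks broaden as they elute later.  Merging within a
measurement is a greedy sweep in descending intensity: a peak is
dropped if it is mergeable into an already-retained (stronger) peak.
The same sweep over the pooled peaks of all measurements — ignoring
which measurement a peak came from — groups peaks into *peak clusters*,
each summarised by its founder's position and one intensity per
measurement.  The clusters' intensities form the feature matrix used
for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .model import FeatureMatrix, Peak, PeakCluster, PeakList


@dataclass
class MergeConditions:
    t_tol: float = 0.003  # Vs/cm²
    r_base: float = 3.0   # s
    r_frac: float = 0.1   # dimensionless, times r(P)

    def validate(self) -> None:
        if self.t_tol <= 0 or self.r_base <= 0 or self.r_frac <= 0:
            raise ValueError("all merge tolerances must be positive")


def mergeable(p: Peak, q: Peak, c: MergeConditions | None = None) -> bool:
    """True iff Q lies within the position tolerances around the
    retained peak P (the retention tolerance is computed from r(P))."""
    c = c or MergeConditions()
    return (
        abs(p.t - q.t) < c.t_tol
        and abs(p.r - q.r) < c.r_base + p.r * c.r_frac
    )


def _sweep_order(peaks: Iterable[Peak]) -> List[Peak]:
    # descending intensity; ties by (r, t) lexicographic for determinism
    return sorted(peaks, key=lambda p: (-p.s, p.r, p.t))


def merge_within(peaks: Sequence[Peak], c: MergeConditions | None = None) -> PeakList:
    """Merge near-duplicate peaks of one measurement.

    Greedy sweep in descending intensity: each peak is dropped iff it is
    mergeable into some already-retained peak; retained peaks are
    returned in sweep order.
    """
    c = c or MergeConditions()
    peaks = list(peaks)
    ids = {p.i for p in peaks}
    if len(ids) > 1:
        raise ValueError(f"merge_within expects one measurement, got ids {sorted(ids)}")
    retained: List[Peak] = []
    for p in _sweep_order(peaks):
        if not any(mergeable(keeper, p, c) for keeper in retained):
            retained.append(p)
    return PeakList(detector="merged", peaks=retained)


def merge_all(peak_list: PeakList, c: MergeConditions | None = None) -> PeakList:
    """Apply merge_within separately to each measurement of a list."""
    by_id: Dict[str, List[Peak]] = {}
    for p in peak_list:
        by_id.setdefault(p.i, []).append(p)
    merged: List[Peak] = []
    for mid in sorted(by_id):
        merged.extend(merge_within(by_id[mid], c).peaks)
    return PeakList(detector=peak_list.detector, peaks=merged)


def cluster_across(
    peaks: Sequence[Peak], c: MergeConditions | None = None
) -> List[PeakCluster]:
    """Group the pooled peaks of all measurements into peak clusters.

    Greedy sweep in descending intensity ignoring measurement identity:
    a peak joins the first retained founder it is mergeable into, else
    founds a new cluster.  If several peaks of one measurement land in
    one cluster the maximum intensity is kept.
    """
    c = c or MergeConditions()
    clusters: List[PeakCluster] = []
    for p in _sweep_order(peaks):
        for cluster in clusters:
            founder = cluster.members[0]
            if mergeable(founder, p, c):
                cluster.members.append(p)
                prev = cluster.intensity_by_measurement.get(p.i, -np.inf)
                cluster.intensity_by_measurement[p.i] = max(prev, p.s)
                break
        else:
            clusters.append(
                PeakCluster(
                    cluster_id=f"c{len(clusters) + 1}",
                    r=p.r,
                    t=p.t,
                    members=[p],
                    intensity_by_measurement={p.i: p.s},
                )
            )
    return clusters


def build_feature_matrix(
    clusters: Sequence[PeakCluster],
    measurement_ids: Sequence[str],
    labels: Dict[str, str],
) -> FeatureMatrix:
    """Measurements × clusters intensity table; absent peaks are 0.

    Columns are ordered by descending total cluster intensity.
    """
    for mid in measurement_ids:
        if mid not in labels:
            raise ValueError(f"measurement {mid!r} has no class label")
    ordered = sorted(
        clusters,
        key=lambda cl: (-sum(cl.intensity_by_measurement.values()), cl.cluster_id),
    )
    values = np.zeros((len(measurement_ids), len(ordered)))
    for j, cluster in enumerate(ordered):
        for i, mid in enumerate(measurement_ids):
            values[i, j] = cluster.intensity_by_measurement.get(mid, 0.0)
    fm = FeatureMatrix(
        measurement_ids=list(measurement_ids),
        cluster_ids=[cl.cluster_id for cl in ordered],
        values=values,
        labels={m: labels[m] for m in measurement_ids},
    )
    fm.validate()
    return fm
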