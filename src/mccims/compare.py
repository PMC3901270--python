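"""Asymmetric overlap mapping between detectors' peak lists.

A peak P from list V *maps* to a peak Q from list W if both come from
the same measurement and lie within the position tolerances used for
merging (the retention tolerance computed from r(P), which makes the
relation — and hence the count table — asymmetric).  The overlap count
of V against W is the number of V-peaks with at least one mapping
partner in W; the diagonal of the table equals the list sizes, since
every peak maps to itself.
"""

from __future__ import annotations

from typing import Dict, Sequence

import pandas as pd

from .model import Peak, PeakList
from .postprocess import MergeConditions


def peaks_map(p: Peak, q: Peak, c: MergeConditions | None = None) -> bool:
    c = c or MergeConditions()
    return (
        p.i == q.i
        and abs(p.t - q.t) < c.t_tol
        and abs(p.r - q.r) < c.r_base + p.r * c.r_frac
    )


def overlap_count(v: PeakList, w: PeakList, c: MergeConditions | None = None) -> int:
    """Number of peaks in V that map to at least one peak in W."""
    c = c or MergeConditions()
    by_id: Dict[str, list] = {}
    for q in w:
        by_id.setdefault(q.i, []).append(q)
    return sum(
        1
        for p in v
        if any(peaks_map(p, q, c) for q in by_id.get(p.i, ()))
    )


def overlap_table(
    lists: Dict[str, PeakList] | Sequence[PeakList],
    c: MergeConditions | None = None,
) -> pd.DataFrame:
    """Mapping-count table: entry (V, W) = overlap_count(V, W).

    Not symmetric in general.
    """
    c = c or MergeConditions()
    if not isinstance(lists, dict):
        lists = {pl.detector: pl for pl in lists}
    if not lists:
        raise ValueError("overlap_table requires at least one peak list")
    names = list(lists)
    data = [
        [overlap_count(lists[v], lists[w], c) for w in names] for v in names
    ]
    return pd.DataFrame(data, index=names, columns=names)
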