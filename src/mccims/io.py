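"""Readers and writers for the plain-text measurement, peak-list and
feature-matrix formats.

Measurement dialect
-------------------
Comment lines starting with ``#`` carry ``key=value`` metadata.  The
first non-comment row is the comma-separated T axis (inverse reduced
mobility, Vs/cm²); every following row starts with the retention time in
seconds followed by that spectrum's intensities.  Values are written at
full float precision so write→read round trips are exact.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import (
    FeatureMatrix,
    MeasurementGrid,
    MeasurementMetadata,
    Peak,
    PeakList,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_FLOAT_FMT = "%.17g"

_METADATA_FLOAT_FIELDS = (
    "drift_gas_flow",
    "sample_gas_flow",
    "carrier_gas_flow",
    "mcc_temperature",
)
_METADATA_STR_FIELDS = ("measurement_id", "drift_gas", "polarity")

PEAK_LIST_COLUMNS = ["measurement_id", "peak_id", "t", "r", "s"]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


def read_measurement(path: PathLike) -> MeasurementGrid:
    """Read a measurement matrix file and validate all grid invariants."""
    path = Path(path)
    meta_kv = {}
    t_axis = None
    r_values = []
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if not body:
                    continue
                if "=" not in body:
                    raise FormatError(
                        f"{path}:{lineno}: malformed header line {line!r} "
                        "(expected key=value)"
                    )
                key, _, value = body.partition("=")
                meta_kv[key.strip()] = value.strip()
                continue
            fields = line.split(",")
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            if t_axis is None:
                t_axis = np.array(values)
            else:
                if len(values) != len(t_axis) + 1:
                    raise FormatError(
                        f"{path}:{lineno}: expected {len(t_axis) + 1} fields "
                        f"(retention time + spectrum), got {len(values)}"
                    )
                r_values.append(values[0])
                rows.append(values[1:])
    if t_axis is None:
        raise FormatError(f"{path}: no data rows")
    metadata = _metadata_from_kv(meta_kv, default_id=path.stem)
    grid = MeasurementGrid(
        T=t_axis, R=np.array(r_values), S=np.array(rows), metadata=metadata
    )
    grid.validate()
    return grid


def _metadata_from_kv(kv: dict, default_id: str) -> MeasurementMetadata:
    meta = MeasurementMetadata(measurement_id=kv.get("measurement_id", default_id))
    for name in _METADATA_FLOAT_FIELDS:
        if name in kv:
            try:
                setattr(meta, name, float(kv[name]))
            except ValueError as exc:
                raise FormatError(f"metadata field {name}={kv[name]!r}: {exc}") from exc
    for name in _METADATA_STR_FIELDS[1:]:
        if name in kv:
            setattr(meta, name, kv[name])
    return meta


def write_measurement(grid: MeasurementGrid, path: PathLike) -> None:
    """Write a measurement in the documented dialect."""
    grid.validate()
    path = Path(path)
    meta = grid.metadata
    with open(path, "w") as fh:
        fh.write(f"# measurement_id={meta.measurement_id}\n")
        for name in _METADATA_FLOAT_FIELDS:
            fh.write(f"# {name}={_FLOAT_FMT % getattr(meta, name)}\n")
        fh.write(f"# drift_gas={meta.drift_gas}\n")
        fh.write(f"# polarity={meta.polarity}\n")
        fh.write(",".join(_FLOAT_FMT % t for t in grid.T) + "\n")
        for r, row in zip(grid.R, grid.S):
            fh.write(
                _FLOAT_FMT % r + "," + ",".join(_FLOAT_FMT % v for v in row) + "\n"
            )


def read_peak_list(path: PathLike, detector: str | None = None) -> PeakList:
    """Read a peak-list CSV (columns measurement_id, peak_id, t, r, s).

    Duplicate peak ids within a measurement are kept but logged as a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"measurement_id": str, "peak_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in PEAK_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    dups = df.duplicated(subset=["measurement_id", "peak_id"], keep=False)
    if dups.any():
        logger.warning(
            "%s: %d duplicate peak id(s) within a measurement; keeping all",
            path,
            int(dups.sum()),
        )
    peaks = [
        Peak(i=row.measurement_id, r=float(row.r), t=float(row.t), s=float(row.s))
        for row in df.itertuples()
    ]
    for p in peaks:
        p.validate()
    return PeakList(detector=detector or path.stem, peaks=peaks)


def write_peak_list(peak_list: PeakList, path: PathLike) -> None:
    counters: dict = {}
    records = []
    for p in peak_list:
        counters[p.i] = counters.get(p.i, 0) + 1
        records.append(
            {
                "measurement_id": p.i,
                "peak_id": f"p{counters[p.i]}",
                "t": p.t,
                "r": p.r,
                "s": p.s,
            }
        )
    pd.DataFrame(records, columns=PEAK_LIST_COLUMNS).to_csv(path, index=False)


def write_feature_matrix(fm: FeatureMatrix, path: PathLike) -> None:
    """Write one row per measurement, one column per cluster, plus labels."""
    fm.validate()
    df = pd.DataFrame(fm.values, index=fm.measurement_ids, columns=fm.cluster_ids)
    df.insert(0, "label", [fm.labels[m] for m in fm.measurement_ids])
    df.index.name = "measurement_id"
    df.to_csv(path)


def read_feature_matrix(path: PathLike) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="measurement_id", float_precision="round_trip")
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    labels = {str(m): str(l) for m, l in df["label"].items()}
    values = df.drop(columns="label")
    fm = FeatureMatrix(
        measurement_ids=[str(m) for m in df.index],
        cluster_ids=[str(c) for c in values.columns],
        values=values.to_numpy(dtype=float),
        labels=labels,
    )
    fm.validate()
    return fm
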