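"""Measurement-set homogenization.

Before measurements can be compared, the set must satisfy device-setting
rules (flows within ±5 mL/min of their nominal values, column
temperature within ±2 °C, one drift gas and one polarity for the whole
set) and all measurements must be truncated to a common retention-time
window: retention times below 5 s are instrument artefacts and are
discarded, and every measurement is cut at the smallest maximum
retention time in the set (the *cut-off time*).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .model import MeasurementGrid, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class HomogenizationRules:
    """Acceptance windows for device settings; inclusive boundaries."""

    flow_center: float = 100.0   # drift & sample gas flow, mL/min
    flow_tolerance: float = 5.0
    carrier_center: float = 150.0
    carrier_tolerance: float = 5.0
    temp_center: float = 40.0    # MCC temperature, °C
    temp_tolerance: float = 2.0
    min_retention: float = 5.0   # s


@dataclass
class Verdict:
    measurement_id: str
    accepted: bool
    violations: List[str] = field(default_factory=list)


def _majority(values: Sequence[str]) -> str | None:
    """Most common value; None on an exact tie (warn, reject none)."""
    counts = Counter(values).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def check_rules(
    measurements: Sequence[MeasurementGrid],
    rules: HomogenizationRules | None = None,
) -> Dict[str, Verdict]:
    """Check every measurement against the homogenization rules.

    A measurement is accepted iff all three flows and the temperature
    lie within center±tolerance and its drift gas and polarity match the
    set-wide majority value.  On an exact majority tie no measurement is
    rejected for that field (a warning is logged).
    """
    rules = rules or HomogenizationRules()
    for grid in measurements:
        meta = grid.metadata
        for name in (
            "drift_gas_flow",
            "sample_gas_flow",
            "carrier_gas_flow",
            "mcc_temperature",
            "drift_gas",
            "polarity",
        ):
            if getattr(meta, name, None) is None:
                raise ValidationError(
                    f"measurement {meta.measurement_id!r}: missing metadata "
                    f"field {name!r}"
                )
    majority_gas = _majority([g.metadata.drift_gas for g in measurements])
    majority_pol = _majority([g.metadata.polarity for g in measurements])
    if majority_gas is None:
        logger.warning("drift_gas majority tie; not rejecting on drift_gas")
    if majority_pol is None:
        logger.warning("polarity majority tie; not rejecting on polarity")

    checks = [
        ("drift_gas_flow", rules.flow_center, rules.flow_tolerance),
        ("sample_gas_flow", rules.flow_center, rules.flow_tolerance),
        ("carrier_gas_flow", rules.carrier_center, rules.carrier_tolerance),
        ("mcc_temperature", rules.temp_center, rules.temp_tolerance),
    ]
    verdicts: Dict[str, Verdict] = {}
    for grid in measurements:
        meta = grid.metadata
        violations = [
            name
            for name, center, tol in checks
            if abs(getattr(meta, name) - center) > tol
        ]
        if majority_gas is not None and meta.drift_gas != majority_gas:
            violations.append("drift_gas")
        if majority_pol is not None and meta.polarity != majority_pol:
            violations.append("polarity")
        verdicts[meta.measurement_id] = Verdict(
            measurement_id=meta.measurement_id,
            accepted=not violations,
            violations=violations,
        )
    return verdicts


def compute_cutoff(measurements: Sequence[MeasurementGrid]) -> float:
    """Cut-off time: the smallest maximum retention time in the set."""
    if not measurements:
        raise ValueError("cannot compute a cut-off time for an empty set")
    return float(min(g.R[-1] for g in measurements))


def truncate(
    grid: MeasurementGrid, cutoff: float, min_retention: float = 5.0
) -> MeasurementGrid:
    """Keep exactly the spectra with min_retention <= r <= cutoff."""
    if cutoff <= min_retention:
        raise ValueError(
            f"cutoff ({cutoff}) must exceed min_retention ({min_retention})"
        )
    keep = (grid.R >= min_retention) & (grid.R <= cutoff)
    if not np.any(keep):
        raise ValueError(
            f"no retention times remain in [{min_retention}, {cutoff}]"
        )
    return grid.copy_with(R=grid.R[keep], S=grid.S[keep, :])


def homogenize(
    measurements: Sequence[MeasurementGrid],
    rules: HomogenizationRules | None = None,
) -> List[MeasurementGrid]:
    """Full homogenization: rule check, cut-off, truncation."""
    rules = rules or HomogenizationRules()
    verdicts = check_rules(measurements, rules)
    accepted = [g for g in measurements if verdicts[g.metadata.measurement_id].accepted]
    rejected = len(measurements) - len(accepted)
    if rejected:
        logger.info("homogenization rejected %d measurement(s)", rejected)
    if not accepted:
        raise ValueError("homogenization rejected every measurement")
    cutoff = compute_cutoff(accepted)
    return [truncate(g, cutoff, rules.min_retention) for g in accepted]
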