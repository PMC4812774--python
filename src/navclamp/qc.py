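"""Per-cell inclusion rules.

A recording enters the statistical evaluation only if its holding leak
current does not surpass 100 pA, its series resistance does not surpass
20 MOhm, and the Na+ current displays an activation voltage range of at
least 20 mV in the I-V curve (a guard against poor space/voltage control).
All three boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .results import PassiveProperties, QCMetrics

__all__ = ["QCThresholds", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    max_leak_pa: float = 100.0
    max_rs_mohm: float = 20.0
    min_activation_range_mv: float = 20.0
    #: fraction of the I-V maximum used to define the activation threshold
    activation_threshold_fraction: float = 0.1


def apply_qc(
    passive: PassiveProperties,
    activation_range: float,
    thresholds: QCThresholds = QCThresholds(),
) -> QCMetrics:
    """Pure inclusion decision from the computed per-cell metrics."""
    leak = abs(passive.leak_holding_current)
    reasons = []
    if leak > thresholds.max_leak_pa:
        reasons.append("leak")
    if passive.Rs > thresholds.max_rs_mohm:
        reasons.append("series_resistance")
    if activation_range < thresholds.min_activation_range_mv:
        reasons.append("activation_range")
    return QCMetrics(
        leak=leak,
        Rs=passive.Rs,
        activation_range=activation_range,
        passed=not reasons,
        reasons=reasons,
    )
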