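"""Result containers shared by the trace pipeline, curve fitting and cohort stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import RecordingMetadata

__all__ = [
    "IVCurve",
    "PassiveProperties",
    "InactivationCurve",
    "BoltzmannFit",
    "QCMetrics",
    "CellResult",
    "GroupStats",
    "AnovaResult",
    "TukeyComparison",
    "CohortSummary",
]


@dataclass
class IVCurve:
    """Peak current versus step potential (signed; inward negative)."""

    potentials: np.ndarray  # mV, junction-corrected, strictly increasing
    peaks: np.ndarray  # pA

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.potentials.shape != self.peaks.shape:
            raise ValueError("potentials and peaks must have equal length")
        if self.potentials.size and np.any(np.diff(self.potentials) <= 0):
            raise ValueError("potentials must be strictly increasing")

    def peak_at(self, potential: float, atol: float = 1e-6) -> float:
        idx = np.flatnonzero(np.isclose(self.potentials, potential, atol=atol))
        if idx.size == 0:
            raise ValueError(f"test potential {potential} mV not in I-V curve")
        return float(self.peaks[idx[0]])


@dataclass
class PassiveProperties:
    Cm: float  # pF
    Rs: float  # MOhm
    leak_holding_current: float  # pA, signed mean holding current

    def __post_init__(self):
        if self.Cm <= 0 or self.Rs <= 0:
            raise ValueError("Cm and Rs must be > 0")


@dataclass
class InactivationCurve:
    """Normalized peak test-pulse current versus conditioning prepulse potential."""

    prepulse_potentials: np.ndarray  # mV
    peaks: np.ndarray  # pA at the test potential
    I0: float  # pA, peak elicited from the most negative prepulse

    def __post_init__(self):
        self.prepulse_potentials = np.asarray(self.prepulse_potentials, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.prepulse_potentials.shape != self.peaks.shape:
            raise ValueError("potentials and peaks must have equal length")

    @property
    def normalized(self) -> np.ndarray:
        return self.peaks / self.I0


@dataclass
class BoltzmannFit:
    """Two-parameter descending Boltzmann fit of steady-state inactivation."""

    V_half: float  # mV, half-inactivation potential
    S: float  # mV, slope factor (> 0 for a physical curve)
    rss: float
    converged: bool
    covariance: np.ndarray | None = None


@dataclass
class QCMetrics:
    """Inclusion decision for one cell: leak <= 100 pA, Rs <= 20 MOhm and an
    activation voltage range of at least 20 mV (all boundaries inclusive)."""

    leak: float  # pA magnitude
    Rs: float  # MOhm
    activation_range: float  # mV
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be true exactly when reasons is empty")


@dataclass
class CellResult:
    metadata: RecordingMetadata
    passive: PassiveProperties
    iv: IVCurve
    peak_at_test: float  # pA, signed
    current_density: float  # pA/pF, magnitude
    inactivation_fit: BoltzmannFit | None
    qc: QCMetrics

    def to_row(self) -> dict:
        return {
            "cell_id": self.metadata.cell_id,
            "condition": self.metadata.condition,
            "cell_type": self.metadata.cell_type,
            "Cm_pF": self.passive.Cm,
            "Rs_MOhm": self.passive.Rs,
            "leak_pA": self.passive.leak_holding_current,
            "peak_pA": self.peak_at_test,
            "density_pA_per_pF": self.current_density,
            "V_half_mV": self.inactivation_fit.V_half if self.inactivation_fit else np.nan,
            "slope_mV": self.inactivation_fit.S if self.inactivation_fit else np.nan,
            "qc_pass": self.qc.passed,
            "qc_reasons": ";".join(self.qc.reasons),
        }


@dataclass
class GroupStats:
    label: str
    mean: float
    se: float
    n: int


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    difference: float  # mean_a - mean_b
    q: float
    p: float
    stars: str


@dataclass
class CohortSummary:
    groups: list[GroupStats]
    anova: AnovaResult | None
    tukey: list[TukeyComparison]

    def comparison(self, a: str, b: str) -> TukeyComparison:
        for c in self.tukey:
            if {c.group_a, c.group_b} == {a, b}:
                return c
        raise KeyError(f"no comparison between {a!r} and {b!r}")
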