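"""Voltage-clamp protocol definitions and the shared units-coherent data model.

Conventions used package-wide
-----------------------------
* Units: membrane potential in mV, time in ms, current in pA, capacitance in
  pF, resistance in MOhm, conductance in nS.  With these units nS x mV = pA
  directly; the only conversion needed anywhere is mV / MOhm = nA, handled by
  :func:`mv_over_mohm_to_pa`.
* All stored command potentials are liquid-junction corrected.  The junction
  offset is recorded on the protocol for provenance; the raw amplifier value
  is derivable (level - junction) and never stored, so nothing can be
  corrected twice.
* Inward current is negative in traces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "mv_over_mohm_to_pa",
    "apply_junction_correction",
    "VoltageProtocol",
    "Sweep",
    "GaussianTau",
    "CellParameters",
    "RecordingMetadata",
    "build_activation_protocol",
    "build_inactivation_protocol",
]

#: Default liquid junction potential of the CsF pipette against the bath, mV.
DEFAULT_JUNCTION_MV = -7.0

#: Default holding potential (junction-corrected), mV.
DEFAULT_HOLDING_MV = -77.0


def mv_over_mohm_to_pa(x: float) -> float:
    """Convert a (mV / MOhm) quantity, i.e. nA, to pA."""
    return x * 1000.0


def apply_junction_correction(command_level: float, junction: float) -> float:
    """Return the reported membrane potential for an amplifier command level.

    The reported potential is ``command + junction`` (junction is signed;
    a -7 mV junction turns a -70 mV command into a reported -77 mV).
    """
    if not math.isfinite(junction):
        raise ValueError("junction potential must be finite")
    return command_level + junction


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered family of command-voltage sweeps.

    Each sweep is a list of ``(level_mV, duration_ms)`` epochs.  Exactly one
    epoch position varies across sweeps (``varied_epoch``); its levels must
    form a strictly increasing arithmetic sequence.
    """

    name: str
    holding_potential: float
    epochs_per_sweep: tuple  # tuple of sweeps, each a tuple of (level, duration)
    sampling_rate: float  # Hz
    pn_subpulses: int = 0
    junction_potential: float = DEFAULT_JUNCTION_MV
    varied_epoch: int = 1

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.epochs_per_sweep:
            raise ValueError("protocol needs at least one sweep")
        durations = set()
        for sweep in self.epochs_per_sweep:
            for level, dur in sweep:
                if dur <= 0:
                    raise ValueError("epoch durations must be > 0")
            durations.add(round(sum(d for _, d in sweep), 9))
        if len(durations) != 1:
            raise ValueError("every sweep must have identical total duration")
        levels = self.sweep_levels
        if len(levels) > 1:
            diffs = np.diff(levels)
            if np.any(diffs <= 0):
                raise ValueError("varied-epoch levels must be strictly increasing")
            if not np.allclose(diffs, diffs[0]):
                raise ValueError("varied-epoch increments must be uniform")

    @property
    def sweep_count(self) -> int:
        return len(self.epochs_per_sweep)

    @property
    def sweep_levels(self) -> np.ndarray:
        """Junction-corrected level of the varied epoch, one per sweep."""
        return np.array(
            [sweep[self.varied_epoch][0] for sweep in self.epochs_per_sweep]
        )

    @property
    def total_duration_ms(self) -> float:
        return float(sum(d for _, d in self.epochs_per_sweep[0]))

    @property
    def samples_per_sweep(self) -> int:
        return int(round(self.total_duration_ms * 1e-3 * self.sampling_rate))

    def epoch_onset_ms(self, epoch_index: int) -> float:
        """Start time (ms from sweep start) of the given epoch."""
        return float(sum(d for _, d in self.epochs_per_sweep[0][:epoch_index]))

    def command_waveform(self, sweep_index: int, rate_hz: float | None = None) -> np.ndarray:
        """Sampled command-voltage trace for one sweep, mV."""
        rate = self.sampling_rate if rate_hz is None else rate_hz
        pieces = []
        for level, dur in self.epochs_per_sweep[sweep_index]:
            pieces.append(np.full(int(round(dur * 1e-3 * rate)), float(level)))
        return np.concatenate(pieces)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "sampling_rate_hz": self.sampling_rate,
            "junction_mv": self.junction_potential,
            "holding_mv": self.holding_potential,
            "pn_subpulses": self.pn_subpulses,
            "varied_epoch": self.varied_epoch,
            "sweeps": [[[lv, du] for lv, du in sw] for sw in self.epochs_per_sweep],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "VoltageProtocol":
        doc = json.loads(text)
        return cls(
            name=doc["name"],
            holding_potential=doc["holding_mv"],
            epochs_per_sweep=tuple(
                tuple((lv, du) for lv, du in sw) for sw in doc["sweeps"]
            ),
            sampling_rate=doc["sampling_rate_hz"],
            pn_subpulses=doc["pn_subpulses"],
            junction_potential=doc["junction_mv"],
            varied_epoch=doc["varied_epoch"],
        )


@dataclass
class Sweep:
    """One recorded current trace plus its command voltage."""

    current: np.ndarray  # pA
    command_voltage: np.ndarray  # mV
    sweep_index: int
    is_subpulse: bool = False
    subpulse_scale: float = 1.0

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        self.command_voltage = np.asarray(self.command_voltage, dtype=float)
        if self.current.shape != self.command_voltage.shape:
            raise ValueError("current and command traces must have equal length")


@dataclass(frozen=True)
class GaussianTau:
    """Bell-shaped voltage profile for a gating time constant, ms.

    tau(V) = base + amp * exp(-((V - v_peak) / width)**2)
    """

    base: float
    amp: float
    v_peak: float
    width: float

    def __call__(self, v):
        return self.base + self.amp * np.exp(-(((v - self.v_peak) / self.width) ** 2))


@dataclass
class CellParameters:
    """Ground-truth biophysics of one simulated neuron."""

    Cm: float = 25.0  # pF
    Rs: float = 10.0  # MOhm
    g_leak: float = 2.0  # nS
    E_leak: float = -70.0  # mV
    g_Na: float = 35.0  # nS, maximal
    E_Na: float = 76.1  # mV; overridden from solution Na+ by the simulator config
    act_V_half: float = -42.0  # mV
    act_slope: float = 6.0  # mV
    inact_V_half: float = -62.0  # mV
    inact_slope: float = 6.0  # mV
    tau_m: GaussianTau = field(default_factory=lambda: GaussianTau(0.05, 0.25, -40.0, 15.0))
    tau_h: GaussianTau = field(default_factory=lambda: GaussianTau(1.0, 1.5, -65.0, 20.0))
    noise_sd: float = 3.0  # pA
    cell_type: str = "bipolar"
    condition: str = "control"

    def __post_init__(self):
        for name in ("Cm", "Rs", "g_leak", "g_Na", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.act_slope <= 0 or self.inact_slope <= 0:
            raise ValueError("gating slope factors must be > 0")
        for tau in (self.tau_m, self.tau_h):
            if tau.base <= 0 or tau.amp < 0 or tau.width <= 0:
                raise ValueError("time-constant profiles must be positive")


@dataclass(frozen=True)
class RecordingMetadata:
    cell_id: str
    cell_type: str = "bipolar"
    condition: str = "control"
    day_in_vitro: int = 7
    seed: int = 0


def _step_levels(start: float, stop: float, increment: float) -> np.ndarray:
    if increment <= 0:
        raise ValueError("increment must be > 0")
    span = stop - start
    n_steps = span / increment
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("range must be a whole multiple of the increment")
    return start + increment * np.arange(int(round(n_steps)) + 1)


def build_activation_protocol(
    start: float = -72.0,
    stop: float = 38.0,
    increment: float = 5.0,
    holding: float = DEFAULT_HOLDING_MV,
    holding_duration: float = 20.0,
    step_duration: float = 30.0,
    sampling_rate: float = 20_000.0,
    pn_subpulses: int = 4,
    junction: float = DEFAULT_JUNCTION_MV,
) -> VoltageProtocol:
    """Step-depolarization series for the peak I-V relationship.

    Defaults: holding -77 mV, steps -72 .. +38 mV in 5 mV increments
    (23 sweeps), 4 leak subpulses per main step.  All levels are
    junction-corrected values.
    """
    levels = _step_levels(start, stop, increment)
    sweeps = tuple(
        ((holding, holding_duration), (float(lv), step_duration)) for lv in levels
    )
    return VoltageProtocol(
        name="activation",
        holding_potential=holding,
        epochs_per_sweep=sweeps,
        sampling_rate=sampling_rate,
        pn_subpulses=pn_subpulses,
        junction_potential=junction,
        varied_epoch=1,
    )


def build_inactivation_protocol(
    prepulse_start: float = -82.0,
    prepulse_stop: float = -22.0,
    increment: float = 5.0,
    prepulse_duration: float = 200.0,
    test_level: float = -17.0,
    test_duration: float = 30.0,
    holding: float = DEFAULT_HOLDING_MV,
    holding_duration: float = 20.0,
    sampling_rate: float = 20_000.0,
    pn_subpulses: int = 4,
    junction: float = DEFAULT_JUNCTION_MV,
    allow_nonstandard_duration: bool = False,
) -> VoltageProtocol:
    """Steady-state inactivation series: 200 ms conditioning prepulses
    (-82 mV rising in 5 mV steps) followed by a -17 mV test pulse.

    A prepulse duration other than 200 ms is rejected unless
    ``allow_nonstandard_duration`` is set, because shorter prepulses do not
    reach steady-state channel availability.
    """
    if prepulse_duration != 200.0 and not allow_nonstandard_duration:
        raise ValueError(
            "nonconforming prepulse duration "
            f"({prepulse_duration} ms != 200 ms); pass allow_nonstandard_duration=True"
        )
    levels = _step_levels(prepulse_start, prepulse_stop, increment)
    sweeps = tuple(
        (
            (holding, holding_duration),
            (float(lv), prepulse_duration),
            (test_level, test_duration),
        )
        for lv in levels
    )
    return VoltageProtocol(
        name="inactivation",
        holding_potential=holding,
        epochs_per_sweep=sweeps,
        sampling_rate=sampling_rate,
        pn_subpulses=pn_subpulses,
        junction_potential=junction,
        varied_epoch=1,
    )
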