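"""Biophysical voltage-clamp simulator for whole-cell Na+ current recordings.

Forward model of the recording situation: a single-compartment cell with
membrane capacitance ``Cm`` accessed through a series resistance ``Rs``,
carrying an ohmic leak and a Hodgkin-Huxley-type voltage-gated Na+
conductance with m^3·h gating whose steady states are Boltzmann functions of
voltage.  The clamp delivers a command potential ``Vcmd``; the membrane
potential obeys

    Cm dVm/dt = (Vcmd - Vm)/Rs - g_Na m^3 h (Vm - E_Na) - g_leak (Vm - E_leak)
    dm/dt = (m_inf(Vm) - m)/tau_m(Vm),   dh/dt = (h_inf(Vm) - h)/tau_h(Vm)

and the recorded current is the pipette current (Vcmd - Vm)/Rs.  The raw
current is then passed through a causal low-pass Bessel filter (emulating the
amplifier's 10 kHz hardware filter), resampled to the acquisition rate
(20 kHz), and corrupted with additive Gaussian noise and optional ADC
quantization.  Everything the analysis pipeline must remove — capacitive
charging transients, ohmic leak, filter delay, noise — is therefore present
in the synthetic traces.

Integration uses exponential Euler on the gates and an implicit update on
Vm at a fixed sub-sample step (default 10 us); the stiff time constant is the
charging time Rs*Cm (~0.25 ms for typical cells), which the implicit update
handles stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy import signal

from .protocols import (
    CellParameters,
    RecordingMetadata,
    Sweep,
    VoltageProtocol,
    build_activation_protocol,
    build_inactivation_protocol,
)

__all__ = [
    "SimulatorConfig",
    "nernst_reversal",
    "simulate_sweep",
    "simulate_pn_subpulses",
    "simulate_cell",
    "build_capacitance_protocol",
    "SUBPULSE_HOLDING_MV",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Hyperpolarized holding level for P/N leak subpulses, mV.  Chosen well
#: below the Na+ activation range so the subpulse response is purely linear.
SUBPULSE_HOLDING_MV = -97.0

#: Amplitude of the dedicated capacitance test pulse, mV.
CAPACITANCE_PULSE_MV = -10.0


@dataclass(frozen=True)
class SimulatorConfig:
    """Acquisition-chain settings shared by all sweeps of a recording."""

    integration_step: float = 10.0  # us
    bath_Na: float = 100.0  # mM
    pipette_Na: float = 5.0  # mM
    temperature: float = 295.0  # K
    filter_cutoff: float = 10_000.0  # Hz
    filter_order: int = 4
    adc_bits: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.integration_step <= 0 or self.integration_step > 50.0:
            raise ValueError("integration_step must be in (0, 50] us")
        if self.filter_cutoff <= 0:
            raise ValueError("filter_cutoff must be > 0")

    @property
    def sim_rate_hz(self) -> float:
        return 1e6 / self.integration_step

    def reversal_potential(self) -> float:
        return nernst_reversal(self.bath_Na, self.pipette_Na, self.temperature)


def nernst_reversal(bath: float, pipette: float, temperature: float = 295.0) -> float:
    """Nernst equilibrium potential (mV) for the given Na+ concentrations."""
    if bath <= 0 or pipette <= 0:
        raise ValueError("ion concentrations must be > 0")
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY * math.log(bath / pipette)


@njit(cache=True)
def _integrate(
    vcmd,
    dt,
    cm,
    rs,
    g_leak,
    e_leak,
    g_na,
    e_na,
    m_vh,
    m_k,
    h_vh,
    h_k,
    tm_base,
    tm_amp,
    tm_vp,
    tm_w,
    th_base,
    th_amp,
    th_vp,
    th_w,
    vm0,
    m0,
    h0,
):  # pragma: no cover - exercised through simulate_sweep
    n = vcmd.size
    out = np.empty(n)
    vm = vm0
    m = m0
    h = h0
    inv_rs = 1000.0 / rs  # pA per mV
    half = 0.5 * dt
    for i in range(n):
        vc = vcmd[i]
        # record at the sample instant, before advancing over the interval
        # (DAC step and ADC sample are synchronous)
        out[i] = inv_rs * (vc - vm)
        # Strang splitting: half-step gates, full exponential step on Vm,
        # half-step gates -- each sub-flow is exact for frozen coefficients
        minf = 1.0 / (1.0 + math.exp(-(vm - m_vh) / m_k))
        hinf = 1.0 / (1.0 + math.exp((vm - h_vh) / h_k))
        tm = tm_base + tm_amp * math.exp(-(((vm - tm_vp) / tm_w) ** 2))
        th = th_base + th_amp * math.exp(-(((vm - th_vp) / th_w) ** 2))
        m = minf + (m - minf) * math.exp(-half / tm)
        h = hinf + (h - hinf) * math.exp(-half / th)
        gna = g_na * m * m * m * h
        b = (inv_rs + gna + g_leak) / cm
        v_inf = (inv_rs * vc + gna * e_na + g_leak * e_leak) / (cm * b)
        vm = v_inf + (vm - v_inf) * math.exp(-dt * b)
        minf = 1.0 / (1.0 + math.exp(-(vm - m_vh) / m_k))
        hinf = 1.0 / (1.0 + math.exp((vm - h_vh) / h_k))
        tm = tm_base + tm_amp * math.exp(-(((vm - tm_vp) / tm_w) ** 2))
        th = th_base + th_amp * math.exp(-(((vm - th_vp) / th_w) ** 2))
        m = minf + (m - minf) * math.exp(-half / tm)
        h = hinf + (h - hinf) * math.exp(-half / th)
    return out, vm, m, h


def _steady_state(cell: CellParameters, e_na: float, v_hold: float):
    """Fixed point of (Vm, m, h) while the command sits at ``v_hold``."""
    vm = v_hold
    inv_rs = 1000.0 / cell.Rs
    m = h = 0.0
    for _ in range(200):
        m = 1.0 / (1.0 + math.exp(-(vm - cell.act_V_half) / cell.act_slope))
        h = 1.0 / (1.0 + math.exp((vm - cell.inact_V_half) / cell.inact_slope))
        gna = cell.g_Na * m**3 * h
        vm_new = (inv_rs * v_hold + gna * e_na + cell.g_leak * cell.E_leak) / (
            inv_rs + gna + cell.g_leak
        )
        if abs(vm_new - vm) < 1e-12:
            vm = vm_new
            break
        vm = vm_new
    return vm, m, h


def _acquisition_chain(
    raw: np.ndarray,
    config: SimulatorConfig,
    target_rate: float,
    noise_sd: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Filter at the simulation rate, decimate, add noise, quantize."""
    sim_rate = config.sim_rate_hz
    if config.filter_cutoff > target_rate / 2:
        raise ValueError("filter cutoff must not exceed the Nyquist rate of acquisition")
    if config.filter_cutoff < sim_rate / 2:
        # magnitude-normalized Bessel: exactly -3 dB at the cutoff
        b, a = signal.bessel(
            config.filter_order, config.filter_cutoff, fs=sim_rate, norm="mag"
        )
        zi = signal.lfilter_zi(b, a) * raw[0]
        filtered, _ = signal.lfilter(b, a, raw, zi=zi)
    else:
        filtered = raw
    decim = sim_rate / target_rate
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError(
            "integration step must make the simulation rate an integer multiple "
            "of the acquisition sampling rate"
        )
    acquired = filtered[:: int(round(decim))].copy()
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        acquired += rng.normal(0.0, noise_sd, acquired.size)
    if config.adc_bits is not None:
        lsb = 20_000.0 / 2**config.adc_bits  # +-10 nA full scale
        acquired = np.round(acquired / lsb) * lsb
    return acquired


def _simulate_command(
    cell: CellParameters,
    vcmd_sim: np.ndarray,
    config: SimulatorConfig,
    target_rate: float,
    rng: np.random.Generator | None,
    noise: bool,
) -> np.ndarray:
    if cell.Cm <= 0 or cell.Rs <= 0:
        raise ValueError("simulation requires Cm > 0 and Rs > 0")
    e_na = config.reversal_potential()
    dt_ms = config.integration_step * 1e-3
    vm0, m0, h0 = _steady_state(cell, e_na, float(vcmd_sim[0]))
    raw, vm_end, _, _ = _integrate(
        vcmd_sim,
        dt_ms,
        cell.Cm,
        cell.Rs,
        cell.g_leak,
        cell.E_leak,
        cell.g_Na,
        e_na,
        cell.act_V_half,
        cell.act_slope,
        cell.inact_V_half,
        cell.inact_slope,
        cell.tau_m.base,
        cell.tau_m.amp,
        cell.tau_m.v_peak,
        cell.tau_m.width,
        cell.tau_h.base,
        cell.tau_h.amp,
        cell.tau_h.v_peak,
        cell.tau_h.width,
        vm0,
        m0,
        h0,
    )
    if not math.isfinite(vm_end) or not np.all(np.isfinite(raw[:: max(1, raw.size // 64)])):
        raise RuntimeError(
            "voltage-clamp integration went unstable; reduce integration_step"
        )
    noise_sd = cell.noise_sd if noise else 0.0
    return _acquisition_chain(raw, config, target_rate, noise_sd, rng)


def simulate_sweep(
    cell: CellParameters,
    protocol: VoltageProtocol,
    sweep_index: int,
    config: SimulatorConfig = SimulatorConfig(),
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> Sweep:
    """Simulate one protocol sweep and return the acquired trace."""
    if not 0 <= sweep_index < protocol.sweep_count:
        raise IndexError("sweep_index outside protocol")
    if rng is None and noise and cell.noise_sd > 0:
        rng = np.random.default_rng([config.seed, sweep_index])
    vcmd_sim = protocol.command_waveform(sweep_index, rate_hz=config.sim_rate_hz)
    current = _simulate_command(
        cell, vcmd_sim, config, protocol.sampling_rate, rng, noise
    )
    vcmd_acq = protocol.command_waveform(sweep_index)
    n = min(current.size, vcmd_acq.size)
    return Sweep(current[:n], vcmd_acq[:n], sweep_index)


def simulate_pn_subpulses(
    cell: CellParameters,
    protocol: VoltageProtocol,
    sweep_index: int,
    n: int | None = None,
    config: SimulatorConfig = SimulatorConfig(),
    rng: np.random.Generator | None = None,
    noise: bool = True,
    subpulse_holding: float = SUBPULSE_HOLDING_MV,
) -> list[Sweep]:
    """Simulate the P/N leak-subtraction family for one main sweep.

    Each of the ``n`` subpulses replays the main sweep's command deviation
    from holding scaled by -1/n, delivered from a hyperpolarized holding
    level where the Na+ conductance stays shut, so the response is purely
    linear (leak + capacitive).
    """
    if n is None:
        n = protocol.pn_subpulses
    if n < 1:
        raise ValueError("need at least one subpulse")
    if rng is None and noise and cell.noise_sd > 0:
        rng = np.random.default_rng([config.seed, sweep_index, 1])
    scale = -1.0 / n
    vmain = protocol.command_waveform(sweep_index, rate_hz=config.sim_rate_hz)
    vsub_sim = subpulse_holding + scale * (vmain - protocol.holding_potential)
    vsub_acq = subpulse_holding + scale * (
        protocol.command_waveform(sweep_index) - protocol.holding_potential
    )
    sweeps = []
    for _ in range(n):
        current = _simulate_command(
            cell, vsub_sim, config, protocol.sampling_rate, rng, noise
        )
        m = min(current.size, vsub_acq.size)
        sweeps.append(
            Sweep(current[:m], vsub_acq[:m], sweep_index, is_subpulse=True,
                  subpulse_scale=scale)
        )
    return sweeps


def build_capacitance_protocol(
    holding: float = -77.0,
    amplitude: float = CAPACITANCE_PULSE_MV,
    holding_duration: float = 20.0,
    pulse_duration: float = 30.0,
    sampling_rate: float = 20_000.0,
    junction: float = -7.0,
) -> VoltageProtocol:
    """Single small hyperpolarizing test pulse for passive-property estimation."""
    sweeps = (
        ((holding, holding_duration), (holding + amplitude, pulse_duration)),
    )
    return VoltageProtocol(
        name="captest",
        holding_potential=holding,
        epochs_per_sweep=sweeps,
        sampling_rate=sampling_rate,
        pn_subpulses=0,
        junction_potential=junction,
        varied_epoch=1,
    )


def simulate_cell(
    cell: CellParameters,
    config: SimulatorConfig = SimulatorConfig(),
    metadata: RecordingMetadata | None = None,
    activation: VoltageProtocol | None = None,
    inactivation: VoltageProtocol | None = None,
):
    """Run the full recording session for one cell.

    Produces the activation and inactivation series with their P/N subpulse
    families plus the dedicated capacitance test pulse, bundled with
    provenance.  Deterministic for a given ``metadata.seed``.
    """
    from .bundle import SweepBundle  # local import; bundle depends on this module

    if metadata is None:
        metadata = RecordingMetadata(
            cell_id="cell-0", cell_type=cell.cell_type, condition=cell.condition,
            seed=config.seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence(metadata.seed))
    if activation is None:
        activation = build_activation_protocol()
    if inactivation is None:
        inactivation = build_inactivation_protocol()
    protocols = {p.name: p for p in (activation, inactivation)}
    captest = build_capacitance_protocol(
        holding=activation.holding_potential,
        sampling_rate=activation.sampling_rate,
        junction=activation.junction_potential,
    )
    protocols[captest.name] = captest

    main_sweeps: dict[str, list[Sweep]] = {}
    subpulse_sweeps: dict[str, list[list[Sweep]]] = {}
    for proto in (activation, inactivation):
        mains, subs = [], []
        for k in range(proto.sweep_count):
            mains.append(simulate_sweep(cell, proto, k, config, rng=rng))
            subs.append(
                simulate_pn_subpulses(cell, proto, k, config=config, rng=rng)
            )
        main_sweeps[proto.name] = mains
        subpulse_sweeps[proto.name] = subs
    test_pulse = simulate_sweep(cell, captest, 0, config, rng=rng)
    return SweepBundle(
        metadata=metadata,
        config=config,
        protocols=protocols,
        main_sweeps=main_sweeps,
        subpulse_sweeps=subpulse_sweeps,
        test_pulse=test_pulse,
        test_pulse_delta_mv=CAPACITANCE_PULSE_MV,
    )
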