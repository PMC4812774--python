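from __future__ import annotations

import numpy as np
import pytest

import navclamp as nc
from navclamp.protocols import Sweep


@pytest.fixture(scope="session")
def config():
    return nc.SimulatorConfig()


@pytest.fixture(scope="session")
def default_cell(config):
    """Calibrated default cell (activation midpoint placing the I-V maximum
    on the -12 mV sweep).  Session-scoped: calibration is deterministic."""
    return nc.default_cell_parameters(config)


@pytest.fixture(scope="session")
def activation_protocol():
    return nc.build_activation_protocol()


@pytest.fixture(scope="session")
def inactivation_protocol():
    return nc.build_inactivation_protocol()


def simulate_corrected(cell, protocol, config, noise=False):
    """Simulate all main sweeps with their P/4 families and return the
    leak-subtracted traces."""
    corrected = []
    for k in range(protocol.sweep_count):
        main = nc.simulate_sweep(cell, protocol, k, config, noise=noise)
        subs = nc.simulate_pn_subpulses(cell, protocol, k, config=config, noise=noise)
        corrected.append(nc.p4_subtract(main, subs))
    return corrected


def ideal_rc_sweep(
    cm_pf: float,
    rs_mohm: float,
    delta_v: float = -10.0,
    hold_current: float = 0.0,
    rate_hz: float = 20_000.0,
    n_hold: int = 400,
    n_pulse: int = 600,
    hold_mv: float = -77.0,
) -> Sweep:
    """Analytic whole-cell RC charging response, sampled with the first pulse
    sample exactly at the step onset."""
    dt_ms = 1000.0 / rate_hz
    rc_ms = rs_mohm * cm_pf * 1e-3
    t = np.arange(n_pulse) * dt_ms
    i0 = delta_v / rs_mohm * 1000.0  # pA
    current = np.concatenate(
        [np.full(n_hold, hold_current), hold_current + i0 * np.exp(-t / rc_ms)]
    )
    command = np.concatenate(
        [np.full(n_hold, hold_mv), np.full(n_pulse, hold_mv + delta_v)]
    )
    return Sweep(current, command, 0)
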