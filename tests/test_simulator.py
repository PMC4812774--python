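import math

import numpy as np
import pytest
from scipy import signal

import navclamp as nc
from navclamp.protocols import CellParameters, GaussianTau
from navclamp.simulator import SUBPULSE_HOLDING_MV

from conftest import simulate_corrected


class TestNernst:
    def test_study_solutions(self):
        # 100 mM bath / 5 mM pipette at 295 K: (RT/F) ln 20 = 25.43 mV * ln 20
        assert nc.nernst_reversal(100, 5, 295) == pytest.approx(76.16, abs=0.05)

    def test_symmetry_and_antisymmetry(self):
        assert nc.nernst_reversal(7.3, 7.3, 310) == 0.0
        assert nc.nernst_reversal(5, 100, 295) == pytest.approx(
            -nc.nernst_reversal(100, 5, 295)
        )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            nc.nernst_reversal(0.0, 5.0)


def linear_cell(g_leak=2.0, e_leak=-77.0, rs=0.05):
    return CellParameters(g_Na=0.0, g_leak=g_leak, E_leak=e_leak, Rs=rs, noise_sd=0.0)


class TestSimulateSweep:
    def test_ohmic_steady_state(self, config):
        # 2 nS leak reversing at -77 mV, step to -67 mV: steady current +20 pA
        proto = nc.build_activation_protocol(start=-67.0, stop=-67.0)
        sweep = nc.simulate_sweep(linear_cell(), proto, 0, config, noise=False)
        assert np.mean(sweep.current[-60:]) == pytest.approx(20.0, rel=1e-3)

    def test_step_doubling_convergence(self, default_cell, activation_protocol):
        # halving the integration step moves the peak by < 0.5 %
        k = int(np.argmin(np.abs(activation_protocol.sweep_levels - (-12.0))))
        peaks = []
        for step in (10.0, 5.0):
            cfg = nc.SimulatorConfig(integration_step=step)
            sweep = nc.simulate_sweep(default_cell, activation_protocol, k, cfg, noise=False)
            peaks.append(np.min(sweep.current))
        assert abs(peaks[1] - peaks[0]) / abs(peaks[1]) < 0.005

    def test_holding_steady_state_matches_conductances(self, default_cell, config):
        # noise-free holding current = g_leak(Vh-El) + g_Na m3h (Vh-ENa), within
        # 1 % in the well-clamped (small Rs) limit
        from dataclasses import replace
        cell = replace(default_cell, noise_sd=0.0, Rs=0.1)
        proto = nc.build_activation_protocol(start=-77.0, stop=-77.0)
        sweep = nc.simulate_sweep(cell, proto, 0, config, noise=False)
        vh = -77.0
        minf = 1 / (1 + math.exp(-(vh - cell.act_V_half) / cell.act_slope))
        hinf = 1 / (1 + math.exp((vh - cell.inact_V_half) / cell.inact_slope))
        expected = cell.g_leak * (vh - cell.E_leak) + cell.g_Na * minf**3 * hinf * (
            vh - cell.E_Na
        )
        assert np.mean(sweep.current) == pytest.approx(expected, rel=0.01)

    def test_ideal_clamp_oracle(self, default_cell):
        # With Rs -> 0 the simulated peak approaches the value from a direct
        # closed-form gate relaxation at Vm = Vcmd (1 us sampling), computed
        # without the production integrator.
        from dataclasses import replace

        cell = replace(default_cell, Rs=0.05, g_leak=0.0, noise_sd=0.0)
        v_step, t_hold, t_step = -12.0, 20.0, 30.0
        proto = nc.VoltageProtocol(
            name="oracle",
            holding_potential=-77.0,
            epochs_per_sweep=(((-77.0, t_hold), (v_step, t_step)),),
            sampling_rate=200_000.0,
        )
        cfg = nc.SimulatorConfig(integration_step=5.0, filter_cutoff=100_000.0)
        sim_peak = np.min(nc.simulate_sweep(cell, proto, 0, cfg, noise=False).current)

        def inf(v, vh, k, sign):
            return 1.0 / (1.0 + math.exp(sign * (v - vh) / k))

        m0 = inf(-77.0, cell.act_V_half, cell.act_slope, -1)
        h0 = inf(-77.0, cell.inact_V_half, cell.inact_slope, +1)
        minf = inf(v_step, cell.act_V_half, cell.act_slope, -1)
        hinf = inf(v_step, cell.inact_V_half, cell.inact_slope, +1)
        tm, th = cell.tau_m(v_step), cell.tau_h(v_step)
        t = np.arange(0, t_step, 1e-3)
        m = minf + (m0 - minf) * np.exp(-t / tm)
        h = hinf + (h0 - hinf) * np.exp(-t / th)
        oracle_peak = np.min(cell.g_Na * m**3 * h * (v_step - cell.E_Na))
        assert sim_peak == pytest.approx(oracle_peak, rel=0.02)

    def test_nonphysical_cell_rejected(self, config, activation_protocol):
        # a zero-capacitance cell makes the clamp ODE singular
        cell = CellParameters(Cm=0.0, noise_sd=0.0)
        with pytest.raises(ValueError, match="Cm > 0"):
            nc.simulate_sweep(cell, activation_protocol, 0, config, noise=False)


class TestPnSubpulses:
    def test_quarter_amplitude_steps(self, default_cell, config):
        # main step -77 -> -12 mV (+65 mV): P/4 subpulses step by -16.25 mV
        proto = nc.build_activation_protocol(start=-12.0, stop=-12.0)
        subs = nc.simulate_pn_subpulses(default_cell, proto, 0, config=config, noise=False)
        assert len(subs) == 4
        cmd = subs[0].command_voltage
        assert cmd[0] == SUBPULSE_HOLDING_MV
        assert cmd[-1] - cmd[0] == pytest.approx(-65.0 / 4)

    def test_single_subpulse_full_inverted(self, default_cell, config):
        proto = nc.build_activation_protocol(start=-12.0, stop=-12.0)
        subs = nc.simulate_pn_subpulses(
            default_cell, proto, 0, n=1, config=config, noise=False
        )
        assert len(subs) == 1
        cmd = subs[0].command_voltage
        assert cmd[-1] - cmd[0] == pytest.approx(-65.0)

    def test_linearity_reconstructs_main_response(self, config):
        # On a purely linear cell, (-n) x mean baseline-aligned subpulse
        # response equals the main-step linear response sample-wise.
        cell = linear_cell(g_leak=3.0, e_leak=-60.0, rs=8.0)
        proto = nc.build_activation_protocol(start=-12.0, stop=-12.0)
        main = nc.simulate_sweep(cell, proto, 0, config, noise=False)
        subs = nc.simulate_pn_subpulses(cell, proto, 0, config=config, noise=False)
        onset = 400
        align = lambda x: x - np.mean(x[onset // 2 : onset])
        recon = -4.0 * np.mean([align(s.current) for s in subs], axis=0)
        assert np.allclose(recon, align(main.current), atol=1e-6)


class TestSimulateCell:
    def test_bundle_inventory_and_determinism(self, default_cell, config):
        meta = nc.RecordingMetadata(cell_id="c0", seed=42)
        b1 = nc.simulate_cell(default_cell, config, metadata=meta)
        b2 = nc.simulate_cell(default_cell, config, metadata=meta)
        assert len(b1.main_sweeps["activation"]) == 23
        assert len(b1.main_sweeps["inactivation"]) == 13
        assert all(len(f) == 4 for f in b1.subpulse_sweeps["activation"])
        for name in b1.main_sweeps:
            for s1, s2 in zip(b1.main_sweeps[name], b2.main_sweeps[name]):
                assert np.array_equal(s1.current, s2.current)
        assert np.array_equal(b1.test_pulse.current, b2.test_pulse.current)

    def test_linear_cell_corrected_traces_vanish(self, config):
        cell = linear_cell(rs=10.0)
        b = nc.simulate_cell(cell, config)
        for main, subs in zip(
            b.main_sweeps["activation"], b.subpulse_sweeps["activation"]
        ):
            assert np.max(np.abs(nc.p4_subtract(main, subs))) < 1e-6


class TestAcquisitionFilter:
    def test_dc_gain_and_cutoff_attenuation(self, config):
        b, a = signal.bessel(
            config.filter_order, config.filter_cutoff, fs=config.sim_rate_hz, norm="mag"
        )
        w, h = signal.freqz(b, a, worN=[1e-3, config.filter_cutoff], fs=config.sim_rate_hz)
        assert abs(abs(h[0]) - 1.0) < 1e-6
        assert 20 * np.log10(abs(h[1])) == pytest.approx(-3.0, abs=0.5)

    def test_inactivation_availability_tracks_boltzmann(self, default_cell, config):
        # 200 ms prepulses equilibrate h; normalized peaks follow the
        # generative h-inf curve (well-clamped limit, 2 % tolerance)
        from dataclasses import replace

        cell = replace(default_cell, Rs=0.5, noise_sd=0.0)
        proto = nc.build_inactivation_protocol()
        corrected = simulate_corrected(cell, proto, config)
        curve = nc.build_inactivation_curve(corrected, proto)
        hinf = nc.boltzmann(
            curve.prepulse_potentials, cell.inact_V_half, cell.inact_slope
        )
        assert np.max(np.abs(curve.normalized - hinf / hinf[0])) < 0.02
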