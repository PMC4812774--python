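import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

import navclamp as nc
from navclamp.cohort import _simulate_iv, star_label
from navclamp.results import (
    CellResult,
    IVCurve,
    PassiveProperties,
    QCMetrics,
)
from navclamp.protocols import RecordingMetadata
from navclamp.qc import QCThresholds


def passive(leak=10.0, rs=10.0):
    return PassiveProperties(Cm=25.0, Rs=rs, leak_holding_current=leak)


class TestApplyQC:
    def test_inclusive_boundaries(self):
        qc = nc.apply_qc(passive(leak=100.0, rs=20.0), activation_range=20.0)
        assert qc.passed and qc.reasons == []

    def test_leak_just_over(self):
        qc = nc.apply_qc(passive(leak=100.1, rs=10.0), activation_range=30.0)
        assert not qc.passed and qc.reasons == ["leak"]

    def test_multiple_reasons(self):
        qc = nc.apply_qc(passive(leak=50.0, rs=25.0), activation_range=15.0)
        assert qc.reasons == ["series_resistance", "activation_range"]

    def test_leak_sign_irrelevant(self):
        qc = nc.apply_qc(passive(leak=-150.0), activation_range=30.0)
        assert qc.reasons == ["leak"]

    def test_decision_is_componentwise(self):
        # changing an unrelated metric never flips a reason
        for leak in (0.0, 99.0, 101.0):
            for rs in (5.0, 19.0, 21.0):
                for rng_mv in (10.0, 25.0):
                    qc = nc.apply_qc(passive(leak=leak, rs=rs), rng_mv)
                    assert ("leak" in qc.reasons) == (leak > 100.0)
                    assert ("series_resistance" in qc.reasons) == (rs > 20.0)
                    assert ("activation_range" in qc.reasons) == (rng_mv < 20.0)


class TestAnova:
    def test_hand_computed_example(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3.0 on df (2, 6)
        anova, _ = nc.anova_tukey([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert anova.F == pytest.approx(3.0)
        assert (anova.df_between, anova.df_within) == (2, 6)
        assert anova.p == pytest.approx(sps.f.sf(3.0, 2, 6))

    def test_identical_groups(self):
        anova, tukey = nc.anova_tukey([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert anova.F == pytest.approx(0.0)
        assert anova.p == pytest.approx(1.0)
        assert tukey[0].stars == "ns"

    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        anova, _ = nc.anova_tukey([a, b])
        t, p = sps.ttest_ind(a, b)
        assert anova.F == pytest.approx(t**2, rel=1e-10)
        assert anova.p == pytest.approx(p, rel=1e-10)

    def test_zero_within_variance(self):
        anova, tukey = nc.anova_tukey([[1.0, 1.0], [2.0, 2.0]])
        assert math.isinf(anova.F)
        assert anova.p == 0.0
        assert tukey[0].p == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            nc.anova_tukey([[1.0, 2.0]])
        with pytest.raises(ValueError):
            nc.anova_tukey([[1.0, 2.0], [3.0]])


class TestTukey:
    def test_matches_statsmodels_reference(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 8), rng.normal(0.7, 1, 12), rng.normal(1.2, 1, 6)]
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [8, 12, 6])
        ref = statsmodels.pairwise_tukeyhsd(data, labels)
        _, ours = nc.anova_tukey(groups, labels=["a", "b", "c"])
        for comp, p_ref in zip(ours, ref.pvalues):
            assert comp.p == pytest.approx(p_ref, abs=1e-4)

    def test_star_thresholds(self):
        assert star_label(0.04) == "*"
        assert star_label(0.009) == "**"
        assert star_label(0.004) == "***"
        assert star_label(0.06) == "ns"
        # step function exactly at the figure-legend thresholds
        assert star_label(0.05) == "ns"
        assert star_label(0.01) == "*"
        assert star_label(0.005) == "**"


def make_result(density, condition="g1", qc_pass=True, cell_id="c"):
    qc = QCMetrics(
        leak=10.0, Rs=10.0, activation_range=30.0,
        passed=qc_pass, reasons=[] if qc_pass else ["leak"],
    )
    return CellResult(
        metadata=RecordingMetadata(cell_id=cell_id, condition=condition),
        passive=passive(),
        iv=IVCurve([-12.0], [-density * 25.0]),
        peak_at_test=-density * 25.0,
        current_density=density,
        inactivation_fit=None,
        qc=qc,
    )


class TestSummarize:
    def test_mean_and_se(self):
        summary = nc.summarize_cohort(
            [make_result(d, cell_id=f"c{d}") for d in (40.0, 50.0, 60.0)]
        )
        g = summary.groups[0]
        assert g.mean == pytest.approx(50.0)
        assert g.se == pytest.approx(10.0 / math.sqrt(3))
        assert g.n == 3
        assert summary.anova is None  # single group: no ANOVA, flagged by absence

    def test_group_emptied_by_qc_raises_named_error(self):
        cells = [make_result(50.0, "ok", cell_id="a"),
                 make_result(55.0, "ok", cell_id="b"),
                 make_result(60.0, "bad", qc_pass=False, cell_id="c")]
        with pytest.raises(ValueError, match="bad"):
            nc.summarize_cohort(cells)


class TestKineticsCalibration:
    def test_argmin_on_target_sweep(self, default_cell, config):
        iv = _simulate_iv(
            replace(default_cell, noise_sd=0.0), nc.build_activation_protocol(), config
        )
        assert iv.potentials[int(np.argmin(iv.peaks))] == -12.0

    def test_depolarizing_perturbation_moves_argmin(self, default_cell, config):
        cell = replace(default_cell, act_V_half=default_cell.act_V_half + 10.0,
                       noise_sd=0.0)
        iv = _simulate_iv(cell, nc.build_activation_protocol(), config)
        assert iv.potentials[int(np.argmin(iv.peaks))] > -12.0

    def test_degenerate_grid_rejected(self):
        proto = nc.build_activation_protocol(start=-12.0, stop=-12.0)
        with pytest.raises(ValueError, match="one sweep"):
            nc.calibrate_default_kinetics(protocol=proto)


class TestCohortCalibration:
    def test_zero_spread_fixture_recovers_target(self, config):
        # mean 50, SD 0, n 5: every measured density within 2 % (noise-free)
        fx = nc.CohortFixture("ctl", "bipolar", 50.0, 0.0, 5)
        cells = nc.calibrate_cohort(fx, config=config, master_seed=3)
        densities = []
        for cell in cells:
            bundle = nc.simulate_cell(
                replace(cell, noise_sd=0.0), config,
                inactivation=nc.build_inactivation_protocol(
                    prepulse_start=-82.0, prepulse_stop=-72.0
                ),
            )
            densities.append(nc.analyze_cell(bundle).current_density)
        assert np.allclose(densities, 50.0, rtol=0.02)

    def test_density_scales_linearly_with_target(self, config):
        from navclamp.cohort import _pilot_density

        means = []
        for target in (30.0, 60.0):
            fx = nc.CohortFixture("ctl", "bipolar", target, 0.0, 2)
            cells = nc.calibrate_cohort(fx, config=config, master_seed=4)
            means.append(np.mean([_pilot_density(c, config) for c in cells]))
        assert means[1] == pytest.approx(2 * means[0], rel=0.03)

    def test_single_cell_fixture_rejected(self):
        with pytest.raises(ValueError):
            nc.CohortFixture("ctl", "bipolar", 50.0, 0.0, 1)

    def test_unattainable_target_rejected(self, config):
        fx = nc.CohortFixture("ctl", "bipolar", 5000.0, 0.0, 2)
        with pytest.raises(ValueError, match="unattainable|no measurable"):
            nc.calibrate_cohort(fx, config=config, master_seed=5)
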