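"""Steady-state inactivation analysis and the descending Boltzmann fit.

The availability curve is measured as the peak test-pulse current after a
long conditioning prepulse, normalized to the current elicited from the most
negative prepulse (I0), and fitted to

    I/I0 = 1 / (1 + exp((Vm - V_half) / S))

with V_half the half-inactivation potential and S > 0 the slope factor.
I0 is fixed operationally (no free amplitude), matching its definition.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .protocols import VoltageProtocol
from .results import BoltzmannFit, InactivationCurve, IVCurve

__all__ = [
    "boltzmann",
    "build_inactivation_curve",
    "fit_boltzmann",
    "activation_voltage_range",
]


def boltzmann(vm, v_half: float, s: float):
    """Descending logistic of membrane potential; value in (0, 1) for S > 0."""
    if s == 0:
        raise ValueError("slope factor must be nonzero")
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0
        return 1.0 / (1.0 + np.exp((np.asarray(vm, dtype=float) - v_half) / s))


def build_inactivation_curve(
    corrected_traces: list[np.ndarray],
    protocol: VoltageProtocol,
    peak_window_ms: tuple[float, float] = (0.2, 10.0),
    noise_sd: float | None = None,
) -> InactivationCurve:
    """Peak current per sweep in the test-pulse window, normalized to the
    most-negative-prepulse peak.

    ``noise_sd`` (pA) guards normalization: if |I0| is below five times the
    noise floor the normalization is meaningless and an error is raised.
    When not given, the noise floor is estimated from the pre-step baseline
    of the first trace.
    """
    if len(corrected_traces) != protocol.sweep_count:
        raise ValueError("one corrected trace per protocol sweep required")
    rate = protocol.sampling_rate
    test_epoch = protocol.varied_epoch + 1
    onset_ms = protocol.epoch_onset_ms(test_epoch)
    i0 = int(round((onset_ms + peak_window_ms[0]) * 1e-3 * rate))
    i1 = int(round((onset_ms + peak_window_ms[1]) * 1e-3 * rate))
    peaks = []
    for trace in corrected_traces:
        if i0 >= trace.size:
            raise ValueError("peak search window lies outside the trace")
        peaks.append(float(np.min(trace[i0 : min(i1, trace.size)])))
    peaks = np.array(peaks)
    potentials = protocol.sweep_levels
    I0 = peaks[0]  # most negative prepulse (levels ascend)
    if noise_sd is None:
        n_base = int(round(protocol.epoch_onset_ms(1) * 1e-3 * rate))
        noise_sd = float(np.std(corrected_traces[0][n_base // 2 : n_base])) if n_base > 4 else 0.0
    if abs(I0) < 5 * noise_sd or I0 == 0:
        raise ValueError("reference current I0 indistinguishable from noise; cannot normalize")
    return InactivationCurve(prepulse_potentials=potentials, peaks=peaks, I0=I0)


def fit_boltzmann(
    curve: InactivationCurve,
    v_half_bounds: tuple[float, float] = (-120.0, 0.0),
    s_bounds: tuple[float, float] = (0.5, 30.0),
    xtol: float = 1e-8,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of the normalized availability curve.

    Deterministic derivative-based fit with the analytic Jacobian of the
    logistic.  Initialized at the linearly interpolated 0.5 crossing
    (slope factor 7 mV).  Non-convergence is reported via the ``converged``
    flag, never silently.
    """
    x = curve.prepulse_potentials
    y = curve.normalized
    if x.size < 4:
        raise ValueError("need at least four points to fit the Boltzmann curve")

    # initial midpoint: first downward 0.5 crossing, else midrange
    v0 = 0.5 * (x[0] + x[-1])
    for i in range(x.size - 1):
        if (y[i] - 0.5) * (y[i + 1] - 0.5) <= 0 and y[i] != y[i + 1]:
            v0 = x[i] + (0.5 - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
            break
    v0 = float(np.clip(v0, *v_half_bounds))

    def residuals(p):
        return boltzmann(x, p[0], p[1]) - y

    def jac(p):
        f = boltzmann(x, p[0], p[1])
        core = f * (1.0 - f)
        return np.column_stack((core / p[1], core * (x - p[0]) / p[1] ** 2))

    res = least_squares(
        residuals,
        x0=np.array([v0, 7.0]),
        jac=jac,
        bounds=([v_half_bounds[0], s_bounds[0]], [v_half_bounds[1], s_bounds[1]]),
        xtol=xtol,
        ftol=1e-14,
        gtol=1e-14,
    )
    v_half, s = res.x
    at_bound = (
        np.isclose(s, s_bounds[0]) or np.isclose(s, s_bounds[1])
        or np.isclose(v_half, v_half_bounds[0]) or np.isclose(v_half, v_half_bounds[1])
    )
    rss = float(np.sum(res.fun**2))
    dof = max(x.size - 2, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov = None
    return BoltzmannFit(
        V_half=float(v_half),
        S=float(s),
        rss=rss,
        converged=bool(res.success and not at_bound),
        covariance=cov,
    )


def activation_voltage_range(
    iv: IVCurve,
    threshold_fraction: float = 0.1,
    min_peak_pa: float = 20.0,
) -> float:
    """Voltage span of the I-V curve from activation threshold to peak.

    Defined as (potential of the maximal-magnitude peak) minus (most
    negative potential whose peak magnitude exceeds ``threshold_fraction``
    of the maximum).  The threshold fraction operationalizes "activation
    voltage range" and is recorded with the QC configuration.
    """
    if iv.potentials.size == 0:
        raise ValueError("empty I-V curve")
    mags = np.abs(iv.peaks)
    i_max = int(np.argmax(mags))
    if mags[i_max] < min_peak_pa:
        raise ValueError("no peak current distinguishable from noise in the I-V curve")
    above = np.flatnonzero(mags >= threshold_fraction * mags[i_max])
    return float(iv.potentials[i_max] - iv.potentials[above[0]])
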