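"""Voltage-clamp analysis: subtraction, densities, fits vs grid-search oracles."""

import numpy as np
import pytest

from phaseclamp.params import (
    CellParams,
    GENOTYPES,
    KineticsParamSet,
    VoltageStepProtocol,
    boltzmann,
)
from phaseclamp.synth import simulate_vc_recording
from phaseclamp.synth.vclamp_sim import simulate_vc_sweep
from phaseclamp.trace import SampledTrace
from phaseclamp import vclamp

FS = 5000.0


def _trace(values, dt=1e-3, kind="membrane_current", **meta):
    return SampledTrace(0.0, dt, np.asarray(values, float), kind, meta=dict(meta))


# ---------------------------------------------------------------------------
# subtraction
# ---------------------------------------------------------------------------

def test_subtraction_identity_and_recovery():
    ikr = np.concatenate([np.zeros(100), 50.0 * np.ones(200), np.zeros(100)])
    post = _trace(np.full(400, 7.0), step_mV=0.0)
    pre = _trace(post.values + ikr, step_mV=0.0)
    assert np.all(vclamp.subtract_drug(post, post).trace.values == 0.0)
    assert np.allclose(vclamp.subtract_drug(pre, post).trace.values, ikr)


def test_subtraction_is_linear_in_amplitude():
    rng = np.random.default_rng(0)
    pre = _trace(rng.normal(size=300))
    post = _trace(rng.normal(size=300))
    a = 3.7
    scaled = vclamp.subtract_drug(
        _trace(a * pre.values), _trace(a * post.values)
    ).trace.values
    assert np.allclose(scaled, a * vclamp.subtract_drug(pre, post).trace.values)


def test_subtraction_rejects_timebase_mismatch():
    pre = _trace(np.zeros(100))
    with pytest.raises(ValueError, match="timebase"):
        vclamp.subtract_drug(pre, _trace(np.zeros(101)))
    with pytest.raises(ValueError, match="timebase"):
        vclamp.subtract_drug(pre, _trace(np.zeros(100), dt=2e-3))


# ---------------------------------------------------------------------------
# densities and I-V
# ---------------------------------------------------------------------------

def _constructed_step(protocol, plateau_pA, tail_pA, fs=1000.0):
    n = int(protocol.sweep_duration_s * fs)
    t = np.arange(n) / fs
    v = np.zeros(n)
    in_step = (t >= protocol.step_start_s) & (t < protocol.step_end_s)
    v[in_step] = plateau_pA
    in_tail = (t >= protocol.step_end_s) & (t < protocol.step_end_s + 0.3)
    v[in_tail] = tail_pA
    return vclamp.SubtractedCurrent(
        trace=_trace(v, dt=1.0 / fs, step_mV=0.0), step_mV=0.0
    )


def test_zero_trace_yields_zero_densities(protocol):
    sub = _constructed_step(protocol, 0.0, 0.0)
    pt = vclamp.measure_step_currents(sub, protocol, 25.0)
    assert pt.steady_state_density_pA_per_pF == 0.0
    assert pt.tail_density_pA_per_pF == 0.0


def test_constructed_plateau_density_arithmetic(protocol):
    """50 pA plateau over 25 pF is exactly 2.0 pA/pF."""
    sub = _constructed_step(protocol, 50.0, 120.0)
    pt = vclamp.measure_step_currents(sub, protocol, 25.0)
    assert pt.steady_state_density_pA_per_pF == pytest.approx(2.0)
    assert pt.tail_density_pA_per_pF == pytest.approx(120.0 / 25.0)
    with pytest.raises(ValueError):
        vclamp.measure_step_currents(sub, protocol, -1.0)


def test_iv_densities_match_generator_closed_form(protocol, cell, wt_kinetics):
    """Measured densities equal the analytic gating-model values per step."""
    from test_synth_vclamp import analytic_ikr_trace

    sweeps = simulate_vc_recording(wt_kinetics, cell, protocol, fs_hz=FS)
    kin, vh = wt_kinetics, protocol.holding_mV
    m0 = kin.m_inf(vh)
    hold = kin.g_max_nS * m0 * kin.h_inf(vh) * (vh - kin.E_K_mV)
    for pair in sweeps:
        sub = vclamp.subtract_drug(pair.pre, pair.post)
        pt = vclamp.measure_step_currents(sub, protocol, cell.capacitance_pF)
        ana = analytic_ikr_trace(kin, protocol, pair.step_mV, FS)
        i_end = int(protocol.step_end_s * FS)
        ss = ana[i_end - int(0.2 * FS): i_end].mean() - hold
        # instantaneous tail jump relative to the fully deactivated level
        tail_base = ana[-int(0.5 * FS):].mean()
        tail_seg = ana[i_end: i_end + int(0.5 * FS)] - tail_base
        tail = tail_seg[np.argmax(np.abs(tail_seg))]
        assert pt.steady_state_density_pA_per_pF == pytest.approx(
            ss / cell.capacitance_pF, rel=0.01, abs=1e-3
        )
        assert pt.tail_density_pA_per_pF == pytest.approx(
            tail / cell.capacitance_pF, rel=0.01, abs=1e-3
        )


def test_steady_state_monotone_without_inactivation(protocol, cell):
    """Disabling inactivation removes the bell: argmax at the top step."""
    kin = KineticsParamSet(
        g_max_nS=1.0, inact_vhalf_mV=500.0, label="no_inact"
    )  # availability ~1 across the protocol range
    sweeps = simulate_vc_recording(kin, cell, protocol, fs_hz=2000.0)
    points = [
        vclamp.measure_step_currents(
            vclamp.subtract_drug(p.pre, p.post), protocol, cell.capacitance_pF
        )
        for p in sweeps
    ]
    res = vclamp.build_iv_curves(points)
    ss = res["table"]["steady_state_pA_per_pF"].to_numpy()
    assert np.all(np.diff(ss) >= -1e-9)
    assert res["v_max_steady"] == protocol.step_levels_mV[-1]


def test_iv_curve_input_validation():
    pts = [vclamp.IVPoint(v, 0.0, 0.0) for v in (-20.0, 0.0)]
    with pytest.raises(ValueError):
        vclamp.build_iv_curves(pts)
    pts = [vclamp.IVPoint(v, 0.0, 0.0) for v in (-20.0, 0.0, 0.0)]
    with pytest.raises(ValueError, match="duplicate"):
        vclamp.build_iv_curves(pts)


# ---------------------------------------------------------------------------
# kinetics fits vs brute-force grid oracles
# ---------------------------------------------------------------------------

def _grid_oracle_mono(t, y, tau_grid_ms):
    """Dense grid-search least squares for A(1 − e^(−t/τ)) + C."""
    best = (None, np.inf)
    for tau in tau_grid_ms / 1000.0:
        X = np.column_stack([1.0 - np.exp(-t / tau), np.ones_like(t)])
        coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = float(((y - X @ coef) ** 2).sum())
        if r < best[1]:
            best = (tau * 1000.0, r)
    return best[0]


def test_activation_fit_self_consistency():
    t = np.arange(0, 2.0, 1e-3)
    y = 80.0 * (1.0 - np.exp(-t / 0.1)) + 5.0
    fit = vclamp.fit_activation(y, dt=1e-3)
    assert fit.tau_ms == pytest.approx(100.0, abs=0.1)
    assert fit.amplitude_pA == pytest.approx(80.0, rel=1e-3)


def test_activation_fit_matches_grid_oracle():
    """20 random noise-free traces: fitted τ within 1% of the grid optimum."""
    rng = np.random.default_rng(7)
    tau_grid = np.geomspace(1.0, 2000.0, 3000)
    for _ in range(20):
        tau = rng.uniform(20.0, 1200.0)  # ms
        amp = rng.uniform(10.0, 300.0) * rng.choice([-1.0, 1.0])
        c = rng.uniform(-20.0, 20.0)
        t = np.arange(0, 4.0, 2e-3)
        y = amp * (1.0 - np.exp(-t / (tau / 1000.0))) + c
        fit = vclamp.fit_activation(y, dt=2e-3)
        oracle = _grid_oracle_mono(t, y, tau_grid)
        assert fit.tau_ms == pytest.approx(oracle, rel=0.01)
        assert fit.tau_ms == pytest.approx(tau, rel=0.01)


def test_activation_tau_invariant_to_amplitude_scaling():
    t = np.arange(0, 3.0, 2e-3)
    y = 50.0 * (1.0 - np.exp(-t / 0.35)) + 2.0
    tau1 = vclamp.fit_activation(y, dt=2e-3).tau_ms
    tau2 = vclamp.fit_activation(100.0 * y, dt=2e-3).tau_ms
    assert tau1 == pytest.approx(tau2, rel=1e-6)


def _grid_oracle_biexp(t, y, tau_f_truth_s, tau_s_truth_s):
    """Coarse 2-D grid + local refinement, linear solve for amplitudes."""
    def rss_at(tf, ts):
        X = np.column_stack([np.exp(-t / tf), np.exp(-t / ts), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ coef) ** 2).sum())

    grid = np.geomspace(0.01, 10.0, 40)
    best = (None, None, np.inf)
    for i, tf in enumerate(grid):
        for ts in grid[i + 1:]:
            r = rss_at(tf, ts)
            if r < best[2]:
                best = (tf, ts, r)
    tf0, ts0, _ = best
    fine_f = tf0 * np.geomspace(0.8, 1.25, 40)
    fine_s = ts0 * np.geomspace(0.8, 1.25, 40)
    best = (tf0, ts0, np.inf)
    for tf in fine_f:
        for ts in fine_s:
            if tf >= ts:
                continue
            r = rss_at(tf, ts)
            if r < best[2]:
                best = (tf, ts, r)
    return best[0] * 1000.0, best[1] * 1000.0


def test_deactivation_fit_matches_grid_oracle_and_truth():
    """Biexponential (τ_f 300 ms, τ_s 2000 ms, A_f/A_s = 2): both τ within 2%."""
    t = np.arange(0, 8.0, 4e-3)
    y = 100.0 * np.exp(-t / 0.3) + 50.0 * np.exp(-t / 2.0) + 3.0
    fit = vclamp.fit_deactivation(y, dt=4e-3)
    assert not fit.degenerate
    assert fit.tau_fast_ms == pytest.approx(300.0, rel=0.02)
    assert fit.tau_slow_ms == pytest.approx(2000.0, rel=0.02)
    oracle_f, oracle_s = _grid_oracle_biexp(t, y, 0.3, 2.0)
    assert fit.tau_fast_ms == pytest.approx(oracle_f, rel=0.02)
    assert fit.tau_slow_ms == pytest.approx(oracle_s, rel=0.02)


def test_monoexponential_input_flagged_degenerate():
    t = np.arange(0, 5.0, 2e-3)
    y = 120.0 * np.exp(-t / 0.5) + 1.0
    fit = vclamp.fit_deactivation(y, dt=2e-3)
    assert fit.degenerate
    # the collapsed fit still reproduces the decay: one component carries
    # (nearly) all amplitude or the two constants coincide
    total = abs(fit.amp_fast_pA) + abs(fit.amp_slow_pA)
    assert (
        min(abs(fit.amp_fast_pA), abs(fit.amp_slow_pA)) / total < 0.01
        or fit.tau_slow_ms / fit.tau_fast_ms < 1.5
    )


def test_deactivation_component_ordering(protocol, cell):
    for label in ("A561T_cis", "N996I_trans"):
        kin = GENOTYPES[label]
        sweeps = simulate_vc_recording(kin, cell, protocol, fs_hz=FS,
                                       step_levels_mV=[0.0])
        sub = vclamp.subtract_drug(sweeps[0].pre, sweeps[0].post)
        fit = vclamp.fit_deactivation(
            sub.trace, (protocol.step_end_s, protocol.sweep_duration_s)
        )
        assert fit.tau_fast_ms <= fit.tau_slow_ms
        assert fit.tau_fast_ms == pytest.approx(kin.tau_deact_fast_s * 1000, rel=0.02)
        assert fit.tau_slow_ms == pytest.approx(kin.tau_deact_slow_s * 1000, rel=0.02)


def test_cis_lines_deactivate_faster_than_trans(protocol, cell):
    """Slow deactivation is faster (smaller τ_s) with the SNP in cis."""
    taus = {}
    for label in ("A561T_cis", "A561T_trans", "N996I_cis", "N996I_trans"):
        sweeps = simulate_vc_recording(GENOTYPES[label], cell, protocol,
                                       fs_hz=FS, step_levels_mV=[0.0])
        sub = vclamp.subtract_drug(sweeps[0].pre, sweeps[0].post)
        taus[label] = vclamp.fit_deactivation(
            sub.trace, (protocol.step_end_s, protocol.sweep_duration_s)
        ).tau_slow_ms
    assert taus["A561T_cis"] < taus["A561T_trans"]
    assert taus["N996I_cis"] < taus["N996I_trans"]


# ---------------------------------------------------------------------------
# activation curve
# ---------------------------------------------------------------------------

def test_boltzmann_curve_recovery():
    v = np.arange(-50.0, 41.0, 10.0)
    tails = 7.3 * boltzmann(v, -20.0, 7.0)
    fit = vclamp.fit_activation_curve(v, tails)
    assert fit.vhalf_mV == pytest.approx(-20.0, abs=0.5)
    assert fit.slope_mV == pytest.approx(7.0, abs=0.5)
    assert fit.normalized_tails.max() == pytest.approx(1.0)


def test_activation_curve_rejects_flat_input():
    with pytest.raises(ValueError):
        vclamp.fit_activation_curve([-40, -20, 0, 20], [1.0, 1.0, 1.0, 1.0])


def test_cis_trans_activation_curves_overlap(protocol, cell):
    """Voltage dependence of activation is shared: |ΔV½| < 2 mV."""
    vhalf = {}
    for label in ("A561T_cis", "A561T_trans"):
        sweeps = simulate_vc_recording(GENOTYPES[label], cell, protocol, fs_hz=2000.0)
        pts = [
            vclamp.measure_step_currents(
                vclamp.subtract_drug(p.pre, p.post), protocol, cell.capacitance_pF
            )
            for p in sweeps
        ]
        fit = vclamp.fit_activation_curve(
            [p.voltage_mV for p in pts], [p.tail_density_pA_per_pF for p in pts]
        )
        vhalf[label] = fit.vhalf_mV
    assert abs(vhalf["A561T_cis"] - vhalf["A561T_trans"]) < 2.0
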