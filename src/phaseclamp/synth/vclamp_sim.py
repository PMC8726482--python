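"""Phenomenological voltage-clamp simulator for the E4031-subtraction assay.

Generates paired pre-/post-drug current sweeps under a square step protocol.
The drug-sensitive component follows the gating model of
:class:`~phaseclamp.params.KineticsParamSet`:

* activation relaxes exponentially toward the Boltzmann steady state with the
  voltage-dependent time constant ``tau_act(V)``;
* the activation variable is carried by two components (weights ``frac_fast``
  and ``1 − frac_fast``) which share ``tau_act`` while opening but close with
  their own time constants, so the tail current on return to holding decays
  as the biexponential ``A_f·exp(−t/τ_f) + A_s·exp(−t/τ_s)``;
* steady-state inactivation scales the open probability instantaneously
  (hERG inactivation is far faster than activation), producing the
  bell-shaped steady-state I–V.

The blocker is modeled as pure conductance scaling: the post-drug sweep
carries ``(1 − block_fraction)`` of the drug-sensitive current plus the
unblocked leak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from ..params import CellParams, KineticsParamSet, VoltageStepProtocol
from ..trace import SampledTrace


@dataclass
class VCSweepPair:
    """One protocol sweep: pre- and post-drug currents at one step level."""

    step_mV: float
    pre: SampledTrace
    post: SampledTrace


def _segment_gate(m0: float, m_inf: float, tau: float, n: int, dt: float) -> np.ndarray:
    """Gate trajectory over one constant-voltage segment.

    Per-sample geometric recurrence m[i] = m_inf + (m[i−1] − m_inf)·f with
    f = exp(−dt/τ), evaluated as a cumulative product.
    """
    if n == 0:
        return np.empty(0)
    f = np.exp(-dt / tau)
    decay = np.cumprod(np.full(n, f))
    return m_inf + (m0 - m_inf) * decay


def simulate_vc_sweep(
    kinetics: KineticsParamSet,
    cell: CellParams,
    protocol: VoltageStepProtocol,
    step_mV: float,
    block_fraction: float = 1.0,
    noise_sd_pA: float = 0.0,
    fs_hz: float = 20_000.0,
    rng: np.random.Generator | None = None,
) -> VCSweepPair:
    """Simulate the pre/post-drug current pair for a single step level."""
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block_fraction must lie in [0, 1]")
    for name in ("g_max_nS", "E_K_mV", "tau_deact_fast_s", "tau_deact_slow_s"):
        if not np.isfinite(getattr(kinetics, name)):
            raise ValueError(f"non-finite kinetics parameter {name}")
    rng = rng or np.random.default_rng(cell.seed)
    dt = 1.0 / fs_hz
    vh = protocol.holding_mV

    segments = [  # (voltage, duration)
        (vh, protocol.pre_step_s),
        (step_mV, protocol.step_duration_s),
        (vh, protocol.tail_duration_s),
    ]
    counts = [int(round(d * fs_hz)) for _, d in segments]

    m_fast = m_slow = float(kinetics.m_inf(vh))  # start at holding steady state
    gate_parts, volt_parts = [], []
    for (v, _), n in zip(segments, counts):
        m_target = float(kinetics.m_inf(v))
        # opening follows the activation tau; closing follows each
        # component's deactivation tau
        if m_target >= m_fast:
            tau_f = tau_s = float(kinetics.tau_act(v))
        else:
            tau_f, tau_s = kinetics.tau_deact_fast_s, kinetics.tau_deact_slow_s
        gf = _segment_gate(m_fast, m_target, tau_f, n, dt)
        gs = _segment_gate(m_slow, m_target, tau_s, n, dt)
        if n:
            m_fast, m_slow = float(gf[-1]), float(gs[-1])
        gate_parts.append(kinetics.frac_fast * gf + (1.0 - kinetics.frac_fast) * gs)
        volt_parts.append(np.full(n, v))

    m = np.concatenate(gate_parts)
    v_cmd = np.concatenate(volt_parts)
    h = np.asarray(kinetics.h_inf(v_cmd))
    i_kr = kinetics.g_max_nS * m * h * (v_cmd - kinetics.E_K_mV)  # nS·mV = pA
    i_leak = cell.leak_conductance_nS * (v_cmd - cell.leak_reversal_mV)

    def trace(i_drug_scale: float) -> SampledTrace:
        sig = i_leak + i_drug_scale * i_kr
        if noise_sd_pA > 0:
            sig = sig + rng.normal(0.0, noise_sd_pA, sig.size)
        return SampledTrace(
            t0=0.0,
            dt=dt,
            values=sig,
            signal_kind="membrane_current",
            meta={"step_mV": step_mV, "label": kinetics.label},
        )

    return VCSweepPair(step_mV=step_mV, pre=trace(1.0), post=trace(1.0 - block_fraction))


def simulate_vc_recording(
    kinetics: KineticsParamSet,
    cell: CellParams | None = None,
    protocol: VoltageStepProtocol | None = None,
    block_fraction: float = 1.0,
    noise_sd_pA: float = 0.0,
    fs_hz: float = 20_000.0,
    step_levels_mV: Sequence[float] | None = None,
) -> List[VCSweepPair]:
    """Simulate paired pre/post-drug sweeps for every protocol step level.

    ``block_fraction`` defaults to 1.0, modeling the full block obtained with
    a saturating blocker concentration.
    """
    cell = cell or CellParams()
    protocol = protocol or VoltageStepProtocol()
    levels = protocol.step_levels_mV if step_levels_mV is None else step_levels_mV
    rng = np.random.default_rng(cell.seed)
    return [
        simulate_vc_sweep(
            kinetics, cell, protocol, float(v), block_fraction, noise_sd_pA, fs_hz, rng
        )
        for v in levels
    ]
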