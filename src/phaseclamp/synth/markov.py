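"""Three-state Markov-chain hERG model (closed ↔ open ↔ inactivated).

A second, mechanistic tier of current generation: state occupancies obey a
linear master equation with voltage-dependent transition rates, and the
biexponential tail relaxation emerges from the two nonzero eigenvalues of the
rate matrix at the holding potential rather than being imposed. Used to test
that the empirical biexponential fitter recovers mechanistically generated
time constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ..params import CellParams, KineticsParamSet, VoltageStepProtocol
from ..trace import SampledTrace

_STATES = ("C", "O", "I")


@dataclass(frozen=True)
class MarkovRates:
    """Voltage-dependent rates of the linear chain C ↔ O ↔ I.

    Each transition rate is ``r0 · exp(z · V)`` with V in mV and r0 in 1/s;
    the sign of z encodes the voltage sensitivity (opening and inactivation
    accelerate with depolarization, their reverses with hyperpolarization).
    Defaults give activation/deactivation on the hundreds-of-ms scale and
    inactivation an order of magnitude faster, as for hERG.
    """

    alpha0: float = 8.0     # C -> O at 0 mV, 1/s
    z_alpha: float = 0.035
    beta0: float = 1.2      # O -> C at 0 mV, 1/s
    z_beta: float = -0.045
    kappa0: float = 60.0    # O -> I at 0 mV, 1/s
    z_kappa: float = 0.015
    lam0: float = 20.0      # I -> O at 0 mV, 1/s
    z_lam: float = -0.025

    def rates(self, v_mV: float) -> Tuple[float, float, float, float]:
        """(alpha, beta, kappa, lam) at voltage ``v_mV``; all positive."""
        out = (
            self.alpha0 * np.exp(self.z_alpha * v_mV),
            self.beta0 * np.exp(self.z_beta * v_mV),
            self.kappa0 * np.exp(self.z_kappa * v_mV),
            self.lam0 * np.exp(self.z_lam * v_mV),
        )
        if any(r <= 0 for r in out):
            raise ValueError("all transition rates must be positive")
        return out

    def generator(self, v_mV: float) -> np.ndarray:
        """3×3 rate matrix Q acting on occupancy column vectors (C, O, I)."""
        a, b, k, l = self.rates(v_mV)
        q = np.array(
            [
                [-a, b, 0.0],
                [a, -(b + k), l],
                [0.0, k, -l],
            ]
        )
        if not np.allclose(q.sum(axis=0), 0.0, atol=1e-12):
            raise ValueError("rate matrix does not conserve probability")
        return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Occupancy null vector of Q, normalized to sum to 1."""
    w, vecs = np.linalg.eig(q)
    i = int(np.argmin(np.abs(w)))
    p = np.real(vecs[:, i])
    p = p / p.sum()
    if np.any(p < -1e-9):
        raise ValueError("stationary distribution has negative mass")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def holding_relaxation_taus(rates: MarkovRates, holding_mV: float) -> Tuple[float, float]:
    """Time constants (fast, slow; seconds) implied by the two nonzero
    eigenvalues of the rate matrix at the holding potential."""
    w = np.linalg.eigvals(rates.generator(holding_mV))
    w = np.sort(np.real(w))  # most negative first; ~0 last
    tau_fast, tau_slow = -1.0 / w[0], -1.0 / w[1]
    return float(tau_fast), float(tau_slow)


def _propagate(q: np.ndarray, p0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Occupancies at times ``t``: exp(Q t) p0 via eigendecomposition."""
    w, vecs = np.linalg.eig(q)
    c = np.linalg.solve(vecs, p0)
    p = np.real(vecs @ (c[:, None] * np.exp(np.outer(w, t))))
    return p  # shape (3, len(t))


def simulate_markov_herg(
    rates: MarkovRates,
    kinetics: KineticsParamSet,
    cell: CellParams | None = None,
    protocol: VoltageStepProtocol | None = None,
    step_mV: float = 0.0,
    fs_hz: float = 20_000.0,
    return_occupancies: bool = False,
):
    """Simulate one sweep of the Markov model at a single step level.

    Occupancies start at the stationary distribution of the holding
    potential; within each constant-voltage epoch the master equation is
    solved exactly. Returns the current trace
    ``g_max · P(open) · (V − E_K)`` (pA), and optionally the occupancy
    matrix (3 × n) for conservation checks.
    """
    cell = cell or CellParams()
    protocol = protocol or VoltageStepProtocol()
    dt = 1.0 / fs_hz
    vh = protocol.holding_mV

    segments = [
        (vh, protocol.pre_step_s),
        (step_mV, protocol.step_duration_s),
        (vh, protocol.tail_duration_s),
    ]
    p = stationary_distribution(rates.generator(vh))
    occ_parts, volt_parts = [], []
    for v, dur in segments:
        n = int(round(dur * fs_hz))
        t = dt * (1.0 + np.arange(n))
        occ = _propagate(rates.generator(v), p, t)
        p = occ[:, -1]
        occ_parts.append(occ)
        volt_parts.append(np.full(n, v))

    occ = np.concatenate(occ_parts, axis=1)
    v_cmd = np.concatenate(volt_parts)
    current = kinetics.g_max_nS * occ[1] * (v_cmd - kinetics.E_K_mV)
    trace = SampledTrace(
        t0=0.0,
        dt=dt,
        values=current,
        signal_kind="membrane_current",
        meta={"step_mV": step_mV, "model": "markov3"},
    )
    if return_occupancies:
        return trace, occ
    return trace
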