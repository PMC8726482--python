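"""Parameter sets for the synthetic generators and the packaged genotype configs.

The packaged :data:`GENOTYPES` table holds one hERG gating parameter set per
cell line studied: isogenic wild type, and the two LQT2 missense lines
(pore-loop A561T, C-terminal N996I) each with the common K897T polymorphism on
the mutant allele (*cis*) or on the wild-type allele (*trans*).

Calibration policy
------------------
Quantities the source study prints as group means are used to fix generator
parameters in closed form:

* ``g_max`` is derived from the printed maximal tail current density
  (3.3 / 0.8 / 1.9 pA/pF for WT / A561T-cis / N996I-cis) via
  :func:`gmax_for_tail_density`, so that the full analysis pipeline recovers
  the printed number from simulated recordings.
* activation time-constant tables are scaled so the −30 mV τ of each *cis*
  line is 21% (A561T) / 33% (N996I) faster than its *trans* counterpart.

Quantities the study does not print (Boltzmann midpoints/slopes, absolute τ
values, capacitance) are fixed once at values typical for hERG in hiPSC-CMs
at physiological temperature and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

#: K+ reversal potential (mV) from the recording solutions (5.4 mM out /
#: 145 mM in, Nernst at 36 degC).
E_K_MV = -88.0

#: default cell capacitance used for density normalization, pF
DEFAULT_CAPACITANCE_PF = 20.0


def boltzmann(v: np.ndarray | float, vhalf: float, slope: float) -> np.ndarray | float:
    """Rising Boltzmann 1 / (1 + exp((vhalf − v)/slope))."""
    return 1.0 / (1.0 + np.exp((vhalf - np.asarray(v, dtype=float)) / slope))


@dataclass(frozen=True)
class VoltageStepProtocol:
    """Square step protocol from a fixed holding potential.

    Each sweep holds at ``holding_mV``, steps to one test level for
    ``step_duration_s``, then returns to holding for ``tail_duration_s``;
    sweeps repeat every ``cycle_length_s``.
    """

    holding_mV: float = -40.0
    step_levels_mV: tuple = tuple(np.arange(-50.0, 41.0, 10.0))
    step_duration_s: float = 4.0
    cycle_length_s: float = 10.0
    tail_duration_s: float = 5.0
    pre_step_s: float = 1.0  # holding epoch recorded before the step

    def __post_init__(self) -> None:
        levels = np.asarray(self.step_levels_mV, dtype=float)
        if levels.size and np.any(np.diff(levels) <= 0):
            raise ValueError("step levels must be strictly increasing")
        if self.step_duration_s + self.tail_duration_s >= self.cycle_length_s:
            raise ValueError("step + tail must fit inside the cycle length")
        if self.pre_step_s + self.step_duration_s + self.tail_duration_s > self.cycle_length_s:
            raise ValueError("pre-step + step + tail exceed the cycle length")

    @property
    def step_start_s(self) -> float:
        return self.pre_step_s

    @property
    def step_end_s(self) -> float:
        return self.pre_step_s + self.step_duration_s

    @property
    def sweep_duration_s(self) -> float:
        return self.pre_step_s + self.step_duration_s + self.tail_duration_s


#: WT activation time-constant table, voltage (mV) -> tau (s). hERG
#: activation is slow at negative potentials and accelerates with
#: depolarization; values are typical for 36 degC recordings.
WT_TAU_ACT_TABLE: Dict[float, float] = {
    -50.0: 1.40,
    -40.0: 1.15,
    -30.0: 0.90,
    -20.0: 0.65,
    -10.0: 0.45,
    0.0: 0.32,
    10.0: 0.22,
    20.0: 0.16,
    30.0: 0.12,
    40.0: 0.09,
}


@dataclass
class KineticsParamSet:
    """Phenomenological hERG (I_Kr) gating parameter set.

    Activation follows a rising Boltzmann (``act_vhalf_mV``, ``act_slope_mV``)
    approached with voltage-dependent time constant ``tau_act``; steady-state
    inactivation is a falling Boltzmann (``inact_vhalf_mV``,
    ``inact_slope_mV``) treated as instantaneous (hERG inactivation is 1–2
    orders of magnitude faster than activation). Deactivation on return to
    holding is biexponential with fast/slow constants ``tau_deact_fast_s`` <
    ``tau_deact_slow_s`` mixed by ``frac_fast``.
    """

    g_max_nS: float
    E_K_mV: float = E_K_MV
    act_vhalf_mV: float = -25.0
    act_slope_mV: float = 7.0
    tau_act_table: Dict[float, float] = field(
        default_factory=lambda: dict(WT_TAU_ACT_TABLE)
    )
    tau_deact_fast_s: float = 0.20
    tau_deact_slow_s: float = 1.00
    frac_fast: float = 0.6
    inact_vhalf_mV: float = -60.0
    inact_slope_mV: float = 20.0
    label: str = "WT"

    def __post_init__(self) -> None:
        if not np.isfinite(self.g_max_nS) or self.g_max_nS < 0:
            raise ValueError("g_max must be finite and non-negative")
        if not self.tau_deact_fast_s < self.tau_deact_slow_s:
            raise ValueError("tau_deact_fast must be smaller than tau_deact_slow")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must lie in [0, 1]")
        for v in (self.act_slope_mV, self.inact_slope_mV):
            if v <= 0:
                raise ValueError("Boltzmann slopes must be positive")

    def tau_act(self, v_mV: float | np.ndarray) -> float | np.ndarray:
        """Activation time constant at voltage ``v_mV`` (linear interpolation)."""
        vs = np.array(sorted(self.tau_act_table))
        taus = np.array([self.tau_act_table[v] for v in vs])
        return np.interp(v_mV, vs, taus)

    def m_inf(self, v_mV):
        """Steady-state activation."""
        return boltzmann(v_mV, self.act_vhalf_mV, self.act_slope_mV)

    def h_inf(self, v_mV):
        """Steady-state availability (1 − inactivation)."""
        return 1.0 - boltzmann(v_mV, self.inact_vhalf_mV, self.inact_slope_mV)


@dataclass(frozen=True)
class CellParams:
    """Passive cell properties for voltage-clamp synthesis."""

    capacitance_pF: float = DEFAULT_CAPACITANCE_PF
    leak_conductance_nS: float = 0.5
    leak_reversal_mV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class APShapeParams:
    """Target morphology of a synthesized cardiomyocyte action potential."""

    MDP_mV: float = -72.0
    mDP_mV: float = -68.0
    APA_mV: float = 105.0
    Vmax_V_per_s: float = 25.0
    APD20_ms: float = 150.0
    APD50_ms: float = 300.0
    APD90_ms: float = 380.0
    cycle_length_ms: float = 1000.0
    diastolic_slope_mV_per_s: float = 15.0
    noise_sd_mV: float = 0.0
    n_beats: int = 12

    def __post_init__(self) -> None:
        if not (self.APD20_ms < self.APD50_ms < self.APD90_ms < self.cycle_length_ms):
            raise ValueError("need APD20 < APD50 < APD90 < cycle length")
        if self.mDP_mV < self.MDP_mV:
            raise ValueError("takeoff potential (mDP) cannot be below MDP")
        if self.APA_mV <= 0:
            raise ValueError("AP amplitude must be positive")


@dataclass
class FPShapeParams:
    """Target morphology of a synthesized MEA field-potential beat."""

    spike_amp_uV: float = 800.0
    twave_amp_uV: float = 60.0
    FPD_ms: float = 350.0
    beat_period_ms: float = 1250.0
    noise_sd_uV: float = 8.0
    n_beats: int = 24

    def __post_init__(self) -> None:
        if not 0 < self.FPD_ms < self.beat_period_ms:
            raise ValueError("need 0 < FPD < beat period")
        if self.spike_amp_uV <= 0:
            raise ValueError("spike amplitude must be positive")


@dataclass(frozen=True)
class DrugModel:
    """Hill-type conductance-block model of a hERG blocker (E4031).

    ``arrhythmia_onset_nM`` maps event category to the lowest concentration at
    which the generator injects that event.
    """

    IC50_nM: float = 10.0
    hill_coeff: float = 1.0
    max_fpd_prolongation_frac: float = 0.5
    arrhythmia_onset_nM: tuple = (
        ("abnormal_repol", 30.0),
        ("fibrillation", 300.0),
        ("quiescence", 1000.0),
    )

    def __post_init__(self) -> None:
        if self.IC50_nM <= 0 or self.hill_coeff <= 0:
            raise ValueError("IC50 and Hill coefficient must be positive")

    def fpd_prolongation(self, concentration_nM: float) -> float:
        """Fractional FPD prolongation 1 + max·c^h/(c^h + IC50^h)."""
        if concentration_nM < 0:
            raise ValueError("concentration must be non-negative")
        c = concentration_nM**self.hill_coeff
        return 1.0 + self.max_fpd_prolongation_frac * c / (c + self.IC50_nM**self.hill_coeff)


@dataclass(frozen=True)
class DdpcrSimParams:
    """Two-channel ddPCR well: mean copies per partition for each allele."""

    n_partitions: int = 20000
    lambda_K: float = 0.5
    lambda_T: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        if self.lambda_K < 0 or self.lambda_T < 0:
            raise ValueError("per-partition concentrations must be non-negative")


# ---------------------------------------------------------------------------
# closed-form calibration
# ---------------------------------------------------------------------------

def gmax_for_tail_density(
    target_density_pA_per_pF: float,
    kin: KineticsParamSet,
    protocol: VoltageStepProtocol | None = None,
    capacitance_pF: float = DEFAULT_CAPACITANCE_PF,
) -> float:
    """Conductance (nS) giving a requested peak tail density.

    The tail measurement reports the instantaneous current jump on return to
    holding after the most depolarized step, referenced to the fully
    deactivated late-tail level. In the gating model that jump is
    ``g · (m_end − m_inf(Vh)) · h_inf(Vh) · (Vh − E_K)`` with ``m_end`` the
    activation reached by the end of the step; inverting gives g.
    """
    protocol = protocol or VoltageStepProtocol()
    v_top = float(np.max(protocol.step_levels_mV))
    vh = protocol.holding_mV
    m0 = kin.m_inf(vh)
    m_inf_top = kin.m_inf(v_top)
    m_end = m_inf_top + (m0 - m_inf_top) * np.exp(
        -protocol.step_duration_s / kin.tau_act(v_top)
    )
    drive = (m_end - m0) * kin.h_inf(vh) * (vh - kin.E_K_mV)
    if drive == 0:
        raise ValueError("degenerate kinetics: no tail current is generated")
    return target_density_pA_per_pF * capacitance_pF / drive


def _scaled_tau_table(scale: float) -> Dict[float, float]:
    return {v: tau * scale for v, tau in WT_TAU_ACT_TABLE.items()}


def _make_genotypes() -> Dict[str, KineticsParamSet]:
    base = KineticsParamSet(g_max_nS=1.0)
    proto = VoltageStepProtocol()

    def calibrated(label, density, tau_scale, tau_f, tau_s):
        kin = replace(
            base,
            tau_act_table=_scaled_tau_table(tau_scale),
            tau_deact_fast_s=tau_f,
            tau_deact_slow_s=tau_s,
            label=label,
        )
        kin.g_max_nS = gmax_for_tail_density(density, kin, proto)
        return kin

    # tau_act scales: cis lines are 21% (A561T) / 33% (N996I) faster than
    # their trans counterparts at -30 mV; tail densities are the printed
    # maxima (cis == trans within each pair: densities did not differ).
    return {
        "WT": calibrated("WT", 3.3, 1.00, 0.20, 1.00),
        "A561T_cis": calibrated("A561T_cis", 0.8, 0.667 * 0.79, 0.15, 0.70),
        "A561T_trans": calibrated("A561T_trans", 0.8, 0.667, 0.18, 1.10),
        "N996I_cis": calibrated("N996I_cis", 1.9, 0.778 * 0.67, 0.14, 0.80),
        "N996I_trans": calibrated("N996I_trans", 1.9, 0.778, 0.19, 1.20),
    }


#: packaged per-genotype gating parameter sets (see module docstring)
GENOTYPES: Dict[str, KineticsParamSet] = _make_genotypes()
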