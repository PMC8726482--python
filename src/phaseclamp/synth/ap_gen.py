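"""Parametric cardiomyocyte action-potential train synthesis.

Waveforms are built beat by beat from morphological targets (MDP, takeoff
potential, amplitude, upstroke velocity, APD20/50/90) rather than from a
biophysical membrane model: the upstroke is a linear ramp whose slope is the
requested Vmax, repolarization is a monotone (PCHIP) curve pinned to the
requested repolarization levels at the requested durations, and diastole is
either a linear depolarizing ramp from MDP to the takeoff potential
(spontaneous mode) or a rest at MDP until the next stimulus (paced mode).
By construction the matching feature extractor should recover every target
exactly up to sampling resolution, which is what makes parameter-recovery
testing well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from ..params import APShapeParams
from ..trace import SampledTrace


class CaptureInfeasibleError(ValueError):
    """Pacing period too short for 1:1 capture at the requested APD."""


@dataclass
class APTrainTruth:
    """Ground truth emitted with a synthesized train."""

    takeoff_times_s: np.ndarray
    stimulus_times_s: Optional[np.ndarray]
    shape: APShapeParams
    answered: Optional[np.ndarray] = None  # per-stimulus capture mask
    meta: dict = field(default_factory=dict)


def _beat_anchor_curve(shape: APShapeParams):
    """Monotone repolarization interpolator and key beat times (ms from takeoff)."""
    peak = shape.MDP_mV + shape.APA_mV
    vmax_mv_per_ms = shape.Vmax_V_per_s  # V/s == mV/ms
    t_peak = (peak - shape.mDP_mV) / vmax_mv_per_ms
    if t_peak >= shape.APD20_ms:
        raise ValueError("upstroke longer than APD20; raise Vmax or APD20")
    # phase-3 foot: finish the descent from the 90% level to MDP
    t_mdp = shape.APD90_ms + max(20.0, 0.35 * (shape.APD90_ms - shape.APD50_ms))
    anchors_t = np.array([t_peak, shape.APD20_ms, shape.APD50_ms, shape.APD90_ms, t_mdp])
    anchors_v = np.array(
        [
            peak,
            peak - 0.20 * shape.APA_mV,
            peak - 0.50 * shape.APA_mV,
            peak - 0.90 * shape.APA_mV,
            shape.MDP_mV,
        ]
    )
    return PchipInterpolator(anchors_t, anchors_v), t_peak, t_mdp, peak


def _eval_beat(u_ms: np.ndarray, shape: APShapeParams, repol, t_peak: float,
               t_mdp: float, takeoff_mV: float) -> np.ndarray:
    """Evaluate one beat at times ``u_ms`` (ms since takeoff, < t_mdp)."""
    peak = shape.MDP_mV + shape.APA_mV
    v = np.empty_like(u_ms)
    up = u_ms < t_peak
    # linear upstroke at exactly Vmax; takeoff potential may be MDP (paced)
    v[up] = takeoff_mV + (peak - takeoff_mV) * (u_ms[up] / t_peak)
    v[~up] = repol(u_ms[~up])
    return v


def synthesize_ap_train(
    shape: APShapeParams,
    pacing_hz: Optional[float] = None,
    seed: int = 0,
    fs_hz: float = 40_000.0,
    on_capture_loss: str = "raise",
):
    """Synthesize an AP train and its ground truth.

    Parameters
    ----------
    pacing_hz : float or None
        None selects spontaneous mode: the cell depolarizes from MDP to the
        takeoff potential along ``diastolic_slope_mV_per_s``, so the cycle
        length is set by that slope. A frequency selects paced mode with the
        stimulus train at that rate.
    on_capture_loss : {"raise", "skip"}
        When the pacing period cannot accommodate a full AP, either raise
        :class:`CaptureInfeasibleError` or answer every second stimulus
        (2:1 following), emulating loss of 1:1 capture at fast rates.

    Returns
    -------
    (SampledTrace, APTrainTruth)
    """
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / fs_hz
    if pacing_hz is not None:
        # the stimulus initiates the AP from full repolarization, so the
        # upstroke departs from MDP; keep the slope equal to the requested
        # Vmax by building the beat curve with that takeoff
        from dataclasses import replace

        shape_eff = replace(shape, mDP_mV=shape.MDP_mV)
    else:
        shape_eff = shape
    repol, t_peak, t_mdp, _ = _beat_anchor_curve(shape_eff)

    if pacing_hz is None:
        if shape.diastolic_slope_mV_per_s <= 0:
            raise ValueError("spontaneous mode needs a positive diastolic slope")
        diastole_ms = (shape.mDP_mV - shape.MDP_mV) / (
            shape.diastolic_slope_mV_per_s / 1000.0
        )
        period_ms = t_mdp + diastole_ms
        takeoffs = 10.0 + period_ms * np.arange(shape.n_beats)
        stim = None
        answered = None
        takeoff_mV = shape.mDP_mV
    else:
        period_ms = 1000.0 / pacing_hz
        stride = 1
        if period_ms <= t_mdp:
            if on_capture_loss == "raise":
                raise CaptureInfeasibleError(
                    f"pacing period {period_ms:.0f} ms cannot fit an AP "
                    f"lasting {t_mdp:.0f} ms"
                )
            stride = int(np.ceil(t_mdp / period_ms)) + (t_mdp % period_ms == 0)
        stim = 10.0 + period_ms * np.arange(shape.n_beats * stride)
        answered = np.zeros(stim.size, dtype=bool)
        answered[::stride] = True
        takeoffs = stim[answered] + 2.0  # 2 ms latency after the stimulus
        takeoff_mV = shape.MDP_mV  # stimulus initiates from full repolarization

    total_ms = takeoffs[-1] + t_mdp + 100.0
    n = int(round(total_ms / dt_ms))
    t_ms = dt_ms * np.arange(n)
    v = np.full(n, shape.MDP_mV)

    for k, tk in enumerate(takeoffs):
        sel = (t_ms >= tk) & (t_ms < tk + t_mdp)
        v[sel] = _eval_beat(t_ms[sel] - tk, shape, repol, t_peak, t_mdp, takeoff_mV)
        # diastolic interval after this beat
        t_next = takeoffs[k + 1] if k + 1 < len(takeoffs) else total_ms
        dia = (t_ms >= tk + t_mdp) & (t_ms < t_next)
        if pacing_hz is None:
            v[dia] = shape.MDP_mV + (shape.diastolic_slope_mV_per_s / 1000.0) * (
                t_ms[dia] - (tk + t_mdp)
            )
        else:
            v[dia] = shape.MDP_mV
    # diastole before the first beat
    head = t_ms < takeoffs[0]
    v[head] = takeoff_mV if pacing_hz is None else shape.MDP_mV

    if shape.noise_sd_mV > 0:
        v = v + rng.normal(0.0, shape.noise_sd_mV, n)

    trace = SampledTrace(
        t0=0.0, dt=1.0 / fs_hz, values=v, signal_kind="membrane_potential",
        meta={"mode": "spontaneous" if pacing_hz is None else f"paced_{pacing_hz}Hz"},
    )
    truth = APTrainTruth(
        takeoff_times_s=takeoffs / 1000.0,
        stimulus_times_s=None if stim is None else stim / 1000.0,
        shape=shape,
        answered=answered,
        meta={"period_ms": period_ms, "t_mdp_ms": t_mdp},
    )
    return trace, truth
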