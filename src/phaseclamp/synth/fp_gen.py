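"""MEA field-potential synthesis with drug response and arrhythmic events.

Each beat is a sharp biphasic depolarization spike (the Na+-driven component)
followed by a broad repolarization wave whose peak sits exactly one field
potential duration (FPD) after the spike extremum. A Hill-type conductance
block model prolongs the FPD with drug concentration. Three arrhythmia-like
event types can be injected:

* ``abnormal_repol`` — an EAD-like secondary deflection after the
  repolarization wave, at half the repolarization-wave amplitude;
* ``fibrillation`` — spike amplitude collapses below 30% of baseline and the
  inter-beat intervals become irregular (CV > 0.25);
* ``quiescence`` — electrical silence, noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..params import DrugModel, FPShapeParams
from ..trace import SampledTrace

#: morphology constants (ms); narrow spike, broad repolarization wave
SPIKE_SIGMA_MS = 1.5
TWAVE_SIGMA_MS = 25.0
EAD_SIGMA_MS = 30.0
#: fibrillation injection: amplitude scale and interval CV
FIB_AMP_SCALE = 0.18
FIB_INTERVAL_CV = 0.35


@dataclass
class FPTruth:
    """Ground truth emitted with a synthesized FP recording."""

    spike_times_s: np.ndarray
    fpd_ms: float
    event: str
    concentration_nM: float
    shape: FPShapeParams
    meta: dict = field(default_factory=dict)


def _gauss(t_ms: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center_ms) / sigma_ms) ** 2)


def synthesize_fp_recording(
    shape: FPShapeParams,
    drug: Optional[DrugModel] = None,
    concentration_nM: float = 0.0,
    event: str = "none",
    seed: int = 0,
    fs_hz: float = 12_500.0,
    duration_s: Optional[float] = None,
):
    """Synthesize one well's field-potential recording plus ground truth.

    Returns
    -------
    (SampledTrace, FPTruth)
    """
    if concentration_nM < 0:
        raise ValueError("concentration must be non-negative")
    if event not in ("none", "abnormal_repol", "fibrillation", "quiescence"):
        raise ValueError(f"unknown event type {event!r}")
    rng = np.random.default_rng(seed)
    drug = drug or DrugModel()

    fpd_ms = shape.FPD_ms * drug.fpd_prolongation(concentration_nM)
    fpd_ms = min(fpd_ms, 0.9 * shape.beat_period_ms)

    if duration_s is None:
        duration_s = (shape.n_beats + 0.5) * shape.beat_period_ms / 1000.0
    n = int(round(duration_s * fs_hz))
    t_ms = (1000.0 / fs_hz) * np.arange(n)
    sig = np.zeros(n)

    if event == "quiescence":
        spikes = np.empty(0)
    elif event == "fibrillation":
        # standardize the jitter so the realized interval CV hits the target
        z = rng.standard_normal(shape.n_beats)
        z = (z - z.mean()) / z.std(ddof=1)
        intervals = shape.beat_period_ms * (1.0 + FIB_INTERVAL_CV * z)
        intervals = np.clip(intervals, 0.3 * shape.beat_period_ms, None)
        spikes = 200.0 + np.cumsum(intervals) - intervals[0]
        spikes = spikes[spikes < t_ms[-1] - fpd_ms - 100.0]
    else:
        spikes = 200.0 + shape.beat_period_ms * np.arange(shape.n_beats)
        spikes = spikes[spikes < t_ms[-1] - fpd_ms - 100.0]

    amp_scale = FIB_AMP_SCALE if event == "fibrillation" else 1.0
    for s in spikes:
        # biphasic depolarization spike: dominant positive lobe, small
        # trailing negative lobe; extremum at the spike time itself
        sig += amp_scale * shape.spike_amp_uV * (
            _gauss(t_ms, s, SPIKE_SIGMA_MS)
            - 0.45 * _gauss(t_ms, s + 2.5 * SPIKE_SIGMA_MS, 1.6 * SPIKE_SIGMA_MS)
        )
        sig += amp_scale * shape.twave_amp_uV * _gauss(t_ms, s + fpd_ms, TWAVE_SIGMA_MS)
        if event == "abnormal_repol":
            # EAD-like deflection between the repolarization wave and the
            # next beat, at half the repolarization-wave amplitude
            ead_center = s + fpd_ms + 0.45 * (shape.beat_period_ms - fpd_ms)
            sig += 0.5 * shape.twave_amp_uV * _gauss(t_ms, ead_center, EAD_SIGMA_MS)

    if shape.noise_sd_uV > 0:
        sig = sig + rng.normal(0.0, shape.noise_sd_uV, n)

    trace = SampledTrace(
        t0=0.0, dt=1.0 / fs_hz, values=sig, signal_kind="field_potential",
        meta={"event": event, "concentration_nM": concentration_nM},
    )
    truth = FPTruth(
        spike_times_s=spikes / 1000.0,
        fpd_ms=fpd_ms,
        event=event,
        concentration_nM=concentration_nM,
        shape=shape,
    )
    return trace, truth
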