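"""MEA field-potential analysis: beats, FPD, ΔΔFPD, arrhythmia scoring.

Beats are detected as depolarization spikes exceeding an amplitude
threshold; the field-potential duration (FPD) of each beat runs from the
spike extremum to the repolarization-wave peak. Drug dose–response is
summarized as the percent FPD change from baseline corrected for the vehicle
response (ΔΔFPD). Arrhythmia-like events are classified into weighted
categories — none (0), abnormal repolarization / EAD-like (2), fibrillation
(3), quiescence (4) — and a group risk score is the mean of per-well scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trace import SampledTrace

MIN_SPIKE_AMP_UV = 100.0
REFRACTORY_MS = 250.0
#: repolarization-peak search starts this long after the spike
REPOL_BLANK_MS = 60.0

#: weighted arrhythmia categories, in increasing severity
SCORE_MAP = {"none": 0, "abnormal_repol": 2, "fibrillation": 3, "quiescence": 4}
SEVERITY_ORDER = ("none", "abnormal_repol", "fibrillation", "quiescence")

# classifier thresholds quantifying the qualitative event definitions
FIB_AMP_FRACTION = 0.30    # median spike amp below this fraction of baseline
FIB_INTERVAL_CV = 0.25     # and inter-beat interval CV above this
EAD_REL_AMP = 0.25         # secondary deflection vs repolarization-wave amplitude


@dataclass
class FPBeat:
    spike_time_s: float
    spike_amp_uV: float
    repol_peak_time_s: float
    FPD_ms: float

    def __post_init__(self) -> None:
        if self.repol_peak_time_s <= self.spike_time_s or self.FPD_ms <= 0:
            raise ValueError("repolarization peak must follow the spike")


@dataclass
class FPRecordingSummary:
    median_FPD_ms: Optional[float]
    beat_period_ms: Optional[float]
    median_spike_amp_uV: Optional[float]
    n_beats: int


@dataclass(frozen=True)
class ArrhythmiaCall:
    category: str
    score: int

    def __post_init__(self) -> None:
        if SCORE_MAP.get(self.category) != self.score:
            raise ValueError("score must equal the category's fixed weight")


def detect_beats(
    trace: SampledTrace,
    min_amp_uV: float = MIN_SPIKE_AMP_UV,
    refractory_ms: float = REFRACTORY_MS,
) -> List[FPBeat]:
    """Detect beats as depolarization spikes above ``min_amp_uV``.

    The spike time is the extremum of |signal| within each suprathreshold
    burst; the repolarization peak is the maximum between the end of the
    spike blanking period and the next spike (or trace end). Returns an
    empty list on quiescent input.
    """
    if trace.signal_kind != "field_potential":
        raise ValueError("beat detection expects a field-potential trace")
    v = trace.values
    refr = int(round(refractory_ms / 1000.0 / trace.dt))
    peaks, _ = find_peaks(np.abs(v), height=min_amp_uV, distance=max(refr, 1))
    blank = int(round(REPOL_BLANK_MS / 1000.0 / trace.dt))
    # locate the repolarization peak on a lightly smoothed copy (~12 ms
    # moving average): the wave is tens of ms wide, so smoothing removes
    # noise-driven jitter of the argmax without shifting the peak
    width = max(int(round(0.012 / trace.dt)), 1)
    v_smooth = np.convolve(v, np.ones(width) / width, mode="same")
    beats = []
    for k, i in enumerate(peaks):
        j_next = peaks[k + 1] if k + 1 < len(peaks) else len(v)
        lo = min(i + blank, len(v) - 1)
        hi = max(j_next - blank // 2, lo + 1)
        seg = v_smooth[lo:hi]
        if seg.size == 0:
            continue
        i_rep = lo + int(np.argmax(seg))
        fpd_ms = (i_rep - i) * trace.dt * 1000.0
        if fpd_ms <= 0:
            continue
        beats.append(
            FPBeat(
                spike_time_s=trace.t0 + i * trace.dt,
                spike_amp_uV=float(abs(v[i])),
                repol_peak_time_s=trace.t0 + i_rep * trace.dt,
                FPD_ms=float(fpd_ms),
            )
        )
    return beats


def measure_fpd(beats: Sequence[FPBeat]) -> FPRecordingSummary:
    """Median FPD, beat period and spike amplitude over the whole recording."""
    n = len(beats)
    if n == 0:
        return FPRecordingSummary(None, None, None, 0)
    fpd = float(np.median([b.FPD_ms for b in beats]))
    amp = float(np.median([b.spike_amp_uV for b in beats]))
    if n >= 2:
        isi = np.diff([b.spike_time_s for b in beats]) * 1000.0
        period = float(np.median(isi))
    else:
        period = None
    return FPRecordingSummary(
        median_FPD_ms=fpd, beat_period_ms=period, median_spike_amp_uV=amp, n_beats=n
    )


def compute_ddfpd(
    baseline: pd.DataFrame,
    drug: pd.DataFrame,
    vehicle: pd.DataFrame,
) -> pd.DataFrame:
    """Vehicle-corrected percent FPD change per concentration (ΔΔFPD).

    Inputs are tidy tables with columns ``well_id``, ``concentration_nM``
    (absent or NaN in ``baseline``) and ``FPD_ms``. Per well,
    ΔFPD_c = 100·(FPD_c − FPD_baseline)/FPD_baseline; per concentration,
    ΔΔFPD_c = ΔFPD_drug,c − mean(ΔFPD_vehicle,c). Returns one row per drug
    well × concentration with columns ``dfpd_pct`` and ``ddfpd_pct``.
    """
    base = baseline.set_index("well_id")["FPD_ms"]

    def delta(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        missing = set(out["well_id"]) - set(base.index)
        if missing:
            raise ValueError(f"wells without a baseline measurement: {sorted(missing)}")
        b = base.loc[out["well_id"]].to_numpy()
        out["dfpd_pct"] = 100.0 * (out["FPD_ms"].to_numpy() - b) / b
        return out

    d_drug, d_veh = delta(drug), delta(vehicle)
    veh_mean = d_veh.groupby("concentration_nM")["dfpd_pct"].mean()
    conc_mismatch = set(d_drug["concentration_nM"].unique()) - set(veh_mean.index)
    if conc_mismatch:
        raise ValueError(f"no vehicle arm at concentrations {sorted(conc_mismatch)}")
    d_drug = d_drug.copy()
    d_drug["ddfpd_pct"] = (
        d_drug["dfpd_pct"].to_numpy()
        - veh_mean.loc[d_drug["concentration_nM"]].to_numpy()
    )
    return d_drug


def _has_ead(
    trace: SampledTrace, beats: Sequence[FPBeat], rel_amp: float
) -> bool:
    """Secondary post-repolarization deflection ≥ rel_amp × repol amplitude."""
    # moving-average smoothing (~12 ms) so broadband noise does not mimic a
    # deflection; EAD-like waves are tens of ms wide and pass unattenuated
    width = max(int(round(0.012 / trace.dt)), 1)
    kernel = np.ones(width) / width
    v = np.convolve(trace.values, kernel, mode="same")
    gap = int(round(2.5 * REPOL_BLANK_MS / 1000.0 / trace.dt))
    n_flagged = 0
    for k, b in enumerate(beats):
        i_rep = trace.index_at(b.repol_peak_time_s)
        repol_amp = abs(v[i_rep])
        if repol_amp == 0:
            continue
        i_end = (
            trace.index_at(beats[k + 1].spike_time_s) - gap // 2
            if k + 1 < len(beats)
            else len(v)
        )
        seg = v[i_rep + gap: i_end]
        if seg.size < 3:
            continue
        peaks, props = find_peaks(seg, height=rel_amp * repol_amp,
                                  prominence=0.5 * rel_amp * repol_amp)
        if peaks.size:
            n_flagged += 1
    # require the deflection on more than one beat to reject isolated noise
    return n_flagged >= max(2, len(beats) // 6) if beats else False


def classify_arrhythmia(
    trace: SampledTrace,
    beats: Sequence[FPBeat],
    baseline: FPRecordingSummary,
    fib_amp_fraction: float = FIB_AMP_FRACTION,
    fib_interval_cv: float = FIB_INTERVAL_CV,
    ead_rel_amp: float = EAD_REL_AMP,
) -> ArrhythmiaCall:
    """Classify one recording into the weighted arrhythmia categories.

    Precedence quiescence > fibrillation > abnormal repolarization > none:
    quiescence = no detectable beats; fibrillation = median spike amplitude
    below ``fib_amp_fraction`` of baseline together with inter-beat interval
    CV above ``fib_interval_cv``; abnormal repolarization = EAD-like
    secondary deflection of at least ``ead_rel_amp`` of the
    repolarization-wave amplitude before the next beat.
    """
    if baseline is None or baseline.n_beats == 0 or baseline.median_spike_amp_uV is None:
        raise ValueError("a beating baseline summary is required for classification")
    if len(beats) == 0:
        return ArrhythmiaCall("quiescence", SCORE_MAP["quiescence"])
    summ = measure_fpd(beats)
    amp_frac = summ.median_spike_amp_uV / baseline.median_spike_amp_uV
    if len(beats) >= 3:
        isi = np.diff([b.spike_time_s for b in beats])
        cv = float(np.std(isi, ddof=1) / np.mean(isi))
    else:
        cv = 0.0
    if amp_frac < fib_amp_fraction and cv > fib_interval_cv:
        return ArrhythmiaCall("fibrillation", SCORE_MAP["fibrillation"])
    if _has_ead(trace, beats, ead_rel_amp):
        return ArrhythmiaCall("abnormal_repol", SCORE_MAP["abnormal_repol"])
    return ArrhythmiaCall("none", SCORE_MAP["none"])


def most_severe(calls: Sequence[ArrhythmiaCall]) -> ArrhythmiaCall:
    """The most severe category observed across a well's recordings."""
    if not calls:
        raise ValueError("empty call list")
    return max(calls, key=lambda c: SEVERITY_ORDER.index(c.category))


def score_group(calls: Sequence[ArrhythmiaCall]) -> dict:
    """Mean ± SEM of per-well weighted scores."""
    if not calls:
        raise ValueError("empty call list")
    scores = np.array([c.score for c in calls], dtype=float)
    sem = float(np.std(scores, ddof=1) / np.sqrt(scores.size)) if scores.size > 1 else 0.0
    return {"mean_score": float(scores.mean()), "sem": sem, "n_wells": scores.size}
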