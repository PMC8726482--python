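"""Action-potential detection and feature extraction from current clamp.

Upstrokes are detected as threshold crossings of dV/dt with refractory
suppression; each detected AP is then measured for the standard panel:
maximum diastolic potential (MDP), takeoff potential (mDP), amplitude (APA),
maximal upstroke velocity (Vmax), the action-potential durations at 20/50/90%
repolarization, and cycle length. Trains are summarized as mean ± SEM over at
least 10 consecutive beats, and 1:1 stimulus capture is assessed for paced
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .trace import SampledTrace

DVDT_THRESHOLD_V_PER_S = 5.0
REFRACTORY_MS = 100.0
CAPTURE_WINDOW_MS = 150.0
MIN_BEATS_FOR_SUMMARY = 10
#: minimum peak prominence (mV) for an upstroke candidate; APs are ~100 mV
MIN_PEAK_PROMINENCE_MV = 20.0


def _boxcar(v: np.ndarray, width_s: float, dt: float) -> np.ndarray:
    w = max(int(round(width_s / dt)), 1)
    if w == 1:
        return v
    return np.convolve(v, np.ones(w) / w, mode="same")

FEATURES = (
    "APD20_ms", "APD50_ms", "APD90_ms", "MDP_mV", "mDP_mV",
    "APA_mV", "Vmax_V_per_s", "cycle_length_ms",
)


@dataclass
class APEvent:
    """Bookkeeping for one detected action potential."""

    takeoff_time_s: float
    peak_time_s: float
    next_MDP_time_s: float

    def __post_init__(self) -> None:
        if not self.takeoff_time_s < self.peak_time_s < self.next_MDP_time_s:
            raise ValueError("event times must satisfy takeoff < peak < next MDP")


@dataclass
class APFeatureSet:
    APD20_ms: float
    APD50_ms: float
    APD90_ms: float
    MDP_mV: float
    mDP_mV: float
    APA_mV: float
    Vmax_V_per_s: float
    cycle_length_ms: float
    missing: tuple = ()

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in FEATURES}


@dataclass
class APTrainSummary:
    """Per-feature mean ± SEM over the analyzed beats."""

    means: dict
    sems: dict
    n_beats_used: int


def detect_aps(
    trace: SampledTrace,
    dvdt_threshold_V_per_s: float = DVDT_THRESHOLD_V_PER_S,
    refractory_ms: float = REFRACTORY_MS,
    min_prominence_mV: float = MIN_PEAK_PROMINENCE_MV,
) -> List[APEvent]:
    """Detect APs and locate each takeoff at the dV/dt threshold crossing.

    Candidate upstrokes are prominent voltage peaks (≥ ``min_prominence_mV``,
    separated by the refractory period); the takeoff is then found by walking
    back from the peak to the last sample whose (lightly smoothed) forward
    slope is below ``dvdt_threshold_V_per_s``. This two-stage scheme keeps the
    takeoff at sub-sample accuracy while being immune to broadband noise,
    which cannot produce a prominent peak. Returns an empty list on quiescent
    input; a final upstroke without a completed diastole is dropped.
    """
    if trace.signal_kind != "membrane_potential":
        raise ValueError("AP detection expects a membrane-potential trace")
    v = trace.values
    refr = max(int(round(refractory_ms / 1000.0 / trace.dt)), 1)
    peaks, _ = find_peaks(v, prominence=min_prominence_mV, distance=refr)
    if peaks.size == 0:
        return []
    vs = _boxcar(v, 0.0003, trace.dt)
    slope = np.empty_like(vs)
    slope[:-1] = np.diff(vs) / (trace.dt * 1000.0)  # V/s
    slope[-1] = 0.0

    events = []
    for k, i_peak in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        # the upstroke is the last suprathreshold slope run before the peak
        # (the detected peak may sit a little beyond it on a noisy plateau)
        up = np.flatnonzero(slope[lo:i_peak] >= dvdt_threshold_V_per_s)
        if up.size == 0:
            continue
        j = lo + up[-1]
        sub = np.flatnonzero(slope[lo:j] < dvdt_threshold_V_per_s)
        if sub.size == 0:
            continue  # upstroke truncated by the trace start
        i_take = lo + sub[-1] + 1
        if i_take >= i_peak:
            i_take = i_peak - 1
        j_end = peaks[k + 1] if k + 1 < len(peaks) else len(v)
        i_mdp = i_peak + int(np.argmin(vs[i_peak:j_end]))
        if k + 1 >= len(peaks) and i_mdp >= len(v) - 1:
            continue  # truncated final beat: no complete diastole
        events.append(
            APEvent(
                takeoff_time_s=trace.t0 + i_take * trace.dt,
                peak_time_s=trace.t0 + i_peak * trace.dt,
                next_MDP_time_s=trace.t0 + i_mdp * trace.dt,
            )
        )
    return events


def _max_upstroke_V_per_s(v: np.ndarray, i_take: int, i_peak: int, dt: float) -> float:
    """Maximal dV/dt on the upstroke via a Savitzky-Golay derivative.

    A quadratic SG derivative is exact on a linear ramp while averaging
    out broadband noise; the window is capped at half the upstroke length
    so the estimate never mixes in the pre-takeoff or post-peak curvature.
    """
    lo = max(i_take - 2, 0)
    hi = min(i_peak + 3, len(v))
    seg = v[lo:hi]
    if seg.size < 5:
        return float(np.max(np.gradient(seg) / (dt * 1000.0))) if seg.size else np.nan
    win = int(round(0.0015 / dt))
    win = min(win, max((i_peak - i_take) // 2 * 2 + 1, 5), seg.size - (seg.size + 1) % 2)
    if win < 5:
        win = 5
    if win % 2 == 0:
        win -= 1
    deriv = savgol_filter(seg, win, polyorder=2, deriv=1, delta=dt * 1000.0)
    return float(np.max(deriv))


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float) -> Optional[float]:
    """First downward crossing of ``level``, linearly interpolated."""
    below = v <= level
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(t[0])
    frac = (v[i - 1] - level) / (v[i - 1] - v[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extract_ap_features(
    trace: SampledTrace,
    event: APEvent,
    prev_event: Optional[APEvent] = None,
    next_event: Optional[APEvent] = None,
) -> APFeatureSet:
    """Measure the feature panel for one detected AP.

    MDP is the minimum over the diastolic interval preceding the upstroke
    (bounded by the previous event's diastolic minimum when available), mDP
    is the potential at the dV/dt takeoff, APA = peak − MDP, Vmax the
    maximal upstroke dV/dt, and APD_x the time from takeoff to
    repolarization to ``peak − x% · APA``. Cycle length is takeoff-to-takeoff
    when a neighboring event is supplied, else NaN. A repolarization level
    not reached before the next beat leaves that APD as NaN and lists it in
    ``missing``.
    """
    v = trace.values
    t = trace.times
    i_take = trace.index_at(event.takeoff_time_s)
    i_peak = trace.index_at(event.peak_time_s)
    i_next = trace.index_at(event.next_MDP_time_s)
    if not (0 <= i_take < i_peak < i_next < len(v)):
        raise ValueError("event does not lie fully inside the trace")

    # landmarks read from a lightly smoothed copy where the waveform is
    # broad (diastole, repolarization); the peak and takeoff samples are
    # read raw because they are sharp
    v_smooth = _boxcar(v, 0.001, trace.dt)
    i_dia0 = trace.index_at(prev_event.next_MDP_time_s) if prev_event else 0
    mdp = float(np.min(v_smooth[i_dia0:i_take])) if i_take > i_dia0 else float(v[i_take])
    mdp_take = float(v[i_take])
    peak = float(v[i_peak])
    apa = peak - mdp

    vmax = _max_upstroke_V_per_s(v, i_take, i_peak, trace.dt)

    t_take = t[i_take]
    missing = []
    apds = {}
    for pct in (20, 50, 90):
        level = peak - pct / 100.0 * apa
        tc = _crossing_time(t[i_peak:i_next + 1], v_smooth[i_peak:i_next + 1], level)
        if tc is None:
            apds[pct] = np.nan
            missing.append(f"APD{pct}_ms")
        else:
            apds[pct] = (tc - t_take) * 1000.0

    if next_event is not None:
        cl = (next_event.takeoff_time_s - event.takeoff_time_s) * 1000.0
    elif prev_event is not None:
        cl = (event.takeoff_time_s - prev_event.takeoff_time_s) * 1000.0
    else:
        cl = np.nan

    return APFeatureSet(
        APD20_ms=apds[20], APD50_ms=apds[50], APD90_ms=apds[90],
        MDP_mV=mdp, mDP_mV=mdp_take, APA_mV=apa, Vmax_V_per_s=vmax,
        cycle_length_ms=cl, missing=tuple(missing),
    )


def extract_train_features(trace: SampledTrace, events: Sequence[APEvent]) -> pd.DataFrame:
    """Per-AP feature table for a detected train (one row per event)."""
    rows = []
    for k, ev in enumerate(events):
        prev_ev = events[k - 1] if k > 0 else None
        next_ev = events[k + 1] if k + 1 < len(events) else None
        rows.append(extract_ap_features(trace, ev, prev_ev, next_ev).as_dict())
    return pd.DataFrame(rows)


def summarize_train(features: Sequence[APFeatureSet] | pd.DataFrame) -> APTrainSummary:
    """Mean ± SEM per feature over ≥ 10 consecutive APs."""
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(
        [f.as_dict() for f in features]
    )
    n = len(df)
    if n < MIN_BEATS_FOR_SUMMARY:
        raise ValueError(
            f"need at least {MIN_BEATS_FOR_SUMMARY} consecutive APs, got {n}"
        )
    means = df[list(FEATURES)].mean().to_dict()
    sems = (df[list(FEATURES)].std(ddof=1) / np.sqrt(df[list(FEATURES)].notna().sum())).to_dict()
    return APTrainSummary(means=means, sems=sems, n_beats_used=n)


def check_pacing_capture(
    stimulus_times_s: Sequence[float],
    events: Sequence[APEvent],
    capture_window_ms: float = CAPTURE_WINDOW_MS,
    min_fraction: float = 0.95,
) -> dict:
    """Assess 1:1 stimulus capture.

    Captured iff at least ``min_fraction`` of stimuli are answered by exactly
    one AP inside the post-stimulus window and no ectopic APs fall between
    stimuli. Returns ``{"captured": bool, "followed_fraction": float}``.
    """
    stim = np.asarray(stimulus_times_s, dtype=float)
    if stim.size == 0:
        raise ValueError("empty stimulus list")
    if stim.size < 5:
        raise ValueError("capture assessment needs at least 5 stimuli")
    takeoffs = np.asarray([e.takeoff_time_s for e in events])
    win = capture_window_ms / 1000.0
    answered = 0
    matched = np.zeros(takeoffs.size, dtype=bool)
    for s in stim:
        in_win = np.flatnonzero((takeoffs >= s) & (takeoffs <= s + win))
        if in_win.size == 1:
            answered += 1
            matched[in_win[0]] = True
    frac = answered / stim.size
    ectopic = int(np.sum(~matched))
    return {
        "captured": bool(frac >= min_fraction and ectopic == 0),
        "followed_fraction": float(frac),
        "n_ectopic": ectopic,
    }
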