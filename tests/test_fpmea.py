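"""MEA field-potential analysis: beats, FPD, ΔΔFPD, arrhythmia scoring."""

import numpy as np
import pandas as pd
import pytest

from phaseclamp.params import DrugModel, FPShapeParams
from phaseclamp.synth import synthesize_fp_recording
from phaseclamp.trace import SampledTrace
from phaseclamp import fpmea

FS = 4000.0


def test_noise_only_trace_has_no_beats():
    rng = np.random.default_rng(0)
    tr = SampledTrace(0.0, 1 / FS, rng.normal(0, 8.0, 40000), "field_potential")
    assert fpmea.detect_beats(tr) == []


def test_beats_found_at_truth_times():
    """0.8 Hz paced 30 s recording: 24 beats at the generated spike times."""
    shape = FPShapeParams(n_beats=24)
    tr, truth = synthesize_fp_recording(shape, seed=1, fs_hz=FS)
    beats = fpmea.detect_beats(tr)
    assert len(beats) == 24
    det = np.array([b.spike_time_s for b in beats])
    assert np.max(np.abs(det - truth.spike_times_s)) < 2e-3


def test_fpd_and_period_recovery():
    shape = FPShapeParams(FPD_ms=350.0, beat_period_ms=1250.0)
    tr, _ = synthesize_fp_recording(shape, seed=2, fs_hz=FS)
    summ = fpmea.measure_fpd(fpmea.detect_beats(tr))
    assert summ.median_FPD_ms == pytest.approx(350.0, abs=1.0)
    assert summ.beat_period_ms == pytest.approx(1250.0, abs=1.0)


def test_single_beat_boundary():
    beat = fpmea.FPBeat(1.0, 500.0, 1.35, 350.0)
    summ = fpmea.measure_fpd([beat])
    assert summ.median_FPD_ms == 350.0
    assert summ.beat_period_ms is None
    empty = fpmea.measure_fpd([])
    assert empty.n_beats == 0 and empty.median_FPD_ms is None


def test_hill_prolongation_half_at_ic50():
    """At c = IC50 with Hill slope 1 the FPD gains half the maximal effect."""
    drug = DrugModel(IC50_nM=10.0, hill_coeff=1.0, max_fpd_prolongation_frac=0.5)
    assert drug.fpd_prolongation(10.0) == pytest.approx(1.25)
    shape = FPShapeParams(FPD_ms=300.0)
    tr, truth = synthesize_fp_recording(shape, drug, concentration_nM=10.0,
                                        seed=3, fs_hz=FS)
    assert truth.fpd_ms == pytest.approx(375.0)
    summ = fpmea.measure_fpd(fpmea.detect_beats(tr))
    assert summ.median_FPD_ms == pytest.approx(375.0, abs=1.5)


def test_zero_concentration_leaves_fpd_unchanged():
    shape = FPShapeParams(FPD_ms=320.0)
    tr, _ = synthesize_fp_recording(shape, concentration_nM=0.0, seed=4, fs_hz=FS)
    summ = fpmea.measure_fpd(fpmea.detect_beats(tr))
    assert summ.median_FPD_ms == pytest.approx(320.0, abs=1.0)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def _dose_tables(drug_resp, veh_resp, baseline_fpd=300.0):
    conc = [1.0, 10.0, 100.0]
    base = pd.DataFrame({"well_id": ["d1", "v1"], "FPD_ms": [baseline_fpd] * 2})
    drug = pd.DataFrame(
        [{"well_id": "d1", "concentration_nM": c, "FPD_ms": baseline_fpd * f}
         for c, f in zip(conc, drug_resp)]
    )
    veh = pd.DataFrame(
        [{"well_id": "v1", "concentration_nM": c, "FPD_ms": baseline_fpd * f}
         for c, f in zip(conc, veh_resp)]
    )
    return base, drug, veh


def test_ddfpd_zero_when_drug_equals_vehicle():
    base, drug, veh = _dose_tables([1.1, 1.2, 1.3], [1.1, 1.2, 1.3])
    out = fpmea.compute_ddfpd(base, drug, veh)
    assert np.allclose(out["ddfpd_pct"], 0.0)


def test_ddfpd_reproduces_hill_curve_under_flat_vehicle():
    model = DrugModel(IC50_nM=10.0, hill_coeff=1.0, max_fpd_prolongation_frac=0.5)
    conc = [1.0, 10.0, 100.0]
    factors = [model.fpd_prolongation(c) for c in conc]
    base, drug, veh = _dose_tables(factors, [1.0, 1.0, 1.0])
    out = fpmea.compute_ddfpd(base, drug, veh)
    expected = 100.0 * (np.array(factors) - 1.0)
    assert np.allclose(out["ddfpd_pct"], expected, rtol=0.01)


def test_ddfpd_immune_to_uniform_vehicle_drift():
    model = DrugModel()
    conc = [1.0, 10.0, 100.0]
    factors = [model.fpd_prolongation(c) for c in conc]
    base, drug, _ = _dose_tables(factors, [1.0] * 3)
    flat = fpmea.compute_ddfpd(base, drug, _dose_tables(factors, [1.0] * 3)[2])
    # vehicle drifting +5 percentage points shifts both arms' ΔFPD equally
    base2, drug2, veh2 = _dose_tables([f + 0.05 for f in factors], [1.05] * 3)
    drifted = fpmea.compute_ddfpd(base2, drug2, veh2)
    assert np.allclose(drifted["ddfpd_pct"], flat["ddfpd_pct"], atol=1e-9)


def test_ddfpd_requires_baseline():
    base, drug, veh = _dose_tables([1.1] * 3, [1.0] * 3)
    with pytest.raises(ValueError, match="baseline"):
        fpmea.compute_ddfpd(base[base.well_id == "v1"], drug, veh)


# ---------------------------------------------------------------------------
# arrhythmia classification and scoring
# ---------------------------------------------------------------------------

def test_category_calls_on_injected_events(fp_cohort):
    baseline, wells = fp_cohort
    for trace, beats, _ in wells[:4]:
        call = fpmea.classify_arrhythmia(trace, beats, baseline)
        assert call.category == trace.meta["event"]


def test_quiescent_recording_scores_four(fp_cohort):
    baseline, _ = fp_cohort
    tr, _ = synthesize_fp_recording(FPShapeParams(n_beats=12), event="quiescence",
                                    seed=99, fs_hz=FS)
    call = fpmea.classify_arrhythmia(tr, fpmea.detect_beats(tr), baseline)
    assert call == fpmea.ArrhythmiaCall("quiescence", 4)


def test_classifier_accuracy_on_labeled_cohort(fp_cohort):
    """≥ 95% correct calls over 200 labeled synthetic wells."""
    baseline, wells = fp_cohort
    correct = sum(
        fpmea.classify_arrhythmia(tr, beats, baseline).category == label
        for tr, beats, label in wells
    )
    assert correct / len(wells) >= 0.95


def test_classifier_threshold_sensitivity(fp_cohort):
    """±20% on all thresholds changes at most 5% of the cohort's calls."""
    baseline, wells = fp_cohort
    def calls(scale):
        return [
            fpmea.classify_arrhythmia(
                tr, beats, baseline,
                fib_amp_fraction=fpmea.FIB_AMP_FRACTION * scale,
                fib_interval_cv=fpmea.FIB_INTERVAL_CV * scale,
                ead_rel_amp=fpmea.EAD_REL_AMP * scale,
            ).category
            for tr, beats, _ in wells
        ]
    ref = calls(1.0)
    for scale in (0.8, 1.2):
        changed = sum(a != b for a, b in zip(ref, calls(scale)))
        assert changed / len(wells) <= 0.05


def test_classification_requires_baseline():
    tr, _ = synthesize_fp_recording(FPShapeParams(n_beats=3), seed=0, fs_hz=FS)
    with pytest.raises(ValueError, match="baseline"):
        fpmea.classify_arrhythmia(tr, [], fpmea.FPRecordingSummary(None, None, None, 0))


def test_score_weight_map_and_group_mean():
    calls = [fpmea.ArrhythmiaCall(c, s) for c, s in
             [("none", 0), ("none", 0), ("abnormal_repol", 2),
              ("fibrillation", 3), ("quiescence", 4)]]
    res = fpmea.score_group(calls)
    assert res["mean_score"] == pytest.approx(1.8)
    assert res["n_wells"] == 5
    with pytest.raises(ValueError):
        fpmea.score_group([])
    with pytest.raises(ValueError):
        fpmea.ArrhythmiaCall("fibrillation", 2)  # weight map is fixed


def test_severity_precedence():
    calls = [fpmea.ArrhythmiaCall("abnormal_repol", 2),
             fpmea.ArrhythmiaCall("quiescence", 4),
             fpmea.ArrhythmiaCall("none", 0)]
    assert fpmea.most_severe(calls).category == "quiescence"


def test_group_score_matches_mixture_expectation():
    """Simulated cohort with a known category mixture: the mean weighted
    score lands within 2 SEM of the mixture expectation."""
    rng = np.random.default_rng(21)
    categories = ("none", "abnormal_repol", "fibrillation", "quiescence")
    probs = (0.5, 0.2, 0.2, 0.1)
    expected = sum(p * fpmea.SCORE_MAP[c] for c, p in zip(categories, probs))
    draws = rng.choice(len(categories), size=200, p=probs)
    calls = [
        fpmea.ArrhythmiaCall(categories[i], fpmea.SCORE_MAP[categories[i]])
        for i in draws
    ]
    res = fpmea.score_group(calls)
    assert abs(res["mean_score"] - expected) <= 2 * res["sem"]
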