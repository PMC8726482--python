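import numpy as np
import pytest

from phaseclamp.params import (
    CellParams,
    FPShapeParams,
    GENOTYPES,
    VoltageStepProtocol,
)
from phaseclamp.synth import synthesize_fp_recording
from phaseclamp import fpmea


@pytest.fixture(scope="session")
def protocol():
    return VoltageStepProtocol()


@pytest.fixture(scope="session")
def cell():
    return CellParams()


@pytest.fixture(scope="session")
def wt_kinetics():
    return GENOTYPES["WT"]


#: reduced sampling rates used in cohort-style tests; the waveform features
#: of interest (hundreds of ms) remain oversampled by orders of magnitude
FP_COHORT_FS = 4000.0
AP_COHORT_FS = 10_000.0


@pytest.fixture(scope="session")
def fp_cohort():
    """200 labeled synthetic MEA wells (50 per category) plus a baseline.

    Returns (baseline_summary, [(trace, beats, truth_label), ...]).
    """
    shape = FPShapeParams(n_beats=12)
    base_trace, _ = synthesize_fp_recording(shape, seed=10_000, fs_hz=FP_COHORT_FS)
    baseline = fpmea.measure_fpd(fpmea.detect_beats(base_trace))
    wells = []
    categories = ("none", "abnormal_repol", "fibrillation", "quiescence")
    for i in range(200):
        event = categories[i % 4]
        trace, truth = synthesize_fp_recording(
            shape, event=event, seed=20_000 + i, fs_hz=FP_COHORT_FS
        )
        wells.append((trace, fpmea.detect_beats(trace), truth.event))
    return baseline, wells
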