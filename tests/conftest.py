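import numpy as np
import pytest

from ecgpipe import AnalysisConfig, SynthSpec, generate


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def sinus_record():
    """Clean-ish 60 s sinus record at 250 Hz with ground truth."""
    return generate(SynthSpec(duration_s=60.0, mean_hr_bpm=70, seed=7))


@pytest.fixture
def quiet_spec():
    """Noise-free generator spec (all noise amplitudes zero, no DC)."""
    return SynthSpec(
        duration_s=30.0,
        drift_amp_mV=0.0,
        powerline_amp_mV=0.0,
        emg_amp_mV=0.0,
        dc_offset_mV=0.0,
        seed=11,
    )


def match_beats(detected, true, fs, tol_s=0.05):
    """Sensitivity and positive predictivity of detections vs truth."""
    detected = np.asarray(detected)
    true = np.asarray(true)
    tol = int(round(tol_s * fs))
    if true.size == 0 or detected.size == 0:
        return 0.0, 0.0
    sens = np.mean([np.abs(detected - t).min() <= tol for t in true])
    ppv = np.mean([np.abs(true - d).min() <= tol for d in detected])
    return float(sens), float(ppv)
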