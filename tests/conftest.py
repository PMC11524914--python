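import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import erp2ch as e

settings.register_profile(
    "suite", derandomize=True, max_examples=15, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

FS = 250.0


def build_epochs(data, fs=FS, window=(-200.0, 800.0), kind="standard",
                 baseline=(-200.0, 0.0)):
    """EpochSet from an [epochs x time x channels] array."""
    return e.EpochSet(data=np.asarray(data, float), fs=fs,
                      window=window, baseline=baseline, kind=kind)


def sinusoid_epochs(freq, n_epochs, phase_offsets=None, amp=1.0, fs=FS,
                    window=(-200.0, 800.0), phase_ch1=None):
    """Narrowband two-channel epochs: Fp2 lags Fp1 by the given per-epoch
    phase offset."""
    n_t = int(round((window[1] - window[0]) * fs / 1000.0))
    t = (window[0] + np.arange(n_t) * 1000.0 / fs) / 1000.0
    if phase_offsets is None:
        phase_offsets = np.zeros(n_epochs)
    if phase_ch1 is None:
        phase_ch1 = np.zeros(n_epochs)
    data = np.empty((n_epochs, n_t, 2))
    for n in range(n_epochs):
        arg = 2 * np.pi * freq * t + phase_ch1[n]
        data[n, :, 0] = amp * np.cos(arg)
        data[n, :, 1] = amp * np.cos(arg - phase_offsets[n])
    return build_epochs(data, fs=fs, window=window)


@pytest.fixture(scope="session")
def cn_session():
    """One full CN-profile oddball session (schedule, recording, responses)."""
    spec = e.SessionSpec()
    sched = e.generate_schedule(spec, seed=101)
    prof = e.default_profiles()["CN"]
    rec = e.synthesize_recording(sched, prof, spec, seed=102)
    beh = e.simulate_behavior(sched, prof, seed=103)
    return spec, sched, rec, beh


@pytest.fixture(scope="session")
def cn_epochs(cn_session):
    """Preprocessed standard/target epochs of the CN session."""
    spec, sched, rec, _ = cn_session
    filt = e.bandpass_fir(rec)
    out = {}
    for kind in ("standard", "target"):
        ep = e.baseline_correct(e.make_epochs(filt, sched, kind))
        ep, _ = e.reject_artifacts(ep)
        out[kind] = ep
    return out
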