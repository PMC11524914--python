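"""PLV and coherence: analytic identities, estimator calibration against
independent oracles, band features, and boundedness properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
import hypothesis.extra.numpy as hnp
from scipy.special import i0, i1

import erp2ch as e
from erp2ch.connectivity import CoherenceSpectrum, NFFT
from conftest import build_epochs, sinusoid_epochs

BETA = e.BANDS["beta"]


def test_plv_identical_channels_is_one(cn_epochs):
    """Fp2 an exact copy of Fp1 in every epoch: PLV(t) = 1 everywhere."""
    ep = cn_epochs["target"]
    data = ep.data.copy()
    data[:, :, 1] = data[:, :, 0]
    w = e.plv_waveform(build_epochs(data, kind="target"), BETA)
    np.testing.assert_allclose(w.values, 1.0, atol=1e-12)


def test_plv_uniform_phase_offsets_cancel():
    """Offsets {0, pi/2, pi, 3pi/2} across four epochs sum to zero (fourth
    roots of unity)."""
    rng = np.random.default_rng(0)
    base = rng.standard_normal(250)
    y1 = np.sin(2 * np.pi * 20.0 * np.arange(250) / 250.0)
    y2 = np.cos(2 * np.pi * 20.0 * np.arange(250) / 250.0)
    data = np.stack([
        np.stack([base + y1, y1], axis=1),
        np.stack([base + y1, y2], axis=1),
        np.stack([base + y1, -y1], axis=1),
        np.stack([base + y1, -y2], axis=1),
    ])
    w = e.plv_waveform(build_epochs(data), BETA)
    # sign-flipped pairs cancel exactly at every sample
    np.testing.assert_allclose(w.values, 0.0, atol=1e-9)


def test_plv_recovers_von_mises_concentration():
    """kappa=2 phase offsets, N=256: the measured PLV must match both the
    brute-force resultant of the sampled offsets and the analytic
    I1(2)/I0(2) = 0.698."""
    rng = np.random.default_rng(1)
    offsets = rng.vonmises(0.0, 2.0, size=256)
    ep = sinusoid_epochs(20.0, 256, phase_offsets=offsets,
                         phase_ch1=rng.uniform(0, 2 * np.pi, 256))
    w = e.plv_waveform(ep, BETA)
    probe = w.values[np.abs(w.times - 300.0).argmin()]
    oracle = np.abs(np.exp(1j * offsets).mean())
    assert probe == pytest.approx(oracle, abs=0.03)
    assert probe == pytest.approx(i1(2.0) / i0(2.0), abs=0.05)


def test_plv_invariant_to_common_phase_offset():
    rng = np.random.default_rng(2)
    offsets = rng.vonmises(0.0, 3.0, size=32)
    ph1 = rng.uniform(0, 2 * np.pi, 32)
    a = e.plv_waveform(sinusoid_epochs(20.0, 32, offsets, phase_ch1=ph1),
                       BETA)
    b = e.plv_waveform(sinusoid_epochs(20.0, 32, offsets,
                                       phase_ch1=ph1 + 1.234), BETA)
    mid = slice(25, 225)
    np.testing.assert_allclose(a.values[mid], b.values[mid], atol=0.01)


def test_plv_rejects_single_epoch_and_bad_band():
    ep = build_epochs(np.random.default_rng(3).standard_normal((1, 250, 2)))
    with pytest.raises(ValueError):
        e.plv_waveform(ep, BETA)
    ep2 = build_epochs(np.random.default_rng(3).standard_normal((4, 250, 2)))
    with pytest.raises(ValueError):
        e.plv_waveform(ep2, (30.0, 13.0))


def test_plv_features_constants_ties_and_bump():
    times = np.arange(250) * 4.0 - 200.0
    flat = e.PLVWaveform(values=np.full(250, 0.5), times=times,
                         band=BETA, n_epochs=10)
    f = e.plv_features(flat)
    assert f["PLV_max_B"] == 0.5
    assert f["PLV_P200_B"] == f["PLV_P300_B"] == f["PLV_P_B"] == 0.5
    bump = np.maximum(0.2, 0.9 - np.abs(times - 400.0) / 500.0)
    f2 = e.plv_features(e.PLVWaveform(values=bump, times=times, band=BETA,
                                      n_epochs=10))
    assert f2["PLV_time_B"] == 400.0
    two = np.full(250, 0.3)
    two[np.flatnonzero(times == 252.0)[0]] = 0.8
    two[np.flatnonzero(times == 500.0)[0]] = 0.8
    f3 = e.plv_features(e.PLVWaveform(values=two, times=times, band=BETA,
                                      n_epochs=10))
    assert f3["PLV_time_B"] == 252.0          # earliest of equal maxima


# ---------------------------------------------------------------- coherence

def test_coherence_linear_dependence_gives_one():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((8, 250))
    data = np.stack([x, 0.5 * x], axis=2)
    c = e.coherence_spectrum(build_epochs(data))
    good = c.values[1:-1]                     # interior bins carry power
    np.testing.assert_allclose(good, 1.0, atol=1e-9)


def test_coherence_sign_flipped_pair_cancels():
    """Two epochs share Fp1; Fp2 of epoch 2 is the negative of epoch 1:
    the averaged cross-spectrum vanishes, so C(f) = 0 exactly."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal(250)
    y = rng.standard_normal(250)
    data = np.stack([np.stack([x, y], axis=1),
                     np.stack([x, -y], axis=1)])
    c = e.coherence_spectrum(build_epochs(data))
    np.testing.assert_allclose(c.values, 0.0, atol=1e-9)


def test_coherence_white_noise_bias_is_one_over_n():
    """Independent channels, N=64 segments: E[C] ~ 1/N (Welch estimator
    bias), checked against the Monte-Carlo mean over replicates."""
    rng = np.random.default_rng(6)
    means = []
    for _ in range(30):
        data = rng.standard_normal((64, 250, 2))
        c = e.coherence_spectrum(build_epochs(data))
        means.append(c.values[1:-1].mean())
    assert np.mean(means) == pytest.approx(1 / 64, rel=0.2)


def test_coherence_small_instance_matches_direct_dft():
    """8-sample epochs: the pipeline must agree with a naive direct-DFT
    implementation of the Welch-over-epochs estimator to 1e-9."""
    rng = np.random.default_rng(7)
    data = rng.standard_normal((5, 8, 2))
    ep = build_epochs(data, window=(0.0, 32.0), baseline=(0.0, 0.0))
    c = e.coherence_spectrum(ep, post_only=True)

    # oracle: explicit loops, no rfft; periodic Hann taper
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(8) / 8)
    demeaned = data - data.mean(axis=1, keepdims=True)
    n_bins = NFFT // 2 + 1
    wxy = np.zeros(n_bins, complex)
    wxx = np.zeros(n_bins)
    wyy = np.zeros(n_bins)
    for ei in range(5):
        X = np.zeros(n_bins, complex)
        Y = np.zeros(n_bins, complex)
        for k in range(n_bins):
            for n in range(8):
                w = np.exp(-2j * np.pi * k * n / NFFT)
                X[k] += demeaned[ei, n, 0] * win[n] * w
                Y[k] += demeaned[ei, n, 1] * win[n] * w
        wxy += X * np.conj(Y) / 5
        wxx += np.abs(X) ** 2 / 5
        wyy += np.abs(Y) ** 2 / 5
    denom = wxx * wyy
    oracle = np.where(denom > 0, np.abs(wxy) ** 2 / np.maximum(denom, 1e-300),
                      0.0)
    np.testing.assert_allclose(c.values, oracle, atol=1e-9)


def test_coherence_rejects_single_epoch():
    with pytest.raises(ValueError):
        e.coherence_spectrum(build_epochs(np.zeros((1, 250, 2))))


def test_coherence_invariant_under_channel_scaling():
    rng = np.random.default_rng(8)
    data = rng.standard_normal((10, 250, 2))
    scaled = data * np.array([3.7, 0.2])
    a = e.coherence_spectrum(build_epochs(data))
    b = e.coherence_spectrum(build_epochs(scaled))
    np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def _spectrum(values, freqs=None):
    values = np.asarray(values, float)
    if freqs is None:
        freqs = np.fft.rfftfreq(NFFT, d=1 / 250.0)
    return CoherenceSpectrum(values=values, freqs=freqs, n_segments=10)


def test_coh_features_flat_and_rising():
    freqs = np.fft.rfftfreq(NFFT, d=1 / 250.0)
    flat = _spectrum(np.full(freqs.size, 0.6))
    f = e.coh_features(flat)
    for sfx in ("T", "A", "B"):
        assert f[f"COH_mean_{sfx}"] == pytest.approx(0.6)
        assert f[f"COH_std_{sfx}"] == pytest.approx(0.0, abs=1e-12)
    rising = np.zeros(freqs.size)
    m = (freqs >= 13) & (freqs < 30)
    rising[m] = np.linspace(0, 1, m.sum())
    f2 = e.coh_features(_spectrum(rising))
    assert f2["COH_freq_B"] == pytest.approx(freqs[m][-1])
    assert freqs[m][-1] == pytest.approx(30.0, abs=1.0)


def test_coh_features_hand_computed_band():
    # five bins {0.2, 0.4, 0.6, 0.8, 1.0}: mean 0.6, sample SD x100 = 31.62
    freqs = np.array([14.0, 15.0, 16.0, 17.0, 18.0, 40.0])
    values = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 0.0])
    f = e.coh_features(_spectrum(values, freqs), bands={"beta": (13.0, 30.0)},
                       overall=(13.0, 30.0))
    assert f["COH_mean_B"] == pytest.approx(0.6)
    assert f["COH_std_B"] == pytest.approx(31.62, abs=0.01)


def test_coh_features_empty_band_errors():
    freqs = np.array([20.0, 25.0])
    with pytest.raises(ValueError):
        e.coh_features(_spectrum(np.array([0.5, 0.5]), freqs),
                       bands={"theta": (4.0, 8.0)})


@given(hnp.arrays(np.float64, (4, 250, 2),
                  elements=st.floats(-50, 50, allow_nan=False,
                                     allow_infinity=False)))
def test_plv_and_coherence_bounded_on_fuzzed_data(data):
    if np.ptp(data) == 0:
        return
    ep = build_epochs(data)
    w = e.plv_waveform(ep, BETA)
    assert np.all((w.values >= 0) & (w.values <= 1))
    c = e.coherence_spectrum(ep)
    assert np.all((c.values >= 0) & (c.values <= 1))
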