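"""Synthetic oddball generator: schedule composition, determinism, evoked
recovery, coupling monotonicity, behaviour and cohorts."""

import numpy as np
import pytest
from dataclasses import replace

import erp2ch as e
from erp2ch.synth import ComponentSpec, _mean_habituation


@pytest.mark.parametrize("seed", range(10))
def test_schedule_composition_exact_for_all_seeds(seed):
    sched = e.generate_schedule(e.SessionSpec(), seed=seed)
    assert (sched.kinds == "standard").sum() == 256
    assert (sched.kinds == "target").sum() == 64
    # targets never adjacent: at least one standard in between
    pos = np.flatnonzero(sched.kinds == "target")
    assert np.all(np.diff(pos) >= 2)
    # onsets on the lead_in + i*soa grid
    np.testing.assert_allclose(sched.onsets, 1.0 + np.arange(320) * 1.0)


def test_schedule_deterministic_under_seed():
    a = e.generate_schedule(seed=7)
    b = e.generate_schedule(seed=7)
    np.testing.assert_array_equal(a.onsets, b.onsets)
    assert list(a.kinds) == list(b.kinds)
    c = e.generate_schedule(seed=8)
    assert list(a.kinds) != list(c.kinds)


def test_schedule_rejects_impossible_target_count():
    with pytest.raises(ValueError):
        e.generate_schedule(e.SessionSpec(n_standard=10, n_target=40), seed=0)


def _quiet_profile(**kw):
    comps = {kind: {n: ComponentSpec(0.0, c.lat, 0.0)
                    for n, c in d.items()}
             for kind, d in e.GroupProfile().components.items()}
    return replace(e.GroupProfile(), components=comps, noise_scale=0.0,
                   heterogeneity=0.0, amp_heterogeneity=0.0, **kw)


def test_silent_profile_yields_identical_channels():
    sched = e.generate_schedule(e.SessionSpec(n_standard=16, n_target=4),
                                seed=0)
    prof = _quiet_profile(beta_coupling_kappa=1e9)
    rec = e.synthesize_recording(sched, prof,
                                 e.SessionSpec(n_standard=16, n_target=4),
                                 seed=0)
    np.testing.assert_allclose(rec.samples[0], rec.samples[1], atol=1e-9)


def test_noise_free_component_recovery():
    """With zero noise and zero jitter, the averaged epoch must show the
    configured deflection at the configured latency within one sample.

    Oracle: a direct argmin scan over raw epoch slices of the recording —
    independent of the preprocessing/detection code paths."""
    spec = e.SessionSpec(n_standard=32, n_target=8)
    sched = e.generate_schedule(spec, seed=1)
    prof = _quiet_profile()
    prof.components["standard"]["N100"] = ComponentSpec(-4.0, 148.0, 0.0)
    rec = e.synthesize_recording(sched, prof, spec, seed=2)
    onsets = sched.of_kind("standard")
    idx = (onsets * rec.fs).astype(int)
    epochs = np.stack([rec.samples[:, i - 50:i + 200].mean(axis=0)
                       for i in idx])
    avg = epochs.mean(axis=0)
    times = -200 + np.arange(250) * 4.0
    k = int(np.argmin(avg))
    assert abs(times[k] - 148.0) <= 4.0
    # the acquisition filters shave ~25% amplitude; the extremum must stay
    # in that neighbourhood of the configured -4 uV
    assert -4.2 <= avg[k] <= -2.7


def test_beta_plv_monotone_in_kappa():
    """Mean beta-band PLV is non-decreasing in the coupling concentration
    (10-seed means over a kappa sweep)."""
    spec = e.SessionSpec(n_standard=64, n_target=16)
    kappas = [0.0, 1.0, 2.0, 5.0, 20.0]
    means = []
    for kappa in kappas:
        vals = []
        for seed in range(10):
            sched = e.generate_schedule(spec, seed=seed)
            prof = replace(e.GroupProfile(), beta_coupling_kappa=kappa,
                           heterogeneity=0.0, amp_heterogeneity=0.0)
            rec = e.synthesize_recording(sched, prof, spec, seed=100 + seed)
            ep = e.baseline_correct(
                e.make_epochs(e.bandpass_fir(rec), sched, "standard"))
            w = e.plv_waveform(ep, e.BANDS["beta"])
            vals.append(w.values.mean())
        means.append(np.mean(vals))
    assert np.all(np.diff(means) > 0)


def test_kappa_zero_vs_twenty_single_seed(cn_session):
    spec = e.SessionSpec(n_standard=64, n_target=16)
    sched = e.generate_schedule(spec, seed=3)
    plvs = {}
    for kappa in (0.0, 20.0):
        prof = replace(e.GroupProfile(), beta_coupling_kappa=kappa,
                       heterogeneity=0.0, amp_heterogeneity=0.0)
        rec = e.synthesize_recording(sched, prof, spec, seed=4)
        ep = e.make_epochs(e.bandpass_fir(rec), sched, "standard")
        plvs[kappa] = e.plv_waveform(ep, e.BANDS["beta"]).values.mean()
    assert plvs[20.0] > plvs[0.0]


def test_recording_determinism_and_amplitude_bound(cn_session):
    spec, sched, rec, _ = cn_session
    rec2 = e.synthesize_recording(sched, e.default_profiles()["CN"], spec,
                                  seed=102)
    np.testing.assert_array_equal(rec.samples, rec2.samples)
    assert np.abs(rec.samples).max() <= 393.0


def test_clipping_profile_raises():
    spec = e.SessionSpec(n_standard=8, n_target=2)
    sched = e.generate_schedule(spec, seed=0)
    prof = _quiet_profile()
    prof.components["target"]["P300"] = ComponentSpec(900.0, 400.0, 0.0)
    with pytest.raises(ValueError, match="clip"):
        e.synthesize_recording(sched, prof, spec, seed=0)


# ---------------------------------------------------------------- behaviour

def test_behavior_no_misses_no_false_alarms():
    sched = e.generate_schedule(seed=5)
    prof = replace(e.GroupProfile(), miss_rate=0.0, false_alarm_rate=0.0)
    beh = e.simulate_behavior(sched, prof, seed=6)
    assert len(beh) == 64


def test_behavior_deterministic_rt_and_misses():
    sched = e.generate_schedule(seed=5)
    prof = replace(e.GroupProfile(), miss_rate=0.0, false_alarm_rate=0.0,
                   rt_sd=0.0)
    beh = e.simulate_behavior(sched, prof, seed=6)
    rts = (beh.press_times - sched.of_kind("target")) * 1000.0
    np.testing.assert_allclose(rts, 340.0, atol=1e-9)
    prof_miss = replace(prof, miss_rate=1.0)
    assert len(e.simulate_behavior(sched, prof_miss, seed=6)) == 0


def test_behavior_rejects_rt_mean_outside_window():
    sched = e.generate_schedule(seed=5)
    with pytest.raises(ValueError):
        e.simulate_behavior(sched, replace(e.GroupProfile(), rt_mean=50.0),
                            seed=0)


def test_p200_habituation_mean_factor():
    # closed-form mean of h**i over 256 trials
    assert _mean_habituation(1.0) == 1.0
    h = 0.997
    expected = np.mean(h ** np.arange(256))
    assert _mean_habituation(h) == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------------------ cohorts

def test_cohort_counts_and_determinism():
    spec = e.SessionSpec(n_standard=16, n_target=4)
    cohort = e.CohortSpec(n_per_subgroup={s: 2 for s in
                                          ("CN", "SCD", "aMCI", "naMCI")},
                          session=spec, master_seed=9)
    a = e.generate_cohort(cohort)
    b = e.generate_cohort(cohort)
    assert len(a) == 8
    assert [c.participant_id for c, *_ in a] == \
        [c.participant_id for c, *_ in b]
    np.testing.assert_array_equal(a[0][1].samples, b[0][1].samples)
    np.testing.assert_array_equal(a[-1][3].press_times, b[-1][3].press_times)


def test_cohort_cn_beta_plv_exceeds_amci():
    """The CN profile's tighter beta coupling must surface as higher
    measured beta PLV than aMCI in a simulated (small) cohort."""
    cohort = e.CohortSpec(n_per_subgroup={"CN": 6, "aMCI": 6},
                          master_seed=21)
    means = {"CN": [], "aMCI": []}
    for cov, rec, sched, _ in e.iter_cohort(cohort):
        ep = e.baseline_correct(
            e.make_epochs(e.bandpass_fir(rec), sched, "standard"))
        ep = e.random_select(ep, 64, seed=1)
        means[cov.subgroup].append(
            e.plv_waveform(ep, e.BANDS["beta"]).values.mean())
    assert np.mean(means["CN"]) > np.mean(means["aMCI"])
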