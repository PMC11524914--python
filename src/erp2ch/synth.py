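"""Synthetic auditory-oddball EEG sessions.

Generates the study conditions end to end: the stimulus schedule (256
standard + 64 rare target tones at a 4:1 ratio, 1,000 ms onset-to-onset),
a two-channel prefrontal recording with controllable evoked components and
inter-channel beta-band phase coupling, and key-press behaviour — so every
pipeline stage can be exercised and calibrated without cohort data.

Signal model per channel (μV)::

    x(t) = 1/f background (partially shared between channels)
         + beta oscillation, per-epoch phase; Fp1-Fp2 offset ~ von Mises(0, κ)
         + Gaussian-windowed evoked deflections (N100, P200, P300)
    -> emulated device filters (zero-phase Butterworth: band-stop 55-65 Hz,
       high-pass 2.6 Hz, low-pass 43 Hz) -> 15-bit quantization over ±393 μV.

The beta oscillation is laid down in per-stimulus segments covering
[onset−200, onset+800) ms, which tile the session exactly at the default
1,000 ms SOA; the epoch cut downstream therefore sees one coherent
oscillation per trial with an independent inter-channel phase offset,
making the phase-locking value across epochs directly controlled by κ.
A multiplicative post-stimulus gain over 300–500 ms (``beta_erd_gain`` < 1)
produces event-related beta desynchronization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from .io import (EventLog, Recording, ResponseLog, CovariateRecord,
                 INPUT_RANGE_UV, QUANT_STEP_UV, SUBGROUPS)

__all__ = [
    "SessionSpec", "ComponentSpec", "GroupProfile", "CohortSpec",
    "generate_schedule", "synthesize_recording", "simulate_behavior",
    "generate_cohort", "iter_cohort", "default_profiles", "inject_artifacts",
]


@dataclass
class SessionSpec:
    """Oddball paradigm parameters (defaults = the study protocol)."""

    n_standard: int = 256
    n_target: int = 64
    soa: float = 1000.0          # onset-to-onset asynchrony, ms
    stim_duration: float = 50.0  # ms
    fs: float = 250.0            # Hz
    lead_in: float = 1000.0      # pre-task recording, ms

    def __post_init__(self):
        if self.soa < self.stim_duration:
            raise ValueError("SOA shorter than the stimulus itself")
        if self.n_standard < 0 or self.n_target < 0:
            raise ValueError("negative stimulus counts")

    @property
    def n_events(self) -> int:
        return self.n_standard + self.n_target

    @property
    def duration_s(self) -> float:
        """Total session length in seconds (lead-in + one SOA per stimulus)."""
        return (self.lead_in + self.n_events * self.soa) / 1000.0


@dataclass
class ComponentSpec:
    """One evoked component: mean amplitude (μV, signed), mean latency and
    latency jitter SD (ms)."""

    amp: float
    lat: float
    jitter: float = 0.0

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("latency jitter SD must be >= 0")


#: Gaussian half-widths of the evoked shapes, ms.  Chosen so the deflections
#: stay inside their detection windows under latency jitter.
COMPONENT_SIGMA = {"N100": 25.0, "P200": 35.0, "P300": 60.0}


#: single-pass retention of a unit Gaussian deflection through the full
#: linear chain (device filters + 0.1–30 Hz analysis bandpass + baseline
#: correction), measured once per component width.  Configured amplitudes
#: are divided by these so the *measured* averaged-waveform amplitudes land
#: at the desired values.
CHAIN_RETENTION = {"N100": 0.766, "P200": 0.683, "P300": 0.538}

#: averaged-waveform amplitudes (μV) the defaults aim for, per epoch kind —
#: the morphology typical of elderly prefrontal oddball ERPs (dominant N100,
#: clear P200, small standard P300, large target P300)
TARGET_MEASURED_AMP = {
    "standard": {"N100": -3.57, "P200": 3.29, "P300": 3.21},
    "target": {"N100": -4.05, "P200": 6.09, "P300": 7.64},
}
DEFAULT_LATENCY = {
    "standard": {"N100": 147.0, "P200": 245.0, "P300": 435.0},
    "target": {"N100": 144.0, "P200": 251.0, "P300": 400.0},
}
DEFAULT_JITTER = {
    "standard": {"N100": 18.0, "P200": 30.0, "P300": 78.0},
    "target": {"N100": 20.0, "P200": 24.0, "P300": 45.0},
}


def _jitter_smear(name: str, jitter: float) -> float:
    """Amplitude retention of the across-trial average under Gaussian
    latency jitter: a Gaussian bump of SD σ averaged over jittered copies
    widens to sqrt(σ² + jitter²) and its peak shrinks accordingly."""
    sigma = COMPONENT_SIGMA[name]
    return sigma / math.hypot(sigma, jitter)


def _mean_habituation(h: float, n_trials: int = 256) -> float:
    """Mean of h**i over the standard trials (expected P200 scale factor)."""
    if h == 1.0:
        return 1.0
    return (1.0 - h ** n_trials) / (n_trials * (1.0 - h))


def _default_components(p300_target_jitter: float = 45.0,
                        p200_habituation: float = 0.9985):
    """Evoked parameters whose *measured* averaged amplitudes equal
    ``TARGET_MEASURED_AMP`` after filtering, jitter smear and (for the
    standard P200) habituation decay."""
    out = {}
    for kind in ("standard", "target"):
        comps = {}
        for name in ("N100", "P200", "P300"):
            jit = DEFAULT_JITTER[kind][name]
            if kind == "target" and name == "P300":
                jit = p300_target_jitter
            base = TARGET_MEASURED_AMP[kind][name] / (
                CHAIN_RETENTION[name] * _jitter_smear(name, jit))
            if kind == "standard" and name == "P200":
                base /= _mean_habituation(p200_habituation)
            comps[name] = ComponentSpec(base, DEFAULT_LATENCY[kind][name], jit)
        out[kind] = comps
    return out


@dataclass
class GroupProfile:
    """Generative profile of one diagnostic subgroup.

    ``components[kind][name]`` holds the evoked parameters per epoch kind.
    ``beta_coupling_kappa`` is the von Mises concentration of the Fp1–Fp2
    phase difference of the shared beta oscillation (higher = tighter
    coupling = higher PLV/coherence).  ``beta_erd_gain`` multiplies the beta
    amplitude over 300–500 ms post-stimulus (< 1 yields ERD, 1 = no ERD).
    ``p200_habituation`` is a per-trial multiplicative decay of the
    standard-epoch P200 amplitude.  ``shared_noise_frac`` is the fraction of
    1/f background *power* common to the two channels (sets the baseline
    coherence level away from the beta band); ``beta_amp_rel`` scales the
    beta oscillation amplitude relative to ``noise_scale``.
    """

    components: dict = field(default_factory=_default_components)
    beta_coupling_kappa: float = 2.5
    beta_erd_gain: float = 0.7
    noise_scale: float = 5.0        # μV RMS of the 1/f background
    beta_amp_rel: float = 0.9
    shared_noise_frac: float = 0.72
    rt_mean: float = 340.0          # ms
    rt_sd: float = 75.0             # ms
    miss_rate: float = 0.02
    false_alarm_rate: float = 0.004
    p200_habituation: float = 0.9985
    #: per-participant lognormal scatter (sigma of log) applied to kappa,
    #: rt_sd and the target P300 latency jitter when drawing a cohort, so
    #: group statistics face realistic between-subject variance
    heterogeneity: float = 0.15
    #: per-participant lognormal scatter of a global evoked-amplitude gain
    #: (elderly ERP amplitudes vary by tens of percent across individuals;
    #: without this, negligible waveform-shape couplings between groups
    #: would read as significant at cohort scale)
    amp_heterogeneity: float = 0.35

    def __post_init__(self):
        if self.beta_coupling_kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (0 <= self.miss_rate <= 1 and 0 <= self.false_alarm_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.beta_erd_gain <= 0:
            raise ValueError("beta_erd_gain must be positive")
        if not (0 <= self.shared_noise_frac <= 1):
            raise ValueError("shared_noise_frac must lie in [0, 1]")


def default_profiles() -> dict:
    """Default per-subgroup profiles.

    These are *synthetic* profiles, not estimates: they encode the
    qualitative group structure reported for this paradigm — beta coupling
    ordered CN > SCD > naMCI > aMCI, no beta ERD in the MCI subgroups,
    higher target P300 latency jitter and response-time variability in MCI
    (worst behaviour in naMCI), and faster standard-trial P200 habituation
    in MCI.  Evoked amplitudes and mean latencies are identical across
    subgroups, so plain component features carry no group signal.
    """
    base = GroupProfile()
    out = {}
    for sub, kappa, erd, t_jit, rt_sd, miss, fa, hab in [
        ("CN",    2.10, 0.70, 42.0, 68.0, 0.018, 0.006, 0.9990),
        ("SCD",   1.95, 0.70, 46.0, 76.0, 0.024, 0.008, 0.9988),
        ("aMCI",  1.45, 1.00, 56.0, 84.0, 0.028, 0.009, 0.9970),
        ("naMCI", 1.65, 1.00, 53.0, 90.0, 0.038, 0.012, 0.9975),
    ]:
        comps = _default_components(p300_target_jitter=t_jit,
                                    p200_habituation=hab)
        out[sub] = replace(base, components=comps, beta_coupling_kappa=kappa,
                           beta_erd_gain=erd, rt_sd=rt_sd, miss_rate=miss,
                           false_alarm_rate=fa, p200_habituation=hab)
    return out


@dataclass
class CohortSpec:
    """A synthetic cohort: participants per subgroup plus their profiles."""

    n_per_subgroup: dict = field(
        default_factory=lambda: {s: 2 for s in SUBGROUPS})
    profiles: dict = field(default_factory=default_profiles)
    session: SessionSpec = field(default_factory=SessionSpec)
    master_seed: int = 0


# demographics used when drawing covariates, loosely matched to an elderly
# memory-clinic cohort: (age mean, age sd, male fraction, edu mean, edu sd)
DEMOGRAPHICS = {
    "CN":    (72.3, 6.2, 0.57, 11.8, 4.6),
    "SCD":   (71.3, 6.2, 0.45, 12.1, 4.5),
    "aMCI":  (74.3, 6.8, 0.65, 12.2, 4.7),
    "naMCI": (73.1, 6.4, 0.52, 12.7, 4.7),
}


# --------------------------------------------------------------------------
# Schedule
# --------------------------------------------------------------------------

def generate_schedule(spec: SessionSpec = SessionSpec(), seed: int = 0) -> EventLog:
    """Draw a stimulus schedule: onsets at ``lead_in + i*soa``; target
    positions uniform over all position subsets with no two targets adjacent
    (at least one standard between consecutive targets).
    """
    n = spec.n_events
    k = spec.n_target
    if k > (n + 1) // 2:
        raise ValueError("too many targets for the non-adjacency constraint")
    rng = np.random.default_rng(seed)
    # stars-and-bars bijection: choosing k of n-k+1 slots and spreading them
    # out yields a uniform draw over all k-subsets with pairwise gaps >= 2
    slots = np.sort(rng.choice(n - k + 1, size=k, replace=False))
    target_pos = slots + np.arange(k)
    kinds = np.array(["standard"] * n, dtype=object)
    kinds[target_pos] = "target"
    onsets = (spec.lead_in + np.arange(n) * spec.soa) / 1000.0
    return EventLog(onsets=onsets, kinds=kinds,
                    stimulus_duration=spec.stim_duration)


# --------------------------------------------------------------------------
# Recording synthesis
# --------------------------------------------------------------------------

def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f power spectrum (spectrally shaped white)."""
    n_bins = n // 2 + 1
    spec = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(n_bins)
    amp[1:] = 1.0 / np.sqrt(f[1:])          # power ~ 1/f
    x = np.fft.irfft(spec * amp, n=n)
    return x / x.std()


@lru_cache(maxsize=4)
def _device_filter_taps(fs: float) -> np.ndarray:
    """Zero-phase emulation of the acquisition filters (2nd-order 55–65 Hz
    band-stop, 1st-order 2.6 Hz high-pass, 8th-order 43 Hz low-pass
    Butterworth): a linear-phase FIR matched to the cascade's single-pass
    magnitude response.  Matching the magnitude while discarding the phase
    keeps the evoked latencies where they were configured."""
    sections = [signal.butter(1, 2.6, "highpass", fs=fs, output="sos"),
                signal.butter(8, 43.0, "lowpass", fs=fs, output="sos")]
    if fs / 2 > 65.0:
        sections.insert(0, signal.butter(2, [55.0, 65.0], "bandstop",
                                         fs=fs, output="sos"))
    sos = np.vstack(sections)
    freqs = np.linspace(0, fs / 2, 513)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    numtaps = int(2 * fs) + 1
    return signal.firwin2(numtaps, freqs, np.abs(h), fs=fs)


def synthesize_recording(schedule: EventLog, profile: GroupProfile,
                         spec: SessionSpec = SessionSpec(),
                         seed: int = 0) -> Recording:
    """Synthesize the two-channel recording for one session.

    Applied in order: 1/f background (partially shared across channels),
    the coupled beta oscillation, evoked components, the emulated device
    filters (zero-phase so configured latencies are preserved), and 15-bit
    amplitude quantization.  Raises if the composite signal would clip the
    ±393 μV input range.
    """
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    last_needed = (schedule.onsets[-1] + 0.8) * fs
    if last_needed > n:
        n = int(np.ceil(last_needed)) + 1
    rng = np.random.default_rng(seed)
    t_axis = np.arange(n) / fs

    x = np.zeros((2, n))
    if profile.noise_scale > 0:
        shared = _one_over_f_noise(n, fs, rng)
        own = [_one_over_f_noise(n, fs, rng) for _ in range(2)]
        c = profile.shared_noise_frac
        for ch in range(2):
            x[ch] += profile.noise_scale * (math.sqrt(c) * shared
                                            + math.sqrt(1 - c) * own[ch])

    # ---- beta oscillation, per-stimulus segments ----------------------
    beta_amp = profile.beta_amp_rel * profile.noise_scale
    if beta_amp > 0:
        kappa = profile.beta_coupling_kappa
        seg_pre, seg_post = 0.2, 0.8      # s, tiles the default SOA exactly
        for onset in schedule.onsets:
            i0 = int(round((onset - seg_pre) * fs))
            i1 = int(round((onset + seg_post) * fs))
            i0c = max(i0, 0)
            seg_t = t_axis[i0c:i1] - onset
            f_beta = rng.uniform(16.0, 22.0)
            psi = rng.uniform(0, 2 * np.pi)
            delta = 0.0 if kappa > 1e6 else rng.vonmises(0.0, kappa)
            env = np.full(seg_t.size, beta_amp)
            if profile.beta_erd_gain != 1.0:
                env *= _erd_envelope(seg_t, profile.beta_erd_gain)
            phase = 2 * np.pi * f_beta * seg_t + psi
            x[0, i0c:i1] += env * np.cos(phase)
            x[1, i0c:i1] += env * np.cos(phase - delta)

    # ---- evoked components -------------------------------------------
    std_counter = 0
    for onset, kind in zip(schedule.onsets, schedule.kinds):
        for name, comp in profile.components[kind].items():
            amp = comp.amp
            if kind == "standard" and name == "P200":
                amp *= profile.p200_habituation ** std_counter
            lat = comp.lat + (rng.standard_normal() * comp.jitter
                              if comp.jitter > 0 else 0.0)
            sigma = COMPONENT_SIGMA[name] / 1000.0
            t_peak = onset + lat / 1000.0
            i0 = max(int((t_peak - 4 * sigma) * fs), 0)
            i1 = min(int((t_peak + 4 * sigma) * fs) + 1, n)
            tt = t_axis[i0:i1] - t_peak
            bump = amp * np.exp(-tt**2 / (2 * sigma**2))
            x[0, i0:i1] += bump
            x[1, i0:i1] += bump
        if kind == "standard":
            std_counter += 1

    # ---- device filter emulation + quantization ----------------------
    taps = _device_filter_taps(fs)
    x = np.stack([signal.fftconvolve(ch, taps, mode="same") for ch in x])
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > INPUT_RANGE_UV:
        raise ValueError(f"synthesized signal clips the ±{INPUT_RANGE_UV:g} μV "
                         f"input range (peak {peak:.1f} μV)")
    x = np.round(x / QUANT_STEP_UV) * QUANT_STEP_UV
    return Recording(samples=x, fs=fs)


def _erd_envelope(seg_t: np.ndarray, gain: float) -> np.ndarray:
    """Multiplicative beta envelope: ``gain`` over 300–500 ms post-stimulus
    with 50 ms raised-cosine ramps (avoids broadband clicks)."""
    env = np.ones_like(seg_t)
    ramp = 0.05
    lo, hi = 0.3, 0.5
    env[(seg_t >= lo + ramp) & (seg_t < hi - ramp)] = gain
    for edge, rising in ((lo, True), (hi - ramp, False)):
        m = (seg_t >= edge) & (seg_t < edge + ramp)
        ph = (seg_t[m] - edge) / ramp                 # 0..1 across the ramp
        s = 0.5 - 0.5 * np.cos(np.pi * ph)            # smoothstep 0..1
        env[m] = 1 + (gain - 1) * (s if rising else (1 - s))
    return env


# --------------------------------------------------------------------------
# Behaviour
# --------------------------------------------------------------------------

def simulate_behavior(schedule: EventLog, profile: GroupProfile,
                      seed: int = 0, soa: float = 1000.0) -> ResponseLog:
    """Simulate key presses: each target is answered with probability
    ``1 - miss_rate`` at onset + RT, RT ~ Normal(rt_mean, rt_sd) truncated
    to (100, soa) ms; each standard draws a false alarm with probability
    ``false_alarm_rate``."""
    if not (100.0 < profile.rt_mean < soa):
        raise ValueError("rt_mean must lie inside the (100, soa) ms window")
    rng = np.random.default_rng(seed)
    presses = []
    for onset, kind in zip(schedule.onsets, schedule.kinds):
        if kind == "target":
            if rng.random() < profile.miss_rate:
                continue
            rt = _trunc_normal(rng, profile.rt_mean, profile.rt_sd, 100.0, soa)
        else:
            if rng.random() >= profile.false_alarm_rate:
                continue
            rt = _trunc_normal(rng, profile.rt_mean, max(profile.rt_sd, 1.0),
                               100.0, soa)
        presses.append(onset + rt / 1000.0)
    return ResponseLog(press_times=np.sort(np.asarray(presses)))


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return mean
    for _ in range(1000):
        v = mean + sd * rng.standard_normal()
        if lo < v < hi:
            return v
    return float(np.clip(mean, lo + 1e-9, hi - 1e-9))


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def _draw_covariates(sub: str, idx: int, rng) -> CovariateRecord:
    mean_age, sd_age, male_frac, mean_edu, sd_edu = DEMOGRAPHICS[sub]
    age = float(np.clip(mean_age + sd_age * rng.standard_normal(), 54, 90))
    edu = float(np.clip(mean_edu + sd_edu * rng.standard_normal(), 0, 22))
    sex = "M" if rng.random() < male_frac else "F"
    return CovariateRecord(participant_id=f"{sub}-{idx:03d}", age=age,
                           sex=sex, education=edu, subgroup=sub)


def iter_cohort(cohort: CohortSpec):
    """Yield ``(CovariateRecord, Recording, EventLog, ResponseLog)`` per
    participant.  Fully deterministic under the master seed: every
    participant gets an independent seed stream spawned from it."""
    order = [s for s in SUBGROUPS if cohort.n_per_subgroup.get(s, 0) > 0]
    total = sum(cohort.n_per_subgroup.get(s, 0) for s in order)
    children = np.random.SeedSequence(cohort.master_seed).spawn(total)
    i = 0
    for sub in order:
        profile = cohort.profiles[sub]
        for idx in range(cohort.n_per_subgroup[sub]):
            ss = children[i]
            i += 1
            s_cov, s_sched, s_rec, s_beh, s_het = ss.spawn(5)
            cov = _draw_covariates(sub, idx, np.random.default_rng(s_cov))
            pprof = _individualize(profile, np.random.default_rng(s_het))
            sched = generate_schedule(cohort.session,
                                      seed=np.random.default_rng(s_sched))
            rec = synthesize_recording(sched, pprof, cohort.session,
                                       seed=np.random.default_rng(s_rec))
            beh = simulate_behavior(sched, pprof,
                                    seed=np.random.default_rng(s_beh),
                                    soa=cohort.session.soa)
            yield cov, rec, sched, beh


def _individualize(profile: GroupProfile, rng) -> GroupProfile:
    """Participant-level profile: lognormal scatter on the coupling
    concentration, RT variability and target P300 latency jitter."""
    h = profile.heterogeneity
    ha = profile.amp_heterogeneity
    if h <= 0 and ha <= 0:
        return profile
    draw = lambda s: float(np.exp(s * rng.standard_normal()))
    gain = draw(ha)
    comps = {kind: {name: replace(c, amp=c.amp * gain)
                    for name, c in d.items()}
             for kind, d in profile.components.items()}
    tp = comps["target"]["P300"]
    comps["target"]["P300"] = replace(tp, jitter=tp.jitter * draw(h))
    return replace(profile, components=comps,
                   beta_coupling_kappa=profile.beta_coupling_kappa * draw(h),
                   rt_sd=profile.rt_sd * draw(h))


def generate_cohort(cohort: CohortSpec) -> list:
    return list(iter_cohort(cohort))


# --------------------------------------------------------------------------
# Artifact injection (to exercise amplitude-based rejection)
# --------------------------------------------------------------------------

def inject_artifacts(rec: Recording, events: EventLog, epoch_indices,
                     amplitude: float = 150.0, seed: int = 0) -> Recording:
    """Return a copy of ``rec`` with a large transient spike inside each of
    the given epochs (both channels), to exercise artifact rejection."""
    rng = np.random.default_rng(seed)
    x = rec.samples.copy()
    for i in epoch_indices:
        onset = events.onsets[i]
        j = int((onset + rng.uniform(0.0, 0.6)) * rec.fs)
        width = int(0.02 * rec.fs) + 1
        x[:, j:j + width] += amplitude
    return Recording(samples=x, fs=rec.fs, channel_labels=rec.channel_labels,
                     start_time=rec.start_time)
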