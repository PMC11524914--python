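"""Time-frequency analysis: ERSP and ITC maps with permutation
significance against the pre-stimulus baseline, and time-trial maps.

The short-time transform is a sliding 64-sample Hann-tapered FFT with a
hop of one sample (bins at k·fs/64 ≈ 3.9 Hz at 250 Hz).  ERSP is the
trial-averaged power expressed as ``10·log10(P(f,t) / P̄_baseline(f))``
dB — positive values are event-related synchronization (ERS), negative
event-related desynchronization (ERD).  ITC is the magnitude of the
trial-averaged unit phasor, in [0, 1].  Significance masks come from
resampling baseline time bins with replacement per trial and recomputing
the statistic (pointwise two-sided p, no cluster correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import rfftfreq

from .io import EpochSet

__all__ = ["TFMap", "TrialTimeMap", "stft_epochs", "ersp", "itc",
           "permutation_baseline_test", "time_trial_map"]

WIN = 64                     # STFT window, samples
DISPLAY_BAND = (2.0, 30.0)   # analysis crop, Hz


@dataclass
class TFMap:
    values: np.ndarray          # [frequency x time]
    freqs: np.ndarray           # Hz
    times: np.ndarray           # ms (frame centers)
    kind: str                   # "ersp_dB" | "itc"
    n_trials: int
    mask: np.ndarray | None = None      # True where permutation p < alpha

    def crop(self, lo: float = DISPLAY_BAND[0], hi: float = DISPLAY_BAND[1]):
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return TFMap(values=self.values[m], freqs=self.freqs[m],
                     times=self.times, kind=self.kind, n_trials=self.n_trials,
                     mask=None if self.mask is None else self.mask[m])


@dataclass
class TrialTimeMap:
    """Epoch-by-time image of the two-channel mean voltage, smoothed along
    the trial axis."""

    values: np.ndarray          # [smoothed epoch x time], μV
    times: np.ndarray           # ms
    kind: str
    smooth: int


@dataclass
class STFTSpectra:
    """Complex spectra per trial/frequency/frame, channel-resolved:
    ``coeffs[trial, channel, frequency, frame]``."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray           # ms, frame centers
    baseline: tuple

    @property
    def power(self) -> np.ndarray:
        """Channel-averaged power, [trial x frequency x frame]."""
        return (np.abs(self.coeffs) ** 2).mean(axis=1)

    @property
    def baseline_frames(self) -> np.ndarray:
        return (self.times >= self.baseline[0]) & (self.times < self.baseline[1])


def stft_epochs(ep: EpochSet, win: int = WIN, taper: str = "hann") -> STFTSpectra:
    """Sliding-window FFT of every epoch (hop = 1 sample)."""
    if ep.n_times < win:
        raise ValueError(f"epoch ({ep.n_times} samples) shorter than the "
                         f"{win}-sample analysis window")
    w = signal.get_window(taper, win)
    frames = np.lib.stride_tricks.sliding_window_view(ep.data, win, axis=1)
    # frames: [trial, frame, channel, win] -> taper + FFT over the last axis
    coeffs = np.fft.rfft(frames * w, axis=-1)
    coeffs = coeffs.transpose(0, 2, 3, 1)       # trial, channel, freq, frame
    freqs = rfftfreq(win, d=1.0 / ep.fs)
    n_frames = ep.n_times - win + 1
    centers = ep.times[0] + (np.arange(n_frames) + (win - 1) / 2.0) \
        * 1000.0 / ep.fs
    return STFTSpectra(coeffs=coeffs, freqs=freqs, times=centers,
                       baseline=ep.baseline)


def ersp(spectra: STFTSpectra, baseline: tuple | None = None) -> TFMap:
    """Event-related spectral perturbation in dB relative to the mean
    baseline power per frequency."""
    base = spectra.baseline if baseline is None else tuple(baseline)
    p = spectra.power.mean(axis=0)                      # freq x frame
    bmask = (spectra.times >= base[0]) & (spectra.times < base[1])
    if not bmask.any():
        raise ValueError("no STFT frames inside the baseline window")
    ref = p[:, bmask].mean(axis=1, keepdims=True)
    if np.any(ref <= 0):
        raise ValueError("zero baseline power; ERSP undefined")
    with np.errstate(divide="ignore"):       # silent bins -> -inf dB
        values = 10.0 * np.log10(p / ref)
    return TFMap(values=values, freqs=spectra.freqs,
                 times=spectra.times, kind="ersp_dB",
                 n_trials=spectra.coeffs.shape[0])


def itc(spectra: STFTSpectra) -> TFMap:
    """Inter-trial coherence: |trial mean of unit phasors|, averaged over
    the two channels."""
    if spectra.coeffs.shape[0] < 2:
        raise ValueError("ITC needs at least 2 trials")
    c = spectra.coeffs
    mag = np.abs(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(mag > 0, c / mag, 0.0)
    val = np.abs(phasors.mean(axis=0)).mean(axis=0)     # freq x frame
    return TFMap(values=np.clip(val, 0.0, 1.0), freqs=spectra.freqs,
                 times=spectra.times, kind="itc",
                 n_trials=spectra.coeffs.shape[0])


def permutation_baseline_test(spectra: STFTSpectra, tfmap: TFMap,
                              n_perm: int = 200, alpha: float = 0.01,
                              seed: int = 0) -> np.ndarray:
    """Pointwise two-sided permutation mask against the baseline.

    Null distribution: per surrogate, trials are bootstrapped with
    replacement and one baseline frame is resampled per drawn trial; the
    map statistic — baseline-referenced dB power or ITC — is recomputed
    from those draws, giving a per-frequency null sample.  (Resampling
    frames alone would freeze the between-trial variance component and
    make the null spuriously narrow, because neighbouring baseline frames
    overlap almost completely at hop 1.)  ``p = (1 + #{null at least as
    extreme}) / (1 + n_perm)``, two-sided pointwise; mask = ``p < alpha``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    bidx = np.flatnonzero(spectra.baseline_frames)
    if bidx.size < 2:
        raise ValueError("baseline too short to resample")
    rng = np.random.default_rng(seed)
    n_trials = spectra.coeffs.shape[0]
    null = np.empty((n_perm, spectra.freqs.size))
    frame_draws = rng.choice(bidx, size=(n_perm, n_trials))
    trial_draws = rng.integers(0, n_trials, size=(n_perm, n_trials))
    if tfmap.kind == "ersp_dB":
        power = spectra.power                            # trial, freq, frame
        # each surrogate gets its own bootstrapped dB reference, so the
        # null carries the sampling error of the baseline anchor as well
        # (otherwise rows whose baseline happened to be low light up)
        base_mean = power[:, :, bidx].mean(axis=2)       # trial x freq
        ref_draws = rng.integers(0, n_trials, size=(n_perm, n_trials))
        for k in range(n_perm):
            p = power[trial_draws[k], :, frame_draws[k]].mean(axis=0)
            ref_k = base_mean[ref_draws[k]].mean(axis=0)
            null[k] = 10.0 * np.log10(p / ref_k)
    elif tfmap.kind == "itc":
        c = spectra.coeffs
        mag = np.abs(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            phasors = np.where(mag > 0, c / mag, 0.0)
        for k in range(n_perm):
            ph = phasors[trial_draws[k], :, :, frame_draws[k]]
            null[k] = np.abs(ph.mean(axis=0)).mean(axis=0)
    else:
        raise ValueError(f"unknown map kind {tfmap.kind!r}")
    hi = (null[:, :, None] >= tfmap.values[None, :, :]).sum(axis=0)
    lo = (null[:, :, None] <= tfmap.values[None, :, :]).sum(axis=0)
    p = 2.0 * (1 + np.minimum(hi, lo)) / (1 + n_perm)
    return np.minimum(p, 1.0) < alpha


def time_trial_map(ep: EpochSet, smooth: int = 10) -> TrialTimeMap:
    """Two-channel mean trace per epoch in presentation order, smoothed by
    a ``smooth``-epoch boxcar along the trial axis (valid convolution:
    ``n − smooth + 1`` rows)."""
    if smooth < 1:
        raise ValueError("smoothing window must be >= 1")
    if ep.n_epochs < smooth:
        raise ValueError("fewer epochs than the smoothing window")
    order = np.argsort(ep.epoch_event_index)
    traces = ep.channel_mean()[order]
    if smooth == 1:
        sm = traces
    else:
        kernel = np.ones(smooth) / smooth
        sm = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="valid"), 0, traces)
    return TrialTimeMap(values=sm, times=ep.times, kind=ep.kind, smooth=smooth)
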