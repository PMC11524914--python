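"""Inter-channel phase synchronization: PLV over time, coherence over
frequency, and their band-wise summary features.

Phase locking value (per time sample, across epochs)::

    PLV(t) = (1/N) | sum_n exp(j * theta(t, n)) |

where ``theta(t, n)`` is the Fp1−Fp2 instantaneous phase difference of
epoch ``n`` after band-pass filtering and the Hilbert transform, and ``N``
the number of epochs.  1 = perfect phase locking, 0 = none.

Magnitude-squared coherence (per frequency bin)::

    C_xy(f) = |W_xy(f)|^2 / (W_xx(f) * W_yy(f))

with cross- and auto-spectral densities averaged Welch-style over epochs:
each epoch's post-stimulus span is one Hann-tapered segment (no
within-epoch subsegmentation — epochs are only 250 samples long), FFT
length 256, giving ~0.98 Hz bins at 250 Hz.

Edge handling: band-pass + Hilbert run on epochs padded with 200 ms of
mirrored samples on each side; the pad is discarded, which keeps the
boundary phase bias out of the epoch proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.fft import irfft, rfft, rfftfreq

from .io import BANDS, EpochSet

__all__ = ["PLVWaveform", "CoherenceSpectrum", "ConnectivityFeatures",
           "plv_waveform", "plv_features", "coherence_spectrum",
           "coh_features", "band_phases"]

PAD_MS = 200.0          # mirror padding for filtering + Hilbert
NFFT = 256              # Welch FFT length (next power of two above 250)


@dataclass
class PLVWaveform:
    values: np.ndarray           # PLV(t), in [0, 1]
    times: np.ndarray            # ms relative to stimulus onset
    band: tuple
    n_epochs: int

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("PLV out of [0, 1]")


@dataclass
class CoherenceSpectrum:
    values: np.ndarray           # C_xy(f), in [0, 1]
    freqs: np.ndarray            # Hz, 0..fs/2
    n_segments: int

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("coherence out of [0, 1]")


@dataclass
class ConnectivityFeatures:
    """Band summary features; keys like ``PLV_max_B`` / ``COH_mean_A`` plus
    all-band ``COH_mean`` / ``COH_std``."""

    values: dict = field(default_factory=dict)

    def update(self, other: dict):
        self.values.update(other)


@lru_cache(maxsize=16)
def _band_taps(fs: float, lo: float, hi: float) -> np.ndarray:
    # Hamming FIR; transition width trades sharpness against epoch length
    trans = max(2.0, 0.25 * (hi - lo))
    numtaps = int(round(3.3 * fs / trans))
    numtaps = min(numtaps | 1, 251)
    return signal.firwin(numtaps, [lo, hi], pass_zero=False,
                         window="hamming", fs=fs)


def band_phases(ep: EpochSet, band: tuple) -> np.ndarray:
    """Instantaneous phase per epoch/time/channel for the given band,
    shape (epochs, times, 2).  Mirror-padded before filtering + Hilbert;
    the pad is discarded."""
    lo, hi = band
    if not (0 < lo < hi < ep.fs / 2):
        raise ValueError("band must lie inside (0, fs/2)")
    pad = int(round(PAD_MS * ep.fs / 1000.0))
    x = np.concatenate([ep.data[:, pad:0:-1, :], ep.data,
                        ep.data[:, -2:-pad - 2:-1, :]], axis=1)
    taps = _band_taps(ep.fs, lo, hi)
    # zero-phase: symmetric taps, 'same' alignment along the time axis
    xf = _convolve_same(x, taps, axis=1)
    analytic = signal.hilbert(xf, axis=1)
    return np.angle(analytic[:, pad:pad + ep.n_times, :])


def _convolve_same(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """FFT convolution along one axis, 'same' alignment (vectorized over the
    remaining axes)."""
    n = x.shape[axis]
    L = taps.size
    nfft = int(2 ** np.ceil(np.log2(n + L - 1)))
    shape = [1] * x.ndim
    shape[axis] = -1
    T = rfft(taps, nfft).reshape(shape)
    y = irfft(rfft(x, nfft, axis=axis) * T, nfft, axis=axis)
    start = (L - 1) // 2
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, start + n)
    return y[tuple(sl)]


def plv_waveform(ep: EpochSet, band: tuple) -> PLVWaveform:
    """PLV(t) across epochs for one frequency band."""
    if ep.n_epochs < 2:
        raise ValueError("PLV over a single epoch is identically 1; "
                         "need at least 2 epochs")
    phases = band_phases(ep, band)
    theta = phases[:, :, 0] - phases[:, :, 1]
    plv = np.abs(np.exp(1j * theta).mean(axis=0))
    return PLVWaveform(values=np.clip(plv, 0.0, 1.0), times=ep.times,
                       band=tuple(band), n_epochs=ep.n_epochs)


def plv_features(w: PLVWaveform, p200_win=(180.0, 300.0),
                 p300_win=(300.0, 600.0), pos_win=(0.0, 700.0),
                 suffix: str = "B") -> dict:
    """Summary features of one PLV waveform: maximum and its time (earliest
    on ties), and means over the P200, P300 and positive windows."""
    t, v = w.times, w.values
    imax = int(np.argmax(v))          # argmax returns the earliest maximum
    out = {f"PLV_max_{suffix}": float(v[imax]),
           f"PLV_time_{suffix}": float(t[imax])}
    for name, (lo, hi) in (("P200", p200_win), ("P300", p300_win),
                           ("P", pos_win)):
        m = (t >= lo) & (t < hi)
        out[f"PLV_{name}_{suffix}"] = float(v[m].mean())
    return out


def coherence_spectrum(ep: EpochSet, post_only: bool = True) -> CoherenceSpectrum:
    """Welch-over-epochs magnitude-squared coherence between Fp1 and Fp2.

    Each epoch contributes one Hann-tapered segment (its post-stimulus
    span by default); cross/auto spectra are averaged over segments before
    forming the ratio.  A single epoch is rejected — one segment yields
    C ≡ 1 identically.
    """
    if ep.n_epochs < 2:
        raise ValueError("coherence over one segment is identically 1; "
                         "need at least 2 epochs")
    data = ep.data
    if post_only:
        data = data[:, ep.time_mask(0.0, ep.window[1]), :]
    seg = data - data.mean(axis=1, keepdims=True)
    win = signal.get_window("hann", seg.shape[1])
    X = rfft(seg[:, :, 0] * win, n=NFFT, axis=1)
    Y = rfft(seg[:, :, 1] * win, n=NFFT, axis=1)
    wxy = (X * np.conj(Y)).mean(axis=0)
    wxx = (np.abs(X) ** 2).mean(axis=0)
    wyy = (np.abs(Y) ** 2).mean(axis=0)
    denom = wxx * wyy
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(wxy) ** 2 / denom
    c[denom == 0] = 0.0
    freqs = rfftfreq(NFFT, d=1.0 / ep.fs)
    return CoherenceSpectrum(values=np.clip(c, 0.0, 1.0), freqs=freqs,
                             n_segments=ep.n_epochs)


def coh_features(c: CoherenceSpectrum, bands: dict | None = None,
                 overall: tuple = (4.0, 30.0)) -> dict:
    """Per-band maximum (+ its frequency, earliest on ties), mean and SD of
    the coherence bins, plus the all-band mean/SD over ``overall``.

    SDs are reported on a 0–100 scale (percentile of the SD of a [0, 1]
    quantity), matching how ``COH_std`` is conventionally tabulated.
    """
    bands = dict(BANDS if bands is None else bands)
    out = {}
    for name, (lo, hi) in bands.items():
        m = (c.freqs >= lo) & (c.freqs < hi)
        if not m.any():
            raise ValueError(f"band {name} contains no frequency bins")
        v = c.values[m]
        suffix = name[0].upper() if name in ("theta", "alpha", "beta") else name
        imax = int(np.argmax(v))
        out[f"COH_max_{suffix}"] = float(v[imax])
        out[f"COH_freq_{suffix}"] = float(c.freqs[m][imax])
        out[f"COH_mean_{suffix}"] = float(v.mean())
        out[f"COH_std_{suffix}"] = float(np.std(v, ddof=1) * 100.0)
    m = (c.freqs >= overall[0]) & (c.freqs < overall[1])
    out["COH_mean"] = float(c.values[m].mean())
    out["COH_std"] = float(np.std(c.values[m], ddof=1) * 100.0)
    return out
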