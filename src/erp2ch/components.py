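"""ERP component extraction and behavioral measures.

Detection windows follow prefrontal elderly ERP morphology: N100 in
[60, 200) ms (most-negative strict local extremum), P200 in [180, 300) ms
and P300 in [300, 600) ms (most-positive strict local extrema).  A peak
must reach 2 μV in magnitude and must not sit on a window boundary,
otherwise the component is marked absent — absence is a value, not an
error, and analysis continues when the P300 is missing but N100 or P200
are present.

Per-trial P300 variability is estimated on the two-channel mean trace of
each epoch, low-pass smoothed at 10 Hz, as the windowed maximum in
[300, 600) ms; SDs across trials (sample SD, n−1) give ``P300_lat_std``
and ``P300_amp_std``.  ``P300_amp_mean`` is the mean amplitude of the
*averaged* waveform over the P300 window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import COMPONENT_WINDOWS, EpochSet, EventLog, ResponseLog
from .preprocess import ERPWaveform

__all__ = ["ComponentPeak", "ComponentSet", "BehavioralMeasures",
           "detect_components", "single_trial_p300", "behavioral_measures"]


@dataclass
class ComponentPeak:
    latency: float = np.nan      # ms
    amplitude: float = np.nan    # μV
    present: bool = False


@dataclass
class ComponentSet:
    """Detected components on the two-channel mean trace (the participant
    value) and per channel; plus P300 across-trial statistics."""

    mean_trace: dict = field(default_factory=dict)    # name -> ComponentPeak
    per_channel: dict = field(default_factory=dict)   # label -> {name: peak}
    p300_amp_mean: float = np.nan
    p300_lat_std: float = np.nan
    p300_amp_std: float = np.nan


@dataclass
class BehavioralMeasures:
    cor_no: int
    err_rate: float              # percent
    rt_mean: float = np.nan      # ms, correct target responses only
    rt_std: float = np.nan
    n_trials: int = 0


def _find_peak(trace: np.ndarray, times: np.ndarray, window: tuple,
               polarity: int, min_amp: float) -> ComponentPeak:
    """Largest strict local extremum of the given polarity inside the
    half-open window, excluding the window's edge samples."""
    inside = np.flatnonzero((times >= window[0]) & (times < window[1]))
    if inside.size < 3:
        return ComponentPeak()
    y = polarity * trace
    best = None
    # skip the first/last sample of the window: boundary peaks don't count
    for i in inside[1:-1]:
        if 0 < i < len(y) - 1 and y[i] > y[i - 1] and y[i] > y[i + 1]:
            if y[i] >= min_amp and (best is None or y[i] > y[best]):
                best = i     # strict '>' keeps the earliest of equal peaks
    if best is None:
        return ComponentPeak()
    return ComponentPeak(latency=float(times[best]),
                         amplitude=float(trace[best]), present=True)


def detect_components(erp: ERPWaveform, windows: dict | None = None,
                      min_amp: float = 2.0) -> ComponentSet:
    """Extract N100/P200/P300 from an averaged waveform.

    Components are reported from the two-channel mean trace; per-channel
    detections are retained alongside.
    """
    windows = dict(COMPONENT_WINDOWS if windows is None else windows)
    times = erp.times
    if times[0] > min(w[0] for w in windows.values()) or \
       times[-1] < max(w[1] for w in windows.values()) - 1000.0 / erp.fs:
        raise ValueError("waveform does not cover the component windows")
    polarity = {"N100": -1, "P200": +1, "P300": +1}
    out = ComponentSet()
    out.mean_trace = {
        name: _find_peak(erp.channel_mean, times, win, polarity[name], min_amp)
        for name, win in windows.items()
    }
    out.per_channel = {
        "Fp1": {name: _find_peak(erp.values[:, 0], times, win,
                                 polarity[name], min_amp)
                for name, win in windows.items()},
        "Fp2": {name: _find_peak(erp.values[:, 1], times, win,
                                 polarity[name], min_amp)
                for name, win in windows.items()},
    }
    p300_mask = (times >= windows["P300"][0]) & (times < windows["P300"][1])
    out.p300_amp_mean = float(erp.channel_mean[p300_mask].mean())
    return out


@np.errstate(invalid="ignore")
def single_trial_p300(ep: EpochSet, window: tuple = (300.0, 600.0),
                      smooth_hz: float = 10.0):
    """Per-epoch P300 latency and amplitude.

    Each epoch's two-channel mean trace is low-pass filtered (4th-order
    Butterworth, zero phase) at ``smooth_hz`` and the maximum inside the
    half-open window is taken.  Returns ``(latencies_ms, amplitudes_uv)``
    arrays, one entry per epoch.
    """
    if ep.n_epochs < 2:
        raise ValueError("need at least 2 epochs for across-trial statistics")
    traces = ep.channel_mean()
    if smooth_hz and smooth_hz < ep.fs / 2:
        sos = signal.butter(4, smooth_hz, "lowpass", fs=ep.fs, output="sos")
        traces = signal.sosfiltfilt(sos, traces, axis=1)
    times = ep.times
    mask = (times >= window[0]) & (times < window[1])
    seg = traces[:, mask]
    idx = np.argmax(seg, axis=1)
    lats = times[mask][idx]
    amps = seg[np.arange(seg.shape[0]), idx]
    return lats.astype(float), amps.astype(float)


def trial_std(values: np.ndarray) -> float:
    """Sample SD (n−1 denominator), the estimator used for every
    across-trial variability feature."""
    return float(np.std(values, ddof=1))


def behavioral_measures(events: EventLog, responses: ResponseLog, kind: str,
                        resp_window: tuple = (100.0, 1000.0)
                        ) -> BehavioralMeasures:
    """Correct-response count, error rate (%) and RT statistics.

    A press inside ``resp_window`` ms after a target onset makes that
    target correct (the first press claims the trial; each press claims at
    most one trial).  A target without a press is an error.  A standard
    with a press in its window is an error (false alarm); without one it is
    correct.  RT mean/SD are computed over correct target responses only.
    """
    soa = np.min(np.diff(events.onsets)) * 1000.0 if len(events) > 1 else np.inf
    if resp_window[1] > soa:
        raise ValueError("response window longer than the stimulus SOA: "
                         "windows would overlap")
    onsets = events.of_kind(kind)
    presses = responses.press_times
    used = np.zeros(len(presses), dtype=bool)
    hits = np.zeros(len(onsets), dtype=bool)
    rts = []
    for i, onset in enumerate(onsets):
        lo = onset + resp_window[0] / 1000.0
        hi = onset + resp_window[1] / 1000.0
        cand = np.flatnonzero((presses >= lo) & (presses < hi) & ~used)
        if cand.size:
            used[cand[0]] = True
            hits[i] = True
            rts.append((presses[cand[0]] - onset) * 1000.0)
    n = len(onsets)
    if kind == "target":
        correct = int(hits.sum())
    else:
        correct = int(n - hits.sum())       # a claimed standard = false alarm
    errors = n - correct
    rt_mean = rt_std = np.nan
    if kind == "target" and len(rts) >= 1:
        rt_mean = float(np.mean(rts))
        rt_std = trial_std(np.asarray(rts)) if len(rts) >= 2 else np.nan
    return BehavioralMeasures(cor_no=correct, err_rate=100.0 * errors / n,
                              rt_mean=rt_mean, rt_std=rt_std, n_trials=n)
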