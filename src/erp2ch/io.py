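"""Shared data model and file I/O for the two-channel prefrontal ERP pipeline.

All analyses operate on two prefrontal channels (Fp1, Fp2 of the 10/20
system) sampled at 250 Hz.  Conventions used everywhere downstream:

* amplitudes in microvolts (μV), times in milliseconds relative to stimulus
  onset (onset = 0), frequencies in Hz;
* epoch windows are half-open ``[t_start, t_end)``; sample ``k`` of an epoch
  maps to ``t_start + k / fs * 1000`` ms (4 ms steps at 250 Hz);
* recordings are stored as ``[channels x timepoints]`` arrays, epochs as
  ``[epochs x timepoints x channels]``.

On-disk formats: EDF (European Data Format) or plain TSV for recordings,
TSV for event/response logs, covariates and the output feature table, JSON
for run configuration.  TSV files are UTF-8, tab-separated, ``.`` decimal,
with a mandatory header row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Fixed analysis constants
# --------------------------------------------------------------------------

#: device input range, μV (recordings beyond this are physically impossible)
INPUT_RANGE_UV = 393.0
#: device amplitude resolution: 15-bit over the ±393 μV input range
QUANT_STEP_UV = 2 * INPUT_RANGE_UV / 2**15

#: canonical frequency bands, Hz (half-open [lo, hi))
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: the seven narrow ranges used for band-wise coherence comparisons
SEVEN_BANDS = {
    "theta": (4.0, 8.0),
    "low_alpha": (8.0, 10.0),
    "high_alpha": (10.0, 13.0),
    "low_beta": (13.0, 16.0),
    "middle_beta": (16.0, 20.0),
    "high_beta": (20.0, 23.0),
    "very_high_beta": (23.0, 30.0),
}

#: component search windows, ms (half-open)
COMPONENT_WINDOWS = {
    "N100": (60.0, 200.0),
    "P200": (180.0, 300.0),
    "P300": (300.0, 600.0),
}

#: subgroup -> main group mapping (fixed)
SUBGROUPS = ("CN", "SCD", "aMCI", "naMCI")
MAIN_GROUP = {"CN": "HC", "SCD": "HC", "aMCI": "MCI", "naMCI": "MCI"}

#: feature-table column order; beta-band connectivity uses the plain Table
#: names, alpha/theta variants carry _A/_T suffixes.
FEATURE_COLUMNS = [
    "Cor_no", "Err_rate", "RT_mean", "RT_std",
    "N100_lat", "N100_amp", "P200_lat", "P200_amp",
    "P300_lat", "P300_lat_std", "P300_amp", "P300_amp_std", "P300_amp_mean",
    "PLV_max_B", "PLV_time_B", "PLV_P200_B", "PLV_P300_B", "PLV_P_B",
    "COH_max_B", "COH_freq_B", "COH_mean_B", "COH_std_B",
    "COH_mean", "COH_std",
    "PLV_max_A", "PLV_time_A", "PLV_P200_A", "PLV_P300_A", "PLV_P_A",
    "COH_max_A", "COH_freq_A", "COH_mean_A", "COH_std_A",
    "PLV_max_T", "PLV_time_T", "PLV_P200_T", "PLV_P300_T", "PLV_P_T",
    "COH_max_T", "COH_freq_T", "COH_mean_T", "COH_std_T",
]


class ParticipantExcluded(RuntimeError):
    """Raised when a participant's data cannot survive preprocessing."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous two-channel EEG.

    Parameters
    ----------
    samples : ndarray, shape (2, n_timepoints)
        Amplitudes in μV, channel order Fp1, Fp2.
    fs : float
        Sampling rate, Hz.
    channel_labels : tuple of str
    start_time : float
        Recording clock zero, seconds.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple = ("Fp1", "Fp2")
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise ValueError("Recording requires exactly 2 channels "
                             f"(got shape {self.samples.shape})")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EventLog:
    """Stimulus onsets (seconds from recording start) and their kinds."""

    onsets: np.ndarray
    kinds: np.ndarray          # array of "standard" / "target"
    stimulus_duration: float = 50.0   # ms

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.onsets.size == 0:
            raise ValueError("EventLog must contain at least one stimulus")
        if self.onsets.size != self.kinds.size:
            raise ValueError("onsets and kinds length mismatch")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        bad = set(self.kinds) - {"standard", "target"}
        if bad:
            raise ValueError(f"unknown stimulus kinds: {sorted(bad)}")

    def of_kind(self, kind: str) -> np.ndarray:
        return self.onsets[self.kinds == kind]

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class ResponseLog:
    """Button-press times, seconds from recording start.  May be empty."""

    press_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.press_times = np.asarray(self.press_times, dtype=float)
        if self.press_times.size and np.any(np.diff(self.press_times) <= 0):
            raise ValueError("response times must be strictly increasing")

    def __len__(self) -> int:
        return self.press_times.size


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``data[epoch, timepoint, channel]`` in μV.

    ``window`` and ``baseline`` are (start, end) in ms relative to onset,
    half-open.  ``epoch_event_index`` maps each epoch back to its row in the
    originating :class:`EventLog` (presentation order).
    """

    data: np.ndarray
    fs: float
    window: tuple
    baseline: tuple = (-200.0, 0.0)
    kind: str = "standard"
    epoch_event_index: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be [epochs x time x channels]")
        if self.data.shape[0] < 1:
            raise ValueError("EpochSet requires at least one epoch")
        if not (self.window[0] <= self.baseline[0]
                and self.baseline[1] <= self.window[1]):
            raise ValueError("baseline must lie within the epoch window")
        if self.epoch_event_index is None:
            self.epoch_event_index = np.arange(self.data.shape[0])
        else:
            self.epoch_event_index = np.asarray(self.epoch_event_index)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms: ``t_start + k / fs * 1000``."""
        return self.window[0] + np.arange(self.n_times) * 1000.0 / self.fs

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask for the half-open interval [start, end) ms."""
        t = self.times
        return (t >= start) & (t < end)

    def channel_mean(self) -> np.ndarray:
        """Two-channel mean trace per epoch, shape (epochs, time)."""
        return self.data.mean(axis=2)


@dataclass
class CovariateRecord:
    participant_id: str
    age: float
    sex: str                     # "M" / "F"
    education: float             # years
    subgroup: str                # CN / SCD / aMCI / naMCI

    def __post_init__(self):
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.age < 0 or self.education < 0:
            raise ValueError("age and education must be non-negative")

    @property
    def main_group(self) -> str:
        return MAIN_GROUP[self.subgroup]


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def read_recording(path, fmt: str | None = None) -> Recording:
    """Read a two-channel recording from EDF or TSV.

    TSV layout: header ``time  Fp1  Fp2``, time in seconds, amplitudes μV.
    The format is inferred from the suffix unless ``fmt`` is given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "tsv":
        return _read_tsv_recording(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [ch for ch in ("Fp1", "Fp2") if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF file {path} lacks channel(s): {missing}")
    picks = [raw.ch_names.index("Fp1"), raw.ch_names.index("Fp2")]
    data = raw.get_data(picks=picks) * 1e6   # mne returns volts
    return Recording(samples=data, fs=float(raw.info["sfreq"]),
                     channel_labels=("Fp1", "Fp2"))


def _read_tsv_recording(path: Path) -> Recording:
    df = pd.read_csv(path, sep="\t")
    for col in ("time", "Fp1", "Fp2"):
        if col not in df.columns:
            raise ValueError(f"TSV recording {path} missing column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise ValueError("non-uniform sampling in TSV recording")
    fs = 1.0 / dt[0]
    data = np.vstack([df["Fp1"].to_numpy(float), df["Fp2"].to_numpy(float)])
    return Recording(samples=data, fs=fs, start_time=float(t[0]))


def read_events(path) -> tuple[EventLog, ResponseLog]:
    """Parse an event TSV (columns ``onset_s``, ``kind``) into stimulus and
    response logs.  ``kind`` is one of standard/target/response."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "kind"):
        if col not in df.columns:
            raise ValueError(f"event file missing column {col!r}")
    bad = set(df["kind"]) - {"standard", "target", "response"}
    if bad:
        raise ValueError(f"unknown kind token(s): {sorted(bad)}")
    # order-independent of on-disk row permutation: sort by onset
    df = df.sort_values("onset_s", kind="mergesort")
    stim = df[df["kind"] != "response"]
    resp = df[df["kind"] == "response"]
    if stim.empty:
        raise ValueError("event file contains no stimulus rows")
    events = EventLog(onsets=stim["onset_s"].to_numpy(float),
                      kinds=stim["kind"].to_numpy(object))
    responses = ResponseLog(press_times=resp["onset_s"].to_numpy(float))
    return events, responses


def read_covariates(path) -> list[CovariateRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CovariateRecord(participant_id=str(r.participant_id), age=float(r.age),
                        sex=str(r.sex), education=float(r.education),
                        subgroup=str(r.subgroup))
        for r in df.itertuples(index=False)
    ]


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_events(events: EventLog, responses: ResponseLog, path) -> None:
    rows = [(t, k) for t, k in zip(events.onsets, events.kinds)]
    rows += [(t, "response") for t in responses.press_times]
    rows.sort(key=lambda r: r[0])
    df = pd.DataFrame(rows, columns=["onset_s", "kind"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_tsv_recording(rec: Recording, path) -> None:
    t = rec.start_time + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t, "Fp1": rec.samples[0], "Fp2": rec.samples[1]})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_feature_table(rows: pd.DataFrame, path) -> None:
    """Write the per-participant feature table as TSV.

    One row per (participant, epoch kind); raises on duplicates.  Values are
    written in full repr precision so the table round-trips losslessly.
    """
    if rows.duplicated(subset=["participant_id", "kind"]).any():
        raise ValueError("duplicate (participant_id, kind) rows in feature table")
    rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Minimal EDF writer
# --------------------------------------------------------------------------
# EDF stores 16-bit samples with a per-signal linear physical<->digital map.
# We write the device's native range (±393 μV) so the quantization step
# matches the hardware's 15-bit resolution.

def write_edf(rec: Recording, path, *, physical_range: float = INPUT_RANGE_UV,
              patient_id: str = "X", recording_id: str = "erp2ch") -> None:
    """Write a :class:`Recording` to an EDF file.

    The recording is padded with zeros to a whole number of 1-second data
    records (EDF requires fixed-size records); readers that honour the
    header will still report the padded length, so prefer whole-second
    recordings for exact round trips.
    """
    if np.max(np.abs(rec.samples)) > physical_range:
        raise ValueError("samples exceed the EDF physical range")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = 2
    n_rec = int(np.ceil(rec.n_samples / fs))
    pad = n_rec * fs - rec.n_samples
    data = np.pad(rec.samples, ((0, 0), (0, pad)))

    dig_min, dig_max = -(2**14), 2**14 - 1      # 15-bit, as the device
    phys_min, phys_max = -physical_range, physical_range
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    def pad_field(s, n):
        s = str(s)[:n]
        return s.ljust(n).encode("ascii")

    header = b"".join([
        pad_field("0", 8),
        pad_field(patient_id, 80),
        pad_field(recording_id, 80),
        pad_field("01.01.20", 8),
        pad_field("00.00.00", 8),
        pad_field(256 * (ns + 1), 8),
        pad_field("", 44),
        pad_field(n_rec, 8),
        pad_field("1", 8),          # record duration, seconds
        pad_field(ns, 4),
    ])
    labels = [pad_field(lbl, 16) for lbl in rec.channel_labels]
    per_signal = b"".join([
        *labels,
        *[pad_field("AgAgCl electrode", 80)] * ns,
        *[pad_field("uV", 8)] * ns,
        *[pad_field(f"{phys_min:g}", 8)] * ns,
        *[pad_field(f"{phys_max:g}", 8)] * ns,
        *[pad_field(dig_min, 8)] * ns,
        *[pad_field(dig_max, 8)] * ns,
        *[pad_field("HP:2.6Hz LP:43Hz N:55-65Hz", 80)] * ns,
        *[pad_field(fs, 8)] * ns,
        *[pad_field("", 32)] * ns,
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        # records: for each second, all samples of signal 1 then signal 2
        rec3 = digital.reshape(ns, n_rec, fs).transpose(1, 0, 2)
        fh.write(rec3.tobytes())


# --------------------------------------------------------------------------
# Helpers shared across modules
# --------------------------------------------------------------------------

def sample_index(times_ms: Sequence[float], fs: float, t_start_ms: float) -> np.ndarray:
    """Map epoch-relative times (ms) to sample indices on the epoch grid."""
    return np.round((np.asarray(times_ms) - t_start_ms) * fs / 1000.0).astype(int)


def as_dict(obj) -> dict:
    """Dataclass -> plain dict (for JSON serialization)."""
    return dataclasses.asdict(obj)
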