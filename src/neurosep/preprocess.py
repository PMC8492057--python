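"""Continuous-recording preprocessing for evoked-potential analysis.

The chain implemented here mirrors standard somatosensory-evoked-potential
(SEP) practice: excision and interpolation of the electrical stimulation
artifact, zero-phase Butterworth band-pass filtering, epoching around
stimulus onsets, and average re-referencing.  All operations are pure
functions of their inputs; trials that cannot be formed (events too close to
the recording edge) are dropped with a logged warning, never silently
renumbered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

#: channel names treated as non-EEG peripheral electrodes
PERIPHERAL_CHANNELS = ("CNAP", "CMAP")


@dataclass
class Recording:
    """Continuous multichannel recording with stimulus event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts (CMAP channel in millivolts).
    srate : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels; names in :data:`PERIPHERAL_CHANNELS` are excluded
        from EEG-only operations such as average re-referencing.
    events : list of (int, str)
        ``(sample_index, intensity_label)`` pairs, strictly increasing.
    """

    data: np.ndarray
    srate: float
    ch_names: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match channel count")
        samples = [int(s) for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event samples must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event samples out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def eeg_picks(self) -> np.ndarray:
        """Indices of EEG (non-peripheral) channels."""
        return np.array(
            [i for i, n in enumerate(self.ch_names) if n not in PERIPHERAL_CHANNELS],
            dtype=int,
        )

    def pick(self, names) -> "Recording":
        idx = [self.ch_names.index(n) for n in names]
        return replace(self, data=self.data[idx], ch_names=list(names))


@dataclass
class Epochs:
    """Epoched data: trials x channels x samples with a time axis in ms.

    ``metadata`` carries one row per retained trial (presented intensity,
    behavioral response, original trial index).
    """

    data: np.ndarray
    times: np.ndarray  # ms relative to stimulus onset
    srate: float
    ch_names: list = field(default_factory=list)
    metadata: pd.DataFrame = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be 3-D (trials x channels x samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=range(self.data.shape[0]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_indices(self, t_min: float, t_max: float) -> np.ndarray:
        """Sample indices with t_min <= t <= t_max (ms)."""
        return np.nonzero((self.times >= t_min) & (self.times <= t_max))[0]

    def average(self) -> np.ndarray:
        """Grand average across trials, shape (channels, samples)."""
        return self.data.mean(axis=0)


def interpolate_stimulus_artifact(rec: Recording, window=(-2.0, 4.0)) -> Recording:
    """Replace the stimulation artifact around each event by interpolation.

    Samples inside ``window`` (ms relative to each event) are replaced by a
    piecewise cubic Hermite interpolant (PCHIP) anchored on the two samples
    flanking each side of the excised window.  All other samples are returned
    bit-identical.  Events with insufficient context are skipped with a
    warning.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be an increasing (lo, hi) pair in ms")
    out = rec.data.copy()
    n = rec.n_samples
    i_lo = int(np.floor(lo * rec.srate / 1000.0))
    i_hi = int(np.ceil(hi * rec.srate / 1000.0))
    for sample, _ in rec.events:
        a, b = sample + i_lo, sample + i_hi  # inclusive excision bounds
        if a - 2 < 0 or b + 2 >= n:
            logger.warning("event at sample %d too close to edge; artifact not interpolated", sample)
            continue
        anchors = np.array([a - 2, a - 1, b + 1, b + 2])
        inside = np.arange(a, b + 1)
        interp = PchipInterpolator(anchors, out[:, anchors], axis=1)
        out[:, inside] = interp(inside)
    return replace(rec, data=out)


def zero_phase_bandpass(x: np.ndarray, low: float, high: float, srate: float,
                        order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The filter is applied once forward and once backward (``filtfilt``), so
    the net phase response is zero and the magnitude response is the squared
    single-pass Butterworth response.
    """
    nyq = srate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=srate, output="sos")
    settle = int(3 * srate / low)
    if np.asarray(x).shape[axis] < 3 * settle:
        warnings.warn("segment short relative to filter settle length; edge effects possible")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def zero_phase_highpass(x: np.ndarray, cutoff: float, srate: float,
                        order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth high-pass (used for the peripheral nerve channel)."""
    if not (0 < cutoff < srate / 2.0):
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=srate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def epoch_data(rec: Recording, window=(-100.0, 600.0)) -> Epochs:
    """Cut the recording into stimulus-locked epochs.

    ``window`` is in ms relative to stimulus onset; the sample at 0 ms is the
    event sample itself.  Events without full window coverage are dropped
    (logged); metadata records the original trial index and intensity label.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be increasing")
    i_lo = int(round(lo * rec.srate / 1000.0))
    i_hi = int(round(hi * rec.srate / 1000.0))
    offsets = np.arange(i_lo, i_hi + 1)
    times = offsets * 1000.0 / rec.srate
    rows, chunks = [], []
    for trial, (sample, label) in enumerate(rec.events):
        a, b = sample + i_lo, sample + i_hi
        if a < 0 or b >= rec.n_samples:
            logger.warning("trial %d dropped: epoch window outside recording", trial)
            continue
        chunks.append(rec.data[:, a:b + 1])
        rows.append({"trial": trial, "intensity": label, "event_sample": sample})
    if not chunks:
        raise ValueError("no valid events to epoch")
    meta = pd.DataFrame(rows).reset_index(drop=True)
    return Epochs(np.stack(chunks), times, rec.srate, list(rec.ch_names), meta)


def rereference_average(obj):
    """Re-reference EEG channels to the common average.

    Works on :class:`Recording` or :class:`Epochs`; peripheral channels
    (CNAP/CMAP) are excluded from the average and left untouched.  After the
    operation the per-sample mean over EEG channels is zero.
    """
    if isinstance(obj, Recording):
        picks = obj.eeg_picks()
        if picks.size < 2:
            raise ValueError("average reference requires >= 2 EEG channels")
        data = obj.data.copy()
        data[picks] -= data[picks].mean(axis=0, keepdims=True)
        return replace(obj, data=data)
    if isinstance(obj, Epochs):
        picks = np.array([i for i, n in enumerate(obj.ch_names)
                          if n not in PERIPHERAL_CHANNELS], dtype=int)
        if picks.size < 2:
            raise ValueError("average reference requires >= 2 EEG channels")
        data = obj.data.copy()
        data[:, picks] -= data[:, picks].mean(axis=1, keepdims=True)
        return replace(obj, data=data)
    raise TypeError("expected Recording or Epochs")


def amplitude_threshold_rejection(epochs: Epochs, threshold_uv: float) -> Epochs:
    """Flag trials whose peak absolute EEG amplitude exceeds ``threshold_uv``.

    Stands in for manual visual artifact screening.  Flagged trials are kept
    in place with ``valid=False`` in the metadata (tombstoned, not deleted).
    """
    picks = np.array([i for i, n in enumerate(epochs.ch_names)
                      if n not in PERIPHERAL_CHANNELS], dtype=int)
    peak = np.abs(epochs.data[:, picks]).max(axis=(1, 2))
    meta = epochs.metadata.copy()
    meta["valid"] = peak <= threshold_uv
    n_bad = int((~meta["valid"]).sum())
    if n_bad:
        logger.info("amplitude rejection tombstoned %d trials (> %.1f uV)", n_bad, threshold_uv)
    return replace(epochs, metadata=meta)
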