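"""Per-trial scalar features: SEP peaks, pre-stimulus alpha, peripheral amps.

Extractors operate on epoched data (component epochs from the CCA stage, or
raw peripheral channels) and return one value per trial.  All extractors are
deterministic pure functions; the pre-stimulus alpha pipeline segments the
data *before* filtering so no post-stimulus activity can leak into the
pre-stimulus estimate.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .preprocess import Epochs, zero_phase_highpass


def _component_series(epochs: Epochs) -> np.ndarray:
    """(n_trials, n_samples) view of single-channel component epochs."""
    if epochs.data.shape[1] != 1:
        raise ValueError("expected single-channel (component) epochs")
    return epochs.data[:, 0, :]


def n20_peak_amplitude(component_epochs: Epochs, search_window=(15.0, 30.0),
                       halfwidth: float = 2.0):
    """Single-trial N20 peak amplitudes.

    The subject-level N20 latency is the minimum of the average component
    waveform inside ``search_window`` (ms); per trial, the amplitude is the
    minimum value within +/- ``halfwidth`` ms around that latency.

    Returns ``(amplitudes, latency_ms)``.
    """
    x = _component_series(component_epochs)
    t = component_epochs.times
    idx = component_epochs.time_indices(*search_window)
    if idx.size == 0:
        raise ValueError("search window outside epochs")
    avg = x.mean(axis=0)
    j = idx[np.argmin(avg[idx])]
    if j == idx[0] or j == idx[-1]:
        warnings.warn("average N20 minimum lies on the search-window boundary; "
                      "latency may be mis-localized")
    latency = t[j]
    sel = component_epochs.time_indices(latency - halfwidth, latency + halfwidth)
    return x[:, sel].min(axis=1), float(latency)


def window_mean_amplitude(component_epochs: Epochs, window) -> np.ndarray:
    """Mean amplitude per trial over a fixed time window (ms)."""
    idx = component_epochs.time_indices(*window)
    if idx.size == 0:
        raise ValueError("empty averaging window")
    return _component_series(component_epochs)[:, idx].mean(axis=1)


def prestimulus_alpha(epochs_raw: Epochs, spatial_filter: np.ndarray,
                      band=(8.0, 13.0), segment=(-500.0, -5.0),
                      average_window=(-200.0, -10.0), order: int = 4) -> np.ndarray:
    """Log pre-stimulus alpha-envelope amplitude per trial.

    Per trial: project the raw (unfiltered) pre-stimulus segment through the
    CCA spatial filter, mirror-pad the segment to both sides (full segment
    length), zero-phase Butterworth band-pass in ``band``, take the Hilbert
    envelope, crop the padding, average the envelope over ``average_window``
    and return the natural log.

    ``epochs_raw`` must cover ``segment``; the segment must end before 0 ms
    so no post-stimulus signal leaks into the estimate.
    """
    if segment[1] > 0:
        raise ValueError("pre-stimulus segment must end before stimulus onset")
    w = np.asarray(spatial_filter, dtype=float)
    picks = [i for i, n in enumerate(epochs_raw.ch_names)
             if n not in ("CNAP", "CMAP")]
    if len(picks) != w.size:
        raise ValueError("spatial filter length does not match EEG channel count")
    idx = epochs_raw.time_indices(*segment)
    if idx.size < 8:
        raise ValueError("pre-stimulus segment too short")
    comp = np.einsum("c,ncs->ns", w, epochs_raw.data[:, picks][:, :, idx])
    t_seg = epochs_raw.times[idx]
    n_seg = comp.shape[1]
    # symmetric (mirror) padding of full segment length on each side
    padded = np.concatenate([comp[:, ::-1], comp, comp[:, ::-1]], axis=1)
    sos = signal.butter(order, list(band), btype="bandpass",
                        fs=epochs_raw.srate, output="sos")
    filtered = signal.sosfiltfilt(sos, padded, axis=1)
    envelope = np.abs(signal.hilbert(filtered, axis=1))[:, n_seg:2 * n_seg]
    sel = (t_seg >= average_window[0]) & (t_seg <= average_window[1])
    if not np.any(sel):
        raise ValueError("averaging window outside the pre-stimulus segment")
    mean_env = envelope[:, sel].mean(axis=1)
    if np.any(mean_env <= 0):
        raise ValueError("non-positive envelope mean: degenerate input")
    return np.log(mean_env)


def peripheral_amplitudes(cnap_epochs: Epochs = None, cmap_epochs: Epochs = None,
                          cnap_search=(5.0, 9.0), cmap_neg_search=(5.0, 11.0),
                          cmap_pos_search=(10.0, 20.0), baseline=(-20.0, -5.0),
                          highpass_hz: float = 70.0):
    """Per-trial peripheral nerve (CNAP) and muscle (CMAP) amplitudes.

    CNAP: the channel is zero-phase high-pass filtered at ``highpass_hz``;
    the subject-level peak latency is located in ``cnap_search`` on the
    average; per trial the maximum within +/-1 ms of that latency is taken.

    CMAP: after baseline correction (mean over ``baseline`` ms), the
    peak-to-peak amplitude is the maximum within +/-1 ms of the
    subject-level positive-peak latency (searched in ``cmap_pos_search``)
    minus the minimum within +/-1 ms of the negative-peak latency (searched
    in ``cmap_neg_search``).

    Returns a dict with keys ``cnap`` and ``cmap`` (None when the
    corresponding epochs are missing).
    """
    out = {"cnap": None, "cmap": None}
    if cnap_epochs is not None:
        x = _component_series(cnap_epochs)
        xf = zero_phase_highpass(x, highpass_hz, cnap_epochs.srate, axis=1)
        t = cnap_epochs.times
        idx = cnap_epochs.time_indices(*cnap_search)
        lat = t[idx[np.argmax(xf.mean(axis=0)[idx])]]
        sel = cnap_epochs.time_indices(lat - 1.0, lat + 1.0)
        out["cnap"] = xf[:, sel].max(axis=1)
    if cmap_epochs is not None:
        x = _component_series(cmap_epochs)
        t = cmap_epochs.times
        base = cmap_epochs.time_indices(*baseline)
        if base.size:
            x = x - x[:, base].mean(axis=1, keepdims=True)
        avg = x.mean(axis=0)
        i_neg = cmap_epochs.time_indices(*cmap_neg_search)
        i_pos = cmap_epochs.time_indices(*cmap_pos_search)
        lat_neg = t[i_neg[np.argmin(avg[i_neg])]]
        lat_pos = t[i_pos[np.argmax(avg[i_pos])]]
        sel_neg = cmap_epochs.time_indices(lat_neg - 1.0, lat_neg + 1.0)
        sel_pos = cmap_epochs.time_indices(lat_pos - 1.0, lat_pos + 1.0)
        out["cmap"] = x[:, sel_pos].max(axis=1) - x[:, sel_neg].min(axis=1)
    return out


def zscore_within(values: np.ndarray) -> np.ndarray:
    """z-transform a vector (per-subject standardization of continuous measures)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-transform a constant vector")
    return (v - v.mean()) / sd


#: column dictionary of the trial table written by the pipeline
TRIAL_TABLE_COLUMNS = {
    "subject": "subject identifier",
    "trial": "stimulation event index within the session (0-based)",
    "block": "experimental block index",
    "intensity": "presented stimulus intensity ('weak' | 'strong')",
    "response": "reported intensity ('weak' | 'strong' | 'none')",
    "n20_amp": "signed single-trial N20 peak amplitude (uV; negative peak)",
    "n140_amp": "mean amplitude 140-160 ms, low-frequency stream (uV)",
    "alpha_log": "log pre-stimulus 8-13 Hz envelope amplitude (log uV)",
    "cnap_amp": "compound nerve action potential peak (uV)",
    "cmap_amp": "compound muscle action potential peak-to-peak (mV)",
    "valid": "False for tombstoned trials (dropped or no response)",
}
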