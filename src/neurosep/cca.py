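"""Template-matching canonical correlation analysis for single-trial SEPs.

The decomposition finds spatial filters ``w_x`` maximizing the correlation
between the horizontally concatenated single-trial epochs ``X = [x_1 ... x_N]``
and ``Y = [xbar ... xbar]``, the grand-average evoked response replicated N
times.  Because averaging cancels background activity, this is a template
match between each trial and the shared evoked morphology.  The optimization
is solved as a symmetric generalized eigenproblem on the whitened
cross-covariance (see docs/methods.md for the derivation); all components
are returned in descending order of canonical correlation.

The filter describes how to *extract* the component from the channels; the
corresponding activation pattern ``A = Cov(X) w_x`` describes how the
component *projects to* the channels and is the physiologically
interpretable quantity (a tangential dipole for the N20-P35 complex).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .preprocess import Epochs, PERIPHERAL_CHANNELS


class RankDeficientError(np.linalg.LinAlgError):
    """Covariance is numerically singular and no shrinkage was requested."""


@dataclass
class CCAResult:
    """Fitted template-matching CCA decomposition.

    ``w_x`` / ``w_y`` hold one spatial filter per column; ``rho`` the
    canonical correlations (descending, in [0, 1]); ``patterns`` the
    unit-norm activation patterns ``Cov(X) w_x``.  ``selected`` and ``sign``
    identify the standardized SEP component: after standardization its
    grand-average waveform is negative at the N20 latency.
    """

    w_x: np.ndarray           # (n_eeg_channels, K)
    w_y: np.ndarray           # (n_eeg_channels, K)
    rho: np.ndarray           # (K,)
    patterns: np.ndarray      # (n_eeg_channels, K), unit columns
    mean_waveforms: np.ndarray  # (K, n_window_samples): filtered grand average
    window: tuple             # (ms, ms) used for fitting
    window_times: np.ndarray  # ms axis of mean_waveforms
    ch_names: list            # EEG channels the filters apply to
    cov_x: np.ndarray         # channel covariance of the concatenated trials
    selected: int = None
    sign: int = 1

    @property
    def n_components(self) -> int:
        return self.w_x.shape[1]

    def selected_filter(self) -> np.ndarray:
        if self.selected is None:
            raise ValueError("no component selected; run select_and_standardize first")
        return self.sign * self.w_x[:, self.selected]


def _eeg_picks(epochs: Epochs) -> np.ndarray:
    return np.array([i for i, n in enumerate(epochs.ch_names)
                     if n not in PERIPHERAL_CHANNELS], dtype=int)


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    p = cov.shape[0]
    return (1.0 - gamma) * cov + gamma * (np.trace(cov) / p) * np.eye(p)


def _inv_sqrt(cov: np.ndarray, label: str, gamma: float) -> np.ndarray:
    vals, vecs = linalg.eigh(cov)
    tol = vals.max() * cov.shape[0] * np.finfo(float).eps
    if vals.min() <= tol:
        raise RankDeficientError(
            f"{label} covariance is rank deficient (e.g. average-referenced data); "
            f"pass shrinkage > 0 (current {gamma:g}) to regularize")
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def fit_template_cca(epochs: Epochs, window=(5.0, 80.0), shrinkage: float = 1e-6) -> CCAResult:
    """Fit the template-matching CCA on a post-stimulus window.

    ``X`` concatenates the windowed single trials along time, ``Y`` the
    replicated grand average; both are channel-mean-centered.  ``shrinkage``
    regularizes the covariances as ``(1-g) C + g tr(C)/p I`` (needed for
    rank-deficient average-referenced data).
    """
    if epochs.n_trials < 2:
        raise ValueError("need >= 2 trials to fit the template CCA")
    idx = epochs.time_indices(*window)
    if idx.size == 0:
        raise ValueError("fit window outside the epoch time axis")
    picks = _eeg_picks(epochs)
    n_ch = picks.size
    if n_ch > epochs.n_trials * idx.size:
        raise ValueError("more channels than time points: problem underdetermined")

    trials = epochs.data[:, picks][:, :, idx]            # (N, ch, T)
    avg = trials.mean(axis=0)                            # (ch, T)
    n_trials, _, n_t = trials.shape
    X = np.concatenate(list(trials), axis=1)             # (ch, N*T)
    Y = np.tile(avg, (1, n_trials))                      # (ch, N*T)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    m = Xc.shape[1]
    cxx = Xc @ Xc.T / (m - 1)
    cyy = Yc @ Yc.T / (m - 1)
    cxy = Xc @ Yc.T / (m - 1)
    if shrinkage > 0:
        cxx_r, cyy_r = _shrink(cxx, shrinkage), _shrink(cyy, shrinkage)
    else:
        cxx_r, cyy_r = cxx, cyy
    wxx = _inv_sqrt(cxx_r, "X", shrinkage)
    wyy = _inv_sqrt(cyy_r, "Y", shrinkage)
    # symmetric problem: eigenvectors of M M^T with M the whitened cross-cov
    M = wxx @ cxy @ wyy
    U, s, Vt = linalg.svd(M)
    rho = np.clip(s, 0.0, 1.0)
    w_x = wxx @ U
    w_y = wyy @ Vt.T
    # normalize filters to unit variance of the projected signals
    for k in range(w_x.shape[1]):
        vx = w_x[:, k] @ cxx_r @ w_x[:, k]
        vy = w_y[:, k] @ cyy_r @ w_y[:, k]
        if vx > 0:
            w_x[:, k] /= np.sqrt(vx)
        if vy > 0:
            w_y[:, k] /= np.sqrt(vy)

    patterns = cxx @ w_x
    norms = np.linalg.norm(patterns, axis=0)
    patterns = patterns / np.where(norms > 0, norms, 1.0)
    mean_waveforms = w_x.T @ avg
    return CCAResult(
        w_x=w_x, w_y=w_y, rho=rho, patterns=patterns,
        mean_waveforms=mean_waveforms, window=tuple(window),
        window_times=epochs.times[idx].copy(),
        ch_names=[epochs.ch_names[i] for i in picks], cov_x=cxx,
    )


def activation_patterns(result: CCAResult, X: np.ndarray = None) -> np.ndarray:
    """Activation patterns ``A = Cov(X) W_x`` with unit-norm columns.

    If ``X`` (channels x samples) is given, its covariance is used;
    otherwise the covariance stored at fit time.
    """
    if X is None:
        cov = result.cov_x
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != result.w_x.shape[0]:
            raise ValueError("X channel count does not match the fitted filters")
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T / (X.shape[1] - 1)
    A = cov @ result.w_x
    norms = np.linalg.norm(A, axis=0)
    return A / np.where(norms > 0, norms, 1.0)


def select_and_standardize(result: CCAResult, template_pattern=None,
                           n20_latency: float = 20.0, top_k: int = 4,
                           similarity_threshold: float = 0.5) -> CCAResult:
    """Pick the SEP component among the leading components and fix its sign.

    Among the ``top_k`` components with largest canonical correlation, the
    one whose unit activation pattern is most collinear with
    ``template_pattern`` (absolute cosine similarity) is selected; without a
    template the component with maximal correlation wins (ties broken toward
    the lower index).  The sign factor is chosen so the component's
    grand-average waveform is negative at the N20 latency.
    """
    k = min(top_k, result.n_components)
    if template_pattern is not None:
        t = np.asarray(template_pattern, dtype=float)
        t = t / np.linalg.norm(t)
        sims = np.abs(result.patterns[:, :k].T @ t)
        if np.all(sims < similarity_threshold):
            raise ValueError(
                f"no component among the first {k} matches the template pattern "
                f"(max |cos| = {sims.max():.3f} < {similarity_threshold})")
        selected = int(np.argmax(sims))
    else:
        selected = 0  # rho is sorted descending; stable tie-break
    j = int(np.argmin(np.abs(result.window_times - n20_latency)))
    value = result.mean_waveforms[selected, j]
    sign = 1 if value <= 0 else -1
    return replace(result, selected=selected, sign=sign)


def project_trials(epochs: Epochs, result: CCAResult, component: int = None) -> Epochs:
    """Apply the standardized spatial filter to (full-length) epochs.

    The same filter can be applied to differently filtered versions of the
    data (e.g. a 0.5-45 Hz stream for late components, or raw pre-stimulus
    segments for the alpha pipeline), as long as the channel set matches.
    Returns single-"channel" epochs of the component time courses.
    """
    picks = [epochs.ch_names.index(n) if n in epochs.ch_names else None
             for n in result.ch_names]
    if any(p is None for p in picks):
        raise ValueError("epochs lack channels the CCA filters were fitted on")
    if component is None:
        w = result.selected_filter()
        name = f"cca{result.selected}"
    else:
        w = result.sign * result.w_x[:, component] if component == result.selected \
            else result.w_x[:, component]
        name = f"cca{component}"
    data = np.einsum("c,ncs->ns", w, epochs.data[:, picks])[:, None, :]
    return Epochs(data=data, times=epochs.times.copy(), srate=epochs.srate,
                  ch_names=[name], metadata=epochs.metadata.copy())
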