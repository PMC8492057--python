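"""Synthetic somatosensory-discrimination experiments.

This module generates complete synthetic median-nerve stimulation
experiments with the statistical structure the downstream analysis assumes:

* a pseudo-randomized two-intensity stimulus sequence (equiprobable weak /
  strong stimuli, uniform inter-stimulus intervals, block structure, first
  stimulus always weak as a perceptual anchor);
* a latent cortical *excitability* process, modelled as a stationary AR(1),
  that (a) anti-modulates the 8-13 Hz alpha amplitude of the simulated
  sensorimotor source and (b) modulates the per-trial excitatory
  post-synaptic current scale of the evoked response;
* a scalp voltage model ``U = I * N_neurons * LF``: the single-trial evoked
  amplitude is the product of the post-synaptic current scale ``I`` (latent,
  excitability-coupled), a neuron-count factor that grows with presented
  stimulus intensity, and a fixed lead-field gain, projected to the scalp
  through a tangential-dipole-like channel pattern;
* peripheral control channels: a compound nerve action potential (CNAP,
  peak 5-9 ms) and a biphasic compound muscle action potential (CMAP,
  5-20 ms), both scaling with presented intensity only;
* a signal-detection-theoretic observer whose internal criterion shifts
  with excitability, producing binary "strong"/"weak" intensity reports.

Two product levels are offered.  :func:`generate_experiment` renders the
full continuous multichannel recording (for exercising the preprocessing /
CCA / feature-extraction chain), while :func:`simulate_subject_table` and
:func:`simulate_study` emit trial-level tables directly from the latents
(with configurable measurement noise standing in for the single-trial
extraction step) — the fast path used for statistical calibration studies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .preprocess import Recording

WEAK, STRONG = "weak", "strong"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere positions (abstract montage)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def tangential_dipole_pattern(n_channels: int) -> np.ndarray:
    """Unit-norm dipolar channel pattern (one positive, one negative pole)."""
    pos = fibonacci_sphere(n_channels)
    moment = np.array([1.0, 0.15, 0.35])
    pat = pos @ (moment / np.linalg.norm(moment))
    return pat / np.linalg.norm(pat)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment.

    Defaults describe one experimental session: 1000 stimuli in 5 blocks,
    inter-stimulus intervals uniform on [1463, 1563] ms (mean 1513 ms),
    sampled at 5000 Hz on a 32-channel abstract montage.  The observer's
    target sensitivity is d' = 1.14 with criterion fluctuations coupled to
    the excitability latent; alpha amplitude is anti-coupled to excitability
    and the evoked-response current scale shrinks with excitability (higher
    excitability -> smaller driving force -> smaller N20).
    """

    n_subjects: int = 12
    n_trials: int = 1000
    n_blocks: int = 5
    srate: float = 5000.0
    n_channels: int = 32
    isi_low: float = 1463.0   # ms
    isi_high: float = 1563.0  # ms
    block_gap: float = 2000.0  # ms of silence between blocks
    intensity_levels: dict = field(default_factory=lambda: {WEAK: 1.0, STRONG: 1.15})

    # scalp projection patterns (None -> default tangential dipole)
    pattern_sep: np.ndarray = None
    pattern_alpha: np.ndarray = None

    # voltage model U = I * N_neurons * LF
    epsc_gain: float = 2.5        # uV: baseline post-synaptic current scale I
    n_neurons_gain: float = 1.0   # multiplier on the intensity level
    leadfield_gain: float = 1.0   # LF, constant across trials
    epsc_coupling: float = -0.25  # excitability -> I (negative: depolarized state, smaller EPSC)

    # latent excitability AR(1)
    excitability_ar_coef: float = 0.95
    excitability_sd: float = 1.0  # stationary SD

    # alpha source
    alpha_base_log: float = 0.69  # log uV RMS of the alpha source at e = 0 (~2 uV)
    alpha_coupling: float = -0.7  # excitability -> log alpha envelope
    alpha_log_noise_sd: float = 0.2

    # SDT observer
    observer_dprime: float = 1.14
    criterion_base: float = 0.0
    criterion_coupling: float = -0.10  # excitability -> criterion (negative: excitable -> liberal)
    subject_dprime_sd: float = 0.30    # between-subject spread of d'
    subject_criterion_sd: float = 0.15
    no_response_rate: float = 0.02

    # peripheral channels
    cnap_gain: float = 10.0   # uV
    cmap_gain: float = 5.0    # mV
    cnap_noise_sd: float = 0.8
    cmap_noise_sd: float = 0.15
    cmap_percept_coupling: float = 0.0  # optional thumb-twitch -> percept path (off)

    # background noise
    noise_sd: float = 0.5  # uV per EEG channel (broadband 1/f)

    # measurement noise of the table-level fast path (emulates single-trial
    # extraction error of the rendered pipeline)
    n20_meas_noise_sd: float = 0.36   # uV
    alpha_log_meas_noise_sd: float = 0.29

    seed: int = 0

    def __post_init__(self):
        if self.pattern_sep is None:
            self.pattern_sep = tangential_dipole_pattern(self.n_channels)
        self.pattern_sep = np.asarray(self.pattern_sep, dtype=float)
        if self.pattern_alpha is None:
            self.pattern_alpha = self.pattern_sep.copy()
        self.pattern_alpha = np.asarray(self.pattern_alpha, dtype=float)
        self.validate()

    def validate(self):
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if not self.isi_low < self.isi_high:
            raise ValueError("need isi_low < isi_high")
        if abs(self.excitability_ar_coef) >= 1:
            raise ValueError("excitability AR(1) coefficient must satisfy |phi| < 1 (stationarity)")
        if np.linalg.norm(self.pattern_sep) == 0 or np.linalg.norm(self.pattern_alpha) == 0:
            raise ValueError("projection patterns must be non-zero")
        if set(self.intensity_levels) != {WEAK, STRONG}:
            raise ValueError("intensity_levels must have exactly 'weak' and 'strong' keys")
        for name in ("epsc_gain", "n_neurons_gain", "leadfield_gain", "noise_sd",
                     "observer_dprime", "excitability_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pattern_sep"] = np.asarray(d["pattern_sep"]).tolist()
        d["pattern_alpha"] = np.asarray(d["pattern_alpha"]).tolist()
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("pattern_sep", "pattern_alpha"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    @classmethod
    def from_yaml(cls, text_or_stream) -> "GeneratorConfig":
        if hasattr(text_or_stream, "read"):
            d = yaml.safe_load(text_or_stream)
        else:
            d = yaml.safe_load(io.StringIO(text_or_stream))
        return cls.from_dict(d)


@dataclass
class SyntheticDataset:
    """One fully rendered synthetic session plus its ground truth."""

    recording: Recording
    events: list                 # (sample, label)
    responses: np.ndarray        # per-trial 'weak' | 'strong' | 'none'
    latents: pd.DataFrame        # excitability, alpha_env, sep_gain, ...
    truth: GeneratorConfig

    def __post_init__(self):
        n = len(self.events)
        if not (len(self.responses) == len(self.latents) == n):
            raise ValueError("events, responses and latents must have equal length")
        labels = {lab for _, lab in self.events}
        if not labels <= {WEAK, STRONG}:
            raise ValueError("intensity labels must be 'weak' or 'strong'")
        if self.events and self.events[0][1] != WEAK:
            raise ValueError("first stimulus must be weak")


# ---------------------------------------------------------------------------
# stage 1: stimulus sequence
# ---------------------------------------------------------------------------

def generate_stimulus_sequence(config: GeneratorConfig, seed=None):
    """Pseudo-randomized two-intensity sequence with uniform ISIs.

    Returns ``(events, blocks)``: events are ``(sample_index, label)`` with
    exactly balanced weak/strong counts (|#strong - #weak| <= 1), the first
    stimulus weak, ISIs drawn uniformly from [isi_low, isi_high] ms, and a
    silent gap between consecutive blocks.  ``blocks`` gives the block index
    of every trial.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_trials
    n_strong = n // 2
    labels = np.array([WEAK] * (n - n_strong) + [STRONG] * n_strong, dtype=object)
    rng.shuffle(labels)
    # anchor: sequence starts with a weak stimulus
    if labels[0] != WEAK:
        j = int(np.nonzero(labels == WEAK)[0][0])
        labels[0], labels[j] = labels[j], labels[0]
    isis_ms = rng.uniform(config.isi_low, config.isi_high, size=n - 1)
    per_block = int(np.ceil(n / config.n_blocks))
    blocks = np.minimum(np.arange(n) // per_block, config.n_blocks - 1)
    onset_ms = np.empty(n)
    onset_ms[0] = 1000.0  # lead-in
    for t in range(1, n):
        gap = config.block_gap if blocks[t] != blocks[t - 1] else 0.0
        onset_ms[t] = onset_ms[t - 1] + isis_ms[t - 1] + gap
    samples = np.round(onset_ms * config.srate / 1000.0).astype(int)
    events = list(zip(samples.tolist(), labels.tolist()))
    return events, blocks


# ---------------------------------------------------------------------------
# stage 2: latent processes
# ---------------------------------------------------------------------------

def simulate_trial_latents(config: GeneratorConfig, events, seed=None) -> pd.DataFrame:
    """Per-trial latents: excitability AR(1), alpha envelope, SEP gain.

    * ``excitability`` follows a stationary AR(1) with coefficient
      ``excitability_ar_coef`` and stationary SD ``excitability_sd``.
    * ``alpha_env = exp(alpha_base_log + alpha_coupling * e + noise)`` —
      with the default negative coupling, excitable states carry low alpha.
    * ``sep_gain = epsc_gain * (1 + epsc_coupling * e) * n_neurons_gain *
      intensity_level * leadfield_gain`` — the voltage model with the
      post-synaptic current scale I(e) and the intensity-driven neuron count.
    """
    if abs(config.excitability_ar_coef) >= 1:
        raise ValueError("excitability AR(1) coefficient must satisfy |phi| < 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(events)
    phi, sd = config.excitability_ar_coef, config.excitability_sd
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    innov = rng.normal(0.0, innov_sd, size=n) if sd > 0 else np.zeros(n)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t]
    alpha_env = np.exp(config.alpha_base_log + config.alpha_coupling * e
                       + rng.normal(0.0, config.alpha_log_noise_sd, size=n))
    labels = np.array([lab for _, lab in events], dtype=object)
    level = np.array([config.intensity_levels[lab] for lab in labels])
    current_scale = config.epsc_gain * (1.0 + config.epsc_coupling * e)
    current_scale = np.maximum(current_scale, 0.05 * config.epsc_gain)
    sep_gain = current_scale * config.n_neurons_gain * level * config.leadfield_gain
    return pd.DataFrame({
        "trial": np.arange(n),
        "intensity": labels,
        "intensity_level": level,
        "excitability": e,
        "alpha_env": alpha_env,
        "epsc_current": current_scale,
        "sep_gain": sep_gain,
    })


# ---------------------------------------------------------------------------
# stage 3: rendering
# ---------------------------------------------------------------------------

def sep_template(srate: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit evoked waveform: negative extremum -1 at 20 ms, positive at 35 ms.

    Support is 5-80 ms post-stimulus (zero outside), emulating the N20-P35
    complex after 30-200 Hz band-pass filtering.
    """
    t = np.arange(0.0, 80.0 + 1000.0 / srate, 1000.0 / srate)
    w = (-np.exp(-((t - 20.0) / 3.5) ** 2)
         + 0.55 * np.exp(-((t - 35.0) / 6.0) ** 2))
    taper = np.clip((t - 5.0) / 5.0, 0, 1) * np.clip((80.0 - t) / 10.0, 0, 1)
    w = w * taper
    w = w / np.abs(w.min())
    return t, w


def cnap_template(srate: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit compound nerve action potential: positive peak at 7 ms (5-9 ms)."""
    t = np.arange(0.0, 15.0 + 1000.0 / srate, 1000.0 / srate)
    w = np.exp(-((t - 7.0) / 0.9) ** 2)
    return t, w / w.max()


def cmap_template(srate: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit biphasic muscle potential: negative peak ~8 ms, positive ~14 ms."""
    t = np.arange(0.0, 25.0 + 1000.0 / srate, 1000.0 / srate)
    w = -0.9 * np.exp(-((t - 8.0) / 1.5) ** 2) + np.exp(-((t - 14.0) / 2.5) ** 2)
    return t, w / np.abs(w).max()


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                srate: float) -> np.ndarray:
    """Spatially correlated 1/f noise, unit variance per channel."""
    n_fft = n_samples
    freqs = np.fft.rfftfreq(n_fft, 1.0 / srate)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    white = rng.standard_normal((n_channels, n_fft))
    spec = np.fft.rfft(white, axis=1) * scale
    pink = np.fft.irfft(spec, n=n_fft, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    # smooth spatial correlation from inter-channel distance on the sphere
    pos = fibonacci_sphere(n_channels)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2 * 0.8 ** 2))
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(n_channels))
    mixed = chol @ pink
    mixed /= mixed.std(axis=1, keepdims=True)
    return mixed


def render_recording(config: GeneratorConfig, events, latents: pd.DataFrame,
                     seed=None) -> Recording:
    """Render the continuous multichannel recording.

    EEG channels carry ``sep_gain_t x unit template`` projected through
    ``pattern_sep``, an 8-13 Hz oscillation whose per-trial pre-stimulus
    envelope follows ``alpha_env`` projected through ``pattern_alpha``, and
    spatially correlated 1/f background noise.  Two peripheral channels
    (CNAP in uV, CMAP in mV) scale with presented intensity only.
    """
    import warnings as _warnings
    rng = np.random.default_rng(config.seed if seed is None else seed)
    srate = config.srate
    samples = np.array([s for s, _ in events])
    n_total = int(samples[-1] + 1.0 * srate)  # 1 s tail
    if len(samples) > 1:
        shortest_isi = np.diff(samples).min() / srate * 1000.0
        if shortest_isi < 80.0:
            _warnings.warn("evoked template longer than shortest ISI: responses overlap")
    n_ch = config.n_channels
    eeg = np.zeros((n_ch, n_total))

    # evoked responses
    _, tmpl = sep_template(srate)
    gains = latents["sep_gain"].to_numpy()
    for s, g in zip(samples, gains):
        seg = eeg[:, s:s + tmpl.size]
        seg += np.outer(config.pattern_sep, g * tmpl[: seg.shape[1]])

    # alpha source: continuous narrowband noise, per-trial envelope modulation
    alpha_env = latents["alpha_env"].to_numpy()
    if np.any(alpha_env > 0):
        carrier = rng.standard_normal(n_total)
        sos = signal.butter(4, [8.0, 13.0], btype="bandpass", fs=srate, output="sos")
        carrier = signal.sosfiltfilt(sos, carrier)
        # amplitude-normalize: keep the random 8-13 Hz phase evolution but a
        # flat unit envelope, so the per-trial latent is exactly the realized
        # pre-stimulus amplitude (controlled ground truth for recovery tests)
        analytic = signal.hilbert(carrier)
        carrier = np.sqrt(2.0) * np.real(analytic / np.abs(analytic))
        carrier /= carrier.std()
        # envelope: step per trial segment, smoothed by a 100 ms moving average
        bounds = np.r_[0, (samples[:-1] + samples[1:]) // 2, n_total]
        mod = np.empty(n_total)
        for i in range(len(samples)):
            mod[bounds[i]:bounds[i + 1]] = alpha_env[i]
        k = max(int(0.1 * srate), 1)
        mod = np.convolve(mod, np.ones(k) / k, mode="same")
        eeg += np.outer(config.pattern_alpha, carrier * mod)

    # background noise
    if config.noise_sd > 0:
        eeg += config.noise_sd * _pink_noise(rng, n_ch, n_total, srate)

    # peripheral channels (intensity-dependent only)
    levels = latents["intensity_level"].to_numpy()
    cnap = np.zeros(n_total)
    cmap = np.zeros(n_total)
    _, wn = cnap_template(srate)
    _, wm = cmap_template(srate)
    for s, lv in zip(samples, levels):
        segn = cnap[s:s + wn.size]
        segn += config.cnap_gain * lv * wn[: segn.size]
        segm = cmap[s:s + wm.size]
        segm += config.cmap_gain * lv * wm[: segm.size]
    if config.cnap_noise_sd > 0:
        cnap = cnap + config.cnap_noise_sd * rng.standard_normal(n_total)
    if config.cmap_noise_sd > 0:
        cmap = cmap + config.cmap_noise_sd * rng.standard_normal(n_total)

    data = np.vstack([eeg, cnap[None, :], cmap[None, :]])
    names = [f"ch{i}" for i in range(n_ch)] + ["CNAP", "CMAP"]
    return Recording(data=data, srate=srate, ch_names=names, events=list(events))


# ---------------------------------------------------------------------------
# stage 4: the SDT observer
# ---------------------------------------------------------------------------

def simulate_responses(latents: pd.DataFrame, events, config: GeneratorConfig,
                       seed=None, dprime=None, criterion_base=None) -> np.ndarray:
    """Binary intensity reports from an equal-variance SDT observer.

    Internal evidence is ``d' * 1[strong] + N(0, 1)``; the report is
    "strong" when evidence exceeds ``d'/2 + c_t`` where the instantaneous
    criterion ``c_t = criterion_base + criterion_coupling * excitability_t``.
    Placing the neutral point at d'/2 makes the estimated SDT criterion c
    equal ``c_t`` on average.  A small fraction of trials receives no
    response ('none'), emulating missed button presses.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d = config.observer_dprime if dprime is None else dprime
    c0 = config.criterion_base if criterion_base is None else criterion_base
    e = latents["excitability"].to_numpy()
    is_strong = np.array([lab == STRONG for _, lab in events])
    evidence = d * is_strong + rng.standard_normal(len(events))
    if config.cmap_percept_coupling != 0.0 and "cmap_true" in latents:
        evidence = evidence + config.cmap_percept_coupling * latents["cmap_true"].to_numpy()
    threshold = d / 2.0 + c0 + config.criterion_coupling * e
    resp = np.where(evidence > threshold, STRONG, WEAK).astype(object)
    if config.no_response_rate > 0:
        resp[rng.random(len(events)) < config.no_response_rate] = "none"
    return resp


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------

def generate_experiment(config: GeneratorConfig, seed=None) -> SyntheticDataset:
    """Compose sequence -> latents -> rendering -> responses for one session."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_seq, s_lat, s_rec, s_resp = [s.generate_state(1)[0] % (2 ** 31) for s in root.spawn(4)]
    events, blocks = generate_stimulus_sequence(config, seed=s_seq)
    latents = simulate_trial_latents(config, events, seed=s_lat)
    latents["block"] = blocks
    recording = render_recording(config, events, latents, seed=s_rec)
    responses = simulate_responses(latents, events, config, seed=s_resp)
    latents = latents.assign(response=responses)
    return SyntheticDataset(recording=recording, events=events,
                            responses=responses, latents=latents, truth=config)


def simulate_subject_table(config: GeneratorConfig, seed, subject_id=0,
                           dprime=None, criterion_base=None) -> pd.DataFrame:
    """Trial-level table for one subject without rendering the EEG.

    Measured features are the generating latents plus independent Gaussian
    measurement noise (``n20_meas_noise_sd``, ``alpha_log_meas_noise_sd``),
    emulating the residual error of single-trial extraction from the
    rendered recording.  The signed N20 amplitude is ``-sep_gain`` (the unit
    template has extremum -1) plus noise; alpha is reported on the log scale.
    """
    root = np.random.SeedSequence(seed)
    s_seq, s_lat, s_resp, s_meas = [s.generate_state(1)[0] % (2 ** 31) for s in root.spawn(4)]
    events, blocks = generate_stimulus_sequence(config, seed=s_seq)
    latents = simulate_trial_latents(config, events, seed=s_lat)
    responses = simulate_responses(latents, events, config, seed=s_resp,
                                   dprime=dprime, criterion_base=criterion_base)
    rng = np.random.default_rng(s_meas)
    n = len(events)
    tbl = latents.copy()
    tbl["block"] = blocks
    tbl["subject"] = subject_id
    tbl["response"] = responses
    tbl["n20_amp"] = -tbl["sep_gain"] + rng.normal(0, config.n20_meas_noise_sd, n)
    tbl["alpha_log"] = (np.log(tbl["alpha_env"])
                        + rng.normal(0, config.alpha_log_meas_noise_sd, n))
    lvl = tbl["intensity_level"].to_numpy()
    tbl["cnap_amp"] = config.cnap_gain * lvl + rng.normal(0, config.cnap_noise_sd, n)
    tbl["cmap_amp"] = config.cmap_gain * lvl + rng.normal(0, config.cmap_noise_sd, n)
    tbl["valid"] = tbl["response"] != "none"
    return tbl


def simulate_study(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Multi-subject study at the trial-table level.

    Each subject gets an independent session seed plus subject-level draws of
    sensitivity (SD ``subject_dprime_sd``) and baseline criterion
    (SD ``subject_criterion_sd``) around the configured population values.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(config.n_subjects + 1)
    rng = np.random.default_rng(children[0].generate_state(1)[0] % (2 ** 31))
    tables = []
    for s in range(config.n_subjects):
        d_s = max(config.observer_dprime + rng.normal(0, config.subject_dprime_sd), 0.1)
        c_s = config.criterion_base + rng.normal(0, config.subject_criterion_sd)
        sub_seed = children[s + 1].generate_state(1)[0] % (2 ** 31)
        tables.append(simulate_subject_table(config, sub_seed, subject_id=s,
                                             dprime=d_s, criterion_base=c_s))
    return pd.concat(tables, ignore_index=True)
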