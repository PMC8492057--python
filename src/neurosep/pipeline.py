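"""End-to-end orchestration: simulate -> preprocess -> CCA -> features -> stats.

A run is driven by a :class:`RunConfig` and writes all artifacts plus a
manifest (config hash, seed, package version) into a run directory; the same
config and seed reproduce the trial table byte-identically.

The study-level statistics operate on per-trial feature tables.  By default
the first ``render_subjects`` subjects are pushed through the full
electrophysiological chain (continuous rendering, artifact interpolation,
filtering, epoching, CCA extraction, feature measurement) while the
remaining subjects use the generator's table-level fast path, which emulates
the extraction step with calibrated measurement noise.  This keeps
calibration studies with many synthetic subjects tractable without changing
the statistical structure the analysis sees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic_data import (GeneratorConfig, generate_experiment,
                             simulate_subject_table, STRONG)
from . import preprocess as pp
from . import cca as cca_mod
from . import features as feat
from . import sdt as sdt_mod
from . import inference as inf
from .io import save_dataset, save_trial_table, load_trial_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible pipeline run description."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    out_dir: str = "neurosep_run"
    render_subjects: int = 1        # subjects pushed through the full EEG chain
    sep_band: tuple = (30.0, 200.0)
    epoch_window: tuple = (-100.0, 600.0)
    cca_window: tuple = (5.0, 80.0)
    n20_search: tuple = (15.0, 30.0)
    alpha_band: tuple = (8.0, 13.0)
    alpha_segment: tuple = (-500.0, -5.0)
    alpha_average: tuple = (-200.0, -10.0)
    low_band: tuple = (0.5, 45.0)   # stream for the late (N140) component
    n140_window: tuple = (140.0, 160.0)
    n_perm: int = 100_000
    run_sdt: bool = True
    run_paths: bool = True
    save_recordings: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(
            {"generator": self.generator.to_dict(),
             **{f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                if f.name not in ("generator", "out_dir")}},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subject_seeds(seed: int, n: int):
    """Fan a global seed out into per-subject child seeds (< 2**31)."""
    root = np.random.SeedSequence(seed)
    return [c.generate_state(1)[0] % (2 ** 31) for c in root.spawn(n + 1)]


def process_rendered_subject(run: RunConfig, subject_id: int, seed: int,
                             dprime=None, criterion_base=None,
                             save_path=None) -> pd.DataFrame:
    """Full chain for one subject: render, preprocess, extract, measure."""
    cfg = run.generator
    dataset = generate_experiment(cfg, seed=seed)
    if dprime is not None or criterion_base is not None:
        from .synthetic_data import simulate_responses
        resp = simulate_responses(dataset.latents, dataset.events, cfg,
                                  seed=seed + 1, dprime=dprime,
                                  criterion_base=criterion_base)
        dataset.latents["response"] = resp
        dataset = dataclasses.replace(dataset, responses=resp)
    if save_path is not None:
        save_dataset(dataset, save_path)
    rec = dataset.recording
    srate = rec.srate

    rec = pp.interpolate_stimulus_artifact(rec)
    eeg_names = [n for n in rec.ch_names if n not in pp.PERIPHERAL_CHANNELS]
    raw_eeg = rec.pick(eeg_names)
    raw_eeg = pp.rereference_average(raw_eeg)

    # SEP stream: 30-200 Hz band-pass
    sep_rec = dataclasses.replace(
        raw_eeg, data=pp.zero_phase_bandpass(raw_eeg.data, *run.sep_band, srate))
    sep_epochs = pp.epoch_data(sep_rec, run.epoch_window)
    result = cca_mod.fit_template_cca(sep_epochs, window=run.cca_window)
    result = cca_mod.select_and_standardize(result,
                                            template_pattern=cfg.pattern_sep)
    comp = cca_mod.project_trials(sep_epochs, result)
    n20, n20_lat = feat.n20_peak_amplitude(comp, run.n20_search)

    # low-frequency stream for the late component
    low_rec = dataclasses.replace(
        raw_eeg, data=pp.zero_phase_bandpass(raw_eeg.data, *run.low_band, srate))
    low_epochs = pp.epoch_data(low_rec, run.epoch_window)
    comp_low = cca_mod.project_trials(low_epochs, result)
    n140 = feat.window_mean_amplitude(comp_low, run.n140_window)

    # pre-stimulus alpha from the raw (unfiltered) stream
    raw_epochs = pp.epoch_data(raw_eeg, (run.alpha_segment[0], 0.0))
    alpha = feat.prestimulus_alpha(raw_epochs, result.selected_filter(),
                                   band=run.alpha_band,
                                   segment=run.alpha_segment,
                                   average_window=run.alpha_average)

    # peripheral channels from the artifact-interpolated stream
    periph = pp.epoch_data(rec.pick(["CNAP"]), (-30.0, 40.0))
    periph_m = pp.epoch_data(rec.pick(["CMAP"]), (-30.0, 40.0))
    amps = feat.peripheral_amplitudes(cnap_epochs=periph, cmap_epochs=periph_m)

    tbl = dataset.latents.copy()
    tbl["subject"] = subject_id
    tbl["n20_amp"] = n20
    tbl["n20_latency"] = n20_lat
    tbl["n140_amp"] = n140
    tbl["alpha_log"] = alpha
    tbl["cnap_amp"] = amps["cnap"]
    tbl["cmap_amp"] = amps["cmap"]
    tbl["valid"] = tbl["response"] != "none"
    return tbl


def build_trial_table(run: RunConfig) -> pd.DataFrame:
    """Per-trial feature table for all subjects of the study."""
    cfg = run.generator
    seeds = _subject_seeds(run.seed, cfg.n_subjects)
    rng = np.random.default_rng(seeds[0])
    tables = []
    out = Path(run.out_dir)
    for s in range(cfg.n_subjects):
        d_s = max(cfg.observer_dprime + rng.normal(0, cfg.subject_dprime_sd), 0.1)
        c_s = cfg.criterion_base + rng.normal(0, cfg.subject_criterion_sd)
        if s < run.render_subjects:
            save_path = out / f"subject{s:02d}.h5" if run.save_recordings else None
            tbl = process_rendered_subject(run, s, seeds[s + 1], dprime=d_s,
                                           criterion_base=c_s, save_path=save_path)
        else:
            tbl = simulate_subject_table(cfg, seeds[s + 1], subject_id=s,
                                         dprime=d_s, criterion_base=c_s)
        tables.append(tbl)
    return pd.concat(tables, ignore_index=True)


def _estimate_to_dict(e: inf.EffectEstimate) -> dict:
    return {"outcome": e.outcome, "predictor": e.predictor, "beta": e.beta,
            "stat": e.stat, "df": e.df, "p": e.p, "ci_95": list(e.ci_95),
            "method": e.method, "note": e.note}


def _contrast_to_dict(c: sdt_mod.BinContrast) -> dict:
    return {"sort_var": c.sort_var, "measure": c.measure,
            "mean_low": c.mean_low, "mean_high": c.mean_high,
            "t": c.t, "df": c.df, "p": c.p, "cohens_d": c.cohens_d,
            "ci_95": list(c.ci_95)}


def analyze_trial_table(run: RunConfig, table: pd.DataFrame) -> dict:
    """SDT summaries, quintile contrasts and path estimates for a study table."""
    report = {"subjects": {}, "contrasts": {}, "paths": []}
    seeds = _subject_seeds(run.seed + 1, table["subject"].nunique())
    if run.run_sdt:
        for i, (sid, sub) in enumerate(table.groupby("subject")):
            valid = sub[sub["response"] != "none"]
            res = sdt_mod.rates_from_trials(valid["intensity"], valid["response"])
            acc = float((valid["intensity"] == valid["response"]).mean())
            p_perm = sdt_mod.permutation_accuracy_test(
                valid["intensity"].to_numpy(), valid["response"].to_numpy(),
                n_perm=run.n_perm, seed=seeds[i + 1])
            report["subjects"][int(sid)] = {
                "accuracy": acc, "d_prime": res.d_prime, "criterion_c": res.criterion_c,
                "hit_rate": res.hit_rate, "fa_rate": res.fa_rate,
                "p_permutation": p_perm,
                "p_permutation_bonferroni": min(1.0, p_perm * table["subject"].nunique()),
            }
        for sort_var in ("alpha_log", "n20_amp"):
            if sort_var not in table:
                continue
            for measure in ("criterion_c", "d_prime"):
                c = sdt_mod.extreme_bin_contrast(table, sort_var, measure)
                report["contrasts"][f"{sort_var}:{measure}"] = _contrast_to_dict(c)
    if run.run_paths:
        include_cmap = True
        paths = inf.two_stage_paths(table, include_cmap_path=include_cmap)
        report["paths"] = [_estimate_to_dict(e) for e in paths]
    accs = [v["accuracy"] for v in report["subjects"].values()]
    if accs:
        report["summary"] = {
            "mean_accuracy": float(np.mean(accs)),
            "mean_d_prime": float(np.mean([v["d_prime"] for v in report["subjects"].values()])),
            "mean_criterion_c": float(np.mean([v["criterion_c"] for v in report["subjects"].values()])),
        }
    return report


def run_pipeline(run: RunConfig, resume: bool = True) -> Path:
    """Execute the full pipeline; returns the run directory.

    With ``resume=True`` an existing trial table whose manifest hash matches
    the current configuration is reused (so toggling only the analysis
    stages does not regenerate the data).
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    trials_path = out / "trials.tsv"
    chash = run.config_hash()

    reuse = False
    if resume and manifest_path.exists() and trials_path.exists():
        old = json.loads(manifest_path.read_text())
        reuse = old.get("config_hash") == chash and old.get("seed") == run.seed
    if reuse:
        logger.info("reusing cached trial table (%s)", trials_path)
        table = load_trial_table(trials_path)
    else:
        table = build_trial_table(run)
        save_trial_table(table, trials_path)

    report = analyze_trial_table(run, table)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    manifest = {"config_hash": chash, "seed": run.seed, "version": __version__,
                "generator": run.generator.to_dict(),
                "n_trials_table": int(len(table))}
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out


def make_report(run_dir) -> str:
    """Human-readable summary of a finished run."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"no report.json in {run_dir}: empty or unfinished run")
    rep = json.loads(report_path.read_text())
    lines = [f"neurosep run: {run_dir}", ""]
    if rep.get("summary"):
        s = rep["summary"]
        lines += [f"mean accuracy      : {100 * s['mean_accuracy']:.2f}%",
                  f"mean d'            : {s['mean_d_prime']:.3f}",
                  f"mean criterion c   : {s['mean_criterion_c']:.3f}", ""]
    if rep.get("subjects"):
        lines.append("subject  acc     d'      c       p_perm(bonf)")
        for sid, v in rep["subjects"].items():
            lines.append(f"{sid:>7}  {100 * v['accuracy']:5.1f}%  {v['d_prime']:5.2f}  "
                         f"{v['criterion_c']:+.3f}  {v['p_permutation_bonferroni']:.4g}")
        lines.append("")
    if rep.get("contrasts"):
        lines.append("extreme-quintile contrasts (low vs high bin):")
        for key, c in rep["contrasts"].items():
            lines.append(f"  {key:<22} low={c['mean_low']:+.3f} high={c['mean_high']:+.3f} "
                         f"t({c['df']})={c['t']:+.2f} p={c['p']:.4g} d={c['cohens_d']:+.2f}")
        lines.append("")
    if rep.get("paths"):
        lines.append("effect paths (two-stage estimates):")
        for e in rep["paths"]:
            lines.append(f"  {e['outcome']:<14} ~ {e['predictor']:<14} "
                         f"beta={e['beta']:+.3f} p={e['p']:.3g} [{e['method']}]")
    return "\n".join(lines)
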