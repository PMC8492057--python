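"""Group-level effect estimation on single-trial tables.

Two complementary routes:

* :func:`fit_mixed_model` — linear mixed-effects models for continuous
  outcomes (random intercepts and, where stated, random slopes per subject),
  delegated to statsmodels' ``MixedLM``.  Degrees of freedom follow the
  normal approximation (flagged in the result).  Formulas with a binary
  outcome fall back to the two-stage route, since the host ecosystem offers
  no frequentist logit-link GLMM.
* :func:`two_stage_paths` — a desk-scale path analysis: each within-subject
  regression of the effect-path system is fitted per subject (logistic for
  the binary perceived intensity), and the per-subject coefficients are
  tested against zero with one-sample t-tests.  This two-stage
  summary-statistics approach approximates a multi-level path model; it is
  validated for effect *direction* and type-I calibration, not for
  reproducing multi-level path coefficients.

Continuous predictors are z-transformed within subject before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .features import zscore_within
from .synthetic_data import STRONG

logger = logging.getLogger(__name__)

CONTINUOUS_VARS = ("alpha_log", "n20_amp", "n140_amp", "cnap_amp", "cmap_amp", "p15_amp")

#: named model formulas (outcome, predictors, random slopes, binary flag)
MODEL_FORMULAS = {
    "n20~alpha": dict(outcome="n20_amp", predictors=["alpha_log"],
                      re_slopes=["alpha_log"], binary=False),
    "n20~alpha+intensity": dict(outcome="n20_amp",
                                predictors=["alpha_log", "intensity_num"],
                                re_slopes=["alpha_log"], binary=False),
    "perceived~p15+intensity": dict(outcome="perceived_num",
                                    predictors=["p15_amp", "intensity_num"],
                                    re_slopes=[], binary=True),
    "perceived~n140+intensity": dict(outcome="perceived_num",
                                     predictors=["n140_amp", "intensity_num"],
                                     re_slopes=["n140_amp", "intensity_num"],
                                     binary=True),
    "n140~intensity+alpha": dict(outcome="n140_amp",
                                 predictors=["intensity_num", "alpha_log"],
                                 re_slopes=["alpha_log"], binary=False),
    "intercept_only": dict(outcome="n20_amp", predictors=[],
                           re_slopes=[], binary=False),
}

#: the effect-path system: (outcome, predictors, binary outcome?)
PATH_SYSTEM = [
    ("n20_amp", ["intensity_num", "alpha_log"], False),
    ("cnap_amp", ["intensity_num"], False),
    ("cmap_amp", ["intensity_num"], False),
    ("perceived_num", ["intensity_num", "n20_amp", "alpha_log", "cmap_amp"], True),
]


@dataclass
class EffectEstimate:
    """One fixed-effect (or group-level) coefficient with its test."""

    predictor: str
    outcome: str
    beta: float
    stat: float
    df: float
    p: float
    ci_95: tuple
    method: str  # 'mixed_model' | 'two_stage'
    note: str = ""


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding and within-subject z-transform of continuous measures."""
    df = table.copy()
    df = df[df["response"] != "none"]
    if "valid" in df:
        df = df[df["valid"].astype(bool)]
    df["intensity_num"] = (df["intensity"] == STRONG).astype(float)
    df["perceived_num"] = (df["response"] == STRONG).astype(float)
    for col in CONTINUOUS_VARS:
        if col in df:
            df[col] = df.groupby("subject")[col].transform(
                lambda v: zscore_within(v.to_numpy())
                if v.std(ddof=1) > 0 else v)  # constants pass through
    return df.reset_index(drop=True)


def fit_mixed_model(trial_table: pd.DataFrame, formula_id: str,
                    predictor: str = None) -> EffectEstimate:
    """Fit a named mixed-effects formula and report one fixed effect.

    ``predictor`` defaults to the first predictor of the formula.  Binary
    outcomes (and non-converged fits) are delegated to the two-stage route
    with a logged downgrade.
    """
    if formula_id not in MODEL_FORMULAS:
        raise KeyError(f"unknown formula id {formula_id!r}; "
                       f"choose from {sorted(MODEL_FORMULAS)}")
    spec = MODEL_FORMULAS[formula_id]
    predictor = predictor or (spec["predictors"][0] if spec["predictors"]
                              else "Intercept")
    df = _prepare(trial_table)
    if df["subject"].nunique() < 5:
        raise ValueError("mixed model needs >= 5 subjects")
    if spec["binary"]:
        logger.info("%s: binary outcome -> two-stage logistic route", formula_id)
        return _two_stage_single(df, spec["outcome"], spec["predictors"],
                                 predictor, binary=True,
                                 note="binary outcome: two-stage logistic")
    formula = f"{spec['outcome']} ~ " + (" + ".join(spec["predictors"]) or "1")
    re_formula = "~" + " + ".join(spec["re_slopes"]) if spec["re_slopes"] else "~1"
    note = "normal-approximation p-value"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject"],
                                re_formula=re_formula)
            fit = model.fit(reml=True, method="lbfgs")
        usable = (np.isfinite(fit.params[predictor])
                  and np.isfinite(fit.bse[predictor]))
        if not fit.converged:
            # per-subject standardization puts the random-intercept variance
            # on the boundary; such singular fits are routine and usable
            boundary = np.linalg.eigvalsh(np.atleast_2d(fit.cov_re)).min() < 1e-3
            if usable and boundary:
                note += "; singular random-effects fit (variance on boundary)"
            else:
                raise RuntimeError("mixed model did not converge")
        elif not usable:
            raise RuntimeError("mixed model produced non-finite estimates")
    except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("%s: %s -> downgrading to two-stage", formula_id, exc)
        return _two_stage_single(df, spec["outcome"], spec["predictors"],
                                 predictor, binary=False,
                                 note=f"downgraded: {exc}")
    beta = float(fit.params[predictor])
    se = float(fit.bse[predictor])
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    ci = (beta - 1.96 * se, beta + 1.96 * se)
    return EffectEstimate(predictor=predictor, outcome=spec["outcome"],
                          beta=beta, stat=float(z), df=np.inf, p=float(p),
                          ci_95=ci, method="mixed_model", note=note)


def _fit_subject(sub: pd.DataFrame, outcome: str, predictors: list,
                 binary: bool) -> np.ndarray:
    """One within-subject regression; returns [intercept, *slopes]."""
    cols = sub[predictors].to_numpy() if predictors else np.empty((len(sub), 0))
    X = sm.add_constant(cols, has_constant="add")
    y = sub[outcome].to_numpy()
    if binary:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if np.any(np.abs(fit.params[1:]) > 15):
            raise np.linalg.LinAlgError("separation (divergent logistic coefficients)")
        return fit.params
    return sm.OLS(y, X).fit().params


def _two_stage_single(df: pd.DataFrame, outcome: str, predictors: list,
                      predictor: str, binary: bool, note: str = "") -> EffectEstimate:
    pos = 0 if predictor == "Intercept" else predictors.index(predictor) + 1
    coefs = []
    for sid, sub in df.groupby("subject"):
        try:
            coefs.append(_fit_subject(sub, outcome, predictors, binary)[pos])
        except np.linalg.LinAlgError as exc:
            logger.warning("subject %s excluded from path %s: %s", sid, outcome, exc)
    coefs = np.asarray(coefs, dtype=float)
    n = coefs.size
    beta = float(coefs.mean())
    if n < 2:
        warnings.warn("single subject: within-subject estimate, no group test")
        return EffectEstimate(predictor=predictor, outcome=outcome, beta=beta,
                              stat=np.nan, df=0, p=np.nan, ci_95=(np.nan, np.nan),
                              method="two_stage", note=note or "single subject")
    t, p = stats.ttest_1samp(coefs, 0.0)
    sem = coefs.std(ddof=1) / np.sqrt(n)
    ci = stats.t.interval(0.95, n - 1, loc=beta, scale=sem) if sem > 0 else (beta, beta)
    return EffectEstimate(predictor=predictor, outcome=outcome, beta=beta,
                          stat=float(t), df=n - 1, p=float(p), ci_95=tuple(ci),
                          method="two_stage", note=note)


def two_stage_paths(trial_table: pd.DataFrame, include_cmap_path: bool = True):
    """Fit the full effect-path system by the two-stage route.

    Paths: N20 ~ intensity + alpha; CNAP ~ intensity; CMAP ~ intensity;
    perceived ~ intensity + N20 + alpha + CMAP (logistic).  Returns one
    :class:`EffectEstimate` per (outcome, predictor) pair.
    """
    df = _prepare(trial_table)
    estimates = []
    for outcome, predictors, binary in PATH_SYSTEM:
        preds = list(predictors)
        if outcome == "perceived_num" and not include_cmap_path:
            preds.remove("cmap_amp")
        missing = [p for p in preds + [outcome] if p not in df]
        if missing:
            logger.warning("skipping path %s ~ %s: missing %s", outcome, preds, missing)
            continue
        for pred in preds:
            estimates.append(_two_stage_single(df, outcome, preds, pred, binary))
    return estimates


def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Within-subject standard errors of condition means (for figures).

    ``values`` is subjects x conditions with no missing cells.  Each
    subject's mean is removed (and the grand mean restored) before computing
    per-condition SD/sqrt(n); the result is scaled by sqrt(k/(k-1)) for k
    conditions to undo the variance bias of the centering.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, >= 2 of each")
    if np.any(~np.isfinite(v)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = v.shape
    centered = v - v.mean(axis=1, keepdims=True) + v.mean()
    se = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return se * np.sqrt(k / (k - 1))
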