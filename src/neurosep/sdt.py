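"""Signal detection theory estimation and quintile-binning contrasts.

Equal-variance Gaussian SDT: sensitivity ``d' = Phi^-1(hit) - Phi^-1(fa)``
and response bias ``c = -0.5 (Phi^-1(hit) + Phi^-1(fa))``, where the hit
rate is p(report strong | strong stimulus) and the false-alarm rate
p(report strong | weak stimulus).  Positive c is a bias toward reporting
"weak".  The binning machinery sorts trials by an electrophysiological
variable and contrasts the SDT measures between the lowest and highest
quantile bins across subjects with a paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import WEAK, STRONG


@dataclass
class SDTResult:
    """Hit/false-alarm rates with derived sensitivity and bias."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    n_strong: int
    n_weak: int
    corrected: bool = False


@dataclass
class BinContrast:
    """Group-level contrast of an SDT measure between extreme bins."""

    sort_var: str
    measure: str
    low_values: np.ndarray    # per-subject value in the lowest bin
    high_values: np.ndarray   # per-subject value in the highest bin
    t: float
    df: int
    p: float
    cohens_d: float
    ci_95: tuple              # CI of mean(high - low)
    bin_fraction: float = 0.2

    @property
    def mean_low(self) -> float:
        return float(np.mean(self.low_values))

    @property
    def mean_high(self) -> float:
        return float(np.mean(self.high_values))


def rates_from_trials(stimuli, responses):
    """Empirical hit and false-alarm rates with extreme-rate correction.

    Rates of exactly 0 or 1 are replaced by ``1/(2N)`` and ``1 - 1/(2N)``
    (N = trials in that stimulus category) so the normal quantile stays
    finite; the returned result flags whether the correction fired.
    Trials with response 'none' are excluded.
    """
    stimuli = np.asarray(stimuli, dtype=object)
    responses = np.asarray(responses, dtype=object)
    keep = responses != "none"
    stimuli, responses = stimuli[keep], responses[keep]
    n_strong = int(np.sum(stimuli == STRONG))
    n_weak = int(np.sum(stimuli == WEAK))
    for n, name in ((n_strong, STRONG), (n_weak, WEAK)):
        if n == 0:
            raise ValueError(f"no '{name}' stimulus trials with a response")
    hit = np.sum((stimuli == STRONG) & (responses == STRONG)) / n_strong
    fa = np.sum((stimuli == WEAK) & (responses == STRONG)) / n_weak
    corrected = False

    def _fix(rate, n):
        nonlocal corrected
        if rate == 0.0:
            corrected = True
            return 1.0 / (2 * n)
        if rate == 1.0:
            corrected = True
            return 1.0 - 1.0 / (2 * n)
        return rate

    hit, fa = _fix(hit, n_strong), _fix(fa, n_weak)
    d, c = d_prime_and_criterion(hit, fa)
    return SDTResult(hit_rate=hit, fa_rate=fa, d_prime=d, criterion_c=c,
                     n_strong=n_strong, n_weak=n_weak, corrected=corrected)


def d_prime_and_criterion(hit: float, fa: float):
    """d' and criterion c from hit and false-alarm rates in (0, 1)."""
    if not (0.0 < hit < 1.0 and 0.0 < fa < 1.0):
        raise ValueError("rates must lie strictly in (0, 1); "
                         "use rates_from_trials for the extreme-rate correction")
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(fa)
    return zh - zf, -0.5 * (zh + zf)


def cohens_d_paired(differences) -> float:
    """Paired-samples effect size: mean(diff) / sd(diff) (n-1 denominator)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: effect size undefined")
    return float(d.mean() / sd)


def extreme_bin_contrast(trial_table: pd.DataFrame, sort_var: str,
                         measure: str = "criterion_c",
                         bin_fraction: float = 0.2) -> BinContrast:
    """Contrast an SDT measure between the extreme bins of a sorted variable.

    Per subject, valid trials are stable-sorted by ``sort_var`` (original
    trial order breaks ties); the lowest and highest ``floor(n*bin_fraction)``
    trials form the extreme bins, in which the SDT measure (``'d_prime'`` or
    ``'criterion_c'``) is estimated.  Group level: paired t-test of
    high-vs-low across subjects, paired Cohen's d, and a 95% CI of the mean
    difference.
    """
    if measure not in ("d_prime", "criterion_c"):
        raise ValueError("measure must be 'd_prime' or 'criterion_c'")
    lows, highs = [], []
    for _, sub in trial_table.groupby("subject", sort=True):
        valid = sub[sub["response"] != "none"]
        if "valid" in valid:
            valid = valid[valid["valid"].astype(bool)]
        n = len(valid)
        if n < 50:
            raise ValueError("need >= 50 valid trials per subject for binning")
        order = valid.sort_values(sort_var, kind="stable")
        k = int(np.floor(n * bin_fraction))
        for bin_df, store in ((order.iloc[:k], lows), (order.iloc[-k:], highs)):
            res = rates_from_trials(bin_df["intensity"], bin_df["response"])
            if res.corrected:
                warnings.warn("extreme-rate correction applied inside a bin")
            store.append(getattr(res, measure))
    low, high = np.asarray(lows), np.asarray(highs)
    diff = high - low
    t, p = stats.ttest_rel(high, low)
    n_sub = diff.size
    sem = diff.std(ddof=1) / np.sqrt(n_sub)
    ci = stats.t.interval(0.95, n_sub - 1, loc=diff.mean(), scale=sem) if sem > 0 \
        else (diff.mean(), diff.mean())
    return BinContrast(sort_var=sort_var, measure=measure, low_values=low,
                       high_values=high, t=float(t), df=n_sub - 1, p=float(p),
                       cohens_d=cohens_d_paired(diff), ci_95=tuple(ci),
                       bin_fraction=bin_fraction)


def permutation_accuracy_test(stimuli, responses, n_perm: int = 100_000,
                              seed=None, family_size: int = None,
                              add_one: bool = False):
    """Permutation p-value for above-chance discrimination accuracy.

    The null distribution arises from randomly remapping responses to
    stimuli ``n_perm`` times; ``p`` is the proportion of surrogate
    accuracies strictly greater than the observed one (``add_one`` switches
    to the (b+1)/(n+1) estimator).  Since a random remapping's accuracy
    depends only on how many 'strong' responses land on 'strong' stimuli,
    surrogates are drawn from the equivalent hypergeometric distribution.
    Trials with response 'none' are excluded.  With ``family_size`` a
    Bonferroni-adjusted p is returned alongside.
    """
    stimuli = np.asarray(stimuli, dtype=object)
    responses = np.asarray(responses, dtype=object)
    if stimuli.shape != responses.shape:
        raise ValueError("stimuli and responses must have equal length")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-value will be very coarse")
    keep = responses != "none"
    stimuli, responses = stimuli[keep], responses[keep]
    n = stimuli.size
    n_strong_stim = int(np.sum(stimuli == STRONG))
    n_strong_resp = int(np.sum(responses == STRONG))
    observed = int(np.sum(stimuli == responses))
    rng = np.random.default_rng(seed)
    # matches = 2k + n - n_strong_stim - n_strong_resp, k ~ Hypergeometric
    k = rng.hypergeometric(n_strong_stim, n - n_strong_stim, n_strong_resp,
                           size=n_perm)
    surrogate = 2 * k + n - n_strong_stim - n_strong_resp
    greater = int(np.sum(surrogate > observed))
    p = (greater + 1) / (n_perm + 1) if add_one else greater / n_perm
    if family_size is not None:
        return p, min(1.0, p * family_size)
    return p
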