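"""Behavioral statistics: RT filtering, SDT categorization, Bayesian
bootstrap, and correlation reporting.

Operates on the tidy per-trial table produced by :mod:`contourpass.cohort`
(or real data in the same schema): one row per trial with columns
``subject_id, group, block, pass_index, trial_index, noise_level,
stimulus_class, response, correct, rt_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)

#: RT outlier bounds in seconds; values *strictly* outside are excluded,
#: so the boundary values themselves are retained.
RT_LOW = 0.25
RT_HIGH = 4.0

#: Default number of Bayesian-bootstrap posterior draws.
N_BOOT_DRAWS = 4000


# ---------------------------------------------------------------------------
# RT filtering
# ---------------------------------------------------------------------------

def filter_rt(trials: pd.DataFrame, lo: float = RT_LOW, hi: float = RT_HIGH
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude RT outliers: keep trials with ``lo <= rt_s <= hi``.

    Returns (filtered trials, per-subject exclusion log with columns
    ``subject_id, n_total, n_excluded, fraction_excluded``).
    """
    if "rt_s" not in trials.columns:
        raise InvalidArgumentError("trial table lacks an rt_s column")
    keep = (trials["rt_s"] >= lo) & (trials["rt_s"] <= hi)
    log = (trials.assign(_excluded=~keep)
           .groupby("subject_id", as_index=False)
           .agg(n_total=("_excluded", "size"), n_excluded=("_excluded", "sum")))
    log["fraction_excluded"] = log["n_excluded"] / log["n_total"]
    return trials[keep].copy(), log


# ---------------------------------------------------------------------------
# signal detection categorization
# ---------------------------------------------------------------------------

def sdt_categorize(trials: pd.DataFrame) -> pd.DataFrame:
    """Hit / miss / false-alarm / correct-rejection counts per subject and
    noise level, with percentages relative to the class trial counts."""
    t = trials
    is_signal = t["stimulus_class"] == "signal"
    said_yes = t["response"] == "yes"
    cat = np.where(is_signal, np.where(said_yes, "hits", "misses"),
                   np.where(said_yes, "false_alarms", "correct_rejections"))
    counts = (t.assign(_cat=cat)
              .groupby(["subject_id", "noise_level", "_cat"])
              .size().unstack("_cat", fill_value=0).reset_index())
    for col in ("hits", "misses", "false_alarms", "correct_rejections"):
        if col not in counts:
            counts[col] = 0
    n_signal = counts["hits"] + counts["misses"]
    n_noise = counts["false_alarms"] + counts["correct_rejections"]
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["hit_pct"] = 100.0 * counts["hits"] / n_signal
        counts["miss_pct"] = 100.0 * counts["misses"] / n_signal
        counts["fa_pct"] = 100.0 * counts["false_alarms"] / n_noise
        counts["cr_pct"] = 100.0 * counts["correct_rejections"] / n_noise
    return counts


def dprime_criterion(counts: pd.DataFrame, loglinear: bool = True
                     ) -> pd.DataFrame:
    """Optional d' and criterion c per row of an SDT count table.

    Uses the log-linear correction (add 0.5 to each cell) by default so
    perfect scores stay finite.
    """
    h, m = counts["hits"].to_numpy(float), counts["misses"].to_numpy(float)
    f = counts["false_alarms"].to_numpy(float)
    c = counts["correct_rejections"].to_numpy(float)
    if loglinear:
        h, m, f, c = h + 0.5, m + 0.5, f + 0.5, c + 0.5
    zh = stats.norm.ppf(h / (h + m))
    zf = stats.norm.ppf(f / (f + c))
    out = counts.copy()
    out["d_prime"] = zh - zf
    out["criterion_c"] = -0.5 * (zh + zf)
    return out


# ---------------------------------------------------------------------------
# Bayesian bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootResult:
    """Posterior summary of one statistic under the Bayesian bootstrap."""

    statistic: str
    draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def bayes_boot(values, statistic: str = "mean", n_draws: int = N_BOOT_DRAWS,
               rng: np.random.Generator | None = None) -> BootResult:
    """Bayesian bootstrap of a location statistic.

    Each posterior draw weights the n observations with a flat
    Dirichlet(1, ..., 1) vector and evaluates the weighted statistic
    ("mean" or "median"); the credible interval is the 2.5/97.5 percentile
    band of the draws.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            "Bayesian bootstrap needs at least 2 observations")
    if statistic not in ("mean", "median"):
        raise InvalidArgumentError(f"unsupported statistic {statistic!r}")
    rng = rng if rng is not None else np.random.default_rng()
    weights = rng.dirichlet(np.ones(values.size), size=n_draws)
    if statistic == "mean":
        draws = weights @ values
    else:
        draws = np.array([_weighted_median(values, w) for w in weights])
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootResult(statistic=statistic, draws=draws,
                      median=float(np.median(draws)),
                      ci_low=float(lo), ci_high=float(hi))


def boot_compare(a: BootResult, b: BootResult) -> float:
    """Posterior probability that the statistic of A exceeds that of B,
    from paired comparison of the (independent) posterior draws."""
    n = min(a.draws.size, b.draws.size)
    return float(np.mean(a.draws[:n] > b.draws[:n]))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson_ci(x, y, conf: float = 0.95) -> dict:
    """Pearson r with Fisher-z confidence interval and t-test p value.

    Reported df is n - 2, matching the r(df) reporting convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("correlation needs at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance input")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) < 1.0:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = 0.0
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / np.sqrt(n - 3)
    zcrit = float(stats.norm.ppf(0.5 + conf / 2.0))
    return dict(r=r, ci_low=float(np.tanh(z - zcrit * zse)),
                ci_high=float(np.tanh(z + zcrit * zse)), p=p, df=df, n=n)


# ---------------------------------------------------------------------------
# accuracy / RT summaries
# ---------------------------------------------------------------------------

def accuracy_by_subject(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per subject x noise level (tidy)."""
    return (trials.groupby(["subject_id", "group", "noise_level"],
                           as_index=False)
            .agg(n_trials=("correct", "size"), prop_correct=("correct", "mean")))


def summarize_accuracy(trials: pd.DataFrame, n_draws: int = N_BOOT_DRAWS,
                       rng: np.random.Generator | None = None) -> dict:
    """Group medians of subject-level accuracy with bootstrap CIs per level.

    The bootstrap resamples subject-level summaries (one value per subject),
    matching per-participant group figures; returns the subject table, the
    group summary, and the per-level posterior probability that the first
    group (alphabetically) exceeds the second.
    """
    rng = rng if rng is not None else np.random.default_rng()
    subj = accuracy_by_subject(trials)
    groups = sorted(subj["group"].unique())
    rows, prob = [], {}
    for lv, g_lv in subj.groupby("noise_level"):
        boots = {}
        for grp, g in g_lv.groupby("group"):
            b = bayes_boot(g["prop_correct"].to_numpy(), "median",
                           n_draws=n_draws, rng=rng)
            boots[grp] = b
            rows.append(dict(group=grp, noise_level=lv,
                             median=float(np.median(g["prop_correct"])),
                             boot_median=b.median, ci_low=b.ci_low,
                             ci_high=b.ci_high, n_subjects=len(g)))
        if len(groups) == 2 and all(g in boots for g in groups):
            prob[lv] = boot_compare(boots[groups[0]], boots[groups[1]])
    return dict(by_subject=subj, summary=pd.DataFrame(rows),
                p_first_greater=prob)


def rt_by_subject(trials: pd.DataFrame) -> pd.DataFrame:
    """Median RT per subject x noise level (apply filter_rt first)."""
    return (trials.groupby(["subject_id", "group", "noise_level"],
                           as_index=False)
            .agg(n_trials=("rt_s", "size"), median_rt=("rt_s", "median")))


def summarize_rt(trials: pd.DataFrame, n_draws: int = N_BOOT_DRAWS,
                 rng: np.random.Generator | None = None) -> dict:
    """Group medians of subject-level median RT with bootstrap CIs."""
    rng = rng if rng is not None else np.random.default_rng()
    subj = rt_by_subject(trials)
    groups = sorted(subj["group"].unique())
    rows, prob = [], {}
    for lv, g_lv in subj.groupby("noise_level"):
        boots = {}
        for grp, g in g_lv.groupby("group"):
            b = bayes_boot(g["median_rt"].to_numpy(), "median",
                           n_draws=n_draws, rng=rng)
            boots[grp] = b
            rows.append(dict(group=grp, noise_level=lv,
                             median=float(np.median(g["median_rt"])),
                             boot_median=b.median, ci_low=b.ci_low,
                             ci_high=b.ci_high, n_subjects=len(g)))
        if len(groups) == 2 and all(g in boots for g in groups):
            prob[lv] = boot_compare(boots[groups[0]], boots[groups[1]])
    return dict(by_subject=subj, summary=pd.DataFrame(rows),
                p_first_greater=prob)
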