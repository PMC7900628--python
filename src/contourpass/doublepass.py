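"""Double-pass agreement/accuracy analysis and internal-noise estimation.

In a double-pass experiment the identical stimulus sequence is shown twice.
The pair (percent agreement pa between the two passes, percent correct pc
pooled over both) separates stimulus-driven from internally driven response
variability.  Two summaries are provided:

* the comparative log-linear index ``pc = m * log10(pa / 100) + 100`` fitted
  through the fixed point (pa, pc) = (100, 100) -- implemented exactly as
  printed, on the percent scale; and
* a quantitative observer-model estimator: a linear-amplifier observer with
  external noise SD fixed at 1, signal offset d, criterion gamma = d/2, and
  internal/external noise ratio r = sigma_i / sigma_e.  Its exact (pc, pa)
  predictions use the bivariate normal orthant probability (Owen's T), and
  the inverse map recovers (d, r) from an observed (pc, pa) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import owens_t

from .errors import (
    AlignmentError,
    DegenerateFitError,
    FeasibilityError,
    InvalidArgumentError,
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DoublePassPoint:
    """Per-participant (pa, pc) pair at one noise level."""

    subject_id: str
    group: str
    noise_level: float
    pa: float          # percent agreement between passes, 0..100
    pc: float          # percent correct pooled over both passes, 0..100
    n_trials: int      # trials per pass


@dataclass
class SlopeFit:
    """One-parameter regression through the fixed point (100, 100)."""

    group: str
    noise_level: float
    m: float
    se: float
    ci_low: float
    ci_high: float
    n_points: int

    def predict(self, pa) -> np.ndarray:
        """Predicted percent correct at percent agreement ``pa``."""
        pa = np.asarray(pa, dtype=float)
        out = self.m * np.log10(pa / 100.0) + 100.0
        return float(out) if out.ndim == 0 else out


@dataclass
class LamModel:
    """Linear-amplifier observer: sigma_e = 1, signal offset d, ratio r."""

    d: float
    r: float
    gamma: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise InvalidArgumentError("noise ratio r must be >= 0")


# ---------------------------------------------------------------------------
# agreement / accuracy
# ---------------------------------------------------------------------------

def predict_accuracy_from_agreement(pa, m: float):
    """The log-linear relation ``pc = m * log10(pa/100) + 100`` (percent)."""
    pa = np.asarray(pa, dtype=float)
    out = m * np.log10(pa / 100.0) + 100.0
    return float(out) if out.ndim == 0 else out


def agreement_and_accuracy(pass1: pd.DataFrame, pass2: pd.DataFrame
                           ) -> DoublePassPoint:
    """Compute (pa, pc) from two matched passes of one subject at one level.

    Trials are aligned on (noise_level, trial_index); pa is the percentage
    of trials with identical responses, pc the percentage of correct
    responses pooled over both passes.
    """
    keys = ["noise_level", "trial_index"]
    p1 = pass1.sort_values(keys).reset_index(drop=True)
    p2 = pass2.sort_values(keys).reset_index(drop=True)
    if len(p1) != len(p2) or len(p1) == 0:
        raise AlignmentError(
            f"pass trial counts differ ({len(p1)} vs {len(p2)}) or are empty")
    if not (p1[keys].values == p2[keys].values).all():
        raise AlignmentError("pass-1 and pass-2 trial sets do not match")
    if not (p1["stimulus_class"].values == p2["stimulus_class"].values).all():
        raise AlignmentError("stimulus classes differ between passes")
    n = len(p1)
    same = (p1["response"].values == p2["response"].values).sum()
    n_correct = p1["correct"].values.sum() + p2["correct"].values.sum()
    sid = str(p1["subject_id"].iloc[0]) if "subject_id" in p1 else ""
    grp = str(p1["group"].iloc[0]) if "group" in p1 else ""
    return DoublePassPoint(
        subject_id=sid, group=grp,
        noise_level=float(p1["noise_level"].iloc[0]),
        pa=100.0 * same / n, pc=100.0 * n_correct / (2 * n), n_trials=n)


def doublepass_points(trials: pd.DataFrame) -> list[DoublePassPoint]:
    """All per-subject (pa, pc) points at the repeated noise levels."""
    points = []
    for (sid, lv), g in trials.groupby(["subject_id", "noise_level"]):
        passes = set(g["pass_index"])
        if passes != {1, 2}:
            continue
        points.append(agreement_and_accuracy(
            g[g["pass_index"] == 1], g[g["pass_index"] == 2]))
    return points


# ---------------------------------------------------------------------------
# agreement/accuracy slope fit and comparison
# ---------------------------------------------------------------------------

def fit_agreement_slope(points: list[DoublePassPoint], group: str = "",
                  noise_level: float = float("nan")) -> SlopeFit:
    """Least squares for ``pc = m log10(pa/100) + 100`` through (100, 100).

    With x = log10(pa/100) and y = pc - 100 the slope is m = sum(xy)/sum(x^2);
    its standard error comes from the one-parameter regression with n - 1
    residual degrees of freedom, and the 95% CI from the t distribution.
    """
    pts = [p for p in points]
    if not pts:
        raise DegenerateFitError("no points to fit")
    x = np.log10(np.array([p.pa for p in pts]) / 100.0)
    y = np.array([p.pc for p in pts]) - 100.0
    informative = np.abs(x) > 0
    if informative.sum() < 1 or np.sum(x ** 2) == 0:
        raise DegenerateFitError(
            "all points have pa = 100; the slope is unidentified")
    m = float(np.sum(x * y) / np.sum(x ** 2))
    n = len(pts)
    resid = y - m * x
    df = n - 1
    if df > 0 and np.sum(resid ** 2) > 0:
        s2 = float(np.sum(resid ** 2) / df)
        se = float(np.sqrt(s2 / np.sum(x ** 2)))
        tcrit = float(stats.t.ppf(0.975, df))
    else:
        se, tcrit = 0.0, 0.0
    return SlopeFit(group=group, noise_level=noise_level, m=m, se=se,
                  ci_low=m - tcrit * se, ci_high=m + tcrit * se, n_points=n)


def compare_slopes(fit_a: SlopeFit, fit_b: SlopeFit) -> dict:
    """Welch t test on the difference of two independently fitted slopes."""
    if fit_a.se == 0 and fit_b.se == 0:
        raise DegenerateFitError("both slopes have zero standard error")
    if fit_a.m == fit_b.m and fit_a.se == fit_b.se:
        # identical fits: difference is exactly zero
        return dict(t_ratio=0.0, df=float(fit_a.n_points + fit_b.n_points - 2),
                    p=1.0, diff=0.0)
    va, vb = fit_a.se ** 2, fit_b.se ** 2
    dfa, dfb = fit_a.n_points - 1, fit_b.n_points - 1
    t = (fit_a.m - fit_b.m) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / dfa + vb ** 2 / dfb)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return dict(t_ratio=float(t), df=float(df), p=p,
                diff=float(fit_a.m - fit_b.m))


# ---------------------------------------------------------------------------
# linear-amplifier model predictions and inversion
# ---------------------------------------------------------------------------

def _phi2_equal(a: float, rho: float) -> float:
    """P(Z1 <= a, Z2 <= a) for standard bivariate normal with correlation rho,
    via the exact Owen's-T identity (abs error well below 1e-6)."""
    if rho >= 1.0:
        return float(stats.norm.cdf(a))
    k = np.sqrt((1.0 - rho) / (1.0 + rho))
    return float(stats.norm.cdf(a) - 2.0 * owens_t(a, k))


def lam_predict(model: LamModel) -> dict:
    """Exact expected (pc, pa) in percent for the LAM observer.

    Per class c with mean mu_c (d for signal, 0 for noise), a single pass
    answers yes with probability Phi(a_c), a_c = (mu_c - gamma)/sqrt(1+r^2);
    the two passes share the frozen external noise, so their decision
    variables correlate at rho = 1/(1+r^2) and
    P(both yes) = Phi2(a_c, a_c; rho).
    """
    r, d, gamma = model.r, model.d, model.gamma
    scale = np.sqrt(1.0 + r * r)
    rho = 1.0 / (1.0 + r * r)
    pa_acc = 0.0
    p_yes = {}
    for cls, mu in (("signal", d), ("noise", 0.0)):
        a = (mu - gamma) / scale
        p_yes[cls] = float(stats.norm.cdf(a))
        both_yes = _phi2_equal(a, rho)
        both_no = _phi2_equal(-a, rho)
        pa_acc += 0.5 * (both_yes + both_no)
    pc = 50.0 * (p_yes["signal"] + 1.0 - p_yes["noise"])
    return dict(expected_pc=pc, expected_pa=100.0 * pa_acc)


def _pa_for(h: float, rho: float) -> float:
    """Expected pa (fraction of 100) for half-separation h and correlation rho."""
    return 100.0 * (_phi2_equal(h, rho) + _phi2_equal(-h, rho))


def estimate_sigma_ratio(point: DoublePassPoint) -> dict:
    """Invert the LAM: recover (d, r) from an observed (pc, pa) pair.

    Assumes an unbiased criterion gamma = d/2, under which
    pc = 100 * Phi(h) with h = (d/2)/sqrt(1+r^2), so pc fixes h directly and
    pa is solved for rho = 1/(1+r^2) by bracketed root finding.
    """
    pc, pa = point.pc, point.pa
    if not (50.0 < pc < 100.0):
        raise FeasibilityError(
            f"pc = {pc:.2f} outside (50, 100): the unbiased LAM cannot "
            "represent at- or below-chance accuracy")
    if pa >= 100.0:
        return dict(r_hat=0.0, d_hat=2.0 * stats.norm.ppf(pc / 100.0),
                    converged=True)
    h = float(stats.norm.ppf(pc / 100.0))
    pa_floor = _pa_for(h, 0.0)    # r -> infinity: passes independent
    if pa < pa_floor:
        raise FeasibilityError(
            f"pa = {pa:.2f} below the independence floor {pa_floor:.2f} "
            f"implied by pc = {pc:.2f}")
    f = lambda rho: _pa_for(h, rho) - pa
    lo, hi = 1e-12, 1.0 - 1e-12
    if f(hi) < 0:                 # pa above the r=0 ceiling (pa ~ 100)
        return dict(r_hat=0.0, d_hat=2.0 * h, converged=True)
    if f(lo) > 0:
        raise FeasibilityError("pa at or below the independence floor")
    rho = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    r = float(np.sqrt(1.0 / rho - 1.0))
    d = float(2.0 * h * np.sqrt(1.0 + r * r))
    return dict(r_hat=r, d_hat=d, converged=True)


def sigma_ratio_table(points: list[DoublePassPoint]) -> pd.DataFrame:
    """Per-point LAM estimates; infeasible points are flagged, not dropped."""
    rows = []
    for p in points:
        row = dict(subject_id=p.subject_id, group=p.group,
                   noise_level=p.noise_level, pa=p.pa, pc=p.pc,
                   n_trials=p.n_trials, r_hat=np.nan, d_hat=np.nan,
                   feasible=False)
        try:
            est = estimate_sigma_ratio(p)
            row.update(r_hat=est["r_hat"], d_hat=est["d_hat"], feasible=True)
        except FeasibilityError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_doublepass(trials: pd.DataFrame) -> dict:
    """Full double-pass analysis of a trial table.

    Returns per-subject points, per group-by-level slope fits, the slope
    comparisons between groups at each repeated level, and LAM estimates.
    """
    points = doublepass_points(trials)
    levels = sorted({p.noise_level for p in points})
    groups = sorted({p.group for p in points})
    fits = {}
    for g in groups:
        for lv in levels:
            sel = [p for p in points if p.group == g and p.noise_level == lv]
            if sel:
                fits[(g, lv)] = fit_agreement_slope(sel, group=g, noise_level=lv)
    comparisons = {}
    if len(groups) == 2:
        ga, gb = groups
        for lv in levels:
            if (ga, lv) in fits and (gb, lv) in fits:
                comparisons[lv] = compare_slopes(fits[(ga, lv)],
                                                 fits[(gb, lv)])
    return dict(points=points, fits=fits, comparisons=comparisons,
                sigma_ratios=sigma_ratio_table(points))
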