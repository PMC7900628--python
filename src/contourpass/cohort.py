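"""Synthetic observer cohort: behavioral responses, reaction times, gaze.

The cohort emulates a two-group contour-detection study (an ASD-like and a
TD-like group, default sizes 24 and 32) so that every downstream analysis has
data with the statistical structure it assumes.  Each subject is a
linear-amplifier-style observer operating on element *orientations* (never
pixels): a template statistic is computed over the contour positions and
their adjacent background positions, corrupted by additive plus
stimulus-dependent internal Gaussian noise, and thresholded at a criterion.

Three decision channels are available:

``"channel"`` (default)
    Two bandwidth-limited orientation channels centered on the known jitter
    orientations 60 +/- delta (the blocked design fixes delta within a
    block), each a circular-Gaussian tuning curve; every template element
    contributes its best channel response.  A collinearity (good
    continuation) term -- the mean axial alignment of consecutive contour
    positions -- is added with a small weight.  The collinearity of a
    jittered contour depends on the random +/- assignment, which gives
    signal trials genuine stimulus-driven (external) variability that grows
    with delta and is frozen across double-pass repeats.

``"matched"``
    The same two-template idea with raw cosine similarity,
    ``max(cos 2(theta - 60 -/+ delta))``, and no collinearity term.

``"cosine"``
    The plain statistic ``sum w cos 2(theta - 60) / sum w``.  Because the
    balanced +/-45 deg jitter makes the two class means coincide, this
    channel is at exact chance at delta = 45 and below chance beyond; it is
    kept for diagnostics and for studying that regime.

All generative RT and gaze parameters are stand-ins with the qualitative
structure of the study (group RT offset, noise-dependent slowing, larger and
noise-dependent gaze dispersion in the ASD-like group); they are not
estimates of any real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stimulus as st
from .errors import InvalidArgumentError

DEG = np.pi / 180.0


# ---------------------------------------------------------------------------
# observer and subject parameters
# ---------------------------------------------------------------------------

@dataclass
class ObserverParams:
    """Generative observer for one subject.

    Internal noise SD at jitter level delta is
    ``sqrt(sigma_add**2 + (k_mult * delta)**2)`` in decision-statistic units.
    ``criterion`` of None means the unbiased per-level midpoint between the
    expected signal and noise statistics.
    """

    sigma_add: float = 0.030
    k_mult: float = 0.0016          # per degree of external jitter
    criterion: float | None = None
    lapse: float = 0.01
    template_weight_bg: float = 0.60
    decision_rule: str = "channel"  # "channel" | "matched" | "cosine"
    channel_bandwidth: float = 30.0   # orientation tuning SD, degrees
    collinearity_weight: float = 0.20
    # shifted-gamma reaction times
    rt_shift: float = 0.45          # s
    rt_scale: float = 0.25          # s
    rt_shape: float = 2.0
    rt_noise_slope: float = 0.006   # relative scale increase per degree
    # per-trial mean gaze points
    gaze_mu: tuple[float, float] = (0.0, 0.0)   # degrees
    gaze_sigma0: float = 0.55       # minor-axis SD, degrees
    gaze_noise_slope: float = 0.010 # relative SD increase per degree
    gaze_aspect: float = 1.6        # x/y SD ratio (horizontal elongation)
    gaze_outlier_rate: float = 0.055  # tracking-loss mixture weight
    gaze_outlier_sigma: float = 20.0  # degrees

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.k_mult < 0:
            raise InvalidArgumentError("noise parameters must be >= 0")
        if not (0 <= self.lapse <= 1):
            raise InvalidArgumentError("lapse must lie in [0, 1]")
        if self.rt_shape <= 0 or self.rt_scale <= 0 or self.gaze_sigma0 <= 0:
            raise InvalidArgumentError(
                "rt_shape, rt_scale and gaze_sigma0 must be positive")
        if self.decision_rule not in ("channel", "matched", "cosine"):
            raise InvalidArgumentError(
                f"unknown decision rule {self.decision_rule!r}")
        if self.channel_bandwidth <= 0:
            raise InvalidArgumentError("channel_bandwidth must be positive")

    def internal_sd(self, noise_level: float) -> float:
        return float(np.hypot(self.sigma_add, self.k_mult * noise_level))


@dataclass
class SubjectProfile:
    subject_id: str
    group: str                      # "ASD" | "TD"
    age: float
    iq: float
    observer: ObserverParams


@dataclass
class Template:
    """Decision template: grid indices with weights.

    The first ``n_contour`` indices are the contour path positions in path
    order (the collinearity term needs consecutive neighbors); the rest are
    adjacent background positions.
    """

    indices: np.ndarray
    weights: np.ndarray
    n_contour: int

    def __post_init__(self) -> None:
        if self.indices.size == 0:
            raise InvalidArgumentError("template must contain positions")
        if self.indices.size != self.weights.size:
            raise InvalidArgumentError("indices and weights differ in length")


def build_template(grid: st.HexGrid, contour_indices: np.ndarray,
                   weight_bg: float) -> Template:
    """Contour positions at weight 1 plus their hex-adjacent background
    positions at ``weight_bg`` (dropped entirely when ``weight_bg == 0``)."""
    contour_indices = np.asarray(contour_indices, dtype=int)
    if weight_bg == 0.0:
        return Template(indices=contour_indices,
                        weights=np.ones(contour_indices.size),
                        n_contour=contour_indices.size)
    adj = st.hex_neighbor_indices(grid, contour_indices)
    idx = np.concatenate([contour_indices, adj])
    w = np.concatenate([np.ones(contour_indices.size),
                        np.full(adj.size, float(weight_bg))])
    return Template(indices=idx, weights=w, n_contour=contour_indices.size)


# ---------------------------------------------------------------------------
# decision statistics
# ---------------------------------------------------------------------------

def decision_statistic(trial_stimulus: st.TrialStimulus,
                       template: Template) -> float:
    """Cosine template statistic ``sum w cos 2(theta - 60) / sum w`` in [-1, 1]."""
    theta = trial_stimulus.orientations[template.indices]
    c = np.cos(2.0 * DEG * (theta - 60.0))
    return float(np.sum(template.weights * c) / np.sum(template.weights))


def _wrap90(a: np.ndarray) -> np.ndarray:
    """Axial angular difference wrapped to [-90, 90)."""
    return (a + 90.0) % 180.0 - 90.0


def matched_pair_statistic(trial_stimulus: st.TrialStimulus,
                           template: Template, noise_level: float) -> float:
    """Matched-pair statistic: per-element best cosine match to 60 +/- delta."""
    theta = trial_stimulus.orientations[template.indices]
    m = np.maximum(np.cos(2.0 * DEG * (theta - 60.0 - noise_level)),
                   np.cos(2.0 * DEG * (theta - 60.0 + noise_level)))
    return float(np.sum(template.weights * m) / np.sum(template.weights))


def collinearity_statistic(contour_orientations: np.ndarray) -> float:
    """Mean axial alignment of consecutive contour positions,
    ``mean cos 2(theta_i - theta_{i+1})`` in [-1, 1] (good continuation)."""
    th = np.asarray(contour_orientations, dtype=float)
    if th.size < 2:
        raise InvalidArgumentError("collinearity needs >= 2 positions")
    return float(np.mean(np.cos(2.0 * DEG * _wrap90(np.diff(th)))))


def channel_statistic(trial_stimulus: st.TrialStimulus, template: Template,
                      observer: ObserverParams) -> float:
    """Default decision statistic: tuned orientation channels plus
    collinearity (see module docstring)."""
    delta = trial_stimulus.noise_level
    orient = trial_stimulus.orientations[np.newaxis, :]
    return float(_statistic_matrix(orient, template, "channel", delta,
                                   observer)[0])


def _statistic_matrix(orientations: np.ndarray, template: Template,
                      rule: str, noise_level: float,
                      observer: "ObserverParams | None" = None) -> np.ndarray:
    """Vectorized statistic for a (n_trials, n_elements) orientation stack."""
    theta = orientations[:, template.indices]
    if rule == "cosine":
        m = np.cos(2.0 * DEG * (theta - 60.0))
    elif rule == "matched":
        m = np.maximum(np.cos(2.0 * DEG * (theta - 60.0 - noise_level)),
                       np.cos(2.0 * DEG * (theta - 60.0 + noise_level)))
    else:  # channel
        bw = observer.channel_bandwidth
        d1 = _wrap90(theta - (60.0 - noise_level))
        d2 = _wrap90(theta - (60.0 + noise_level))
        m = np.maximum(np.exp(-d1 ** 2 / (2.0 * bw ** 2)),
                       np.exp(-d2 ** 2 / (2.0 * bw ** 2)))
    s = m @ template.weights / template.weights.sum()
    if rule == "channel" and observer.collinearity_weight != 0.0:
        th_c = theta[:, :template.n_contour]
        coll = np.mean(np.cos(2.0 * DEG * _wrap90(np.diff(th_c, axis=1))),
                       axis=1)
        s = s + observer.collinearity_weight * coll
    return s


def _channel_bg_mean(noise_level: float, bandwidth: float,
                     _cache: dict = {}) -> float:
    """Mean response of the two-channel bank to a uniform orientation
    (numeric integral over the 180-degree period, cached)."""
    key = (round(noise_level, 6), round(bandwidth, 6))
    if key not in _cache:
        u = np.linspace(-90.0, 90.0, 4001)
        d1 = _wrap90(u - noise_level)
        d2 = _wrap90(u + noise_level)
        m = np.maximum(np.exp(-d1 ** 2 / (2.0 * bandwidth ** 2)),
                       np.exp(-d2 ** 2 / (2.0 * bandwidth ** 2)))
        _cache[key] = float(np.trapezoid(m, u) / 180.0)
    return _cache[key]


def expected_statistics(observer: ObserverParams, noise_level: float,
                        n_contour: int = 12, n_adjacent: int = 28
                        ) -> tuple[float, float]:
    """Expected statistic on signal and noise trials for the observer's rule.

    Background elements are uniform on (-90, 90]: their mean response is 0
    (cosine), ``(2/pi) sin(2 delta)`` (matched), or a numeric tuning-curve
    integral (channel).  Contour elements contribute ``cos(2 delta)``
    (cosine) or exactly 1 (matched / channel); under balanced jitter the
    expected collinearity of the contour is ``5/11 + (6/11) cos(4 delta)``
    for 12 elements and 0 for uniform orientations.
    """
    w = observer.template_weight_bg
    n_adj = 0 if w == 0.0 else n_adjacent
    total = n_contour + w * n_adj
    rule = observer.decision_rule
    if rule == "matched":
        mu_bg = (2.0 / np.pi) * np.sin(2.0 * DEG * noise_level)
        mu_contour = 1.0
    elif rule == "channel":
        mu_bg = _channel_bg_mean(noise_level, observer.channel_bandwidth)
        mu_contour = 1.0
    else:
        mu_bg = 0.0
        mu_contour = float(np.cos(2.0 * DEG * noise_level))
    mu_signal = (n_contour * mu_contour + w * n_adj * mu_bg) / total
    mu_noise = mu_bg
    if rule == "channel" and observer.collinearity_weight != 0.0:
        n_half = n_contour // 2
        p_same = (2 * n_half * (n_half - 1)) / (n_contour * (n_contour - 1))
        coll_sig = p_same + (1.0 - p_same) * float(
            np.cos(4.0 * DEG * noise_level))
        mu_signal += observer.collinearity_weight * coll_sig
    return float(mu_signal), float(mu_noise)


def unbiased_criterion(observer: ObserverParams, noise_level: float,
                       **kwargs) -> float:
    """Criterion midway between the expected signal and noise statistics."""
    mu_s, mu_n = expected_statistics(observer, noise_level, **kwargs)
    return 0.5 * (mu_s + mu_n)


# ---------------------------------------------------------------------------
# per-trial simulation primitives
# ---------------------------------------------------------------------------

def simulate_response(trial_stimulus: st.TrialStimulus,
                      observer: ObserverParams, rng: np.random.Generator,
                      template: Template) -> dict:
    """Simulate the yes/no response to one trial.

    The decision statistic ``s`` (per the observer's rule) is corrupted by
    an internal draw ``eps ~ N(0, sigma_i^2)`` and compared to the criterion;
    with probability ``lapse`` the response is replaced by a fair coin.
    """
    delta = trial_stimulus.noise_level
    if observer.decision_rule == "cosine":
        s = decision_statistic(trial_stimulus, template)
    elif observer.decision_rule == "matched":
        s = matched_pair_statistic(trial_stimulus, template, delta)
    else:
        s = channel_statistic(trial_stimulus, template, observer)
    gamma = (observer.criterion if observer.criterion is not None
             else unbiased_criterion(observer, delta))
    eps = rng.normal(0.0, observer.internal_sd(delta))
    yes = bool(s + eps > gamma)
    if observer.lapse > 0 and rng.random() < observer.lapse:
        yes = bool(rng.random() < 0.5)
    correct = yes == (trial_stimulus.stimulus_class == "signal")
    return dict(response="yes" if yes else "no", correct=correct,
                decision_stat=s)


def simulate_rt(noise_level: float, observer: ObserverParams,
                rng: np.random.Generator, size=None):
    """Shifted-gamma reaction time(s):
    ``rt_shift + Gamma(rt_shape, rt_scale * (1 + rt_noise_slope * delta))``."""
    scale = observer.rt_scale * (1.0 + observer.rt_noise_slope * noise_level)
    draw = rng.gamma(observer.rt_shape, scale, size=size)
    return observer.rt_shift + draw


def simulate_gaze(observer: ObserverParams, noise_level: float,
                  n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """One mean-gaze point per trial (degrees), bivariate normal around the
    subject's habitual offset with noise-dependent dispersion plus a small
    isotropic tracking-loss mixture.  Points outside the screen are kept;
    clipping is the analysis's job."""
    sd = observer.gaze_sigma0 * (1.0 + observer.gaze_noise_slope * noise_level)
    pts = rng.normal(0.0, 1.0, size=(n_trials, 2))
    pts[:, 0] *= sd * observer.gaze_aspect
    pts[:, 1] *= sd
    pts += np.asarray(observer.gaze_mu)
    if observer.gaze_outlier_rate > 0:
        lost = rng.random(n_trials) < observer.gaze_outlier_rate
        n_lost = int(lost.sum())
        if n_lost:
            pts[lost] = rng.normal(0.0, observer.gaze_outlier_sigma,
                                   size=(n_lost, 2))
    return pts


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class GroupConfig:
    """Population distribution of observer parameters for one group.

    Subject-level parameters are log-normal around the group means, partly
    driven by a shared per-subject "noisiness" latent u ~ N(0, 1) that also
    loads (negatively) on IQ and (positively) on gaze dispersion, planting
    the IQ-accuracy and gaze-area-performance correlations the analyses
    look for.
    """

    name: str
    n_subjects: int
    observer: ObserverParams
    iq_mean: float = 100.0
    iq_sd: float = 15.0
    iq_noise_loading: float = -0.5  # corr(u, IQ)
    gaze_center_sd: float = 0.08    # SD of per-subject mean gaze offset, deg
    sigma_add_lognorm_sd: float = 0.25
    k_mult_lognorm_sd: float = 0.22
    weight_bg_lognorm_sd: float = 0.20
    gaze_sigma_lognorm_sd: float = 0.25
    rt_shift_lognorm_sd: float = 0.12
    latent_loading: float = 0.6     # share of each log-param SD driven by u
    age_range: tuple[float, float] = (8.0, 16.0)


def default_cohort_config() -> "CohortConfig":
    """The default two-group study configuration.

    The ASD-like group has modestly larger additive internal noise, a
    clearly larger stimulus-dependent noise coefficient, a slightly noisier
    template, a higher lapse rate, slower RTs, and larger / more
    noise-sensitive gaze dispersion with more tracking loss; IQ means and
    SDs follow the study's group descriptives (84 +/- 17 vs 102 +/- 13).
    """
    asd_observer = ObserverParams(
        sigma_add=0.035, k_mult=0.0038, template_weight_bg=0.75, lapse=0.035,
        rt_shift=0.62, rt_scale=0.33, rt_noise_slope=0.008,
        gaze_sigma0=0.85, gaze_noise_slope=0.016, gaze_outlier_rate=0.14,
    )
    td_observer = ObserverParams(
        sigma_add=0.030, k_mult=0.0016, template_weight_bg=0.60, lapse=0.010,
        rt_shift=0.45, rt_scale=0.25, rt_noise_slope=0.006,
        gaze_sigma0=0.55, gaze_noise_slope=0.010, gaze_outlier_rate=0.055,
    )
    return CohortConfig(groups=(
        GroupConfig(name="ASD", n_subjects=24, observer=asd_observer,
                    iq_mean=84.0, iq_sd=17.0, gaze_center_sd=0.08),
        GroupConfig(name="TD", n_subjects=32, observer=td_observer,
                    iq_mean=102.0, iq_sd=13.0, gaze_center_sd=0.04),
    ))


@dataclass
class CohortConfig:
    groups: tuple[GroupConfig, ...] = ()
    spec: st.StimulusSpec = field(default_factory=st.StimulusSpec)
    n_signal: int = 30
    n_noise: int = 30

    def __post_init__(self) -> None:
        if not self.groups:
            object.__setattr__(self, "groups",
                               default_cohort_config().groups)


# ---------------------------------------------------------------------------
# subject and cohort simulation
# ---------------------------------------------------------------------------

def sample_subject(group: GroupConfig, subject_id: str,
                   rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's observer parameters from the group distribution."""
    u = rng.normal()                      # shared noisiness latent
    lam = group.latent_loading
    res = np.sqrt(1.0 - lam ** 2)

    def lognorm(mean: float, sd_log: float) -> float:
        z = lam * u + res * rng.normal()
        # exp(sd*z) has mean exp(sd^2/2); divide it out so the group mean holds
        return mean * float(np.exp(sd_log * z - sd_log ** 2 / 2.0))

    base = group.observer
    rho = group.iq_noise_loading
    iq = group.iq_mean + group.iq_sd * (
        rho * u + np.sqrt(1.0 - rho ** 2) * rng.normal())
    observer = replace(
        base,
        sigma_add=lognorm(base.sigma_add, group.sigma_add_lognorm_sd),
        k_mult=lognorm(base.k_mult, group.k_mult_lognorm_sd),
        template_weight_bg=lognorm(base.template_weight_bg,
                                   group.weight_bg_lognorm_sd),
        gaze_sigma0=lognorm(base.gaze_sigma0, group.gaze_sigma_lognorm_sd),
        rt_shift=base.rt_shift * float(np.exp(
            group.rt_shift_lognorm_sd * rng.normal()
            - group.rt_shift_lognorm_sd ** 2 / 2.0)),
        gaze_mu=tuple(rng.normal(0.0, group.gaze_center_sd, size=2)),
    )
    age = float(rng.uniform(*group.age_range))
    return SubjectProfile(subject_id=subject_id, group=group.name,
                          age=age, iq=float(iq), observer=observer)


def simulate_session(subject: SubjectProfile, spec: st.StimulusSpec,
                     rng: np.random.Generator, n_signal: int = 30,
                     n_noise: int = 30,
                     grid: st.HexGrid | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one subject through the full eight-block session.

    Returns (trials, gaze) tables.  Stimuli in the two pass-2 blocks are
    exact replicas of their pass-1 blocks, so the decision statistic is
    identical across passes trial-by-trial while internal draws are fresh.
    """
    grid = grid if grid is not None else st.build_hex_grid(
        spec.n_cols, spec.n_rows, spec.spacing)
    blocks = st.generate_session_design(spec, rng, n_signal=n_signal,
                                        n_noise=n_noise, grid=grid)
    obs = subject.observer
    trial_rows = []
    gaze_rows = []
    for blk in blocks:
        delta = blk.noise_level
        template = build_template(grid, blk.trials[0].contour_indices,
                                  obs.template_weight_bg)
        orient = np.stack([t.orientations for t in blk.trials])
        stats = _statistic_matrix(orient, template, obs.decision_rule, delta,
                                  obs)
        gamma = (obs.criterion if obs.criterion is not None
                 else unbiased_criterion(obs, delta))
        eps = rng.normal(0.0, obs.internal_sd(delta), size=len(blk.trials))
        yes = stats + eps > gamma
        if obs.lapse > 0:
            lapse = rng.random(len(blk.trials)) < obs.lapse
            coin = rng.random(len(blk.trials)) < 0.5
            yes = np.where(lapse, coin, yes)
        rts = simulate_rt(delta, obs, rng, size=len(blk.trials))
        gaze = simulate_gaze(obs, delta, len(blk.trials), rng)
        for i, trial in enumerate(blk.trials):
            is_signal = trial.stimulus_class == "signal"
            trial_rows.append(dict(
                subject_id=subject.subject_id, group=subject.group,
                age=subject.age, iq=subject.iq, block=blk.block_index,
                pass_index=blk.pass_index, trial_index=i,
                noise_level=delta, stimulus_class=trial.stimulus_class,
                response="yes" if yes[i] else "no",
                correct=bool(yes[i] == is_signal), rt_s=float(rts[i]),
                decision_stat=float(stats[i])))
            gaze_rows.append(dict(
                subject_id=subject.subject_id, group=subject.group,
                block=blk.block_index, trial_index=i, noise_level=delta,
                stimulus_class=trial.stimulus_class,
                x_deg=float(gaze[i, 0]), y_deg=float(gaze[i, 1])))
    return pd.DataFrame(trial_rows), pd.DataFrame(gaze_rows)


@dataclass
class CohortData:
    trials: pd.DataFrame
    gaze: pd.DataFrame
    subjects: pd.DataFrame


def simulate_cohort(config: CohortConfig | None = None,
                    master_seed: int = 0) -> CohortData:
    """Simulate the full study: subjects, sessions, gaze.

    A single master seed drives everything; child streams are spawned per
    subject (numpy SeedSequence), so any subject can be re-simulated
    independently and the outputs are byte-identical across runs.
    """
    config = config if config is not None else CohortConfig()
    spec = config.spec
    grid = st.build_hex_grid(spec.n_cols, spec.n_rows, spec.spacing)
    root = np.random.SeedSequence(master_seed)

    subject_rows = []
    trial_tables = []
    gaze_tables = []
    counter = 0
    for group in config.groups:
        for k in range(group.n_subjects):
            counter += 1
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            sid = f"{group.name}{k + 1:02d}"
            subject = sample_subject(group, sid, rng)
            trials, gaze = simulate_session(
                subject, spec, rng, n_signal=config.n_signal,
                n_noise=config.n_noise, grid=grid)
            trial_tables.append(trials)
            gaze_tables.append(gaze)
            obs = subject.observer
            subject_rows.append(dict(
                subject_id=sid, group=group.name, age=subject.age,
                iq=subject.iq, sigma_add=obs.sigma_add, k_mult=obs.k_mult,
                template_weight_bg=obs.template_weight_bg, lapse=obs.lapse,
                rt_shift=obs.rt_shift, gaze_sigma0=obs.gaze_sigma0,
                gaze_noise_slope=obs.gaze_noise_slope,
                gaze_mu_x=obs.gaze_mu[0], gaze_mu_y=obs.gaze_mu[1]))
    return CohortData(trials=pd.concat(trial_tables, ignore_index=True),
                      gaze=pd.concat(gaze_tables, ignore_index=True),
                      subjects=pd.DataFrame(subject_rows))
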