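"""Configuration, table I/O, and seeded orchestration of the full pipeline.

``run_pipeline`` chains: cohort simulation -> RT filtering -> accuracy and
RT summaries -> SDT categorization -> double-pass analysis -> gaze
point-pattern analysis -> dispersion-performance correlations, writing
tidy CSV tables, a machine-readable ``results.json``, and summary figures.
A single master seed makes every stage (including bootstrap draws and
envelope simulations) reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import cohort as ch
from . import doublepass as dp
from . import gaze as gz
from . import stimulus as st
from .errors import SchemaError

logger = logging.getLogger(__name__)

TRIALS_COLUMNS = ["subject_id", "group", "block", "pass_index",
                  "trial_index", "noise_level", "stimulus_class",
                  "response", "correct", "rt_s"]
GAZE_COLUMNS = ["subject_id", "group", "block", "trial_index",
                "noise_level", "stimulus_class", "x_deg", "y_deg"]
SUBJECTS_COLUMNS = ["subject_id", "group", "age", "iq"]

_NUMERIC = {"block": int, "pass_index": int, "trial_index": int,
            "noise_level": float, "rt_s": float, "x_deg": float,
            "y_deg": float, "age": float, "iq": float}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisOptions:
    quadrats: tuple[int, int] = (5, 5)
    n_sim_envelope: int = 19
    n_boot_draws: int = 4000
    rt_bounds: tuple[float, float] = (bh.RT_LOW, bh.RT_HIGH)
    ppm_quadrature: tuple[int, int] = (64, 36)
    k_subsample: int = 1500           # max points per group for K analysis


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    spec: st.StimulusSpec = field(default_factory=st.StimulusSpec)
    cohort: ch.CohortConfig = field(default_factory=ch.CohortConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = self.spec.to_dict()
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        spec = st.StimulusSpec.from_dict(d.get("spec", {}))
        groups = []
        for g in d.get("cohort", {}).get("groups", []):
            g = dict(g)
            g["observer"] = ch.ObserverParams(**_tupled(g["observer"],
                                                        ["gaze_mu"]))
            groups.append(ch.GroupConfig(**_tupled(g, ["age_range"])))
        cohort = ch.CohortConfig(
            groups=tuple(groups) or ch.default_cohort_config().groups,
            spec=spec,
            n_signal=d.get("cohort", {}).get("n_signal", 30),
            n_noise=d.get("cohort", {}).get("n_noise", 30))
        analysis = AnalysisOptions(**_tupled(
            d.get("analysis", {}),
            ["quadrats", "rt_bounds", "ppm_quadrature"]))
        return cls(spec=spec, cohort=cohort, analysis=analysis,
                   seed=int(d.get("seed", 0)),
                   out_dir=str(d.get("out_dir", "results")))


def _plainify(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _tupled(d: dict, keys: list[str]) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# table I/O with schema validation
# ---------------------------------------------------------------------------

def _validate(df: pd.DataFrame, required: list[str], name: str
              ) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")
    for col in required:
        if col not in _NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{name}: column {col!r} has non-numeric value at row "
                f"{int(bad[0]) + 2} (1-based, counting the header)")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise SchemaError(
                f"{name}: column {col!r} has missing value at row {row}")
        df[col] = coerced.astype(_NUMERIC[col])
    return df


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _validate(df, TRIALS_COLUMNS, "trials")
    if df["correct"].dtype != bool:
        df["correct"] = df["correct"].astype(str).str.lower().isin(
            ["true", "1", "yes"])
    return df


def read_gaze(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), GAZE_COLUMNS, "gaze")


def read_subjects(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), SUBJECTS_COLUMNS, "subjects")


def write_tables(data: ch.CohortData, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("trials", data.trials), ("gaze", data.gaze),
                     ("subjects", data.subjects)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _stage(name):
    logger.info("pipeline stage: %s", name)


def analyze_behavior(trials: pd.DataFrame, options: AnalysisOptions,
                     rng: np.random.Generator) -> dict:
    """RT filtering, accuracy/RT summaries, SDT counts, IQ correlation."""
    lo, hi = options.rt_bounds
    filtered, exclusions = bh.filter_rt(trials, lo, hi)
    acc = bh.summarize_accuracy(trials, options.n_boot_draws, rng)
    rt = bh.summarize_rt(filtered, options.n_boot_draws, rng)
    sdt = bh.sdt_categorize(trials)
    out = dict(filtered=filtered, rt_exclusions=exclusions,
               accuracy=acc, rt=rt, sdt=sdt)
    if "iq" in trials.columns:
        subj_acc = acc["by_subject"].groupby("subject_id")[
            "prop_correct"].mean()
        subj_iq = trials.groupby("subject_id")["iq"].first()
        merged = pd.concat([subj_acc, subj_iq], axis=1).dropna()
        out["iq_accuracy_corr"] = bh.pearson_ci(merged["iq"],
                                                merged["prop_correct"])
    return out


def analyze_gaze(gaze_df: pd.DataFrame, options: AnalysisOptions,
                 rng: np.random.Generator) -> dict:
    """Clipping, quadrat tests, ppm fits with LR tests, K envelopes,
    pairwise distances, ellipses, dispersion."""
    pattern, exclusions = gz.clip_to_window(gaze_df)
    data = pattern.data
    nx, ny = options.quadrats
    quad = {}
    for (grp, cls), g in data.groupby(["group", "stimulus_class"]):
        res = gz.quadrat_test(gz.PointPattern(g, pattern.window), nx, ny)
        quad[f"{grp}_{cls}"] = {k: res[k] for k in ("chi2", "df", "p")}

    # mark (signal vs noise) effect per group, log-quadratic trend; null and
    # full models share the mark-stratified quadrature so the LR is valid
    mark_tests = {}
    for grp, g in data.groupby("group"):
        pat = gz.PointPattern(g, pattern.window)
        null = gz.fit_ppm(pat, 2, strata=("stimulus_class",),
                          quadrature=options.ppm_quadrature)
        full = gz.fit_ppm(pat, 2, covariates=("stimulus_class",),
                          quadrature=options.ppm_quadrature)
        mark_tests[grp] = gz.lr_test(null, full)

    # pooled models: group and noise effects on intensity (with spatial
    # interactions, mirroring the hyperframe analysis); all fits share the
    # group-by-noise stratified quadrature
    data2 = data.copy()
    data2["noise_level"] = data2["noise_level"].astype(str)
    pat_all = gz.PointPattern(data2, pattern.window)
    strata = ("group", "noise_level")
    qd = options.ppm_quadrature
    m_spatial = gz.fit_ppm(pat_all, 2, strata=strata, quadrature=qd)
    m_group = gz.fit_ppm(pat_all, 2, covariates=("group",), strata=strata,
                         quadrature=qd)
    m_gn = gz.fit_ppm(pat_all, 2, covariates=strata, strata=strata,
                      quadrature=qd)
    m_gn_int = gz.fit_ppm(pat_all, 2, covariates=strata,
                          interactions=("group",), strata=strata,
                          quadrature=qd)
    effects = dict(
        group=gz.lr_test(m_spatial, m_group),
        noise_level=gz.lr_test(m_group, m_gn),
        group_x_spatial=gz.lr_test(m_gn, m_gn_int),
    )

    # K function with envelope per group (on a subsample for tractability)
    k_env = {}
    for grp, g in data.groupby("group"):
        take = min(len(g), options.k_subsample)
        idx = rng.choice(len(g), size=take, replace=False)
        sub = gz.PointPattern(g.iloc[np.sort(idx)].reset_index(drop=True),
                              pattern.window)
        m = gz.fit_ppm(sub, 2, quadrature=options.ppm_quadrature)
        k_env[grp] = gz.kinhom_envelope(sub, m, n_sim=options.n_sim_envelope,
                                        rng=rng)

    pairdist = {g: {k: v for k, v in s.items() if k != "distances"}
                for g, s in gz.group_pairwise_distances(data).items()}

    ellipses = []
    ftests = []
    for (grp, lv), g in data.groupby(["group", "noise_level"]):
        es = gz.variance_ellipse(g[["x_deg", "y_deg"]].to_numpy())
        ellipses.append(dict(group=grp, noise_level=lv, var_max=es.var_max,
                             var_min=es.var_min, area=es.area,
                             orientation_deg=es.orientation_deg, n=es.n))
        ft = gz.variance_f_test(es.var_max, es.n, es.var_min, es.n)
        ftests.append(dict(group=grp, noise_level=lv, **ft))

    dispersion = gz.per_subject_dispersion(data, options.n_boot_draws, rng)
    return dict(pattern=pattern, exclusions=exclusions, quadrat=quad,
                mark_tests=mark_tests, effects=effects, k_envelopes=k_env,
                pairwise=pairdist, ellipses=pd.DataFrame(ellipses),
                elongation_f=pd.DataFrame(ftests), dispersion=dispersion)


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full simulate -> analyze -> report chain.

    Returns the results dictionary (also written to
    ``<out_dir>/results.json``); figures and tidy CSVs are written next to
    it.  Any stage failure raises with the stage name in the message;
    partial outputs written so far are retained.
    """
    config = config if config is not None else RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    results: dict = dict(seed=config.seed)

    stage = "simulate"
    try:
        _stage(stage)
        data = ch.simulate_cohort(config.cohort, master_seed=config.seed)
        write_tables(data, out)

        stage = "behavior"
        _stage(stage)
        beh = analyze_behavior(data.trials, config.analysis,
                               np.random.default_rng(seeds[0]))
        beh["accuracy"]["summary"].to_csv(out / "accuracy_summary.csv",
                                          index=False)
        beh["sdt"].to_csv(out / "sdt_counts.csv", index=False)
        results["rt_exclusions"] = beh["rt_exclusions"].to_dict("records")
        results["accuracy"] = beh["accuracy"]["summary"].to_dict("records")
        results["accuracy_p_first_greater"] = beh["accuracy"][
            "p_first_greater"]
        results["rt"] = beh["rt"]["summary"].to_dict("records")
        results["rt_p_first_greater"] = beh["rt"]["p_first_greater"]
        if "iq_accuracy_corr" in beh:
            results["iq_accuracy_corr"] = beh["iq_accuracy_corr"]

        stage = "doublepass"
        _stage(stage)
        dp_res = dp.analyze_doublepass(data.trials)
        pts = pd.DataFrame([vars(p) for p in dp_res["points"]])
        pts.to_csv(out / "doublepass_points.csv", index=False)
        dp_res["sigma_ratios"].to_csv(out / "sigma_ratio_estimates.csv",
                                      index=False)
        results["slope_fits"] = {
            f"{g}_{lv:g}": dict(m=f.m, se=f.se, ci_low=f.ci_low,
                                ci_high=f.ci_high, n_points=f.n_points)
            for (g, lv), f in dp_res["fits"].items()}
        results["slope_comparisons"] = {
            f"{lv:g}": c for lv, c in dp_res["comparisons"].items()}
        results["sigma_ratio_medians"] = {
            f"{g}_{lv:g}": float(v) for (g, lv), v in
            dp_res["sigma_ratios"].groupby(["group", "noise_level"])
            ["r_hat"].median().items()}
        with open(out / "slope_fits.json", "w") as fh:
            json.dump(_plainify(results["slope_fits"]), fh, indent=2)

        stage = "gaze"
        _stage(stage)
        gres = analyze_gaze(data.gaze, config.analysis,
                            np.random.default_rng(seeds[1]))
        gres["ellipses"].to_csv(out / "ellipses.csv", index=False)
        for grp, env in gres["k_envelopes"].items():
            env.to_csv(out / f"kinhom_{grp}.csv", index=False)
        results["gaze_exclusions"] = gres["exclusions"].to_dict("records")
        results["quadrat_tests"] = gres["quadrat"]
        results["mark_tests"] = gres["mark_tests"]
        results["intensity_effects"] = gres["effects"]
        results["pairwise_distances"] = gres["pairwise"]
        results["dispersion_p_first_greater"] = {
            f"{lv:g}": p for lv, p in
            gres["dispersion"]["p_first_greater"].items()}
        with open(out / "gaze_tests.json", "w") as fh:
            json.dump(_plainify(dict(quadrat=gres["quadrat"],
                                     mark=gres["mark_tests"],
                                     effects=gres["effects"])), fh, indent=2)

        stage = "correlations"
        _stage(stage)
        acc_subj = beh["accuracy"]["by_subject"]
        rt_subj = beh["rt"]["by_subject"]
        iq_tab = data.trials.groupby("subject_id", as_index=False)[
            "iq"].first()
        corr = gz.gaze_area_correlations(gres["pattern"].data, acc_subj,
                                         rt_subj, iq_tab)
        results["gaze_area_correlations"] = corr

        stage = "figures"
        _stage(stage)
        make_figures(results, data, dp_res, out)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    with open(out / "results.json", "w") as fh:
        json.dump(_plainify(results), fh, indent=2)
    return results


def make_figures(results: dict, data: ch.CohortData, dp_res: dict,
                 out_dir) -> list[str]:
    """Summary figures: accuracy and RT medians with bootstrap CIs,
    pc-vs-pa double-pass scatter, gaze-position histograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []

    def errbar(ax, recs, value="boot_median"):
        df = pd.DataFrame(recs)
        for grp, g in df.groupby("group"):
            g = g.sort_values("noise_level")
            ax.errorbar(g["noise_level"], g[value],
                        yerr=[g[value] - g["ci_low"],
                              g["ci_high"] - g[value]],
                        marker="o", capsize=3, label=str(grp))
        ax.set_xlabel("external noise (deg)")
        ax.legend()

    fig, ax = plt.subplots(figsize=(5, 4))
    errbar(ax, results["accuracy"])
    ax.set_ylabel("proportion correct (group median)")
    fig.tight_layout()
    p = out / "fig_accuracy.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    fig, ax = plt.subplots(figsize=(5, 4))
    errbar(ax, results["rt"])
    ax.set_ylabel("median RT (s)")
    fig.tight_layout()
    p = out / "fig_rt.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    pts = pd.DataFrame([vars(q) for q in dp_res["points"]])
    for ax, lv in zip(axes, sorted(pts["noise_level"].unique())):
        sel = pts[pts["noise_level"] == lv]
        for grp, g in sel.groupby("group"):
            ax.scatter(g["pa"], g["pc"], s=18, label=str(grp), alpha=0.7)
        pa_line = np.linspace(max(sel["pa"].min(), 40), 100, 100)
        for (grp, flv), f in dp_res["fits"].items():
            if flv == lv:
                ax.plot(pa_line, f.predict(pa_line), lw=1)
        ax.set_title(f"noise {lv:g} deg")
        ax.set_xlabel("percent agreement")
    axes[0].set_ylabel("percent correct")
    axes[0].legend()
    fig.tight_layout()
    p = out / "fig_doublepass.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    groups = sorted(data.gaze["group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 3.2))
    axes = np.atleast_1d(axes)
    for ax, grp in zip(axes, groups):
        g = data.gaze[data.gaze["group"] == grp]
        ax.hist2d(g["x_deg"], g["y_deg"], bins=31,
                  range=[[-20, 20], [-11.25, 11.25]])
        ax.set_title(f"{grp} gaze positions")
        ax.set_xlabel("x (deg)")
        ax.set_ylabel("y (deg)")
    fig.tight_layout()
    p = out / "fig_gaze_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))
    return written
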