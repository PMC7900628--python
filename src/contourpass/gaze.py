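"""Spatial point-pattern analysis of gaze positions.

Gaze samples (one mean position per trial, in degrees of visual angle) are
treated as a marked spatial point pattern on the rectangular screen window
[-20, 20] x [-11.25, 11.25] deg (area 900 deg^2).  The analyses mirror the
standard point-process toolbox:

* quadrat chi-square test of complete spatial randomness;
* inhomogeneous Poisson process models with a log-quadratic spatial trend
  and categorical covariates (group, noise level, stimulus class), fitted by
  the Berman-Turner quadrature device (a weighted Poisson regression);
* likelihood-ratio tests between nested intensity models;
* the inhomogeneous K function with border edge-correction and a pointwise
  simulation envelope;
* pairwise-distance summaries, variance ellipses with F tests, per-subject
  dispersion, and dispersion-performance correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .behavior import bayes_boot, boot_compare, pearson_ci
from .errors import (
    FitError,
    GeometryError,
    InsufficientDataError,
    InvalidArgumentError,
    NestingError,
)

logger = logging.getLogger(__name__)

#: Screen window in degrees: (xmin, xmax, ymin, ymax).
SCREEN_WINDOW = (-20.0, 20.0, -11.25, 11.25)

#: chi-square quantile at 0.95 with 2 df, used by the 95% variance ellipse.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, 2))


def window_area(window=SCREEN_WINDOW) -> float:
    x0, x1, y0, y1 = window
    return (x1 - x0) * (y1 - y0)


# ---------------------------------------------------------------------------
# point pattern container and clipping
# ---------------------------------------------------------------------------

@dataclass
class PointPattern:
    """Points with optional marks inside a rectangular window."""

    data: pd.DataFrame                  # columns x_deg, y_deg + mark columns
    window: tuple = SCREEN_WINDOW

    def __post_init__(self) -> None:
        for col in ("x_deg", "y_deg"):
            if col not in self.data.columns:
                raise InvalidArgumentError(f"pattern lacks column {col}")

    @property
    def points(self) -> np.ndarray:
        return self.data[["x_deg", "y_deg"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)


def clip_to_window(gaze: pd.DataFrame, window=SCREEN_WINDOW
                   ) -> tuple[PointPattern, pd.DataFrame]:
    """Keep only gaze positions inside the screen (boundary inclusive).

    Returns the clipped pattern and an exclusion summary per group (or a
    single row when no group column is present).
    """
    x = gaze["x_deg"].to_numpy(float)
    y = gaze["y_deg"].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("non-finite gaze coordinates")
    x0, x1, y0, y1 = window
    keep = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if "group" in gaze.columns:
        log = (gaze.assign(_out=~keep).groupby("group", as_index=False)
               .agg(n_total=("_out", "size"), n_excluded=("_out", "sum")))
    else:
        log = pd.DataFrame(dict(group=["all"], n_total=[len(gaze)],
                                n_excluded=[int((~keep).sum())]))
    log["fraction_excluded"] = log["n_excluded"] / log["n_total"]
    return PointPattern(gaze[keep].reset_index(drop=True), window), log


# ---------------------------------------------------------------------------
# quadrat test
# ---------------------------------------------------------------------------

def quadrat_test(pattern: PointPattern, nx: int = 5, ny: int = 5) -> dict:
    """Chi-square test of complete spatial randomness on an nx-by-ny grid
    of equal-area quadrats (df = nx*ny - 1)."""
    n = len(pattern)
    if n < 1:
        raise InsufficientDataError("quadrat test needs at least one point")
    x0, x1, y0, y1 = pattern.window
    pts = pattern.points
    ix = np.clip(((pts[:, 0] - x0) / (x1 - x0) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((pts[:, 1] - y0) / (y1 - y0) * ny).astype(int), 0, ny - 1)
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    expected = n / (nx * ny)
    if expected < 5:
        logger.warning("quadrat_test: expected count per quadrat %.2f < 5",
                       expected)
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = nx * ny - 1
    return dict(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
                counts=counts)


# ---------------------------------------------------------------------------
# inhomogeneous Poisson model (Berman-Turner quadrature)
# ---------------------------------------------------------------------------

def _spatial_terms(x: np.ndarray, y: np.ndarray, degree: int) -> dict:
    terms = {}
    if degree >= 1:
        terms["x"] = x
        terms["y"] = y
    if degree >= 2:
        terms["x2"] = x * x
        terms["y2"] = y * y
        terms["xy"] = x * y
    if degree > 2:
        raise InvalidArgumentError("spatial_degree above 2 not supported")
    return terms


@dataclass
class IntensityModel:
    """Fitted log-linear intensity: log lambda = X beta.

    ``coefficients`` maps design-column names to estimates; ``loglik`` is
    the Berman-Turner approximation of the Poisson process log-likelihood
    (up to a model-independent constant, so differences between fits on the
    same quadrature are valid LR statistics).
    """

    coefficients: pd.Series
    bse: pd.Series
    loglik: float
    df: int
    spatial_degree: int
    covariates: tuple
    interactions: tuple
    strata: tuple                     # replication structure of the device
    levels: dict                      # covariate -> ordered levels
    quadrature: tuple
    n_points: int
    window: tuple
    integral: float                   # quadrature estimate of int lambda

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        """Build the design matrix for arbitrary locations/marks."""
        cols = {"const": np.ones(len(df))}
        cols.update(_spatial_terms(df["x_deg"].to_numpy(float),
                                   df["y_deg"].to_numpy(float),
                                   self.spatial_degree))
        for cov in self.covariates:
            for lev in self.levels[cov][1:]:
                cols[f"{cov}[{lev}]"] = (df[cov] == lev).astype(float)
        for cov in self.interactions:
            sp = _spatial_terms(df["x_deg"].to_numpy(float),
                                df["y_deg"].to_numpy(float),
                                self.spatial_degree)
            for lev in self.levels[cov][1:]:
                ind = (df[cov] == lev).astype(float).to_numpy()
                for name, vals in sp.items():
                    cols[f"{cov}[{lev}]:{name}"] = ind * vals
        X = pd.DataFrame(cols)
        return X[list(self.coefficients.index)]

    def intensity(self, df: pd.DataFrame) -> np.ndarray:
        """lambda at the rows of ``df`` (needs x_deg, y_deg and any marks)."""
        X = self.design(df).to_numpy(float)
        return np.exp(X @ self.coefficients.to_numpy(float))


def _quadrature_frame(pattern: PointPattern, strata_cols: tuple,
                      quadrature: tuple[int, int]) -> pd.DataFrame:
    """Berman-Turner device: data plus dummy points with counting weights.

    Each stratum (unique combination of the ``strata_cols`` marks) is a
    point pattern over the full window; dummy points on a regular grid are
    replicated per stratum, and every quadrature tile's area is split
    evenly among the (data + dummy) points falling in it within the
    stratum.
    """
    nqx, nqy = quadrature
    x0, x1, y0, y1 = pattern.window
    gx = x0 + (np.arange(nqx) + 0.5) * (x1 - x0) / nqx
    gy = y0 + (np.arange(nqy) + 0.5) * (y1 - y0) / nqy
    GX, GY = np.meshgrid(gx, gy)
    dummy = pd.DataFrame(dict(x_deg=GX.ravel(), y_deg=GY.ravel()))
    tile_area = window_area(pattern.window) / (nqx * nqy)

    data = pattern.data
    if strata_cols:
        strata = (data[list(strata_cols)].drop_duplicates()
                  .sort_values(list(strata_cols)).reset_index(drop=True))
    else:
        strata = pd.DataFrame([{}])

    frames = []
    for _, srow in strata.iterrows():
        sel = np.ones(len(data), dtype=bool)
        for cov, val in srow.items():
            sel &= (data[cov] == val).to_numpy()
        d = data[sel][["x_deg", "y_deg"]].copy()
        d["_z"] = 1.0
        dm = dummy.copy()
        dm["_z"] = 0.0
        both = pd.concat([d, dm], ignore_index=True)
        for cov, val in srow.items():
            both[cov] = val
        ix = np.clip(((both["x_deg"] - x0) / (x1 - x0) * nqx).astype(int),
                     0, nqx - 1)
        iy = np.clip(((both["y_deg"] - y0) / (y1 - y0) * nqy).astype(int),
                     0, nqy - 1)
        tile = iy * nqx + ix
        counts = np.bincount(tile, minlength=nqx * nqy)
        both["_w"] = tile_area / counts[tile]
        frames.append(both)
    return pd.concat(frames, ignore_index=True)


def fit_ppm(pattern: PointPattern, spatial_degree: int = 2,
            covariates: tuple = (), interactions: tuple = (),
            quadrature: tuple[int, int] = (64, 36),
            strata: tuple | None = None) -> IntensityModel:
    """Fit an inhomogeneous Poisson point-process model.

    ``log lambda(x, y) = b0 + b1 x + b2 y + b3 x^2 + b4 y^2 + b5 xy`` plus
    main effects of the requested categorical mark covariates and, if
    listed in ``interactions``, their interactions with all spatial terms.
    The Berman-Turner quadrature reduces the point-process likelihood to a
    weighted Poisson regression, solved by iteratively reweighted least
    squares.

    ``strata`` declares the replication structure of the quadrature device
    (one sub-pattern per unique mark combination); it defaults to
    ``covariates``.  To compare nested models by likelihood ratio, fit both
    with the *same* strata -- e.g. the no-group-effect null for a
    group-stratified pattern is ``covariates=(), strata=("group",)``.
    """
    if len(pattern) < 1:
        raise InsufficientDataError("cannot fit a model to an empty pattern")
    for cov in interactions:
        if cov not in covariates:
            raise InvalidArgumentError(
                f"interaction covariate {cov!r} missing from covariates")
    strata = tuple(covariates) if strata is None else tuple(strata)
    missing = set(covariates) - set(strata)
    if missing:
        raise InvalidArgumentError(
            f"covariates {sorted(missing)} must be part of the strata so "
            "dummy points carry their values")
    quad = _quadrature_frame(pattern, strata, quadrature)
    levels = {cov: sorted(pattern.data[cov].unique())
              for cov in covariates}

    model = IntensityModel(
        coefficients=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        loglik=np.nan, df=0, spatial_degree=spatial_degree,
        covariates=tuple(covariates), interactions=tuple(interactions),
        strata=strata, levels=levels, quadrature=tuple(quadrature),
        n_points=len(pattern), window=pattern.window, integral=np.nan)

    # assemble design over quadrature points (same builder as predictions)
    cols = {"const": np.ones(len(quad))}
    cols.update(_spatial_terms(quad["x_deg"].to_numpy(float),
                               quad["y_deg"].to_numpy(float), spatial_degree))
    for cov in covariates:
        for lev in levels[cov][1:]:
            cols[f"{cov}[{lev}]"] = (quad[cov] == lev).astype(float)
    for cov in interactions:
        sp = _spatial_terms(quad["x_deg"].to_numpy(float),
                            quad["y_deg"].to_numpy(float), spatial_degree)
        for lev in levels[cov][1:]:
            ind = (quad[cov] == lev).astype(float).to_numpy()
            for name, vals in sp.items():
                cols[f"{cov}[{lev}]:{name}"] = ind * vals
    X = pd.DataFrame(cols)
    w = quad["_w"].to_numpy(float)
    yv = (quad["_z"] / quad["_w"]).to_numpy(float)

    Xm = X.to_numpy(float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise FitError("design matrix is rank deficient")
    params, bse, loglik, mu = _irls_poisson(Xm, yv, w)
    model.coefficients = pd.Series(params, index=X.columns)
    model.bse = pd.Series(bse, index=X.columns)
    model.loglik = loglik
    model.df = int(X.shape[1])
    model.integral = float(np.sum(w * mu))
    return model


#: linear-predictor bound during IRLS; tight gaze clouds on a wide window
#: legitimately drive log lambda below -700 at the edges, which would
#: underflow, so eta is clipped far outside any statistically relevant range
_ETA_CLIP = 35.0


def _irls_poisson(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  max_iter: int = 200, tol: float = 1e-10
                  ) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Weighted Poisson regression with log link by IRLS.

    Maximizes sum_j w_j (y_j log mu_j - mu_j) with mu = exp(X beta); this is
    the Berman-Turner approximation of the point-process log-likelihood (up
    to a beta-independent constant).  Returns (beta, se, loglik, mu).
    """
    n, p = X.shape
    beta = np.zeros(p)
    # start from the homogeneous solution on the intercept column
    beta[0] = np.log(max(np.sum(w * y) / np.sum(w), 1e-300))

    def objective(b):
        eta = np.clip(X @ b, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * eta, 0.0)
        return float(np.sum(w * (term - mu))), mu, eta

    ll, mu, eta = objective(beta)
    for _ in range(max_iter):
        wt = w * mu                       # IRLS working weights
        z = eta + (y - mu) / np.maximum(mu, 1e-300)   # working response
        sw = np.sqrt(wt)
        try:
            step_beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw,
                                            rcond=None)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"IRLS linear solve failed: {exc}") from exc
        # step-halving line search for robustness on extreme intensities
        new_ll, new_mu, new_eta = objective(step_beta)
        frac = 1.0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            frac /= 2.0
            if frac < 1e-8:
                break
            trial = beta + frac * (step_beta - beta)
            new_ll, new_mu, new_eta = objective(trial)
            step_beta = trial
        if not np.isfinite(new_ll):
            raise FitError("IRLS diverged (non-finite log-likelihood)")
        converged = abs(new_ll - ll) <= tol * (abs(ll) + 1.0)
        beta, ll, mu, eta = step_beta, new_ll, new_mu, new_eta
        if converged:
            break
    else:
        raise FitError(f"IRLS did not converge in {max_iter} iterations")
    # observed = expected Fisher information for the canonical link
    wt = w * mu
    info = (X * wt[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    return beta, np.sqrt(np.maximum(np.diag(cov), 0.0)), ll, mu


def lr_test(model_null: IntensityModel, model_full: IntensityModel) -> dict:
    """Likelihood-ratio test between nested intensity models fitted on the
    same pattern and quadrature."""
    if model_null.quadrature != model_full.quadrature or \
            model_null.n_points != model_full.n_points:
        raise NestingError("models were fitted on different data/quadrature")
    if model_null.strata != model_full.strata:
        raise NestingError(
            "models use different quadrature strata; refit the null with "
            "strata matching the full model")
    if model_null.df >= model_full.df:
        raise NestingError("null model must have fewer parameters")
    if not set(model_null.coefficients.index) <= \
            set(model_full.coefficients.index):
        raise NestingError("null model terms are not a subset of the full")
    chi2 = 2.0 * (model_full.loglik - model_null.loglik)
    df = model_full.df - model_null.df
    return dict(chi2=float(chi2), df=int(df),
                p=float(stats.chi2.sf(max(chi2, 0.0), df)))


# ---------------------------------------------------------------------------
# simulation of inhomogeneous Poisson patterns
# ---------------------------------------------------------------------------

def simulate_ipp(intensity, window=SCREEN_WINDOW,
                 rng: np.random.Generator | None = None,
                 lambda_max: float | None = None) -> np.ndarray:
    """Simulate an inhomogeneous Poisson pattern by thinning.

    ``intensity`` is either a callable ``f(x, y) -> rate`` or a constant.
    Returns an (n, 2) array of points.
    """
    rng = rng if rng is not None else np.random.default_rng()
    x0, x1, y0, y1 = window
    if np.isscalar(intensity):
        lam = float(intensity)
        n = rng.poisson(lam * window_area(window))
        return np.column_stack([rng.uniform(x0, x1, n),
                                rng.uniform(y0, y1, n)])
    if lambda_max is None:
        gx = np.linspace(x0, x1, 201)
        gy = np.linspace(y0, y1, 201)
        GX, GY = np.meshgrid(gx, gy)
        lambda_max = float(np.max(intensity(GX, GY))) * 1.05
    if not np.isfinite(lambda_max) or lambda_max < 0:
        raise InvalidArgumentError("intensity bound must be finite and >= 0")
    n = rng.poisson(lambda_max * window_area(window))
    pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    if n == 0:
        return pts
    accept = rng.random(n) < intensity(pts[:, 0], pts[:, 1]) / lambda_max
    return pts[accept]


def model_intensity_function(model: IntensityModel, marks: dict | None = None):
    """Wrap a fitted model as a callable f(x, y) for simulation."""
    marks = marks or {}

    def f(x, y):
        x = np.asarray(x, dtype=float)
        df = pd.DataFrame(dict(x_deg=x.ravel(),
                               y_deg=np.asarray(y, dtype=float).ravel()))
        for k, v in marks.items():
            df[k] = v
        return model.intensity(df).reshape(np.shape(x))

    return f


# ---------------------------------------------------------------------------
# inhomogeneous K function
# ---------------------------------------------------------------------------

def kinhom(points: np.ndarray, lam: np.ndarray, r_grid: np.ndarray,
           window=SCREEN_WINDOW) -> np.ndarray:
    """Border-corrected inhomogeneous K estimate.

    For each r, centers are the points at least r from the boundary;
    K(r) = mean over centers i of sum_{j != i, d_ij <= r} 1 / lambda(x_j).
    Under a Poisson process with the true intensity this is unbiased for
    pi r^2.
    """
    points = np.asarray(points, dtype=float)
    lam = np.asarray(lam, dtype=float)
    x0, x1, y0, y1 = window
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.max() > min(x1 - x0, y1 - y0) / 2.0:
        raise GeometryError("r exceeds half the shorter window side")
    n = len(points)
    if n < 2:
        return np.zeros_like(r_grid)
    border = np.minimum.reduce([points[:, 0] - x0, x1 - points[:, 0],
                                points[:, 1] - y0, y1 - points[:, 1]])
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    inv_lam = 1.0 / lam
    out = np.empty_like(r_grid)
    for k, r in enumerate(r_grid):
        centers = border >= r
        if not centers.any():
            out[k] = np.nan
            continue
        contrib = ((d[centers] <= r) * inv_lam[None, :]).sum(axis=1)
        out[k] = contrib.mean()
    return out


def kinhom_envelope(pattern: PointPattern, model: IntensityModel,
                    r_grid=None, n_sim: int = 99,
                    rng: np.random.Generator | None = None,
                    marks: dict | None = None) -> pd.DataFrame:
    """K-hat for the data plus a pointwise min/max envelope from ``n_sim``
    simulations of the fitted inhomogeneous Poisson model."""
    rng = rng if rng is not None else np.random.default_rng()
    if r_grid is None:
        r_grid = np.linspace(0.0, 5.0, 26)
    r_grid = np.asarray(r_grid, dtype=float)
    f = model_intensity_function(model, marks)
    pts = pattern.points
    lam_data = f(pts[:, 0], pts[:, 1])
    if np.any(lam_data <= 0):
        raise InvalidArgumentError("fitted intensity must be positive")
    k_obs = kinhom(pts, lam_data, r_grid, pattern.window)
    sims = np.empty((n_sim, r_grid.size))
    for i in range(n_sim):
        sp = simulate_ipp(f, pattern.window, rng)
        sims[i] = (kinhom(sp, f(sp[:, 0], sp[:, 1]), r_grid, pattern.window)
                   if len(sp) >= 2 else 0.0)
    return pd.DataFrame(dict(
        r=r_grid, k_obs=k_obs, k_theo=np.pi * r_grid ** 2,
        lo=np.nanmin(sims, axis=0), hi=np.nanmax(sims, axis=0)))


# ---------------------------------------------------------------------------
# distances, ellipses, dispersion
# ---------------------------------------------------------------------------

def pairwise_distance_summary(points: np.ndarray) -> dict:
    """Median and quartiles of all n(n-1)/2 Euclidean pairwise distances."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise InsufficientDataError("pairwise distances need >= 2 points")
    d = pdist(points)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return dict(median=float(med), q1=float(q1), q3=float(q3), distances=d)


@dataclass
class EllipseSummary:
    """Variance ellipse of a 2-D point cloud."""

    center: tuple[float, float]
    var_max: float
    var_min: float
    orientation_deg: float       # major-axis angle from horizontal, CCW
    area: float                  # coverage ellipse area
    n: int
    degenerate: bool = False


def variance_ellipse(points: np.ndarray, coverage: float = 0.95
                     ) -> EllipseSummary:
    """Covariance eigendecomposition of a point cloud.

    The area of the coverage ellipse is pi * c * sqrt(var_max * var_min)
    with c the chi-square(2 df) quantile at ``coverage`` (5.991 for 95%).
    Collinear clouds are flagged degenerate with zero area.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise InsufficientDataError("variance ellipse needs >= 3 points")
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    var_min, var_max = float(max(evals[0], 0.0)), float(evals[1])
    major = evecs[:, 1]
    orientation = float(np.degrees(np.arctan2(major[1], major[0]))) % 180.0
    c = float(stats.chi2.ppf(coverage, 2))
    degenerate = var_min <= 1e-12 * max(var_max, 1.0)
    area = 0.0 if degenerate else float(np.pi * c * np.sqrt(var_max * var_min))
    return EllipseSummary(center=tuple(points.mean(axis=0)),
                          var_max=var_max, var_min=var_min,
                          orientation_deg=orientation, area=area,
                          n=len(points), degenerate=degenerate)


def variance_f_test(var_a: float, n_a: int, var_b: float, n_b: int) -> dict:
    """Two-sided F test for a ratio of variances."""
    if var_a <= 0 or var_b <= 0:
        raise InvalidArgumentError("variances must be positive")
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError("F test needs n >= 2 per sample")
    F = var_a / var_b
    df1, df2 = n_a - 1, n_b - 1
    p_one = stats.f.sf(F, df1, df2) if F >= 1 else stats.f.cdf(F, df1, df2)
    return dict(F=float(F), df1=df1, df2=df2,
                p=float(min(1.0, 2.0 * p_one)))


def per_subject_dispersion(gaze: pd.DataFrame, n_draws: int = 4000,
                           rng: np.random.Generator | None = None) -> dict:
    """Total gaze SD per subject x noise level and group comparison.

    The per-cell dispersion is sqrt(var_x + var_y) over the repeated trials
    of that subject at that noise level; groups are compared per level with
    the Bayesian bootstrap on the subject-level values.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for (sid, lv), g in gaze.groupby(["subject_id", "noise_level"]):
        if len(g) < 2:
            logger.info("per_subject_dispersion: skipping %s at %s "
                        "(single point)", sid, lv)
            continue
        rows.append(dict(
            subject_id=sid,
            group=g["group"].iloc[0] if "group" in g else "",
            noise_level=lv,
            sd_total=float(np.sqrt(g["x_deg"].var(ddof=1)
                                   + g["y_deg"].var(ddof=1))),
            n_trials=len(g)))
    table = pd.DataFrame(rows)
    groups = sorted(table["group"].unique())
    prob = {}
    if len(groups) == 2:
        for lv, g_lv in table.groupby("noise_level"):
            boots = {grp: bayes_boot(g["sd_total"].to_numpy(), "mean",
                                     n_draws=n_draws, rng=rng)
                     for grp, g in g_lv.groupby("group")}
            if len(boots) == 2:
                prob[lv] = boot_compare(boots[groups[0]], boots[groups[1]])
    return dict(table=table, p_first_greater=prob)


def mean_gaze_positions(gaze: pd.DataFrame) -> pd.DataFrame:
    """Mean gaze position per subject (pooled over trials)."""
    return (gaze.groupby(["subject_id", "group"], as_index=False)
            .agg(x_deg=("x_deg", "mean"), y_deg=("y_deg", "mean"),
                 n=("x_deg", "size")))


def group_pairwise_distances(gaze: pd.DataFrame) -> dict:
    """Pairwise distances between subjects' mean gaze positions, per group."""
    means = mean_gaze_positions(gaze)
    out = {}
    for grp, g in means.groupby("group"):
        summ = pairwise_distance_summary(g[["x_deg", "y_deg"]].to_numpy())
        out[grp] = summ
    return out


def subject_gaze_areas(gaze: pd.DataFrame, coverage: float = 0.95,
                       method: str = "ellipse") -> pd.DataFrame:
    """Per-subject gaze area pooled over trials.

    ``method="ellipse"`` (default) uses the coverage variance-ellipse area;
    ``method="hull"`` the convex-hull area.
    """
    rows = []
    for (sid, grp), g in gaze.groupby(["subject_id", "group"]):
        pts = g[["x_deg", "y_deg"]].to_numpy(float)
        if method == "ellipse":
            area = variance_ellipse(pts, coverage).area
        elif method == "hull":
            from scipy.spatial import ConvexHull
            area = float(ConvexHull(pts).volume)
        else:
            raise InvalidArgumentError(f"unknown area method {method!r}")
        rows.append(dict(subject_id=sid, group=grp, area=area, n=len(pts)))
    return pd.DataFrame(rows)


def gaze_area_correlations(gaze: pd.DataFrame, accuracy: pd.DataFrame,
                           rt: pd.DataFrame | None = None,
                           iq: pd.DataFrame | None = None,
                           coverage: float = 0.95) -> dict:
    """Correlations of per-subject gaze area with performance and IQ.

    ``accuracy`` needs columns (subject_id, prop_correct) -- subject means
    are taken if multiple rows per subject; ``rt`` likewise with median_rt;
    ``iq`` with iq.  Missing subjects are dropped with a warning.
    """
    areas = subject_gaze_areas(gaze, coverage).set_index("subject_id")
    out = {}

    def corr_with(table, col, name):
        merged = areas.join(
            table.groupby("subject_id")[col].mean(), how="inner")
        dropped = len(areas) - len(merged)
        if dropped:
            logger.warning("gaze_area_correlations: dropped %d subjects "
                           "missing from %s", dropped, name)
        out[name] = pearson_ci(merged["area"], merged[col])

    corr_with(accuracy, "prop_correct", "accuracy")
    if rt is not None:
        corr_with(rt, "median_rt", "rt")
    if iq is not None:
        corr_with(iq, "iq", "iq")
    return out
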