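"""Gabor contour-in-noise stimulus generation.

A field of Gabor patches sits on an invisible regular hexagonal grid
(default 39 columns x 25 rows, 1.044 deg spacing, 975 elements).  On signal
trials a straight 12-element contour with mean orientation 60 deg from
horizontal is embedded along a lattice direction near the screen center;
external noise is injected by tilting half of the contour elements by +delta
and half by -delta, which preserves the mean contour orientation exactly
while setting its orientation SD to delta.  Background elements (and every
element on noise trials) carry independent uniform orientations on
(-90, 90] deg.

Coordinates are degrees of visual angle, origin at screen center, x rightward
and y upward.  Orientations are degrees from horizontal, counter-clockwise
positive, wrapped to (-90, 90]; a Gabor's "orientation" is its stripe axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    BalancedAssignmentError,
    ConfigurationError,
    GeometryError,
    InvalidArgumentError,
    UnsupportedDirectionError,
)

logger = logging.getLogger(__name__)

SQRT3 = float(np.sqrt(3.0))

#: Lattice directions (degrees from horizontal) along which straight runs of
#: grid points exist in a row-oriented hexagonal grid.
LATTICE_DIRECTIONS = (0.0, 60.0, 120.0)


# ---------------------------------------------------------------------------
# specification and trial containers
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """Geometric and photometric description of the display.

    Defaults reproduce the reference experiment: a 16:9 screen of
    40 x 22.5 deg at 48 px/deg (1920 x 1080), 5.75 cpd Gabors with a
    0.087 deg Gaussian envelope truncated at a 0.522 deg diameter, shown at
    75% Michelson contrast for 200 ms.
    """

    n_cols: int = 39
    n_rows: int = 25
    spacing: float = 1.044
    gabor_sf: float = 5.75
    gabor_sigma: float = 0.087
    gabor_diameter: float = 0.522
    contrast: float = 0.75
    contour_length: int = 12
    contour_orientation: float = 60.0
    noise_levels: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0)
    double_pass_levels: tuple[float, ...] = (10.0, 45.0)
    screen_deg: tuple[float, float] = (40.0, 22.5)
    px_per_deg: float = 48.0
    duration_ms: float = 200.0  # metadata only; no timing is simulated

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise InvalidArgumentError("grid dimensions must be >= 1")
        if self.spacing <= 0:
            raise InvalidArgumentError("spacing must be positive")
        if self.contour_length % 2 != 0:
            raise InvalidArgumentError("contour_length must be even")
        if not (0 < self.contrast <= 1) and self.contrast != 0:
            raise InvalidArgumentError("contrast must lie in [0, 1]")
        for lv in self.noise_levels:
            if not (0 <= lv < 90):
                raise InvalidArgumentError(
                    f"noise level {lv} outside [0, 90) degrees")
        missing = [lv for lv in self.double_pass_levels
                   if lv not in self.noise_levels]
        if missing:
            raise ConfigurationError(
                f"double-pass levels {missing} not among noise levels")

    @property
    def n_elements(self) -> int:
        return self.n_cols * self.n_rows

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("noise_levels", "double_pass_levels", "screen_deg"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        for k in ("noise_levels", "double_pass_levels", "screen_deg"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class HexGrid:
    """Hexagonal grid of element positions (bounding box centered on origin)."""

    cols: np.ndarray   # (n,) int
    rows: np.ndarray   # (n,) int
    x: np.ndarray      # (n,) float, degrees
    y: np.ndarray      # (n,) float, degrees
    spacing: float

    def __len__(self) -> int:
        return self.x.size

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates."""
        return np.column_stack([self.x, self.y])


@dataclass
class TrialStimulus:
    """One display: per-element orientations plus the generating metadata."""

    trial_id: int
    stimulus_class: str               # "signal" | "noise"
    noise_level: float                # jitter delta, degrees
    orientations: np.ndarray          # (n_elements,) degrees in (-90, 90]
    contour_indices: np.ndarray       # (contour_length,) grid indices
    seed: int                         # child seed used for this trial's draws

    def copy(self) -> "TrialStimulus":
        return replace(
            self,
            orientations=self.orientations.copy(),
            contour_indices=self.contour_indices.copy(),
        )


@dataclass
class Block:
    """An ordered block of trials at one noise level."""

    block_index: int                  # 1-based position in the session
    pass_index: int                   # 1 or 2
    noise_level: float
    trials: list[TrialStimulus] = field(default_factory=list)


# ---------------------------------------------------------------------------
# orientation helpers
# ---------------------------------------------------------------------------

def wrap_orientation(theta):
    """Wrap orientation(s) in degrees to the interval (-90, 90]."""
    w = np.asarray(theta, dtype=float)
    w = ((w + 90.0) % 180.0) - 90.0
    w = np.where(w == -90.0, 90.0, w)
    return float(w) if np.isscalar(theta) else w


def unwrap_about(theta, center: float):
    """Map orientation(s) to the representative in (center-90, center+90]."""
    w = np.asarray(theta, dtype=float)
    w = ((w - center + 90.0) % 180.0) - 90.0
    w = np.where(w == -90.0, 90.0, w)
    out = w + center
    return float(out) if np.isscalar(theta) else out


def _uniform_orientations(rng: np.random.Generator, size) -> np.ndarray:
    """Independent uniform draws on (-90, 90] degrees."""
    return 90.0 - rng.uniform(0.0, 180.0, size=size)


# ---------------------------------------------------------------------------
# grid and contour geometry
# ---------------------------------------------------------------------------

def build_hex_grid(n_cols: int, n_rows: int, spacing: float) -> HexGrid:
    """Build a row-oriented hexagonal grid with its bounding box centered.

    Rows are horizontal with vertical pitch ``spacing * sqrt(3)/2``; odd rows
    (1-based rows 2, 4, ...) are offset by ``spacing / 2`` so each interior
    point has six nearest neighbors at exactly ``spacing``.
    """
    if n_cols < 1 or n_rows < 1:
        raise InvalidArgumentError("n_cols and n_rows must be >= 1")
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive")
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cols = cols.ravel()
    rows = rows.ravel()
    x = cols * spacing + (rows % 2) * (spacing / 2.0)
    y = rows * (spacing * SQRT3 / 2.0)
    x = x - (x.min() + x.max()) / 2.0
    y = y - (y.min() + y.max()) / 2.0
    return HexGrid(cols=cols, rows=rows, x=x, y=y, spacing=spacing)


def select_contour_path(grid: HexGrid, length: int, path_angle: float
                        ) -> np.ndarray:
    """Select ``length`` consecutive collinear grid indices along a lattice axis.

    The run whose midpoint lies closest to the screen center is returned
    (ties broken deterministically by midpoint coordinates, then indices).
    With the default 39 x 25 centered grid an even-length run along 60 deg
    cannot straddle the exact center -- a grid row lies on the horizontal
    midline -- so the midpoint sits half a row pitch from the origin.
    """
    angle = float(path_angle) % 180.0
    if not any(abs(angle - a) < 1e-9 for a in LATTICE_DIRECTIONS):
        raise UnsupportedDirectionError(
            f"path angle {path_angle} deg is not a lattice direction "
            f"{LATTICE_DIRECTIONS} of the hexagonal grid")
    if length < 2:
        raise InvalidArgumentError("contour length must be >= 2")

    s = grid.spacing
    rad = np.deg2rad(angle)
    step = np.array([np.cos(rad) * s, np.sin(rad) * s])

    # integer lattice key: after bbox centering x is a multiple of s/4 and y a
    # multiple of s*sqrt(3)/2, so quantize by those units
    def key(px, py):
        return (int(round(4.0 * px / s)), int(round(2.0 * py / (s * SQRT3))))

    index_of = {key(px, py): i for i, (px, py) in
                enumerate(zip(grid.x, grid.y))}

    pts = grid.points
    best = None
    for i0 in range(len(grid)):
        start = pts[i0]
        run = [i0]
        ok = True
        for k in range(1, length):
            p = start + k * step
            j = index_of.get(key(p[0], p[1]))
            if j is None:
                ok = False
                break
            run.append(j)
        if not ok:
            continue
        mid = start + (length - 1) / 2.0 * step
        score = (float(np.hypot(mid[0], mid[1])),
                 round(mid[0], 9), round(mid[1], 9), i0)
        if best is None or score < best[0]:
            best = (score, run)
    if best is None:
        raise GeometryError(
            f"no run of {length} collinear points along {path_angle} deg "
            f"fits inside the grid")
    return np.asarray(best[1], dtype=int)


def hex_neighbor_indices(grid: HexGrid, indices: np.ndarray,
                         tol: float = 1e-6) -> np.ndarray:
    """Grid indices adjacent (at one lattice spacing) to any of ``indices``,
    excluding ``indices`` themselves."""
    pts = grid.points
    sel = pts[np.asarray(indices, dtype=int)]
    d = np.linalg.norm(pts[:, None, :] - sel[None, :, :], axis=2)
    near = (d <= grid.spacing + tol).any(axis=1)
    near[np.asarray(indices, dtype=int)] = False
    # drop the selected points themselves (distance 0 handled above)
    return np.flatnonzero(near)


# ---------------------------------------------------------------------------
# orientation assignment
# ---------------------------------------------------------------------------

def assign_orientations(grid: HexGrid, contour_indices: np.ndarray,
                        stimulus_class: str, noise_level: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw the per-element orientation field for one trial.

    Background positions (all positions on noise trials) get independent
    uniform orientations on (-90, 90].  On signal trials exactly half of the
    contour elements are tilted to ``60 + delta`` and half to ``60 - delta``
    (assignment by random permutation), so the unwrapped contour mean is 60
    exactly and its population SD is exactly ``delta``.
    """
    if stimulus_class not in ("signal", "noise"):
        raise InvalidArgumentError(
            f"stimulus_class must be 'signal' or 'noise', got {stimulus_class!r}")
    if not (0 <= noise_level < 90):
        raise InvalidArgumentError("noise level must lie in [0, 90) degrees")
    contour_indices = np.asarray(contour_indices, dtype=int)

    orientations = _uniform_orientations(rng, len(grid))
    if stimulus_class == "signal":
        n = contour_indices.size
        if n % 2 != 0:
            raise BalancedAssignmentError(
                "balanced +/- jitter needs an even contour length")
        signs = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        signs = signs[rng.permutation(n)]
        contour = 60.0 + signs * noise_level
        orientations[contour_indices] = wrap_orientation(contour)
    return orientations


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_stimulus(spec: StimulusSpec, trial: TrialStimulus,
                    grid: HexGrid | None = None) -> np.ndarray:
    """Render one trial to a luminance image in [0, 1] (background 0.5).

    Each element is an odd-symmetric (sine-phase) Gabor: carrier stripes
    along the element orientation, Gaussian envelope SD ``gabor_sigma``,
    truncated at ``gabor_diameter / 2``.  Sine phase makes each patch
    zero-mean, so the image mean equals the background.  Overlapping patches
    are summed; values are clipped to [0, 1] and clipping is logged.
    """
    if spec.px_per_deg <= 0:
        raise InvalidArgumentError("px_per_deg must be positive")
    grid = grid if grid is not None else build_hex_grid(
        spec.n_cols, spec.n_rows, spec.spacing)

    w_px = int(round(spec.screen_deg[0] * spec.px_per_deg))
    h_px = int(round(spec.screen_deg[1] * spec.px_per_deg))
    img = np.zeros((h_px, w_px))

    ppd = spec.px_per_deg
    radius = spec.gabor_diameter / 2.0
    r_px = int(np.ceil(radius * ppd))
    amp = spec.contrast / 2.0  # Michelson contrast on a 0.5 background
    two_pi_f = 2.0 * np.pi * spec.gabor_sf

    # pixel-center coordinate grids for one patch window
    span = np.arange(-r_px, r_px + 1)
    theta = np.deg2rad(trial.orientations)
    for (ex, ey, th) in zip(grid.x, grid.y, theta):
        # element center in pixel coordinates (row 0 = top)
        cx = ex * ppd + w_px / 2.0 - 0.5
        cy = h_px / 2.0 - ey * ppd - 0.5
        icx, icy = int(round(cx)), int(round(cy))
        xs = icx + span
        ys = icy + span
        vx = np.clip(xs, 0, w_px - 1)
        vy = np.clip(ys, 0, h_px - 1)
        dx = (xs - cx) / ppd
        dy = (cy - ys) / ppd  # back to y-up degrees
        DX, DY = np.meshgrid(dx, dy)
        rr2 = DX ** 2 + DY ** 2
        mask = rr2 <= radius ** 2
        # distance across the stripes (perpendicular to orientation axis)
        v = -DX * np.sin(th) + DY * np.cos(th)
        patch = amp * np.sin(two_pi_f * v) \
            * np.exp(-rr2 / (2.0 * spec.gabor_sigma ** 2))
        patch = np.where(mask, patch, 0.0)
        # additive accumulation with border clipping
        inside = (xs >= 0) & (xs < w_px)
        inside_y = (ys >= 0) & (ys < h_px)
        img[np.ix_(vy[inside_y], vx[inside])] += patch[np.ix_(inside_y, inside)]

    img += 0.5
    n_clip = int(np.count_nonzero((img < 0) | (img > 1)))
    if n_clip:
        logger.info("render_stimulus: clipped %d pixels to [0, 1]", n_clip)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# block / session design
# ---------------------------------------------------------------------------

def generate_block(spec: StimulusSpec, noise_level: float,
                   rng: np.random.Generator, n_signal: int = 30,
                   n_noise: int = 30, grid: HexGrid | None = None,
                   contour_indices: np.ndarray | None = None,
                   block_index: int = 1, pass_index: int = 1) -> Block:
    """Generate one block: randomly interleaved signal and noise trials,
    each with a fresh stimulus sample."""
    if n_signal < 0 or n_noise < 0:
        raise InvalidArgumentError("trial counts must be >= 0")
    grid = grid if grid is not None else build_hex_grid(
        spec.n_cols, spec.n_rows, spec.spacing)
    if contour_indices is None:
        contour_indices = select_contour_path(
            grid, spec.contour_length, spec.contour_orientation)

    classes = ["signal"] * n_signal + ["noise"] * n_noise
    order = rng.permutation(len(classes))
    trials: list[TrialStimulus] = []
    for t, idx in enumerate(order):
        cls = classes[idx]
        child_seed = int(rng.integers(0, 2 ** 31))
        trial_rng = np.random.default_rng(child_seed)
        orientations = assign_orientations(
            grid, contour_indices, cls, noise_level, trial_rng)
        trials.append(TrialStimulus(
            trial_id=t, stimulus_class=cls, noise_level=noise_level,
            orientations=orientations, contour_indices=contour_indices.copy(),
            seed=child_seed))
    return Block(block_index=block_index, pass_index=pass_index,
                 noise_level=noise_level, trials=trials)


def generate_session_design(spec: StimulusSpec, rng: np.random.Generator,
                            n_signal: int = 30, n_noise: int = 30,
                            grid: HexGrid | None = None) -> list[Block]:
    """Generate the eight-block session.

    Blocks 1-6 run the six noise levels in random order (pass 1); blocks 7-8
    repeat the double-pass levels (default 10 and 45 deg) as exact
    stimulus-by-stimulus replicas of their pass-1 blocks, in random order,
    always last.
    """
    missing = [lv for lv in spec.double_pass_levels
               if lv not in spec.noise_levels]
    if missing:
        raise ConfigurationError(
            f"double-pass levels {missing} absent from noise levels")
    grid = grid if grid is not None else build_hex_grid(
        spec.n_cols, spec.n_rows, spec.spacing)
    contour = select_contour_path(
        grid, spec.contour_length, spec.contour_orientation)

    level_order = [spec.noise_levels[i]
                   for i in rng.permutation(len(spec.noise_levels))]
    blocks = []
    by_level = {}
    for b, lv in enumerate(level_order, start=1):
        block = generate_block(spec, lv, rng, n_signal, n_noise, grid=grid,
                               contour_indices=contour, block_index=b,
                               pass_index=1)
        blocks.append(block)
        by_level[lv] = block

    repeat_order = [spec.double_pass_levels[i]
                    for i in rng.permutation(len(spec.double_pass_levels))]
    for b, lv in enumerate(repeat_order, start=len(level_order) + 1):
        first = by_level[lv]
        replica = Block(
            block_index=b, pass_index=2, noise_level=lv,
            trials=[t.copy() for t in first.trials])
        blocks.append(replica)
    return blocks


def block_metadata(blocks: list[Block]) -> "pd.DataFrame":  # noqa: F821
    """Tidy per-trial metadata table for a session design."""
    import pandas as pd

    rows = []
    for blk in blocks:
        for t in blk.trials:
            rows.append(dict(trial_id=t.trial_id, block=blk.block_index,
                             pass_index=blk.pass_index,
                             noise_level=blk.noise_level,
                             stimulus_class=t.stimulus_class, seed=t.seed))
    return pd.DataFrame(rows)


def orientation_table(spec: StimulusSpec, trial: TrialStimulus,
                      grid: HexGrid | None = None) -> "pd.DataFrame":  # noqa: F821
    """Per-element sidecar table (grid index, position, orientation, contour flag)."""
    import pandas as pd

    grid = grid if grid is not None else build_hex_grid(
        spec.n_cols, spec.n_rows, spec.spacing)
    is_contour = np.zeros(len(grid), dtype=bool)
    is_contour[trial.contour_indices] = True
    return pd.DataFrame(dict(
        grid_index=np.arange(len(grid)), col=grid.cols, row=grid.rows,
        x_deg=grid.x, y_deg=grid.y, orientation_deg=trial.orientations,
        is_contour=is_contour))
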