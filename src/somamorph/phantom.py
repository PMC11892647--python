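"""Synthetic ganglion-pair phantoms with planted morphometric structure.

The generator emulates the population structure of a bilaterally symmetric
pair of roughly ellipsoidal invertebrate ganglia in which

* soma volumes are lognormal and span more than two orders of magnitude,
* roughly half the somata sit on the ganglion surface (depth 0) and the
  rest are fully internalized (surface distance >= the superficial
  threshold tau),
* dorsal-face superficial somata are systematically larger than ventral
  ones (multiplicative ``dorsal_scale`` on volume), and
* among internalized somata log-volume declines linearly with depth, with
  Gaussian noise calibrated so the planted Spearman correlation between
  depth and volume hits ``target_depth_rho``.

Cells are rasterized as non-overlapping spheres into an integer label
volume (0 = background, k = cell k) under the voxel-center convention:
voxel index ``(i, j, k)`` sits at physical position
``((i+0.5)*sx, (j+0.5)*sy, (k+0.5)*sz)`` micrometres.

Axis convention: axis 0 = left-right (the mirror axis), axis 1 =
dorsoventral (+ = dorsal), axis 2 = anteroposterior (nerve-exit caps at
the +-z poles of each ellipsoid).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import rankdata

__all__ = [
    "SimConfig",
    "PlantedCell",
    "GroundTruthTable",
    "LabelVolume",
    "sample_cell_population",
    "rasterize_cells",
    "generate_ganglion_pair",
    "ellipsoid_surface_distance",
]

Side = Literal["left", "right"]
Face = Literal["dorsal", "ventral", "other", "none"]
DepthClass = Literal["superficial", "internalized"]


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a cell (over-dense config)."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic ganglion pair.

    Defaults plant the population structure of the real dataset: 542 + 557
    cells, 526 of them internalized, volumes spanning two orders of
    magnitude, dorsal > ventral superficial volumes, and a depth-volume
    Spearman correlation of -0.368 among internalized cells.
    """

    grid_shape: tuple[int, int, int] = (312, 180, 204)
    spacing_um: tuple[float, float, float] = (1.625, 1.625, 1.625)
    ganglion_semi_axes_um: tuple[float, float, float] = (115.0, 125.0, 145.0)
    n_cells_left: int = 542
    n_cells_right: int = 557
    internal_fraction: float = 526 / 1099
    logvol_mu: float = 7.6           # log µm³; median soma ≈ 16 µm diameter
    logvol_sigma: float = 1.4        # >100-fold 1st-99th percentile volume range
    dorsal_scale: float = 1.8        # multiplicative volume factor, dorsal face
    depth_slope: float = -0.02       # d(log volume)/d(depth), per µm
    target_depth_rho: float = -0.368
    superficial_threshold_um: float = 8.125
    depth_max_um: float = 60.0       # deepest planted cell-to-surface distance
    min_radius_um: float = 4.0       # soma diameter >= 8 µm
    cap_half_angle_deg: float = 3.0  # nerve-exit exclusion caps at ±z poles
    # commissure exclusion: no superficial cells on the medial pole facing
    # the partner ganglion (the crevice between the pair is bridged by the
    # closing ball, so somata there would be buried inside the mask)
    medial_cap_half_angle_deg: float = 25.0
    face_other_band: float = 0.3     # |normal·DV axis| below this → face "other"
    ganglion_gap_um: float = 4.0     # medial gap between the two ellipsoids
    max_place_attempts: int = 10_000
    seed: int = 0
    mirror_exact: bool = False       # left = exact mirror copy of right (testing)

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """Coarse-grid preset (2.5 µm voxels) for fast end-to-end runs.

        Identical planted population; only the rasterization grid changes.
        """
        kw = dict(grid_shape=(204, 116, 132), spacing_um=(2.5, 2.5, 2.5))
        kw.update(overrides)
        return cls(**kw)

    # -- derived geometry ------------------------------------------------
    @property
    def grid_extent_um(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * np.asarray(self.spacing_um, float)

    @property
    def ganglion_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(left_center, right_center) in physical µm coordinates."""
        ext = self.grid_extent_um
        ax = self.ganglion_semi_axes_um[0]
        off = ax + self.ganglion_gap_um / 2.0
        mid = ext / 2.0
        left = mid + np.array([-off, 0.0, 0.0])
        right = mid + np.array([+off, 0.0, 0.0])
        return left, right

    def validate(self) -> None:
        sp = np.asarray(self.spacing_um, float)
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError("spacing_um must be 3 positive reals")
        a = np.asarray(self.ganglion_semi_axes_um, float)
        if np.any(a <= 0):
            raise ValueError("ganglion_semi_axes_um must be positive")
        if self.n_cells_left < 0 or self.n_cells_right < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.internal_fraction <= 1.0:
            raise ValueError("internal_fraction must be in [0, 1]")
        if self.min_radius_um <= 0 or self.superficial_threshold_um <= 0:
            raise ValueError("radii and thresholds must be positive")
        if self.depth_max_um <= self.superficial_threshold_um:
            raise ValueError("depth_max_um must exceed superficial_threshold_um")
        if self.mirror_exact and self.n_cells_left != self.n_cells_right:
            raise ValueError("mirror_exact requires equal left/right counts")
        # ellipsoid pair must fit with >= 2-voxel margin on every side
        ext = self.grid_extent_um
        margin = 2.0 * sp
        need_x = 4 * a[0] + self.ganglion_gap_um + 2 * margin[0]
        if need_x > ext[0]:
            raise ValueError(f"grid too small along axis 0: need {need_x:.1f} µm, have {ext[0]:.1f}")
        for axis in (1, 2):
            need = 2 * a[axis] + 2 * margin[axis]
            if need > ext[axis]:
                raise ValueError(f"grid too small along axis {axis}: need {need:.1f} µm, have {ext[axis]:.1f}")


@dataclass(frozen=True)
class PlantedCell:
    """Ground truth for one synthetic soma (a sphere)."""

    cell_id: int
    center_um: tuple[float, float, float]
    radius_um: float
    side: Side
    face: Face
    depth_um: float          # min distance from the sphere to the ellipsoid surface
    depth_class: DepthClass

    @property
    def volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_um**3


@dataclass
class GroundTruthTable:
    """Planted parameters for every cell plus the generating config."""

    rows: list[PlantedCell]
    config: SimConfig

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[PlantedCell]:
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.rows],
                "side": [c.side for c in self.rows],
                "face": [c.face for c in self.rows],
                "cx_um": [c.center_um[0] for c in self.rows],
                "cy_um": [c.center_um[1] for c in self.rows],
                "cz_um": [c.center_um[2] for c in self.rows],
                "radius_um": [c.radius_um for c in self.rows],
                "depth_um": [c.depth_um for c in self.rows],
                "depth_class": [c.depth_class for c in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: Optional[SimConfig] = None) -> "GroundTruthTable":
        df = pd.read_csv(path)
        rows = [
            PlantedCell(
                cell_id=int(r.cell_id),
                center_um=(float(r.cx_um), float(r.cy_um), float(r.cz_um)),
                radius_um=float(r.radius_um),
                side=r.side,
                face=r.face,
                depth_um=float(r.depth_um),
                depth_class=r.depth_class,
            )
            for r in df.itertuples()
        ]
        return cls(rows=rows, config=config if config is not None else SimConfig())


@dataclass
class LabelVolume:
    """3D integer label grid with physical voxel spacing in µm."""

    labels: np.ndarray                      # int array, 0 = background
    spacing_um: tuple[float, float, float]
    true_mask: Optional[np.ndarray] = None  # generating ellipsoid pair, if synthetic

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _sample_surface_points(
    rng: np.random.Generator, semi_axes: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted sample of points (and unit outward normals) on an ellipsoid.

    Uniform sphere directions are reweighted by the surface-element Jacobian
    so the sample is uniform per unit area, not per unit solid angle.
    """
    a = semi_axes
    pts = np.empty((n, 3))
    nrm = np.empty((n, 3))
    w_max = float(np.max([a[1] * a[2], a[0] * a[2], a[0] * a[1]]))
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        w = np.sqrt(
            (u[:, 0] * a[1] * a[2]) ** 2
            + (u[:, 1] * a[0] * a[2]) ** 2
            + (u[:, 2] * a[0] * a[1]) ** 2
        )
        keep = rng.uniform(0, w_max, size=m) < w
        u = u[keep]
        take = min(len(u), n - got)
        u = u[:take]
        p = u * a
        nv = p / a**2
        nv /= np.linalg.norm(nv, axis=1, keepdims=True)
        pts[got : got + take] = p
        nrm[got : got + take] = nv
        got += take
    return pts, nrm


def ellipsoid_surface_distance(point: Sequence[float], semi_axes: Sequence[float]) -> float:
    """Exact distance from an interior point to an ellipsoid surface.

    Solves the standard Lagrange condition: the foot point is
    ``p_i = a_i^2 q_i / (t + a_i^2)`` with t the root of
    ``sum (a_i q_i / (t + a_i^2))^2 = 1``; for interior points
    t lies in (-a_min^2, 0].
    """
    q = np.asarray(point, float)
    a = np.asarray(semi_axes, float)
    s = float(np.sum((q / a) ** 2))
    if s >= 1.0:
        raise ValueError("point is not strictly inside the ellipsoid")
    if np.allclose(q, 0.0):
        return float(a.min())

    def f(t: float) -> float:
        return float(np.sum((a * q / (t + a**2)) ** 2)) - 1.0

    lo = -float(a.min()) ** 2
    # f(t) -> +inf as t -> lo+ (when q has a component on the short axis);
    # f(0) = s - 1 < 0.
    eps = 1e-9 * float(a.min()) ** 2
    t0 = lo + eps
    while f(t0) < 0:  # q nearly orthogonal to short axis: widen toward 0
        eps *= 10.0
        t0 = lo + eps
        if t0 >= 0:
            return float(a.min() * (1 - math.sqrt(s)))  # degenerate fallback
    t = brentq(f, t0, 0.0, xtol=1e-12)
    foot = a**2 * q / (t + a**2)
    return float(np.linalg.norm(foot - q))


# ---------------------------------------------------------------------------
# depth-noise calibration
# ---------------------------------------------------------------------------

_CALIBRATION_CACHE: dict[tuple, float] = {}


def _truncated_logvol(
    rng: np.random.Generator,
    mean: np.ndarray,
    sigma: float,
    log_floor: float,
    log_ceil: float,
) -> np.ndarray:
    """Gaussian log-volumes, resampled into [log_floor, log_ceil]."""
    x = mean + sigma * rng.normal(size=mean.shape)
    bad = (x < log_floor) | (x > log_ceil)
    for _ in range(200):
        if not bad.any():
            break
        x[bad] = mean[bad] + sigma * rng.normal(size=int(bad.sum()))
        bad = (x < log_floor) | (x > log_ceil)
    np.clip(x, log_floor, log_ceil, out=x)
    return x


def calibrate_depth_noise_sd(config: SimConfig) -> float:
    """Noise SD of internal-cell log-volume that realizes ``target_depth_rho``.

    Solved by bisection of a Monte-Carlo estimate of Spearman(depth,
    log-volume) under the actual sampling scheme (uniform depths, linear
    log-volume model, radius-floor truncation). Deterministic: uses a
    fixed internal RNG, independent of the phantom seed.
    """
    key = (
        round(config.depth_slope, 12),
        round(config.target_depth_rho, 12),
        round(config.superficial_threshold_um, 12),
        round(config.depth_max_um, 12),
        round(config.logvol_mu, 12),
        round(config.min_radius_um, 12),
        round(config.logvol_sigma, 12),
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    slope, target = config.depth_slope, config.target_depth_rho
    if slope == 0.0 or target == 0.0:
        # null configuration: no depth trend to calibrate against
        _CALIBRATION_CACHE[key] = config.logvol_sigma
        return config.logvol_sigma
    if slope * target < 0:
        raise ValueError("depth_slope and target_depth_rho must have the same sign")

    log_floor = math.log(4.0 / 3.0 * math.pi) + 3 * math.log(config.min_radius_um)
    log_ceil = np.inf
    d_lo, d_hi = config.superficial_threshold_um, config.depth_max_um

    def realized_rho(sigma: float) -> float:
        rng = np.random.default_rng(123_456_789)
        vals = []
        for _ in range(6):
            d = rng.uniform(d_lo, d_hi, size=4000)
            mean = config.logvol_mu + slope * d
            lv = _truncated_logvol(rng, mean, sigma, log_floor, log_ceil)
            rd, rv = rankdata(d), rankdata(lv)
            vals.append(float(np.corrcoef(rd, rv)[0, 1]))
        return float(np.mean(vals))

    span = d_hi - d_lo
    hi = abs(slope) * span * 20 + 10 * config.logvol_sigma
    f_lo = realized_rho(1e-9) - target   # nearly deterministic: rho ≈ ±1
    f_hi = realized_rho(hi) - target     # rho ≈ 0
    sign = 1.0 if target > 0 else -1.0
    if sign * f_lo < 0:
        raise ValueError(
            "target_depth_rho stronger than the depth trend can produce; "
            "increase |depth_slope|"
        )
    sd = brentq(lambda s: realized_rho(s) - target, 1e-9, hi, xtol=1e-4)
    _CALIBRATION_CACHE[key] = float(sd)
    return float(sd)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def _sample_base_volumes(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Lognormal soma volumes (µm³), resampled above the radius floor."""
    floor = 4.0 / 3.0 * math.pi * config.min_radius_um**3
    v = rng.lognormal(config.logvol_mu, config.logvol_sigma, size=n)
    bad = v < floor
    for _ in range(200):
        if not bad.any():
            break
        v[bad] = rng.lognormal(config.logvol_mu, config.logvol_sigma, size=int(bad.sum()))
        bad = v < floor
    np.clip(v, floor, None, out=v)
    return v


def _radius_of_volume(v: np.ndarray | float) -> np.ndarray | float:
    return (3.0 * np.asarray(v) / (4.0 * math.pi)) ** (1.0 / 3.0)


def _place_one_ganglion(
    rng: np.random.Generator, config: SimConfig, n_cells: int
) -> list[dict]:
    """Sample one ganglion in its local frame (ellipsoid centered at origin).

    Returns dicts with keys center, radius, face, depth, depth_class, in
    placement order (descending size). Raises PlacementError when the
    attempt cap is hit.
    """
    if n_cells == 0:
        return []
    a = np.asarray(config.ganglion_semi_axes_um, float)
    tau = config.superficial_threshold_um
    n_int = int(round(n_cells * config.internal_fraction))
    n_sup = n_cells - n_int
    cap_cos = math.cos(math.radians(config.cap_half_angle_deg))
    medial_cos = math.cos(math.radians(config.medial_cap_half_angle_deg))

    noise_sd = calibrate_depth_noise_sd(config)
    log_floor = math.log(4.0 / 3.0 * math.pi) + 3 * math.log(config.min_radius_um)

    # superficial: base volume (dorsal scaling applied at the accepted
    # position); internal: depth first, then depth-dependent volume.
    sup_vol = _sample_base_volumes(rng, n_sup, config)
    int_depth = rng.uniform(tau, config.depth_max_um, size=n_int)
    int_mean = config.logvol_mu + config.depth_slope * int_depth
    int_vol = np.exp(_truncated_logvol(rng, int_mean, noise_sd, log_floor, np.inf))

    queue: list[tuple[float, str, float, float]] = []  # (sort radius, kind, volume, depth)
    for v in sup_vol:
        queue.append((float(_radius_of_volume(v)), "sup", float(v), 0.0))
    for v, d in zip(int_vol, int_depth):
        queue.append((float(_radius_of_volume(v)), "int", float(v), float(d)))
    queue.sort(key=lambda t: -t[0])  # largest first raises packing success

    centers = np.empty((n_cells, 3))
    radii = np.empty(n_cells)
    out: list[dict] = []
    n_placed = 0
    for idx, (_, kind, vol, depth) in enumerate(queue):
        placed = False
        for _ in range(config.max_place_attempts):
            p, nrm = _sample_surface_points(rng, a, 1)
            p, nrm = p[0], nrm[0]
            if kind == "sup":
                u = p / a
                un = u / np.linalg.norm(u)
                if abs(un[2]) > cap_cos:
                    continue  # nerve-exit cap
                if -un[0] > medial_cos:
                    continue  # commissure cap (medial pole, local -x)
                ny = float(nrm[1])
                if ny > config.face_other_band:
                    face, v_eff = "dorsal", vol * config.dorsal_scale
                elif ny < -config.face_other_band:
                    face, v_eff = "ventral", vol
                else:
                    face, v_eff = "other", vol
                r = float(_radius_of_volume(v_eff))
                c = p - nrm * r
                d_rec, klass = 0.0, "superficial"
            else:
                r = float(_radius_of_volume(vol))
                c = p - nrm * (depth + r)
                face, d_rec, klass = "none", depth, "internalized"
            if n_placed:
                dd = np.linalg.norm(centers[:n_placed] - c, axis=1)
                if np.any(dd <= radii[:n_placed] + r):
                    continue
            centers[n_placed] = c
            radii[n_placed] = r
            n_placed += 1
            out.append(
                dict(center=c.copy(), radius=r, face=face, depth=d_rec, depth_class=klass)
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {idx} (r={_radius_of_volume(vol):.2f} µm, "
                f"{kind}) after {config.max_place_attempts} attempts; "
                "configuration too dense"
            )
    return out


def sample_cell_population(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[PlantedCell]:
    """Sample the full bilateral cell population (no rasterization).

    The right ganglion is sampled first; the left is sampled independently
    with the same distributional parameters and mirrored across the
    midsagittal plane (``mirror_exact`` instead copies the right side).
    Cell ids are consecutive from 1, left side first.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _, right_c = config.ganglion_centers_um
    ext = config.grid_extent_um

    right_local = _place_one_ganglion(rng, config, config.n_cells_right)
    if config.mirror_exact:
        left_local = [dict(d, center=d["center"].copy()) for d in right_local]
    else:
        left_local = _place_one_ganglion(rng, config, config.n_cells_left)

    cells: list[PlantedCell] = []
    cid = 1
    for d in left_local:
        c = d["center"] + right_c          # place in right frame, then mirror x
        c = np.array([ext[0] - c[0], c[1], c[2]])
        cells.append(
            PlantedCell(
                cell_id=cid,
                center_um=tuple(float(x) for x in c),
                radius_um=d["radius"],
                side="left",
                face=d["face"],
                depth_um=d["depth"],
                depth_class=d["depth_class"],
            )
        )
        cid += 1
    for d in right_local:
        c = d["center"] + right_c
        cells.append(
            PlantedCell(
                cell_id=cid,
                center_um=tuple(float(x) for x in c),
                radius_um=d["radius"],
                side="right",
                face=d["face"],
                depth_um=d["depth"],
                depth_class=d["depth_class"],
            )
        )
        cid += 1
    return cells


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, spacing, center, semi_axes) -> np.ndarray:
    sp = np.asarray(spacing, float)
    a = np.asarray(semi_axes, float)
    c = np.asarray(center, float)
    lo = np.maximum(0, np.floor((c - a) / sp - 0.5).astype(int))
    hi = np.minimum(np.asarray(shape), np.ceil((c + a) / sp + 0.5).astype(int))
    mask = np.zeros(shape, bool)
    idx = np.indices(hi - lo).astype(float)
    for ax in range(3):
        idx[ax] = (idx[ax] + lo[ax] + 0.5) * sp[ax]
    q = ((idx[0] - c[0]) / a[0]) ** 2 + ((idx[1] - c[1]) / a[1]) ** 2 + ((idx[2] - c[2]) / a[2]) ** 2
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = q <= 1.0
    return mask


def rasterize_cells(cells: Sequence[PlantedCell], config: SimConfig) -> LabelVolume:
    """Rasterize planted spheres into an integer label volume.

    A voxel gets label k iff its center lies inside cell k's sphere; the
    planted non-overlap invariant makes the assignment unambiguous. The
    generating ellipsoid pair is stored as ``true_mask``.
    """
    config.validate()
    shape = tuple(int(n) for n in config.grid_shape)
    sp = np.asarray(config.spacing_um, float)
    ext = config.grid_extent_um
    labels = np.zeros(shape, np.int32)
    for cell in cells:
        c = np.asarray(cell.center_um, float)
        r = cell.radius_um
        if np.any(c - r < 0) or np.any(c + r > ext):
            raise ValueError(
                f"cell {cell.cell_id} (r={r:.2f} µm at {tuple(np.round(c, 1))}) "
                "extends beyond the grid"
            )
        lo = np.maximum(0, np.floor((c - r) / sp - 0.5).astype(int))
        hi = np.minimum(shape, np.ceil((c + r) / sp + 0.5).astype(int))
        idx = np.indices(hi - lo).astype(float)
        for ax in range(3):
            idx[ax] = (idx[ax] + lo[ax] + 0.5) * sp[ax]
        inside = (idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2 + (idx[2] - c[2]) ** 2 <= r * r
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = cell.cell_id
    left_c, right_c = config.ganglion_centers_um
    true_mask = _ellipsoid_mask(shape, sp, left_c, config.ganglion_semi_axes_um)
    true_mask |= _ellipsoid_mask(shape, sp, right_c, config.ganglion_semi_axes_um)
    return LabelVolume(labels=labels, spacing_um=tuple(float(s) for s in sp), true_mask=true_mask)


def generate_ganglion_pair(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> tuple[LabelVolume, GroundTruthTable]:
    """Sample and rasterize a full bilateral phantom.

    ``seed`` overrides ``config.seed``; all randomness flows from a single
    ``numpy.random.default_rng`` so identical (config, seed) pairs give
    byte-identical label volumes.
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    cells = sample_cell_population(config, rng)
    volume = rasterize_cells(cells, config)
    return volume, GroundTruthTable(rows=cells, config=config)
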