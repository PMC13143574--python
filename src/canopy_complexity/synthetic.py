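"""Synthetic point clouds and index tables with known ground truth.

Every generator is deterministic given its arguments (and seed, where
randomness is involved). They provide:

* analytic fractal and Euclidean bodies whose box dimension is known
  (plane -> 2, line -> 1, solid cube -> 3, Menger sponge -> ln 20/ln 3);
* uniform bodies whose plane entropies approach closed-form limits;
* canopies with a prescribed exponential decay of point density with
  height, emulating the sampling-density bias of mobile laser scans of
  15 m x 15 m forest plots (dense understory returns near the scanner,
  sparse returns near the canopy top);
* paired index tables drawn from a known linear errors-in-variables model
  for regression-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PointCloud

__all__ = [
    "CanopyParams",
    "generate_plane",
    "generate_line",
    "generate_uniform_cube",
    "generate_uniform_slab",
    "generate_menger_sponge",
    "generate_biased_canopy",
    "generate_paired_indices",
]


@dataclass(frozen=True)
class CanopyParams:
    """Parameters of the biased-canopy generator.

    ``density_decay`` is the exponential rate (per meter) at which the
    expected point density falls with height; 0 gives a uniform slab.
    """

    side: float = 15.0
    height: float = 20.0
    n_points: int = 200_000
    density_decay: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.side <= 0 or self.height <= 0 or self.n_points <= 0:
            raise ValueError("side, height and n_points must be positive")
        if self.density_decay < 0:
            raise ValueError("density_decay must be >= 0")


def generate_plane(side: float = 15.0, spacing: float = 0.05, z: float = 0.0) -> PointCloud:
    """Regular grid on [0, side]**2 at constant height z (box dimension 2)."""
    if not 0 < spacing < side:
        raise ValueError("need 0 < spacing < side")
    ticks = np.arange(0.0, side + spacing / 2, spacing)
    xx, yy = np.meshgrid(ticks, ticks, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    return PointCloud(pts, source_id="plane")


def generate_line(length: float = 16.0, spacing: float = 0.05) -> PointCloud:
    """Collinear points along x (box dimension 1)."""
    if not 0 < spacing < length:
        raise ValueError("need 0 < spacing < length")
    x = np.arange(0.0, length + spacing / 2, spacing)
    pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return PointCloud(pts, source_id="line")


def generate_uniform_cube(side: float = 15.0, n_points: int = 200_000, seed: int = 0) -> PointCloud:
    """I.i.d. uniform points in [0, side]**3 (box dimension -> 3 when dense)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, side, size=(n_points, 3))
    return PointCloud(pts, source_id=f"cube-{seed}")


def generate_uniform_slab(
    side: float = 15.0, height: float = 10.0, n_points: int = 50_000, seed: int = 0
) -> PointCloud:
    """I.i.d. uniform points in [0, side]**2 x [0, height]."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, side, size=(n_points, 2))
    z = rng.uniform(0.0, height, size=n_points)
    return PointCloud(np.column_stack([xy, z]), source_id=f"slab-{seed}")


def generate_menger_sponge(level: int = 4, side: float = 15.0) -> PointCloud:
    """Centers of the retained sub-cubes of a level-``level`` Menger sponge.

    Each recursion subdivides every cube 3 x 3 x 3 and keeps the 20
    sub-cubes that are neither face centers nor the body center; the
    generator emits the 20**level final-level cube centers scaled to
    [0, side]**3. The sponge's Hausdorff dimension is ln 20 / ln 3
    (about 2.7268).
    """
    if not 1 <= level <= 5:
        raise ValueError(f"level must be in 1..5, got {level}")
    # retained offsets: at most one coordinate equals 1 (drop face/body centers)
    base = np.array(
        [
            (i, j, k)
            for i in range(3)
            for j in range(3)
            for k in range(3)
            if (i == 1) + (j == 1) + (k == 1) <= 1
        ],
        dtype=np.int64,
    )
    cells = np.zeros((1, 3), dtype=np.int64)
    for _ in range(level):
        cells = (cells[:, None, :] * 3 + base[None, :, :]).reshape(-1, 3)
    centers = (cells + 0.5) / 3 ** level * side
    return PointCloud(centers.astype(np.float64), source_id=f"menger-{level}")


def generate_biased_canopy(params: CanopyParams | None = None, **kwargs) -> PointCloud:
    """Canopy slab whose point density decays exponentially with height.

    x, y are uniform on [0, side]**2; z is drawn from the truncated
    exponential density proportional to exp(-rate * z) on [0, height], so
    the expected count per 1 m layer falls geometrically and the mean
    nearest-neighbour distance rises monotonically with height — the
    signature of sampling density bias in mobile laser scans. With the
    default rate (0.3/m) and height (20 m) the trend spans 20 layers and
    the Mann–Kendall screen flags the cloud.
    """
    if params is None:
        params = CanopyParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either CanopyParams or keyword arguments, not both")
    rng = np.random.default_rng(params.seed)
    xy = rng.uniform(0.0, params.side, size=(params.n_points, 2))
    u = rng.uniform(0.0, 1.0, size=params.n_points)
    rate = params.density_decay
    if rate == 0.0:
        z = u * params.height
    else:
        # inverse CDF of the exponential truncated to [0, height]
        z = -np.log1p(-u * (1.0 - np.exp(-rate * params.height))) / rate
    return PointCloud(
        np.column_stack([xy, z]), source_id=f"canopy-r{rate}-{params.seed}"
    )


def generate_paired_indices(
    n: int = 170,
    slope: float = 4.75,
    intercept: float = -1.07,
    noise_sd_x: float = 0.282,
    noise_sd_y: float = 1.15,
    sites: int = 4,
    seed: int = 0,
    db_range: tuple = (0.5, 2.5),
) -> pd.DataFrame:
    """Paired index table from a linear errors-in-variables model.

    A latent true index Db* is uniform on ``db_range``; the observed
    columns are db = Db* + N(0, noise_sd_x**2) and
    ce = slope * Db* + intercept + N(0, noise_sd_y**2). Site labels are
    assigned round-robin. The defaults emulate a 170-plot field campaign
    with error-SD ratio noise_sd_x/noise_sd_y ~ 0.245 and an observed
    correlation near 0.82.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    latent = rng.uniform(db_range[0], db_range[1], size=n)
    db = latent + rng.normal(0.0, noise_sd_x, size=n)
    ce = slope * latent + intercept + rng.normal(0.0, noise_sd_y, size=n)
    site_labels = [f"site-{i % sites + 1}" for i in range(n)]
    return pd.DataFrame(
        {
            "source_id": [f"plot-{i:04d}" for i in range(n)],
            "site": site_labels,
            "db": db,
            "ce": ce,
            "n_points": np.full(n, 1_000_000, dtype=np.int64),
            "t_db": np.full(n, np.nan),
            "t_ce": np.full(n, np.nan),
        }
    )
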