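"""Box dimension (Db) of a 3D point cloud by voxel-halving box counting.

A cubic grid with side length equal to the cloud's largest componentwise
extent is laid over the cloud, anchored at its minimum corner. The voxel
side is then halved repeatedly; at each scale r the number N(r) of voxels
containing at least one point is counted. Db is the slope of the ordinary
least-squares regression

    ln N = b0 + b1 * ln(1/r)

fitted over all scales except the first (the single initial box carries no
information about space filling and is excluded). For point clouds Db lies
in [0, 3]: each halving can multiply the occupied count by at most 8 and
never decreases it, so every pairwise slope — and therefore the OLS slope —
is bounded by 0 and 3.

Halving stops at the last scale with r >= ``min_voxel`` (default 0.5 m),
a guard against occlusion and sampling-density artefacts at fine scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateExtentError, InsufficientScalesError
from .io import as_points

__all__ = [
    "BoxCountSeries",
    "DbResult",
    "BoxDimension",
    "voxel_occupancy_counts",
    "fit_box_dimension",
    "box_dimension",
]


@dataclass(frozen=True)
class BoxCountSeries:
    """Paired voxel side-lengths and occupied-voxel counts.

    ``r`` strictly halves between consecutive entries; counts are
    non-decreasing as r decreases and grow by at most a factor 8 per
    halving.
    """

    r: np.ndarray
    n_occupied: np.ndarray
    initial_extent: float
    min_voxel: float

    def __len__(self) -> int:
        return len(self.r)

    @property
    def entries(self):
        return list(zip(self.r.tolist(), self.n_occupied.tolist()))


@dataclass(frozen=True)
class DbResult:
    """Fitted box dimension with the regression diagnostics."""

    db: float
    intercept: float
    r_squared: float
    series: BoxCountSeries
    n_fit_points: int


def _voxel_count(pts: np.ndarray, origin: np.ndarray, r: float, n_cells: int) -> int:
    """Occupied-voxel count at side length r, upper boundary clamped."""
    idx = np.floor((pts - origin) / r).astype(np.int64)
    np.clip(idx, 0, n_cells - 1, out=idx)
    # pack the three indices into one int64 key; n_cells <= 2^20 is ample
    key = (idx[:, 0] * n_cells + idx[:, 1]) * n_cells + idx[:, 2]
    return int(np.unique(key).size)


def voxel_occupancy_counts(cloud, min_voxel: float = 0.5) -> BoxCountSeries:
    """Count occupied voxels at successive halvings of a cubic grid.

    The initial side r0 is the maximum componentwise extent of the cloud;
    scale k has r = r0 / 2**k and is included while r >= min_voxel. The
    grid is anchored at the cloud's minimum corner and points exactly on
    the upper boundary are clamped into the last voxel.

    Raises
    ------
    DegenerateExtentError
        If all points coincide (zero extent).
    InsufficientScalesError
        If fewer than 4 scales satisfy r >= min_voxel (the regression
        needs at least 3 points after the first scale is dropped).
    """
    if min_voxel <= 0:
        raise ValueError(f"min_voxel must be positive, got {min_voxel}")
    pts = as_points(cloud)
    origin = pts.min(axis=0)
    extent = float((pts.max(axis=0) - origin).max())
    if extent == 0.0:
        raise DegenerateExtentError("all points coincide; box counting undefined")
    n_scales = int(np.floor(np.log2(extent / min_voxel))) + 1
    # guard against log2 rounding at exact powers of two
    while extent / 2 ** n_scales >= min_voxel:
        n_scales += 1
    while n_scales > 1 and extent / 2 ** (n_scales - 1) < min_voxel:
        n_scales -= 1
    if n_scales < 4:
        raise InsufficientScalesError(
            f"only {n_scales} scale(s) with r >= {min_voxel} m for extent "
            f"{extent:.3f} m; need at least 4"
        )
    rs = extent / 2.0 ** np.arange(n_scales)
    counts = np.empty(n_scales, dtype=np.int64)
    for k in range(n_scales):
        counts[k] = _voxel_count(pts, origin, rs[k], 2 ** k)
    return BoxCountSeries(rs, counts, initial_extent=extent, min_voxel=min_voxel)


def fit_box_dimension(series: BoxCountSeries) -> DbResult:
    """OLS fit of ln N on ln(1/r), excluding the first (whole-cloud) scale."""
    if len(series) < 4:
        raise InsufficientScalesError(
            f"series has {len(series)} entries; need at least 4 "
            "(3 usable after first-scale exclusion)"
        )
    x = np.log(1.0 / series.r[1:])
    y = np.log(series.n_occupied[1:].astype(np.float64))
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = float(((y - ym) ** 2).sum())
    r2 = 1.0 if syy == 0.0 else 1.0 - float(((y - intercept - slope * x) ** 2).sum()) / syy
    return DbResult(
        db=slope,
        intercept=intercept,
        r_squared=r2,
        series=series,
        n_fit_points=len(x),
    )


class BoxDimension(BaseEstimator):
    """Box-dimension estimator for 3D point clouds.

    Parameters
    ----------
    min_voxel : float, default 0.5
        Smallest voxel side length (meters) included in the halving series.

    Attributes
    ----------
    dimension_ : float
        The fitted box dimension (regression slope), in [0, 3].
    intercept_ : float
        Intercept of the log-log regression.
    r_squared_ : float
        Coefficient of determination of the log-log fit.
    series_ : BoxCountSeries
        The (r, N) pairs the fit was computed from.
    n_fit_points_ : int
        Number of scales entering the regression (first scale excluded).

    Examples
    --------
    >>> from canopy_complexity.synthetic import generate_plane
    >>> round(BoxDimension().fit(generate_plane(15, 0.05)).dimension_, 6)
    2.0
    """

    def __init__(self, min_voxel: float = 0.5):
        self.min_voxel = min_voxel

    def fit(self, X, y=None):
        """Compute the box dimension of the cloud ``X`` ((n, 3) array or
        PointCloud)."""
        series = voxel_occupancy_counts(X, min_voxel=self.min_voxel)
        result = fit_box_dimension(series)
        self.dimension_ = result.db
        self.intercept_ = result.intercept
        self.r_squared_ = result.r_squared
        self.series_ = series
        self.n_fit_points_ = result.n_fit_points
        return self

    def fit_result(self, X) -> DbResult:
        """Fit and return the full :class:`DbResult`."""
        self.fit(X)
        return DbResult(
            db=self.dimension_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            series=self.series_,
            n_fit_points=self.n_fit_points_,
        )


def box_dimension(cloud, min_voxel: float = 0.5) -> DbResult:
    """Box dimension of a cloud: voxel counting + log-log OLS in one call."""
    return BoxDimension(min_voxel=min_voxel).fit_result(cloud)
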