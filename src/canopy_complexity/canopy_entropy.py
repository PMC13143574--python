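"""Canopy entropy (CE): KDE-based differential entropy of a point cloud.

CE measures the homogeneity of the biomass distribution. The cloud is
projected onto the three orthogonal planes (xy, xz, yz); on each plane the
point density p(u, v) is estimated with an equal-weight isotropic Gaussian
kernel density estimate (fixed bandwidth, default 0.2 m); the plane
entropy is the differential entropy

    CE_uv = -integral p(u,v) ln p(u,v) du dv,

evaluated as a renormalized Riemann sum on a regular grid covering the
plane's bounding box padded by five bandwidths (so the truncated kernel
mass is negligible); and the three plane entropies are combined by the
Pythagorean formula

    CE = sqrt(CE_xy**2 + CE_xz**2 + CE_yz**2).

Mobile and terrestrial LiDAR sample near surfaces more densely than distant
ones (sampling density bias, SDB), mostly along z. Before the density
estimate the cloud is therefore screened for a height trend in point
spacing: it is cut into horizontal layers (default 1 m), the mean
nearest-neighbour distance per layer is computed, and a Hamed–Rao
Mann–Kendall test is applied to that sequence. If a trend is detected
(p < alpha) the cloud is resampled to the centers of occupied voxels,
starting at a voxel size equal to the largest per-layer mean
nearest-neighbour distance and growing by 10% per iteration until the
trend disappears.

Because a probability density integrates to one over the cloud's footprint,
plane entropies — and hence CE — grow with plot extent; CE values are only
comparable between plots of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import InsufficientPointsError, SDBConvergenceError
from .io import PointCloud, as_points
from .trend import MKTestResult, mk_trend_test

__all__ = [
    "LayerProfile",
    "SDBReport",
    "CEResult",
    "CanopyEntropy",
    "layer_profile",
    "voxel_center_resample",
    "correct_sdb",
    "plane_entropy",
    "canopy_entropy",
]


@dataclass(frozen=True)
class LayerProfile:
    """Per-layer nearest-neighbour statistics of a cloud.

    ``mean_nn_distance`` is NaN for layers with fewer than 2 points; such
    layers are excluded from the trend-test sequence.
    """

    layer_floors: np.ndarray
    mean_nn_distance: np.ndarray
    n_points: np.ndarray

    @property
    def distance_sequence(self) -> np.ndarray:
        """Defined per-layer means, ordered by height, NaN layers dropped."""
        return self.mean_nn_distance[~np.isnan(self.mean_nn_distance)]


@dataclass(frozen=True)
class SDBReport:
    """Log of the sampling-density-bias detection/correction loop."""

    initial_profile: LayerProfile
    tests: tuple
    voxel_sizes: tuple
    iterations: int
    biased_initially: bool
    final_voxel_size: float | None


@dataclass(frozen=True)
class CEResult:
    """The three plane entropies and their Pythagorean combination."""

    ce_xy: float
    ce_xz: float
    ce_yz: float
    ce: float
    sdb: SDBReport
    n_points_used: int


def layer_profile(cloud, layer_width: float = 1.0) -> LayerProfile:
    """Mean 3D nearest-neighbour distance per horizontal layer.

    Layers are [z_min + k*w, z_min + (k+1)*w); the topmost point is
    included in the last layer. The nearest neighbour is sought within the
    same layer only.
    """
    if layer_width <= 0:
        raise ValueError(f"layer_width must be positive, got {layer_width}")
    pts = as_points(cloud)
    if len(pts) < 2:
        raise InsufficientPointsError("need at least 2 points for a layer profile")
    z = pts[:, 2]
    zmin, zmax = z.min(), z.max()
    n_layers = max(1, int(np.ceil((zmax - zmin) / layer_width)))
    idx = np.minimum(((z - zmin) / layer_width).astype(np.int64), n_layers - 1)
    floors = zmin + layer_width * np.arange(n_layers)
    means = np.full(n_layers, np.nan)
    counts = np.zeros(n_layers, dtype=np.int64)
    for k in range(n_layers):
        layer_pts = pts[idx == k]
        counts[k] = len(layer_pts)
        if counts[k] >= 2:
            dists, _ = cKDTree(layer_pts).query(layer_pts, k=2)
            means[k] = float(dists[:, 1].mean())
    return LayerProfile(floors, means, counts)


def voxel_center_resample(cloud, voxel_size: float) -> PointCloud:
    """Replace all points in each occupied voxel by the voxel center.

    The grid is anchored at the cloud's minimum corner; points on the
    upper boundary fall into the last voxel along that axis.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    pts = as_points(cloud)
    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / voxel_size).astype(np.int64)
    # clamp exact upper-boundary points back into the outermost voxel
    upper = np.maximum(np.floor((pts.max(axis=0) - origin) / voxel_size - 1e-12), 0)
    idx = np.minimum(idx, upper.astype(np.int64))
    uniq = np.unique(idx, axis=0)
    centers = origin + (uniq + 0.5) * voxel_size
    source = cloud.source_id if isinstance(cloud, PointCloud) else ""
    return PointCloud(centers, source_id=source)


def correct_sdb(
    cloud,
    layer_width: float = 1.0,
    alpha: float = 0.05,
    growth: float = 1.10,
    max_iter: int = 50,
):
    """Detect and correct the z-direction sampling density bias.

    Returns ``(corrected_cloud, SDBReport)``. The cloud is returned
    unchanged when the layer nearest-neighbour sequence shows no
    Mann–Kendall trend (or has fewer than 4 usable layers, where the test
    has no power). Otherwise the original cloud is voxel-center resampled,
    starting at the largest per-layer mean nearest-neighbour distance and
    multiplying the voxel size by ``growth`` each iteration, until the
    trend disappears.

    Raises
    ------
    SDBConvergenceError
        If ``max_iter`` resampling rounds still leave a detectable trend;
        the partial report rides on the exception.
    """
    pts = as_points(cloud)
    source = cloud.source_id if isinstance(cloud, PointCloud) else ""
    profile = layer_profile(pts, layer_width=layer_width)
    seq = profile.distance_sequence
    initial_test = mk_trend_test(seq, alpha=alpha)
    if not initial_test.trend_detected:
        report = SDBReport(profile, (initial_test,), (), 0, False, None)
        return PointCloud(pts, source_id=source), report

    tests = [initial_test]
    voxel_sizes = []
    voxel = float(np.nanmax(profile.mean_nn_distance))
    resampled = None
    for iteration in range(1, max_iter + 1):
        resampled = voxel_center_resample(pts, voxel)
        voxel_sizes.append(voxel)
        if len(resampled) < 2:
            # collapsed to a single voxel: trivially trend-free
            test = MKTestResult(0, 0.0, 0.0, 1.0, False, len(resampled))
        else:
            test = mk_trend_test(
                layer_profile(resampled, layer_width=layer_width).distance_sequence,
                alpha=alpha,
            )
        tests.append(test)
        if not test.trend_detected:
            report = SDBReport(
                profile, tuple(tests), tuple(voxel_sizes), iteration, True, voxel
            )
            return resampled, report
        voxel *= growth

    report = SDBReport(
        profile, tuple(tests), tuple(voxel_sizes), max_iter, True, voxel_sizes[-1]
    )
    raise SDBConvergenceError(
        f"trend still detected after {max_iter} resampling iterations "
        f"(last voxel size {voxel_sizes[-1]:.3f} m)",
        report=report,
    )


def _kde_on_grid(pts2d: np.ndarray, bandwidth: float, grid_step: float):
    """Exact equal-weight isotropic Gaussian KDE evaluated on a regular grid.

    The grid covers the bounding box padded by 5 bandwidths per side, with
    cells of side ``grid_step`` evaluated at their centers. The separable
    Gaussian kernel lets the full evaluation factor into one matrix product:
    p[i, j] = sum_k A[i, k] B[j, k] with A, B the per-axis kernel matrices.
    """
    h2 = bandwidth * bandwidth
    lo = pts2d.min(axis=0) - 5 * bandwidth
    hi = pts2d.max(axis=0) + 5 * bandwidth
    nu = max(1, int(np.ceil((hi[0] - lo[0]) / grid_step)))
    nv = max(1, int(np.ceil((hi[1] - lo[1]) / grid_step)))
    u = lo[0] + (np.arange(nu) + 0.5) * grid_step
    v = lo[1] + (np.arange(nv) + 0.5) * grid_step
    a = np.exp(-((u[:, None] - pts2d[None, :, 0]) ** 2) / (2 * h2))
    b = np.exp(-((v[:, None] - pts2d[None, :, 1]) ** 2) / (2 * h2))
    density = (a @ b.T) / (len(pts2d) * 2 * np.pi * h2)
    return density, grid_step * grid_step


def plane_entropy(
    points2d, bandwidth: float = 0.2, grid_step: float = 0.1
) -> float:
    """Differential entropy of the Gaussian-KDE density of 2D points.

    The density is renormalized so the Riemann sum over the padded grid is
    exactly 1 before the entropy sum; cells with density below 1e-300
    contribute zero. Units: nats, plus the log of the squared length unit
    (entropy of a density over m**2).
    """
    pts = np.asarray(points2d, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
    if len(pts) == 0:
        raise InsufficientPointsError("plane entropy needs at least one point")
    if bandwidth <= 0 or grid_step <= 0:
        raise ValueError("bandwidth and grid_step must be positive")
    if grid_step > bandwidth:
        raise ValueError("grid_step must not exceed the bandwidth")
    density, cell_area = _kde_on_grid(pts, bandwidth, grid_step)
    total = density.sum() * cell_area
    density = density / total
    mask = density >= 1e-300
    p = density[mask]
    return float(-(p * np.log(p)).sum() * cell_area)


class CanopyEntropy(BaseEstimator):
    """Canopy-entropy estimator for 3D point clouds.

    Parameters
    ----------
    bandwidth : float, default 0.2
        Isotropic Gaussian KDE bandwidth in meters.
    layer_width : float, default 1.0
        Height-layer thickness for the sampling-density-bias screen.
    alpha : float, default 0.05
        Significance level of the Mann–Kendall trend test.
    growth : float, default 1.10
        Multiplicative voxel-size growth per bias-correction iteration.
    grid_step : float, default 0.1
        Riemann-grid cell side for the entropy quadrature; must not exceed
        the bandwidth.
    max_iter : int, default 50
        Cap on bias-correction iterations.
    correct_bias : bool, default True
        Set False to skip the SDB screen entirely (density estimated on
        the raw cloud).

    Attributes
    ----------
    entropy_ : float
        The combined canopy entropy CE.
    entropy_xy_, entropy_xz_, entropy_yz_ : float
        The three plane entropies.
    sdb_report_ : SDBReport
        Log of the bias detection/correction loop.
    n_points_used_ : int
        Points entering the density estimate (after any resampling).
    """

    def __init__(
        self,
        bandwidth: float = 0.2,
        layer_width: float = 1.0,
        alpha: float = 0.05,
        growth: float = 1.10,
        grid_step: float = 0.1,
        max_iter: int = 50,
        correct_bias: bool = True,
    ):
        self.bandwidth = bandwidth
        self.layer_width = layer_width
        self.alpha = alpha
        self.growth = growth
        self.grid_step = grid_step
        self.max_iter = max_iter
        self.correct_bias = correct_bias

    def fit(self, X, y=None):
        """Compute CE for the cloud ``X`` ((n, 3) array or PointCloud)."""
        pts = as_points(X)
        if self.correct_bias:
            corrected, report = correct_sdb(
                pts,
                layer_width=self.layer_width,
                alpha=self.alpha,
                growth=self.growth,
                max_iter=self.max_iter,
            )
            pts = corrected.points
        else:
            profile = layer_profile(pts, layer_width=self.layer_width)
            report = SDBReport(
                profile,
                (MKTestResult(0, 0.0, 0.0, 1.0, False, 0),),
                (),
                0,
                False,
                None,
            )
        self.entropy_xy_ = plane_entropy(pts[:, [0, 1]], self.bandwidth, self.grid_step)
        self.entropy_xz_ = plane_entropy(pts[:, [0, 2]], self.bandwidth, self.grid_step)
        self.entropy_yz_ = plane_entropy(pts[:, [1, 2]], self.bandwidth, self.grid_step)
        self.entropy_ = float(
            np.sqrt(self.entropy_xy_ ** 2 + self.entropy_xz_ ** 2 + self.entropy_yz_ ** 2)
        )
        self.sdb_report_ = report
        self.n_points_used_ = len(pts)
        return self

    def fit_result(self, X) -> CEResult:
        """Fit and return the full :class:`CEResult`."""
        self.fit(X)
        return CEResult(
            ce_xy=self.entropy_xy_,
            ce_xz=self.entropy_xz_,
            ce_yz=self.entropy_yz_,
            ce=self.entropy_,
            sdb=self.sdb_report_,
            n_points_used=self.n_points_used_,
        )


def canopy_entropy(
    cloud,
    bandwidth: float = 0.2,
    layer_width: float = 1.0,
    alpha: float = 0.05,
    grid_step: float = 0.1,
    growth: float = 1.10,
    max_iter: int = 50,
) -> CEResult:
    """Canopy entropy of a cloud: SDB screen + three plane KDEs in one call."""
    est = CanopyEntropy(
        bandwidth=bandwidth,
        layer_width=layer_width,
        alpha=alpha,
        growth=growth,
        grid_step=grid_step,
        max_iter=max_iter,
    )
    return est.fit_result(cloud)
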