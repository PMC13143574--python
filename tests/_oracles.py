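"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (dict loops, all-pairs scans, direct
formulas, numerical minimization) and shares no code path with the
package.
"""

import numpy as np
from scipy import optimize


def brute_voxel_count(points, origin, r, n_cells):
    """Occupied-voxel count by a per-point dict loop with boundary clamp."""
    occupied = set()
    for p in points:
        key = []
        for d in range(3):
            i = int((p[d] - origin[d]) // r)
            if i >= n_cells:
                i = n_cells - 1
            key.append(i)
        occupied.add(tuple(key))
    return len(occupied)


def brute_voxel_series(points, min_voxel):
    """Full halving series by repeated brute counting."""
    points = np.asarray(points, float)
    origin = points.min(axis=0)
    extent = (points.max(axis=0) - origin).max()
    out = []
    k = 0
    while extent / 2 ** k >= min_voxel:
        out.append((extent / 2 ** k, brute_voxel_count(points, origin, extent / 2 ** k, 2 ** k)))
        k += 1
    return out


def brute_layer_nn_means(points, layer_width):
    """Per-layer mean 3D nearest-neighbour distance by an all-pairs scan."""
    points = np.asarray(points, float)
    z = points[:, 2]
    zmin = z.min()
    n_layers = max(1, int(np.ceil((z.max() - zmin) / layer_width)))
    means = []
    for k in range(n_layers):
        lo, hi = zmin + k * layer_width, zmin + (k + 1) * layer_width
        if k == n_layers - 1:
            sel = points[(z >= lo)]
        else:
            sel = points[(z >= lo) & (z < hi)]
        if len(sel) < 2:
            means.append(np.nan)
            continue
        d2 = ((sel[:, None, :] - sel[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        means.append(np.sqrt(d2.min(axis=1)).mean())
    return np.array(means)


def brute_plane_entropy(points2d, bandwidth, grid_step, pad=5.0):
    """KDE entropy by an explicit per-point accumulation loop."""
    pts = np.asarray(points2d, float)
    lo = pts.min(axis=0) - pad * bandwidth
    hi = pts.max(axis=0) + pad * bandwidth
    nu = max(1, int(np.ceil((hi[0] - lo[0]) / grid_step)))
    nv = max(1, int(np.ceil((hi[1] - lo[1]) / grid_step)))
    u = lo[0] + (np.arange(nu) + 0.5) * grid_step
    v = lo[1] + (np.arange(nv) + 0.5) * grid_step
    uu, vv = np.meshgrid(u, v, indexing="ij")
    dens = np.zeros_like(uu)
    for x0, y0 in pts:
        dens += np.exp(-((uu - x0) ** 2 + (vv - y0) ** 2) / (2 * bandwidth ** 2))
    dens /= len(pts) * 2 * np.pi * bandwidth ** 2
    area = grid_step ** 2
    dens /= dens.sum() * area
    p = dens[dens >= 1e-300]
    return float(-(p * np.log(p)).sum() * area)


def brute_ols_slope(x, y):
    """Textbook least-squares slope and intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return slope, y.mean() - slope * x.mean()


def brute_deming(x, y, delta):
    """Deming line by numerically minimizing the weighted orthogonal SSE.

    delta = sigma_x/sigma_y. For a candidate line the latent x* of each
    point has a closed form; the outer 2-parameter problem is solved with
    Nelder-Mead from the OLS start.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    lam = 1.0 / delta ** 2  # error-variance ratio sigma_y^2/sigma_x^2

    def sse(params):
        a, b = params
        # minimize sum lam*(x-xs)^2 + (y-a-b*xs)^2 over xs per point
        xs = (lam * x + b * (y - a)) / (lam + b ** 2)
        return (lam * (x - xs) ** 2 + (y - a - b * xs) ** 2).sum()

    b0, a0 = brute_ols_slope(x, y)[0], 0.0
    a0 = y.mean() - b0 * x.mean()
    res = optimize.minimize(sse, [a0, b0], method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return res.x[1], res.x[0]  # slope, intercept


def brute_mk_s(seq):
    """MK statistic by explicit pair enumeration."""
    s = 0
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(seq[j] > seq[i]) - int(seq[j] < seq[i])
    return s


def brute_mk_variance(seq):
    """Tie-corrected null variance of S by the direct formula."""
    n = len(seq)
    var = n * (n - 1) * (2 * n + 5)
    for v in set(seq):
        t = list(seq).count(v)
        if t > 1:
            var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0
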