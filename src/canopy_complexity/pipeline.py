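"""End-to-end batch analysis: both indices per cloud, then the comparison.

``run_compute`` walks a set of cloud files (or a directory), computes the
box dimension and canopy entropy of each with separate wall-clock timings,
and collects one :class:`~canopy_complexity.io.IndexRecord` per cloud.
Per-cloud failures are logged and skipped so one corrupt file cannot sink
a large batch. ``run_compare`` turns a results table with site labels into
the full statistical report: Pearson r, the range-ratio delta, pooled and
per-site Deming fits with translation formulas in both directions, and
power-law runtime scaling fits. Timings are recorded with a monotonic
clock and never influence the index values.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .box_dimension import BoxDimension
from .canopy_entropy import CanopyEntropy
from .comparison import (
    deming_regression,
    error_ratio,
    fit_power_scaling,
    pearson,
    per_group_deming,
)
from .errors import CanopyComplexityError, PipelineError
from .io import IndexRecord, crop_to_plot, read_point_cloud, write_index_records

__all__ = ["RunConfig", "run_compute", "run_compare"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of the batch pipeline, with field defaults.

    All lengths in meters; ``alpha`` is the Mann–Kendall significance
    level; ``growth`` the per-iteration voxel growth of the bias
    correction; ``plot_side`` the crop window (cropping only happens when
    ``crop_center`` is set).
    """

    min_voxel: float = 0.5
    bandwidth: float = 0.2
    layer_width: float = 1.0
    alpha: float = 0.05
    growth: float = 1.10
    grid_step: float = 0.1
    plot_side: float = 15.0
    crop_center: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("min_voxel", "bandwidth", "layer_width", "growth", "grid_step", "plot_side"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "crop_center" in raw and raw["crop_center"] is not None:
            raw["crop_center"] = tuple(raw["crop_center"])
        return cls(**raw)


def _collect_paths(inputs) -> list:
    paths = []
    for item in np.atleast_1d(inputs):
        p = Path(item)
        if p.is_dir():
            paths.extend(
                sorted(
                    q
                    for q in p.iterdir()
                    if q.suffix.lower() in (".las", ".laz", ".xyz", ".txt", ".csv")
                )
            )
        else:
            paths.append(p)
    return paths


def compute_indices_for_cloud(cloud, config: RunConfig) -> IndexRecord:
    """Both indices for one in-memory cloud, each stage timed separately."""
    t0 = time.monotonic()
    db = BoxDimension(min_voxel=config.min_voxel).fit(cloud)
    t_db = time.monotonic() - t0

    t0 = time.monotonic()
    ce = CanopyEntropy(
        bandwidth=config.bandwidth,
        layer_width=config.layer_width,
        alpha=config.alpha,
        growth=config.growth,
        grid_step=config.grid_step,
    ).fit(cloud)
    t_ce = time.monotonic() - t0

    return IndexRecord(
        source_id=cloud.source_id,
        n_points=len(cloud),
        db=db.dimension_,
        ce=ce.entropy_,
        ce_xy=ce.entropy_xy_,
        ce_xz=ce.entropy_xz_,
        ce_yz=ce.entropy_yz_,
        sdb_detected=ce.sdb_report_.biased_initially,
        final_voxel_size=ce.sdb_report_.final_voxel_size,
        t_db=round(t_db, 3),
        t_ce=round(t_ce, 3),
    )


def run_compute(inputs, config: RunConfig | None = None, out_csv=None) -> pd.DataFrame:
    """Compute both indices for every readable cloud in ``inputs``.

    Parameters
    ----------
    inputs : path, sequence of paths, or a directory
    config : RunConfig, optional
    out_csv : path, optional
        When given, the result table is also written there with the fixed
        results header.

    Returns
    -------
    DataFrame with one IndexRecord row per successfully processed cloud.

    Raises
    ------
    PipelineError
        If no cloud could be processed at all.
    """
    config = config or RunConfig()
    records = []
    for path in _collect_paths(inputs):
        try:
            t0 = time.monotonic()
            cloud = read_point_cloud(path)
            t_read = time.monotonic() - t0
            if config.crop_center is not None:
                cloud = crop_to_plot(cloud, config.crop_center, config.plot_side)
            record = compute_indices_for_cloud(cloud, config)
            logger.info(
                "%s: n=%d read=%.2fs db=%.3f (%.2fs) ce=%.3f (%.2fs)",
                path.name, record.n_points, t_read,
                record.db, record.t_db, record.ce, record.t_ce,
            )
            records.append(record)
        except (CanopyComplexityError, OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", path, exc)
    if not records:
        raise PipelineError("no cloud in the input set could be processed")
    df = pd.DataFrame([r.as_dict() for r in records])
    if out_csv is not None:
        write_index_records(records, out_csv)
    return df


def _fit_to_dict(fit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "se_slope": fit.se_slope,
        "se_intercept": fit.se_intercept,
        "ci_slope": list(fit.ci_slope),
        "ci_intercept": list(fit.ci_intercept),
        "delta": fit.delta,
        "n": fit.n,
    }


def run_compare(table: pd.DataFrame, delta_policy: str = "global") -> dict:
    """Full statistical comparison of the db and ce columns of a table.

    The table needs ``db`` and ``ce`` columns; ``site`` enables per-site
    fits and positive ``t_db``/``t_ce`` with ``n_points`` enable the
    runtime scaling fits. Returns a JSON-serializable dict with Pearson
    r/p, delta, the pooled Deming fit, translation formulas in both
    directions, per-site fits, and the scaling fits where available.
    """
    if len(table) < 3:
        raise ValueError("comparison needs at least 3 rows")
    db = table["db"].to_numpy(dtype=np.float64)
    ce = table["ce"].to_numpy(dtype=np.float64)
    r, p = pearson(db, ce)
    delta = error_ratio(db, ce)
    pooled = deming_regression(db, ce, delta)
    # the symmetric fit inverts exactly: db = (ce - intercept)/slope
    inverse = {
        "slope": 1.0 / pooled.slope,
        "intercept": -pooled.intercept / pooled.slope,
    }
    report = {
        "n": int(len(table)),
        "pearson_r": r,
        "pearson_p": p,
        "delta": delta,
        "deming_pooled": _fit_to_dict(pooled),
        "ce_from_db": {"slope": pooled.slope, "intercept": pooled.intercept},
        "db_from_ce": inverse,
    }
    if "site" in table.columns and table["site"].nunique() > 1:
        report["deming_per_site"] = {
            site: _fit_to_dict(fit)
            for site, fit in per_group_deming(table, delta_policy=delta_policy).items()
        }
    for col in ("t_db", "t_ce"):
        if col in table.columns:
            t = table[col].to_numpy(dtype=np.float64)
            n_pts = table["n_points"].to_numpy(dtype=np.float64)
            ok = np.isfinite(t) & (t > 0) & (n_pts > 0)
            if ok.sum() >= 3:
                fit = fit_power_scaling(t[ok], n_pts[ok])
                report[f"scaling_{col}"] = {
                    "a": fit.a, "b": fit.b,
                    "se_a": fit.se_a, "se_b": fit.se_b,
                    "r_squared": fit.r_squared,
                }
    return report
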