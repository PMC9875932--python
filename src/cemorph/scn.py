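"""Structural covariance networks from age-residualized thickness.

Every image (one subject-session observation of one method and image type)
is a sample; per region, thickness is residualized on age by OLS, the
region-by-region Pearson correlation matrix of the residuals is
thresholded into binary undirected graphs over a grid of thresholds, and
network integration is summarised by global efficiency

    E_glob = 1 / (N (N-1)) * sum_{i != j} 1 / d_ij

with d_ij the unweighted shortest-path length (1/inf = 0 for disconnected
pairs), computed by breadth-first search expanded simultaneously from all
sources.  Uncertainty bands come from repeatedly rebuilding the network
from random 80% subsamples of the images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, UndefinedStatisticError

__all__ = [
    "ResidualMatrix",
    "SCNGraph",
    "EfficiencyCurve",
    "default_tau_grid",
    "residualize_age",
    "correlation_matrix",
    "threshold_graph",
    "global_efficiency",
    "efficiency_curve",
    "subsample_band",
    "group_contrast",
]


@dataclass(frozen=True)
class ResidualMatrix:
    """Age-adjusted thickness residuals, one row per image."""

    image_ids: list[str]
    roi_names: list[str]
    residuals: np.ndarray  # image x region, mm

    @property
    def n_images(self) -> int:
        return self.residuals.shape[0]


@dataclass(frozen=True)
class SCNGraph:
    """Binary undirected graph at one correlation threshold."""

    roi_names: list[str]
    adjacency: np.ndarray  # symmetric bool, zero diagonal
    threshold: float


@dataclass(frozen=True)
class EfficiencyCurve:
    """Global efficiency over a threshold grid, with subsample SD bands."""

    thresholds: np.ndarray
    e_glob: np.ndarray
    band_sd: np.ndarray | None = None
    group: str = ""
    method: str = ""
    image_type: str = ""


def default_tau_grid() -> np.ndarray:
    """Threshold grid 0.00 .. 0.99 at 0.01 intervals (100 values)."""
    return np.round(np.arange(0, 100) * 0.01, 2)


def residualize_age(
    table: pd.DataFrame,
    *,
    method: str | None = None,
    image_type: str | None = None,
    group: str | None = None,
) -> ResidualMatrix:
    """Residualize thickness on age, per region, over the selected images.

    Selection filters are optional; the OLS age model is fitted within the
    selected image set, so it should match the set the network will be
    built from.
    """
    sub = table
    for col, val in (("method", method), ("image_type", image_type), ("group", group)):
        if val is not None:
            sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError("selection matched no rows")
    wide = sub.pivot_table(
        index=["subject_id", "session_index", "age"],
        columns="roi",
        values="thickness_mm",
        sort=True,
    )
    wide = wide.dropna()
    if len(wide) < 3:
        raise DegenerateDesignError("need at least 3 complete images")
    ages = wide.index.get_level_values("age").to_numpy(dtype=float)
    if np.unique(ages).size < 2:
        raise DegenerateDesignError("constant age across selected images")
    Y = wide.to_numpy()
    X = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ coef
    ids = [f"{s}/{i}" for s, i, _ in wide.index]
    return ResidualMatrix(
        image_ids=ids, roi_names=list(wide.columns), residuals=residuals
    )


def correlation_matrix(residuals: ResidualMatrix | np.ndarray) -> np.ndarray:
    """Region-by-region Pearson correlation across images."""
    R = residuals.residuals if isinstance(residuals, ResidualMatrix) else np.asarray(residuals)
    names = (
        residuals.roi_names
        if isinstance(residuals, ResidualMatrix)
        else [str(i) for i in range(R.shape[1])]
    )
    if R.shape[0] < 3:
        raise UndefinedStatisticError("need at least 3 images")
    sd = R.std(axis=0)
    if (sd == 0).any():
        bad = names[int(np.argmax(sd == 0))]
        raise UndefinedStatisticError(f"constant residual column for region {bad!r}")
    corr = np.corrcoef(R, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return corr


def threshold_graph(corr: np.ndarray, tau: float, roi_names=None) -> SCNGraph:
    """Binary graph with an edge (i, j), i != j, iff corr[i, j] >= tau.

    Signed thresholding: negative correlations never create edges for the
    non-negative threshold grid.
    """
    corr = _check_corr(corr)
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    adj = corr >= tau
    np.fill_diagonal(adj, False)
    names = list(roi_names) if roi_names is not None else [str(i) for i in range(len(corr))]
    return SCNGraph(roi_names=names, adjacency=adj, threshold=float(tau))


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by level-synchronous BFS.

    Expands the reachable set of every source simultaneously with boolean
    matrix products (float32 so the product runs through BLAS); entry stays
    inf for disconnected pairs.
    """
    n = adj.shape[0]
    a = adj.astype(np.float32)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    d = 0
    while True:
        nxt = reach | ((reach.astype(np.float32) @ a) > 0)
        new = nxt & ~reach
        if not new.any():
            break
        d += 1
        dist[new] = d
        reach = nxt
    return dist


def global_efficiency(graph: SCNGraph | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    1 for a complete graph, 0 for an edgeless one; finite on disconnected
    graphs because unreachable pairs contribute 0.
    """
    adj = graph.adjacency if isinstance(graph, SCNGraph) else np.asarray(graph, dtype=bool)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    if not adj.any():
        return 0.0
    dist = _distance_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def efficiency_curve(
    corr: np.ndarray,
    tau_grid: np.ndarray | None = None,
    roi_names=None,
    **labels,
) -> EfficiencyCurve:
    """Global efficiency of the thresholded graph for each tau in the grid."""
    corr = _check_corr(corr)
    grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, dtype=float)
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("tau grid must lie within [0, 1]")
    e = np.array(
        [global_efficiency(threshold_graph(corr, t, roi_names)) for t in grid]
    )
    return EfficiencyCurve(thresholds=grid, e_glob=e, **labels)


def subsample_band(
    residuals: ResidualMatrix,
    fraction: float = 0.8,
    reps: int = 1000,
    tau_grid: np.ndarray | None = None,
    seed: int = 0,
    **labels,
) -> EfficiencyCurve:
    """Efficiency curve with an SD band from image subsampling.

    For each repetition, ``floor(fraction * n_images)`` images are drawn
    without replacement, the correlation matrix and efficiency curve are
    recomputed, and the per-threshold sample SD across repetitions is
    reported as the band.  The point estimate comes from the full image
    set.  ``reps=0`` skips the band (band is NaN).
    """
    grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, dtype=float)
    n = residuals.n_images
    m = int(np.floor(fraction * n))
    if m < 3:
        raise ValueError("too few images for the requested subsample fraction")
    full = efficiency_curve(correlation_matrix(residuals), grid)
    if reps == 0:
        band = np.full(grid.shape, np.nan)
    else:
        rng = np.random.default_rng(seed)
        curves = np.empty((reps, grid.size))
        R = residuals.residuals
        for rep in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            corr = correlation_matrix(R[idx])
            curves[rep] = efficiency_curve(corr, grid).e_glob
        band = curves.std(axis=0, ddof=1)
    return EfficiencyCurve(
        thresholds=grid, e_glob=full.e_glob, band_sd=band, **labels
    )


def group_contrast(
    table: pd.DataFrame,
    tau_star: float = 0.5,
    *,
    methods=None,
    image_types=("pre", "CE"),
    fraction: float = 0.8,
    reps: int = 1000,
    residualize: str = "per-group",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group global efficiency at tau*, with subsample SD bands.

    Builds one network per (group, method, image type).  With
    ``residualize="per-group"`` the age model is fitted within each group's
    image set; ``"pooled"`` fits it across both groups before splitting.
    Returns one row per combination plus a ``ppms_gt_rrms`` flag column.
    """
    groups = sorted(table["group"].unique())
    for g in ("PPMS", "RRMS"):
        if g not in groups:
            raise ValueError(f"group {g} missing from table")
    if residualize not in ("per-group", "pooled"):
        raise ValueError(f"unknown residualize mode {residualize!r}")
    if methods is None:
        methods = [m for m in table["method"].unique() if m != "TRUE"]

    rows = []
    grid = np.array([tau_star])
    for method in methods:
        for itype in image_types:
            per_group: dict[str, tuple[float, float, int]] = {}
            if residualize == "pooled":
                pooled = residualize_age(table, method=method, image_type=itype)
                grp_of = {
                    iid: g
                    for iid, g in zip(
                        pooled.image_ids,
                        _image_groups(table, method, itype, pooled.image_ids),
                    )
                }
            for g in ("PPMS", "RRMS"):
                if residualize == "per-group":
                    res = residualize_age(
                        table, method=method, image_type=itype, group=g
                    )
                else:
                    mask = np.array([grp_of[iid] == g for iid in pooled.image_ids])
                    res = ResidualMatrix(
                        image_ids=[
                            iid for iid, m_ in zip(pooled.image_ids, mask) if m_
                        ],
                        roi_names=pooled.roi_names,
                        residuals=pooled.residuals[mask],
                    )
                curve = subsample_band(
                    res, fraction=fraction, reps=reps, tau_grid=grid, seed=seed
                )
                per_group[g] = (
                    float(curve.e_glob[0]),
                    float(curve.band_sd[0]),
                    res.n_images,
                )
            flag = per_group["PPMS"][0] > per_group["RRMS"][0]
            for g in ("PPMS", "RRMS"):
                e, sd, n_img = per_group[g]
                rows.append(
                    {
                        "group": g,
                        "method": method,
                        "image_type": itype,
                        "tau": tau_star,
                        "e_glob": e,
                        "band_sd": sd,
                        "n_images": n_img,
                        "ppms_gt_rrms": flag,
                    }
                )
    return pd.DataFrame(rows)


def _image_groups(table, method, itype, image_ids) -> list[str]:
    sub = table[(table["method"] == method) & (table["image_type"] == itype)]
    lookup = {
        f"{sid}/{sess}": grp
        for (sid, sess, grp), _ in sub.groupby(
            ["subject_id", "session_index", "group"], sort=False
        )
    }
    return [lookup[iid] for iid in image_ids]
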