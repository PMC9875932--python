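"""Paired agreement statistics between non-enhanced and CE measurements.

Pearson correlation, consistency ICC for the mean of two ratings
(two-way mixed-effects ANOVA), Bland-Altman bias and limits of agreement,
subject-wise cross-region correlations, and tests for comparing two
dependent correlations (subject-level bootstrap; Steiger/Pearson-Filon z
as a cross-check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSeries",
    "ReliabilityResult",
    "paired_global_series",
    "pearson",
    "icc_consistency_mean2",
    "icc_agreement_mean2",
    "bland_altman",
    "reliability_result",
    "reliability_report",
    "subject_wise_correlations",
    "compare_dependent_correlations",
]


@dataclass(frozen=True)
class PairedSeries:
    """Matched pre/CE observations of one quantity.

    ``x`` holds the non-enhanced values, ``y`` the contrast-enhanced twins,
    ``labels`` the unit identifiers (e.g. "subject/session").
    """

    labels: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise AlignmentError("labels, x and y must have equal length")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise AlignmentError("paired series must not contain missing values")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class ReliabilityResult:
    """Agreement summary for one paired series."""

    n_pairs: int
    pearson_r: float
    icc_c2: float
    bland_altman_bias: float
    bland_altman_loa: tuple[float, float]
    subset_label: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bland_altman_loa_low"], d["bland_altman_loa_high"] = d.pop(
            "bland_altman_loa"
        )
        return d


def _as_xy(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, PairedSeries):
        return series.x, series.y
    x, y = series
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def paired_global_series(
    table: pd.DataFrame,
    method: str,
    *,
    identical_params_only: bool = False,
) -> PairedSeries:
    """Global-mean thickness pairs (pre, CE) for one method.

    Pairs are matched on (subject, session); sessions missing either image
    type (e.g. simulated processing failures) are dropped, and the drop
    count is logged.
    """
    from .synthetic import global_mean_table

    sub = table[table["method"] == method]
    if identical_params_only:
        sub = sub[sub["identical_params"]]
    gm = global_mean_table(sub)
    wide = gm.pivot_table(
        index=["subject_id", "session_index"],
        columns="image_type",
        values="thickness_mm",
    )
    for col in ("pre", "CE"):
        if col not in wide.columns:
            raise AlignmentError(f"no {col!r} rows for method {method!r}")
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide)
    if dropped:
        logger.info(
            "method %s: dropped %d unmatched session(s) without a pre/CE twin",
            method,
            dropped,
        )
    labels = np.array([f"{s}/{i}" for s, i in wide.index])
    return PairedSeries(labels=labels, x=wide["pre"].to_numpy(), y=wide["CE"].to_numpy())


def pearson(series) -> float:
    """Sample Pearson product-moment correlation of a paired series."""
    x, y = _as_xy(series)
    if len(x) < 3:
        raise UndefinedStatisticError("pearson requires at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError(
            "pearson undefined: zero variance on one side"
        )
    return float(stats.pearsonr(x, y).statistic)


def _anova_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) mean squares for n x 2 paired data."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc_consistency_mean2(series) -> float:
    """ICC(C,2): consistency ICC for the mean of k=2 ratings.

    Two-way mixed-effects ANOVA with subjects as rows and the two image
    types as columns: ICC(C,k) = (MS_rows - MS_err) / MS_rows.  Invariant
    to a fixed offset between the raters (the column effect is removed).
    """
    x, y = _as_xy(series)
    if len(x) < 3:
        raise UndefinedStatisticError("ICC requires at least 3 pairs")
    ms_rows, _, ms_err = _anova_mean_squares(x, y)
    if ms_rows <= 0:
        raise UndefinedStatisticError("ICC undefined: no between-subject variance")
    return float((ms_rows - ms_err) / ms_rows)


def icc_agreement_mean2(series) -> float:
    """ICC(A,2): absolute-agreement ICC for the mean of k=2 ratings."""
    x, y = _as_xy(series)
    if len(x) < 3:
        raise UndefinedStatisticError("ICC requires at least 3 pairs")
    n = len(x)
    ms_rows, ms_cols, ms_err = _anova_mean_squares(x, y)
    denom = ms_rows + (ms_cols - ms_err) / n
    if denom <= 0:
        raise UndefinedStatisticError("ICC(A,2) undefined for this input")
    return float((ms_rows - ms_err) / denom)


def bland_altman(series) -> tuple[float, tuple[float, float]]:
    """Bland-Altman bias and 95% limits of agreement of y - x.

    bias = mean(y - x); limits = bias +/- 1.96 * SD(y - x) with the
    (n-1)-denominator sample SD.
    """
    x, y = _as_xy(series)
    if len(x) < 2:
        raise UndefinedStatisticError("bland_altman requires at least 2 pairs")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def reliability_result(series: PairedSeries, subset_label: str = "") -> ReliabilityResult:
    """Bundle r, ICC(C,2) and Bland-Altman statistics for one series."""
    bias, loa = bland_altman(series)
    return ReliabilityResult(
        n_pairs=len(series),
        pearson_r=pearson(series),
        icc_c2=icc_consistency_mean2(series),
        bland_altman_bias=bias,
        bland_altman_loa=loa,
        subset_label=subset_label,
    )


def reliability_report(table: pd.DataFrame, methods=None) -> pd.DataFrame:
    """One ReliabilityResult row per method x pair subset.

    Subsets are "all" pairs and the "identical-params" sequence-parameter
    subset; methods default to every non-TRUE method in the table.
    """
    if methods is None:
        methods = [m for m in table["method"].unique() if m != "TRUE"]
    rows = []
    for method in methods:
        for subset, flag in (("all", False), ("identical-params", True)):
            series = paired_global_series(
                table, method, identical_params_only=flag
            )
            res = reliability_result(series, subset_label=subset)
            rows.append({"method": method, **res.to_dict()})
    return pd.DataFrame(rows)


def subject_wise_correlations(
    table: pd.DataFrame, method: str, min_rois: int = 3
) -> pd.DataFrame:
    """Per (subject, session) Pearson r across regions between pre and CE.

    For each session with both image types, correlates the two region
    vectors (e.g. 64 values each).  Sessions with fewer than ``min_rois``
    common regions are skipped with a logged warning.
    """
    sub = table[table["method"] == method]
    wide = sub.pivot_table(
        index=["subject_id", "session_index", "roi"],
        columns="image_type",
        values="thickness_mm",
    )
    if "pre" not in wide.columns or "CE" not in wide.columns:
        raise AlignmentError(f"method {method!r} lacks pre or CE rows")
    wide = wide.dropna().reset_index()
    rows = []
    for (sid, sess), grp in wide.groupby(["subject_id", "session_index"], sort=False):
        if len(grp) < min_rois:
            logger.warning(
                "subject %s session %s: only %d common regions, skipped",
                sid,
                sess,
                len(grp),
            )
            continue
        rows.append(
            {
                "subject_id": sid,
                "session_index": sess,
                "n_rois": len(grp),
                "r": pearson((grp["pre"].to_numpy(), grp["CE"].to_numpy())),
            }
        )
    return pd.DataFrame(rows)


def _align(series_a: PairedSeries, series_b: PairedSeries) -> tuple[np.ndarray, ...]:
    if len(series_a) != len(series_b):
        raise AlignmentError("series have different lengths")
    order_b = {lab: i for i, lab in enumerate(series_b.labels)}
    try:
        idx = np.array([order_b[lab] for lab in series_a.labels])
    except KeyError as e:
        raise AlignmentError(f"label {e.args[0]!r} missing from series_b") from None
    return series_a.x, series_a.y, series_b.x[idx], series_b.y[idx]


def _pearson_filon_z(xa, ya, xb, yb) -> tuple[float, float]:
    """Steiger's z for two dependent, non-overlapping correlations."""
    n = len(xa)
    c = np.corrcoef(np.column_stack([xa, ya, xb, yb]), rowvar=False)
    r_jk, r_hm = c[0, 1], c[2, 3]
    r_jh, r_jm, r_kh, r_km = c[0, 2], c[0, 3], c[1, 2], c[1, 3]
    # Pearson-Filon covariance of the two sample correlations
    k = (
        (r_jh - r_jk * r_kh) * (r_km - r_kh * r_hm)
        + (r_jm - r_jh * r_hm) * (r_kh - r_jk * r_jh)
        + (r_jh - r_jm * r_hm) * (r_km - r_jk * r_jm)
        + (r_jm - r_jk * r_km) * (r_kh - r_km * r_hm)
    )
    cov_z = k / (2 * (1 - r_jk**2) * (1 - r_hm**2))
    dz = np.arctanh(r_jk) - np.arctanh(r_hm)
    z = dz * np.sqrt((n - 3) / (2 - 2 * cov_z))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_dependent_correlations(
    series_a: PairedSeries,
    series_b: PairedSeries,
    *,
    n_boot: int = 5000,
    seed: int = 0,
    method: str = "bootstrap",
) -> tuple[float, float]:
    """Compare r(series_a) vs r(series_b) measured on the same units.

    Returns (difference, two-sided p).  The default is a subject-level
    bootstrap of the Fisher-z difference (``n_boot`` resamples, seeded);
    ``method="steiger"`` uses the Steiger/Pearson-Filon asymptotic z test
    for dependent non-overlapping correlations instead.
    """
    xa, ya, xb, yb = _align(series_a, series_b)
    r_a = pearson((xa, ya))
    r_b = pearson((xb, yb))
    diff = r_a - r_b
    if method == "steiger":
        _, p = _pearson_filon_z(xa, ya, xb, yb)
        return diff, p
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")

    n = len(xa)
    rng = np.random.default_rng(seed)
    dz = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sa = np.corrcoef(xa[idx], ya[idx])[0, 1]
        sb = np.corrcoef(xb[idx], yb[idx])[0, 1]
        sa = min(max(sa, -0.999999), 0.999999)
        sb = min(max(sb, -0.999999), 0.999999)
        dz[b] = np.arctanh(sa) - np.arctanh(sb)
    p = 2 * min(np.mean(dz <= 0), np.mean(dz >= 0))
    return diff, float(min(p, 1.0))
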