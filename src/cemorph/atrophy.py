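"""Longitudinal atrophy rates and group effect sizes.

Per-patient annual atrophy rates are the ordinary-least-squares slope of
thickness (mm) on age (years) across all of a patient's time points,
fitted separately per method, image type and scope (global mean or single
region).  Patients contributing fewer than ``min_timepoints`` sessions to
a series are discarded, mirroring the >= 3 time-point inclusion rule.
Group contrasts are summarised with Cohen's d (pooled SD).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, UndefinedStatisticError

__all__ = [
    "fit_patient_slope",
    "compute_atrophy_rates",
    "cohens_d",
    "group_effect_table",
    "regional_atrophy_map",
]

RATE_COLUMNS = [
    "subject_id",
    "group",
    "method",
    "image_type",
    "scope",
    "slope",
    "intercept",
    "n_timepoints",
]


def fit_patient_slope(ages, values) -> tuple[float, float]:
    """OLS line of value on age; returns (slope mm/year, intercept mm)."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 2 or np.unique(ages).size < 2:
        raise DegenerateDesignError("need at least 2 distinct ages")
    slope, intercept = np.polyfit(ages, values, deg=1)
    return float(slope), float(intercept)


def _fit_slopes_matrix(ages: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of ``values`` on ``ages``."""
    X = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return coef[1], coef[0]  # slopes, intercepts


def compute_atrophy_rates(
    table: pd.DataFrame,
    min_timepoints: int = 3,
    scope: str = "global",
) -> pd.DataFrame:
    """Per-patient atrophy rates for every (method, image type) series.

    ``scope`` is "global" (unweighted mean over regions), "roi" (one rate
    per region) or "both".  A patient is filtered per series: a subject
    whose CE sessions were lost to processing failures may still
    contribute a pre-image rate.  The number of filtered-out subjects is
    recorded in ``result.attrs["n_excluded"]``.
    """
    if table.empty:
        raise ValueError("empty morphometry table")
    if scope not in ("global", "roi", "both"):
        raise ValueError(f"unknown scope {scope!r}")

    rows: list[dict] = []
    n_excluded = 0

    def fit_series(sub: pd.DataFrame, scope_label: str, sid, grp, method, itype):
        nonlocal n_excluded
        pivot = sub.pivot_table(
            index=["session_index", "age"],
            columns="roi",
            values="thickness_mm",
            sort=True,
        )
        n_tp = len(pivot)
        if n_tp < min_timepoints:
            n_excluded += 1
            return
        ages = pivot.index.get_level_values("age").to_numpy(dtype=float)
        if np.unique(ages).size < 2:
            raise DegenerateDesignError(
                f"subject {sid}: all ages identical in {method}/{itype}"
            )
        if scope_label == "global":
            values = pivot.to_numpy().mean(axis=1, keepdims=True)
            scopes = ["global"]
        else:
            values = pivot.to_numpy()
            scopes = list(pivot.columns)
        slopes, intercepts = _fit_slopes_matrix(ages, values)
        for s, sl, ic in zip(scopes, slopes, intercepts):
            rows.append(
                {
                    "subject_id": sid,
                    "group": grp,
                    "method": method,
                    "image_type": itype,
                    "scope": s,
                    "slope": sl,
                    "intercept": ic,
                    "n_timepoints": n_tp,
                }
            )

    scope_labels = ["global", "roi"] if scope == "both" else [scope]
    grouped = table.groupby(["subject_id", "method", "image_type"], sort=False)
    for (sid, method, itype), sub in grouped:
        grp = sub["group"].iloc[0]
        for scope_label in scope_labels:
            fit_series(sub, scope_label, sid, grp, method, itype)

    result = pd.DataFrame(rows, columns=RATE_COLUMNS)
    result.attrs["n_excluded"] = n_excluded
    return result


def cohens_d(a, b, paired: bool = False) -> float:
    """Cohen's d between two samples.

    Default is the classic pooled-SD formula
    d = (mean(a) - mean(b)) / s_pooled with the (n-1)-weighted pooled
    variance.  ``paired=True`` uses mean(a - b) / SD(a - b) instead
    (requires equal lengths).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired cohens_d requires equal-length samples")
        d = a - b
        sd = np.std(d, ddof=1)
        if sd == 0:
            raise UndefinedStatisticError("cohens_d undefined: zero SD of differences")
        return float(np.mean(d) / sd)
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("cohens_d requires n >= 2 per group")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300)
    if np.sqrt(pooled_var) <= scale * 1e-12:  # degenerate up to rounding
        raise UndefinedStatisticError("cohens_d undefined: zero pooled SD")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))


def _maybe_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d, or NaN where undefined (degenerate spread / too few)."""
    try:
        return cohens_d(a, b)
    except UndefinedStatisticError:
        return float("nan")


def group_effect_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Group summary in the layout of the study's atrophy-rate table.

    Per method, emits three rows: mean global slope of each group for
    non-enhanced and CE images with the pre-vs-CE Cohen's d, and an
    effect-size row with the PPMS-vs-RRMS d per image type.  Cells without
    subjects (or with zero pooled SD) are reported as NaN, never as zero.
    """
    glob = rates[rates["scope"] == "global"]
    if glob.empty:
        raise ValueError("no global-scope rates")
    out = []
    for method, sub in glob.groupby("method", sort=False):
        def slopes(group, itype):
            sel = sub[(sub["group"] == group) & (sub["image_type"] == itype)]
            return sel["slope"].to_numpy()

        cell = {
            (g, t): slopes(g, t) for g in ("PPMS", "RRMS") for t in ("pre", "CE")
        }
        for g in ("PPMS", "RRMS"):
            out.append(
                {
                    "method": method,
                    "row": g,
                    "non_enhanced": float(np.mean(cell[g, "pre"]))
                    if cell[g, "pre"].size
                    else float("nan"),
                    "ce": float(np.mean(cell[g, "CE"]))
                    if cell[g, "CE"].size
                    else float("nan"),
                    "d": _maybe_d(cell[g, "pre"], cell[g, "CE"]),
                    "n_non_enhanced": int(cell[g, "pre"].size),
                    "n_ce": int(cell[g, "CE"].size),
                }
            )
        out.append(
            {
                "method": method,
                "row": "effect_size_ppms_vs_rrms",
                "non_enhanced": _maybe_d(cell["PPMS", "pre"], cell["RRMS", "pre"]),
                "ce": _maybe_d(cell["PPMS", "CE"], cell["RRMS", "CE"]),
                "d": float("nan"),
                "n_non_enhanced": int(
                    cell["PPMS", "pre"].size + cell["RRMS", "pre"].size
                ),
                "n_ce": int(cell["PPMS", "CE"].size + cell["RRMS", "CE"].size),
            }
        )
    return pd.DataFrame(out)


def regional_atrophy_map(
    table: pd.DataFrame, min_timepoints: int = 3
) -> pd.DataFrame:
    """Mean per-region atrophy slope per (method, image type, group, region)."""
    rates = compute_atrophy_rates(table, min_timepoints=min_timepoints, scope="roi")
    out = (
        rates.groupby(["method", "image_type", "group", "scope"], sort=False)["slope"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"scope": "roi", "mean": "mean_slope", "count": "n_subjects"})
    )
    return out
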