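"""Covariance networks: residualization, thresholding, global efficiency."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import floyd_warshall

import cemorph
from cemorph.exceptions import DegenerateDesignError, UndefinedStatisticError
from cemorph.scn import (
    ResidualMatrix,
    correlation_matrix,
    default_tau_grid,
    efficiency_curve,
    global_efficiency,
    group_contrast,
    residualize_age,
    subsample_band,
    threshold_graph,
)


def _table(ages, values, roi_names, **meta):
    """values: image x region array -> long-format table."""
    rows = []
    for i, age in enumerate(ages):
        for j, roi in enumerate(roi_names):
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "group": meta.get("group", "RRMS"),
                    "session_index": 0,
                    "age": age,
                    "image_type": "pre",
                    "method": "DL",
                    "roi": roi,
                    "thickness_mm": values[i, j],
                    "identical_params": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- residuals


def test_residuals_vanish_for_exact_age_lines():
    ages = np.array([40.0, 45.0, 50.0, 55.0])
    values = np.column_stack([2.5 - 0.01 * ages, 3.0 + 0.02 * ages])
    res = residualize_age(_table(ages, values, ["a", "b"]))
    assert np.allclose(res.residuals, 0.0, atol=1e-10)
    assert np.abs(res.residuals.mean(axis=0)).max() < 1e-9


def test_residuals_equal_centered_values_without_age_effect():
    rng = np.random.default_rng(0)
    ages = np.linspace(40, 60, 30)
    values = rng.normal(2.5, 0.1, (30, 3))
    # make values orthogonal to age so the fitted slope is exactly 0
    ages_c = ages - ages.mean()
    values = values - np.outer(ages_c, (ages_c @ values) / (ages_c @ ages_c))
    res = residualize_age(_table(ages, values, ["a", "b", "c"]))
    assert np.allclose(res.residuals, values - values.mean(axis=0), atol=1e-10)


def test_residualization_affine_in_age_invariance():
    """Adding any per-region linear function of age leaves the SCN unchanged."""
    rng = np.random.default_rng(1)
    ages = np.linspace(40, 60, 40)
    values = rng.normal(2.5, 0.1, (40, 4))
    names = ["a", "b", "c", "d"]
    base = correlation_matrix(residualize_age(_table(ages, values, names)))
    shifted = values + np.outer(ages, rng.normal(0, 0.05, 4)) + rng.normal(0, 1, 4)
    pert = correlation_matrix(residualize_age(_table(ages, shifted, names)))
    assert np.allclose(base, pert, atol=1e-8)


def test_residualize_age_recovers_generator_slopes():
    cfg = cemorph.CohortConfig(
        n_ppms=0,
        n_rrms=250,
        roi_names=("lh_a", "lh_b"),
        mu_roi={"lh_a": 2.5, "lh_b": 2.7},
        n_factors=0,
        seed=2,
    )
    truth = cemorph.generate_true_cohort(cfg)
    sub = truth[truth["roi"] == "lh_a"]
    slope, _ = np.polyfit(sub["age"], sub["thickness_mm"], 1)
    # cross-sectional age slope mixes the true within-subject slope with
    # baseline-age confounding; within-subject design removes that
    per_subject = [
        np.polyfit(g["age"], g["thickness_mm"], 1)[0]
        for _, g in sub.groupby("subject_id")
    ]
    per_subject = np.asarray(per_subject)
    se = per_subject.std(ddof=1) / np.sqrt(per_subject.size)
    assert abs(per_subject.mean() - (-0.003)) < 2 * se


def test_residualize_errors():
    ages = np.array([40.0, 40.0, 40.0])
    values = np.full((3, 2), 2.5)
    with pytest.raises(DegenerateDesignError):
        residualize_age(_table(ages, values, ["a", "b"]))
    with pytest.raises(ValueError):
        residualize_age(_table(ages, values, ["a", "b"]), method="nope")


# ---------------------------------------------------------------- correlation


def test_correlation_matrix_identical_columns():
    rng = np.random.default_rng(3)
    col = rng.normal(0, 1, 30)
    R = np.column_stack([col, col, rng.normal(0, 1, 30)])
    corr = correlation_matrix(R)
    assert corr[0, 1] == pytest.approx(1.0)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)


def test_correlation_matrix_null_simulation():
    rng = np.random.default_rng(4)
    corr = correlation_matrix(rng.normal(0, 1, (10_000, 5)))
    off = corr[np.triu_indices_from(corr, 1)]
    assert np.abs(off).max() < 0.05


def test_correlation_matrix_constant_column_names_region():
    R = np.column_stack([np.ones(10), np.arange(10.0)])
    res = ResidualMatrix(image_ids=[str(i) for i in range(10)],
                         roi_names=["flat", "ok"], residuals=R)
    with pytest.raises(UndefinedStatisticError, match="flat"):
        correlation_matrix(res)


# ---------------------------------------------------------------- thresholding


def test_threshold_complete_and_empty():
    corr = np.ones((4, 4))
    g = threshold_graph(corr, 0.5)
    assert g.adjacency.sum() == 4 * 3  # complete, no self-loops
    corr2 = np.eye(4) + 0.3 * (np.ones((4, 4)) - np.eye(4))
    assert threshold_graph(corr2, 0.9).adjacency.sum() == 0


def test_threshold_counts_enumerated():
    vals = [0.9, 0.6, 0.4, 0.2, 0.1, 0.05]
    corr = np.eye(4)
    iu = np.triu_indices(4, 1)
    corr[iu] = vals
    corr = corr + corr.T - np.diag(np.diag(corr))
    np.fill_diagonal(corr, 1.0)
    g = threshold_graph(corr, 0.5)
    assert g.adjacency.sum() // 2 == 2  # entries >= 0.5: {0.9, 0.6}


def test_threshold_rejects_asymmetric_input():
    corr = np.eye(3)
    corr[0, 1] = 0.5
    with pytest.raises(ValueError):
        threshold_graph(corr, 0.2)
    with pytest.raises(ValueError):
        threshold_graph(np.eye(3), 1.5)


# ---------------------------------------------------------------- efficiency


def test_global_efficiency_reference_graphs():
    k3 = ~np.eye(3, dtype=bool)
    assert global_efficiency(k3) == pytest.approx(1.0)
    assert global_efficiency(np.zeros((5, 5), dtype=bool)) == 0.0
    p3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
    assert global_efficiency(p3) == pytest.approx(5 / 6)


def test_global_efficiency_matches_independent_oracles():
    """Exact agreement with networkx and Floyd-Warshall on 200 random graphs."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(2, 13))
        p = rng.uniform(0.05, 0.9)
        adj = rng.random((n, n)) < p
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        ours = global_efficiency(adj)
        gx = nx.from_numpy_array(adj.astype(int))
        assert ours == pytest.approx(nx.global_efficiency(gx), abs=1e-12)
        dist = floyd_warshall(adj.astype(float), unweighted=True)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        np.fill_diagonal(inv, 0.0)
        inv[np.isinf(dist)] = 0.0
        assert ours == pytest.approx(inv.sum() / (n * (n - 1)), abs=1e-12)


def test_efficiency_bounds_complete_iff_one_edgeless_iff_zero():
    rng = np.random.default_rng(6)
    for _ in range(50):
        n = int(rng.integers(2, 10))
        adj = rng.random((n, n)) < rng.uniform(0, 1)
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        e = global_efficiency(adj)
        assert 0.0 <= e <= 1.0
        complete = adj.sum() == n * (n - 1)
        assert (e == 1.0) == complete
        assert (e == 0.0) == (adj.sum() == 0)


def test_efficiency_curve_constant_for_perfect_correlation():
    corr = np.ones((5, 5))
    curve = efficiency_curve(corr)
    assert curve.thresholds.size == 100  # 0.00 .. 0.99 at 0.01 steps
    assert np.allclose(curve.e_glob, 1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_efficiency_curve_non_increasing(seed):
    rng = np.random.default_rng(seed)
    R = rng.normal(0, 1, (12, 6)) + rng.normal(0, 1, (12, 1))
    curve = efficiency_curve(correlation_matrix(R), default_tau_grid())
    assert (np.diff(curve.e_glob) <= 1e-12).all()


# ---------------------------------------------------------------- subsampling


def _residuals(R):
    return ResidualMatrix(
        image_ids=[str(i) for i in range(R.shape[0])],
        roi_names=[f"r{j}" for j in range(R.shape[1])],
        residuals=R,
    )


def test_subsample_band_zero_for_rank_one_structure():
    rng = np.random.default_rng(7)
    col = rng.normal(0, 1, 40)
    R = np.column_stack([col, col, col])
    curve = subsample_band(_residuals(R), reps=20, tau_grid=np.array([0.0, 0.5, 0.9]))
    assert np.allclose(curve.band_sd, 0.0)
    assert np.allclose(curve.e_glob, 1.0)


def test_subsample_band_deterministic_given_seed():
    rng = np.random.default_rng(8)
    R = rng.normal(0, 1, (50, 4)) + rng.normal(0, 1, (50, 1))
    grid = np.array([0.2, 0.5])
    c1 = subsample_band(_residuals(R), reps=50, tau_grid=grid, seed=9)
    c2 = subsample_band(_residuals(R), reps=50, tau_grid=grid, seed=9)
    assert np.array_equal(c1.band_sd, c2.band_sd)
    assert np.array_equal(c1.e_glob, c2.e_glob)


def test_subsample_band_shrinks_with_sample_size():
    grid = np.array([0.3, 0.5])
    sds = {}
    for n in (200, 2000):
        rng = np.random.default_rng(10)
        common = rng.normal(0, 0.7, (n, 1))
        R = common + rng.normal(0, 1, (n, 6))
        sds[n] = subsample_band(
            _residuals(R), reps=60, tau_grid=grid, seed=11
        ).band_sd.mean()
    assert sds[2000] < sds[200]


def test_subsample_band_rejects_tiny_sets():
    rng = np.random.default_rng(12)
    with pytest.raises(ValueError):
        subsample_band(_residuals(rng.normal(0, 1, (3, 3))), fraction=0.5, reps=5)


# ---------------------------------------------------------------- group contrast


def test_group_contrast_layout_and_direction(small_study):
    _, _, _, measured = small_study
    out = group_contrast(measured, reps=10, seed=0, methods=["DL"])
    # one row per group x method x image type
    assert len(out) == 2 * 1 * 2
    assert set(out["group"]) == {"PPMS", "RRMS"}
    assert out["ppms_gt_rrms"].dtype == bool


def test_group_contrast_exchangeable_groups_show_no_systematic_gap():
    """With identical group generative parameters the efficiency gap is
    within the subsampling uncertainty."""
    cfg, models = cemorph.default_study_config()
    cfg = dataclasses.replace(
        cfg,
        n_ppms=20,
        n_rrms=20,
        loading_scale_by_group={"PPMS": 0.10, "RRMS": 0.10},
        slope_mean_by_group={"PPMS": -0.003, "RRMS": -0.003},
        sessions_ppms=cfg.sessions_rrms,
        seed=13,
    )
    dl_pre = [m for m in models if m.method == "DL" and m.image_type == "pre"]
    _, measured = cemorph.simulate_study(cfg, dl_pre)
    out = group_contrast(
        measured, reps=40, seed=1, methods=["DL"], image_types=("pre",)
    ).set_index("group")
    gap = abs(out.loc["PPMS", "e_glob"] - out.loc["RRMS", "e_glob"])
    band = np.hypot(out.loc["PPMS", "band_sd"], out.loc["RRMS", "band_sd"])
    assert gap < 4 * band + 0.05


def test_group_contrast_requires_both_groups():
    rng = np.random.default_rng(14)
    ages = np.linspace(40, 50, 10)
    table = _table(ages, rng.normal(2.5, 0.1, (10, 3)), ["a", "b", "c"])
    with pytest.raises(ValueError, match="PPMS"):
        group_contrast(table, reps=0)
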