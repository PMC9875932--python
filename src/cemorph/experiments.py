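"""Calibration recovery experiments.

Small, fully synthetic experiments that tie the package's statistics back
to the closed forms they were calibrated against: attenuation of the
Pearson correlation between two noisy measurements of a common latent
thickness, the matching consistency ICC, Bland-Altman recovery of a
simulated CE bias, Cohen's d between group slope distributions, and the
>= 3 time-point inclusion rule on a cohort with known sub-threshold
patients.  All functions are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .atrophy import cohens_d, compute_atrophy_rates
from .reliability import bland_altman, icc_consistency_mean2, pearson
from .synthetic import CohortConfig, default_study_config, generate_true_cohort, latent_pair_sample

__all__ = [
    "attenuation_reliability",
    "bland_altman_recovery",
    "slope_effect_size",
    "timepoint_filter_counts",
    "scn_direction_rate",
]


def _rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def attenuation_reliability(
    noise_sd: float,
    n_pairs: int,
    n_seeds: int = 100,
    *,
    latent_mean: float = 2.5,
    latent_sd: float = 0.10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean Pearson r and ICC(C,2) of repeated noisy-pair simulations.

    Each replicate draws ``n_pairs`` latent values N(latent_mean,
    latent_sd^2) and two observed copies with independent N(0, noise_sd^2)
    noise.  The expectation of r is the attenuation value
    latent_sd^2 / (latent_sd^2 + noise_sd^2), and of ICC(C,2) the
    Spearman-Brown step-up 2r/(1+r).
    """
    rs = np.empty(n_seeds)
    iccs = np.empty(n_seeds)
    for i in range(n_seeds):
        x, y = latent_pair_sample(
            n_pairs,
            noise_sd_x=noise_sd,
            latent_mean=latent_mean,
            latent_sd=latent_sd,
            seed=_rng(seed, i),
        )
        rs[i] = pearson((x, y))
        iccs[i] = icc_consistency_mean2((x, y))
    return float(rs.mean()), float(iccs.mean())


def bland_altman_recovery(
    bias_mean: float,
    bias_sd: float = 0.05,
    noise_sd: float = 0.0295,
    n_pairs: int = 454,
    n_seeds: int = 100,
    *,
    seed: int = 0,
) -> float:
    """Mean recovered Bland-Altman bias over seeded CE-pair simulations."""
    biases = np.empty(n_seeds)
    for i in range(n_seeds):
        x, y = latent_pair_sample(
            n_pairs,
            noise_sd_x=noise_sd,
            bias_mean=bias_mean,
            bias_sd=bias_sd,
            seed=_rng(seed, i),
        )
        biases[i], _ = bland_altman((x, y))
    return float(biases.mean())


def slope_effect_size(
    mean_a: float,
    mean_b: float,
    sd: float,
    n_per_group: int = 50_000,
    *,
    seed: int = 0,
) -> float:
    """Cohen's d between two normal slope distributions (a minus b)."""
    rng = _rng(seed, 0)
    a = rng.normal(mean_a, sd, n_per_group)
    b = rng.normal(mean_b, sd, n_per_group)
    return cohens_d(a, b)


def timepoint_filter_counts(*, seed: int = 0) -> dict[str, int]:
    """Apply the >= 3 time-point rule to a 75-patient cohort in which one
    PPMS and one RRMS patient have only two sessions.

    Returns the number of rated patients overall and per group.
    """
    config = dataclasses.replace(CohortConfig(), seed=seed)
    truth = generate_true_cohort(config)
    for sid in ("P001", "R001"):
        truth = truth[
            ~((truth["subject_id"] == sid) & (truth["session_index"] >= 2))
        ]
    rates = compute_atrophy_rates(truth, min_timepoints=3)
    subjects = rates.drop_duplicates("subject_id")
    return {
        "n_total": int(truth["subject_id"].nunique()),
        "n_rated": int(len(subjects)),
        "n_ppms": int((subjects["group"] == "PPMS").sum()),
        "n_rrms": int((subjects["group"] == "RRMS").sum()),
    }


def scn_direction_rate(
    n_seeds: int = 100,
    tau_star: float = 0.5,
    *,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of seeds with PPMS > RRMS global efficiency at tau*.

    Runs the default cohort with the DL-like measurement channels and
    builds per-group networks for both image types.
    """
    from .scn import (
        correlation_matrix,
        global_efficiency,
        residualize_age,
        threshold_graph,
    )
    from .synthetic import simulate_study

    wins = {"pre": 0, "CE": 0}
    for i in range(n_seeds):
        cfg, models = default_study_config()
        cfg = dataclasses.replace(cfg, seed=int(_rng(seed, i).integers(2**31)))
        dl = [m for m in models if m.method == "DL"]
        _, measured = simulate_study(cfg, dl)
        for itype in ("pre", "CE"):
            e = {}
            for grp in ("PPMS", "RRMS"):
                res = residualize_age(
                    measured, method="DL", image_type=itype, group=grp
                )
                corr = correlation_matrix(res)
                e[grp] = global_efficiency(threshold_graph(corr, tau_star))
            if e["PPMS"] > e["RRMS"]:
                wins[itype] += 1
    return {k: v / n_seeds for k, v in wins.items()}
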