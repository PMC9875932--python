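"""Synthetic longitudinal paired-morphometry cohorts.

This module generates long-format cortical-thickness tables with the
statistical structure of a two-group longitudinal multiple-sclerosis study:
same-session pairs of non-enhanced ("pre") and contrast-enhanced ("CE")
T1w-derived measurements, produced by two morphometry methods (a
deep-learning-like method "DL" and a FreeSurfer-like method "FS") that
differ in measurement noise, in systematic CE bias, and in processing
failure rate on CE images.

The generative model for the noise-free ("true") thickness of subject *i*,
session *j*, region *r* is

    T[i, j, r] = mu_roi[r] + b_i + beta_i * (age_ij - age_i0)
                 + lambda_g * sum_f L[i, f] * w[r, f] + u[i, r]

with a global between-subject offset ``b_i ~ N(0, sigma_subject^2)``, a
group-specific annual atrophy slope ``beta_i ~ N(slope_mean_g, slope_sd_g^2)``
(age in years is the regressor), latent factors ``L[i, f] ~ N(0, 1)`` with
fixed positive region weights ``w[r, f]`` inducing cross-region covariance
(scaled per group by ``lambda_g``), and a per-subject regional idiosyncrasy
``u[i, r] ~ N(0, sigma_roi^2)``.

Measurements add, per method and image type, a session-level noise term
shared across regions, an independent per-region noise term, and (for CE
images) a per-subject bias drawn once per subject x model.  Sessions whose
acquisition parameters are flagged as non-identical carry a larger
session-level noise, emulating sequence-parameter variability.

All randomness flows from a single master seed through counter-based
substreams per (subject, model), so enlarging the cohort never perturbs
already-generated subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "GROUPS",
    "IMAGE_TYPES",
    "MORPH_COLUMNS",
    "VisitSchedule",
    "CohortConfig",
    "MeasurementModel",
    "default_roi_names",
    "default_mu_roi",
    "default_study_config",
    "generate_true_cohort",
    "simulate_measurements",
    "simulate_study",
    "global_mean_table",
    "latent_pair_sample",
]

GROUPS = ("PPMS", "RRMS")
IMAGE_TYPES = ("pre", "CE")

#: Column order of a long-format morphometry table.
MORPH_COLUMNS = [
    "subject_id",
    "group",
    "session_index",
    "age",
    "image_type",
    "method",
    "roi",
    "thickness_mm",
    "identical_params",
]

# 32 Desikan-Killiany-style gyral labels per hemisphere (the atlas' 34
# cortical labels minus the two pole regions), with plausible mean
# thicknesses in mm.  64 regions total, matching the evaluation scheme.
_DK_REGION_MEANS: dict[str, float] = {
    "bankssts": 2.55,
    "caudalanteriorcingulate": 2.65,
    "caudalmiddlefrontal": 2.60,
    "cuneus": 1.95,
    "entorhinal": 3.30,
    "fusiform": 2.75,
    "inferiorparietal": 2.50,
    "inferiortemporal": 2.80,
    "isthmuscingulate": 2.45,
    "lateraloccipital": 2.20,
    "lateralorbitofrontal": 2.70,
    "lingual": 2.05,
    "medialorbitofrontal": 2.50,
    "middletemporal": 2.90,
    "parahippocampal": 2.80,
    "paracentral": 2.45,
    "parsopercularis": 2.65,
    "parsorbitalis": 2.75,
    "parstriangularis": 2.55,
    "pericalcarine": 1.65,
    "postcentral": 2.05,
    "posteriorcingulate": 2.50,
    "precentral": 2.60,
    "precuneus": 2.40,
    "rostralanteriorcingulate": 2.85,
    "rostralmiddlefrontal": 2.45,
    "superiorfrontal": 2.75,
    "superiorparietal": 2.20,
    "superiortemporal": 2.85,
    "supramarginal": 2.60,
    "transversetemporal": 2.40,
    "insula": 3.05,
}


def default_roi_names() -> tuple[str, ...]:
    """64 region labels: 32 Desikan-Killiany-style names per hemisphere."""
    return tuple(
        f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DK_REGION_MEANS
    )


def default_mu_roi() -> dict[str, float]:
    """Default per-region population mean thickness (mm)."""
    return {
        f"{hemi}_{name}": mu
        for hemi in ("lh", "rh")
        for name, mu in _DK_REGION_MEANS.items()
    }


@dataclass(frozen=True)
class VisitSchedule:
    """Visit plan for one clinical group.

    The number of sessions per subject is ``min_sessions + Poisson(poisson_lambda)``
    and visits are spaced ``interval_years`` apart.
    """

    poisson_lambda: float
    interval_years: float
    min_sessions: int = 3

    def validate(self, name: str) -> None:
        if self.poisson_lambda < 0:
            raise ConfigurationError(f"{name}.poisson_lambda must be >= 0")
        if self.interval_years < 0:
            raise ConfigurationError(f"{name}.interval_years must be >= 0")
        if self.min_sessions < 1:
            raise ConfigurationError(f"{name}.min_sessions must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """All parameters of the synthetic cohort generator.

    Defaults emulate the study conditions: 9 PPMS and 66 RRMS patients,
    ~6-monthly RRMS and ~annual PPMS visits, 64 cortical regions, group
    atrophy slopes of -0.012 (PPMS) and -0.003 (RRMS) mm/year.
    """

    n_ppms: int = 9
    n_rrms: int = 66
    sessions_rrms: VisitSchedule = field(
        default_factory=lambda: VisitSchedule(5.0, 0.5)
    )
    sessions_ppms: VisitSchedule = field(
        default_factory=lambda: VisitSchedule(3.0, 1.0)
    )
    baseline_age_range: tuple[float, float] = (25.0, 60.0)
    roi_names: tuple[str, ...] = field(default_factory=default_roi_names)
    mu_roi: dict[str, float] = field(default_factory=default_mu_roi)
    sigma_subject: float = 0.10
    sigma_roi: float = 0.05
    slope_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"PPMS": -0.012, "RRMS": -0.003}
    )
    slope_sd_by_group: dict[str, float] = field(
        default_factory=lambda: {"PPMS": 0.0296, "RRMS": 0.0296}
    )
    n_factors: int = 6
    loading_scale_by_group: dict[str, float] = field(
        default_factory=lambda: {"PPMS": 0.12, "RRMS": 0.08}
    )
    factor_weight_range: tuple[float, float] = (0.8, 1.2)
    factor_sparsity: float = 0.25
    identical_params_fraction: float = 213.0 / 454.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_ppms < 0:
            raise ConfigurationError("n_ppms must be >= 0")
        if self.n_rrms < 0:
            raise ConfigurationError("n_rrms must be >= 0")
        if self.n_ppms + self.n_rrms < 1:
            raise ConfigurationError("n_ppms + n_rrms must be >= 1")
        self.sessions_rrms.validate("sessions_rrms")
        self.sessions_ppms.validate("sessions_ppms")
        lo, hi = self.baseline_age_range
        if not lo <= hi:
            raise ConfigurationError("baseline_age_range must satisfy low <= high")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ConfigurationError("roi_names must be unique")
        if not self.roi_names:
            raise ConfigurationError("roi_names must be non-empty")
        missing = [r for r in self.roi_names if r not in self.mu_roi]
        if missing:
            raise ConfigurationError(f"mu_roi missing entries for {missing[:3]}")
        for r in self.roi_names:
            if not self.mu_roi[r] > 0:
                raise ConfigurationError(f"mu_roi[{r!r}] must be > 0")
        for name in ("sigma_subject", "sigma_roi"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for g in GROUPS:
            if g not in self.slope_mean_by_group:
                raise ConfigurationError(f"slope_mean_by_group missing group {g}")
            if self.slope_sd_by_group.get(g, -1.0) < 0:
                raise ConfigurationError(f"slope_sd_by_group[{g}] must be >= 0")
            if self.n_factors > 0 and self.loading_scale_by_group.get(g, -1.0) < 0:
                raise ConfigurationError(f"loading_scale_by_group[{g}] must be >= 0")
        if self.n_factors < 0:
            raise ConfigurationError("n_factors must be >= 0")
        if not 0.0 <= self.identical_params_fraction <= 1.0:
            raise ConfigurationError("identical_params_fraction must be in [0, 1]")
        if not 0.0 < self.factor_sparsity <= 1.0:
            raise ConfigurationError("factor_sparsity must be in (0, 1]")


@dataclass(frozen=True)
class MeasurementModel:
    """Noise/bias model of one (method, image type) measurement channel.

    ``noise_sd`` is the independent per-region noise (mm).  The
    session-level terms are shared across all regions of one image:
    ``session_noise_sd`` applies to sessions acquired with identical
    sequence parameters, ``session_noise_sd_variable`` to the rest (it
    defaults to ``session_noise_sd``).  ``bias_mean``/``bias_sd`` describe
    the systematic CE offset, drawn once per subject x model; ``failure_rate``
    is the probability that a CE session fails processing and is dropped.
    """

    method: str
    image_type: str
    noise_sd: float = 0.0
    session_noise_sd: float = 0.0
    session_noise_sd_variable: float | None = None
    bias_mean: float = 0.0
    bias_sd: float = 0.0
    failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.image_type not in IMAGE_TYPES:
            raise ConfigurationError(
                f"image_type must be one of {IMAGE_TYPES}, got {self.image_type!r}"
            )
        if self.noise_sd < 0 or self.session_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.session_noise_sd_variable is not None and self.session_noise_sd_variable < 0:
            raise ConfigurationError("session_noise_sd_variable must be >= 0")
        if not 0.0 <= self.failure_rate < 1.0:
            raise ConfigurationError("failure_rate must be in [0, 1)")
        if self.image_type == "pre" and self.bias_mean != 0.0:
            raise ConfigurationError("bias_mean must be 0 for image_type 'pre'")
        if self.bias_sd < 0:
            raise ConfigurationError("bias_sd must be >= 0")

    @property
    def session_sd_variable(self) -> float:
        return (
            self.session_noise_sd
            if self.session_noise_sd_variable is None
            else self.session_noise_sd_variable
        )


# --------------------------------------------------------------------------
# default study configuration


def _session_level_sd(global_sd: float, roi_sd: float, n_roi: int) -> float:
    """Session-level noise SD that yields ``global_sd`` on the n-region mean.

    The global mean of one image carries noise variance
    ``session_sd^2 + roi_sd^2 / n_roi``; solve for the session term.
    """
    var = global_sd**2 - roi_sd**2 / n_roi
    if var < 0:
        raise ConfigurationError(
            "per-region noise too large for the requested global-mean noise"
        )
    return math.sqrt(var)


def _variable_level_global_sd(all_sd: float, ident_sd: float, p_ident: float) -> float:
    """Global-mean noise SD of variable-parameter sessions.

    Chosen so that the identical/variable mixture (fraction ``p_ident``
    identical) has overall noise variance ``all_sd^2``.
    """
    var = (all_sd**2 - p_ident * ident_sd**2) / (1.0 - p_ident)
    if var < 0:
        raise ConfigurationError("subset noise SD exceeds the overall noise SD")
    return math.sqrt(var)


def default_study_config() -> tuple[CohortConfig, list[MeasurementModel]]:
    """Packaged defaults emulating the study conditions.

    Measurement-noise levels are calibrated through the attenuation formula
    r = sigma_T^2 / (sigma_T^2 + sigma_e^2) so that, with a latent
    between-subject SD of 0.10 mm on the global mean, the test-retest
    correlations of the global mean reproduce the reference values
    r = 0.92 (DL) / 0.75 (FS) over all pairs and 0.96 / 0.87 on the
    identical-sequence-parameter subset: per-image global-mean noise SDs
    0.0204 / 0.0357 mm (DL, identical/variable) and 0.0387 / 0.0703 mm (FS).
    CE biases are 0.06 mm (DL) and 0.17 mm (FS); the FS CE channel drops
    17/454 of sessions.
    """
    config = CohortConfig()
    n_roi = len(config.roi_names)
    p_ident = config.identical_params_fraction

    specs = {
        # method: (per-ROI noise sd, global-mean sd identical, global-mean sd all)
        "DL": (0.16, 0.0204, 0.0295),
        "FS": (0.20, 0.0387, 0.0577),
    }
    ce_bias = {"DL": 0.06, "FS": 0.17}
    ce_failure = {"DL": 0.0, "FS": 17.0 / 454.0}

    models: list[MeasurementModel] = []
    for method, (roi_sd, g_ident, g_all) in specs.items():
        g_var = _variable_level_global_sd(g_all, g_ident, p_ident)
        sess_ident = _session_level_sd(g_ident, roi_sd, n_roi)
        sess_var = _session_level_sd(g_var, roi_sd, n_roi)
        for image_type in IMAGE_TYPES:
            models.append(
                MeasurementModel(
                    method=method,
                    image_type=image_type,
                    noise_sd=roi_sd,
                    session_noise_sd=sess_ident,
                    session_noise_sd_variable=sess_var,
                    bias_mean=ce_bias[method] if image_type == "CE" else 0.0,
                    bias_sd=0.02 if image_type == "CE" else 0.0,
                    failure_rate=ce_failure[method] if image_type == "CE" else 0.0,
                )
            )
    return config, models


# --------------------------------------------------------------------------
# random-stream plumbing

# Root keys of the independent substream families.
_KEY_WEIGHTS = 0
_KEY_SUBJECT = 1
_KEY_MEASURE = 2


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for (seed, key); stable under cohort growth."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))
    )


def _subject_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    ids = [f"P{i + 1:03d}" for i in range(config.n_ppms)]
    groups = ["PPMS"] * config.n_ppms
    ids += [f"R{i + 1:03d}" for i in range(config.n_rrms)]
    groups += ["RRMS"] * config.n_rrms
    return ids, groups


def factor_weights(config: CohortConfig) -> np.ndarray:
    """Fixed non-negative region-by-factor loading weights (region x factor).

    Each region loads on a factor with probability ``factor_sparsity``
    (with a magnitude drawn from ``factor_weight_range``), giving a
    block-like covariance structure: region pairs sharing a factor are
    strongly coupled, the rest only through the global subject offset.
    """
    rng = _stream(config.seed, _KEY_WEIGHTS)
    lo, hi = config.factor_weight_range
    shape = (len(config.roi_names), config.n_factors)
    magnitude = rng.uniform(lo, hi, size=shape)
    gate = rng.random(shape) < config.factor_sparsity
    return magnitude * gate


# --------------------------------------------------------------------------
# generation


def generate_true_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the noise-free cohort table (method "TRUE", image type "pre").

    Returns a long-format table with one row per (subject, session, region)
    following the generative model in the module docstring.  Deterministic
    given ``config`` (which carries the seed).
    """
    config.validate()
    n_roi = len(config.roi_names)
    mu = np.array([config.mu_roi[r] for r in config.roi_names])
    weights = factor_weights(config)

    ids, groups = _subject_ids(config)
    schedule = {"PPMS": config.sessions_ppms, "RRMS": config.sessions_rrms}

    sub_col, grp_col, sess_col = [], [], []
    age_col, thick_col, ident_col = [], [], []

    for k, (sid, grp) in enumerate(zip(ids, groups)):
        rng = _stream(config.seed, _KEY_SUBJECT, k)
        plan = schedule[grp]
        n_sessions = plan.min_sessions + int(rng.poisson(plan.poisson_lambda))
        baseline = rng.uniform(*config.baseline_age_range)
        b = rng.normal(0.0, config.sigma_subject)
        beta = rng.normal(
            config.slope_mean_by_group[grp], config.slope_sd_by_group[grp]
        )
        latent = rng.standard_normal(config.n_factors)
        u = rng.normal(0.0, config.sigma_roi, size=n_roi)
        ident = rng.random(n_sessions) < config.identical_params_fraction

        dage = plan.interval_years * np.arange(n_sessions)
        scale = config.loading_scale_by_group.get(grp, 0.0) if config.n_factors else 0.0
        profile = mu + b + scale * (weights @ latent) + u
        thick = profile[None, :] + beta * dage[:, None]

        sub_col.append(np.repeat(sid, n_sessions * n_roi))
        grp_col.append(np.repeat(grp, n_sessions * n_roi))
        sess_col.append(np.repeat(np.arange(n_sessions), n_roi))
        age_col.append(np.repeat(baseline + dage, n_roi))
        ident_col.append(np.repeat(ident, n_roi))
        thick_col.append(thick.ravel())

    n_total = sum(a.size for a in sub_col)
    table = pd.DataFrame(
        {
            "subject_id": np.concatenate(sub_col),
            "group": np.concatenate(grp_col),
            "session_index": np.concatenate(sess_col).astype(np.int64),
            "age": np.concatenate(age_col),
            "image_type": np.repeat("pre", n_total),
            "method": np.repeat("TRUE", n_total),
            "roi": np.tile(np.asarray(config.roi_names), n_total // n_roi),
            "thickness_mm": np.concatenate(thick_col),
            "identical_params": np.concatenate(ident_col),
        }
    )
    if (table["thickness_mm"] <= 0).any():
        bad = table.loc[table["thickness_mm"] <= 0, "roi"].iloc[0]
        raise ConfigurationError(
            f"generated non-positive thickness (first at roi {bad!r}); "
            "reduce variance parameters or raise mu_roi"
        )
    return table


def simulate_measurements(
    true_table: pd.DataFrame,
    models: list[MeasurementModel],
    seed: int,
) -> pd.DataFrame:
    """Apply measurement models to a true cohort table.

    For each model: Y = T + delta_subject * [CE] + g_session + eps, with
    ``delta_subject ~ N(bias_mean, bias_sd^2)`` drawn once per subject x
    model, ``g_session`` shared across regions of one image, and ``eps``
    independent per region.  CE sessions are dropped whole with probability
    ``failure_rate``.  Rows of all models are concatenated.
    """
    if not models:
        raise ConfigurationError("models must be non-empty")
    bad_types = set(true_table["image_type"]) - set(IMAGE_TYPES)
    if bad_types:
        raise ConfigurationError(f"unknown image_type labels in table: {bad_types}")

    # Precompute one (sessions x regions) truth block per subject; the
    # model loop then only does array arithmetic.
    subjects: list[str] = []
    blocks: list[dict] = []
    for sid, sub in true_table.groupby("subject_id", sort=False):
        pivot = sub.pivot_table(
            index="session_index", columns="roi", values="thickness_mm", sort=False
        )
        sessions = pivot.index.to_numpy()
        meta = sub.drop_duplicates("session_index").set_index("session_index")
        subjects.append(sid)
        blocks.append(
            {
                "truth": pivot.to_numpy(),
                "rois": pivot.columns.to_numpy(),
                "sessions": sessions,
                "ages": meta.loc[sessions, "age"].to_numpy(),
                "ident": meta.loc[sessions, "identical_params"].to_numpy(dtype=bool),
                "group": sub["group"].iloc[0],
            }
        )

    frames: list[pd.DataFrame] = []
    for mi, model in enumerate(models):
        for si, blk in enumerate(blocks):
            rng = _stream(seed, _KEY_MEASURE, mi, si)
            delta = rng.normal(model.bias_mean, model.bias_sd)
            n_sessions, n_roi = blk["truth"].shape
            failure_draw = rng.random(n_sessions)
            g_draw = rng.standard_normal(n_sessions)
            eps = rng.standard_normal((n_sessions, n_roi)) * model.noise_sd

            sess_sd = np.where(
                blk["ident"], model.session_noise_sd, model.session_sd_variable
            )
            values = blk["truth"] + (g_draw * sess_sd)[:, None] + eps
            if model.image_type == "CE":
                values = values + delta
                keep = failure_draw >= model.failure_rate
            else:
                keep = np.ones(n_sessions, dtype=bool)
            if not keep.any():
                continue

            kept = np.flatnonzero(keep)
            n_rows = kept.size * n_roi
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(subjects[si], n_rows),
                        "group": np.repeat(blk["group"], n_rows),
                        "session_index": np.repeat(blk["sessions"][kept], n_roi),
                        "age": np.repeat(blk["ages"][kept], n_roi),
                        "image_type": np.repeat(model.image_type, n_rows),
                        "method": np.repeat(model.method, n_rows),
                        "roi": np.tile(blk["rois"], kept.size),
                        "thickness_mm": values[kept].ravel(),
                        "identical_params": np.repeat(blk["ident"][kept], n_roi),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_study(
    config: CohortConfig | None = None,
    models: list[MeasurementModel] | None = None,
    measurement_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate truth and measured tables in one call.

    The measurement seed defaults to ``config.seed`` offset by a fixed
    constant so truth and measurement streams never collide.
    """
    if config is None and models is None:
        config, models = default_study_config()
    elif config is None or models is None:
        raise ConfigurationError("pass both config and models, or neither")
    truth = generate_true_cohort(config)
    mseed = config.seed if measurement_seed is None else measurement_seed
    measured = simulate_measurements(truth, models, seed=mseed)
    return truth, measured


def global_mean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse regions to the unweighted global mean thickness per image.

    Returns one row per (subject, session, method, image type) with the mean
    over all regions present, keeping group, age and the sequence-parameter
    flag.
    """
    keys = [
        "subject_id",
        "group",
        "session_index",
        "age",
        "image_type",
        "method",
        "identical_params",
    ]
    out = (
        table.groupby(keys, sort=False, as_index=False)["thickness_mm"]
        .mean()
        .reset_index(drop=True)
    )
    return out


def latent_pair_sample(
    n_pairs: int,
    *,
    noise_sd_x: float,
    noise_sd_y: float | None = None,
    latent_mean: float = 2.5,
    latent_sd: float = 0.10,
    bias_mean: float = 0.0,
    bias_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired noisy measurements of a common latent value.

    Each pair shares a latent ``T ~ N(latent_mean, latent_sd^2)``; the two
    sides add independent noise (SDs ``noise_sd_x``/``noise_sd_y``) and the
    second side a per-pair bias ``N(bias_mean, bias_sd^2)``.  This is the
    closed-form attenuation setting used for reliability calibration:
    E[r] = latent_sd^2 / sqrt((latent_sd^2+sx^2)(latent_sd^2+sy^2)).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if noise_sd_y is None:
        noise_sd_y = noise_sd_x
    latent = rng.normal(latent_mean, latent_sd, size=n_pairs)
    x = latent + rng.normal(0.0, noise_sd_x, size=n_pairs)
    y = latent + rng.normal(0.0, noise_sd_y, size=n_pairs)
    if bias_mean != 0.0 or bias_sd > 0.0:
        y = y + rng.normal(bias_mean, bias_sd, size=n_pairs)
    return x, y
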