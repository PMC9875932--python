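# Methods

This note documents the statistical model behind the synthetic cohort,
the estimators, the numerical choices, and the limits of what the test
suite can show.

## The synthetic cohort model

The generator emulates a longitudinal two-group MS cohort: `n_ppms = 9`
primary progressive and `n_rrms = 66` relapsing remitting patients.
Visit counts are `3 + Poisson(λ)` with λ = 5 (RRMS, 0.5-year spacing) and
λ = 3 (PPMS, 1.0-year spacing); the minimum of three sessions reflects
that most patients in such registries have enough follow-up to pass the
≥ 3 time-point rule, and the expected total session count lands near the
scale of the study being emulated (hundreds of same-session pairs).
Baseline ages are uniform on 25–60 years.

Noise-free thickness of subject *i*, session *j*, region *r* (64
Desikan-Killiany-style regions, 32 per hemisphere; the two pole regions
are omitted from the default label set):

```
T[i,j,r] = mu_roi[r] + b_i + beta_i (age_ij − age_i0)
           + lambda_g Σ_f L[i,f] w[r,f] + u[i,r]
```

| parameter | default | units | role |
|---|---|---|---|
| `mu_roi` | region-specific, 1.65–3.30 | mm | population mean thickness per region |
| `sigma_subject` (b_i) | 0.10 | mm | global between-subject offset, shared across regions |
| `slope_mean_by_group` (beta) | −0.012 / −0.003 | mm/year | PPMS / RRMS mean annual atrophy |
| `slope_sd_by_group` | 0.0296 | mm/year | between-patient slope spread |
| `sigma_roi` (u) | 0.05 | mm | per-subject regional idiosyncrasy |
| `n_factors`, `factor_sparsity` | 6, 0.25 | — | latent covariance factors; each region loads on a factor with p = 0.25 |
| `factor_weight_range` | U(0.8, 1.2) | — | loading magnitudes (non-negative) |
| `loading_scale_by_group` | 0.12 / 0.08 | mm | PPMS / RRMS factor scale (1.5× ratio) |

The sparse, non-negative factor loadings give a block-like covariance
structure: region pairs sharing a factor are strongly coupled, all others
only through the global offset `b_i`.  Scaling the loadings 1.5× for PPMS
makes that group's structural covariance uniformly stronger, so its SCN
is denser at any threshold — the directional group difference the SCN
analysis is designed to detect.  The base magnitude (0.08) and the
factor layout were calibrated once, by simulation, so that the group
difference in global efficiency at τ = 0.5 is reproduced in ≈ 99% of
seeds despite the dominant source of variability at n = 9 PPMS subjects
(coherent, matrix-wide jitter of the sample correlations); a dense
loading design is measurably less robust because a single weak factor
realization can empty the whole graph.

### Measurement model

Each measurement channel (method × image type; defaults "DL"/"FS" ×
"pre"/"CE") adds

```
Y = T + delta_i·[CE] + g_session + eps_region
```

* `delta_i ~ N(bias_mean, bias_sd²)`, one draw per subject × channel:
  CE bias means 0.06 mm (DL) and 0.17 mm (FS), spread 0.02 mm.
* `g_session`, shared across all regions of one image — the component that
  moves the global mean.
* `eps_region`, independent per region: SD 0.16 mm (DL) and 0.20 mm (FS).
* CE sessions are dropped whole with probability 17/454 for the FS-like
  channel (processing failures); DL never fails.

Noise levels are calibrated through the attenuation formula
r = σ_T²/(σ_T²+σ_e²) with σ_T = 0.10 mm on the global mean: per-image
global-mean noise SDs of 0.0204 / 0.0387 mm (DL / FS) for sessions with
identical acquisition parameters and 0.0357 / 0.0703 mm for the rest
(fraction 213/454 identical) reproduce r = 0.96 / 0.87 on the
identical-parameter subset and 0.92 / 0.75 over all pairs.  The
session-level SD is derived as `sqrt(g² − σ_roi²/64)` so that the
shared-plus-regional decomposition hits those global targets exactly.
Sequence-parameter variability therefore acts at the session level, which
matches its physical origin (whole-image contrast changes).

Randomness: one master seed; independent PCG64 substreams per subject and
per (subject, channel) derived by `SeedSequence` spawn keys, so enlarging
the cohort or adding channels never perturbs existing draws, and
identical (config, seed) reruns are byte-identical.

### What the generator does not model

No images, segmentation or thickness computation; no lesions, scanner or
field-strength effects beyond the session-level noise; no per-region
atrophy-rate differences (all regions of a subject share one slope); the
identical-parameters subset is a single boolean per session, not a model
of TI/TR.  Passing tests therefore demonstrate that the *estimators*
recover known structure under realistic noise, not that any particular
MRI pipeline achieves these numbers on real data.

## Estimators and numerical choices

* **Pearson r** (`scipy.stats.pearsonr`); zero variance on either side
  raises an explicit undefined-statistic error, never a silent 0 or 1.
* **ICC(C,2)** from the two-way (subjects × image types) ANOVA mean
  squares, `(MS_rows − MS_err)/MS_rows`; fixed to the mean-rating (k = 2)
  consistency form.  ICC(A,2) is provided but not used in reports.
  Cross-checked in the test suite against pingouin's `ICC(C,k)`/`ICC(A,k)`
  to 1e−9.
* **Bland–Altman**: bias = mean(CE − pre), limits ± 1.96 × sample SD
  (n − 1 denominator).
* **Dependent-correlation comparison**: subject-level bootstrap (5000
  resamples, seeded) of the Fisher-z difference, two-sided sign-based p;
  a Steiger/Pearson–Filon asymptotic z is available behind
  `method="steiger"` as a cross-check.  The bootstrap is the default
  because it avoids normality assumptions at modest n.
* **Atrophy rates**: OLS of thickness on age per (subject, method, image
  type, scope); series with fewer than `min_timepoints = 3` sessions are
  excluded *per series*, so a subject whose CE images failed can still
  contribute a non-enhanced rate.  Age, not session index, is the
  regressor.  The global mean is the unweighted mean over the 64 regions
  (FreeSurfer's own header MeanThickness, which is area-weighted, is used
  when reading real `aparc.stats` files).
* **Cohen's d**: classic pooled-SD formula for both the group contrast
  and the pre-vs-CE contrast (a paired variant exists behind a flag; the
  unpaired form is the default and is what the reports use).  Pooled SDs
  within 1e−12 of the data scale are treated as degenerate (undefined),
  not as d = ±∞.
* **SCN construction**: every image (subject-session observation of one
  method and image type) is a sample; age residualization is OLS per
  region, fitted within the image set of each network
  (`residualize="per-group"` default; `"pooled"` fits across groups
  before splitting).  Thresholding is signed — an edge requires
  r ≥ τ, so negative correlations never create edges on the non-negative
  grid (0.00–0.99, step 0.01).
* **Global efficiency** is computed from scratch: level-synchronous BFS
  expanded from all sources simultaneously via boolean matrix products,
  with 1/∞ = 0 for disconnected pairs.  Verified exactly against
  networkx and `scipy` Floyd–Warshall on random graphs.
* **Subsample bands**: `floor(0.8 n)` images drawn *without* replacement,
  1000 repetitions by default, band = per-threshold sample SD; the point
  estimate always comes from the full image set.  Examples and pipeline
  smoke tests use far fewer repetitions; results at the default scale are
  identical in structure.
* **Serialization**: morphometry tables round-trip CSV at full precision
  (`%.17g`, `float_precision="round_trip"` on read); derived report CSVs
  use 6 significant digits.  Every output carries the master seed and a
  configuration hash, and reruns are bit-identical.

## Recovery experiments

`cemorph.experiments` (used by `scripts/acceptance.py` and the test
suite) re-derives the calibration targets at run time: attenuation
reliability averaged over 100 seeded replicates of 454 (or 213) pairs,
Cohen's d from 50,000 slope draws per group, CE-bias recovery over 100
replicates, and the 73-of-75 time-point filter count.  These run in
seconds on one CPU.  The SCN direction experiment (PPMS > RRMS at
τ = 0.5, DL channels, 100 seeded cohorts) takes about a minute.

## Known limitations

* Group mean atrophy rates from a *single* 75-patient cohort are noisy
  (SE ≈ 0.01 mm/year for 9 PPMS patients); only the population-level
  recovery over seeds, and the direct distribution-level effect sizes,
  are asserted quantitatively.
* The bootstrap p for dependent correlations is resolution-limited by the
  number of resamples (p ≥ 1/5000 at defaults).
* With 9 subjects the PPMS covariance matrix is inherently unstable;
  ~1% of seeds invert the efficiency ordering at τ = 0.5, matching the
  calibrated design, and no statistical test between group efficiency
  curves is provided.
* `read_dldirect_stats` accepts any one-row wide CSV; mapping its region
  names onto FreeSurfer `StructName`s is tool-version dependent and left
  to a user-supplied alias table.
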