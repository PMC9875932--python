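# cemorph

**Reliability, atrophy-rate and covariance-network analysis for paired
contrast-enhanced / non-enhanced brain morphometry.**

Clinical MRI protocols often include only a contrast-enhanced (CE)
T1-weighted image, which standard morphometry pipelines handle poorly.
Evaluating whether cortical thickness can be measured reliably from CE
images requires a specific statistical toolkit: paired agreement between
same-session non-enhanced and CE measurements, longitudinal atrophy rates
per patient, group effect sizes, and structural covariance networks (SCNs)
with resampling uncertainty.  `cemorph` implements that evaluation as a
reusable, fully tested pipeline for researchers in quantitative
neuroimaging — together with a synthetic-cohort generator that emulates
the data structure of a longitudinal multiple-sclerosis study (9 primary
progressive / PPMS and 66 relapsing remitting / RRMS patients, ~454
same-session image pairs, 64 Desikan-Killiany-style cortical regions, two
morphometry methods), so every stage can be verified end-to-end against
known ground truth without any MRI data.

## Statistics implemented

* **Pearson r** between paired measurements; under independent measurement
  noise the expected value follows the attenuation formula
  r = σ_T² / √((σ_T²+σ_A²)(σ_T²+σ_B²)).
* **ICC(C,2)** — consistency intraclass correlation for the mean of k = 2
  ratings from the two-way mixed-effects ANOVA:
  ICC(C,k) = (MS_BS − MS_E)/MS_BS (absolute-agreement ICC(A,2) is also
  available).  On equal-variance pairs ICC(C,2) = 2r/(1+r).
* **Bland–Altman** bias and 95% limits of agreement, bias ± 1.96·SD(y−x).
* **Subject-wise correlations** across the 64 regional thicknesses of each
  session, and a subject-level bootstrap (plus Steiger z) for comparing
  two dependent correlations.
* **Atrophy rates**: per-patient OLS slope of thickness (mm) on age
  (years), per method × image type, with the ≥ 3 time-point inclusion
  rule; group contrasts via pooled-SD **Cohen's d**.
* **SCNs**: per-region age residualization, inter-regional correlation,
  binary graphs over a 0.01-step threshold grid, **global efficiency**
  E_glob = (1/(N(N−1))) Σ_{i≠j} 1/d_ij computed from scratch by BFS, and
  ±1 SD bands from 1000 rebuilds on random 80% image subsamples.

## Worked example

```bash
python examples/reliability_attenuation.py
```

```
DL-like: r = 0.917, ICC(C,2) = 0.957, bias = 0.061 mm, LoA = [-0.023, 0.144] mm
FS-like: r = 0.740, ICC(C,2) = 0.851, bias = 0.171 mm, LoA = [0.007, 0.335] mm
```

454 simulated same-session pairs of a global mean thickness (latent
N(2.5, 0.10²) mm) are measured twice with independent noise.  At the
DL-like noise level (σ_e = 0.0295 mm) the correlation is barely
attenuated (r ≈ 0.92, ICC ≈ 0.96); the FS-like level (σ_e = 0.0577 mm)
drops it to r ≈ 0.75.  The Bland–Altman bias recovers the simulated CE
overestimation (0.06 vs 0.17 mm), which the consistency ICC ignores by
construction.

Other examples: `examples/atrophy_rates.py` (per-patient slopes and the
group effect-size table), `examples/scn_efficiency.py` (PPMS vs RRMS
global efficiency at τ = 0.5 with subsample bands),
`examples/full_pipeline.py` (all artifacts of an end-to-end run).  The
same stages are scriptable via the thin CLI:

```bash
cemorph run-all --seed 1 --out results/
cemorph scn results/cohort.csv --tau-star 0.5 --reps 200
```

Real data can be loaded instead of simulated: long-format CSV tables
(`subject_id,group,session_index,age,image_type,method,roi,thickness_mm`),
FreeSurfer `?h.aparc.stats` files (`read_freesurfer_aparc_stats`) and
per-subject DL+DiReCT result CSVs (`read_dldirect_stats`).

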