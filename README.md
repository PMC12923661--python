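# tractshift

Paired pre- vs intraoperative diffusion-MRI tractometry of the
dentato-rubro-thalamic tract (DRTT) and arcuate fasciculus (AF), with a
synthetic phantom cohort generator that makes the whole pipeline testable
end to end.

## The problem

Resection of pediatric posterior fossa tumors can disturb the cerebellar
outflow pathway — the DRTT, which runs from the dentate nucleus through the
(contralateral, for its decussating component) thalamus to the motor
cortex — and such disturbance is a candidate mechanism for postoperative
speech disorders (cerebellar mutism). Intraoperative diffusion MRI allows
the tract to be re-measured mid-surgery, but the comparison is delicate:
volumes shrink with brain shift, intraoperative SNR is lower, and
reconstructions sometimes fail. This package implements that comparison as
a reusable, tested pipeline:

* **Tracking** — deterministic FACT propagation over a discrete fiber-peak
  field: 1-mm seed grid, 1-mm steps, termination at peak amplitude < 0.01,
  turn angle > 60°, or the gray-white matter interface.
* **Gating** — AND/NOT ROI waypoint logic (dentate, thalamus, motor cortex;
  corpus callosum and tumor excluded), the decussating vs non-decussating
  DRTT split by the motor-end hemisphere, and a cohort-percentile length
  filter for the AF.
* **Tractometry** — tract volume (voxels visited, % of supratentorial white
  matter), cylinder-equivalent diameter `2·sqrt(V/(π·L))`, whole-tract
  FA/MD as across-streamline means, and 55-segment along-tract FA/MD
  profiles on the mean centerline (`55 = ceil(138 mm / 2.55 mm)`).
* **Microstructure** — OLS log-linear tensor fit, FA/MD maps, and the
  white-matter b0-series SNR statistic.
* **Statistics** — paired Wilcoxon signed-rank tests, linear mixed models
  with a patient random intercept (± SNR or age covariate), paired Cohen's
  d with 0.2/0.5/0.8 bands, rank-sum contrasts by speech-disturbance label,
  per-segment tests of mean change with Benjamini-Hochberg FDR per panel,
  logistic regression of outcome on demographics, and change-vs-ventricle
  correlations.
* **Phantom** — paired synthetic "patients": spline-tube bundles (d-DRTT,
  nd-DRTT, AF, both hemispheres) with tensors and Rician-noise DWI, plus
  injected surgical effects (bundle compression, a localized MD elevation
  at the dentate end, an SNR drop, tumor resection) recorded as ground
  truth.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
tractshift demo --n 6 --seed 7 --out demo
```

generates six synthetic patient pairs, tracks and segments their tracts,
and writes `metrics.csv`, `profiles.csv`, `subjects.csv` and `stats/`.
The paired normalized-volume battery (`stats/paired.csv`) from that exact
command reads:

```
  tract  side      metric  n_pairs  percent_change  wilcoxon_p  effect_d     band  lmm_p
 d_DRTT  left volume_norm        6        -31.3459      0.0312   -4.1671    large 0.0000
 d_DRTT right volume_norm        6        -38.7811      0.0312   -4.7337    large 0.0000
nd_DRTT  left volume_norm        6         -7.9428      0.0938   -0.9449    large 0.0206
nd_DRTT right volume_norm        6         -5.4612      0.3125   -0.6638 moderate 0.1039
     AF  left volume_norm        6        -7.4756      0.0312   -1.1333    large 0.0055
     AF right volume_norm        6        -3.7384      0.1562   -0.6766 moderate 0.0975
```

The injected compression (radius ×0.7 on the d-DRTT, ×0.95 on the AF, none
on the nd-DRTT) surfaces exactly where it should: large volume losses in
the decussating DRTT, small ones in the AF control, and the weakest changes
in the non-decussating DRTT. `stats/global.csv` shows the measured
white-matter SNR dropping by 9.1% (injected noise factor 0.906 ≙ 9.4%),
with the paired Wilcoxon p = 0.031 at n = 6. In the along-tract results
(`stats/segments.csv`) the injected MD elevation concentrates in the
dentate-end segments of the left d-DRTT (per-segment z ≈ 2–3 over segments
6–14, near zero elsewhere), though six subjects are too few for
BH-significance there — the 30-subject validation runs in
`scripts/acceptance.py` quantify the localization properly.

The same stages are available as library calls (`make_cohort`,
`run_cohort`, `run_stats`) and as file-based commands (`tractshift phantom`,
`tractshift track`, `tractshift all --config cfg.yaml`).

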