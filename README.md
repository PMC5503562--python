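# prolifindex

Pan-cancer analysis of tumor cell proliferation from bulk RNA-seq. The package
computes a per-sample **proliferative index (PI)** — the median normalized
expression of a PCNA-associated meta-gene set (canonically the 131-gene
metaPCNA set of Venet et al.) — and asks where proliferation matters for a
patient's outcome:

* **PI computation** from raw count matrices, with counts-per-million
  normalization for cross-cohort comparisons and a variance-stabilizing
  transform for within-cancer survival work.
* **Survival association**: univariate Cox proportional-hazards fits of
  overall survival on PI, per cancer, and on *every transcript* (a batched
  Efron/Newton fit makes the transcriptome scan cheap). Cancers whose PI–
  survival association survives Bonferroni correction across cancers are
  **proliferation-informative cancers (PICs)**.
* **Cross-cancer signature**: transcripts significant (Cox p < 0.05) in at
  least 9 of 19 cancers; Ward clustering of cancers on their −log10 p
  profiles recovers the PIC/non-PIC split.
* **Extreme-survivor classifiers**: per cancer, the k = 18 shortest-surviving
  uncensored patients (outcome 0) vs the 18 longest-surviving patients
  (outcome 1); genes z-scaled within cancer, cohorts pooled, 70/30
  outcome-stratified split; LASSO / ridge (5-fold CV, one-standard-error
  rule), random forest and linear SVM; test-set ROC-AUC, DeLong comparisons,
  and a permutation null over random cancer subsets.
* **Genomic and pharmacologic links**: Spearman association of PI with
  log10 somatic mutation burden; per-gene Wilcoxon contrasts of PI by
  missense/nonsense mutation status combined across cancers with Fisher's
  method and BH FDR; PI vs drug EC50 in cell-line panels; and scoring of
  connectivity-style probe × treatment rank matrices by the median rank of
  PI probes.

Real inputs of this kind (TCGA Level 3 counts, clinical follow-up tables,
MAF-like mutation calls, CCLE drug panels, CMap rank matrices) are read from
plain TSV/CSV. Because none are redistributable, the package ships a
**synthetic multi-cancer cohort generator** (`prolifindex.simulate`) that
plants a latent proliferation factor with known gene loadings, hazard
coefficients, mutation-burden slope and drug effects, so every stage of the
pipeline can be validated against ground truth.

## Model sketch

For patient *i* in cancer *c*: latent proliferation `z_i ~ N(mu_c, 1)`;
counts `x_gi ~ NB(s_i q_g exp(beta_g z_i + ...), phi_g)` with `beta_g > 0` on
the PI gene set; survival `T_i ~ Exp(h0 exp(gamma_c z_i + eta_c w_i))` where
`gamma_c > 0` exactly in planted PICs and `w_i` is a cancer-specific
auxiliary program driving non-PIC survival. PI is the median over the PI
genes; the Cox Wald test of survival on PI recovers `gamma_c`; everything
downstream follows the analyses above.

## Worked example

`scripts/acceptance.py` regenerates a default synthetic world and runs the
whole analysis from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (seed 1):

```
simulated 19 cancers x 150 patients, 400 genes; planted PICs: ['C01', ..., 'C07']
Spearman(PI, planted z) = 0.986  (131 PI genes used)
PICs called (Bonferroni < 0.05): ['C01', 'C02', 'C03', 'C04', 'C05', 'C06', 'C07']
shared survival transcripts (p<0.05 in >=9/19): 76
2-cluster Ward cut sizes [12, 7]; matches planted PICs: True
LASSO test AUC: PIC-only 0.865 vs all-cancer 0.629
permutation null (20 draws of 7): rho(#PICs, AUC) = 0.684 (p = 0.000876); ...
Spearman(PI, log10 mutation burden) = 0.932 (p = 0, n = 2850)
gene-mutation scan: 400 genes combined; ... planted drivers at q<0.1: 3/3
EC50 correlations: q<0.1 for ['drug01', 'drug02', 'drug03', 'drug04', 'drug22'] ...
anti-proliferative treatment percentiles: [0.0, 0.067, 0.0, 0.05, 0.0]
```

Reading this: the PI computed from simulated counts tracks the planted
proliferation score almost perfectly (rho 0.99); exactly the seven planted
PICs clear the Bonferroni bar, and the Ward cut over shared survival
transcripts reproduces the same 7/12 partition; the extreme-survivor LASSO
trained on PICs only generalizes far better (AUC 0.865) than the one trained
on all cancers (0.629), and random 7-cancer subsets perform in proportion to
how many PICs they contain; mutation burden and the three planted driver
genes are recovered, and the planted growth-suppressing treatments fall in
the bottom decile of the PI-activation ranking. The script writes an empty
JSON object to `--out` (this artifact's acceptance checks are property-based
and live in `tests/test_acceptance.py`).

## Command-line interface

```
prolifindex [--config run.yaml] [--seed N] [--out DIR] [--log-level info] <cmd>
```

Subcommands: `load-check`, `simulate`, `pi`, `survival`, `pics`, `model`,
`permute`, `mutations`, `drugs`. Every run writes a `manifest.json` with
inputs, thresholds, seed, and versions. `prolifindex simulate --out dir/`
writes a complete synthetic dataset (expression, clinical, mutation, drug and
rank-matrix tables plus the latent truth) in the same formats the analysis
commands read.

## Layout

```
src/prolifindex/
  io.py        readers/writers, cohort filtering, validated containers
  index.py     CPM, VST, PI, group comparisons, PCA-PI correlations
  survival.py  Cox fits (Efron/Newton), scans, PIC labels, clustering, KM
  model.py     dichotomization, penalized models, AUC/DeLong, permutation
  assoc.py     mutation-burden/gene scans, Fisher/BH, EC50, rank matrices
  simulate.py  ground-truth generator
  pipeline.py  stage wiring      config.py  YAML config + manifests
  cli.py       click interface
docs/methods.md   model, assumptions, numerical choices, limitations
```

See `docs/methods.md` for the statistical details and the explicit list of
what the synthetic generator does and does not emulate.
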