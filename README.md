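# crossprot

Cross-platform concordance analysis for affinity proteomics in
cerebrospinal fluid (CSF).

Aptamer panels (SomaScan-style, thousands of SOMAmer reagents read out in
relative fluorescence units) and antibody/PEA panels (Olink-style, log2 NPX
units) measure overlapping but not identical sets of proteins, and a
substantial fraction of reagents on either platform does not reproduce —
within the platform or across platforms.  `crossprot` implements the full
head-to-head comparison pipeline for a cohort measured on two independent
aptamer runs and one antibody run:

* **IO & harmonization** — wide (ADAT-style) and long (NPX) delimited
  readers, log2 transform + per-reagent z-scaling, UniProt-ID-set reagent
  pairing (protein complexes match only on the complete ID set), sample
  alignment.
* **QC** — PCA (variance to a target, top loadings, PC–phenotype screens,
  1.5×IQR score outliers) and calibrator-based coefficients of variation:
  intra-assay (per plate, averaged) and inter-assay (pooled across plates),
  with CV = σ/μ on the linear RFU scale and
  CV = √(exp((ln2·σ_NPX)²) − 1) on the log2 NPX scale.
* **Reproducibility score** — Spearman ρ of each aptamer across the two
  runs (intra) and against UniProt-matched antibody assays (inter),
  categorized good (ρ ≥ 0.5) / moderate (0.3 ≤ ρ < 0.5) / poor (ρ < 0.3)
  and combined into a 12-level score: 1–9 for reagents represented on both
  platforms (intra × best-inter category), A–C for aptamer-only reagents.
  Scores 1–3 and A form the "reproducible set".
* **Association screens** — per-reagent regressions of z-scored protein
  levels on clinical traits and CSF biomarkers with covariate adjustment
  (sex, age, CSF total protein, biomarker technique when applicable),
  Bonferroni control, and a LASSO held-out variance-explained evaluation.
* **Overlap enrichment** — the size of the intersection of top-K (default
  500) reagents across several phenotype rankings, compared against a
  with-replacement bootstrap null
  (E[|∩|] = N·(1 − (1 − 1/N)^K)^m) with add-one empirical p-values, plus
  2×2 odds-ratio/chi-square enrichment of reproducible vs complete sets.
* **Synthetic study generator** — a cohort + three-assay simulator with
  known ground truth (bimodal reagent fidelity, plate structure, planted
  phenotype effects) used to validate every stage.

## Worked example

```python
import crossprot as cp
from crossprot.core import Platform

study = cp.simulate_study(cp.SimulationConfig(
    n_samples=300, n_proteins=400, n_soma_reagents=500,
    n_olink_reagents=150), seed=7)

# harmonize study samples (calibrators are for CV only)
mats = {}
for plat, m in study.matrices.items():
    pm = study.plate_maps[plat]
    mats[plat] = cp.log2_zscale(m.subset_samples(pm.study_samples()))

table = cp.score_reagents(mats[Platform.SOMA_A], mats[Platform.SOMA_B],
                          mats[Platform.OLINK], study.annotations)
print(table["score"].value_counts().sort_index())

null = cp.bootstrap_overlap_null(N=7289, k=500, m=3, B=10000, seed=1)
print(round(null.sim_mean, 3), round(null.sim_sd, 3),
      round(null.expected_closed_form, 3))
```

prints

```
score
1     16
2      1
3     29
9     97
A    127
B      1
C    229
Name: count, dtype: int64
2.108 1.43 2.124
```

With a third of reagents planted in the high-fidelity class, scored
aptamers split into the reproducible branches (1–3 for antibody-matched
proteins, A for aptamer-only) and the non-reproducible ones (9, C); the
moderate cells stay nearly empty because the fidelity mixture is bimodal.
The bootstrap null says that three random top-500 lists drawn from a
7,289-reagent universe share only ~2.1 reagents by chance (SD ~1.4),
matching the analytic expectation 2.124 — an observed overlap of dozens of
reagents is therefore overwhelming evidence of shared signal.

A command-line layer mirrors the stages:

```sh
crossprot simulate --seed 7 --outdir study/
crossprot qc --matrix study/soma_b.tsv --platform SOMA_B \
    --plate-map study/soma_b_plates.tsv --phenotypes study/phenotypes.tsv \
    --outdir qc/
crossprot score --soma-a study/soma_a.tsv --soma-b study/soma_b.tsv \
    --olink study/olink.tsv --annotations study/annotations.tsv --outdir score/
```

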