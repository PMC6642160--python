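# rccpath

A whole-slide histopathology analysis pipeline for renal cell carcinoma
(RCC), built as an importable Python library with a thin command-line
wrapper.  It covers the full arc from slide pixels to patient prognosis:

1. **Tiling & background filtering** — slides are cut into 512×512 patches
   with 50% overlap; a patch is discarded as background when at least half
   of its pixels have mean-RGB intensity above 210.
2. **Patch classification** — a pluggable scorer contract (`score` →
   class probabilities, `embed` → penultimate-layer feature vector) with a
   bundled CPU-trainable reference backbone, slide-level 70/15/15 splits,
   minority-class augmentation and inverse-frequency sampling weights for
   the 43/14/43 subtype imbalance among clear-cell (KIRC), papillary
   (KIRP) and chromophobe (KICH) RCC.
3. **DAG-SVM multiclass head** — the N-class problem is decomposed into
   N(N−1)/2 linear soft-margin SVMs over the embeddings; prediction walks a
   directed-acyclic elimination path with exactly N−1 classifier
   evaluations.  The metric panel reports accuracy, precision/recall,
   Cohen's κ = (p_o − p_e)/(1 − p_e) and rank-based micro/macro AUC.
4. **Heatmaps & morphometry** — per-pixel averaging of overlapping patch
   probabilities, strict thresholding at 0.95, removal of regions smaller
   than one third of the main region, then tumor-region shape features
   (area, convex area, filled area, perimeter, axes, eccentricity,
   solidity) and nuclei features from hierarchical-Otsu segmentation.
5. **Survival stratification** — patient-level image features feed an
   L1-penalized Cox model, h(t|x) = h₀(t)·exp(xᵀβ) with penalty λ‖β‖₁
   chosen by 10-fold cross-validated partial-likelihood deviance.  Patients
   are stratified low/high risk by a two-level cross-validation: an outer
   leave-one-out loop in which each held-out patient is assigned by the
   median training risk index, so no patient's outcome touches their own
   assignment.  Groups are compared by log-rank, Kaplan–Meier curves and a
   multivariate Cox model with clinical covariates.

Everything is testable without external data: the `synthetic` module
generates tissue-like slides with ground-truth tumor masks, nuclei images
with analytic geometry, separable embedding clusters, and survival cohorts
with known hazard structure.

## Worked example

`examples/06_full_pipeline.py` runs the whole study on the synthetic demo
dataset (30 subtype slides, 10 normals, a 48-patient survival cohort in
which a latent hazard driver also scales tumor area):

```
subtype task: accuracy 1.000, kappa 1.000, micro-AUC 0.999
tumor/normal task: accuracy 1.000
univariate feature screen (log-rank p per feature):
          feature  p_value  significant
       total_area 0.001912         True
 main_region_area 0.001912         True
  total_perimeter 0.001329         True
nuclei_total_area 0.032475         True
integrative model: log-rank p 2.80e-03, hazard ratio 3.46
```

The subtype panel shows the DAG-SVM resolving the three engineered tissue
textures essentially perfectly; the feature screen recovers the planted
association between tumor area and hazard (each p-value is a log-rank test
on a stratification built from that feature alone), and the integrative
model combines the significant features into one risk index whose high-risk
group dies about 3.5× faster.  The other scripts in `examples/` exercise
each capability in isolation (tiling, DAG-SVM, masking/morphometry, nuclei
segmentation, survival stratification).

A thin CLI mirrors the stages:

```bash
rccpath fixtures --out demo --seed 0       # materialize the demo dataset
rccpath tile demo/subtype/KIRC_0.png --out patches --tile-size 64
rccpath run-all --out results --seed 0     # both pipelines end to end
```

## Layout

```
src/rccpath/
  synthetic.py    # fixture generators (slides, nuclei, clusters, cohorts)
  tiling.py       # grid extraction + background filter
  scorer.py       # split, scorer contract, augmentation, sample weights
  dagsvm.py       # pairwise SVM bank, DAG inference, metric panel
  heatmap.py      # probability heatmaps, slide scores, mask cleanup
  morphometry.py  # region/nuclei shape features, patient aggregation
  survival.py     # KM, log-rank, lasso-Cox, two-level CV stratification
  pipeline.py     # end-to-end orchestration + demo dataset
  cli.py          # thin click wrapper
```

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
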