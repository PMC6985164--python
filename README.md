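# omicsfuse

Integrative multi-omics tumour subtyping at desk scale.

Molecular subtypes of a cancer look different depending on which data
type you cluster: mRNA, protein, miRNA and DNA-methylation profiles of
the same tumours routinely produce conflicting patient groupings.
`omicsfuse` implements the full analysis chain that resolves this for
small cohorts (tens of samples):

1. **Similarity network fusion (SNF).**  Each layer becomes a patient
   similarity network `W(i,j) = exp(−d²(i,j)/(α·ε(i,j)))` with a locally
   adaptive bandwidth `ε(i,j) = (μᵢ + μⱼ + d(i,j))/3` (μᵢ = mean
   distance from sample *i* to its K nearest neighbours).  Per-layer
   global status matrices `P` and local K-NN kernels `S` are
   cross-diffused, `P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ`, for *t*
   iterations (defaults K=24, α=0.7, t=25), and the fused network is
   clustered by normalized-Laplacian spectral clustering, with the
   number of clusters chosen by the eigengap heuristic.
2. **Biomarker selection.**  A diagonal, regularized neighbourhood
   component analysis (NCA) maximizes the soft leave-one-out accuracy
   `F(w) = (1/n) Σᵢ Σ_{j:yⱼ=yᵢ} p_ij − λ Σ_r w_r²` with
   `p_ij ∝ exp(−Σ_r w_r²|x_ir − x_jr|)`, yielding one nonnegative weight
   per feature; panels are the top-weighted features (fixed size or
   weight threshold), with a 3–10-feature minimal-panel search by CV loss.
3. **Subtype classifiers.**  Cubic KNN (Minkowski exponent 3) and
   quadratic/Gaussian SVMs with stratified 5-fold cross-validation,
   CV-loss-minimizing hyperparameter search, posterior probabilities
   with a 0.7 low-confidence flag, and transfer of a trained panel
   classifier to an external cohort.
4. **Drug-response inference.**  An exhaustive nearest-neighbour search
   (squared Euclidean) over standard-normalized biomarker profiles; a
   cell line's per-drug response is the category of the median z-scored
   activity area of its 10 nearest data-bearing neighbours
   (sensitive z>0.8 / intermediate / resistant z<−0.8), evaluated
   leave-one-out with the quadratic weighted Cohen's kappa.
5. **Statistics.**  Welch t-tests with Benjamini–Hochberg FDR control,
   hypergeometric gene-set enrichment, Kaplan–Meier curves with log-rank
   tests, and chi-square / Fisher association tests.

A first-class synthetic-data module generates multi-layer cohorts with
planted subtypes and deliberately *discordant* per-layer signal, so
every stage can be exercised against known ground truth.

## Worked example

Run the whole pipeline on the reference synthetic cohort (45 samples,
two subtypes, four layers, three of them 40% discordant):

```bash
omicsfuse run --outdir myrun --seed 3
```

which prints (abridged):

```json
{
  "fuse":     {"k": 2, "n_samples": 45},
  "cluster":  {"n_clusters": 2, "ari_vs_truth": 1.0, "agreement_vs_truth": 1.0},
  "biomarkers": {"layer": "methylation", "panel_size": 50},
  "classify": {"family": "knn", "cv_accuracy": 1.0},
  "transfer": {"agreement_with_clustering": 1.0, "agreement_vs_truth": 1.0,
               "low_confidence": 0, "n_features_used": 50},
  "drugs":    {"mean_kappa": 0.6232, "n_drugs": 24},
  "stats":    {"n_significant_q05": 40,
               "median_survival": {"1": 31.62, "2": 9.37}, "logrank_p": 0.0}
}
```

Reading the numbers: the eigengap picks `k = 2` clusters; the fused
network recovers the planted subtypes perfectly (`ari_vs_truth = 1.0`)
even though each discordant layer alone clusters at ARI ≈ 0.3; the
50-feature NCA panel trains a cubic-KNN classifier to 100% 5-fold CV
accuracy, which also labels an independently generated cohort perfectly;
the nearest-neighbour drug predictor agrees with the observed ordinal
drug categories at a mean quadratic kappa of 0.62 over 24 drugs; and 40
of 200 methylation features are differentially abundant at q < 0.05,
with clearly separated survival curves.

A rerun with the same `--outdir` and seed skips every stage (checksummed
resume); every output carries a provenance sidecar JSON.  Individual
stages are available as subcommands: `simulate`, `fuse`, `cluster`,
`select-biomarkers`, `train-classifier`, `predict-drugs`,
`benchmark-drugs`, `stats`.

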