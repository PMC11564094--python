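# ehrkit

Exploratory analysis toolkit for electronic health record (EHR) tables.

Clinical patient-visit tables are mixed-type (labs, vitals, diagnoses,
demographics, dates), heavily missing, and riddled with selection,
surveillance, normalization and imputation biases.  `ehrkit` packages the
full exploratory workflow for such data behind one annotated data
container:

- **`EHRFrame`** — an observations × variables matrix (rows = patient
  visits) with aligned obs/var annotation tables, layers, embeddings,
  pairwise relations and a results store, following the AnnData slot
  layout (`X`, `obs`, `var`, `layers`, `obsm`, `varm`, `obsp`, `uns`);
  stores round-trip exactly through an h5ad-compatible hierarchical file.
- **Quality control** — missingness metrics, winsorization, clipping,
  standardized-mean-difference bias screens, and **Little's MCAR test**:
  for missingness patterns *j* with *m_j* rows observing *p_j* of *p*
  variables,
  `d² = Σ_j m_j (ȳ_obs,j − μ̂_obs,j)ᵀ Σ̂_obs,j⁻¹ (ȳ_obs,j − μ̂_obs,j)`
  with EM-estimated grand mean μ̂ and covariance Σ̂, asymptotically
  χ²(Σ_j p_j − p) under the null that data are missing completely at
  random.
- **Imputation** — explicit, mean/median/mode, k-nearest-neighbor, and
  iterative random forests (MissForest).
- **Encoding & normalization** — lossless one-hot / label encoding;
  log1p, min-max, max-abs, robust, z-score, Yeo–Johnson power and
  quantile normalization, each optionally fit per group; OLS
  residualization of unwanted covariates.
- **Patient landscape** — highly variable features, PCA, k-NN graph, UMAP
  and Leiden clustering.
- **Inference** — group-vs-rest feature ranking (Welch t-tests for
  numerics, likelihood-ratio g-tests `G = 2 Σ O ln(O/E)` for categoricals,
  Benjamini–Hochberg adjustment); Kaplan–Meier curves with Greenwood
  bands, multivariate log-rank tests, Cox proportional hazards,
  bootstrap-CI concordance index; GLMs with likelihood-ratio comparison.
- **Causal inference** — backdoor adjustment sets found by d-separation
  search on a user DAG, linear-regression effect estimation, and six
  refuters (placebo treatment, random common cause, data subsets,
  unobserved-confounder sensitivity, dummy outcome, bootstrap).
- **Cohort tracking** — a provenance log of filtering steps with
  population counts and tracked-variable distributions, rendered as
  tableone-style tables and consort-style flow data.
- **Synthetic cohorts** — generators for mixed-type cohorts, MCAR / MAR /
  MNAR missingness with logistic parameterizations, survival outcomes with
  known hazard ratios, and linear structural causal models with recorded
  true effects, so every stage is verifiable without external data.

## Worked example: imputation bias under MAR missingness

Missing-at-random (MAR) data — here driven by length of stay through
`P(missing) = logistic(1.2·z + −0.6)` — distorts naive imputations:

```python
import numpy as np
from ehrkit.synth import CohortConfig, NumericFeature, make_cohort, inject_mar
from ehrkit import qc
from ehrkit.impute import impute_simple, impute_missforest

cfg = CohortConfig(
    n_patients=2000,
    numeric_features=[NumericFeature("num_medications", mean=16, sd=8),
                      NumericFeature("time_in_hospital", mean=4, sd=2)],
    correlation=0.6, seed=0)
cohort = make_cohort(cfg)
mar = inject_mar(cohort, "num_medications", "time_in_hospital",
                 scale=1.2, offset=-0.6, seed=0)

res = qc.little_mcar_test(mar)
print(f"Little's MCAR test: d2={res.statistic:.2f}, dof={res.dof}, "
      f"p={res.p_value:.2e}")

mean_imp, _ = impute_simple(mar, "mean", variables=["num_medications"])
mf_imp, _ = impute_missforest(mar, max_iter=5, n_trees=50, seed=0)
for label, frame in [("original", cohort), ("mean-imputed", mean_imp),
                     ("missforest", mf_imp)]:
    v = frame.numeric_matrix(["num_medications"])[0][:, 0]
    print(f"{label:13s} mean={v.mean():6.2f}  sd={v.std(ddof=1):5.2f}")
```

prints

```
Little's MCAR test: d2=431.58, dof=1, p=7.36e-96
original      mean= 15.82  sd= 7.93
mean-imputed  mean= 14.15  sd= 6.03
missforest    mean= 15.79  sd= 7.24
```

Little's test correctly rejects MCAR (the missingness depends on an
observed variable).  Mean imputation drags the mean down — the rows that
went missing were preferentially the long stays with many medications —
and shrinks the spread; the iterative-forest imputer, which can exploit
the correlated length-of-stay column, restores both location and scale far
more faithfully.

## Command line

```sh
ehrkit io convert visits.csv visits.h5ad
ehrkit qc metrics visits.h5ad
ehrkit qc little visits.h5ad
ehrkit encode visits.h5ad encoded.h5ad --method one_hot
ehrkit impute encoded.h5ad full.h5ad --method knn --k 20
ehrkit survival logrank surv.csv --duration t --event e --group arm
ehrkit causal data.h5ad --graph dag.txt --treatment T --outcome Y --refute all
```

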