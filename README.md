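# panfuse

Consensus-voted molecular subtype discovery, cross-fusion attention
classification and survival-forest prognosis for bulk transcriptomics.

Bulk expression cohorts (e.g. tumour RNA-seq) rarely come with ground-truth
subtype labels, yet subtypes drive treatment decisions. `panfuse` addresses
this in three linked stages:

1. **Pseudo-labels from a voting "scoring network".** Five clustering
   algorithms — K-Means, a full-covariance Gaussian mixture, Ward
   agglomerative clustering, CLARANS and K-Medoids (PAM) — partition the
   samples under a common Euclidean metric. Their label spaces are aligned by
   Hungarian assignment and each sample receives a consensus label by
   majority vote; the number of subtypes k is picked by mean silhouette.
2. **A CNN + BiLSTM classifier with cross-attention fusion**, trained against
   the consensus pseudo-labels. A sample's expression vector, ordered by
   training-set variance, is encoded by a convolutional (spatial) branch and
   a bidirectional-LSTM (temporal) branch, projected to a shared `L × d`
   token grid and fused by

       Fcg = softmax(Fc · Fgᵀ / √d) · (Fc + Fg),

   then mean-pooled into a fully connected softmax head (cross-entropy loss,
   early stopping). Hub genes are selected as the intersection of
   L1-regularised logistic selection and random-forest permutation
   importance.
3. **A prognostic risk model.** Per-gene univariate Cox screening (Efron
   ties), a random survival forest ranking the screened genes, and a
   multivariable Cox refit of the top genes yielding the proportional-
   hazards risk function

       f(t|x) = f0(t) · exp(coef₁·gene₁ + … + coefₘ·geneₘ),

   with a Breslow baseline. Patients are stratified at the cutoff maximising
   the standardised log-rank statistic over all admissible cutpoints
   (maximally selected rank statistics), with Kaplan-Meier curves and the
   concordance index for evaluation.

A seeded synthetic-data module generates cohorts with planted subtypes and
linked right-censored survival so the whole pipeline is testable without any
external download. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
import numpy as np
from panfuse import (SimulationConfig, simulate_expression, simulate_survival,
                     ConsensusClusterer, PrognosticModel)

cfg = SimulationConfig(n_samples=120, n_genes=60, k_subtypes=3,
                       n_informative=24, effect_size=3.0, seed=7)
X, truth, _ = simulate_expression(cfg)

res = ConsensusClusterer(k=None, k_candidates=[2, 3, 4], seed=0).fit(X)
print(res.summary())

surv = simulate_survival(X, ["G0001", "G0002"], [0.8, -0.8],
                         baseline_rate=0.1, censor_rate=0.2, seed=8)
prog = PrognosticModel(X, surv, top_m=4, n_trees=200, seed=0).fit()
print(prog.summary())
```

prints

```
Consensus subtype clustering (5-voter scoring network)
  samples: 120    k: 3
  mean silhouette of consensus: 0.1375
  mean voter agreement: 0.987
  ties broken by centroid: 0
  cluster sizes: 0:39, 1:37, 2:44
  k scan (mean silhouette): k=2:0.080, k=3:0.137, k=4:0.099

Prognostic risk model (Cox screen -> survival forest -> Cox refit)
  samples: 120    events: 93
  genes passing univariate screen (p < 0.05): 21
  survival forest: 200 trees, OOB error 0.214 (plateau: True)
  risk function genes (4): G0001, G0002, G0010, G0014
  coefficients: G0001=+1.184, G0002=-0.774, G0010=+0.312, G0014=+0.126
  concordance index: 0.843
  maxstat cutoff: 30.9 (|standardised log-rank| = 10.70)
  high/low split: 36/84, log-rank p = 1.04e-26 (post-selection)
```

The k scan correctly picks the three planted subtypes; the two genes driving
the simulated hazard (coefficients +0.8 / −0.8) head the fitted risk
function with the right signs; the high-risk group separates sharply (the
log-rank p is post-selection — the cutoff was chosen to maximise exactly this
separation, so read it descriptively).

The same flow is scriptable from the shell:

```bash
panfuse simulate --seed 5 --out cohort/
panfuse cluster  --expr cohort/expr.tsv --k 3 --seed 1 --out labels.tsv
panfuse train    --expr cohort/expr.tsv --labels labels.tsv --seed 2 --out model/
panfuse select   --expr cohort/expr.tsv --labels labels.tsv --out selection.tsv
panfuse prognosis --expr cohort/expr.tsv --surv cohort/surv.tsv --out prog/
panfuse run      --config run.toml --out results/   # all stages, one seed
```

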