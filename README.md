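# morbiclust

Which clustering algorithm should an epidemiologist trust to find
multimorbidity clusters — groups of patients who share combinations of
long-term health conditions — in a binary diagnosis matrix? In real
records the true clusters are unknown, so the question can only be
answered on simulated cohorts where they are known. `morbiclust` packages
that benchmark end to end:

* **a generative simulator** of correlated binary disease data with known
  patient clusters: patients are assigned to one of *K* disease clusters
  (exponential or uniform cluster weights), each cluster receives
  `max(Poisson(5), 2)` of the *D* = 26 diseases (with or without overlap),
  and each patient's binary disease vector arises from a multivariate
  probit model — a latent Gaussian vector with an equicorrelated block
  (correlation ρ) over the cluster's diseases, thresholded at
  Φ⁻¹(1 − p) so each in-cluster disease has prevalence *p* — plus
  independent background noise OR-ed into every cell at rate *q*;
* **four patient-clustering algorithms**, as scikit-learn-style
  estimators: `LatentClassAnalysis` (Bernoulli-mixture latent class model
  fitted by EM, with BIC / sample-size-adjusted BIC / entropy model
  selection), `BinaryKMeans` (Lloyd k-means on the raw 0/1 matrix),
  `MCAKMeans` (multiple correspondence analysis, then k-means on the row
  coordinates) and `KMeansHCA` (k-means with 50 pre-clusters, then Ward
  agglomeration of the centroids — the scalable stand-in for hierarchical
  clustering of every patient);
* **evaluation machinery**: the Hubert–Arabie adjusted Rand Index (aRI),
  within-cluster morbidity profiles, greedy one-to-one cluster matching by
  Pearson correlation (threshold 0.5), bootstrap stability over resampled
  cohorts, exclusivity and observed/expected prevalence ratios, and
  prevalence-difference cluster naming;
* **a scenario runner** sweeping ρ, noise, prevalence or the requested
  number of clusters over replicate simulations, summarised as median and
  quartile aRI against the known labels;
* **a synthetic EHR-like generator** (49 conditions, marginals matching a
  UK primary-care cohort of multimorbid men aged 65–84, Gaussian-copula
  planted correlation blocks) so the full real-data pipeline can be
  exercised without any data access.

## Worked example

```python
import numpy as np
from morbiclust import (SimConfig, generate, filter_multimorbid,
                        LatentClassAnalysis, adjusted_rand_index)

sim = filter_multimorbid(generate(SimConfig(
    n_patients=2000, n_clusters=3, rho=0.5,
    within_prevalence=0.15, noise_prob=0.005, seed=1)))
model = LatentClassAnalysis(n_classes=3, random_state=0).fit(sim.cohort)
print(sim.cohort.n_patients,
      round(adjusted_rand_index(model.labels_, sim.true_labels), 3))
```

prints

```
370 0.806
```

i.e. of 2,000 simulated patients, 370 have two or more conditions and
enter the analysis, and the latent class partition agrees with the planted
clusters at aRI 0.81 (1 = identical, 0 = chance). Sweeping a parameter
over replicates:

```python
from morbiclust import Scenario, run_scenario
result = run_scenario(Scenario(base=SimConfig(), sweep_parameter="rho",
                               sweep_values=[0.3, 0.9],
                               algorithms=("kmeans",), n_replicates=100,
                               seed=1))
print(result.table[["sweep_value", "median_ari"]].round(3).to_string(index=False))
```

```
 sweep_value  median_ari
         0.3       0.425
         0.9       0.633
```

— binary k-means recovers the planted clusters much better when
within-cluster correlation is high. The same commands are available from
the shell via the `morbiclust` entry point (`morbiclust simulate`,
`morbiclust cluster`, `morbiclust evaluate ari`, `morbiclust scenario`,
`morbiclust ehr-synth`, ...).

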