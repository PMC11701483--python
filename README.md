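# biotypegcn

Population-graph convolutional deep clustering for imaging-derived
disorder **biotypes** — data-driven subgroups of a clinical population
defined by functional network connectivity (FNC) rather than symptom
criteria — together with the validation toolbox such a claim needs:
internal cluster indices, baseline comparators, fold stability,
cross-cohort template projection, discriminative-connectivity analysis,
and longitudinal treatment-response models.

The package is aimed at researchers in functional connectomics and
computational psychiatry who want to subtype a patient cohort from
resting-state FNC plus phenotypes, and at methodologists who want a
fully synthetic, seed-deterministic testbed for population-graph deep
clustering.

## The model

Each subject contributes an FNC vector: the upper triangle of the
Pearson correlation matrix between C = 53 independent-component time
courses, d = C(C−1)/2 = 1378 features, with components grouped into 7
functional networks (SC, AU, SM, VI, CC, DM, CB with 5, 2, 9, 9, 17, 7,
4 components).

Subjects are nodes of a **population graph**: node features X are the
FNC vectors; the edge weight between subjects u, v is

    A_uv = ( 1[gender_u = gender_v] + 1[|age_u − age_v| ≤ w] ) · κ(f_u, f_v)

with an optional Gaussian kernel κ on the correlation distance between
FNC vectors and top-k sparsification. A graph-convolutional autoencoder
(layers H′ = ReLU(Â H W), Â = D^(−1/2)(A+I)D^(−1/2)) maps X to embeddings
Z and back, and is trained by jointly minimizing

    L = γ₁·L_rec + γ₂·L_CE + γ₃·L_cluster ,   γ = (0.01, 0.01, 0.1)

where L_rec is the feature reconstruction error, L_CE a patient-vs-control
binary cross-entropy on a one-logit head, and L_cluster a deep K-means
loss on the patient embeddings — a soft-min over squared centroid
distances annealed toward the hard K-means objective. K is chosen by the
elbow of the cluster-sum-of-squares (CSS) curve; patients are assigned to
the nearest centroid, and per-biotype mean FNC vectors serve as
**templates** that project new cohorts onto the same biotypes by Euclidean
distance. Downstream statistics (covariate-adjusted two-sample t-tests,
Cohen's d, Benjamini–Hochberg FDR, top-100 discriminative edges grouped
into networks, linear mixed-effects treatment models) characterize and
validate the biotypes.

Real cohorts of this kind are access-restricted, so the package ships a
first-class synthetic-cohort generator (`biotypegcn.synthetic`) that
plants subtype structure as network-block FNC shifts, covariate effects,
and biotype×medication recovery profiles. See `docs/methods.md` for the
generative model, parameter defaults, and design decisions.

## Worked example

```python
import numpy as np
from biotypegcn import (CohortSpec, TrainingConfig, build_graph,
                        generate_cohort, train)
from biotypegcn.evaluation import select_k
from sklearn.metrics import adjusted_rand_score

spec = CohortSpec(seed=1)            # 200 HC + 400 patients, 2 subtypes, C=53
subjects, fnc = generate_cohort(spec)
graph = build_graph(subjects, fnc)   # age/gender edges, FNC kernel, top-10

config = TrainingConfig(K=2, seed=1)
k, curve = select_k(graph, config, range(1, 9))
model = train(graph, config)

truth = np.array([s.true_subtype for s in subjects if s.diagnosis == "patient"])
print("selected K:", k)
print("biotype sizes:", np.bincount(model.assignments)[1:])
print("ARI vs planted subtypes:", round(adjusted_rand_score(truth, model.assignments), 3))
```

Output:

```
selected K: 2
biotype sizes: [200 200]
ARI vs planted subtypes: 1.0
```

The elbow of the CSS curve picks K = 2 (the planted number of subtypes),
the two biotypes have the planted 200/200 sizes, and the adjusted Rand
index of 1.0 means the assignment reproduces the hidden subtype labels
exactly at this effect size.

There is also a CLI covering the whole pipeline
(`biotypegcn simulate|features|graph|fit|evaluate|project|discriminate|treat|pipeline`);
each stage writes delimited-text outputs with checksum sidecars and a
provenance record.

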