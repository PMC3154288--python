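# thermoprofile

Composition-based analysis of protein thermostability. The package asks a
classic protein-engineering question: which primary-structure attributes
separate **mesostable** enzymes (optimum temperature below 70 °C, class `T`)
from **thermostable** ones (above 70 °C, class `F`) — and can unsupervised
methods recover that separation without ever seeing the labels? It is
written for computational biologists who want a tested, end-to-end,
library-first implementation of the attribute-weighting + clustering
methodology, exercised on synthetic cohorts with planted compositional
effects so every stage is verifiable without any external dataset.

## What it computes

**Featurization.** Each sequence becomes ~888 numeric attributes: amino-acid
counts, full-length frequencies and standard-residue percentages; 400
overlapping dipeptide counts and frequencies; C/H/N/O/S atom counts of the
molecular formula; counts/frequencies of positively charged {R,K,H},
negatively charged {D,E}, and Kyte–Doolittle hydrophilic/hydrophobic
residues; and ProtParam-style descriptors — length, average molecular
weight, isoelectric point (bisection root of the Henderson–Hasselbalch net
charge), Ikai's aliphatic index
`AI = X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu))`, and the 280 nm molar
extinction coefficient `ε = 1490·n_Tyr + 5500·n_Trp + 125·⌊n_Cys/2⌋`
(non-reduced) with its mass-normalised absorbance.

**Cleaning.** Duplicate records, attributes with sample SD ≤ 0.1, and the
later member of any attribute pair with |Pearson r| > 0.9 are removed, in
that order; survivors are min–max normalized to [0, 1].

**Attribute weighting.** Eleven algorithms score each attribute against the
class: information gain `H(Y) − H(Y|A)`, gain ratio, χ², Gini gain,
symmetric uncertainty `2·I(A;Y)/(H(A)+H(Y))`, deterministic Relief
(nearest hit/miss), leave-one-feature-out OneR error, deviation (scaled
SD), linear-SVM |w|, first-PCA loadings, and point-biserial correlation.
Weights are normalized to [0, 1]; attributes with weight > 0.5 form one
reduced dataset per method, and a vote tally counts how many methods
selected each attribute.

**Clustering.** k-means, k-medoids (PAM), support vector clustering
(minimal enclosing sphere in Gaussian-kernel space with segment-sampling
adjacency) and a diagonal-covariance EM Gaussian mixture, each with k = 2,
run on the full cleaned table and on every reduced dataset; clusters are
mapped to T/F by the accuracy-maximizing permutation.

**Trees and networks.** Greedy decision-tree induction under gain-ratio /
info-gain / Gini / accuracy criteria, decision stumps, seeded random
forests, four published threshold-rule models as executable classifiers,
feed-forward and Elman back-propagation networks under 10-fold
cross-validation, and a stepwise screen labelling attributes by
importance = 1 − p from a one-way ANOVA F test.

## Worked example

`examples/` holds one short script per capability. The central phenomenon —
the choice of weighting algorithm flips EM clustering between chance and
near-perfect — from `python examples/04_clustering_grid.py`:

```
mapped accuracy (true class sizes: 300 T / 100 F):

dataset    FCdb  uncertainty  correlation  deviation    pca
kmeans    0.562        0.988        0.962      0.725  0.555
kmedoids  0.520        0.988        0.970      0.718  0.528
svc       0.740        0.750        0.750      0.750  0.748
em        0.512        0.982        0.962      0.725  0.525

EM row, mapped class counts per dataset:
  FCdb         T=259  F=141  acc=0.512
  uncertainty  T=293  F=107  acc=0.983
  correlation  T=291  F=109  acc=0.963
  deviation    T=390  F=10   acc=0.725
  pca          T=252  F=148  acc=0.525
```

Rows are clusterers, columns the attribute-selection used to build each
dataset (`FCdb` = full cleaned table). EM on the uncertainty- and
correlation-selected tables recovers the planted T/F structure almost
exactly (~0.98 mapped accuracy; predicted class counts close to the true
300/100), while the same algorithm on the deviation- or PCA-selected
tables sits at or below the 0.75 majority baseline. The vote tally from
`examples/03_attribute_weighting.py` shows why:

```
pct_Q       9
count_Q     8
pct_E       8
pct_N       8
pct_K       7
```

nine of the eleven weighting methods flag the glutamine percentage — the
strongest planted effect — as important; uncertainty and correlation select
compact sets of exactly such attributes, whereas deviation rewards rare
high-variance dipeptides that carry no class signal.

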