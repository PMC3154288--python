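# Methods

This note records the models implemented in `thermoprofile`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make every run reproducible.

## Problem setting

Two classes of proteins are compared: mesostable (`T`, optimum temperature
below 70 °C) and thermostable (`F`, above 70 °C). The boundary value 70 °C
is deliberately unlabelable: a record tagged `temp=70` is kept but reported
as labelless rather than forced into a class. All downstream stages consume
a records × attributes table of numeric composition features; the single
categorical attribute (the N-terminal residue) is carried through I/O but
excluded from every numeric computation.

## Featurization conventions

* **Alphabet.** The standard 20 residues plus the ambiguity/rare codes
  B, Z, X, U, O, J. Nonstandard residues count only toward
  `count_other`/`freq_other`; they are excluded from molecular weight, the
  molecular formula, pI, residue classes, and dipeptides (a window touching
  a nonstandard residue contributes to no pair). Rationale: the
  other-residue frequency is itself a useful attribute, and charging or
  weighing an unknown residue would inject arbitrary constants.
* **Two denominators.** `freq_*` divides by the full length L; `pct_*`
  divides by the number of standard residues and scales by 100. The two
  families are deliberately not exact rescalings of one another — otherwise
  the |r| > 0.9 correlation filter would delete one family wholesale.
* **Mass, formula, pKa tables.** Average (not monoisotopic) residue masses
  and residue atom counts ship as versioned JSON under
  `src/thermoprofile/data/`; peptide values are residue sums plus one
  water. The pI uses the EMBOSS pKa set (N-terminus 8.6, C-terminus 3.6;
  side chains K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) with
  bisection to 1e-4 pH on [0, 14]; the net charge is strictly decreasing in
  pH, so the root is unique. Any published pKa set would do — what matters
  is that it is pinned and versioned.
* **Extinction at 280 nm.** ε = 1490·nTyr + 5500·nTrp, plus 125 per
  complete cystine pair (⌊nCys/2⌋ — all possible pairs) in the non-reduced
  state. Absorbance = ε / MW.
* **Hydrophilic/hydrophobic.** Pinned to the sign of the Kyte–Doolittle
  index: {R,K,N,D,Q,E,H,P,Y,W,S,T,G} vs {A,C,F,I,L,M,V}; the two sets
  partition the standard 20, so their frequencies sum to 1 over standard
  residues.

## Cleaning

Order: duplicate records (first kept) → attributes with sample SD ≤ 0.1 →
correlated attributes. The SD filter operates on raw, pre-normalization
values; on composition data this removes most `freq_*` attributes (their
raw spread is far below 0.1) while counts and percentages survive — a
direct consequence of applying an absolute SD threshold across families
with different scales, and worth knowing when interpreting which attributes
reach the later stages. The correlation filter scans pairs in schema order
and drops the later member of any pair with |r| > 0.9; a dropped attribute
is never used to drop others. Keep-earlier is a determinism choice; using
|r| treats anticorrelated duplicates as equally redundant. Min–max
normalization is fitted once on the training table; re-applied values clip
into [0, 1] so fixed decision thresholds stay meaningful for new sequences.

## Attribute weighting

Numeric attributes are discretized by equal-frequency cutting into k = 10
bins for the entropy/χ²/Gini/uncertainty measures and for OneR. An
attribute with ≤ k distinct values passes through with one bin per value:
quantile cutting would otherwise merge the sparse levels of a skewed
binary attribute into a single bin and zero out its association with the
class. Entropies are in bits.

* **Relief** is the deterministic full-pass variant: every example in turn,
  k = 1 nearest hit and miss under Manhattan distance on range-normalized
  attributes, per-attribute diff |x − x′|/range, w = mean(diff_miss −
  diff_hit). Determinism was chosen over sampling for testability; ties
  break toward the lowest record index.
* **OneR weighting** follows the literal definition: the weight of A is the
  training error of a OneR model built on the table *without* A, so an
  attribute is important when its removal forces a worse one-rule
  classifier. Because that error equals the minimum error over the
  remaining attributes, the weights are near-constant except at the single
  best attribute — after max-normalization nearly everything clears a 0.5
  threshold, which is why the OneR-selected dataset is almost the full
  table. A `single_feature` mode (1 − error of OneR on A alone) is provided
  for users who want a discriminative variant.
* **SVM** weights are |w| of a soft-margin linear SVM (hinge loss, C = 1,
  inputs already min–max normalized). The dual is solved as a
  box-constrained QP by L-BFGS-B with the bias absorbed into an augmented
  constant feature (avoiding the equality constraint); solver tolerance
  1e-4.
* **PCA** weights are the absolute loadings of the first principal
  component of the z-standardized table (population SD; zero-variance
  columns get weight 0).
* **Deviation** is SD/mean by default (minimum/maximum scalings
  selectable).
* Weights are normalized by the maximum absolute raw weight; an all-zero
  vector passes through. Selection keeps attributes with normalized weight
  strictly above 0.5; a weight exactly at the threshold is flagged in the
  selection result rather than selected.

## Clustering

All algorithms run on the min–max normalized matrix with k = 2.

* **k-means**: k-means++ seeding, Lloyd iterations, Euclidean distance;
  stops when the centroid shift falls below 1e-6 or after 300 iterations.
  The within-cluster sum of squares is recorded per iteration and is
  non-increasing.
* **k-medoids**: PAM — greedy BUILD from the most central point, then
  best-improvement SWAP until no swap lowers the summed distance. Medoids
  are always data rows.
* **SVC**: minimal enclosing sphere of the Gaussian-kernel image (width q,
  default 1.0; soft-margin cap C, default 1.0 = hard sphere), solved by
  projected gradient onto the capped simplex with a step from the largest
  kernel eigenvalue. Two points are adjacent when all 10 sampled points on
  their connecting segment lie inside the sphere — evaluated entirely from
  the linear Gram matrix, so the cost does not grow with dimensionality.
  Clusters are the connected components; bounded support vectors and
  components beyond the k largest are assigned to the nearest retained
  cluster and flagged in the summary. The problem size is capped (default
  2000 records) by the quadratic solver.
* **EM**: diagonal-covariance Gaussian mixture, k-means initialization from
  the same seed, variances floored at 1e-6, stopping when the
  log-likelihood gain drops below 1e-6. The log-likelihood history is
  recorded and is monotone; an empty component triggers exactly one
  re-seeded restart before erroring. Diagonal covariance was chosen because
  the selected-attribute tables are low-dimensional but nearly collinear,
  where full covariances go singular.
* **Evaluation** maps the two clusters onto T/F by the better of the two
  permutations and reports mapped class counts and accuracy; with binary
  labels this accuracy is ≥ 0.5 by construction, and a single-cluster
  solution scores the majority fraction (0.75 at the default 75:25 class
  ratio).

## Trees

Greedy top-down induction; candidate thresholds are midpoints between
consecutive distinct sorted values; `x ≤ threshold` goes left; ties between
splits break by schema order, then lower threshold. Criteria: information
gain, gain ratio (gain / split-information), Gini gain, and accuracy
(training-accuracy gain of the split — the plainest reading of an
"accuracy" criterion). Leaves take the majority class with ties going to T,
the majority class of the study system. Pre-pruning only: max depth, min
leaf size, minimum gain 1e-3; no post-pruning method is pinned. Random
forests use seeded bootstrap resampling and ⌈√p⌉ attributes per split;
with one tree, no bootstrap and full mtry they reduce exactly to plain
induction.

The four published rule models (`stump_gainratio`, `parallel_2level`,
`forest_gini_fig1`, `tree_gainratio_fig2`) encode printed threshold rules
for this problem as executable classifiers over normalized feature vectors
(thresholds 0.500 on the Gln–Asn dipeptide frequency; 0.322 on Glu
percentage with 0.550 on hydrophilic frequency; 0.050 on Asn–Gln with
0.029 on Asn–Thr; 0.596 on hydrophilic frequency with 0.217 on Gln
content). The thresholds are treated as living on the min–max normalized
[0, 1] scale, consistent with models fitted to normalized data. Branches
the source never spelled out return `undetermined` — the models never
guess, and the boundary cases follow the printed inequalities exactly
(e.g. a Gln–Asn frequency of exactly 0.500 is not "greater than" and falls
to T).

## Networks

Both network types use logistic-sigmoid hidden layers, a 2-unit softmax
output, cross-entropy loss and seeded mini-batch back-propagation
(defaults: learning rate 0.01, 500 epochs, batch 32, validation fraction
0.1 with patience 50 and best-weights restore). These specifics are pinned
defaults, not claims about any reference system — only "back-propagation
with early stopping" is inherited from the methodology being implemented.

An Elman network over static feature vectors is ill-defined, so the
recurrence is realised by repeated presentation: the first hidden layer
receives context units holding its previous activation, the context is
zeroed per example, and the input is presented `elman_context_steps` times
(default 2) with gradients back-propagated through the unrolled
presentations. The main weight stream is drawn identically to the MLP's
(context weights come from a separate seeded stream), so one presentation
with zero context weights reproduces the MLP bit-for-bit — a property the
tests assert exactly.

Cross-validation uses a fixed fold-size rule: with n records and k folds,
the first k−1 folds take ⌈n/k⌉ records when (k−1)·⌈n/k⌉ < n (else ⌊n/k⌋)
and the last fold takes the remainder — 2057 records in 10 folds give nine
folds of 206 and one of 203. Per-fold reports carry the thermostable-class
accuracy (`accuracy_F`), mesostable-class accuracy (`accuracy_T`) and
overall accuracy, with an average row; a fold holding a single class
reports the undefined per-class accuracy as missing and it is excluded
from the average. The stepwise screen computes a one-way ANOVA F-test
p-value per attribute and labels importance = 1 − p as important (> 0.95),
marginal (0.90–0.95) or unimportant (< 0.90); a constant, class-identical
attribute gets p = 1.

## Synthetic data: what it emulates and what it does not

The generator draws i.i.d. residues from a class-specific composition:
class T uses a background distribution (Swiss-Prot release-average
frequencies, shipped as data); class F multiplies selected residue
probabilities and renormalises — defaults: Gln ×0.25, Asn ×2.0, Glu ×1.7,
Lys ×1.6, Arg ×1.6 — and adds a first-order Asn→Gln coupling (excess
probability 0.1) that plants an Asn–Gln dipeptide signal beyond
composition. Cohort defaults: 300 T / 100 F (the 75:25 imbalance typical
of curated thermostability sets), log-normal lengths (μ = 5.5, σ = 0.4 on
the log scale, truncated to [50, 2000]), fully seeded.

The effect *directions* follow the thermophile literature (glutamine
depletion, polar/charged enrichment); the *magnitudes* are deliberately
larger than real proteome differences. At 400 sequences of typical length,
per-sequence binomial sampling noise is the dominant variance, and the
weaker effects one might quote from comparative studies leave even a
supervised classifier below ~0.87 training accuracy — no unsupervised
method could then separate the classes at all. The shipped magnitudes give
the two class-conditional distributions roughly the separation that a
cohort of thousands of real sequences exhibits, which is what makes the
package's central phenomenon reproducible at desk scale: EM clustering
near-perfect on uncertainty/correlation-selected attributes, at or below
the majority baseline on deviation/PCA-selected ones.

What the generator does **not** emulate: phylogenetic correlation between
sequences, positional/secondary-structure signal, realistic domain
architecture, or any length–class dependence. Passing tests therefore
demonstrate that the pipeline recovers planted compositional structure —
not that real thermophile proteomes are this separable, nor that these
attribute weights transfer to real data.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at the shipped
default cohort (400 sequences, ~888 raw attributes, cleaned to ~440), with
smaller cohorts for unit-level checks; these sizes were chosen so a
complete run takes seconds on one CPU while keeping all planted-signal
statistics comfortably outside Monte-Carlo noise. Every stochastic
component (generation, k-means++/EM seeding, bootstrap, network
initialisation and batching, fold shuffling) consumes an explicit seed;
identical configuration and seed reproduce byte-identical artifacts, which
the pipeline asserts by hashing its outputs into the run manifest.

## Known limitations

* The SD ≤ 0.1 cleaning threshold is scale-dependent by design; users
  whose attributes live on other scales should adjust it.
* SVC with the default q = 1 on high-dimensional normalized data almost
  always yields a single component (everything inside one sphere); sweeping
  q upward is required for structure, and the component count is only
  empirically (not provably) monotone in q.
* The leave-one-feature-out OneR weighting is nearly non-discriminative by
  construction (see above); it is implemented faithfully rather than
  usefully.
* Elman context handling is one documented construction among several
  plausible ones for static inputs.
* `stepwise_select` reports raw per-attribute p-values; no multiplicity
  correction is applied, matching the screening (not inference) role of
  the 1 − p importance score.
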