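# Methods

This note records the model, the numerical conventions, the synthetic-data
design and the open choices made in `abclass`, in the order a reader would
meet them in the pipeline.

## Problem and data model

Each record is a linear B-cell epitope: a peptide of 5–50 residues over
the 20-letter standard amino-acid alphabet, annotated with a 4-bit label
vector in the fixed order (IgG, IgE, IgA, IgM).  The label order is
canonical across the whole package — readers, models, metrics and writers
— because silent label permutation is the classic failure mode of
multi-label pipelines.  Records containing non-standard residues
(B, J, O, U, X, Z) or lengths outside 5–50 are dropped with a logged
warning rather than imputed: the encoders are defined only over the
20-letter alphabet, and imputation would manufacture composition signal.
Lowercase input is uppercased (case carries no meaning here).  Duplicate
sequences with different labels are kept and reported; deciding a merge
policy would require assay-level information the record does not carry.

## Encoders

*Amino-acid composition* (AAC): `F(i) = N_i / N`, 20 columns.
*Dipeptide composition* (DC): `F(i,j) = N_ij / (N−1)` over ordered
adjacent pairs, 400 columns in row-major alphabet order (AA, AC, …, YY) so
column identity is stable for ranking.  Both are frequency distributions
and sum to 1 exactly.

*Pseudo amino acid composition.*  Three per-residue property scales are
used: hydrophobicity, hydrophilicity (Hopp–Woods) and side-chain mass,
each standardized to zero mean and unit variance over the 20 residues
(population SD).  Type 1 (parallel-correlation) appends λ factors

    θ_k = mean_t Θ(R_t, R_{t+k}),   Θ(a, b) = mean_p (H_p(b) − H_p(a))²

over the three scales; type 2 (amphiphilic, series-correlation) appends
2λ factors τ, the per-property means of products H_p(R_t)·H_p(R_{t+k})
for the hydrophobicity/hydrophilicity pair (so i = 2 and the vector has
20 + 2λ entries, interleaved hydrophobicity-then-hydrophilicity per tier).
Both types normalize by `Σf + w·Σ(order terms)`, making all components a
partition of unity; at w = 0, λ = 0, or (type 1) on a homopolymer they
reduce exactly to AAC.  Defaults λ = 4 (the maximum legal under the
5-residue minimum) and w = 0.05 (the customary weight); both configurable,
and logged because published uses of these encoders frequently omit them.

One asymmetry is worth stating: θ factors are sums of squares and hence
non-negative, but τ factors are products of standardized values and can be
negative, so type-2 components are not guaranteed non-negative (the
partition-of-unity property still holds).  The normalizer is guarded
against the (practically unreachable) non-positive case.

## Information-gain ranking

Features are scored as `IG = H(class) − H(class | feature)` in bits after
Fayyad–Irani MDL-stopped recursive binary discretization: candidate cuts
at value-change boundaries, entropy-minimizing cut accepted only if its
gain clears the MDL threshold `(log2(N−1) + log2(3^k − 2) − [k·H(S) −
k₁·H(S₁) − k₂·H(S₂)]) / N`.  A feature with no accepted cut scores exactly
0 — on small noisy samples this is the correct behaviour, not a bug, and
it materially changes rankings relative to naive equal-width binning.
Because cuts sit at rank boundaries, IG is invariant to strictly monotone
transformations of a feature.  The class variable defaults to the
label-powerset class (one multinomial category per observed combination);
a per-label mode averages the four binary-label gains.  Ranking is
diagnostic: models train on full feature sets by default, and `top_k`
selection is available but off.

## Models

*Binary Relevance* fits four independent one-vs-rest learners; a test
example's bit j is set when member j's positive-class probability reaches
0.5 (no threshold is canonical here; 0.5 is the neutral choice).  The
all-zero prediction is allowed and reported — coercing it to an argmax
label would be an uncited heuristic, and Hamming Loss is well defined
either way.  A label with no positive (or no negative) training examples
yields a constant member, with a warning.

*Label Powerset* maps every label combination observed in training to one
multiclass category, fits a single learner, and decodes predictions
through the codebook; it can never emit an unseen combination.  The
codebook covers observed combinations only (11 on study-shaped data, not
all 15 possible) — combinations without data cannot be learned, and
singleton classes are trained as-is with a warning.  Per-class scores are
the summed probabilities of the combinations containing that class.

*Base learners.*  Random Forest, or AdaBoost over Random Forest
(scikit-learn; SAMME, which for two classes is the textbook binary
update).  Boosting a forest is deliberate but has a known degenerate
regime: a forest large enough to drive its weighted training error to
zero stops boosting after one round, leaving a single member.  On the
synthetic data here this happens routinely, so boosted and unboosted
variants score nearly identically; the evaluation suite therefore checks
non-degradation (boosted averaged HL ≤ unboosted + 0.01) rather than
strict improvement, and any observed gain on real data is outside what
the simulation can certify.  Defaults n_trees = 100 and T = 50 rounds;
the test suite and acceptance script use 40 trees and 4 rounds to keep
simulation runtimes in seconds — a problem-size choice, not a modelling
one.  Models serialize with joblib under a format-version tag; loading
re-encodes raw sequences through the recorded encoder spec, and `fit`
refuses a feature matrix whose columns do not match the declared encoder.

## Metrics

Hamming Loss is the mean fraction of wrong bits per example (XOR
popcount / Q, averaged).  Precision, recall and F1 come from per-label
binary confusion counts, macro (mean of per-label values) and micro
(pooled counts).  A per-label precision or recall with zero denominator
contributes 0 to its macro mean, and per-label F1 with P = R = 0 is 0 —
the conservative convention shared by common multi-label tooling.  Micro
F1 is internally cross-checked as the harmonic mean of micro P and R.

## Evaluation protocol

Five seeded 80:20 splits (default seeds 0–4; the train size is
round-half-even of 0.8·N, so 10,744 records split 8,595/2,149); 5-fold CV
inside each training split (fold assignment seeded from the split seed);
a refit on the full 80% scored on the 20%; arithmetic means over the five
CV and five test reports.  Splits are plain random, matching the protocol
being reproduced; a label-stratified option exists but is off by default.
The label-marginal baseline (each label's training majority bit) is the
floor any model must beat.  The PCA projection fits the top-2 axes on the
training split and applies them to both sides; coordinates are written
for external plotting.

## Synthetic data

The generator's defaults define the study conditions: 11 label
combinations with counts proportional to (6027, 1512, 412, 999, 748, 701,
242, 10, 62, 20, 11) — 10,744 records at scale 1, minimum 2 per
combination after scaling so powerset classes are never empty in smoke
tests — lengths uniform on 5–50, residues i.i.d. from per-combination
profiles.  Profiles are exponential tilts of the uniform background,
`p ∝ exp(s·d)`, where each label contributes a fixed direction (IgG:
+A,+L,+S,−W,−Y; IgE: +E,+F,−Q; IgA: +Q,+T,−E; IgM: +K,+R,−D) and
multi-class combinations add +Q,+P,+V,−H,−C, echoing the compositional
trends reported for curated epitope collections (IgE- and IgA-only
classes differing most in E and Q; multi-class epitopes enriched in Q, P,
V and depleted in H, C).  The default signal strength is 1.0; the
learnability checks use 1.5 ("high" signal), at which a BR forest reaches
held-out Hamming Loss ≈ 0.05 at scale 0.05.  At signal 0 all profiles are
uniform and nothing is learnable (the negative control).

The Markov mode exists to make the dipeptide encoder's advantage
demonstrable rather than assumed: compositional profiles are held uniform
and each label instead boosts the transitions i → i+k (mod 20) for a
label-specific shift k, with multi-class combinations additionally
boosting Q-Q and P-Q.  Because each label's boost pattern is a
permutation, the tilted chain is doubly stochastic and its stationary
composition is exactly uniform — AAC provably carries no class signal,
while DC does.  An earlier design with one signature pair per label was
discarded during construction: single pairs occur too rarely in 5–50-mers
to be learnable and leak into composition.

What passing tests on this generator do **not** show: performance on real
epitope data.  The simulation has no assay noise, no host or pathogen
structure, no motifs beyond first-order transitions, and no label noise;
published benchmark numbers for this task are reproducible only with the
corresponding curated dataset, which users can supply to `abclass
evaluate` (any labelled FASTA/TSV) to obtain the same report layout for
manual comparison.

## Numerical conventions and degenerate inputs

Encoder rows sum to 1 within 1e−9 and match independent brute-force
recomputation to 1e−10; metric values match per-definition recomputation
to 1e−10.  Ranking ties break lexicographically by feature name so
rankings are total orders.  Empty sequences, lam ≥ length, shape
mismatches, unreadable files, malformed labels in training mode, unknown
encoder/strategy names and corrupted or version-mismatched model files
all raise immediately with messages; malformed labels in prediction mode
degrade to unlabelled records with a warning.  All randomness flows from
explicit integer seeds (splits, folds, forests, boosting, generation);
two runs with the same configuration are bit-identical.
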