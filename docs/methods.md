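# Methods

## Model

Drug repositioning is cast as multi-label classification: samples are
drug-perturbation trials (rows of landmark-gene Z-scores), labels are the
14 first-level ATC therapeutic classes, and the classifier is softmax
regression,

    p(y = j | x) = exp(θⱼᵀ x̃) / Σₗ exp(θₗᵀ x̃),

with x̃ the gene vector augmented by a bias input 1 and θ a q × (n+1)
parameter matrix. Because a drug may carry several labels while the softmax
output is a single distribution, the training target for a sample is its
binary label row normalised to sum to 1 (a two-label drug targets 0.5 on
each). The objective is the mean cross-entropy over samples plus a
structural-risk term λ‖W‖²_F over the non-bias weights. θ starts at zero:
the objective is convex, so initialisation affects only the trajectory, and
a zero start makes runs reproducible without a seed entering θ₀.

Optimisation is mini-batch gradient descent; one *iteration* is defined as
one full epoch of seeded, shuffled mini-batches (batch size 32 by default),
which makes "train for 200 iterations, average the last 100" well defined.
Divergence (non-finite loss) aborts with diagnostics. Probabilities are
clamped at 1e-300 inside logarithms only, which cannot alter any finite
result.

### Thresholded classification and accuracy

Predictions are thresholded, not argmaxed: CF_ij = 1 iff p_ij ≥ t. A
sample is counted correct if at least one of its true labels is called
positive; training accuracy uses t = 0.30 on the training fold and
validation accuracy uses t = 0.06 on the validation fold. Per-label
TP/TN/FP/FN counts and a q × q actual-by-predicted confusion matrix (one
row entry per actual label of a sample) are also produced.

Note a structural property of the 0.06 validation threshold with q = 14:
the uniform probability 1/14 ≈ 0.071 already exceeds it, so a weakly
confident model calls many classes positive and validation accuracy
saturates near 1. This is a property of the threshold definition itself,
visible in the cross-validation curves the run log records.

### Hyper-parameter defaults

| parameter | default | meaning |
|---|---|---|
| learning_rate | 0.06 | gradient-descent step size |
| lam (λ) | 1.0 | weight of the L2 structural-risk term |
| batch_size | 32 | mini-batch size (one epoch = one iteration) |
| iterations | 200 | training epochs |
| averaging_window | 100 | final epochs averaged into the probability matrix |
| training_threshold | 0.30 | probability cut for training accuracy |
| validation_threshold | 0.06 | probability cut for validation accuracy |
| k_folds | 5 | drug-level cross-validation folds |
| kmeans_k | 2 | trial-clustering k in preprocessing |
| star_threshold | 0.9 | strict lower bound for star calls |
| rho_threshold | 0.4 | strict lower bound for SD2/SD3 membership |

The learning rate, thresholds and λ are the cross-validated selections the
model is specified with. λ = 1 with an unnormalised Frobenius penalty is
strong regularization: it keeps the weights at the scale where the data
gradient and 2λθ balance, which compresses probabilities toward uniform.
On real-scale data with thousands of samples the averaged probabilities
still span [0, 1]; on the 200-drug synthetic cohorts they top out around
0.2, so downstream network thresholds (star threshold, ER pruning grid)
must be tuned to the cohort's probability scale — the recovery benchmark
does this on a held-out cohort and then freezes the threshold. This is a
scale calibration, not a redefinition: the strict-">" call semantics and
all set definitions are unchanged.

## Preprocessing: credible sets

Replicate trials of one drug are noisy and occasionally discordant. For
each drug the trials are k-means clustered (k = min(2, t) by default —
the smallest split that can reject outlier trials; Euclidean distance on
the raw Z-score vectors, 10 restarts, seeded). Each cluster is scored by
its mean pairwise Pearson correlation; the winner is the representative
group S1. Singleton clusters cannot be scored (intra-class correlation
needs ≥ 2 members) and are treated as worst; if every cluster is a
singleton the group holding trial 0 is taken, a deterministic fallback for
the t = 2 edge case. The mean over *all* trials — not only S1's — is
appended as one extra sample S2, and S = S1 ∪ {S2} is the drug's training
block. Zero-variance trials get correlation 0 with every other trial
rather than being dropped, keeping trial indices stable.

## DTN-T and the Enrichment Ratio

The full-data probability matrix of each of the last `averaging_window`
epochs is recorded; their elementwise mean is averaged per drug over the
drug's credible-set samples (rows stay stochastic), and each drug's known
labels are zeroed, giving the drugs × 14 DTN-T. Cells are probabilities
*pre*-thresholding — the matrix holds continuous values.

Pruning uses the closed rule (edge iff P ≥ threshold), so threshold 1.0
keeps exactly the probability-1 cells. For each ordered property pair,
ER_{X,Y} = (a/b)/(c/d) with a = X-labelled drugs with an edge to Y,
b = all drugs with an edge to Y, c = X-labelled drugs with any edge,
d = all drugs with any edge; the counts always satisfy a ≤ b ≤ d and
a ≤ c ≤ d. The diagonal has no support (known labels are zeroed) and is
stored missing. A zero denominator yields ER = 0 with an audit flag — this
keeps the matrices finite for the stability analysis while preserving the
distinction in the flags. The default pruning grid is 0.20–0.95 in steps
of 0.05 (16 values); the stability matrix is the pairwise Pearson
correlation over the off-diagonal cells finite in both matrices, and the
combined ER matrix is the cellwise mean over the six highest thresholds
(0.70–0.95). Top pairs are ranked descending with a deterministic
lexicographic tie-break.

## Similarity networks and projections

Side-effect similarity is the Jaccard coefficient over side-effect term
sets; structural similarity is the Tanimoto coefficient over fingerprint
bit sets (consumed as precomputed bit sets; descriptor generation from
structures is out of scope). On sets the two coincide — the test suite
uses that identity as a cross-check. Two empty sets score 1 by convention
(two drugs with no recorded side effects are indistinguishable, not
maximally different).

The node-to-community coefficient of drug d toward ATC community C is the
mean similarity of d to the members of C excluding d itself; a community
with no other members contributes 0. Communities overlap (a multi-label
drug belongs to each of its classes' communities). The resulting
drugs × 14 projections (DTN-SE, DTN-ST) are compared with DTN-T per drug
by Spearman correlation with average ranks; the correlation is computed
over all 14 components, including the drug's zeroed known labels (made
configurable by column selection upstream if an exclusion rule is
preferred). Zero-variance vectors leave the drug's ρ missing.

## Star drugs

A star call is a (drug, property) cell of DTN-T with probability strictly
above the star threshold (the wording "more than" fixes the strict
comparison); SD1 collects drugs with a probability-1 call, equality tested
within 1e-9 because the probabilities are iteration averages of floats.
SD2 and SD3 filter star drugs by ρ strictly above the rho threshold
against DTN-SE and DTN-ST respectively (computing ρ for all drugs and
filtering afterwards is equivalent to restricting to star drugs first).
The credible set is SD1 ∪ SD2 ∪ SD3 with per-drug support annotation.

## Synthetic cohorts

The generator emulates the real cohort's geometry: 200 drugs (978 genes,
14 classes, 5–15 trials per drug — about ten on average, matching the
ratio of trials to drugs in the real data) with 25% of drugs carrying two
labels. Each class owns a mean-shift expression pattern of magnitude 1 Z
(random sign) on a random 10% of genes — a pathway-restricted response —
and a drug's trials are the sum of its labels' patterns plus N(0, 1)
noise. Twenty percent of drugs are *planted*: a latent class's expression
pattern is added but the label is withheld, creating exactly the signal a
repositioning pipeline should find. Side-effect and fingerprint sets give
each class a characteristic item block (20 items); a drug includes each
item of its classes' blocks — and of its planted class's block — with
probability 0.7, plus background items (pool 100, rate 0.05). All
randomness derives from one seed via per-sub-generator counter-based
streams, so every stage is independently reproducible.

What the generator does **not** emulate: gene–gene correlation structure,
dose/time covariates (collapsed, as in the source data), class imbalance
beyond the uniform label draw, and the heavy-tailed trial-count
distribution of real screens. Passing recovery tests therefore shows the
pipeline's statistics behave as designed under clean planted signal; they
do not certify performance on real L1000 cohorts.

## Problem sizes and numerical choices

The recovery benchmark and the acceptance script use 200-drug cohorts,
three evaluation seeds plus one held-out tuning seed, chosen as the
smallest scale at which per-class drug counts (~14 per class) make the
enrichment and correlation statistics stable. Tolerances: gradient checks
at 1e-6 relative against central differences; Pearson/ER oracle agreement
at 1e-12; probability-1 equality at 1e-9. Ties in top-pair ranking break
lexicographically; k-fold assignment shuffles drugs with a seeded
generator and splits as evenly as possible.

## Known limitations

* The headline accuracies of full-scale cohorts are not reproduced by the
  synthetic benchmark; the synthetic cohorts are smaller and cleaner, and
  the validation threshold saturates (see above).
* ER values at high pruning thresholds rest on few drugs and are noisy;
  the stability analysis surfaces, but does not correct, this.
* The node-to-community coefficient is one reasonable projection choice
  (mean member similarity, self excluded); alternatives (max, median)
  would change SD2/SD3 composition.
* No significance testing is attached to ER values; ranks, not p-values,
  drive the candidate lists.
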