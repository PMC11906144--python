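# Methods

## The problem and the model

A molecule's odor is not a function of any single receptor: it emerges from
the combinatorial pattern of olfactory receptors (ORs) the molecule
activates, and molecules that differ minutely in structure — enantiomers
like d- and l-menthol — can smell different because they activate different
receptors. `odorcascade` therefore predicts odor in three biologically
ordered steps rather than directly from structure:

1. **Model 1 (binding).** A binary classifier over joint
   [molecule descriptor ‖ receptor descriptor] rows predicts whether a
   (molecule, receptor) pair binds. Binding data are encoded as
   log(EC50) ≥ 0 with 0 reserved for "no binding"; the binary label is
   *positive iff log(EC50) > 0* (strict inequality).
2. **Model 2 (strength).** A regressor over the same joint representation,
   trained on the binding pairs only, predicts log(EC50).
3. **Model 3 (odor).** One binary classifier per *odor community* reads the
   molecule's activation profile — its log(EC50) vector over the fixed
   receptor panel — and predicts whether the molecule evokes that
   community.

At prediction time the three models run as a cascade: Step 1 classifies all
|panel| pairs; Step 2 predicts log(EC50) for the predicted binders only,
with every other profile entry set to exactly 0; Step 3 reads the
assembled profile. Every profile entry is by construction either exactly 0
or a Model-2 output (floored at 0, because a negative prediction would
collide with the non-binding code).

## Odor communities

Free-text odor notes are noisy, redundant and subjective. Instead of
string-level synonym merging, notes are grouped structurally: a
co-annotation graph joins two notes whenever at least one molecule carries
both (edge weight = number of such molecules), and communities are
extracted by agglomerative greedy modularity maximization. Modularity of a
partition is

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(C_i, C_j)

with m the number of edges, A the 0/1 adjacency, k_i the degrees, and δ
the same-community indicator. The greedy algorithm starts from singleton
communities and repeatedly merges the pair with the largest modularity
gain ΔQ, stopping when no merge has ΔQ > 0; equal gains are broken by the
lexicographically smallest community-representative pair so results are
platform-independent. Community indices are renumbered 1..K by descending
size. The implementation maintains incremental between-community weights,
and its running Q is property-tested against from-scratch evaluation of
the double sum after every merge (±1e-9); on small graphs (≤ 6 nodes) the
greedy optimum is compared against exhaustive search over all set
partitions.

Q is computed on the unweighted graph by default — matching the 0/1
adjacency in the definition above — with a `weighted` flag for the
strength-weighted generalization. Isolated notes remain singleton
communities.

Molecules map to communities of their own labels by a majority rule: only
communities holding strictly more than 20% of a molecule's recognized
labels are kept, so a molecule with nine notes in one community and a
stray note elsewhere is treated as having one odor community. If no
community clears 20% (a degenerate many-way tie), the largest community is
kept, ties broken by the smallest index — this fallback prevents unlabeled
molecules while preserving the rule's intent.

## Descriptors

**Molecular** (from isomeric SMILES, via RDKit): the full physicochemical
descriptor list (~210 values; non-finite columns dropped with a warning),
Morgan circular fingerprints (2048 bits, radius 2), RDKit path
fingerprints, and the 166 MACCS substructure keys (the toolkit's dummy
bit 0 is dropped so exactly 166 named keys are exposed). Morgan hashing
includes chirality: with the default hashing, enantiomers receive
identical bit vectors and the cascade could never discriminate d- from
l-menthol, which is a capability the package is explicitly designed to
retain. Parsed molecules are cached by SMILES; featurization is
deterministic.

**Receptor**: overlapping k-mer amino-acid composition for k = 1, 2, 3
("1AAF"–"3AAF") over the full 20^k lexicographic vocabulary, either as raw
counts or as proportions normalized by the window count L − k + 1
("…perc" variants; window-count normalization makes rows sum to exactly 1,
so receptors of different lengths are comparable). The proportions are
emitted on the 0–1 scale. Non-canonical residues (X, B, Z…) are rejected
rather than remapped, since silent mapping would corrupt counts. The
seventh variant flattens a *pre-computed* multiple sequence alignment into
per-position 21-state one-hots (20 amino acids + the gap symbol as an
explicit state); computing the alignment itself is out of scope, the
package consumes an aligned FASTA.

## Class imbalance

Roughly 11 of 12 grid pairs are non-binders. The Model-1 (and Model-3)
datasets are rebalanced by clustering-based undersampling: the majority
class is standardized and clustered with k-means++ into as many clusters
as there are minority samples, and each cluster contributes the member
nearest its centroid (ties to the smallest original index). The result is
an exactly balanced dataset of original samples — no synthetic points.
Balancing is applied once, at dataset level, and the balanced set is what
the classifiers are trained and cross-validated on; this mirrors how such
screens assemble their modeling datasets, and the package's reported
classification metrics are therefore metrics on balanced data.
`nested_cv` also offers a per-training-fold `undersample` option for the
leakage-conservative variant, in which evaluation folds keep the native
imbalance.

Because Model 1 is trained at a 50% prior but deployed at the screen's
~8.7% base rate, its native decision boundary over-predicts binding about
threefold on new molecules, which corrupts Step-3 inputs. The cascade
therefore calibrates a Step-1 score cutoff by prevalence matching: the
chosen method is refit on molecule-grouped cross-validation folds, each
fold's pairs are scored by a model that never saw those molecules (scores
from the refit-on-everything model would be optimistic for its own
training pairs), and the cutoff is the quantile of these out-of-fold
scores at which the predicted positive rate equals the observed grid rate.
The cutoff is recorded in the trained model and applied wherever the
cascade makes binder calls; it can be disabled (`prior_correction=False`)
to recover the classifier's native rule.

## Method panels and validation

The candidate classifiers are logistic regression, linear discriminant
analysis, Gaussian naive Bayes, k-nearest neighbours, linear-kernel and
RBF-kernel support vector machines, a decision tree, random forest,
LightGBM, XGBoost and gradient-boosted trees; the regressors are PLS,
ridge, LASSO, elastic net, linear and RBF support vector regression,
random forest, LightGBM, XGBoost, a decision tree, ordinary least squares,
gradient-boosted trees and Gaussian-process regression. SVM-family,
shrinkage and PLS methods are tuned by 5-fold grid search (C and gamma on
log₂ grids 2⁻⁵…2¹⁰ and 2⁻²⁰…2¹⁰, epsilon 2⁻¹⁰…2⁰, alpha 10⁻³…10²,
L1-ratio 0.1…0.9, PLS components 1…min(30, rank)); other methods run at
library defaults. The linear SVM uses the kernel (dual) solver: with
descriptor dimension far above the sample count the primal coordinate
solver stalls without converging.

Assessment uses nested (double) cross-validation: an outer 5-fold split
holds out each fold for evaluation while method + hyperparameters are
selected by inner 5-fold grid search on the remaining folds, and the
reported metrics are computed on pooled out-of-fold predictions.
Classification folds are stratified, regression folds random, both seeded;
outer-fold count mirrors the stated 5 inner folds. Classification is
scored by F-measure, regression by r². The final deployed model refits the
inner-CV winner on all available data.

Metrics: accuracy (TP+TN)/(TP+FP+FN+TN), precision TP/(TP+FP), recall
TP/(TP+FN), F = harmonic mean of precision and recall; r² = 1 − SS_res/SS_tot,
MAE, RMSE. Ratios with zero denominators are reported as 0 with the metric
name recorded in an `undefined` flag set, so pooled tables never carry NaN
silently; a constant observed vector flags r² the same way while MAE and
RMSE are still returned.

A `fast` panel profile (logistic / linear SVM / random forest for
classification; ridge / linear SVR / random forest for regression, with
coarse grids) exists for end-to-end runs; the full panel is the expensive
path.

## The synthetic study generator

No screen data ships with the package; `synthdata.generate_study` creates
studies with the same statistical shape so every stage is testable. The
defaults mirror the target screen: 63 molecules × 61 receptors (3843
pairs), ≈ 8.7% positive pairs (333/3843), 23 odor labels in six
communities, binder log(EC50) in [3, 7].

Design of the planted signal, and why each piece is there:

- **Molecules** come from a curated list of ~150 real odorant-like
  structures (esters, terpenoids, aldehydes, pyrazines, thiols…, several
  with stereocentres); random SMILES strings are invalid too often to be
  useful, and real structures make cheminformatics featurization
  meaningful. Each molecule is classified into one of six structural
  families by a priority rule — aromatic ring, then any non-aromatic ring
  (terpenoids, lactones, musks), then acyclic carboxyl, aldehyde, ketone,
  and everything else (acyclic alcohols, thiols, ethers). Topology comes
  first in the priority because ring environments dominate a circular
  fingerprint, so the family is exactly the kind of label a
  fingerprint-based model can learn from a few dozen molecules. The study
  panel is drawn family-stratified (screens are assembled to span
  chemistries), topping short families up with programmatically generated
  alkyl homologs.
- **Receptors** are random canonical-alphabet sequences of length 290–330
  (OR-like). Receptors are split into six equal groups — one per molecular
  family — and every member of a group carries 4–7 copies of a
  group-specific trigram motif, the way receptor subfamilies share
  diagnostic motifs; this writes group identity into the composition
  features a model actually sees.
- **Binding** is driven by a family-tuned score: molecule–group affinity
  is the standardized closeness of the molecule's fingerprint to each
  family's centroid, with the molecule's own family leading by at least a
  0.25-sd margin (each odorant has a well-defined primary chemotype while
  graded affinity to the other families persists); a molecule main effect
  and a receptor popularity effect are added, the latter rank-balanced
  within groups so no community is systematically more active; Gaussian
  noise of sd 0.3 (score units) completes the score. Each molecule binds
  its top-scoring receptors; the binder count is a deterministic affine
  function of a molecule latent (promiscuity as a molecular trait) with
  mean 333/3843 × 61 ≈ 5.3, keeping the grid positive fraction on target
  while leaving binding learnable from the descriptors.
- **Odor labels** derive from the true activation profile: a community is
  present when its receptor group holds > 30% of the molecule's total
  activation (the strongest group is always present) — a linear functional
  of the profile, hence learnable by the profile classifiers. A molecule
  draws 2–4 labels from its strongest community; overlapping communities
  co-occur through a characteristic pair of notes fixed per community
  pair (real vocabularies are bridged by the same popular descriptors —
  and at 23 labels / 6 communities, unweighted modularity cannot tolerate
  many *distinct* cross-community label pairs, so repeated overlap must
  reinforce one edge rather than accumulate new ones). Labels are replaced
  uniformly at random at rate 0.01. Molecules binding nothing carry no
  labels, mirroring screens in which some molecules have no annotated
  odor.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning; identical seeds give byte-identical studies. Degenerate draws
(too many unlabeled molecules, too few realized labels) are regenerated
with fresh sub-seeds up to a retry cap, then raise.

**What the generator does not emulate:** real OR phylogeny and sequence
conservation, dose–response measurement error structure, correlated odor
annotations across related molecules, and annotator vocabulary drift.
Passing tests therefore show that the pipeline recovers planted structure
of the right shape and scale — not that it would reach the same accuracy
on laboratory data.

## End-to-end validation protocol

`benchmark.run_cascade_benchmark` generates one study of 63 + 50
molecules, trains the cascade on the first 63, and evaluates (a) nested-CV
pooled metrics of Models 1–3 and (b) held-out recovery: a held-out
molecule counts as recovered when its planted majority community — after
aligning learned to planted communities by label overlap — is among the
communities the full cascade predicts. Molecules that bind nothing carry
no planted community and are excluded from the denominator.

## Numerical choices and degenerate inputs

- Merge tie-break (communities): lexicographically smallest representative
  pair; gains compared with a 1e-15 slack.
- k-means++ runs one initialization (`n_init=1`) in float32; representative
  selection is by argmin distance, first index on ties.
- Zero-variance descriptor columns are dropped inside the modeling
  pipeline (recorded in the model so prediction replays the exact
  vocabulary); the standalone featurizers keep full dimensionality.
- A community with fewer than two positive or two negative molecules has
  its classifier disabled with a warning and is reported as "not assessed"
  at prediction time; fold counts shrink to the minority class size when
  needed (minimum 2).
- An incomplete binding grid is an error naming the missing pairs —
  zero-filling would conflate "unmeasured" with "non-binding".
- Negative log(EC50) inputs are rejected (0 is the non-binding code);
  Model-2 outputs are floored at 0 for the same reason.

## Problem sizes

The shipped tests and the acceptance script run the default-scale study
(63 training molecules × 61 receptors, 50 held-out molecules) with the
fast method panel, 5×5 nested CV, and the oracle suites at n ≤ 20 nodes /
1000 random draws. The full method panel over all descriptor combinations
is the package's expensive path and is exercised only through its unit
tests.

## Known limitations

- Model 3 is trained on measured profiles but deployed on cascade-predicted
  ones; prevalence matching narrows, but does not close, that distribution
  gap. Applicability-domain estimation is explicitly out of scope.
- Nested CV for Model 1 splits over pairs, so a molecule can appear in
  both outer train and test folds through different receptors; the
  held-out-molecule benchmark is the molecule-level check.
- The balanced-dataset evaluation convention means reported classification
  metrics are not estimates of raw-grid performance.
- Greedy modularity inherits the resolution limit; communities a few
  labels wide merge when even two or three distinct cross-community label
  pairs exist. The agglomerative greedy itself is near-optimal on
  structured small graphs but has known failure cases — on the 6-node path
  it merges both end pairs first and locks out the optimal 3+3 split
  (Q 0.26 vs 0.30), and on dense unstructured random graphs (where the
  optimum itself is barely above zero) the greedy/optimal ratio can drop
  to ~0.7; the reference agglomerative implementation in networkx lands on
  the same partitions there.
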