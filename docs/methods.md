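# Methods

## Problem and model

`kmerlasso` learns transcription-factor sequence signals discriminatively
from chromatin peak maps. Peaks are not attributed to known motifs;
instead a two-class problem — 150-bp windows centered on peak summits
(positives) against same-width windows centered 300 bp upstream
(negatives/flanks) — is solved over a feature space of all DNA 8-mers
with up to one interior run of one or two wildcard positions, with a
pattern and its reverse complement collapsed into a single canonical
feature. A count for an example is the number of window positions at
which the pattern or its reverse complement matches the forward strand;
a pattern matched by both orientations at one position, or a palindromic
pattern, counts once there, which makes counting strand-symmetric.
Windows containing N contribute nothing (N matches no pattern position).

Selected features (the `n_top` most discriminative by
|Δ mean| / (pooled SD + 1e-8), ties by dictionary order) are clustered
into G groups by average-linkage hierarchical clustering of
1 − Spearman correlation between count columns. Because the wildcarded
and shifted variants of one binding signal co-occur across the same
examples, a group typically collects the k-mer vocabulary of a single
motif. Defaults follow the assay: ChIP-seq `n_top=5000, G=20`;
DNase/ATAC `n_top=30000, G=200`.

The classifier is a logistic regression with a sparse group lasso
penalty, minimized by monotone FISTA (backtracking line search from a
power-iteration Lipschitz estimate; momentum restart whenever the
accelerated step would increase the objective, so the objective trace is
non-increasing; proximal steps give exactly-zero groups, no epsilon
thresholding). There is no intercept by default; an unpenalized
intercept is available. λ₁ (group level) and λ₂ (k-mer level) are chosen
by stratified K-fold cross-validation on held-out auROC.

## Group weighting (a deliberate design choice)

The group term is λ₁ Σ_g l_g^γ ‖w_g‖₂ with γ configurable. The default
is γ = 0.5, the conventional Yuan–Lin weighting. The alternative γ = 1
(penalty proportional to group size) makes a group's penalty grow ~ l_g
while its achievable signal norm grows only ~ √l_g, so the largest
groups — which after co-occurrence clustering are usually the ones
carrying a motif's variant vocabulary — are zeroed first. Empirically on
the planted-motif benchmark this caps test auROC near 0.85 and inverts
group selection (at strong λ₁ only small noise groups survive); with
γ = 0.5 the same data reach ≈ 0.91 and motif groups are selected as
units. γ = 1 remains available for exact correspondence with the
size-weighted objective.

## Cross-validation selection rule

Mean held-out auROC over stratified folds; by default the largest
(λ₁, λ₂) whose mean is within one standard error of the best is chosen
(the glmnet "1-SE" rule), falling back to the plain maximum with
`rule="best"`. Exact ties always break toward more regularization. On
noisy 250-example folds the plain maximum systematically picks the
weakest grid point and loses ~0.01–0.02 test auROC. An all-zero fold
model is scored 0.5 (its decision values are constant).

## Group reports, empirical null, hits

Per group g and example i the activation is w_g·x_{i,g}. The group is
associated with the class its activations push examples toward (sign of
the sum of class-mean activations): peak groups carry positive weights
on peak-enriched k-mers, flank groups negative weights on flank-enriched
k-mers. The naive sign of the class-mean *difference* labels every
discriminative group positive and is not used; the loss-form
score(g,i) = log(1+exp(−y_i w_g·x_{i,g})) and its class sums are
reported, and the printed max-of-sums association remains available as
`mode="loss_max"`.

Significance: for a peak-class group the activations of the flank
examples form the empirical null; p_i = (1 + #{null ≥ act_i}) / (1 + N_null)
(upper tail; mirrored to the lower tail for flank-class groups whose
evidence is strongly negative activation), Benjamini–Hochberg within the
group's class, significant at q ≤ 0.05, motif-eligible at ≥ 25
significant examples. Calibration holds for examples not used in
fitting; the benchmarks therefore train on one half and call group
membership on the held-out half (on training examples even a regularized
model's calls reflect overfitting, not signal — on pure noise most
training examples get called).

Hits: per significant example the start position maximizing the summed
weight of matching group patterns (either orientation; leftmost on ties,
forward preferred), a 50-bp window centered on the matched k-mer's
center (clipped at edges) exported as FASTA/BED for external motif
tools, plus a dependency-free PFM built from the matched k-mers
(reverse-orientation matches reverse-complemented).

## Multitask training

Two tasks plus a common block: example i of task t is scored by
(w_c + w_t)·x_i; penalties on task blocks are scaled by α = 1.5 and on
the common block by β = 1. The stacked problem is the same sparse group
lasso on (w_c, w_T1, w_T2) with per-block penalty multipliers, solved by
the same FISTA. Per-task group assignments come from clustering the
union feature space on that task's examples; the common assignment from
all examples pooled. As β → ∞ the common block vanishes and the fit
provably decouples into independent per-task fits with α-scaled
penalties (verified numerically to ~1e-8 relative).

Because α > β, a signal used by only one task migrates to the common
block unless it costs the other task something; the separation benchmark
therefore plants the task-private motif label-balanced in the other
task's sequences (as real motifs occur genome-wide without being used in
every context) and plants the two motifs in disjoint subsets of task-1
positives so co-occurrence clustering can separate their vocabularies.
The benchmark's operating point is λ₁ = 0.02·λ₁^max, λ₂ = 0.001·λ₂^max,
G = 10 (separation is stable across 0.01–0.05·λ₁^max).

## Synthetic data

Negatives are order-1 Markov background, by default with the C→G
transition down-weighted ×0.25 (CpG depletion, mimicking vertebrate
genomic background); uniform background available. Positives carry
instances sampled column-wise from position probability matrices,
reverse-complemented with probability 0.5, placed uniformly away from
the outer 5 bp; fractions act independently per plant or, in
`exclusive` mode, partition the positives (one signal per peak).
Planted (motif, start, strand) triples are recorded per sequence.
`dinucleotide_shuffle` is an Eulerian-walk shuffle preserving the exact
dinucleotide multiset and both endpoint bases.

The benchmark motifs are two strong 8-bp cores (AP-1-like TGACTCAT,
E-box-like CACGTGAC) at 0.95 major-base probability per position
(~1.7 bits/position, typical of strong TF core motifs). With diffuse
PWMs (0.85/position) the contiguous-wildcard feature space cannot
separate the classes well (even a ridge classifier on the same features
plateaus near 0.80 auROC), so benchmark results should be read as
applying to strong, core-dominated binding signals. What the synthetic
fixtures do not emulate: GC/CpG differences between peaks and flanks,
peak-strength gradients, cooperative or clustered binding sites,
repeat structure — real-data performance claims require real data.

## Problem sizes and numerics

Benchmarks use 500 positives + 500 flanks (150 bp), an even
train/test split, `n_top=2000`, `G=10`, 5-fold CV over a 4×2 λ grid
(fractions 0.6/0.3/0.1/0.03 of λ₁^max and 0.003/0.0003 of λ₂^max),
chosen so a full recovery run completes in seconds on one core.
Convergence: relative objective change < tol (default 1e-7) on three
consecutive iterations, or a machine-precision descent floor; the
solver-oracle comparisons run with tol=0 to that floor, where the KKT
residual is ~1e-6. λ^max values are computed from the gradient at w=0
and make the zero solution exactly optimal. The independent oracles are
graduated-smoothing minimizers (L-BFGS for the full objective;
exact-Hessian trust-region Newton for the prox, accurate to ~1e-8 by
strong convexity).

## Known limitations

- Group counts after a dendrogram cut can fall below the requested G on
  tied merge heights (a warning is emitted; ids stay dense).
- Empirical p-values on training examples are anti-conservative by
  construction; use held-out or fresh sequences for calibrated calls.
- The multitask solver treats exactly the stacked two-block objective;
  more elaborate task hierarchies are out of scope.
- Feature selection and clustering use the training split only;
  applying a trained model to new sequences recounts features over the
  model's selected subspace.
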