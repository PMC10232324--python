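# Methods

## Problem

Assigning Enzyme Commission (EC) numbers to protein sequences is the
central step of enzyme function annotation.  `enzannot` decomposes it
into three hierarchically related tasks:

1. **Enzyme detection** — binary: is the sequence an enzyme at all?
2. **Function counting** — multiclass over 1..`k_max` (default 8): how
   many distinct EC numbers does the enzyme carry?  Multifunctional
   enzymes are common and high counts are sparse.
3. **EC assignment** — multilabel over the training vocabulary of EC
   numbers, where each full 4-level EC code (and each incomplete code
   such as `1.14.-.-`) is one atomic class.  Treating the 4-level code
   as a tuple avoids the error compounding of predicting the four
   digits with separate models.

## Model

All three tasks share one encoder and are trained jointly.

**Embedding.**  Sequences are normalized to the 20 standard amino acids
plus `X` (B/Z/U/O/J and other nonstandard letters map to `X`; `*` and
gaps are stripped — unusual sequences are represented, not discarded).
The built-in embedder is per-residue one-hot over this 21-letter
alphabet.  Pretrained protein language models can be registered as
plugin embedders with an explicit layer choice; because embedding
quality is task-dependent, `select_embedding` trains one small model
per candidate under an identical configuration and seed and keeps the
candidate with the best validation score (binary F1 for task 1, macro
F1 for task 3; ties break by registration order).  The package never
downloads weights; plugins are interfaces only.

**Encoder.**  A single-layer bidirectional GRU (default 128 units per
direction; the desk-scale configurations below use 32) reads the
embedded sequence.  Padded positions are gated out of the recurrence
(the previous state is carried through), so states at real positions do
not depend on pad length.

**Per-task attention.**  Each task owns a multihead attention layer
(default 4 heads) whose keys and values are the shared GRU states and
whose query is a learned per-head vector — scaled dot-product
attention, `softmax(Q K^T / sqrt(d_h)) V`, with additive −∞ masking of
padding before the softmax.  Together with the gated recurrence this
makes predictions exactly padding-invariant (verified by test).

**Heads and losses.**  The attended summary feeds one dense head per
task: sigmoid (task 1), softmax over counts (task 2), independent
per-class sigmoids (task 3; an enzyme may carry several ECs).  The
composite loss is

    L = BCE_1(all records) + CE_2(enzymes only) + BCE_3(enzymes only)
        + w * Omega

Tasks 2 and 3 are supervised only on enzyme-labeled records, making the
task hierarchy explicit: non-enzymes have no count or EC ground truth.
A batch with no enzymes contributes only the task-1 term — and skips
the penalty too, since the penalty couples head parameters that such a
batch does not supervise (so purely negative data leaves the task-2/3
heads untouched).

**Task-clustering penalty.**  Sharing an encoder across tasks risks
negative transfer.  The penalty

    Omega = ||a_bar||^2 + sum_t lambda_t ||a_t - a_bar||^2,
    a_bar = (1/T) sum_t a_t

pulls the task parameter vectors `a_t` toward their mean while keeping
the mean itself small.  The `a_t` are realized as the flattened final
dense-layer weight matrices of the three heads, zero-padded to a common
length (the heads are the only task-specific parameters).  Defaults:
`lambda = (0.5, 0.1, 0.4)`, penalty weight `w = 0.01` — small enough to
act as a regularizer rather than dominate the fit; both configurable.

**Optimization.**  Adam (default step 1e-3, batch 32, patience 5 — the
desk-scale runs below use step 1e-2, batch 128, patience 10, which the
training-stability tests cover).  Early stopping tracks the mean of
task-1 F1 and task-3 macro-F1 on a validation split and restores the
best parameters.  Recurrent weight blocks are initialized orthogonally
(stable state norms over long unrolls); input projections use a
3×-Glorot scale because sparse one-hot rows otherwise inject too little
signal early in training.  Everything is float64 and fully
deterministic for a fixed seed; the gradient engine (a small
reverse-mode autodiff over numpy) is verified against central finite
differences for every operator and end-to-end through the whole loss.

## Integration

Final EC assignments merge the task outputs with a homology channel
under a small decision policy: records with `p_enzyme` below a gate
threshold `tau1` receive no EC; otherwise candidates from the model's
per-class scores and from annotation transfer are pooled in a declared
precedence order, thresholded at `tau3` (alignment candidates must also
clear an identity floor), de-duplicated at full-tuple identity (first
channel wins), and optionally capped at the task-2 argmax count, with
deterministic tie-breaking (score descending, then EC ascending).

The homology channel transfers the full EC set of the most similar
labeled reference, scored by Jaccard similarity of 3-mer multisets — a
dependency-free similarity; tabular output of an external aligner
(query / subject / percent identity) can be supplied instead.

Policy parameters are tuned by greedy coordinate search maximizing
macro-F1 of the final assignment on a labeled tuning split: fields are
swept in the fixed order `tau1 → identity floor → tau3 → count rule →
precedence`, two full passes, incumbent wins ties — so the achieved
objective is non-decreasing step by step and the search is exactly
reproducible.  Default grids: `tau1 ∈ {0.3, 0.5, 0.7}`, floor
`∈ {0.4, 0.6, 0.9}`, `tau3 ∈ {0.05, 0.1, 0.2, 0.5}`, count rule
`∈ {cap-by-task2, ignore-count}`, precedence over all permutations of
all nonempty channel subsets.  On the benchmark tuning set the greedy
optimum is verified against exhaustive grid search.

## Evaluation

Confusion counting adds two unclassified cells to the usual four: UP
(gold-positive, predictor abstained) and UN (gold-negative, abstained).
Binary metrics:

    ACC    = (TP+TN) / (TP+FP+TN+FN+UP+UN)
    PR     = TP / (TP+FP)          NPV = TN / (TN+FN)
    Recall = TP / (TP+FN+UP)       F1  = 2·PR·Recall / (PR+Recall)

Abstentions therefore depress accuracy and recall but not precision —
the honest summary for annotation tools that refuse hard queries.
Multiclass metrics are one-vs-all macro averages; **mF1 is the harmonic
mean of macro-precision and macro-recall**, not the mean of per-class
F1 (the two disagree on asymmetric inputs; a regression test pins the
former).  Conventions: any 0/0 ratio is 0 and the class still counts in
the macro mean (flagged in the report); a record predicted with no EC
counts as an abstention for tasks 2/3 when it is a gold enzyme, and as
a clean true negative everywhere when it is a gold non-enzyme; for
task 1 an empty assignment is a definite non-enzyme call and only an
explicit no-call abstains.  Task 3 can be scored at EC depth 1–4 by
truncating both gold and predicted codes; correctness at depth L+1
implies correctness at depth L record by record.

Benchmarks are built chronologically: train on records dated at or
before a cutoff (boundary inclusive), test on later windows, remove
test records whose exact sequence occurs in training, and exclude test
records carrying any EC absent from the training vocabulary (a label no
trained method can emit; mixed known/novel records are wholly excluded —
a deliberate conservative choice).

## Synthetic data

The generator builds a toy universe in which function is fully
determined by sequence: a hierarchical vocabulary of depth-4 EC labels
(`n1·n2·n3·n4` Cartesian structure), one distinct motif per label,
enzymes containing the motifs of all their labels at non-overlapping
positions, non-enzymes rejection-sampled to contain no motif.  Point
mutations hit at the configured rate outside motifs and a fifth of it
inside, so labels stay learnable but noisy.  Function counts follow a
geometric-decay distribution `p(m) ∝ 0.5^(m−1)`, `m = 1..8`, mirroring
the sparsity of highly multifunctional enzymes.  Class fractions and
counts use largest-remainder allocation, so a configuration regenerates
byte-identically.

**Standard benchmark:** 2,000 records, labels 3·2·2·2 = 24, motif
length 6, sequence lengths uniform 60–120, 30% non-enzymes, mutation
rate 0.05, 80/10/10 train/tune/test split, seed 7.  The desk-scale
training configuration on it is hidden width 32, 4 heads, batch 128,
step 1e-2, at most 40 epochs; the ablation comparison (joint vs
task-3-only training) uses 12 epochs per arm across 3 seeds.  A
noiseless variant has an exact ceiling: substring matching of the
planted motifs recovers every label (F1 = mF1 = 1), which bounds what
any learner can achieve and validates the labels themselves.

What this data does **not** emulate: real amino-acid composition,
domain architecture, homology structure, or label noise of curated
databases.  Passing the synthetic recovery tests shows the pipeline is
implemented correctly and can extract planted sequence determinants of
function; it does not certify performance on real proteomes, where
function is not a substring property.

## Numerical and design notes

- EC strings parse with 1–4 components; trailing `-` components mark
  unspecified levels, and a specified level after a wildcard is
  rejected.  Incomplete ECs are classes in their own right.
- Attention masking uses an additive −1e9 rather than true −∞ to avoid
  NaNs in the softmax; with ≤1,000 positions the induced weight error
  is far below float64 resolution.
- Probabilities are clamped to [1e-7, 1−1e-7] inside cross-entropies.
- Ties everywhere break deterministically (registration order for
  embedder selection, lexicographic EC order in assignments, incumbent
  wins in greedy search).
- The annotation-table reader keeps enzyme-flag/EC-list consistency as
  a hard error listing offending ids; nothing is silently dropped.
- Duplicate sequences with conflicting annotations are not
  de-duplicated automatically; the chronological splitter treats the
  sequence string as the identity for train/test overlap, which is the
  conservative reading for benchmark hygiene.

## Limitations

- The built-in 3-mer Jaccard similarity is a weak stand-in for a real
  aligner; on the synthetic benchmark the tuned policy typically relies
  on the model channel.  For real data, supply external alignment
  output.
- Pure-numpy training is practical at desk scale (thousands of short
  sequences, minutes on one CPU), not at database scale.
- `select_embedding` judges candidates with small proxy models; with
  very few validation records its ranking is noisy.
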