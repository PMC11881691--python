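# Methods

## The problem

An *orphan enzyme* is a biochemically characterised activity with no known
protein sequence.  Because no sequence exists, similarity search (BLAST,
profile HMMs) cannot find candidate genes for it.  `deepes` implements a
screening strategy that sidesteps sequence similarity entirely: it scores
*chemistry* instead, by predicting for every gene the probability that it
carries out each reaction class (KEGG RClass — a fingerprint of the
substrate–product transformation), and then exploits the genomic clustering
of pathway enzymes in prokaryotes (biosynthetic gene clusters, BGCs) to ask
whether a run of adjacent genes plausibly encodes a chain of L sequential
reactions.

## Model

### Per-class probability

Each reaction class r gets an independent binary classifier

    p_r(x) = sigmoid(W2 · dropout(relu(W1 · e(x) + b1)) + b2)

where `e(x)` is a fixed-length embedding of the protein sequence from a
**frozen** embedder (the reference configuration is the ESM-2 protein
language model, 650M parameters, D = 1280, mean-pooled over residues; this
package ships a deterministic mock for offline work, below).  The decomposed
one-vs-rest formulation is used because reaction-class prediction is
multi-label: a single reaction commonly carries several RClasses.

Training minimises the class-weighted binary cross-entropy

    L(p, y) = −[ w·y·log p + (1−y)·log(1−p) ],    w = |negatives| / |positives|

which counteracts the extreme imbalance of any one class against the rest
of a genome corpus.  The analytic optimum of this loss for a constant
predictor is p\* = wπ/(wπ + 1 − π) at prevalence π — a closed form the test
suite uses to verify the training loop end to end.  Optimisation is Adam
(batch 256, seeded shuffle); the optimiser and batch size are recorded in
each model's training metadata because they are this package's choices, not
field-standard constants.  Examples are put in canonical (id-sorted) order
before the seeded shuffle, so training is invariant to input order.

Hyperparameters default to the selected values of the reference grid —
epochs 20, hidden 64, learning rate 1e-3, dropout 0.1 — and
`grid_search_cv` reproduces the full 108-cell grid
(epochs {1,5,10,20} × hidden {64,128,256} × lr {1e-2,5e-3,1e-3} ×
dropout {0.1,0.25,0.5}) with stratified 10-fold CV selecting on mean AUPRC;
ties go to the cheaper model (fewer epochs, smaller hidden layer, larger
learning rate, smaller dropout).

**Training effort at small corpus size.**  An epoch count tuned on a
~1.9M-example corpus corresponds to ~10^5 optimiser steps; on this
package's 400-example synthetic corpus, 20 epochs is 40 steps, which
leaves the head close to its p ≈ 0.5 initialisation.  End-to-end
demonstrations and the acceptance script therefore train registries with
`epochs=300` (≈ 600 steps), keeping every other hyperparameter at its
default.  This is a problem-size adaptation of optimisation effort, not a
change of the model.

### Reaction and frame scores

For a reaction with classes {r1..rk}, a gene's reaction probability is the
geometric mean of its per-class probabilities, over **all** k classes.  If
any class lacks a trained model the reaction is *unscorable* (MISSING), not
partially averaged — a partial geometric mean would silently change the
statistic's meaning.  All products are computed in log space with a floor
of 1e-12 so saturated sigmoid outputs cannot produce −inf.

The screening statistic slides a frame of W consecutive genes (default 10)
along each contig with stride 1 and scores each frame by the best
*injective* assignment of genes to the L reactions (default 3):

    score(frame) = max over injective g: reactions → genes of
                   ( Π_j p(g(j), reaction_j) )^(1/L)

"Injective" means no gene may serve two reactions.  The default solver
enumerates all W!/(W−L)! assignments exactly (720 at the defaults,
vectorised); a Hungarian solver on log-probabilities is provided for large
W·L and is tested to agree.  A per-reaction greedy argmax is *not*
equivalent (counterexample [[0.9, 0.8], [0.89, 0.1]]: greedy yields
√0.09 ≈ 0.30, the optimum is √0.712 ≈ 0.844) and is deliberately not
offered.  A frame scoring ≥ the threshold (default 0.99) is a hit, and its
assignment names the candidate genes.

Design points that were genuinely open:

- **Assignment order.**  The gene order inside the window is not required
  to follow the reaction order; a `collinear=True` option restricts to
  order-preserving assignments for users who want the stricter reading.
- **Terminal windows.**  Truncated windows at a contig end are scored while
  they still hold at least as many genes as scorable reactions; this keeps
  short contigs — common in metagenome-assembled genomes — screenable.
- **Unscorable reactions in a frame.**  They are dropped from the mean and
  the frame is flagged `partial`; `strict=True` refuses partial frames.
- **Ties.**  Equal-scoring assignments resolve to the lexicographically
  smallest by (reaction order, gene rank); equal genome scores rank by id.

### Input handling

Gene order is taken from protein-FASTA record order (or an explicit
gene-order TSV).  Sequences longer than 4000 residues or containing the
ambiguity code "J" are inadmissible for the embedder and removed before
screening; ranks are **not** renumbered, so a removed gene leaves a gap and
windows keep reflecting true genomic adjacency.  The boundary is inclusive:
a 4000-residue sequence passes.  Other ambiguity codes (B, Z, X, U, O) are
retained; how an embedder maps them is part of its spec.

## Evaluation protocols

**Homology-filtered LOOCV.**  To measure whether the classifiers see past
sequence similarity, a non-redundant validation set is built by clustering
at 0.3 identity and keeping one representative per cluster (longest, ties
by id).  For each query, every homology hit is excluded from the training
corpus, the query's class heads are retrained, and the query is scored
against a seeded sample of 20 non-enzyme negatives.  Precision as a
function of the probability threshold is reported both pooled over all
predictions (micro) and averaged per trial (macro), since the choice is
ambiguous in general usage.  Every retrained model records its training
gene ids, and the suite asserts no excluded or query id ever appears there.

**Pseudo-orphan masking.**  A known gene cluster is made artificially
orphan by removing the orthologous groups (KOs) of its enzymes from
training.  If a class thereby loses every positive example its classifier
*cannot be built* — this untrainable state is first-class and reported, and
a pathway with no trainable reaction is "not testable" rather than an
error.  Otherwise the screen runs and the trial reports whether the top
frame's assignment equals the true cluster.  Genes analogous to
"hypothetical proteins" are excluded from the correctness comparison; if
every assigned gene is hypothetical, correctness is undefined rather than
false.

Homology search and clustering are reached only through the
`HomologyAdapter` contract.  The shipped adapter is a deterministic
alignment-free stand-in (shared k-mer fraction over the smaller set, k=4;
single-linkage clustering); external BLAST/MMseqs2 adapters plug into the
same two-method contract.

## The mock embedder and synthetic study conditions

The mock embedder hashes 3-mer counts into 4096 buckets, L2-normalises,
and applies a fixed seeded Gaussian projection to D dimensions (default
1024).  It is a pure function of (sequence, spec).  Two numbers matter:
the bucket count must be large relative to the ~100 k-mers of one protein
(otherwise chance bucket collisions between unrelated sequences swamp real
shared-k-mer signal), and the projection dimension sets the cross-talk
between orthogonal count vectors, which scales as 1/√D.  At D = 1024 the
spurious cosine between unrelated sequences (≈ 0.03–0.09 for the maximum
over 20 negatives) sits well below genuine shared-motif similarity
(≈ 0.2); at D = 64 the two are the same size, which is fine for
within-family separation but not for cross-family generalisation tests.

The synthetic corpus realises each reaction class as a conserved 20-residue
motif (a catalytic-domain analogue).  Each class has 4 families (KO
analogues): a family is a random consensus sequence (length 60–120) with
the class motif implanted, and members are noisy copies (per-residue
substitution rate 0.05).  Several *small* families per class — rather than
two large ones — matter: when an evaluation protocol excludes the query's
family, the surviving positives share nothing but the motif, which forces
the classifier onto class-level signal exactly as training across many
orthologous groups does at corpus scale.  Defaults give 60 positives and
340 background genes (n = 400; per-class imbalance 19:1, class weight 19).
Genomes are background genes with L consecutive pathway-family genes
planted at declared positions; `plant_families` can pin the planted genes
to a specific (e.g. masked) family.

What the generator does *not* emulate: real substitution matrices, indels,
domain shuffling, shared evolutionary ancestry of background genes,
multi-label enzymes, and the contextual (non-k-mer) signal a protein
language model extracts.  Passing tests therefore demonstrate the
correctness of the statistics, the solvers, and the protocols — not the
biological accuracy any particular embedder achieves on real proteins.

## Numerical choices

- Probability floor 1e-12 before every log; frame and reaction scores are
  clipped into [floor, 1].
- Stable sigmoid (split by sign) in the MLP; loss clamps p to
  [1e-12, 1−1e-12]; a non-finite loss aborts training with diagnostics.
- AUPRC is the step-wise threshold sum (average precision), validated in
  the tests against exhaustive threshold enumeration on small inputs.
- Problem sizes used by the acceptance script: n = 400 corpus, 20 genomes
  of 100 genes, 200 random matrices for the solver oracle, 12 LOOCV
  trials — the package's chosen desk-scale study conditions.

## Known limitations

- The mock embedder is alignment-free k-mer hashing; remote homology that
  a language model would capture is invisible to it, so LOOCV clearance on
  the synthetic conditions is high but not guaranteed to be 100% at every
  seed (clearance failures occur at hair-thin margins where random
  projection cross-talk edges out motif transfer).
- Registries hold every model in memory; the per-model training-id list in
  the metadata (needed for the leakage audit) grows with corpus size.
- `screen` recomputes embeddings per genome unless an HDF5 cache path is
  supplied to `embed_table`.
- The external-tool homology adapters are contract slots; only the
  built-in k-mer adapter is exercised by the test suite.
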