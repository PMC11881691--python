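# deepes

Screening genomes for candidate genes of **orphan enzymes** — enzymatic
activities that are biochemically known but have no sequenced gene, and are
therefore invisible to BLAST and every other similarity search.

`deepes` is aimed at microbiome and natural-product researchers working
with (meta)genome protein catalogues.  It combines two observations:

1. The chemistry of a reaction can be predicted from sequence without any
   close homolog, by classifying protein embeddings into KEGG **reaction
   classes** (RClass — a fingerprint of the substrate–product
   transformation).
2. In prokaryotes, enzymes of sequential pathway reactions tend to sit next
   to each other on the genome (**biosynthetic gene clusters**).

So instead of searching for a sequence nobody knows, `deepes` slides a
window of W consecutive genes along each contig and asks: *does this window
plausibly contain the L sequential reactions of my pathway?*

## The statistic

Each reaction class r has an independent binary classifier — a small MLP
head with a sigmoid output on top of a **frozen** protein-embedding model —
trained with a class-weighted cross-entropy
`−[w·y·log p + (1−y)·log(1−p)]`, `w = |neg|/|pos|`, to survive extreme
label imbalance.  A reaction annotated with classes r1..rk scores
`(p_r1 · … · p_rk)^(1/k)` per gene.  A frame of W genes then scores

    score = max over injective assignments g: reactions → genes
            ( Π_j  p(g(j), reaction_j) )^(1/L)

— every reaction takes the gene giving it the highest probability, but no
gene may serve two reactions, and the geometric mean of the chosen
probabilities is the frame score.  The maximisation is solved exactly
(exhaustive enumeration, with an equivalent Hungarian solver for large
windows); a per-reaction greedy pick is provably not the same statistic.
Frames scoring at or above the threshold (default 0.99) are hits, and the
winning assignment names the candidate genes.  Defaults: W = 10, L = 3.

## Worked example

Everything below runs offline: the built-in deterministic mock embedder
(hashed 3-mer counts + fixed random projection) stands in for a protein
language model, and the synthetic generator produces a labelled corpus and
a genome with one planted 3-gene cluster.

```
$ deepes simulate --seed 7 --out fixtures
corpus of 400 sequences, genome with 1 planted cluster(s) -> fixtures

$ deepes train --pairs fixtures/pairs.tsv --fasta fixtures/corpus.faa \
       --rclass RC00001,RC00002,RC00003 --seed 7 --out registry
saved 3 model(s) to registry

$ mkdir genomes && cp fixtures/genome.faa genomes/
$ deepes screen --genomes genomes --pathway fixtures/pathway.json \
       --registry registry --threshold 0.5 --out frames.tsv
1 genome(s), 25 hit frame(s) -> frames.tsv

$ head -2 frames.tsv
genome_id  contig_id       start_rank  end_rank  score     hit  partial  assignment
genome     genome_contig0  0           9         0.806374  1    0        R1=G0_c1_g0004;R2=G0_c1_g0005;R3=G0_c1_g0006
```

The top frame scores 0.806 and assigns reactions R1–R3 to genes at ranks
4, 5, 6 — exactly the three genes the generator planted
(`fixtures/genome_truth.json` lists them under `"c1:4"`).  A score of 0.81
means the geometric mean of the three chosen per-reaction probabilities is
0.81; with `--threshold 0.99` the same frame would not be called a hit,
which is the intended behaviour of the conservative default on a
desk-scale training corpus.

Evaluation protocols are available under `deepes validate`:
`loocv` retrains classifiers with all homologs of each query excluded and
reports precision against the probability threshold; `mask-bgc` makes a
known cluster artificially orphan by masking its orthologous groups (KOs)
from training and tests whether the screen still recovers it.  If masking
removes every positive example of a class, that classifier cannot be built
and the pathway is reported "not testable" rather than silently scored.

## Library surface

```python
import deepes

spec    = deepes.SyntheticSpec(seed=0)
corpus  = deepes.generate_corpus(spec)
pathway = deepes.pathway_for_corpus(corpus)           # 3 sequential reactions
registry = deepes.train_registry(corpus.examples, spec.rclass_ids,
                                 hp=deepes.Hyperparameters(epochs=300))
genome, truth = deepes.generate_genome(spec, pathway, corpus, "G1",
                                       n_genes=100, bgc_positions=(("c1", 40),))
result = deepes.screen([genome], pathway, registry, W=10, threshold=0.5)[0]
result.top_frame().assignment   # {'R1': ..., 'R2': ..., 'R3': ...}
```

Real data enters through `read_ordered_fasta` / `read_pairs_tsv` (gene
order = FASTA record order; sequences over 4000 residues or containing "J"
are filtered before embedding), and external embedders or homology tools
plug in through `register_embedder` and the `HomologyAdapter` contract.

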