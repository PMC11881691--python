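"""Seed-reproducible synthetic corpora, genomes, and probability fixtures.

Real training data pairs millions of prokaryotic protein sequences with
reaction-class labels via orthologous groups, and real inputs are MAG
protein catalogues possibly containing a biosynthetic gene cluster.  These
generators emulate both at desk scale with controllable signal:

* Each reaction class is realised by a *motif* (a conserved residue block,
  the analogue of a catalytic domain).
* Each orthologous-group analogue ("family", standing in for a KO) has its
  own random consensus sequence with the class motif implanted at a fixed
  position; members are the consensus with independent per-residue
  substitutions at ``noise_rate``.  Several families per class by default,
  so a homology-style exclusion of one family leaves the class motif as the
  only feature shared by the survivors — classifiers are thereby forced
  onto class-level signal, mirroring how training across many orthologous
  groups works at corpus scale, and exclusion tests retain signal.
* Background genes are unlabelled random sequences, sized so each per-class
  binary dataset has the requested negative:positive imbalance.
* Genomes are background genes with L consecutive pathway-family genes
  planted at declared positions.

Every generator is a pure function of its spec and seed — the global numpy
RNG is never consulted — so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .rclass_classifier import SequenceExample, write_pairs_tsv
from .reaction_scoring import PathwaySpec, ProbabilityMatrix, ReactionSpec
from .sequence_io import GeneRecord, GenomeTable

__all__ = [
    "SyntheticSpec",
    "TruthRecord",
    "GenomeTruth",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_genome",
    "pathway_for_corpus",
    "make_probability_fixture",
    "write_corpus",
]

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic world.

    ``imbalance`` is the negative:positive ratio of each per-class binary
    dataset; the number of background genes in the corpus is derived from it.
    ``n_background_genes`` sizes generated genome contigs.
    """

    n_rclasses: int = 3
    families_per_rclass: int = 4
    members_per_family: int = 5
    motif_length: int = 20
    seq_length_range: tuple[int, int] = (60, 120)
    n_background_genes: int = 30
    bgc_positions: tuple[tuple[str, int], ...] = (("c1", 4),)
    noise_rate: float = 0.05
    imbalance: float = 19.0
    hypothetical_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_rclasses,
            self.families_per_rclass,
            self.members_per_family,
            self.motif_length,
            self.n_background_genes,
        ) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if self.seq_length_range[0] < self.motif_length:
            raise ValueError("sequences must be at least motif_length long")

    @property
    def rclass_ids(self) -> list[str]:
        return [f"RC{i + 1:05d}" for i in range(self.n_rclasses)]

    def positives_per_rclass(self) -> int:
        return self.families_per_rclass * self.members_per_family

    def corpus_background_count(self) -> int:
        """Background genes needed so each per-class dataset has the
        requested imbalance (other classes' positives already count as
        negatives)."""
        pos = self.positives_per_rclass()
        n = round(self.imbalance * pos) - (self.n_rclasses - 1) * pos
        if n < 0:
            raise ValueError(
                "imbalance too small for the number of classes: cross-class "
                "negatives alone exceed it"
            )
        return n


@dataclass
class TruthRecord:
    rclass_ids: list[str]
    family_id: str | None = None
    is_bgc_member: bool = False
    is_hypothetical: bool = False


@dataclass
class GenomeTruth:
    """Planted-cluster gene ids per ``"<contig>:<start>"`` position, plus
    which background genes carry the hypothetical-protein analogue flag."""

    planted: dict[str, list[str]]
    hypothetical: set[str]

    def __getitem__(self, position: str) -> list[str]:
        return self.planted[position]

    def __len__(self) -> int:
        return len(self.planted)

    def all_planted(self) -> set[str]:
        return {g for genes in self.planted.values() for g in genes}


@dataclass
class SyntheticCorpus:
    """Generated training corpus plus the generator state genomes draw from."""

    spec: SyntheticSpec
    examples: list[SequenceExample]
    truth: dict[str, TruthRecord]
    motifs: dict[str, str]  # rclass_id -> motif
    families: dict[str, tuple[str, str]]  # family_id -> (rclass_id, consensus)

    def family_ids(self, rclass_id: str) -> list[str]:
        return sorted(f for f, (rc, _) in self.families.items() if rc == rclass_id)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _mutate(rng: np.random.Generator, sequence: str, noise_rate: float) -> str:
    if noise_rate == 0.0:
        return sequence
    chars = np.array(list(sequence))
    hits = rng.random(len(chars)) < noise_rate
    for i in np.flatnonzero(hits):
        choices = _ALPHABET[_ALPHABET != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Build the labelled corpus: motif families per class plus background."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seq_length_range

    motifs: dict[str, str] = {}
    families: dict[str, tuple[str, str]] = {}
    examples: list[SequenceExample] = []
    truth: dict[str, TruthRecord] = {}

    for ri, rclass_id in enumerate(spec.rclass_ids):
        motifs[rclass_id] = _random_seq(rng, spec.motif_length)
        for fi in range(spec.families_per_rclass):
            family_id = f"K{(ri + 1) * 100 + fi:05d}"
            length = int(rng.integers(lo, hi + 1))
            consensus = list(_random_seq(rng, length))
            pos = int(rng.integers(0, length - spec.motif_length + 1))
            consensus[pos : pos + spec.motif_length] = motifs[rclass_id]
            consensus_str = "".join(consensus)
            families[family_id] = (rclass_id, consensus_str)
            for mi in range(spec.members_per_family):
                gene_id = f"{family_id}_m{mi:03d}"
                seq = _mutate(rng, consensus_str, spec.noise_rate)
                examples.append(
                    SequenceExample(
                        gene_id=gene_id,
                        sequence=seq,
                        rclass_ids=frozenset({rclass_id}),
                        ko_id=family_id,
                    )
                )
                truth[gene_id] = TruthRecord(
                    rclass_ids=[rclass_id], family_id=family_id
                )

    for bi in range(spec.corpus_background_count()):
        gene_id = f"bg_{bi:05d}"
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        examples.append(
            SequenceExample(gene_id=gene_id, sequence=seq, rclass_ids=frozenset())
        )
        truth[gene_id] = TruthRecord(rclass_ids=[])

    return SyntheticCorpus(
        spec=spec, examples=examples, truth=truth, motifs=motifs, families=families
    )


def pathway_for_corpus(
    corpus: SyntheticCorpus, L: int = 3, pathway_id: str = "synthetic_pathway"
) -> PathwaySpec:
    """A chain of L sequential reactions, one corpus reaction class each."""
    ids = corpus.spec.rclass_ids
    if L > len(ids):
        raise ValueError(f"corpus has only {len(ids)} reaction classes")
    return PathwaySpec(
        pathway_id=pathway_id,
        reactions=tuple(
            ReactionSpec(reaction_id=f"R{j + 1}", rclass_ids=(ids[j],))
            for j in range(L)
        ),
    )


def generate_genome(
    spec: SyntheticSpec,
    pathway: PathwaySpec,
    corpus: SyntheticCorpus,
    genome_id: str = "G0",
    n_genes: int | None = None,
    bgc_positions: tuple[tuple[str, int], ...] | None = None,
    seed: int | None = None,
    plant_families: dict[str, str] | None = None,
) -> tuple[GenomeTable, GenomeTruth]:
    """Plant one pathway-family gene run per declared position.

    Returns the genome and a truth map: ``"<contig>:<start>" -> planted gene
    ids`` (in reaction order).  Planted genes are fresh noisy members of a
    family carrying each reaction's first class; ``plant_families`` pins the
    family per reaction class (e.g. to plant members of a family that was
    masked from training).  Everything else is background, flagged
    hypothetical-analog at ``spec.hypothetical_rate``.
    """
    n_genes = spec.n_background_genes if n_genes is None else n_genes
    positions = spec.bgc_positions if bgc_positions is None else bgc_positions
    if seed is None:
        seed = (spec.seed ^ zlib.crc32(genome_id.encode())) % (2**31)
    rng = np.random.default_rng(seed)
    lo, hi = spec.seq_length_range
    L = len(pathway)

    by_contig: dict[str, list[tuple[int, int]]] = {}
    for bi, (contig, start) in enumerate(positions):
        if start + L > n_genes:
            raise ValueError(
                f"BGC at {contig}:{start} overflows contig of {n_genes} genes"
            )
        by_contig.setdefault(contig, []).append((start, bi))
    for contig, starts in by_contig.items():
        spans = sorted(range(s, s + L) for s, _ in starts)
        flat = [r for span in spans for r in span]
        if len(set(flat)) != len(flat):
            raise ValueError(f"overlapping BGC positions on contig {contig}")

    contig_names = sorted(by_contig) or ["c1"]
    contigs: dict[str, list[GeneRecord]] = {}
    planted: dict[str, list[str]] = {}
    hypothetical: set[str] = set()
    for contig in contig_names:
        records: list[GeneRecord] = []
        plant_at: dict[int, tuple[int, int]] = {}  # rank -> (bgc idx, reaction idx)
        for start, bi in by_contig.get(contig, []):
            for j in range(L):
                plant_at[start + j] = (bi, j)
            planted[f"{contig}:{start}"] = [""] * L
        for rank in range(n_genes):
            if rank in plant_at:
                bi, j = plant_at[rank]
                reaction = pathway.reactions[j]
                rclass_id = reaction.rclass_ids[0]
                fams = corpus.family_ids(rclass_id)
                if not fams:
                    raise ValueError(f"no family realises {rclass_id!r}")
                if plant_families and rclass_id in plant_families:
                    family_id = plant_families[rclass_id]
                    if family_id not in fams:
                        raise ValueError(
                            f"family {family_id!r} does not realise {rclass_id!r}"
                        )
                else:
                    family_id = fams[int(rng.integers(0, len(fams)))]
                _, consensus = corpus.families[family_id]
                seq = _mutate(rng, consensus, spec.noise_rate)
                gene_id = f"{genome_id}_{contig}_g{rank:04d}"
                start = rank - j
                planted[f"{contig}:{start}"][j] = gene_id
            else:
                seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                gene_id = f"{genome_id}_{contig}_g{rank:04d}"
                if rng.random() < spec.hypothetical_rate:
                    hypothetical.add(gene_id)
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=contig,
                    rank=rank,
                    sequence=seq,
                )
            )
        contigs[contig] = records
    return (
        GenomeTable(genome_id=genome_id, contigs=contigs),
        GenomeTruth(planted=planted, hypothetical=hypothetical),
    )


def make_probability_fixture(
    W: int,
    L: int,
    pattern: str = "constant",
    n_genes: int = 30,
    constant: float = 0.5,
    background: float = 0.01,
    signal: float = 0.99,
    planted_at: int = 4,
    seed: int = 0,
    contig_id: str = "c1",
) -> ProbabilityMatrix:
    """Probability matrices for direct window-scoring tests, no model needed.

    Patterns: ``constant`` (every entry = constant), ``planted`` (background
    everywhere, signal on the diagonal of an L-gene run at ``planted_at``),
    ``random`` (seeded uniform draws).
    """
    import pandas as pd

    if W < L:
        raise ValueError("W must be at least L")
    if pattern == "constant":
        values = np.full((n_genes, L), float(constant))
    elif pattern == "planted":
        values = np.full((n_genes, L), float(background))
        for j in range(L):
            values[planted_at + j, j] = float(signal)
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        values = rng.uniform(size=(n_genes, L))
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "contig_id": [contig_id] * n_genes,
            "rank": list(range(n_genes)),
        }
    )
    return ProbabilityMatrix(
        gene_meta=gene_meta,
        reaction_ids=[f"R{j + 1}" for j in range(L)],
        values=values,
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA + pairs TSV + truth JSON for CLI and round-trip use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "corpus.faa"
    with open(fasta, "w") as fh:
        for e in corpus.examples:
            fh.write(f">{e.gene_id}\n{e.sequence}\n")
    pairs = outdir / "pairs.tsv"
    write_pairs_tsv(corpus.examples, pairs)
    truth = outdir / "truth.json"
    truth.write_text(
        json.dumps({g: asdict(t) for g, t in corpus.truth.items()}, indent=1)
    )
    return {"fasta": fasta, "pairs": pairs, "truth": truth}
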