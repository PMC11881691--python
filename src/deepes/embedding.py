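"""Protein-embedding contract, deterministic mock embedder, and cache.

The reaction-class classifiers consume one fixed-length vector per protein.
In production that vector comes from a frozen protein language model (the
reference configuration is ESM-2 ``esm2_t33_650M_UR50D``, D = 1280, with
mean pooling over residue positions); the embedder's parameters are never
updated during classifier training, so embedding is a pure function of the
sequence.

For fully offline and fast testing this module ships a mock embedder:
3-mer counts hashed into a fixed number of buckets followed by a constant
seeded random projection.  It is pure — output depends only on (sequence,
spec) — and yields linearly separable classes when sequences share motifs,
which is all the downstream pipeline needs to be exercised end to end.

External embedders plug in through :func:`register_embedder`: any callable
mapping a sequence to a 1-D numpy vector of the declared dimension.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np

from .sequence_io import GenomeTable

__all__ = [
    "EmbedderSpec",
    "EmbeddingMatrix",
    "mock_spec",
    "embed",
    "embed_table",
    "register_embedder",
    "sequence_digest",
]

# residues the mock embedder accepts: 20 standard + ambiguity codes the
# admissibility filter lets through (B, Z, X, U, O; "J" is filtered upstream)
_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBZXUO")

_KMER = 3
# bucket space much larger than the k-mers of one protein, so chance
# bucket collisions between unrelated sequences stay rare and shared-motif
# signal dominates the projected features
_N_BUCKETS = 4096


@dataclass(frozen=True)
class EmbedderSpec:
    """Declares which embedder produces vectors and what they look like.

    ``frozen`` is always True: embedder parameters are never trained.
    ``alphabet_policy`` records how ambiguity codes (B, Z, X, U, O) are
    treated; the mock hashes them like any residue ("hash").  ``pooling``
    records how per-residue representations collapse to one vector for
    external models ("mean" assumed).
    """

    name: str
    dimension: int
    frozen: bool = True
    pooling: str = "mean"
    alphabet_policy: str = "hash"

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("embedding dimension must be positive")
        if not self.frozen:
            raise ValueError("embedders are frozen by contract")


def mock_spec(dimension: int = 1024) -> EmbedderSpec:
    """Spec for the built-in k-mer hashing mock embedder.

    The default dimension keeps random-projection cross-talk between
    unrelated sequences (which scales as 1/sqrt(D)) well below genuine
    shared-motif similarity; smaller D is fine for tests that only need
    within-family separation.
    """
    return EmbedderSpec(name="mock-kmer", dimension=dimension)


# ---------------------------------------------------------------------------
# mock embedder internals

_bucket_cache: dict[str, int] = {}


def _bucket(kmer: str) -> int:
    b = _bucket_cache.get(kmer)
    if b is None:
        h = hashlib.blake2b(kmer.encode(), digest_size=8).digest()
        b = int.from_bytes(h, "big") % _N_BUCKETS
        _bucket_cache[kmer] = b
    return b


_projection_cache: dict[int, np.ndarray] = {}


def _projection(dimension: int) -> np.ndarray:
    """Fixed Gaussian projection, seeded from a constant: pure across runs."""
    P = _projection_cache.get(dimension)
    if P is None:
        rng = np.random.default_rng(20230327)
        P = rng.standard_normal((_N_BUCKETS, dimension))
        _projection_cache[dimension] = P
    return P


def _mock_embed(sequence: str, dimension: int) -> np.ndarray:
    counts = np.zeros(_N_BUCKETS)
    n = max(len(sequence) - _KMER + 1, 0)
    if n == 0:  # shorter than one k-mer: hash the whole sequence
        counts[_bucket(sequence)] = 1.0
        n = 1
    else:
        for i in range(n):
            counts[_bucket(sequence[i : i + _KMER])] += 1.0
    # unit-normalised counts through a unit-variance projection keep the
    # feature scale O(1) regardless of sequence length
    return (counts / np.linalg.norm(counts)) @ _projection(dimension)


# ---------------------------------------------------------------------------
# embedder registry

_EMBEDDERS: dict[str, Callable[[str, EmbedderSpec], np.ndarray]] = {}


def register_embedder(
    name: str, fn: Callable[[str, EmbedderSpec], np.ndarray]
) -> None:
    """Register an external embedder adapter under ``name``.

    ``fn(sequence, spec)`` must return a finite 1-D vector of
    ``spec.dimension`` and be deterministic for fixed inputs.
    """
    _EMBEDDERS[name] = fn


register_embedder("mock-kmer", lambda s, spec: _mock_embed(s, spec.dimension))


def embed(sequence: str, spec: EmbedderSpec) -> np.ndarray:
    """Embed one admissible protein sequence into a D-vector.

    Deterministic: identical (sequence, spec) give bitwise-identical output.
    """
    if not sequence:
        raise ValueError("constraint violated: empty sequence")
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise ValueError(
            f"constraint violated: invalid residue(s) {sorted(bad)} in sequence"
        )
    try:
        fn = _EMBEDDERS[spec.name]
    except KeyError:
        raise KeyError(f"no embedder registered under {spec.name!r}") from None
    vec = np.asarray(fn(sequence, spec), dtype=np.float64)
    if vec.shape != (spec.dimension,):
        raise ValueError(
            f"embedder {spec.name!r} returned shape {vec.shape}, "
            f"expected ({spec.dimension},)"
        )
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"embedder {spec.name!r} returned non-finite values")
    return vec


def sequence_digest(sequence: str) -> str:
    return hashlib.sha256(sequence.encode()).hexdigest()


@dataclass
class EmbeddingMatrix:
    """Per-gene embedding vectors with a shared spec."""

    spec: EmbedderSpec
    gene_ids: list[str]
    matrix: np.ndarray  # (n_genes, D)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.gene_ids), self.spec.dimension):
            raise ValueError("embedding matrix shape disagrees with spec")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def get(self, gene_id: str) -> np.ndarray:
        return self.matrix[self._index[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index


def embed_table(
    genes: GenomeTable, spec: EmbedderSpec, cache: str | Path | None = None
) -> EmbeddingMatrix:
    """Embed every gene of a genome; optionally read/extend an HDF5 cache.

    The cache is keyed by (embedder name, sequence digest): warm entries are
    reused, cold ones computed and appended.  A cache written under a
    different dimension than ``spec`` demands is rejected.
    """
    cached: dict[str, np.ndarray] = {}
    if cache is not None and Path(cache).exists():
        with h5py.File(cache, "r") as fh:
            if fh.attrs["embedder_name"] != spec.name:
                raise ValueError(
                    f"cache built with embedder {fh.attrs['embedder_name']!r}, "
                    f"spec demands {spec.name!r}"
                )
            if int(fh.attrs["dimension"]) != spec.dimension:
                raise ValueError(
                    f"cache dimension {int(fh.attrs['dimension'])} does not "
                    f"match spec dimension {spec.dimension}"
                )
            digests = [d.decode() for d in fh["digests"][:]]
            mat = fh["embeddings"][:]
            cached = dict(zip(digests, mat))

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    new: dict[str, np.ndarray] = {}
    for g in genes.genes():
        digest = sequence_digest(g.sequence)
        vec = cached.get(digest)
        if vec is None:
            vec = embed(g.sequence, spec)
            new[digest] = vec
        gene_ids.append(g.gene_id)
        rows.append(np.asarray(vec, dtype=np.float64))

    if cache is not None and new:
        merged = {**cached, **new}
        keys = sorted(merged)
        with h5py.File(cache, "w") as fh:
            fh.attrs["embedder_name"] = spec.name
            fh.attrs["dimension"] = spec.dimension
            fh.attrs["pooling"] = spec.pooling
            fh.attrs["alphabet_policy"] = spec.alphabet_policy
            fh.create_dataset(
                "digests", data=np.array(keys, dtype=h5py.string_dtype())
            )
            fh.create_dataset(
                "embeddings", data=np.stack([merged[k] for k in keys])
            )

    return EmbeddingMatrix(spec=spec, gene_ids=gene_ids, matrix=np.stack(rows))
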