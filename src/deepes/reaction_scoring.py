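"""Per-gene, per-reaction probabilities and the gene x reaction matrix.

One enzyme reaction is often annotated with several reaction classes.  The
probability that a gene performs a reaction is the geometric mean of its
per-RClass classifier outputs over *all* of the reaction's RClasses.  If any
RClass of a reaction lacks a trained model the reaction is unscorable for
every gene (strict policy: a partial geometric mean would silently change
the statistic's meaning), and its matrix column is MISSING (NaN).

All products are taken in log space with a small floor so a saturated
sigmoid output of exactly 0 cannot collapse the mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import EmbeddingMatrix
from .rclass_classifier import ModelRegistry
from .sequence_io import GenomeTable

__all__ = [
    "ReactionSpec",
    "PathwaySpec",
    "ProbabilityMatrix",
    "MISSING",
    "PathwayNotScreenableError",
    "geometric_mean",
    "reaction_probability",
    "build_probability_matrix",
]

#: sentinel for an unscorable (gene, reaction) entry
MISSING = float("nan")

DEFAULT_FLOOR = 1e-12


class PathwayNotScreenableError(ValueError):
    """Every reaction of the pathway lacks at least one classifier."""


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction, identified by the non-empty set of RClasses it carries."""

    reaction_id: str
    rclass_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rclass_ids:
            raise ValueError(f"reaction {self.reaction_id!r} has no RClasses")
        if len(set(self.rclass_ids)) != len(self.rclass_ids):
            raise ValueError(f"duplicate RClasses in reaction {self.reaction_id!r}")


@dataclass(frozen=True)
class PathwaySpec:
    """An ordered chain of sequential reactions (default length L = 3)."""

    pathway_id: str
    reactions: tuple[ReactionSpec, ...]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError("pathway must contain at least one reaction")
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("reaction_ids must be unique within a pathway")

    def __len__(self) -> int:
        return len(self.reactions)

    @staticmethod
    def from_json(path: str | Path) -> "PathwaySpec":
        doc = json.loads(Path(path).read_text())
        return PathwaySpec(
            pathway_id=doc["pathway_id"],
            reactions=tuple(
                ReactionSpec(r["reaction_id"], tuple(r["rclass_ids"]))
                for r in doc["reactions"]
            ),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pathway_id": self.pathway_id,
            "reactions": [
                {"reaction_id": r.reaction_id, "rclass_ids": list(r.rclass_ids)}
                for r in self.reactions
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def geometric_mean(values, floor: float = DEFAULT_FLOOR) -> float:
    """exp(mean(log(max(v, floor)))) over a non-empty list of probabilities."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("geometric mean of an empty list is undefined")
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("values must lie in [0, 1]")
    out = math.exp(float(np.mean(np.log(np.maximum(v, floor)))))
    return min(max(out, floor), 1.0)


def reaction_probability(
    gene_id: str,
    reaction: ReactionSpec,
    registry: ModelRegistry,
    embeddings: EmbeddingMatrix,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Geometric mean of the gene's per-RClass probabilities for a reaction.

    Returns MISSING (NaN) when any of the reaction's RClasses has no model.
    """
    if any(rc not in registry for rc in reaction.rclass_ids):
        return MISSING
    emb = embeddings.get(gene_id)
    probs = [registry.models[rc].predict(emb) for rc in reaction.rclass_ids]
    return geometric_mean(probs, floor=floor)


@dataclass
class ProbabilityMatrix:
    """Genes x reactions probabilities with per-gene contig/rank metadata.

    ``values[i, j]`` is the probability that gene i performs reaction j, or
    NaN when reaction j is unscorable.  ``gene_meta`` has columns
    gene_id, contig_id, rank, aligned with the rows of ``values``.
    """

    gene_meta: pd.DataFrame
    reaction_ids: list[str]
    values: np.ndarray
    pathway: PathwaySpec | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_meta), len(self.reaction_ids)):
            raise ValueError("values shape disagrees with gene/reaction lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def scorable_reactions(self) -> list[int]:
        """Column indices whose reaction has a full set of classifiers."""
        return [
            j
            for j in range(len(self.reaction_ids))
            if np.all(np.isfinite(self.values[:, j]))
        ]

    def to_tsv(self, path: str | Path) -> None:
        df = self.gene_meta.copy()
        for j, rid in enumerate(self.reaction_ids):
            df[rid] = self.values[:, j]
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def build_probability_matrix(
    genes: GenomeTable,
    pathway: PathwaySpec,
    registry: ModelRegistry,
    embeddings: EmbeddingMatrix,
    floor: float = DEFAULT_FLOOR,
) -> ProbabilityMatrix:
    """Dense gene x reaction matrix over admissible, embedded genes.

    Unscorable reactions yield all-MISSING columns; if every reaction is
    unscorable the pathway cannot be screened at all and an error is raised.
    Per-RClass model inference is batched across genes, and per-reaction
    integration happens in log space.
    """
    records = list(genes.genes())
    gene_ids = [g.gene_id for g in records]
    X = np.stack([embeddings.get(g) for g in gene_ids]) if records else np.empty((0, 0))

    scorable = [
        r for r in pathway.reactions if all(rc in registry for rc in r.rclass_ids)
    ]
    if not scorable:
        raise PathwayNotScreenableError(
            f"pathway {pathway.pathway_id!r} not screenable: no reaction has "
            f"a complete set of classifiers"
        )

    # batch per-RClass predictions once, reuse across reactions
    needed = {rc for r in scorable for rc in r.rclass_ids}
    logp: dict[str, np.ndarray] = {}
    for rc in sorted(needed):
        p = registry.models[rc].predict_batch(X)
        logp[rc] = np.log(np.maximum(p, floor))

    values = np.full((len(records), len(pathway.reactions)), np.nan)
    for j, r in enumerate(pathway.reactions):
        if r not in scorable:
            continue
        mean_log = np.mean([logp[rc] for rc in r.rclass_ids], axis=0)
        values[:, j] = np.clip(np.exp(mean_log), floor, 1.0)

    gene_meta = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "contig_id": [g.contig_id for g in records],
            "rank": [g.rank for g in records],
        }
    )
    return ProbabilityMatrix(
        gene_meta=gene_meta,
        reaction_ids=[r.reaction_id for r in pathway.reactions],
        values=values,
        pathway=pathway,
    )
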