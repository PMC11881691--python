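"""Sliding-window screening for gene clusters encoding sequential reactions.

The screening statistic: slide a frame of W consecutive genes (default 10)
along each contig, one gene at a time, and score each frame by the best
*injective* assignment of window genes to the pathway's reactions — each
reaction takes the gene giving it the highest probability, but no gene may
serve two reactions — and take the geometric mean of the assigned
probabilities.  A frame scoring at or above the threshold (default 0.99) is
a hit, and its assignment names the candidate genes.

The maximisation is an assignment problem on log-probabilities.  The default
solver enumerates all injective mappings exactly (at the W = 10, L = 3
defaults that is 720 assignments per frame, vectorised); a Hungarian solver
(`scipy.optimize.linear_sum_assignment`) is available for larger W*L and
must agree with enumeration.  A per-reaction greedy argmax is *not*
equivalent and is deliberately not offered: with probabilities
[[0.9, 0.8], [0.89, 0.1]] greedy forces the pairing (0.9, 0.1) while the
optimum is (0.89, 0.8).

Reactions with no trained classifier are excluded from a frame's mean and
the frame is flagged ``partial``; strict mode refuses partial frames.
Windows never span contig boundaries; terminal truncated windows are scored
while they still hold at least as many genes as scorable reactions, which
keeps short contigs (common in MAGs) screenable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .embedding import EmbedderSpec, embed_table
from .rclass_classifier import ModelRegistry
from .reaction_scoring import (
    DEFAULT_FLOOR,
    PathwaySpec,
    ProbabilityMatrix,
    build_probability_matrix,
)
from .sequence_io import GenomeTable

__all__ = [
    "FrameScore",
    "ScreenResult",
    "score_frame",
    "slide_windows",
    "screen",
    "rank_report",
    "write_frames_tsv",
    "DEFAULT_WINDOW",
    "DEFAULT_THRESHOLD",
]

DEFAULT_WINDOW = 10
DEFAULT_THRESHOLD = 0.99


@dataclass(frozen=True)
class FrameScore:
    """One scored window and its optimal gene-to-reaction assignment."""

    contig_id: str
    start_rank: int
    window_gene_ids: tuple[str, ...]
    assignment: dict[str, str]  # reaction_id -> gene_id, injective on genes
    score: float
    partial: bool = False  # some reactions were unscorable and excluded
    window_ranks: tuple[int, ...] = ()  # genomic ranks (may have gaps)

    @property
    def assigned_genes(self) -> frozenset[str]:
        return frozenset(self.assignment.values())


@dataclass
class ScreenResult:
    """All frames of one genome against one pathway, plus the hits."""

    genome_id: str
    pathway_id: str
    frames: list[FrameScore]
    hits: list[FrameScore]
    parameters: dict = field(default_factory=dict)

    def max_score(self) -> float:
        return max((f.score for f in self.frames), default=float("-inf"))

    def top_frame(self) -> FrameScore | None:
        if not self.frames:
            return None
        return max(self.frames, key=lambda f: f.score)


_PERM_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _perm_array(n_genes: int, k: int) -> np.ndarray:
    """All injective k-tuples over n genes, lexicographic order, shape (P, k)."""
    key = (n_genes, k)
    arr = _PERM_CACHE.get(key)
    if arr is None:
        arr = np.array(list(permutations(range(n_genes), k)), dtype=np.intp)
        _PERM_CACHE[key] = arr
    return arr


def score_frame(
    probs: np.ndarray,
    gene_ids: list[str],
    reaction_ids: list[str],
    contig_id: str = "",
    start_rank: int = 0,
    floor: float = DEFAULT_FLOOR,
    solver: str = "exact",
    collinear: bool = False,
    gene_ranks: list[int] | None = None,
) -> FrameScore:
    """Score one window: best injective assignment, geometric-mean score.

    ``probs`` is (n_genes, n_reactions) with NaN columns for unscorable
    reactions.  Those columns are dropped from the mean and flagged via
    ``partial``.  Ties between equal-scoring assignments go to the
    lexicographically smallest by (reaction order, gene rank).
    ``collinear=True`` restricts to assignments whose gene order follows the
    reaction order.
    """
    probs = np.asarray(probs, float)
    n_genes = probs.shape[0]
    scorable = [j for j in range(probs.shape[1]) if np.all(np.isfinite(probs[:, j]))]
    if not scorable:
        raise ValueError("frame has no scorable reaction")
    k = len(scorable)
    if k > n_genes:
        raise ValueError(
            f"{k} scorable reactions but only {n_genes} genes in window"
        )
    logp = np.log(np.maximum(probs[:, scorable], floor))  # (n_genes, k)

    if solver == "exact":
        perms = _perm_array(n_genes, k)
        if collinear:
            perms = perms[np.all(np.diff(perms, axis=1) > 0, axis=1)]
        totals = logp[perms, np.arange(k)].sum(axis=1)
        best = int(np.argmax(totals))  # first max = lexicographically smallest
        chosen = perms[best]
        best_total = float(totals[best])
    elif solver == "hungarian":
        if collinear:
            raise ValueError("collinear assignments require the exact solver")
        rows, cols = linear_sum_assignment(-logp)
        chosen = np.empty(k, dtype=np.intp)
        chosen[cols] = rows
        best_total = float(logp[chosen, np.arange(k)].sum())
    else:
        raise ValueError(f"unknown solver {solver!r}")

    score = float(np.exp(best_total / k))
    assignment = {
        reaction_ids[scorable[j]]: gene_ids[int(chosen[j])] for j in range(k)
    }
    return FrameScore(
        contig_id=contig_id,
        start_rank=start_rank,
        window_gene_ids=tuple(gene_ids),
        assignment=assignment,
        score=min(score, 1.0),
        partial=k < probs.shape[1],
        window_ranks=tuple(gene_ranks) if gene_ranks is not None else (),
    )


def slide_windows(
    matrix: ProbabilityMatrix,
    W: int = DEFAULT_WINDOW,
    strict: bool = False,
    solver: str = "exact",
    collinear: bool = False,
    floor: float = DEFAULT_FLOOR,
) -> list[FrameScore]:
    """Score every window of up to W consecutive genes, per contig, stride 1.

    Windows never cross contig boundaries.  Terminal windows shorter than W
    are still scored while they hold at least as many genes as scorable
    reactions; a contig with fewer genes than that yields no frames.  With
    ``strict=True`` frames with unscorable reactions are refused entirely
    (no partial frames in the output).
    """
    scorable = matrix.scorable_reactions()
    if not scorable:
        raise ValueError("no scorable reaction in probability matrix")
    k = len(scorable)
    if W < k:
        raise ValueError(f"window W={W} smaller than {k} scorable reactions")
    if strict and k < len(matrix.reaction_ids):
        return []

    frames: list[FrameScore] = []
    meta = matrix.gene_meta
    for contig_id, grp in meta.groupby("contig_id", sort=False):
        idx = grp.index.to_numpy()
        n = len(idx)
        if n < k:
            continue
        for start in range(n):
            stop = min(start + W, n)
            if stop - start < k:
                break
            rows = idx[start:stop]
            frames.append(
                score_frame(
                    matrix.values[rows],
                    gene_ids=meta["gene_id"].iloc[rows].tolist(),
                    reaction_ids=matrix.reaction_ids,
                    contig_id=str(contig_id),
                    start_rank=int(meta["rank"].iloc[rows[0]]),
                    floor=floor,
                    solver=solver,
                    collinear=collinear,
                    gene_ranks=meta["rank"].iloc[rows].tolist(),
                )
            )
    return frames


def screen(
    genomes: list[GenomeTable],
    pathway: PathwaySpec,
    registry: ModelRegistry,
    W: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    embedder_spec: EmbedderSpec | None = None,
    strict: bool = False,
    solver: str = "exact",
    collinear: bool = False,
) -> list[ScreenResult]:
    """Screen genomes for windows likely to encode the pathway's reactions.

    Genes are embedded with the registry's embedder spec (overridable),
    scored per reaction, and window-scanned; hits are frames with score at
    or above the threshold.
    """
    spec = embedder_spec or registry.embedder_spec
    results: list[ScreenResult] = []
    for genome in genomes:
        embeddings = embed_table(genome, spec)
        matrix = build_probability_matrix(genome, pathway, registry, embeddings)
        frames = slide_windows(
            matrix, W=W, strict=strict, solver=solver, collinear=collinear
        )
        results.append(
            ScreenResult(
                genome_id=genome.genome_id,
                pathway_id=pathway.pathway_id,
                frames=frames,
                hits=[f for f in frames if f.score >= threshold],
                parameters={
                    "W": W,
                    "L": len(pathway),
                    "threshold": threshold,
                    "registry_digest": registry.manifest_digest(),
                },
            )
        )
    return results


def rank_report(results: list[ScreenResult], top_k: int | None = None) -> pd.DataFrame:
    """Genomes ranked by their best frame score, descending; ties by id."""
    rows = []
    for r in sorted(results, key=lambda r: (-r.max_score(), r.genome_id)):
        top = r.top_frame()
        rows.append(
            {
                "genome_id": r.genome_id,
                "pathway_id": r.pathway_id,
                "max_score": r.max_score(),
                "n_hits": len(r.hits),
                "top_contig": top.contig_id if top else "",
                "top_start_rank": top.start_rank if top else -1,
            }
        )
    df = pd.DataFrame(rows)
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)


def write_frames_tsv(results: list[ScreenResult], path: str | Path) -> None:
    """One row per frame: location, score, hit/partial flags, assignment."""
    rows = []
    for r in results:
        for f in r.frames:
            end_rank = (
                f.window_ranks[-1]
                if f.window_ranks
                else f.start_rank + len(f.window_gene_ids) - 1
            )
            rows.append(
                {
                    "genome_id": r.genome_id,
                    "contig_id": f.contig_id,
                    "start_rank": f.start_rank,
                    "end_rank": end_rank,
                    "score": f.score,
                    "hit": int(f.score >= r.parameters.get("threshold", DEFAULT_THRESHOLD)),
                    "partial": int(f.partial),
                    "assignment": ";".join(
                        f"{rid}={gid}" for rid, gid in sorted(f.assignment.items())
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
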