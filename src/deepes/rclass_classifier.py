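"""Per-reaction-class binary classifiers over protein embeddings.

Predicting reaction classes is multi-label — one enzyme reaction can carry
several RClass annotations — so it is decomposed into independent binary
classifiers, one per RClass.  Each classifier is a small feed-forward head
on top of the frozen embedder: one hidden layer (ReLU), dropout after the
hidden activation during training, and a sigmoid output giving the
probability that the input gene performs the RClass.

Class imbalance is severe (most genes are negatives for any given RClass),
so training minimises a class-weighted binary cross-entropy

    L(p, y) = -[ w * y * log p + (1 - y) * log(1 - p) ],   w = |neg| / |pos|

which reduces to plain BCE at w = 1.  Hyperparameters (epochs, hidden size,
learning rate, dropout) are selected by grid search with stratified k-fold
cross-validation, comparing mean area under the precision-recall curve
(AUPRC) — the appropriate criterion under heavy imbalance.

The optimiser is Adam with batch size 256 and a seed-controlled shuffle;
training is reproducible from (seed, dataset, hyperparameters) and invariant
to the order in which examples are supplied.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .embedding import EmbedderSpec

__all__ = [
    "LabeledExample",
    "SequenceExample",
    "RClassDataset",
    "Hyperparameters",
    "RClassModel",
    "ModelRegistry",
    "UntrainableRClassError",
    "DegenerateDatasetError",
    "build_rclass_dataset",
    "weighted_loss",
    "train_classifier",
    "predict_rclass",
    "auprc",
    "grid_search_cv",
    "table1_grid",
    "save_registry",
    "load_registry",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "DEFAULT_HYPERPARAMETERS",
    "BATCH_SIZE",
]

BATCH_SIZE = 256
_EPS = 1e-12


class UntrainableRClassError(ValueError):
    """No positive examples remain for the RClass — the failure mode of
    masking every orthologous group carrying a reaction class."""


class DegenerateDatasetError(ValueError):
    """No negative examples: the class weight |neg|/|pos| is undefined."""


@dataclass(frozen=True)
class LabeledExample:
    """One training case: an embedded gene and its (possibly empty) label set."""

    gene_id: str
    embedding: np.ndarray
    rclass_ids: frozenset[str]

    @staticmethod
    def make(gene_id: str, embedding: np.ndarray, rclass_ids) -> "LabeledExample":
        return LabeledExample(gene_id, np.asarray(embedding, float), frozenset(rclass_ids))


@dataclass(frozen=True)
class SequenceExample:
    """A sequence-level training case, before embedding.

    ``ko_id`` is the orthologous-group identifier that linked the sequence to
    its reaction classes; the pseudo-orphan masking protocol removes whole
    KO groups from training, so the corpus must carry it.
    """

    gene_id: str
    sequence: str
    rclass_ids: frozenset[str]
    ko_id: str | None = None


@dataclass
class RClassDataset:
    """Binary one-vs-rest dataset for a single reaction class.

    Negatives are all examples not labelled with the RClass — enzymes of
    other classes and non-enzymes alike.  ``class_weight`` defaults to
    |negatives| / |positives| but may be overridden.
    """

    rclass_id: str
    X: np.ndarray  # (n, D)
    y: np.ndarray  # (n,) in {0,1}
    gene_ids: list[str]
    class_weight: float

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.y) - self.y.sum())


def build_rclass_dataset(
    examples: list[LabeledExample],
    rclass_id: str,
    negative_subsample: int | None = None,
    seed: int = 0,
) -> RClassDataset:
    """Split examples into positives/negatives for one RClass.

    Raises :class:`UntrainableRClassError` when no example carries the
    RClass, and :class:`DegenerateDatasetError` when every example does
    (the weight |neg|/|pos| is undefined).  ``negative_subsample`` keeps a
    seeded random subset of negatives for very large corpora.
    """
    pos = [e for e in examples if rclass_id in e.rclass_ids]
    neg = [e for e in examples if rclass_id not in e.rclass_ids]
    if not pos:
        raise UntrainableRClassError(
            f"untrainable RClass {rclass_id!r}: no positive examples"
        )
    if not neg:
        raise DegenerateDatasetError(
            f"degenerate dataset for {rclass_id!r}: no negative examples"
        )
    if negative_subsample is not None and negative_subsample < len(neg):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(neg), size=negative_subsample, replace=False)
        neg = [neg[i] for i in sorted(idx)]
    ordered = pos + neg
    X = np.stack([e.embedding for e in ordered])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return RClassDataset(
        rclass_id=rclass_id,
        X=X,
        y=y,
        gene_ids=[e.gene_id for e in ordered],
        class_weight=len(neg) / len(pos),
    )


def weighted_loss(predicted_prob, label, class_weight: float):
    """Class-weighted binary cross-entropy; the weight multiplies the
    positive-class term only.  Accepts scalars or arrays; probabilities are
    clamped away from 0 and 1 before the log."""
    p = np.clip(np.asarray(predicted_prob, float), _EPS, 1.0 - _EPS)
    y = np.asarray(label, float)
    return -(class_weight * y * np.log(p) + (1.0 - y) * np.log1p(-p))


@dataclass(frozen=True)
class Hyperparameters:
    epochs: int = 20
    hidden_size: int = 64
    learning_rate: float = 1e-3
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.hidden_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, hidden_size and learning_rate must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


DEFAULT_HYPERPARAMETERS = Hyperparameters()


def table1_grid() -> list[Hyperparameters]:
    """The published 108-cell hyperparameter grid:
    epochs {1,5,10,20} x hidden {64,128,256} x lr {1e-2,5e-3,1e-3}
    x dropout {0.1,0.25,0.5}."""
    return [
        Hyperparameters(e, h, lr, d)
        for e, h, lr, d in product(
            (1, 5, 10, 20), (64, 128, 256), (1e-2, 5e-3, 1e-3), (0.1, 0.25, 0.5)
        )
    ]


@dataclass
class RClassModel:
    """A trained binary head for one reaction class.

    ``weights`` holds W1 (D,H), b1 (H,), W2 (H,), b2 (scalar).  Inference is
    deterministic: dropout is disabled outside training.
    """

    rclass_id: str
    embed_dim: int
    hyperparameters: Hyperparameters
    weights: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def predict(self, embedding: np.ndarray) -> float:
        x = np.asarray(embedding, float)
        if x.shape != (self.embed_dim,):
            raise ValueError(
                f"embedding dimension {x.shape} does not match model "
                f"dimension ({self.embed_dim},)"
            )
        return float(self.predict_batch(x[None, :])[0])

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.embed_dim:
            raise ValueError(
                f"expected (n, {self.embed_dim}) embeddings, got {X.shape}"
            )
        w = self.weights
        h = np.maximum(X @ w["W1"] + w["b1"], 0.0)
        z = h @ w["W2"] + w["b2"]
        return _sigmoid(z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_classifier(
    dataset: RClassDataset,
    hp: Hyperparameters = DEFAULT_HYPERPARAMETERS,
    seed: int = 0,
    embedder_name: str = "",
) -> RClassModel:
    """Train one binary head by Adam on the class-weighted BCE.

    Reproducible from (seed, dataset, hp); the dataset is put into a
    canonical order (sorted by gene_id) before the seeded shuffle, so
    training is invariant to the order examples were supplied in.
    """
    order = np.argsort(np.array(dataset.gene_ids))
    X = np.asarray(dataset.X, float)[order]
    y = np.asarray(dataset.y, float)[order]
    n, D = X.shape
    H = hp.hidden_size
    w = dataset.class_weight
    rng = np.random.default_rng(seed)

    W1 = rng.standard_normal((D, H)) * np.sqrt(2.0 / D)
    b1 = np.zeros(H)
    W2 = rng.standard_normal(H) * np.sqrt(1.0 / H)
    b2 = 0.0
    params = [W1, b1, W2, np.array(b2)]

    # Adam state
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for _ in range(hp.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, BATCH_SIZE):
            idx = perm[start : start + BATCH_SIZE]
            xb, yb = X[idx], y[idx]
            B = len(idx)

            a = xb @ params[0] + params[1]
            h = np.maximum(a, 0.0)
            if hp.dropout_rate > 0.0:
                mask = (rng.random(h.shape) >= hp.dropout_rate) / (
                    1.0 - hp.dropout_rate
                )
                h = h * mask
            else:
                mask = None
            z = h @ params[2] + float(params[3])
            p = _sigmoid(z)

            loss = float(np.mean(weighted_loss(p, yb, w)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss while training {dataset.rclass_id!r} "
                    f"(hp={hp}, seed={seed})"
                )

            # d(mean loss)/dz = (1 + (w-1) y) * (p - y) / B
            s = 1.0 + (w - 1.0) * yb
            dz = s * (p - yb) / B
            gW2 = h.T @ dz
            gb2 = np.array(dz.sum())
            dh = np.outer(dz, params[2])
            if mask is not None:
                dh = dh * mask
            da = dh * (a > 0.0)
            gW1 = xb.T @ da
            gb1 = da.sum(axis=0)

            t += 1
            for i, g in enumerate((gW1, gb1, gW2, gb2)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                params[i] = params[i] - hp.learning_rate * mhat / (
                    np.sqrt(vhat) + eps
                )

    return RClassModel(
        rclass_id=dataset.rclass_id,
        embed_dim=D,
        hyperparameters=hp,
        weights={
            "W1": params[0],
            "b1": params[1],
            "W2": params[2],
            "b2": np.asarray(params[3]),
        },
        training_meta={
            "seed": seed,
            "n_pos": dataset.n_pos,
            "n_neg": dataset.n_neg,
            "class_weight": dataset.class_weight,
            "embedder_name": embedder_name,
            "optimizer": "adam",
            "batch_size": BATCH_SIZE,
            "training_gene_ids": sorted(dataset.gene_ids),
        },
    )


def predict_rclass(model: RClassModel, embedding: np.ndarray) -> float:
    """Probability that the embedded gene performs the model's RClass."""
    return model.predict(embedding)


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, by the step-wise sum over
    score thresholds (average precision).  Requires both classes present."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    if len(y) != len(s) or len(y) == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if y.min() == y.max():
        raise ValueError("AUPRC undefined: labels contain a single class")
    return float(average_precision_score(y, s))


@dataclass
class GridSearchReport:
    rows: list[dict]  # hyperparameters + mean/fold AUPRCs

    def __len__(self) -> int:
        return len(self.rows)


def grid_search_cv(
    examples: list[LabeledExample],
    rclass_id: str,
    grid: list[Hyperparameters] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[Hyperparameters, GridSearchReport]:
    """Select hyperparameters by stratified k-fold CV on mean AUPRC.

    Ties are broken toward the cheaper model: fewer epochs, smaller hidden
    layer, larger learning rate, smaller dropout, in that order.
    """
    if grid is None:
        grid = table1_grid()
    ds_full = build_rclass_dataset(examples, rclass_id)
    if ds_full.n_pos < folds:
        raise ValueError(
            f"only {ds_full.n_pos} positives for {rclass_id!r}: stratified "
            f"{folds}-fold CV impossible; use fewer folds"
        )
    order = np.argsort(np.array(ds_full.gene_ids))
    X, y = ds_full.X[order], ds_full.y[order]
    ids = [ds_full.gene_ids[i] for i in order]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    rows = []
    for hp in grid:
        fold_scores = []
        for k, (tr, te) in enumerate(splits):
            ds = RClassDataset(
                rclass_id=rclass_id,
                X=X[tr],
                y=y[tr],
                gene_ids=[ids[i] for i in tr],
                class_weight=float((y[tr] == 0).sum() / max((y[tr] == 1).sum(), 1)),
            )
            model = train_classifier(ds, hp, seed=seed + k)
            fold_scores.append(auprc(model.predict_batch(X[te]), y[te]))
        rows.append(
            {
                "epochs": hp.epochs,
                "hidden_size": hp.hidden_size,
                "learning_rate": hp.learning_rate,
                "dropout_rate": hp.dropout_rate,
                "mean_auprc": float(np.mean(fold_scores)),
                "fold_auprc": fold_scores,
            }
        )

    best = min(
        zip(grid, rows),
        key=lambda c: (
            -c[1]["mean_auprc"],
            c[0].epochs,
            c[0].hidden_size,
            -c[0].learning_rate,
            c[0].dropout_rate,
        ),
    )[0]
    return best, GridSearchReport(rows=rows)


# ---------------------------------------------------------------------------
# model registry persistence

@dataclass
class ModelRegistry:
    """All trained RClass heads sharing one embedder spec."""

    embedder_spec: EmbedderSpec
    models: dict[str, RClassModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.models.values():
            if m.embed_dim != self.embedder_spec.dimension:
                raise ValueError(
                    f"model {m.rclass_id!r} has dimension {m.embed_dim}, "
                    f"registry spec demands {self.embedder_spec.dimension}"
                )

    def add(self, model: RClassModel) -> None:
        if model.embed_dim != self.embedder_spec.dimension:
            raise ValueError(
                f"model dimension {model.embed_dim} does not match registry "
                f"dimension {self.embedder_spec.dimension}"
            )
        self.models[model.rclass_id] = model

    def __contains__(self, rclass_id: str) -> bool:
        return rclass_id in self.models

    def manifest(self) -> dict:
        return {
            "embedder_spec": {
                "name": self.embedder_spec.name,
                "dimension": self.embedder_spec.dimension,
                "frozen": self.embedder_spec.frozen,
                "pooling": self.embedder_spec.pooling,
                "alphabet_policy": self.embedder_spec.alphabet_policy,
            },
            "models": {
                rid: {
                    "hyperparameters": {
                        "epochs": m.hyperparameters.epochs,
                        "hidden_size": m.hyperparameters.hidden_size,
                        "learning_rate": m.hyperparameters.learning_rate,
                        "dropout_rate": m.hyperparameters.dropout_rate,
                    },
                    "training_meta": {
                        k: v
                        for k, v in m.training_meta.items()
                        if k != "training_gene_ids"
                    },
                }
                for rid, m in sorted(self.models.items())
            },
        }

    def manifest_digest(self) -> str:
        blob = json.dumps(self.manifest(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def save_registry(registry: ModelRegistry, path: str | Path) -> None:
    """Persist a registry as a directory: JSON manifest + one .npz per model."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = registry.manifest()
    manifest["training_gene_ids"] = {
        rid: m.training_meta.get("training_gene_ids", [])
        for rid, m in sorted(registry.models.items())
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for rid, m in registry.models.items():
        np.savez(path / f"{rid}.npz", **m.weights)


def load_registry(
    path: str | Path, expected_spec: EmbedderSpec | None = None
) -> ModelRegistry:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    es = manifest["embedder_spec"]
    spec = EmbedderSpec(
        name=es["name"],
        dimension=int(es["dimension"]),
        frozen=bool(es["frozen"]),
        pooling=es["pooling"],
        alphabet_policy=es["alphabet_policy"],
    )
    if expected_spec is not None and spec != expected_spec:
        raise ValueError(
            f"registry embedder spec {spec} does not match expected "
            f"{expected_spec}"
        )
    models: dict[str, RClassModel] = {}
    for rid, info in manifest["models"].items():
        with np.load(path / f"{rid}.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        meta = dict(info["training_meta"])
        meta["training_gene_ids"] = manifest.get("training_gene_ids", {}).get(rid, [])
        models[rid] = RClassModel(
            rclass_id=rid,
            embed_dim=spec.dimension,
            hyperparameters=Hyperparameters(**info["hyperparameters"]),
            weights=weights,
            training_meta=meta,
        )
    return ModelRegistry(embedder_spec=spec, models=models)


# ---------------------------------------------------------------------------
# training-pair TSV I/O

def read_pairs_tsv(tsv_path: str | Path, fasta_path: str | Path) -> list[SequenceExample]:
    """Read (gene_id, rclass_ids[, ko_id]) pairs plus companion FASTA.

    ``rclass_ids`` is comma-separated; empty means a non-enzyme example.
    """
    from Bio import SeqIO

    seqs = {
        rec.id: str(rec.seq).upper().rstrip("*")
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    out: list[SequenceExample] = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gid = row["gene_id"]
            if gid not in seqs:
                raise KeyError(f"gene {gid!r} missing from FASTA")
            labels = frozenset(
                x for x in (row.get("rclass_ids") or "").split(",") if x
            )
            out.append(
                SequenceExample(
                    gene_id=gid,
                    sequence=seqs[gid],
                    rclass_ids=labels,
                    ko_id=row.get("ko_id") or None,
                )
            )
    return out


def write_pairs_tsv(examples: list[SequenceExample], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "rclass_ids", "ko_id"])
        for e in examples:
            writer.writerow(
                [e.gene_id, ",".join(sorted(e.rclass_ids)), e.ko_id or ""]
            )
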