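"""Sequence embedding: built-in one-hot plus pluggable pretrained embedders.

Every embedder turns a normalized amino-acid sequence into an L x d
matrix (L positions after truncation/padding, d channels) plus a boolean
mask marking real residues.  One-hot over the 21-letter alphabet is
built in and dependency-free.  Pretrained protein language models
(e.g. a transformer embedder with per-layer representations, or an
mLSTM representation learner) register through :func:`register_embedder`
with an explicit layer choice; nothing in this package downloads or
ships model weights.

Because embedding quality dominates downstream performance and the best
choice is task-dependent, :func:`select_embedding` implements a feedback
loop: train one small model per candidate embedder under identical
configuration and seed, score each on a validation split, and keep the
argmax.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .records import ALPHABET, AnnotationTable

__all__ = [
    "EmbeddingMatrix",
    "EmbedderSpec",
    "one_hot_embed",
    "pool_embedding",
    "register_embedder",
    "get_embedder",
    "list_embedders",
    "embed_table",
    "select_embedding",
    "EmbeddingCache",
]

MAX_LEN_DEFAULT = 1000


@dataclass(frozen=True)
class EmbeddingMatrix:
    """L x d matrix with a residue mask and the method that produced it."""

    values: np.ndarray  # (L, d) float
    mask: np.ndarray  # (L,) bool; True at real residues
    method_tag: str

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("embedding must be a 2-D matrix")
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask length must match the matrix rows")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def length(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class EmbedderSpec:
    """Declared contract of an embedding method."""

    name: str
    width: int
    layer: int | None = None  # plugin embedders only
    pooling: str = "none"  # {"none", "mean"}

    def __post_init__(self) -> None:
        if self.pooling not in ("none", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.name == "onehot" and self.layer is not None:
            raise ValueError("layer selection applies to plugin embedders only")

    @property
    def method_tag(self) -> str:
        if self.layer is None:
            return self.name
        return f"plugin:{self.name}:layer{self.layer}"


def one_hot_embed(
    sequence: str, alphabet: str = ALPHABET, max_len: int = MAX_LEN_DEFAULT
) -> EmbeddingMatrix:
    """Indicator encoding: row i is the unit vector of residue i.

    Sequences longer than ``max_len`` are truncated; shorter ones are
    right-padded with all-zero, masked-out rows.
    """
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    index = {ch: i for i, ch in enumerate(alphabet)}
    seq = sequence[:max_len]
    values = np.zeros((max_len, len(alphabet)), dtype=np.float64)
    mask = np.zeros(max_len, dtype=bool)
    for i, ch in enumerate(seq):
        try:
            values[i, index[ch]] = 1.0
        except KeyError:
            raise ValueError(f"residue {ch!r} not in alphabet") from None
        mask[i] = True
    return EmbeddingMatrix(values=values, mask=mask, method_tag="onehot")


def pool_embedding(m: EmbeddingMatrix) -> np.ndarray:
    """Mean over real (unmasked) rows; padding never leaks into the pool."""
    if not m.mask.any():
        raise ValueError("cannot pool a fully masked embedding")
    return m.values[m.mask].mean(axis=0)


# ---------------------------------------------------------------------------
# embedder registry

_REGISTRY: dict[str, tuple[EmbedderSpec, Callable]] = {}


def register_embedder(spec: EmbedderSpec, compute: Callable) -> EmbedderSpec:
    """Register an embedding method under a unique name.

    ``compute(sequence, max_len) -> EmbeddingMatrix`` must return
    matrices of the declared width; the first width mismatch raises.
    """
    if spec.name in _REGISTRY:
        raise ValueError(f"embedder {spec.name!r} already registered")

    def checked(sequence: str, max_len: int = MAX_LEN_DEFAULT) -> EmbeddingMatrix:
        m = compute(sequence, max_len)
        if m.width != spec.width:
            raise ValueError(
                f"embedder {spec.name!r} declared width {spec.width} "
                f"but produced width {m.width}"
            )
        return EmbeddingMatrix(values=m.values, mask=m.mask, method_tag=spec.method_tag)

    _REGISTRY[spec.name] = (spec, checked)
    return spec


def get_embedder(name: str) -> tuple[EmbedderSpec, Callable]:
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown embedder {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def list_embedders() -> list[EmbedderSpec]:
    """Specs in registration order (registration order breaks ties)."""
    return [spec for spec, _ in _REGISTRY.values()]


def unregister_embedder(name: str) -> None:
    if name == "onehot":
        raise ValueError("the built-in one-hot embedder cannot be removed")
    _REGISTRY.pop(name, None)


def _register_builtins() -> None:
    register_embedder(
        EmbedderSpec(name="onehot", width=len(ALPHABET)),
        lambda seq, max_len=MAX_LEN_DEFAULT: one_hot_embed(seq, ALPHABET, max_len),
    )


_register_builtins()


def embed_table(
    table: AnnotationTable, embedder_name: str = "onehot", max_len: int = MAX_LEN_DEFAULT
) -> dict[str, EmbeddingMatrix]:
    """Embed every record of a table with one registered method."""
    _, compute = get_embedder(embedder_name)
    return {r.id: compute(r.sequence, max_len) for r in table}


# ---------------------------------------------------------------------------
# feedback selection

def select_embedding(
    candidates: list[EmbedderSpec],
    train: AnnotationTable,
    validation: AnnotationTable,
    task: int = 3,
    trainer_config=None,
    max_len: int = 200,
):
    """Pick the embedding that maximizes downstream validation score.

    Trains one small multitask model per candidate with an identical
    configuration and seed, scores it on the validation split (binary F1
    for task 1, macro mF1 for task 3), and returns
    ``(best_spec, score_table)``.  Ties break toward the earlier
    candidate in ``candidates``; a candidate whose embedder fails is
    excluded with a warning rather than aborting the selection.
    """
    import warnings

    from .model import ModelConfig, predictions_to_assignments, train as train_model
    from .metrics import evaluate_predictions

    if not candidates:
        raise ValueError("need at least one candidate embedder")
    if len(validation) == 0:
        raise ValueError("validation set must be nonempty")
    if task not in (1, 3):
        raise ValueError("embedding selection scores task 1 or task 3")

    vocab = sorted(set(train.vocabulary) | set(validation.vocabulary))
    scores: list[tuple[EmbedderSpec, float]] = []
    for spec in candidates:
        try:
            _, compute = get_embedder(spec.name)
            emb_train = {r.id: compute(r.sequence, max_len) for r in train}
            emb_val = {r.id: compute(r.sequence, max_len) for r in validation}
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            warnings.warn(f"embedder {spec.name!r} failed to embed: {exc}")
            continue
        config = trainer_config or ModelConfig(
            hidden_width=16, attention_heads=2, max_epochs=5, seed=0,
            ec_vocabulary=tuple(vocab),
        )
        if not config.ec_vocabulary:
            config = replace(config, ec_vocabulary=tuple(vocab))
        model = train_model(train, emb_train, config, validation, emb_val)
        outputs = model.predict(emb_val, ids=validation.ids)
        assignments = predictions_to_assignments(
            validation.ids, outputs, model.config.ec_vocabulary
        )
        metric = "f1" if task == 1 else "mf1"
        report = evaluate_predictions(validation, assignments, task=task)
        scores.append((spec, report[metric]))
    if not scores:
        raise RuntimeError("every candidate embedder failed")
    best = max(scores, key=lambda pair: pair[1])  # max keeps the first argmax
    return best[0], scores


def sequence_hash(sequence: str) -> str:
    return hashlib.sha256(sequence.encode()).hexdigest()[:16]


class EmbeddingCache:
    """HDF5-backed store of embeddings keyed by (method_tag, sequence hash)."""

    def __init__(self, path):
        self.path = str(path)

    def _key(self, method_tag: str, sequence: str) -> str:
        return f"{method_tag.replace('/', '_')}/{sequence_hash(sequence)}"

    def get(self, method_tag: str, sequence: str) -> EmbeddingMatrix | None:
        import h5py

        try:
            with h5py.File(self.path, "r") as fh:
                key = self._key(method_tag, sequence)
                if key not in fh:
                    return None
                grp = fh[key]
                return EmbeddingMatrix(
                    values=grp["values"][...],
                    mask=grp["mask"][...].astype(bool),
                    method_tag=method_tag,
                )
        except FileNotFoundError:
            return None

    def put(self, method_tag: str, sequence: str, m: EmbeddingMatrix) -> None:
        import h5py

        with h5py.File(self.path, "a") as fh:
            key = self._key(method_tag, sequence)
            if key in fh:
                del fh[key]
            grp = fh.create_group(key)
            grp.create_dataset("values", data=m.values)
            grp.create_dataset("mask", data=m.mask)
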