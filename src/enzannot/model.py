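"""The multitask learning core.

One shared bidirectional GRU encoder reads the embedded sequence; its
hidden states serve as keys and values for three task-specific multihead
attention layers (one learned query bank per task), and each attended
summary feeds a small dense head:

* task 1 — enzyme vs non-enzyme (sigmoid probability);
* task 2 — number of functions, 1..k_max (softmax distribution);
* task 3 — per-EC-class scores over the training vocabulary
  (independent sigmoids: an enzyme may carry several EC numbers).

Tasks 2 and 3 are supervised only on enzyme-labeled records — a
non-enzyme has no function count or EC ground truth — which makes the
hierarchy explicit in the loss.  Joint training shares the encoder
across tasks; to keep one task from hijacking it (negative transfer),
the composite loss adds a clustering penalty

    Omega = ||a_bar||^2 + sum_t lambda_t ||a_t - a_bar||^2

over the task-head parameter vectors a_t (flattened head weight
matrices, zero-padded to a common length), pulling them toward their
mean a_bar.  Defaults: lambda = (0.5, 0.1, 0.4).

Attention is the scaled dot-product form softmax(Q K^T / sqrt(d_h)) V
with additive -inf masking of padded positions, so predictions are
invariant to how much padding a batch carries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ec import ECNumber, format_ec, parse_ec
from .embedding import EmbeddingMatrix
from .records import AnnotationTable

__all__ = [
    "ModelConfig",
    "TaskOutputs",
    "TrainedModel",
    "attention_layer",
    "task_clustering_penalty",
    "composite_loss",
    "train",
    "predictions_to_assignments",
]

_EPS = 1e-7
_NEG_INF = -1e9

# placeholder EC used when scoring the task-1 gate as a binary call
_GATE_TOKEN = ECNumber((1, None, None, None))

TASKS = ("task1", "task2", "task3")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the multitask learner."""

    hidden_width: int = 128  # per direction
    recurrent_layers: int = 1
    attention_heads: int = 4
    k_max: int = 8
    lambdas: tuple[float, float, float] = (0.5, 0.1, 0.4)
    penalty_weight: float = 0.01
    ec_vocabulary: tuple[ECNumber, ...] = ()
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    tasks: tuple[str, ...] = TASKS

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if any(lam < 0 for lam in self.lambdas):
            raise ValueError("lambdas must be non-negative")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be non-negative")
        if len(set(self.ec_vocabulary)) != len(self.ec_vocabulary):
            raise ValueError("EC vocabulary contains duplicates")
        if (2 * self.hidden_width) % self.attention_heads != 0:
            raise ValueError("attention_heads must divide 2*hidden_width")
        bad = set(self.tasks) - set(TASKS)
        if bad or not self.tasks:
            raise ValueError(f"tasks must be a nonempty subset of {TASKS}")


@dataclass(frozen=True)
class TaskOutputs:
    """Per-sequence outputs of the three prediction tasks."""

    p_enzyme: float
    count_dist: np.ndarray  # (k_max,), probabilities over 1..k_max
    ec_scores: np.ndarray  # (V,), independent per-class scores in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_enzyme <= 1.0:
            raise ValueError("p_enzyme must be a probability")
        if abs(self.count_dist.sum() - 1.0) > 1e-6:
            raise ValueError("count distribution must sum to 1")
        if self.ec_scores.size and (
            self.ec_scores.min() < 0 or self.ec_scores.max() > 1
        ):
            raise ValueError("EC scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# standalone numerical primitives


def attention_layer(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_h: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_h)) V.

    ``Q`` is n x d_h, ``K`` is m x d_h, ``V`` is m x d_v; the result is
    n x d_v and every attention-weight row sums to 1.  ``mask`` (length
    m, True = attend) excludes key positions via additive -inf.
    """
    Q, K, V = np.asarray(Q, float), np.asarray(K, float), np.asarray(V, float)
    if d_h <= 0:
        raise ValueError("d_h must be positive")
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("Q/K/V shapes are not conformable")
    scores = Q @ K.swapaxes(-1, -2) / np.sqrt(d_h)
    if mask is not None:
        scores = scores + np.where(np.asarray(mask, bool), 0.0, _NEG_INF)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V


def task_clustering_penalty(task_vectors, lambdas) -> float:
    """Omega = ||a_bar||^2 + sum_t lambda_t ||a_t - a_bar||^2.

    ``a_bar`` is the arithmetic mean of the task vectors; the first term
    regularizes the shared scale, the second pulls each task's
    parameters toward the consensus.
    """
    vectors = [np.asarray(v, float).ravel() for v in task_vectors]
    if not vectors:
        raise ValueError("need at least one task vector")
    length = vectors[0].size
    if any(v.size != length for v in vectors):
        raise ValueError("task vectors must have equal length")
    lambdas = list(lambdas)
    if len(lambdas) != len(vectors):
        raise ValueError("one lambda per task vector required")
    if any(lam < 0 for lam in lambdas):
        raise ValueError("lambdas must be non-negative")
    a_bar = np.mean(vectors, axis=0)
    omega = float(a_bar @ a_bar)
    for lam, v in zip(lambdas, vectors):
        diff = v - a_bar
        omega += lam * float(diff @ diff)
    return omega


def composite_loss(
    outputs: list[TaskOutputs],
    labels: list[tuple[bool, int | None, np.ndarray | None]],
    config: ModelConfig,
    task_vectors=None,
) -> tuple[float, dict[str, float]]:
    """Reference composite loss on plain arrays (used for logging/tests).

    ``labels[i] = (is_enzyme, count or None, ec_multihot or None)``.
    Task 1 is binary cross-entropy over all records; tasks 2 and 3 are
    cross-entropies over enzyme records only (0 when the batch has no
    enzymes); the penalty term is ``penalty_weight * Omega`` over the
    supplied task vectors (0 if none are given).
    """
    if not outputs:
        raise ValueError("empty batch")
    bce1, ce2, bce3 = [], [], []
    for out, (is_enz, count, multihot) in zip(outputs, labels):
        y = float(is_enz)
        p = np.clip(out.p_enzyme, _EPS, 1 - _EPS)
        bce1.append(-(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if is_enz:
            if count is not None:
                q = np.clip(out.count_dist[count - 1], _EPS, 1.0)
                ce2.append(-np.log(q))
            if multihot is not None:
                s = np.clip(out.ec_scores, _EPS, 1 - _EPS)
                bce3.append(
                    float(
                        -(multihot * np.log(s) + (1 - multihot) * np.log(1 - s)).mean()
                    )
                )
    parts = {
        "task1": float(np.mean(bce1)),
        "task2": float(np.mean(ce2)) if ce2 else 0.0,
        "task3": float(np.mean(bce3)) if bce3 else 0.0,
    }
    omega = (
        task_clustering_penalty(task_vectors, config.lambdas[: len(task_vectors)])
        if task_vectors
        else 0.0
    )
    parts["penalty"] = config.penalty_weight * omega
    total = sum(parts[t] for t in ("task1", "task2", "task3")) + parts["penalty"]
    return total, parts


# ---------------------------------------------------------------------------
# parameterization


def _init_params(config: ModelConfig, input_width: int, rng) -> dict[str, Tensor]:
    H = config.hidden_width
    D = 2 * H
    heads = config.attention_heads
    dh = D // heads
    V = len(config.ec_vocabulary)

    def glorot(*shape):
        fan_in = shape[0]
        return Tensor.param(rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape))

    def input_weight(*shape):
        # stronger-than-glorot input drive: sparse one-hot rows otherwise
        # inject too little signal to move the recurrent state early on
        fan_in = shape[0]
        return Tensor.param(rng.normal(0.0, 3.0 * np.sqrt(1.0 / fan_in), size=shape))

    def orthogonal(cols: int) -> Tensor:
        # orthogonal recurrent blocks keep state norms stable over long unrolls
        blocks = []
        for _ in range(cols):
            q, _ = np.linalg.qr(rng.normal(size=(H, H)))
            blocks.append(q)
        return Tensor.param(np.concatenate(blocks, axis=1))

    params: dict[str, Tensor] = {}
    for direction in ("fw", "bw"):
        params[f"gru_{direction}_Wx_zr"] = input_weight(input_width, 2 * H)
        params[f"gru_{direction}_Wh_zr"] = orthogonal(2)
        params[f"gru_{direction}_b_zr"] = Tensor.param(np.zeros(2 * H))
        params[f"gru_{direction}_Wx_c"] = input_weight(input_width, H)
        params[f"gru_{direction}_Wh_c"] = orthogonal(1)
        params[f"gru_{direction}_b_c"] = Tensor.param(np.zeros(H))
    head_widths = {"task1": 1, "task2": config.k_max, "task3": max(V, 1)}
    for task in config.tasks:
        for h in range(heads):
            params[f"{task}_q{h}"] = glorot(1, dh)
            params[f"{task}_Wk{h}"] = glorot(D, dh)
            params[f"{task}_Wv{h}"] = glorot(D, dh)
        params[f"{task}_W"] = glorot(D, head_widths[task])
        params[f"{task}_b"] = Tensor.param(np.zeros(head_widths[task]))
    return params


def _gru_direction(
    params, prefix: str, X: Tensor, mask: np.ndarray, reverse: bool
) -> list[Tensor]:
    """Run one GRU direction; returns per-position hidden states (B, H).

    Padded positions carry the previous state forward so the final state
    and all real-position states are independent of pad length.
    """
    B, L, d = X.shape
    H = params[f"{prefix}_Wh_c"].shape[0]
    Wh_zr, b_zr = params[f"{prefix}_Wh_zr"], params[f"{prefix}_b_zr"]
    Wh_c, b_c = params[f"{prefix}_Wh_c"], params[f"{prefix}_b_c"]
    # input carries no gradient, so per-step numpy slices of X are free;
    # one fused weight keeps it to a single input matmul per step
    Wx = ad.concat([params[f"{prefix}_Wx_zr"], params[f"{prefix}_Wx_c"]], axis=1)
    h = Tensor(np.zeros((B, H)))
    states: list[Tensor | None] = [None] * L
    steps = range(L - 1, -1, -1) if reverse else range(L)
    for t in steps:
        p_t = Tensor(X.data[:, t, :]) @ Wx
        zr = ad.sigmoid(p_t[:, : 2 * H] + h @ Wh_zr + b_zr)
        z, r = zr[:, :H], zr[:, H:]
        c = ad.tanh(p_t[:, 2 * H :] + (r * h) @ Wh_c + b_c)
        h_new = (1.0 - z) * h + z * c
        m_t = mask[:, t : t + 1].astype(float)  # (B, 1)
        h = Tensor(m_t) * h_new + Tensor(1.0 - m_t) * h
        states[t] = h
    return states


def _forward(
    params: dict[str, Tensor],
    config: ModelConfig,
    X: Tensor,
    mask: np.ndarray,
) -> dict[str, Tensor]:
    """Full forward pass; returns per-task output tensors for a batch."""
    fw = _gru_direction(params, "gru_fw", X, mask, reverse=False)
    bw = _gru_direction(params, "gru_bw", X, mask, reverse=True)
    per_pos = [ad.concat([f, b], axis=-1) for f, b in zip(fw, bw)]
    states = ad.stack(per_pos, axis=1)  # (B, L, D)
    D = 2 * config.hidden_width
    heads = config.attention_heads
    dh = D // heads
    add_mask = np.where(mask, 0.0, _NEG_INF)[:, None, :]  # (B, 1, L)

    outputs: dict[str, Tensor] = {}
    for task in config.tasks:
        head_outs = []
        for h in range(heads):
            K = states @ params[f"{task}_Wk{h}"]  # (B, L, dh)
            Vv = states @ params[f"{task}_Wv{h}"]  # (B, L, dh)
            scores = params[f"{task}_q{h}"] @ K.swapaxes(1, 2)  # (B, 1, L)
            scores = scores * (1.0 / np.sqrt(dh)) + Tensor(add_mask)
            weights = ad.softmax_lastaxis(scores)
            head_outs.append((weights @ Vv).reshape(-1, dh))
        ctx = ad.concat(head_outs, axis=-1)  # (B, D)
        logits = ctx @ params[f"{task}_W"] + params[f"{task}_b"]
        if task == "task1":
            outputs[task] = ad.sigmoid(logits)
        elif task == "task2":
            outputs[task] = ad.softmax_lastaxis(logits)
        else:
            outputs[task] = ad.sigmoid(logits)
    return outputs


def _penalty_tensor(params: dict[str, Tensor], config: ModelConfig) -> Tensor:
    """Omega over the flattened task-head weight matrices (zero-padded)."""
    vecs = []
    for task in config.tasks:
        vecs.append(params[f"{task}_W"].reshape(-1))
    width = max(v.shape[0] for v in vecs)
    padded = []
    for v in vecs:
        if v.shape[0] < width:
            v = ad.concat([v, Tensor(np.zeros(width - v.shape[0]))], axis=0)
        padded.append(v)
    T = len(padded)
    a_bar = padded[0]
    for v in padded[1:]:
        a_bar = a_bar + v
    a_bar = a_bar * (1.0 / T)
    omega = (a_bar * a_bar).sum()
    for lam, v in zip(config.lambdas, padded):
        diff = v - a_bar
        omega = omega + lam * (diff * diff).sum()
    return omega


def _batch_loss(
    params, config, X, mask, y1, y2, y3, enz_mask
) -> tuple[Tensor, dict[str, float]]:
    outputs = _forward(params, config, X, mask)
    parts: dict[str, float] = {}
    total = Tensor(0.0)
    n_enz = float(enz_mask.sum())
    if "task1" in config.tasks:
        p = outputs["task1"].reshape(-1)
        p = p * (1 - 2 * _EPS) + _EPS  # clamp away from exact 0/1
        t1 = -(Tensor(y1) * p.log() + Tensor(1 - y1) * (1.0 - p).log()).mean()
        total = total + t1
        parts["task1"] = float(t1.data)
    if "task2" in config.tasks:
        if n_enz > 0:
            q = outputs["task2"] * (1 - 2 * _EPS) + _EPS
            ce = -(Tensor(y2) * q.log()).sum(axis=1)
            t2 = (ce * Tensor(enz_mask)).sum() * (1.0 / n_enz)
            total = total + t2
            parts["task2"] = float(t2.data)
        else:
            parts["task2"] = 0.0
    if "task3" in config.tasks:
        if n_enz > 0 and y3.shape[1] > 0:
            s = outputs["task3"] * (1 - 2 * _EPS) + _EPS
            bce = -(Tensor(y3) * s.log() + Tensor(1 - y3) * (1.0 - s).log()).mean(axis=1)
            t3 = (bce * Tensor(enz_mask)).sum() * (1.0 / n_enz)
            total = total + t3
            parts["task3"] = float(t3.data)
        else:
            parts["task3"] = 0.0
    # the penalty couples the task heads; only meaningful when the batch
    # actually supervises them, so skip it on enzyme-free batches
    if config.penalty_weight > 0 and (n_enz > 0 or config.tasks == ("task1",)):
        omega = _penalty_tensor(params, config)
        pen = omega * config.penalty_weight
        total = total + pen
        parts["penalty"] = float(pen.data)
    else:
        parts["penalty"] = 0.0
    return total, parts


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# data assembly


def _assemble(
    table: AnnotationTable, embeddings: dict[str, EmbeddingMatrix], config: ModelConfig
):
    ids = table.ids
    missing = [i for i in ids if i not in embeddings]
    if missing:
        raise ValueError(f"missing embeddings for: {missing[:5]}")
    tags = {embeddings[i].method_tag for i in ids}
    if len(tags) > 1:
        raise ValueError(f"mixed embedding methods: {sorted(tags)}")
    widths = {embeddings[i].width for i in ids}
    if len(widths) > 1:
        raise ValueError("inconsistent embedding widths")
    L_eff = max(int(embeddings[i].mask.sum()) for i in ids)
    X = np.stack([embeddings[i].values[:L_eff] for i in ids])
    mask = np.stack([embeddings[i].mask[:L_eff] for i in ids])
    vocab_index = {ec: j for j, ec in enumerate(config.ec_vocabulary)}
    y1 = np.array([float(bool(r.is_enzyme)) for r in table])
    y2 = np.zeros((len(ids), config.k_max))
    y3 = np.zeros((len(ids), len(config.ec_vocabulary)))
    enz = np.zeros(len(ids))
    unknown: list[str] = []
    for i, r in enumerate(table):
        if not r.is_enzyme:
            continue
        enz[i] = 1.0
        count = min(len(r.ec_numbers), config.k_max)
        y2[i, count - 1] = 1.0
        for ec in r.ec_numbers:
            if ec not in vocab_index:
                unknown.append(f"{r.id}:{format_ec(ec)}")
            else:
                y3[i, vocab_index[ec]] = 1.0
    if unknown:
        raise ValueError(
            "labels absent from the model vocabulary: "
            + ", ".join(unknown[:5])
            + " — filter them out first (see metrics.filter_novel_labels)"
        )
    return X, mask, y1, y2, y3, enz, tags.pop(), L_eff


# ---------------------------------------------------------------------------
# trained model


@dataclass
class TrainedModel:
    params: dict[str, Tensor]
    config: ModelConfig
    method_tag: str
    input_width: int
    history: list[dict] = field(default_factory=list)

    def predict(
        self, embeddings: dict[str, EmbeddingMatrix], ids: list[str] | None = None
    ) -> list[TaskOutputs]:
        """One :class:`TaskOutputs` per input, in input order."""
        if ids is None:
            ids = list(embeddings)
        for i in ids:
            m = embeddings[i]
            if m.method_tag != self.method_tag:
                raise ValueError(
                    f"embedding method {m.method_tag!r} does not match the "
                    f"model's training method {self.method_tag!r}"
                )
            if m.width != self.input_width:
                raise ValueError(
                    f"embedding width {m.width} != training width {self.input_width}"
                )
        V = len(self.config.ec_vocabulary)
        results: list[TaskOutputs] = []
        batch = max(self.config.batch_size, 1)
        for start in range(0, len(ids), batch):
            chunk = ids[start : start + batch]
            L_eff = max(int(embeddings[i].mask.sum()) for i in chunk)
            X = Tensor(np.stack([embeddings[i].values[:L_eff] for i in chunk]))
            mask = np.stack([embeddings[i].mask[:L_eff] for i in chunk])
            with ad.no_grad():
                outs = _forward(self.params, self.config, X, mask)
            n = len(chunk)
            p1 = (
                outs["task1"].data.reshape(-1)
                if "task1" in outs
                else np.ones(n)
            )
            if "task2" in outs:
                p2 = outs["task2"].data
            else:
                p2 = np.full((n, self.config.k_max), 1.0 / self.config.k_max)
            if "task3" in outs and V > 0:
                p3 = outs["task3"].data
            else:
                p3 = np.zeros((n, V))
            for j in range(n):
                dist = p2[j] / p2[j].sum()
                results.append(
                    TaskOutputs(
                        p_enzyme=float(np.clip(p1[j], 0, 1)),
                        count_dist=dist,
                        ec_scores=np.clip(p3[j], 0, 1),
                    )
                )
        return results

    def task_vectors(self) -> list[np.ndarray]:
        """Flattened head weight matrices, zero-padded to a common length."""
        vecs = [self.params[f"{t}_W"].data.ravel() for t in self.config.tasks]
        width = max(v.size for v in vecs)
        return [np.pad(v, (0, width - v.size)) for v in vecs]

    def parameter_hash(self) -> str:
        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(self.params[name].data.tobytes())
        return digest.hexdigest()

    def save(self, path) -> None:
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        meta = {
            "config": _config_to_dict(self.config),
            "method_tag": self.method_tag,
            "input_width": self.input_width,
            "history": self.history,
        }
        np.savez_compressed(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
        config = _config_from_dict(meta["config"])
        params = {
            k[len("param_"):]: Tensor.param(data[k])
            for k in data.files
            if k.startswith("param_")
        }
        return TrainedModel(
            params=params,
            config=config,
            method_tag=meta["method_tag"],
            input_width=meta["input_width"],
            history=meta["history"],
        )


def _config_to_dict(config: ModelConfig) -> dict:
    d = {
        k: getattr(config, k)
        for k in (
            "hidden_width", "recurrent_layers", "attention_heads", "k_max",
            "penalty_weight", "learning_rate", "batch_size", "max_epochs",
            "patience", "seed",
        )
    }
    d["lambdas"] = list(config.lambdas)
    d["tasks"] = list(config.tasks)
    d["ec_vocabulary"] = [format_ec(ec) for ec in config.ec_vocabulary]
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(
        hidden_width=d["hidden_width"],
        recurrent_layers=d["recurrent_layers"],
        attention_heads=d["attention_heads"],
        k_max=d["k_max"],
        lambdas=tuple(d["lambdas"]),
        penalty_weight=d["penalty_weight"],
        ec_vocabulary=tuple(parse_ec(s) for s in d["ec_vocabulary"]),
        learning_rate=d["learning_rate"],
        batch_size=d["batch_size"],
        max_epochs=d["max_epochs"],
        patience=d["patience"],
        seed=d["seed"],
        tasks=tuple(d["tasks"]),
    )


# ---------------------------------------------------------------------------
# training


def train(
    table: AnnotationTable,
    embeddings: dict[str, EmbeddingMatrix],
    config: ModelConfig,
    validation: AnnotationTable | None = None,
    val_embeddings: dict[str, EmbeddingMatrix] | None = None,
) -> TrainedModel:
    """Gradient-train the multitask model.

    Mini-batch Adam on the composite loss; if a validation table is
    given, early stopping tracks the composite validation score (mean of
    task-1 F1 and task-3 mF1 over the trained tasks) with the configured
    patience, and the best-scoring parameters are restored.  Fully
    deterministic for a fixed seed.
    """
    from .metrics import evaluate_predictions

    if validation is not None:
        overlap = set(table.ids) & set(validation.ids)
        if overlap:
            raise ValueError(f"train/validation ids overlap: {sorted(overlap)[:5]}")
        val_vocab = set(validation.vocabulary)
        novel = val_vocab - set(config.ec_vocabulary)
        if novel:
            raise ValueError(
                f"validation labels missing from model vocabulary: "
                f"{[format_ec(e) for e in sorted(novel)][:5]} — apply "
                "metrics.filter_novel_labels first"
            )
    X, mask, y1, y2, y3, enz, tag, _ = _assemble(table, embeddings, config)
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, X.shape[2], rng)
    optimizer = _Adam(params, config.learning_rate)
    model = TrainedModel(
        params=params, config=config, method_tag=tag, input_width=X.shape[2]
    )

    best_score = -np.inf
    best_snapshot: dict[str, np.ndarray] | None = None
    stale = 0
    n = len(table)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_parts: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            optimizer.zero_grad()
            loss, parts = _batch_loss(
                params, config, Tensor(X[idx]), mask[idx],
                y1[idx], y2[idx], y3[idx], enz[idx],
            )
            loss.backward()
            optimizer.step()
            for k, v in parts.items():
                epoch_parts[k] = epoch_parts.get(k, 0.0) + v
            epoch_parts["total"] = epoch_parts.get("total", 0.0) + float(loss.data)
            n_batches += 1
        entry = {f"loss_{k}": v / n_batches for k, v in epoch_parts.items()}
        entry["epoch"] = epoch

        if validation is not None and len(validation) > 0:
            outputs = model.predict(val_embeddings, ids=validation.ids)
            assignments = predictions_to_assignments(
                validation.ids, outputs, config.ec_vocabulary
            )
            scores = []
            if "task1" in config.tasks:
                # task 1 is judged on the enzyme gate alone: an enzyme call
                # with no EC clearing the score threshold is still a call
                gate_calls = {
                    rid: ([_GATE_TOKEN] if out.p_enzyme >= 0.5 else [])
                    for rid, out in zip(validation.ids, outputs)
                }
                rep1 = evaluate_predictions(validation, gate_calls, task=1)
                entry["val_task1_f1"] = rep1["f1"]
                scores.append(rep1["f1"])
            if "task3" in config.tasks and any(r.is_enzyme for r in validation):
                rep3 = evaluate_predictions(validation, assignments, task=3)
                entry["val_task3_mf1"] = rep3["mf1"]
                scores.append(rep3["mf1"])
            score = float(np.mean(scores)) if scores else -entry["loss_total"]
            entry["val_composite"] = score
            model.history.append(entry)
            if score > best_score + 1e-9:
                best_score = score
                best_snapshot = {k: p.data.copy() for k, p in params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        else:
            model.history.append(entry)
    if best_snapshot is not None:
        for k, p in params.items():
            p.data = best_snapshot[k]
    return model


def predict(
    model: TrainedModel, embeddings: dict[str, EmbeddingMatrix],
    ids: list[str] | None = None,
) -> list[TaskOutputs]:
    """Module-level alias for :meth:`TrainedModel.predict`."""
    return model.predict(embeddings, ids=ids)


def predictions_to_assignments(
    ids: list[str],
    outputs: list[TaskOutputs],
    vocabulary: tuple[ECNumber, ...],
    tau1: float = 0.5,
    tau3: float = 0.5,
    use_count: bool = True,
) -> dict[str, list[ECNumber]]:
    """Simple thresholded readout of raw task outputs (no integration).

    Records below the enzyme gate get an empty assignment; otherwise EC
    classes scoring >= tau3 are kept, optionally capped at the task-2
    argmax count m (ties: score desc, then EC ascending).
    """
    assignments: dict[str, list[ECNumber]] = {}
    for rid, out in zip(ids, outputs):
        if out.p_enzyme < tau1:
            assignments[rid] = []
            continue
        scored = [
            (float(s), ec)
            for s, ec in zip(out.ec_scores, vocabulary)
            if s >= tau3
        ]
        scored.sort(key=lambda pair: (-pair[0], pair[1]))
        if use_count and len(out.count_dist):
            m = int(np.argmax(out.count_dist)) + 1
            scored = scored[:m]
        assignments[rid] = [ec for _, ec in scored]
    return assignments
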