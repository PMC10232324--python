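"""Hierarchical integration of task outputs into final EC assignments.

The three task outputs and a homology channel are merged by a small
decision policy: records below the enzyme gate (task 1) receive no EC;
otherwise candidate ECs from the model's per-class scores and from
annotation transfer off the closest labeled neighbor are pooled, scored,
thresholded, and optionally capped at the function count predicted by
task 2.  The policy's thresholds, precedence and count rule are tuned by
greedy coordinate search that maximizes macro-F1 of the final EC
assignment on a labeled tuning set.

The built-in homology channel scores query/reference pairs by Jaccard
similarity of their 3-mer multisets — a dependency-free stand-in for a
fast aligner.  Output from an external aligner (tab-separated
query / subject / percent-identity, outfmt-6 style) can be supplied
instead, in which case percent identity / 100 becomes the score.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .ec import ECNumber, format_ec
from .model import TaskOutputs
from .records import AnnotationTable

__all__ = [
    "PredictionChannel",
    "IntegrationPolicy",
    "kmer_jaccard",
    "align_transfer",
    "read_external_alignment",
    "model_channel",
    "apply_policy",
    "integrate",
    "greedy_integrate",
    "DEFAULT_GRIDS",
]


@dataclass(frozen=True)
class PredictionChannel:
    """Per-record candidate EC numbers with scores from one source."""

    name: str
    kind: str  # {"model", "alignment"}
    candidates: dict  # id -> list[(ECNumber, score)]

    def __post_init__(self) -> None:
        if self.kind not in ("model", "alignment"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        for rid, cands in self.candidates.items():
            for _, score in cands:
                if not 0.0 <= score <= 1.0:
                    raise ValueError(
                        f"channel {self.name!r} score out of [0,1] for {rid!r}"
                    )


@dataclass(frozen=True)
class IntegrationPolicy:
    """The decision rule merging task outputs and channels."""

    tau1: float = 0.5  # enzyme gate on p_enzyme
    tau3: float = 0.1  # EC candidate score threshold
    count_rule: str = "cap-by-task2"  # or "ignore-count"
    precedence: tuple[str, ...] = ("model", "alignment")
    identity_floor: float = 0.6  # alignment channels only
    k_max: int = 8

    def __post_init__(self) -> None:
        for name, value in (("tau1", self.tau1), ("tau3", self.tau3),
                            ("identity_floor", self.identity_floor)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.count_rule not in ("cap-by-task2", "ignore-count"):
            raise ValueError(f"unknown count rule {self.count_rule!r}")
        if len(set(self.precedence)) != len(self.precedence):
            raise ValueError("precedence must not repeat channels")


def _kmers(sequence: str, k: int = 3) -> Counter:
    return Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def kmer_jaccard(a: str, b: str, k: int = 3) -> float:
    """Jaccard similarity of k-mer multisets (1.0 for identical sequences)."""
    ka, kb = _kmers(a, k), _kmers(b, k)
    inter = sum((ka & kb).values())
    union = sum((ka | kb).values())
    return inter / union if union else 0.0


def align_transfer(
    queries: dict[str, str],
    reference: AnnotationTable,
    identity_floor: float = 0.0,
    k: int = 3,
    external: dict[str, tuple[str, float]] | None = None,
) -> PredictionChannel:
    """Annotation transfer from the most similar labeled reference.

    For each query, the nearest enzyme reference by 3-mer Jaccard (or the
    best hit from ``external``, mapping query id -> (subject id, score))
    donates its full EC set with the similarity as score, provided the
    similarity reaches ``identity_floor``.  Queries without a qualifying
    neighbor get an empty candidate list.
    """
    enzymes = [r for r in reference if r.is_enzyme]
    if not enzymes:
        raise ValueError("reference table has no enzyme records")
    by_id = {r.id: r for r in enzymes}
    candidates: dict[str, list[tuple[ECNumber, float]]] = {}
    for qid, seq in queries.items():
        if external is not None:
            hit = external.get(qid)
            if hit is None:
                candidates[qid] = []
                continue
            sid, score = hit
            if sid not in by_id:
                raise ValueError(f"alignment subject {sid!r} not in reference")
            best, best_score = by_id[sid], score
        else:
            best, best_score = None, -1.0
            for r in enzymes:
                score = kmer_jaccard(seq, r.sequence, k)
                if score > best_score:
                    best, best_score = r, score
        if best is not None and best_score >= identity_floor and best_score > 0:
            candidates[qid] = [(ec, float(best_score)) for ec in best.ec_numbers]
        else:
            candidates[qid] = []
    return PredictionChannel(name="alignment", kind="alignment", candidates=candidates)


def read_external_alignment(path) -> dict[str, tuple[str, float]]:
    """Parse outfmt-6-style tabular alignment (query, subject, pct identity).

    Keeps the best-identity hit per query; identities are rescaled from
    percent to [0, 1].
    """
    best: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed alignment line {lineno}: {line!r}")
            qid, sid, ident = parts[0], parts[1], parts[2]
            try:
                score = float(ident) / 100.0
            except ValueError:
                raise ValueError(
                    f"malformed identity {ident!r} on line {lineno}"
                ) from None
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"identity out of range on line {lineno}")
            if qid not in best or score > best[qid][1]:
                best[qid] = (sid, score)
    return best


def model_channel(
    ids: list[str], outputs: list[TaskOutputs], vocabulary
) -> PredictionChannel:
    """Wrap task-3 per-class scores as a candidate channel."""
    candidates = {
        rid: [(ec, float(s)) for ec, s in zip(vocabulary, out.ec_scores)]
        for rid, out in zip(ids, outputs)
    }
    return PredictionChannel(name="model", kind="model", candidates=candidates)


def apply_policy(
    policy: IntegrationPolicy,
    outputs: TaskOutputs,
    channels: list[PredictionChannel],
    record_id: str,
) -> list[ECNumber]:
    """Final EC assignment for one record under a policy.

    Hierarchical gating: below the enzyme gate the assignment is empty.
    Otherwise channels are visited in the policy's precedence order;
    candidates must clear the score threshold (and the identity floor
    for alignment channels), duplicates at full-tuple identity keep the
    first (highest-precedence) occurrence, and if the count rule is
    ``cap-by-task2`` only the top-m candidates survive, where m is the
    argmax of the predicted count distribution.  Ties break by score
    descending, then EC ascending.  Deterministic and idempotent.
    """
    if outputs.p_enzyme < policy.tau1:
        return []
    by_name = {ch.name: ch for ch in channels}
    merged: dict[ECNumber, float] = {}
    for name in policy.precedence:
        ch = by_name.get(name)
        if ch is None:
            continue
        floor = policy.identity_floor if ch.kind == "alignment" else 0.0
        for ec, score in ch.candidates.get(record_id, []):
            if score < policy.tau3 or score < floor:
                continue
            if ec not in merged:  # first (highest-precedence) wins
                merged[ec] = score
    ranked = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    cap = policy.k_max
    if policy.count_rule == "cap-by-task2" and len(outputs.count_dist):
        cap = min(cap, int(np.argmax(outputs.count_dist)) + 1)
    return [ec for ec, _ in ranked[:cap]]


def integrate(
    policy: IntegrationPolicy,
    ids: list[str],
    outputs: list[TaskOutputs],
    channels: list[PredictionChannel],
) -> dict[str, list[ECNumber]]:
    """Apply a policy across a whole prediction batch."""
    return {
        rid: apply_policy(policy, out, channels, rid)
        for rid, out in zip(ids, outputs)
    }


DEFAULT_GRIDS: dict[str, tuple] = {
    "tau1": (0.3, 0.5, 0.7),
    "identity_floor": (0.4, 0.6, 0.9),
    "tau3": (0.05, 0.1, 0.2, 0.5),
    "count_rule": ("cap-by-task2", "ignore-count"),
}

# fixed sweep order for the coordinate search, two full passes
_SWEEP_ORDER = ("tau1", "identity_floor", "tau3", "count_rule", "precedence")


def greedy_integrate(
    channels: list[PredictionChannel],
    ids: list[str],
    outputs: list[TaskOutputs],
    gold: AnnotationTable,
    grids: dict[str, tuple] | None = None,
    level: int = 4,
    k_max: int = 8,
    passes: int = 2,
) -> tuple[IntegrationPolicy, float, list[dict]]:
    """Greedy coordinate search for the policy maximizing final mF1.

    One policy field at a time is optimized over its grid with the
    others held fixed, sweeping fields in the order
    tau1 -> identity_floor -> tau3 -> count_rule -> precedence,
    for ``passes`` full passes.  The objective is the macro-F1 of the
    integrated EC assignment on the tuning set; within a sweep the
    incumbent value wins ties, so the achieved objective is
    non-decreasing across steps.

    Returns (best policy, its mF1, step log).
    """
    from .metrics import evaluate_predictions

    if len(gold) == 0:
        raise ValueError("tuning set must be nonempty")
    grids = dict(DEFAULT_GRIDS) | (grids or {})
    channel_names = tuple(ch.name for ch in channels)
    if "precedence" not in grids:
        # permutations of every nonempty channel subset, so single-channel
        # policies are reachable grid points
        grids["precedence"] = tuple(
            perm
            for size in range(1, len(channel_names) + 1)
            for perm in itertools.permutations(channel_names, size)
        )

    def objective(policy: IntegrationPolicy) -> float:
        assignments = integrate(policy, ids, outputs, channels)
        report = evaluate_predictions(gold, assignments, task=3, level=level,
                                      k_max=k_max)
        return report["mf1"]

    policy = IntegrationPolicy(
        tau1=grids["tau1"][0],
        tau3=grids["tau3"][0],
        count_rule=grids["count_rule"][0],
        precedence=tuple(grids["precedence"][0]),
        identity_floor=grids["identity_floor"][0],
        k_max=k_max,
    )
    best = objective(policy)
    log: list[dict] = [{"step": "init", "value": None, "objective": best}]
    for pass_no in range(passes):
        for name in _SWEEP_ORDER:
            for value in grids[name]:
                if name == "precedence":
                    value = tuple(value)
                trial = replace(policy, **{name: value})
                score = objective(trial)
                if score > best + 1e-12:
                    best, policy = score, trial
                log.append(
                    {
                        "step": f"pass{pass_no}:{name}={value}",
                        "value": value if name != "precedence" else list(value),
                        "objective": best,
                    }
                )
    return policy, best, log
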