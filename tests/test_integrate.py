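"""Annotation transfer, policy application and greedy policy search."""

import itertools

import numpy as np
import pytest

from enzannot.ec import parse_ec
from enzannot.integrate import (
    DEFAULT_GRIDS,
    IntegrationPolicy,
    PredictionChannel,
    align_transfer,
    apply_policy,
    greedy_integrate,
    integrate,
    kmer_jaccard,
    read_external_alignment,
)
from enzannot.model import TaskOutputs
from enzannot.records import AnnotationTable, ProteinRecord


def _rec(rid, seq, ecs):
    parsed = tuple(parse_ec(e) for e in ecs)
    return ProteinRecord(rid, seq, bool(parsed), parsed)


def _out(p_enzyme, count_idx=0, scores=(), k_max=4):
    dist = np.zeros(k_max)
    dist[count_idx] = 1.0
    return TaskOutputs(p_enzyme=p_enzyme, count_dist=dist,
                       ec_scores=np.asarray(scores, float))


class TestAlignTransfer:
    REFERENCE = AnnotationTable(
        [
            _rec("r1", "MKLVAAGG", ["1.1.1.1"]),
            _rec("r2", "WWYYPPQQ", ["2.2.2.2", "2.2.2.3"]),
        ]
    )

    def test_identical_query_scores_one(self):
        ch = align_transfer({"q": "MKLVAAGG"}, self.REFERENCE)
        assert ch.candidates["q"] == [(parse_ec("1.1.1.1"), 1.0)]

    def test_no_shared_kmers_gives_empty(self):
        ch = align_transfer({"q": "DDDDDDDD"}, self.REFERENCE)
        assert ch.candidates["q"] == []

    def test_hand_computed_jaccard_floor(self):
        # 3-mers of ABCDE vs ABCDX share {ABC, BCD}: J = 2/4 = 0.5
        assert kmer_jaccard("MKLVA", "MKLVG") == pytest.approx(2 / 4)
        ref = AnnotationTable([_rec("r1", "MKLVG", ["1.1.1.1"])])
        high = align_transfer({"q": "MKLVA"}, ref, identity_floor=0.4)
        low = align_transfer({"q": "MKLVA"}, ref, identity_floor=0.6)
        assert high.candidates["q"][0][1] == pytest.approx(0.5)
        assert low.candidates["q"] == []

    def test_multiset_jaccard_counts_repeats(self):
        # AAAA: {AA x3}; AAA: {AA x2} -> inter 2, union 3
        assert kmer_jaccard("AAAA", "AAA", k=2) == pytest.approx(2 / 3)

    def test_external_alignment_overrides_builtin(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\tr2\t80.0\textra\ncomment-less line skipped\n#c\n")
        with pytest.raises(ValueError):
            read_external_alignment(p)
        p.write_text("q\tr2\t80.0\nq\tr1\t95.0\n")
        hits = read_external_alignment(p)
        assert hits == {"q": ("r1", 0.95)}
        ch = align_transfer({"q": "DDDD"}, self.REFERENCE, external=hits)
        assert ch.candidates["q"] == [(parse_ec("1.1.1.1"), 0.95)]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_transfer({"q": "MKLV"}, AnnotationTable([_rec("n", "MKLV", [])]))


VOCAB = tuple(parse_ec(s) for s in ["1.1.1.1", "2.6.1.1", "2.6.1.57"])


def _model_channel_for(scores):
    return PredictionChannel(
        name="model", kind="model",
        candidates={"q": [(ec, s) for ec, s in zip(VOCAB, scores)]},
    )


class TestApplyPolicy:
    def test_enzyme_gate_blocks_everything(self):
        policy = IntegrationPolicy(tau1=0.5)
        ch = _model_channel_for([0.9, 0.9, 0.9])
        assert apply_policy(policy, _out(0.1, 0, [0.9] * 3), [ch], "q") == []

    def test_top_m_above_threshold(self):
        # scores {2.6.1.57: 0.9, 2.6.1.1: 0.8, 1.1.1.1: 0.05}, m=2, tau3=0.1
        policy = IntegrationPolicy(tau1=0.5, tau3=0.1, count_rule="cap-by-task2")
        out = _out(0.9, count_idx=1, scores=[0.05, 0.8, 0.9])
        ch = _model_channel_for([0.05, 0.8, 0.9])
        result = apply_policy(policy, out, [ch], "q")
        assert result == [parse_ec("2.6.1.57"), parse_ec("2.6.1.1")]

    def test_lexicographic_tie_break(self):
        policy = IntegrationPolicy(tau1=0.5, tau3=0.1)
        out = _out(0.9, count_idx=0, scores=[0.7, 0.7, 0.0])
        ch = _model_channel_for([0.7, 0.7, 0.0])
        assert apply_policy(policy, out, [ch], "q") == [parse_ec("1.1.1.1")]

    def test_precedence_dedup_keeps_first_channel(self):
        out = _out(0.9, count_idx=0, scores=[0.6, 0.0, 0.0])
        model_ch = _model_channel_for([0.6, 0.0, 0.0])
        align_ch = PredictionChannel(
            name="alignment", kind="alignment",
            candidates={"q": [(parse_ec("1.1.1.1"), 0.95),
                              (parse_ec("2.6.1.1"), 0.95)]},
        )
        policy = IntegrationPolicy(
            tau1=0.5, tau3=0.1, count_rule="ignore-count",
            precedence=("alignment", "model"), identity_floor=0.4,
        )
        result = apply_policy(policy, out, [model_ch, align_ch], "q")
        assert result == [parse_ec("1.1.1.1"), parse_ec("2.6.1.1")]
        # channel list order is irrelevant; declared precedence rules
        result2 = apply_policy(policy, out, [align_ch, model_ch], "q")
        assert result2 == result

    def test_identity_floor_applies_to_alignment_only(self):
        out = _out(0.9, count_idx=0, scores=[0.6, 0.0, 0.0])
        model_ch = _model_channel_for([0.6, 0.0, 0.0])
        align_ch = PredictionChannel(
            name="alignment", kind="alignment",
            candidates={"q": [(parse_ec("2.6.1.1"), 0.5)]},
        )
        policy = IntegrationPolicy(
            tau1=0.5, tau3=0.1, count_rule="ignore-count", identity_floor=0.6,
        )
        result = apply_policy(policy, out, [model_ch, align_ch], "q")
        assert result == [parse_ec("1.1.1.1")]  # alignment hit below floor

    def test_idempotent_and_k_max_capped(self):
        vocab = tuple(parse_ec(f"1.1.1.{i}") for i in range(1, 13))
        ch = PredictionChannel(
            name="model", kind="model",
            candidates={"q": [(ec, 0.9) for ec in vocab]},
        )
        out = TaskOutputs(p_enzyme=1.0, count_dist=np.ones(8) / 8,
                          ec_scores=np.full(12, 0.9))
        policy = IntegrationPolicy(tau1=0.5, tau3=0.1, count_rule="ignore-count",
                                   k_max=8)
        a = apply_policy(policy, out, [ch], "q")
        assert len(a) == 8
        assert a == apply_policy(policy, out, [ch], "q")


def _tuning_setup(n=20, seed=5):
    """Small labeled tuning set with a noisy model channel and a partly
    reliable alignment channel."""
    rng = np.random.default_rng(seed)
    vocab = VOCAB
    records, outputs, align = [], [], {}
    for i in range(n):
        rid = f"q{i}"
        if i % 4 == 0:
            records.append(_rec(rid, "DDDDGGGG" + "A" * i, []))
            outputs.append(_out(rng.uniform(0.0, 0.4), 0,
                                rng.uniform(0, 0.3, size=3)))
            align[rid] = []
        else:
            ec = vocab[i % 3]
            records.append(_rec(rid, "MKLVAAGG" + "A" * i, [str(ec)]))
            scores = rng.uniform(0, 0.4, size=3)
            scores[i % 3] = rng.uniform(0.5, 1.0)
            outputs.append(_out(rng.uniform(0.6, 1.0), 0, scores))
            align[rid] = (
                [(ec, float(rng.uniform(0.6, 1.0)))] if i % 5 else
                [(vocab[(i + 1) % 3], 0.7)]
            )
    table = AnnotationTable(records)
    channels = [
        PredictionChannel(
            name="model", kind="model",
            candidates={f"q{i}": [(ec, float(s)) for ec, s in
                                  zip(vocab, outputs[i].ec_scores)]
                        for i in range(n)},
        ),
        PredictionChannel(name="alignment", kind="alignment", candidates=align),
    ]
    return table, outputs, channels


def exhaustive_policy_search(channels, ids, outputs, gold, grids, k_max=4):
    """Brute-force oracle: evaluate every policy in the full grid."""
    from enzannot.metrics import evaluate_predictions

    best_policy, best = None, -1.0
    for tau1 in grids["tau1"]:
        for tau3 in grids["tau3"]:
            for floor in grids["identity_floor"]:
                for rule in grids["count_rule"]:
                    for prec in grids["precedence"]:
                        policy = IntegrationPolicy(
                            tau1=tau1, tau3=tau3, count_rule=rule,
                            precedence=tuple(prec), identity_floor=floor,
                            k_max=k_max,
                        )
                        assignments = integrate(policy, ids, outputs, channels)
                        score = evaluate_predictions(
                            gold, assignments, task=3, k_max=k_max
                        )["mf1"]
                        if score > best:
                            best, best_policy = score, policy
    return best_policy, best


class TestGreedyIntegrate:
    def test_singleton_grid_returns_that_policy(self):
        table, outputs, channels = _tuning_setup()
        grids = {
            "tau1": (0.5,), "tau3": (0.1,), "identity_floor": (0.6,),
            "count_rule": ("cap-by-task2",),
            "precedence": (("model", "alignment"),),
        }
        policy, score, _ = greedy_integrate(
            channels, table.ids, outputs, table, grids=grids, k_max=4
        )
        assert policy.tau1 == 0.5 and policy.precedence == ("model", "alignment")

    def test_greedy_close_to_exhaustive_and_monotone(self):
        table, outputs, channels = _tuning_setup()
        grids = dict(DEFAULT_GRIDS)
        grids["precedence"] = tuple(
            perm
            for size in (1, 2)
            for perm in itertools.permutations(("model", "alignment"), size)
        )
        policy, score, log = greedy_integrate(
            channels, table.ids, outputs, table, grids=grids, k_max=4
        )
        _, best = exhaustive_policy_search(
            channels, table.ids, outputs, table, grids, k_max=4
        )
        assert score >= best - 0.02
        objectives = [e["objective"] for e in log]
        assert all(b >= a for a, b in zip(objectives, objectives[1:]))

    def test_oracle_channel_reaches_perfect_mf1(self):
        table, outputs, channels = _tuning_setup()
        oracle = PredictionChannel(
            name="oracle", kind="model",
            candidates={r.id: [(ec, 1.0) for ec in r.ec_numbers] for r in table},
        )
        # a confident gate so every true enzyme passes tau1
        boosted = [
            _out(1.0 if r.is_enzyme else 0.0, 0, o.ec_scores)
            for r, o in zip(table, outputs)
        ]
        policy, score, _ = greedy_integrate(
            [oracle] + channels, table.ids, boosted, table,
            grids={"count_rule": ("ignore-count",)}, k_max=4,
        )
        assert score == pytest.approx(1.0)

    def test_empty_tuning_set_rejected(self):
        _, outputs, channels = _tuning_setup()
        with pytest.raises(ValueError):
            greedy_integrate(channels, [], [], AnnotationTable([]), k_max=4)


def test_hierarchy_consistency_property():
    """Gated non-enzymes never carry ECs; assignments never exceed k_max."""
    table, outputs, channels = _tuning_setup(n=40, seed=9)
    policy = IntegrationPolicy(tau1=0.5, tau3=0.05, count_rule="ignore-count",
                               identity_floor=0.4, k_max=4)
    assignments = integrate(policy, table.ids, outputs, channels)
    for rid, out in zip(table.ids, outputs):
        if out.p_enzyme < policy.tau1:
            assert assignments[rid] == []
        assert len(assignments[rid]) <= 4
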