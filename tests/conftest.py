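import numpy as np
import pytest

import enzannot as ez
from enzannot.model import ModelConfig


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark: 2,000 records, 24 motif-bound
    EC labels, 30% non-enzymes, 5% mutation rate, seed 7."""
    config = ez.STANDARD_BENCHMARK
    space = ez.standard_benchmark_space(config)
    table, truth = ez.simulate_records(config, space)
    return config, space, table, truth


def split_80_10_10(table, seed):
    ids = table.ids
    order = np.random.default_rng(seed).permutation(len(ids))
    n = len(ids)
    n_tune, n_test = n // 10, n // 10
    tune = [ids[j] for j in order[:n_tune]]
    test = [ids[j] for j in order[n_tune : n_tune + n_test]]
    train = [ids[j] for j in order[n_tune + n_test :]]
    return table.subset(train), table.subset(tune), table.subset(test)


def fixture_model_config(vocab, seed=7, max_epochs=40):
    """Desk-scale training configuration used on the standard benchmark."""
    return ModelConfig(
        hidden_width=32,
        attention_heads=4,
        ec_vocabulary=tuple(vocab),
        batch_size=128,
        max_epochs=max_epochs,
        patience=10,
        learning_rate=1e-2,
        seed=seed,
    )


@pytest.fixture(scope="session")
def trained_benchmark(benchmark):
    """Model trained once on the benchmark's 80% split, with the greedy
    integration policy tuned on the 10% tuning split; shared by the
    end-to-end tests."""
    from enzannot.integrate import align_transfer, greedy_integrate, model_channel

    config, space, table, truth = benchmark
    train_t, tune_t, test_t = split_80_10_10(table, config.seed)
    emb = ez.embed_table(table, "onehot", max_len=config.length_range[1])
    vocab = tuple(sorted(table.vocabulary))
    mc = fixture_model_config(vocab)
    model = ez.train(
        train_t,
        {i: emb[i] for i in train_t.ids},
        mc,
        tune_t,
        {i: emb[i] for i in tune_t.ids},
    )
    outs_tune = model.predict({i: emb[i] for i in tune_t.ids}, ids=tune_t.ids)
    channels_tune = [
        model_channel(tune_t.ids, outs_tune, vocab),
        align_transfer({r.id: r.sequence for r in tune_t}, train_t),
    ]
    policy, tune_score, log = greedy_integrate(
        channels_tune, tune_t.ids, outs_tune, tune_t, k_max=mc.k_max
    )
    return {
        "config": config,
        "space": space,
        "table": table,
        "splits": (train_t, tune_t, test_t),
        "embeddings": emb,
        "vocab": vocab,
        "model": model,
        "policy": policy,
        "tune_score": tune_score,
        "greedy_log": log,
    }
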