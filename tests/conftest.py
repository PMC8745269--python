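from types import SimpleNamespace

import pytest

from condrank import (
    ConditionVocabulary,
    GeneratorConfig,
    LRMConfig,
    ModelBundle,
    PipelineConfig,
    generate_dataset,
    split_by_transformation,
)

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def vocab():
    return ConditionVocabulary()


@pytest.fixture(scope="session")
def benchmark():
    """500-record rule-generated dataset with 10% label noise, an 80/20
    transformation-level split, and a desk-scale likelihood model trained on
    the training side.  Shared by the pipeline-level tests."""
    data = generate_dataset(
        GeneratorConfig(n_reactions=500, seed=BENCHMARK_SEED, noise_rate=0.1)
    )
    train_idx, test_idx = split_by_transformation(
        data.lines, data.records, (0.8, 0.2), seed=BENCHMARK_SEED
    )
    config = PipelineConfig(
        lrm=LRMConfig(hidden_size=256, epochs=200, seed=BENCHMARK_SEED),
        seed=BENCHMARK_SEED,
    )
    bundle = ModelBundle.train(
        [data.lines[i] for i in train_idx],
        [data.records[i] for i in train_idx],
        config,
    )
    return SimpleNamespace(
        data=data,
        train_idx=train_idx,
        test_idx=test_idx,
        bundle=bundle,
        train_lines=[data.lines[i] for i in train_idx],
        train_records=[data.records[i] for i in train_idx],
        test_lines=[data.lines[i] for i in test_idx],
        test_records=[data.records[i] for i in test_idx],
    )
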