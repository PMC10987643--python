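"""Canonical desk-scale training recipes on the synthetic fixture.

These are the package's own reference runs: a 500-sentence synthetic corpus
with the mock contextual backend, trained on one CPU in a few minutes.  The
model dimensions are scaled down from the benchmark defaults (encoder 32
per direction instead of 256, feature dims 16/16/24/32 instead of
50/50/64/768) because the synthetic task is far easier than the benchmarks
and the full-size model adds nothing but runtime here.
"""

from __future__ import annotations

from dataclasses import replace

from .evaluation import MetricReport, evaluate_corpus
from .fixtures import FixtureSpec, mock_contextual_backend, train_test_fixture
from .model import TaggerModel
from .training import TrainConfig, train_model

__all__ = ["desk_config", "fixture_learnability_run"]


def desk_config(seed: int = 0, **overrides) -> TrainConfig:
    """The desk-scale hyperparameters for fixture runs."""
    base = TrainConfig(
        seed=seed,
        max_epochs=30,
        patience=5,
        batch_size=16,
        learning_rate=2e-3,
        hidden_per_direction=32,
        d_pos=16,
        d_char=16,
        d_lm=24,
        d_ctx=32,
        dropout=0.2,
        charlm_epochs=1,
    )
    return replace(base, **overrides) if overrides else base


def fixture_learnability_run(
    seed: int = 0, n_sentences: int = 500, **config_overrides
) -> tuple[TaggerModel, list[dict], MetricReport]:
    """Train the full model on the synthetic fixture and score the test split.

    The test split draws 20% of its entity surfaces from forms never seen in
    training, so the reported strict F1 includes out-of-vocabulary
    generalization.  Returns (model, epoch log, test report).
    """
    spec = FixtureSpec(n_sentences=n_sentences, seed=seed)
    train, test = train_test_fixture(spec)
    config = desk_config(seed=seed, **config_overrides)
    backend = mock_contextual_backend(d_ctx=config.d_ctx, seed=seed)
    model, log = train_model(config, train, backend=backend)
    report = evaluate_corpus(model, test)
    return model, log, report
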