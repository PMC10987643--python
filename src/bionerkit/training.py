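"""Training protocol: splitting, batching, optimization, early stopping, ablation.

The experimental protocol merges the provided training and development sets
into one pool and holds out a seeded 10% validation split; the test file is
never touched during training.  Optimization is AdamW with gradient-norm
clipping; per-epoch validation uses strict entity-level F1, the
best-validation checkpoint is retained, and training stops at ``max_epochs``
or after ``patience`` epochs without improvement.
"""

from __future__ import annotations

import copy
import logging
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .charlm import CharLMConfig, train_charlm
from .corpus import Corpus, LabeledSentence, validate_bio
from .crf import LabelSet
from .embeddings import ContextualBackend, EmbeddingConfig, EmbeddingLayer
from .evaluation import MetricReport, evaluate_corpus
from .fixtures import mock_contextual_backend
from .model import EncoderConfig, TaggerModel
from .nn import AdamW, clip_global_norm
from .postag import PosTagger, rule_pos_tagger
from .vocab import CharVocab, PosVocab

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SplitPlan", "make_split", "train_model", "run_ablation"]

#: Ablation switch names accepted by :class:`TrainConfig`.
ABLATION_SWITCHES = ("pos", "char", "charlm", "ctx", "bilstm", "crf")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference protocol: subword budget 128, batch size
    64, encoder hidden size 256 per direction, at most 100 epochs, 10%
    validation split.  ``switches`` holds the ablation flags; all on by
    default.  Embedding dimensions are carried here so a config file fully
    determines the model.
    """

    max_length: int = 128
    batch_size: int = 64
    learning_rate: float = 1e-3
    hidden_per_direction: int = 256
    max_epochs: int = 100
    validation_fraction: float = 0.10
    patience: int = 10
    seed: int = 0
    dropout: float = 0.5
    grad_clip: float = 5.0
    weight_decay: float = 0.0
    d_pos: int = 50
    d_char: int = 50
    d_lm: int = 64
    d_ctx: int = 768
    charlm_epochs: int = 3
    bio_constraints: bool = True
    switches: dict[str, bool] = field(
        default_factory=lambda: {name: True for name in ABLATION_SWITCHES}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        unknown = set(self.switches) - set(ABLATION_SWITCHES)
        if unknown:
            raise ValueError(f"unknown ablation switches: {sorted(unknown)}")
        for name in ABLATION_SWITCHES:
            self.switches.setdefault(name, True)
        if not any(
            self.switches[name] for name in ("pos", "char", "charlm", "ctx")
        ):
            raise ValueError("at least one embedding component must be enabled")

    def embedding_config(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            d_pos=self.d_pos,
            d_char=self.d_char,
            d_lm=self.d_lm,
            d_ctx=self.d_ctx,
            max_length=self.max_length,
            use_pos=self.switches["pos"],
            use_char=self.switches["char"],
            use_charlm=self.switches["charlm"],
            use_ctx=self.switches["ctx"],
        )


@dataclass(frozen=True)
class SplitPlan:
    """Seeded partition of the merged training pool into train and validation."""

    train_indices: tuple[int, ...]
    val_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.val_indices):
            raise ValueError("train and validation indices overlap")


def make_split(
    train: Corpus,
    dev: Corpus | None,
    fraction: float = 0.10,
    seed: int = 0,
) -> tuple[Corpus, SplitPlan]:
    """Merge train and dev, then hold out a seeded validation subset.

    Returns the merged pool and the index plan; validation size is
    ``round(fraction * pool size)`` (at least 1).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    sentences = list(train.sentences) + (list(dev.sentences) if dev else [])
    if not sentences:
        raise ValueError("cannot split an empty pool")
    pool = Corpus(sentences)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sentences))
    n_val = min(max(1, int(round(fraction * len(sentences)))), len(sentences) - 1)
    return pool, SplitPlan(
        train_indices=tuple(int(i) for i in order[n_val:]),
        val_indices=tuple(int(i) for i in order[:n_val]),
    )


def _subcorpus(pool: Corpus, indices: tuple[int, ...]) -> Corpus:
    return Corpus([pool.sentences[i] for i in indices])


def _ensure_pos_tags(corpus: Corpus, tagger: PosTagger) -> None:
    for sent in corpus:
        if sent.pos_tags is None:
            sent.pos_tags = tagger(sent.words)


def _check_gold_validity(corpus: Corpus) -> None:
    bad = [i for i, s in enumerate(corpus) if validate_bio(s.tags)]
    if bad:
        raise ValueError(
            f"gold BIO violations under hard constraints in sentences {bad[:20]}"
            + (" ..." if len(bad) > 20 else "")
        )


def _filter_overlength(
    corpus: Corpus, backend: ContextualBackend | None, max_length: int
) -> Corpus:
    if backend is None:
        return corpus
    kept, dropped = [], 0
    for sent in corpus:
        n_sub = 2 + sum(len(backend.subword_tokenize(w)) for w in sent.words)
        if n_sub <= max_length:
            kept.append(sent)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"skipped {dropped} over-length sentence(s) exceeding the "
            f"subword budget of {max_length}",
            stacklevel=2,
        )
    return Corpus(kept)


def build_model(
    config: TrainConfig,
    pool: Corpus,
    backend: ContextualBackend | None,
    pos_tagger: PosTagger = rule_pos_tagger,
) -> TaggerModel:
    """Assemble vocabularies, char-LMs and the tagger for a training pool."""
    sw = config.switches
    _ensure_pos_tags(pool, pos_tagger)
    pos_vocab = (
        PosVocab.from_symbols(s for sent in pool for s in sent.pos_tags)
        if sw["pos"]
        else None
    )
    char_vocab = (
        CharVocab.from_text(w + " " for sent in pool for w in sent.words)
        if sw["char"] or sw["charlm"]
        else None
    )
    charlm_fwd = charlm_bwd = None
    if sw["charlm"]:
        lm_config = CharLMConfig(
            d_hidden=config.d_lm, epochs=config.charlm_epochs, seed=config.seed
        )
        sentences = [sent.words for sent in pool]
        logger.info("training forward/backward character LMs")
        charlm_fwd, _ = train_charlm(sentences, "forward", lm_config, char_vocab)
        charlm_bwd, _ = train_charlm(sentences, "backward", lm_config, char_vocab)
    if sw["ctx"] and backend is None:
        raise ValueError("contextual component enabled but no backend provided")
    emb_config = config.embedding_config()
    if sw["ctx"]:
        emb_config.d_ctx = backend.d_ctx
    embedding_layer = EmbeddingLayer(
        emb_config,
        np.random.default_rng(config.seed + 2),
        pos_vocab=pos_vocab,
        char_vocab=char_vocab if sw["char"] else None,
        charlm_forward=charlm_fwd,
        charlm_backward=charlm_bwd,
        backend=backend if sw["ctx"] else None,
        pos_tagger=pos_tagger,
    )
    labelset = LabelSet.from_labels(pool.label_inventory)
    return TaggerModel(
        labelset,
        embedding_layer,
        EncoderConfig(
            hidden_per_direction=config.hidden_per_direction, dropout=config.dropout
        ),
        use_bilstm=sw["bilstm"],
        use_crf=sw["crf"],
        bio_constraints=config.bio_constraints,
        seed=config.seed + 3,
    )


def _length_bucketed_batches(
    lengths: list[int], batch_size: int, rng: np.random.Generator
) -> list[list[int]]:
    # Bucket by length for cache-friendliness, then shuffle batch order.
    order = sorted(range(len(lengths)), key=lambda i: (lengths[i], i))
    batches = [
        order[i : i + batch_size] for i in range(0, len(order), batch_size)
    ]
    rng.shuffle(batches)
    return batches


def train_model(
    config: TrainConfig,
    train: Corpus,
    dev: Corpus | None = None,
    backend: ContextualBackend | None = None,
    pos_tagger: PosTagger = rule_pos_tagger,
) -> tuple[TaggerModel, list[dict]]:
    """Train a tagger under the standard protocol; returns (model, epoch log).

    The returned model carries the parameters of the epoch with the best
    validation entity-level F1.
    """
    if len(train) == 0:
        raise ValueError("empty training corpus")
    pool = Corpus(list(train.sentences) + (list(dev.sentences) if dev else []))
    _ensure_pos_tags(pool, pos_tagger)
    if config.switches["ctx"]:
        pool = _filter_overlength(pool, backend, config.max_length)
    pool, plan = make_split(
        pool, None, fraction=config.validation_fraction, seed=config.seed
    )
    if config.switches["crf"] and config.bio_constraints:
        _check_gold_validity(pool)
    model = build_model(config, pool, backend, pos_tagger)
    train_part = _subcorpus(pool, plan.train_indices)
    val_part = _subcorpus(pool, plan.val_indices)

    params = model.parameters()
    optimizer = AdamW(
        params, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    shuffle_rng = np.random.default_rng(config.seed + 4)
    lengths = [len(s) for s in train_part]

    best_f1 = -1.0
    best_state: list[np.ndarray] | None = None
    best_epoch = 0
    log: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        batches = _length_bucketed_batches(lengths, config.batch_size, shuffle_rng)
        total_loss, total_sents = 0.0, 0
        for batch in batches:
            optimizer.zero_grad()
            for i in batch:
                sent = train_part.sentences[i]
                total_loss += model.loss_and_grad(
                    sent.words, sent.tags, sent.pos_tags
                )
            for p in params:
                p.grad /= len(batch)
            clip_global_norm(params, config.grad_clip)
            optimizer.step()
            total_sents += len(batch)
        train_loss = total_loss / max(total_sents, 1)
        if not np.isfinite(train_loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        report = evaluate_corpus(model, val_part)
        elapsed = time.perf_counter() - t0
        entry = {
            "epoch": epoch,
            "train_loss": float(train_loss),
            "val_P": report.precision,
            "val_R": report.recall,
            "val_F1": report.f1,
            "elapsed": elapsed,
        }
        log.append(entry)
        logger.info(
            "epoch %d loss %.4f val F1 %.4f (%.1fs)",
            epoch, train_loss, report.f1, elapsed,
        )
        if report.f1 > best_f1:
            best_f1 = report.f1
            best_epoch = epoch
            best_state = [p.value.copy() for p in params]
        elif epoch - best_epoch >= config.patience:
            break
    if best_state is not None:
        for p, v in zip(params, best_state):
            p.value[...] = v
    return model, log


#: The standard ablation grid: the full model plus each component removed.
DEFAULT_ABLATION_GRID: list[tuple[str, dict[str, bool]]] = [
    ("full", {}),
    ("without_pos", {"pos": False}),
    ("without_char", {"char": False}),
    ("without_charlm", {"charlm": False}),
    ("without_ctx", {"ctx": False}),
    ("without_bilstm", {"bilstm": False}),
    ("without_crf", {"crf": False}),
]


def run_ablation(
    config: TrainConfig,
    train: Corpus,
    test: Corpus,
    dev: Corpus | None = None,
    backend: ContextualBackend | None = None,
    grid: list[tuple[str, dict[str, bool]]] | None = None,
    pos_tagger: PosTagger = rule_pos_tagger,
) -> list[dict]:
    """Train one model per ablation condition and report P/R/F1 on ``test``.

    Each condition overrides the named switches; a condition that disables
    every embedding component is a config error.  Rows are reported as-is —
    no ordering between the full model and ablated rows is assumed.
    """
    rows: list[dict] = []
    for name, overrides in grid or DEFAULT_ABLATION_GRID:
        switches = {s: True for s in ABLATION_SWITCHES}
        switches.update(overrides)
        cond_config = replace(config, switches=switches)
        model, _ = train_model(
            cond_config, train, dev, backend=backend, pos_tagger=pos_tagger
        )
        report = evaluate_corpus(model, test)
        rows.append(
            {
                "condition": name,
                "P": report.precision,
                "R": report.recall,
                "F1": report.f1,
            }
        )
        logger.info("ablation %s: F1 %.4f", name, report.f1)
    return rows
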