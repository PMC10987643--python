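"""The multi-feature embedding layer.

Each word of a sentence receives up to four feature vectors, concatenated in
a fixed order into one long input vector for the sequence encoder:

1. **POS** — the word's part-of-speech symbol, one-hot encoded over the POS
   inventory and projected to ``d_pos`` dimensions by a jointly-trained map.
2. **Char** — a bidirectional recurrent encoder over the word's characters;
   the final forward and backward states are concatenated to ``d_char``.
3. **Char-LM** — forward and backward corpus-trained character language
   models read at word boundaries (``d_lm`` each direction); frozen.
4. **Contextual** — per-word vectors from a transformer-style subword
   encoder behind a pluggable contract (``d_ctx``); words are aligned to
   their first subword by default; frozen.

Any component can be disabled (ablation); the concatenation then simply
omits that block and the remaining blocks keep their relative order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .charlm import CharLanguageModel, embed_charlm
from .nn import LSTM, Embedding, Parameter
from .postag import PosTagger, rule_pos_tagger
from .vocab import CharVocab, PosVocab

__all__ = [
    "EmbeddingConfig",
    "ContextualBackend",
    "OverLengthError",
    "PosEmbedder",
    "CharEncoder",
    "embed_pos",
    "embed_contextual",
    "concat_embeddings",
    "EmbeddingLayer",
]

COMPONENT_ORDER = ("pos", "char", "lm_forward", "lm_backward", "ctx")


class OverLengthError(ValueError):
    """A sentence's subword expansion exceeds the contextual length budget."""


@dataclass
class EmbeddingConfig:
    """Dimensions and switches for the embedding layer.

    ``d_pos`` and ``d_char`` default to 50 and ``d_ctx`` to 768, matching the
    reference architecture; ``d_lm`` (per direction) defaults to 64.
    ``max_length`` is the subword budget including the two boundary markers.
    """

    d_pos: int = 50
    d_char: int = 50
    d_lm: int = 64
    d_ctx: int = 768
    max_length: int = 128
    align: str = "first"  # or "mean"
    overlength: str = "truncate"  # or "error"
    use_pos: bool = True
    use_char: bool = True
    use_charlm: bool = True
    use_ctx: bool = True

    def __post_init__(self) -> None:
        for name in ("d_pos", "d_char", "d_lm", "d_ctx"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_length < 3:
            raise ValueError("max_length must leave room for the boundary markers")
        if self.align not in ("first", "mean"):
            raise ValueError(f"unknown alignment: {self.align!r}")
        if self.d_char % 2:
            raise ValueError("d_char must be even (two directions)")

    @property
    def concat_dim(self) -> int:
        total = 0
        if self.use_pos:
            total += self.d_pos
        if self.use_char:
            total += self.d_char
        if self.use_charlm:
            total += 2 * self.d_lm
        if self.use_ctx:
            total += self.d_ctx
        return total


@runtime_checkable
class ContextualBackend(Protocol):
    """Contract a contextual subword encoder must satisfy.

    ``encode`` receives the full boundary-marked, padded subword sequence and
    returns one ``d_ctx``-dimensional vector per subword position.
    """

    d_ctx: int
    cls_token: str
    sep_token: str
    pad_token: str

    def subword_tokenize(self, word: str) -> list[str]: ...

    def encode(self, subwords: Sequence[str]) -> np.ndarray: ...


class PosEmbedder:
    """One-hot POS encoding projected to ``d_pos`` by a trainable map."""

    def __init__(self, vocab: PosVocab, d_pos: int, rng: np.random.Generator) -> None:
        self.vocab = vocab
        self.table = Embedding(len(vocab), d_pos, rng)

    def parameters(self) -> list[Parameter]:
        return self.table.parameters()

    def forward(self, symbols: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(self.vocab.encode(symbols), dtype=np.int64)
        return self.table.forward(ids)

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> None:
        self.table.backward(dy, cache)


def embed_pos(
    symbols: Sequence[str], vocab: PosVocab, projection: np.ndarray
) -> np.ndarray:
    """Functional form: rows of ``projection`` indexed by POS symbol.

    Equivalent to one-hot encoding followed by ``onehot @ projection``; the
    output row for a word depends only on that word's symbol.
    """
    if projection.shape[0] != len(vocab):
        raise ValueError(
            f"projection input dim {projection.shape[0]} != |vocab| {len(vocab)}"
        )
    ids = vocab.encode(symbols)
    return projection[ids]


class CharEncoder:
    """Per-word character BiLSTM; output is the two final states concatenated."""

    def __init__(
        self,
        vocab: CharVocab,
        d_char: int,
        rng: np.random.Generator,
        d_emb: int = 25,
    ) -> None:
        self.vocab = vocab
        self.h = d_char // 2
        self.emb = Embedding(len(vocab), d_emb, rng)
        self.fwd = LSTM(d_emb, self.h, rng)
        self.bwd = LSTM(d_emb, self.h, rng)

    def parameters(self) -> list[Parameter]:
        return self.emb.parameters() + self.fwd.parameters() + self.bwd.parameters()

    def forward(self, word: str) -> tuple[np.ndarray, dict]:
        if not word:
            raise ValueError("cannot encode an empty word")
        ids = np.asarray(self.vocab.encode(word), dtype=np.int64)
        xs, cache_e = self.emb.forward(ids)
        hs_f, cache_f = self.fwd.forward(xs)
        hs_b, cache_b = self.bwd.forward(xs[::-1])
        vec = np.concatenate([hs_f[-1], hs_b[-1]])
        cache = {"e": cache_e, "f": cache_f, "b": cache_b, "n": len(ids)}
        return vec, cache

    def backward(self, dvec: np.ndarray, cache: dict) -> None:
        n, h = cache["n"], self.h
        dhs_f = np.zeros((n, h))
        dhs_f[-1] = dvec[:h]
        dhs_b = np.zeros((n, h))
        dhs_b[-1] = dvec[h:]
        dxs = self.fwd.backward(dhs_f, cache["f"])
        dxs += self.bwd.backward(dhs_b, cache["b"])[::-1]
        self.emb.backward(dxs, cache["e"])


def embed_contextual(
    words: Sequence[str],
    backend: ContextualBackend,
    max_length: int = 128,
    align: str = "first",
    overlength: str = "truncate",
) -> np.ndarray:
    """Per-word vectors from a contextual subword encoder.

    The sentence is subword-tokenized, wrapped in boundary markers, padded to
    ``max_length``, and encoded; each word receives the vector of its first
    subword (or the mean over its subwords).  Boundary and padding vectors
    are discarded.  Sentences whose expansion exceeds ``max_length - 2``
    either raise :class:`OverLengthError` or are truncated, in which case
    words with no surviving subword receive zero vectors.
    """
    pieces = [backend.subword_tokenize(w) for w in words]
    for w, p in zip(words, pieces):
        if not p:
            raise ValueError(f"backend produced no subwords for {w!r}")
    flat: list[str] = [backend.cls_token]
    word_slices: list[tuple[int, int]] = []
    for p in pieces:
        word_slices.append((len(flat), len(flat) + len(p)))
        flat.extend(p)
    flat.append(backend.sep_token)
    if len(flat) > max_length:
        if overlength == "error":
            raise OverLengthError(
                f"{len(flat)} subwords exceed the budget of {max_length}"
            )
        flat = flat[: max_length - 1] + [backend.sep_token]
    budget = len(flat) - 1  # positions before the closing marker
    padded = flat + [backend.pad_token] * (max_length - len(flat))
    vectors = np.asarray(backend.encode(padded))
    if vectors.shape != (max_length, backend.d_ctx):
        raise ValueError(
            f"backend returned {vectors.shape}, expected "
            f"{(max_length, backend.d_ctx)}"
        )
    out = np.zeros((len(words), backend.d_ctx))
    for i, (lo, hi) in enumerate(word_slices):
        hi = min(hi, budget)
        if lo >= hi:
            continue  # truncated away
        out[i] = vectors[lo] if align == "first" else vectors[lo:hi].mean(axis=0)
    return out


def concat_embeddings(components: dict[str, np.ndarray]) -> np.ndarray:
    """Concatenate per-token feature blocks in the fixed component order."""
    present = [name for name in COMPONENT_ORDER if name in components]
    if not present:
        raise ValueError("at least one embedding component is required")
    lengths = {components[name].shape[0] for name in present}
    if len(lengths) > 1:
        raise ValueError(f"component length mismatch: {sorted(lengths)}")
    return np.concatenate([components[name] for name in present], axis=1)


class EmbeddingLayer:
    """Orchestrates the enabled feature components for whole sentences.

    The POS projection and the character encoder are trained jointly with
    the tagger; the char-LMs and the contextual backend are frozen feature
    extractors, so gradients stop at their outputs.
    """

    def __init__(
        self,
        config: EmbeddingConfig,
        rng: np.random.Generator,
        pos_vocab: PosVocab | None = None,
        char_vocab: CharVocab | None = None,
        charlm_forward: CharLanguageModel | None = None,
        charlm_backward: CharLanguageModel | None = None,
        backend: ContextualBackend | None = None,
        pos_tagger: PosTagger = rule_pos_tagger,
    ) -> None:
        self.config = config
        self.pos_tagger = pos_tagger
        self.pos_embedder = None
        self.char_encoder = None
        self.charlm_forward = charlm_forward
        self.charlm_backward = charlm_backward
        self.backend = backend
        if config.use_pos:
            if pos_vocab is None:
                raise ValueError("use_pos requires a PosVocab")
            self.pos_embedder = PosEmbedder(pos_vocab, config.d_pos, rng)
        if config.use_char:
            if char_vocab is None:
                raise ValueError("use_char requires a CharVocab")
            self.char_encoder = CharEncoder(char_vocab, config.d_char, rng)
        if config.use_charlm and (charlm_forward is None or charlm_backward is None):
            raise ValueError("use_charlm requires both trained char-LMs")
        if config.use_ctx and backend is None:
            raise ValueError("use_ctx requires a contextual backend")
        if config.use_ctx and backend is not None and backend.d_ctx != config.d_ctx:
            raise ValueError(
                f"backend d_ctx {backend.d_ctx} != config d_ctx {config.d_ctx}"
            )

    @property
    def dim(self) -> int:
        return self.config.concat_dim

    def component_offsets(self) -> dict[str, tuple[int, int]]:
        """Column range of each enabled block within the concatenation."""
        dims = {
            "pos": self.config.d_pos if self.config.use_pos else 0,
            "char": self.config.d_char if self.config.use_char else 0,
            "lm_forward": self.config.d_lm if self.config.use_charlm else 0,
            "lm_backward": self.config.d_lm if self.config.use_charlm else 0,
            "ctx": self.config.d_ctx if self.config.use_ctx else 0,
        }
        offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for name in COMPONENT_ORDER:
            if dims[name]:
                offsets[name] = (pos, pos + dims[name])
                pos += dims[name]
        return offsets

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        if self.pos_embedder is not None:
            params += self.pos_embedder.parameters()
        if self.char_encoder is not None:
            params += self.char_encoder.parameters()
        return params

    def forward(
        self, words: Sequence[str], pos_symbols: Sequence[str] | None = None
    ) -> tuple[np.ndarray, dict]:
        cfg = self.config
        components: dict[str, np.ndarray] = {}
        cache: dict = {}
        if cfg.use_pos:
            symbols = pos_symbols if pos_symbols is not None else self.pos_tagger(words)
            if len(symbols) != len(words):
                raise ValueError(
                    f"POS tagger returned {len(symbols)} symbols for "
                    f"{len(words)} words"
                )
            components["pos"], cache["pos"] = self.pos_embedder.forward(symbols)
        if cfg.use_char:
            vecs, caches = [], []
            for word in words:
                v, c = self.char_encoder.forward(word)
                vecs.append(v)
                caches.append(c)
            components["char"] = np.stack(vecs)
            cache["char"] = caches
        if cfg.use_charlm:
            fwd, bwd = embed_charlm(words, self.charlm_forward, self.charlm_backward)
            components["lm_forward"], components["lm_backward"] = fwd, bwd
        if cfg.use_ctx:
            components["ctx"] = embed_contextual(
                words,
                self.backend,
                max_length=cfg.max_length,
                align=cfg.align,
                overlength=cfg.overlength,
            )
        return concat_embeddings(components), cache

    def backward(self, dX: np.ndarray, cache: dict) -> None:
        offsets = self.component_offsets()
        if "pos" in cache:
            lo, hi = offsets["pos"]
            self.pos_embedder.backward(dX[:, lo:hi], cache["pos"])
        if "char" in cache:
            lo, hi = offsets["char"]
            for i, word_cache in enumerate(cache["char"]):
                self.char_encoder.backward(dX[i, lo:hi], word_cache)
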