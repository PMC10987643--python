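"""Corpus-trained character-level language models ("data-specific" embeddings).

Two unidirectional recurrent LMs — one reading the sentence's character
stream left-to-right, one right-to-left — are trained on the task corpora
with a next-character objective.  Word embeddings are then read off the
hidden states at word boundaries, following the contextual-string-embedding
convention: the forward vector of a word is the LM state after consuming the
word's *last* character, and the backward vector is the reverse LM state
after consuming (in reverse) the word's *first* character.  Trained LMs are
frozen feature extractors for the tagger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import LSTM, AdamW, Embedding, Linear, softmax_cross_entropy
from .vocab import CharVocab

__all__ = [
    "CharLMConfig",
    "CharLanguageModel",
    "train_charlm",
    "embed_charlm",
    "heldout_perplexity",
]


@dataclass
class CharLMConfig:
    """Character-LM hyperparameters; ``d_hidden`` is the per-direction feature size."""

    d_hidden: int = 64
    d_emb: int = 25
    epochs: int = 3
    learning_rate: float = 2e-3
    heldout_fraction: float = 0.1
    seed: int = 0


class CharLanguageModel:
    """A next-character (or previous-character) recurrent LM over a CharVocab."""

    def __init__(
        self,
        vocab: CharVocab,
        direction: str,
        config: CharLMConfig,
        rng: np.random.Generator,
    ) -> None:
        if direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction: {direction!r}")
        self.vocab = vocab
        self.direction = direction
        self.config = config
        self.emb = Embedding(len(vocab), config.d_emb, rng)
        self.lstm = LSTM(config.d_emb, config.d_hidden, rng)
        self.head = Linear(config.d_hidden, len(vocab), rng)

    @property
    def d_hidden(self) -> int:
        return self.config.d_hidden

    def parameters(self):
        return self.emb.parameters() + self.lstm.parameters() + self.head.parameters()

    def _stream_ids(self, text: str) -> np.ndarray:
        ids = np.asarray(self.vocab.encode(text), dtype=np.int64)
        return ids if self.direction == "forward" else ids[::-1]

    def hidden_states(self, text: str) -> np.ndarray:
        """Hidden state after each consumed character of the directed stream."""
        ids = self._stream_ids(text)
        xs, _ = self.emb.forward(ids)
        hs, _ = self.lstm.forward(xs)
        return hs

    def step_loss(self, text: str, optimizer: AdamW | None = None) -> float:
        """Next-character cross-entropy on one sentence; backprops if optimizing."""
        ids = self._stream_ids(text)
        if len(ids) < 2:
            return 0.0
        inputs, targets = ids[:-1], ids[1:]
        xs, cache_e = self.emb.forward(inputs)
        hs, cache_l = self.lstm.forward(xs)
        logits, cache_h = self.head.forward(hs)
        loss, dlogits = softmax_cross_entropy(logits, targets)
        if optimizer is not None:
            dhs = self.head.backward(dlogits, cache_h)
            dxs = self.lstm.backward(dhs, cache_l)
            self.emb.backward(dxs, cache_e)
        return loss

    def state_arrays(self) -> dict[str, np.ndarray]:
        names = ["emb", "W", "U", "b", "headW", "headb"]
        return {n: p.value for n, p in zip(names, self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        names = ["emb", "W", "U", "b", "headW", "headb"]
        for n, p in zip(names, self.parameters()):
            p.value[...] = arrays[n]


def sentence_stream(words: Sequence[str]) -> str:
    """The running character stream of a sentence: words joined by single spaces."""
    return " ".join(words)


def heldout_perplexity(model: CharLanguageModel, texts: Sequence[str]) -> float:
    """Per-character perplexity of the model on a list of sentence streams."""
    total_loss, total_chars = 0.0, 0
    for text in texts:
        n = len(text) - 1
        if n <= 0:
            continue
        total_loss += model.step_loss(text) * n
        total_chars += n
    if total_chars == 0:
        raise ValueError("held-out slice contains no scoreable characters")
    return float(np.exp(total_loss / total_chars))


def train_charlm(
    sentences: Sequence[Sequence[str]],
    direction: str,
    config: CharLMConfig | None = None,
    vocab: CharVocab | None = None,
) -> tuple[CharLanguageModel, list[dict]]:
    """Train a character LM on the corpus text; returns the model and a log.

    The log records held-out perplexity before training and after each epoch,
    so callers can verify the loss actually decreased.
    """
    if not sentences:
        raise ValueError("cannot train a character LM on an empty corpus")
    config = config or CharLMConfig()
    streams = [sentence_stream(ws) for ws in sentences]
    if vocab is None:
        vocab = CharVocab.from_text(streams)
    rng = np.random.default_rng(config.seed)
    model = CharLanguageModel(vocab, direction, config, rng)

    n_held = max(1, int(round(config.heldout_fraction * len(streams))))
    order = rng.permutation(len(streams))
    held = [streams[i] for i in order[:n_held]]
    train = [streams[i] for i in order[n_held:]] or held

    optimizer = AdamW(model.parameters(), lr=config.learning_rate)
    log = [{"epoch": 0, "heldout_perplexity": heldout_perplexity(model, held)}]
    for epoch in range(1, config.epochs + 1):
        epoch_order = rng.permutation(len(train))
        losses = []
        for i in epoch_order:
            optimizer.zero_grad()
            losses.append(model.step_loss(train[i], optimizer))
            optimizer.step()
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "heldout_perplexity": heldout_perplexity(model, held),
            }
        )
    return model, log


def embed_charlm(
    words: Sequence[str],
    lm_forward: CharLanguageModel,
    lm_backward: CharLanguageModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-word forward and backward LM vectors for one sentence.

    Word ``i`` spans characters ``[s_i, e_i)`` of the running stream.  Its
    forward vector is the forward LM state at stream position ``e_i - 1``;
    its backward vector is the reverse LM state at reversed position
    ``L - 1 - s_i`` (i.e. after consuming the word's first character).
    """
    if lm_forward.direction != "forward" or lm_backward.direction != "backward":
        raise ValueError("pass (forward LM, backward LM) in that order")
    text = sentence_stream(words)
    length = len(text)
    hs_f = lm_forward.hidden_states(text)
    hs_b = lm_backward.hidden_states(text)
    fwd = np.empty((len(words), lm_forward.d_hidden))
    bwd = np.empty((len(words), lm_backward.d_hidden))
    pos = 0
    for i, word in enumerate(words):
        start, end = pos, pos + len(word)
        fwd[i] = hs_f[end - 1]
        bwd[i] = hs_b[length - 1 - start]
        pos = end + 1  # skip the separating space
    return fwd, bwd
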