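"""The sequence tagger: embeddings -> BiLSTM -> emissions -> CRF.

The concatenated feature vectors are encoded by a bidirectional LSTM whose
per-direction hidden size defaults to 256, giving 512-dimensional word
representations; a fully connected layer maps these to per-label emission
scores, and a linear-chain CRF with learned boundary transitions and a hard
BIO constraint mask selects the best label sequence by Viterbi decoding.
Ablation switches replace the CRF by an independent per-token softmax head
and/or bypass the BiLSTM (emissions projected straight from the embedding
vectors).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import crf as crf_ops
from .charlm import CharLanguageModel, CharLMConfig
from .corpus import BioTag, EntitySpan, spans_from_bio
from .crf import LabelSet, build_constraint_mask
from .embeddings import ContextualBackend, EmbeddingConfig, EmbeddingLayer
from .nn import BiLSTM, Linear, Parameter, softmax_cross_entropy
from .postag import PosTagger, rule_pos_tagger
from .vocab import CharVocab, PosVocab

__all__ = ["EncoderConfig", "TaggerModel", "CHECKPOINT_FORMAT_VERSION"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class EncoderConfig:
    """BiLSTM encoder settings; output width is ``2 * hidden_per_direction``."""

    hidden_per_direction: int = 256
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.hidden_per_direction < 1:
            raise ValueError("hidden size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


class TaggerModel:
    """Embeddings, encoder, emission projection and decoding head in one place."""

    def __init__(
        self,
        labelset: LabelSet,
        embedding_layer: EmbeddingLayer,
        encoder_config: EncoderConfig | None = None,
        *,
        use_bilstm: bool = True,
        use_crf: bool = True,
        bio_constraints: bool = True,
        seed: int = 0,
    ) -> None:
        self.labelset = labelset
        self.embeddings = embedding_layer
        self.encoder_config = encoder_config or EncoderConfig()
        self.use_bilstm = use_bilstm
        self.use_crf = use_crf
        self.bio_constraints = bio_constraints
        self.seed = seed
        rng = np.random.default_rng(seed)
        d_in = embedding_layer.dim
        if use_bilstm:
            self.encoder = BiLSTM(d_in, self.encoder_config.hidden_per_direction, rng)
            proj_in = 2 * self.encoder_config.hidden_per_direction
        else:
            self.encoder = None
            proj_in = d_in
        self.projection = Linear(proj_in, labelset.k, rng)
        kk = labelset.k_augmented
        self.transitions = Parameter(rng.uniform(-0.1, 0.1, size=(kk, kk)))
        self.mask = build_constraint_mask(labelset, bio_constraints)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # ----- parameters ---------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = self.embeddings.parameters()
        if self.encoder is not None:
            params += self.encoder.parameters()
        params += self.projection.parameters()
        if self.use_crf:
            params.append(self.transitions)
        return params

    @property
    def encoder_output_dim(self) -> int:
        if self.encoder is None:
            return self.embeddings.dim
        return 2 * self.encoder_config.hidden_per_direction

    # ----- forward ------------------------------------------------------

    def encode(self, bundle: np.ndarray) -> np.ndarray:
        """Encoder output for an embedding matrix (identity when ablated)."""
        if self.encoder is None:
            return bundle
        out, _ = self.encoder.forward(bundle)
        return out

    def emissions(
        self,
        words: Sequence[str],
        pos_symbols: Sequence[str] | None = None,
        *,
        train: bool = False,
    ) -> tuple[np.ndarray, dict]:
        bundle, emb_cache = self.embeddings.forward(words, pos_symbols)
        cache: dict = {"emb": emb_cache}
        if self.encoder is not None:
            encoded, cache["enc"] = self.encoder.forward(bundle)
        else:
            encoded = bundle
        drop = self.encoder_config.dropout
        if train and drop > 0.0:
            keep = (self._dropout_rng.random(encoded.shape) >= drop) / (1.0 - drop)
            encoded = encoded * keep
            cache["drop"] = keep
        P, cache["proj"] = self.projection.forward(encoded)
        return P, cache

    def _backprop_emissions(self, dP: np.ndarray, cache: dict) -> None:
        d_enc = self.projection.backward(dP, cache["proj"])
        if "drop" in cache:
            d_enc = d_enc * cache["drop"]
        if self.encoder is not None:
            d_bundle = self.encoder.backward(d_enc, cache["enc"])
        else:
            d_bundle = d_enc
        self.embeddings.backward(d_bundle, cache["emb"])

    def loss_and_grad(
        self,
        words: Sequence[str],
        gold: Sequence[BioTag],
        pos_symbols: Sequence[str] | None = None,
    ) -> float:
        """Sentence loss; accumulates gradients into all trainable parameters."""
        y = np.asarray([self.labelset.index(str(t)) for t in gold], dtype=np.int64)
        P, cache = self.emissions(words, pos_symbols, train=True)
        if self.use_crf:
            loss, dP, dT = crf_ops.crf_nll_grad(
                P, self.transitions.value, y, self.labelset, self.mask
            )
            self.transitions.grad += dT
        else:
            loss_mean, dP = softmax_cross_entropy(P, y)
            loss, dP = loss_mean * len(y), dP * len(y)
        self._backprop_emissions(dP, cache)
        return float(loss)

    # ----- decoding -----------------------------------------------------

    def decode(
        self, words: Sequence[str], pos_symbols: Sequence[str] | None = None
    ) -> list[BioTag]:
        """Best label sequence for one sentence (Viterbi, or argmax when ablated)."""
        P, _ = self.emissions(words, pos_symbols, train=False)
        if self.use_crf:
            path, _ = crf_ops.viterbi_decode(
                P, self.transitions.value, self.labelset, self.mask
            )
        else:
            path = list(P.argmax(axis=1))
        return self.labelset.tags(path)

    def predict_spans(
        self, words: Sequence[str], pos_symbols: Sequence[str] | None = None
    ) -> list[EntitySpan]:
        return spans_from_bio(self.decode(words, pos_symbols), policy="lenient")

    # ----- checkpointing ------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write all parameter blocks, configs and vocabularies to one archive."""
        path = Path(path)
        emb = self.embeddings
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "labels": list(self.labelset.labels),
            "use_bilstm": self.use_bilstm,
            "use_crf": self.use_crf,
            "bio_constraints": self.bio_constraints,
            "seed": self.seed,
            "encoder_config": asdict(self.encoder_config),
            "embedding_config": asdict(emb.config),
            "pos_symbols": list(emb.pos_embedder.vocab.symbols)
            if emb.pos_embedder
            else None,
            "char_vocab": list(emb.char_encoder.vocab.chars)
            if emb.char_encoder
            else None,
            "charlm": None,
            "backend": None,
        }
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.value
        if emb.charlm_forward is not None:
            meta["charlm"] = {
                "config": asdict(emb.charlm_forward.config),
                "chars": list(emb.charlm_forward.vocab.chars),
            }
            for direction, lm in (
                ("fwd", emb.charlm_forward),
                ("bwd", emb.charlm_backward),
            ):
                for name, arr in lm.state_arrays().items():
                    arrays[f"charlm_{direction}_{name}"] = arr
        backend = emb.backend
        if backend is not None:
            from .fixtures import MockContextualBackend

            if isinstance(backend, MockContextualBackend):
                meta["backend"] = {"kind": "mock", "d_ctx": backend.d_ctx}
                arrays["backend_table"] = backend._table
                arrays["backend_W"] = backend._W
                arrays["backend_V"] = backend._V
                meta["backend"]["chunk"] = backend.chunk
            else:
                meta["backend"] = {"kind": "external"}
        np.savez(path, meta=json.dumps(meta), **arrays)
        return path

    @classmethod
    def load(
        cls,
        path: str | Path,
        backend: ContextualBackend | None = None,
        pos_tagger: PosTagger = rule_pos_tagger,
    ) -> "TaggerModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            arrays = {k: data[k] for k in data.files if k != "meta"}
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta['format_version']}"
            )
        emb_config = EmbeddingConfig(**meta["embedding_config"])
        charlm_fwd = charlm_bwd = None
        if meta["charlm"] is not None:
            lm_config = CharLMConfig(**meta["charlm"]["config"])
            lm_vocab = CharVocab(tuple(meta["charlm"]["chars"]))
            rng = np.random.default_rng(0)
            charlm_fwd = CharLanguageModel(lm_vocab, "forward", lm_config, rng)
            charlm_bwd = CharLanguageModel(lm_vocab, "backward", lm_config, rng)
            for direction, lm in (("fwd", charlm_fwd), ("bwd", charlm_bwd)):
                lm.load_state_arrays(
                    {
                        name: arrays[f"charlm_{direction}_{name}"]
                        for name in lm.state_arrays()
                    }
                )
        if meta["backend"] is not None and backend is None:
            if meta["backend"]["kind"] == "mock":
                from .fixtures import MockContextualBackend

                backend = MockContextualBackend(
                    d_ctx=meta["backend"]["d_ctx"], chunk=meta["backend"]["chunk"]
                )
                backend._table = arrays["backend_table"]
                backend._W = arrays["backend_W"]
                backend._V = arrays["backend_V"]
            else:
                raise ValueError(
                    "checkpoint was trained with an external contextual "
                    "backend; pass it via the backend argument"
                )
        embedding_layer = EmbeddingLayer(
            emb_config,
            np.random.default_rng(meta["seed"]),
            pos_vocab=PosVocab(tuple(meta["pos_symbols"]))
            if meta["pos_symbols"]
            else None,
            char_vocab=CharVocab(tuple(meta["char_vocab"]))
            if meta["char_vocab"]
            else None,
            charlm_forward=charlm_fwd,
            charlm_backward=charlm_bwd,
            backend=backend,
            pos_tagger=pos_tagger,
        )
        model = cls(
            LabelSet.from_labels(meta["labels"]),
            embedding_layer,
            EncoderConfig(**meta["encoder_config"]),
            use_bilstm=meta["use_bilstm"],
            use_crf=meta["use_crf"],
            bio_constraints=meta["bio_constraints"],
            seed=meta["seed"],
        )
        for i, p in enumerate(model.parameters()):
            p.value[...] = arrays[f"param_{i}"]
        return model
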