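"""Feature-embedding components: POS, char encoder, char-LM, contextual, concat."""

import numpy as np
import pytest

from bionerkit.charlm import (
    CharLMConfig,
    embed_charlm,
    heldout_perplexity,
    sentence_stream,
    train_charlm,
)
from bionerkit.embeddings import (
    CharEncoder,
    EmbeddingConfig,
    EmbeddingLayer,
    OverLengthError,
    PosEmbedder,
    concat_embeddings,
    embed_contextual,
    embed_pos,
)
from bionerkit.fixtures import FixtureSpec, generate_corpus, mock_contextual_backend
from bionerkit.postag import PTB_TAGS, rule_pos_tagger
from bionerkit.vocab import CharVocab, PosVocab


@pytest.fixture(scope="module")
def pos_vocab():
    return PosVocab.from_symbols(PTB_TAGS)


@pytest.fixture(scope="module")
def char_vocab():
    return CharVocab.from_text(["abcdefghijklmnopqrstuvwxyz-0123456789 "])


class TestPosFeature:
    def test_rule_tagger_contract(self):
        words = ["BRCA1", "mutations", "were", "observed", "."]
        symbols = rule_pos_tagger(words)
        assert len(symbols) == len(words)
        assert rule_pos_tagger(words) == symbols  # deterministic

    def test_context_freeness(self, pos_vocab):
        rng = np.random.default_rng(0)
        embedder = PosEmbedder(pos_vocab, 50, rng)
        a, _ = embedder.forward(["NN", "DT", "NN"])
        b, _ = embedder.forward(["VB", "NN"])
        np.testing.assert_array_equal(a[0], a[2])
        np.testing.assert_array_equal(a[0], b[1])
        assert a.shape == (3, 50)

    def test_identity_projection_recovers_one_hot(self, pos_vocab):
        eye = np.eye(len(pos_vocab))
        rows = embed_pos(["NN", "nonsense-symbol"], pos_vocab, eye)
        assert rows[0, pos_vocab.index("NN")] == 1.0
        assert rows[0].sum() == 1.0
        # Unknown symbols fall into the reserved bucket.
        assert rows[1, pos_vocab.index("<unk>")] == 1.0

    def test_projection_dimension_checked(self, pos_vocab):
        with pytest.raises(ValueError):
            embed_pos(["NN"], pos_vocab, np.zeros((3, 50)))


class TestCharEncoder:
    def test_output_size_and_determinism(self, char_vocab):
        enc = CharEncoder(char_vocab, 50, np.random.default_rng(1))
        v1, _ = enc.forward("nephritis")
        v2, _ = enc.forward("nephritis")
        assert v1.shape == (50,)
        np.testing.assert_array_equal(v1, v2)

    def test_order_sensitivity(self, char_vocab):
        enc = CharEncoder(char_vocab, 20, np.random.default_rng(2))
        v_abc, _ = enc.forward("abc")
        v_cba, _ = enc.forward("cba")
        assert not np.allclose(v_abc, v_cba)

    def test_empty_word_rejected(self, char_vocab):
        enc = CharEncoder(char_vocab, 10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc.forward("")


@pytest.fixture(scope="module")
def corpus_words():
    corpus = generate_corpus(FixtureSpec(n_sentences=60, seed=5))
    return [s.words for s in corpus]


class TestCharLM:
    def test_training_reduces_heldout_perplexity(self, corpus_words):
        model, log = train_charlm(
            corpus_words, "forward", CharLMConfig(d_hidden=24, epochs=2, seed=0)
        )
        assert log[-1]["heldout_perplexity"] < log[0]["heldout_perplexity"]

    def test_seeded_determinism(self, corpus_words):
        config = CharLMConfig(d_hidden=16, epochs=1, seed=7)
        m1, _ = train_charlm(corpus_words[:20], "forward", config)
        m2, _ = train_charlm(corpus_words[:20], "forward", config)
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_forward_backward_symmetry_on_palindromic_corpus(self):
        # Sentences whose character streams read identically in both
        # directions give the two LMs statistically identical tasks.
        sentences = [["aba", "aba"], ["abcba"], ["aa", "b", "aa"]] * 10
        config = CharLMConfig(d_hidden=16, epochs=2, seed=3)
        _, log_f = train_charlm(sentences, "forward", config)
        _, log_b = train_charlm(sentences, "backward", config)
        pf = log_f[-1]["heldout_perplexity"]
        pb = log_b[-1]["heldout_perplexity"]
        assert pf == pytest.approx(pb, rel=0.2)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_charlm([], "forward")

    def test_boundary_state_definitions(self, corpus_words):
        config = CharLMConfig(d_hidden=16, epochs=1, seed=1)
        lm_f, _ = train_charlm(corpus_words[:15], "forward", config)
        lm_b, _ = train_charlm(corpus_words[:15], "backward", config)
        words = ["IL-2", "levels"]
        fwd, bwd = embed_charlm(words, lm_f, lm_b)
        assert fwd.shape == bwd.shape == (2, 16)
        stream = sentence_stream(words)
        hs_f = lm_f.hidden_states(stream)
        hs_b = lm_b.hidden_states(stream)
        # Word 0 spans chars [0, 4): forward state after char 3,
        # backward state after (reversed) consuming char 0.
        np.testing.assert_array_equal(fwd[0], hs_f[3])
        np.testing.assert_array_equal(bwd[0], hs_b[len(stream) - 1])

    def test_single_word_sentence(self, corpus_words):
        config = CharLMConfig(d_hidden=8, epochs=1, seed=2)
        lm_f, _ = train_charlm(corpus_words[:10], "forward", config)
        lm_b, _ = train_charlm(corpus_words[:10], "backward", config)
        fwd, bwd = embed_charlm(["arthritis"], lm_f, lm_b)
        np.testing.assert_array_equal(
            fwd[0], lm_f.hidden_states("arthritis")[-1]
        )

    def test_backward_vector_is_context_sensitive(self, corpus_words):
        config = CharLMConfig(d_hidden=8, epochs=1, seed=2)
        lm_f, _ = train_charlm(corpus_words[:10], "forward", config)
        lm_b, _ = train_charlm(corpus_words[:10], "backward", config)
        _, bwd_short = embed_charlm(["gene"], lm_f, lm_b)
        _, bwd_long = embed_charlm(["gene", "expression"], lm_f, lm_b)
        assert not np.allclose(bwd_short[0], bwd_long[0])


class TestContextual:
    def test_dimension_and_determinism(self):
        backend = mock_contextual_backend(d_ctx=32, seed=0)
        words = ["IL-2", "induces", "proliferation"]
        a = embed_contextual(words, backend, max_length=32)
        b = embed_contextual(words, backend, max_length=32)
        assert a.shape == (3, 32)
        np.testing.assert_array_equal(a, b)

    def test_first_subword_alignment_with_index_backend(self):
        class IndexBackend:
            d_ctx = 4
            cls_token, sep_token, pad_token = "[CLS]", "[SEP]", "[PAD]"

            def subword_tokenize(self, word):
                return [word[:2], "##" + word[2:4], "##" + word[4:]][
                    : max(1, (len(word) + 1) // 2)
                ]

            def encode(self, subwords):
                return np.arange(len(subwords), dtype=float)[:, None] * np.ones(
                    (1, 4)
                )

        backend = IndexBackend()
        out = embed_contextual(["abcdef"], backend, max_length=8)
        # [CLS] at 0; the word's first subword sits at position 1.
        np.testing.assert_array_equal(out[0], np.full(4, 1.0))
        out_mean = embed_contextual(["abcdef"], backend, max_length=8, align="mean")
        np.testing.assert_array_equal(out_mean[0], np.full(4, 2.0))

    def test_padding_invariance(self):
        backend = mock_contextual_backend(d_ctx=16, seed=1)
        words = ["severe", "nephritis", "observed"]
        small = embed_contextual(words, backend, max_length=16)
        large = embed_contextual(words, backend, max_length=64)
        np.testing.assert_array_equal(small, large)

    def test_overlength_policies(self):
        backend = mock_contextual_backend(d_ctx=8, seed=0)
        words = ["abcdefgh"] * 10  # 2 subwords each -> 22 with markers
        with pytest.raises(OverLengthError):
            embed_contextual(words, backend, max_length=10, overlength="error")
        out = embed_contextual(words, backend, max_length=10, overlength="truncate")
        assert out.shape == (10, 8)
        assert np.all(out[-1] == 0.0)  # fully truncated word gets zeros


class TestConcat:
    def test_dimension_arithmetic(self):
        config = EmbeddingConfig(d_pos=50, d_char=50, d_lm=64, d_ctx=768)
        assert config.concat_dim == 50 + 50 + 2 * 64 + 768 == 996

    def test_ablation_removes_exactly_one_block(self):
        full = EmbeddingConfig(d_pos=50, d_char=50, d_lm=64, d_ctx=768)
        no_pos = EmbeddingConfig(
            d_pos=50, d_char=50, d_lm=64, d_ctx=768, use_pos=False
        )
        assert full.concat_dim - no_pos.concat_dim == 50

    def test_component_order_and_offsets(self):
        n = 3
        blocks = {
            "pos": np.zeros((n, 2)),
            "char": np.ones((n, 3)),
            "lm_forward": np.full((n, 2), 2.0),
            "lm_backward": np.full((n, 2), 3.0),
            "ctx": np.full((n, 4), 4.0),
        }
        out = concat_embeddings(blocks)
        assert out.shape == (n, 13)
        np.testing.assert_array_equal(out[:, 0:2], 0.0 * out[:, 0:2])
        np.testing.assert_array_equal(out[:, 2:5], np.ones((n, 3)))
        np.testing.assert_array_equal(out[:, 5:7], np.full((n, 2), 2.0))
        np.testing.assert_array_equal(out[:, 7:9], np.full((n, 2), 3.0))
        np.testing.assert_array_equal(out[:, 9:13], np.full((n, 4), 4.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concat_embeddings(
                {"pos": np.zeros((3, 2)), "char": np.zeros((2, 2))}
            )

    def test_layer_offsets_match_actual_blocks(self, pos_vocab, char_vocab):
        config = EmbeddingConfig(
            d_pos=8, d_char=6, d_lm=4, d_ctx=16, use_charlm=False
        )
        layer = EmbeddingLayer(
            config,
            np.random.default_rng(0),
            pos_vocab=pos_vocab,
            char_vocab=char_vocab,
            backend=mock_contextual_backend(d_ctx=16, seed=0),
        )
        assert layer.dim == 8 + 6 + 16
        offsets = layer.component_offsets()
        assert offsets == {"pos": (0, 8), "char": (8, 14), "ctx": (14, 30)}
        out, _ = layer.forward(["two", "words"])
        assert out.shape == (2, 30)

    def test_layer_deterministic_across_calls(self, pos_vocab, char_vocab):
        config = EmbeddingConfig(d_pos=4, d_char=4, d_lm=4, d_ctx=8,
                                 use_charlm=False)
        layer = EmbeddingLayer(
            config,
            np.random.default_rng(3),
            pos_vocab=pos_vocab,
            char_vocab=char_vocab,
            backend=mock_contextual_backend(d_ctx=8, seed=3),
        )
        a, _ = layer.forward(["identical", "sentence"])
        b, _ = layer.forward(["identical", "sentence"])
        np.testing.assert_array_equal(a, b)
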