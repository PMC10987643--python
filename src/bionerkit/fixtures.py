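"""Seed-reproducible synthetic BIO corpora and a mock contextual backend.

The generator plants dictionary entities into templated filler sentences so
that every other module can be exercised without downloads.  The surface
dictionaries imitate the statistical quirks of biomedical corpora: entities
span multiple tokens ("chronic nephritis"), mix letters, digits and symbols
("IL-2R"), and include short uppercase abbreviations ("RA"); entity types
are partially cued by nearby context words, so type disambiguation needs
more than surface memorization.  The generated text is NOT linguistically
realistic and carries none of the long-range discourse structure of real
abstracts — results on it demonstrate that the machinery learns and scores
correctly, not benchmark-level performance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import BioTag, Corpus, EntitySpan, LabeledSentence, bio_from_spans
from .evaluation import EvalCounts
from .postag import rule_pos_tagger

__all__ = [
    "FixtureSpec",
    "default_entity_dictionaries",
    "generate_corpus",
    "train_test_fixture",
    "MockContextualBackend",
    "mock_contextual_backend",
    "plant_prediction_errors",
]

_FILLER = (
    "the patient was with of in treatment study results showed after "
    "observed clinical analysis cases reported severe response during "
    "therapy associated increased levels a significant evidence data "
    "measured baseline group control also found"
).split()

# Context cue words emitted next to entities of each default type.
_CUES = {
    "Disease": ("diagnosed", "suffering", "symptoms"),
    "Gene": ("expression", "encoded", "regulated"),
}


def _disease_surfaces() -> list[tuple[str, ...]]:
    stems = ["arthr", "nephr", "hepat", "derm", "card", "neur",
             "gastr", "bronch", "oste", "retin"]
    suffixes = ["itis", "osis", "oma"]
    names = [stem + suf for stem in stems for suf in suffixes]
    surfaces: list[tuple[str, ...]] = [(n,) for n in names]
    surfaces += [("chronic", n) for n in names[::3]]
    surfaces += [(n, "syndrome") for n in names[1::3]]
    surfaces += [("RA",), ("CKD",), ("T2D",)]  # abbreviation variants
    return surfaces


def _gene_surfaces() -> list[tuple[str, ...]]:
    prefixes = ["IL", "TNF", "BRCA", "CD", "TP", "EGFR", "KRAS", "MYC"]
    numbers = ["1", "2", "4", "6", "8", "10", "13", "21", "53"]
    names = [f"{p}-{n}" for p in prefixes for n in numbers[:4]]
    names += [f"{p}-{n}R" for p in prefixes[:4] for n in numbers[4:]]
    surfaces: list[tuple[str, ...]] = [(n,) for n in names]
    surfaces += [(n, "receptor") for n in names[::5]]
    surfaces += [("HLA",), ("ACE",)]
    return surfaces


def default_entity_dictionaries() -> dict[str, list[tuple[str, ...]]]:
    """Two entity types with morphologically distinct, productive surfaces."""
    return {"Disease": _disease_surfaces(), "Gene": _gene_surfaces()}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic corpus.

    ``entity_density`` is the expected number of planted entities per
    sentence (Poisson, truncated to what fits); ``cue_probability`` is the
    chance an entity is preceded by a type-specific cue word, the signal
    that lets a model type OOV surfaces from context.
    """

    n_sentences: int = 500
    entity_types: dict[str, list[tuple[str, ...]]] = field(
        default_factory=default_entity_dictionaries
    )
    entity_density: float = 1.2
    length_range: tuple[int, int] = (6, 14)
    cue_probability: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entity_density < 0:
            raise ValueError("entity_density must be >= 0")
        if not all(self.entity_types.values()):
            raise ValueError("entity dictionaries must be non-empty")
        lo, hi = self.length_range
        max_surface = max(
            (len(s) for surfs in self.entity_types.values() for s in surfs),
            default=0,
        )
        if lo < 1 or hi < lo or hi < max_surface + 1:
            raise ValueError("length_range incompatible with entity surfaces")


def _make_sentence(
    spec: FixtureSpec,
    rng: np.random.Generator,
    dictionaries: dict[str, list[tuple[str, ...]]],
) -> LabeledSentence:
    lo, hi = spec.length_range
    fillers = list(rng.choice(_FILLER, size=int(rng.integers(lo, hi + 1))))
    n_entities = min(int(rng.poisson(spec.entity_density)), len(fillers))
    types = sorted(dictionaries)
    # Entities occupy distinct gaps between filler tokens, so planted spans
    # can never split or touch-merge with one another.
    gaps = sorted(rng.choice(len(fillers) + 1, size=n_entities, replace=False))
    words: list[str] = []
    spans: list[EntitySpan] = []
    prev_gap = 0
    for gap in gaps:
        words.extend(fillers[prev_gap:gap])
        prev_gap = gap
        etype = types[int(rng.integers(len(types)))]
        surface = dictionaries[etype][int(rng.integers(len(dictionaries[etype])))]
        if etype in _CUES and rng.random() < spec.cue_probability:
            words.append(_CUES[etype][int(rng.integers(len(_CUES[etype])))])
        spans.append(EntitySpan(len(words), len(words) + len(surface), etype))
        words.extend(surface)
    words.extend(fillers[prev_gap:])
    tags = bio_from_spans(spans, len(words))
    return LabeledSentence.from_words(words, tags, rule_pos_tagger(words))


def generate_corpus(
    spec: FixtureSpec,
    dictionaries: dict[str, list[tuple[str, ...]]] | None = None,
) -> Corpus:
    """Generate a corpus of ``spec.n_sentences`` labeled sentences.

    Deterministic given ``spec.seed``.  Every planted entity is tagged
    ``B-``/``I-`` exactly over its tokens; all other tokens are ``O``; POS
    tags come from the deterministic rule tagger.
    """
    rng = np.random.default_rng(spec.seed)
    dictionaries = dictionaries or spec.entity_types
    return Corpus([_make_sentence(spec, rng, dictionaries) for _ in range(spec.n_sentences)])


def train_test_fixture(
    spec: FixtureSpec, test_fraction: float = 0.3, oov_fraction: float = 0.2
) -> tuple[Corpus, Corpus]:
    """A train/test corpus pair with partially disjoint entity dictionaries.

    ``oov_fraction`` of each type's surfaces appear only in the test
    dictionary, probing character-level generalization to unseen surface
    forms; the remaining surfaces are shared.
    """
    rng = np.random.default_rng(spec.seed + 1)
    train_dicts: dict[str, list[tuple[str, ...]]] = {}
    test_dicts: dict[str, list[tuple[str, ...]]] = {}
    for etype, surfaces in spec.entity_types.items():
        order = rng.permutation(len(surfaces))
        n_oov = max(1, int(round(oov_fraction * len(surfaces))))
        oov = [surfaces[i] for i in order[:n_oov]]
        shared = [surfaces[i] for i in order[n_oov:]]
        train_dicts[etype] = shared
        test_dicts[etype] = shared + oov
    n_test = max(1, int(round(test_fraction * spec.n_sentences)))
    train_spec = FixtureSpec(
        n_sentences=spec.n_sentences,
        entity_types=spec.entity_types,
        entity_density=spec.entity_density,
        length_range=spec.length_range,
        cue_probability=spec.cue_probability,
        seed=spec.seed,
    )
    test_spec = FixtureSpec(
        n_sentences=n_test,
        entity_types=spec.entity_types,
        entity_density=spec.entity_density,
        length_range=spec.length_range,
        cue_probability=spec.cue_probability,
        seed=spec.seed + 104729,
    )
    train = generate_corpus(train_spec, train_dicts)
    test = generate_corpus(test_spec, test_dicts)
    return train, test


class MockContextualBackend:
    """A tiny deterministic stand-in for a transformer subword encoder.

    Synthetic: subwords are fixed-length character chunks, each hashed into
    a seeded random embedding table; one mixing layer adds a summary of the
    real (non-padding) subwords in the sentence, so outputs are contextual
    while padding positions cannot influence real tokens.  It satisfies the
    same contract the real backend must satisfy, nothing more.
    """

    cls_token = "[CLS]"
    sep_token = "[SEP]"
    pad_token = "[PAD]"

    def __init__(self, d_ctx: int = 64, seed: int = 0, chunk: int = 4,
                 table_size: int = 4096) -> None:
        if d_ctx < 1:
            raise ValueError("d_ctx must be >= 1")
        self.d_ctx = d_ctx
        self.chunk = chunk
        rng = np.random.default_rng(seed)
        self._table = rng.normal(0.0, 1.0, size=(table_size, d_ctx))
        self._W = rng.normal(0.0, 1.0 / np.sqrt(d_ctx), size=(d_ctx, d_ctx))
        self._V = rng.normal(0.0, 1.0 / np.sqrt(d_ctx), size=(d_ctx, d_ctx))

    def subword_tokenize(self, word: str) -> list[str]:
        pieces = [word[i : i + self.chunk] for i in range(0, len(word), self.chunk)]
        return [pieces[0]] + [f"##{p}" for p in pieces[1:]]

    def _lookup(self, subword: str) -> np.ndarray:
        idx = zlib.crc32(subword.encode("utf-8")) % self._table.shape[0]
        return self._table[idx]

    def encode(self, subwords: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(subwords), self.d_ctx))
        real = [i for i, s in enumerate(subwords) if s != self.pad_token]
        if not real:
            return out
        emb = np.stack([self._lookup(subwords[i]) for i in real])
        context = emb.mean(axis=0)
        out[real] = np.tanh(emb @ self._W + context @ self._V)
        return out


def mock_contextual_backend(d_ctx: int = 64, seed: int = 0) -> MockContextualBackend:
    return MockContextualBackend(d_ctx=d_ctx, seed=seed)


def plant_prediction_errors(
    corpus: Corpus,
    boundary_rate: float = 0.0,
    type_swap_rate: float = 0.0,
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[list[BioTag]], EvalCounts]:
    """Perturb gold spans into predictions with exactly known error counts.

    For each gold span one perturbation is drawn: *miss* (span dropped, one
    false negative), *boundary shift* or *type swap* (span replaced by a
    wrong one: one false positive plus one false negative), or *keep* (one
    true positive).  Additionally each sentence may receive one *spurious*
    span over an O-only region (one false positive).  Perturbations that
    cannot be realized without colliding with another span degrade to a
    miss, keeping the returned counts exact.  Returns per-sentence predicted
    tag lists and the implied :class:`EvalCounts`.
    """
    for rate in (boundary_rate, type_swap_rate, miss_rate, spurious_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = EvalCounts()
    all_types = sorted(corpus.entity_types) or ["Spurious"]
    predictions: list[list[BioTag]] = []

    for sent in corpus:
        n = len(sent)
        gold = sent.spans(policy="strict")
        gold_keys = {(s.start, s.end, s.entity_type) for s in gold}
        pred: list[EntitySpan] = []

        def collides(span: EntitySpan) -> bool:
            return any(
                span.start < p.end and p.start < span.end for p in pred
            ) or any(
                span.start < g.end and g.start < span.end
                for g in gold
                if g is not current
            )

        for current in gold:
            u = rng.random()
            if u < miss_rate:
                counts.add(current.entity_type, fn=1)
                continue
            u -= miss_rate
            if u < boundary_rate:
                shifted = _shift_boundary(current, n, rng)
                if (
                    shifted is not None
                    and not collides(shifted)
                    and (shifted.start, shifted.end, shifted.entity_type)
                    not in gold_keys
                ):
                    pred.append(shifted)
                    counts.add(current.entity_type, fn=1)
                    counts.add(shifted.entity_type, fp=1)
                else:
                    counts.add(current.entity_type, fn=1)
                continue
            u -= boundary_rate
            others = [t for t in all_types if t != current.entity_type]
            if u < type_swap_rate and others:
                new_type = others[int(rng.integers(len(others)))]
                swapped = EntitySpan(current.start, current.end, new_type)
                pred.append(swapped)
                counts.add(current.entity_type, fn=1)
                counts.add(new_type, fp=1)
                continue
            pred.append(current)
            counts.add(current.entity_type, tp=1)

        if rng.random() < spurious_rate:
            spurious = _free_region_span(n, gold, pred, all_types, rng)
            if spurious is not None:
                pred.append(spurious)
                counts.add(spurious.entity_type, fp=1)
        predictions.append(bio_from_spans(pred, n))
    return predictions, counts


def _shift_boundary(
    span: EntitySpan, n: int, rng: np.random.Generator
) -> EntitySpan | None:
    options = []
    if span.end < n:
        options.append(EntitySpan(span.start, span.end + 1, span.entity_type))
    if span.end - span.start > 1:
        options.append(EntitySpan(span.start + 1, span.end, span.entity_type))
    if span.start > 0:
        options.append(EntitySpan(span.start - 1, span.end, span.entity_type))
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def _free_region_span(
    n: int,
    gold: Sequence[EntitySpan],
    pred: Sequence[EntitySpan],
    types: Sequence[str],
    rng: np.random.Generator,
) -> EntitySpan | None:
    occupied = [False] * n
    for s in list(gold) + list(pred):
        for i in range(s.start, s.end):
            occupied[i] = True
    free = [i for i in range(n) if not occupied[i]]
    if not free:
        return None
    start = free[int(rng.integers(len(free)))]
    etype = types[int(rng.integers(len(types)))]
    return EntitySpan(start, start + 1, etype)
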