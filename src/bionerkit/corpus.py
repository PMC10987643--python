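"""Reading, writing and validating BIO-tagged corpora.

The on-disk format is the two-column CoNLL dialect used by the preprocessed
biomedical benchmark distributions: one token per line, whitespace/tab
separated columns with the BIO tag in the last column (configurable), and a
blank line terminating each sentence.  An entity is a maximal ``B-X`` run
followed by ``I-X`` tokens of the same type; this module converts losslessly
between tag sequences and half-open token spans.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "BioTag",
    "LabeledSentence",
    "EntitySpan",
    "Corpus",
    "CorpusFormatError",
    "read_conll",
    "write_conll",
    "validate_bio",
    "spans_from_bio",
    "bio_from_spans",
    "spans_to_json",
]


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or invalid tag/span structures."""


@dataclass(frozen=True)
class Token:
    """A single pre-tokenized word; ``index`` is its 0-based sentence position."""

    text: str
    index: int

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise CorpusFormatError(
                f"token text must be non-empty and whitespace-free: {self.text!r}"
            )


@dataclass(frozen=True, order=True)
class BioTag:
    """A BIO label: prefix in {B, I, O}; ``entity_type`` is None iff prefix is O."""

    prefix: str
    entity_type: str | None = None

    def __post_init__(self) -> None:
        if self.prefix not in ("B", "I", "O"):
            raise CorpusFormatError(f"unknown tag prefix: {self.prefix!r}")
        if (self.prefix == "O") != (self.entity_type is None):
            raise CorpusFormatError(
                f"prefix {self.prefix} inconsistent with entity_type "
                f"{self.entity_type!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "BioTag":
        if text == "O":
            return cls("O")
        if len(text) > 2 and text[1] == "-" and text[0] in ("B", "I"):
            return cls(text[0], text[2:])
        raise CorpusFormatError(f"malformed BIO tag: {text!r}")

    def __str__(self) -> str:
        return "O" if self.prefix == "O" else f"{self.prefix}-{self.entity_type}"


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity occupying tokens ``[start, end)`` of one sentence."""

    start: int
    end: int
    entity_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusFormatError(f"invalid span bounds ({self.start}, {self.end})")


@dataclass
class LabeledSentence:
    """A token sequence with parallel BIO tags and optional POS tags."""

    tokens: list[Token]
    tags: list[BioTag]
    pos_tags: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise CorpusFormatError("sentence must contain at least one token")
        if len(self.tags) != n:
            raise CorpusFormatError(
                f"{len(self.tags)} tags for {n} tokens"
            )
        if self.pos_tags is not None and len(self.pos_tags) != n:
            raise CorpusFormatError(
                f"{len(self.pos_tags)} POS tags for {n} tokens"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def words(self) -> list[str]:
        return [t.text for t in self.tokens]

    @classmethod
    def from_words(
        cls,
        words: Sequence[str],
        tags: Sequence[BioTag] | None = None,
        pos_tags: Sequence[str] | None = None,
    ) -> "LabeledSentence":
        toks = [Token(w, i) for i, w in enumerate(words)]
        tgs = list(tags) if tags is not None else [BioTag("O")] * len(toks)
        return cls(toks, tgs, list(pos_tags) if pos_tags is not None else None)

    def spans(self, policy: str = "strict") -> list[EntitySpan]:
        return spans_from_bio(self.tags, policy=policy)


@dataclass
class Corpus:
    """An ordered collection of labeled sentences plus their label inventory."""

    sentences: list[LabeledSentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[LabeledSentence]:
        return iter(self.sentences)

    @property
    def label_inventory(self) -> list[str]:
        """Distinct BIO tags in first-seen order; always contains O."""
        seen: dict[str, None] = {"O": None}
        for sent in self.sentences:
            for tag in sent.tags:
                seen.setdefault(str(tag), None)
        return list(seen)

    @property
    def entity_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for sent in self.sentences:
            for tag in sent.tags:
                if tag.entity_type is not None:
                    seen.setdefault(tag.entity_type, None)
        return list(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.sentences, other.sentences):
            if a.words != b.words or a.tags != b.tags or a.pos_tags != b.pos_tags:
                return False
        return True


def read_conll(
    path: str | Path,
    *,
    token_column: int = 0,
    tag_column: int = -1,
    strict: bool = True,
    allow_missing_tags: bool = False,
) -> Corpus:
    """Read a two-column (or wider) BIO file into a :class:`Corpus`.

    Sentences are split on blank lines; ``-DOCSTART-`` lines are skipped.
    With ``strict=True`` gold files containing orphan ``I-`` tags trigger a
    warning (the data is kept as-is; downstream span extraction decides how
    to treat the violation).

    Raises :class:`CorpusFormatError` with the 1-based line number for lines
    with too few columns or unparseable tags.
    """
    path = Path(path)
    sentences: list[LabeledSentence] = []
    words: list[str] = []
    tags: list[BioTag] = []

    def flush() -> None:
        if words:
            sentences.append(LabeledSentence.from_words(words, tags))
            words.clear()
            tags.clear()

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                flush()
                continue
            if line.startswith("-DOCSTART-"):
                continue
            cols = line.split()
            if len(cols) < 2 and not (allow_missing_tags and len(cols) == 1):
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected >= 2 columns, got {len(cols)}"
                )
            try:
                word = cols[token_column]
                tag = (
                    BioTag("O")
                    if len(cols) == 1
                    else BioTag.parse(cols[tag_column])
                )
            except (IndexError, CorpusFormatError) as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
            words.append(word)
            tags.append(tag)
    flush()

    corpus = Corpus(sentences)
    if strict:
        n_bad = sum(bool(validate_bio(s.tags)) for s in corpus)
        if n_bad:
            warnings.warn(
                f"{path}: {n_bad} sentence(s) contain BIO violations "
                "(orphan I- tags or type mismatches)",
                stacklevel=2,
            )
    return corpus


def write_conll(corpus: Corpus, path: str | Path) -> Path:
    """Write ``corpus`` in the two-column dialect; re-readable to an equal corpus."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus:
            for token, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{token.text}\t{tag}\n")
            fh.write("\n")
    return path


def validate_bio(tags: Sequence[BioTag]) -> list[int]:
    """Return positions at which the BIO structure is violated.

    A position ``i`` is a violation when tag ``i`` is ``I-X`` and it is either
    sentence-initial, follows ``O``, or follows a ``B-Y``/``I-Y`` with Y != X.
    """
    violations: list[int] = []
    for i, tag in enumerate(tags):
        if tag.prefix != "I":
            continue
        if i == 0:
            violations.append(i)
            continue
        prev = tags[i - 1]
        if prev.prefix == "O" or prev.entity_type != tag.entity_type:
            violations.append(i)
    return violations


def spans_from_bio(
    tags: Sequence[BioTag], policy: str = "strict"
) -> list[EntitySpan]:
    """Extract maximal entity spans from a BIO tag sequence.

    strict
        Orphan ``I-`` tags (those flagged by :func:`validate_bio`) are dropped:
        they neither start nor extend a span.
    lenient
        Orphan ``I-`` tags are promoted to span starts, matching common
        prediction post-processing.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy: {policy!r}")
    spans: list[EntitySpan] = []
    start: int | None = None
    current_type: str | None = None

    def close(end: int) -> None:
        nonlocal start, current_type
        if start is not None:
            assert current_type is not None
            spans.append(EntitySpan(start, end, current_type))
        start, current_type = None, None

    for i, tag in enumerate(tags):
        if tag.prefix == "B":
            close(i)
            start, current_type = i, tag.entity_type
        elif tag.prefix == "I":
            if start is not None and tag.entity_type == current_type:
                continue  # extends the open span
            close(i)
            if policy == "lenient":
                start, current_type = i, tag.entity_type
        else:  # O
            close(i)
    close(len(tags))
    return spans


def bio_from_spans(spans: Iterable[EntitySpan], n: int) -> list[BioTag]:
    """Encode non-overlapping spans as a BIO sequence of length ``n``.

    Inverse of :func:`spans_from_bio` under the strict policy.
    """
    tags: list[BioTag] = [BioTag("O")] * n
    occupied = [False] * n
    for span in sorted(spans):
        if span.end > n:
            raise CorpusFormatError(f"span {span} exceeds sentence length {n}")
        if any(occupied[span.start : span.end]):
            raise CorpusFormatError(f"span {span} overlaps a previous span")
        for i in range(span.start, span.end):
            occupied[i] = True
            prefix = "B" if i == span.start else "I"
            tags[i] = BioTag(prefix, span.entity_type)
    return tags


def spans_to_json(corpus: Corpus, policy: str = "strict") -> str:
    """Export every sentence's entity spans as a JSON array of records."""
    records = []
    for sid, sent in enumerate(corpus):
        for span in sent.spans(policy=policy):
            records.append(
                {
                    "sentence_id": sid,
                    "start": span.start,
                    "end": span.end,
                    "type": span.entity_type,
                    "text": " ".join(sent.words[span.start : span.end]),
                }
            )
    return json.dumps(records, ensure_ascii=False, indent=2)
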