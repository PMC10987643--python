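"""A deterministic rule-based part-of-speech tagger.

The tagging model treats the POS tagger as an injected dependency: any
callable mapping a word list to an equal-length list of Penn-Treebank-style
symbols satisfies the contract.  This module ships a small closed-class +
suffix rule tagger so the pipeline runs with no external models; it is not a
serious tagger, but it is deterministic, total, and produces a realistic
symbol inventory for the one-hot POS feature.
"""

from __future__ import annotations

from typing import Callable, Sequence

__all__ = ["PTB_TAGS", "rule_pos_tagger", "PosTagger"]

PosTagger = Callable[[Sequence[str]], list[str]]

#: The symbol inventory the rule tagger can emit.
PTB_TAGS: tuple[str, ...] = (
    "NN", "NNS", "NNP", "JJ", "VB", "VBD", "VBG", "VBN", "VBZ",
    "RB", "DT", "IN", "CC", "PRP", "TO", "MD", "CD", "SYM", ".", ",",
)

_CLOSED: dict[str, str] = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN",
    "with": "IN", "from": "IN", "for": "IN", "into": "IN", "after": "IN",
    "and": "CC", "or": "CC", "but": "CC",
    "to": "TO",
    "is": "VBZ", "are": "VB", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "have": "VB", "had": "VBD",
    "may": "MD", "can": "MD", "could": "MD", "should": "MD", "will": "MD",
    "we": "PRP", "it": "PRP", "they": "PRP",
    "not": "RB", "also": "RB",
    ".": ".", ",": ",", ";": ".", ":": ".", "?": ".", "!": ".",
    "(": "SYM", ")": "SYM", "[": "SYM", "]": "SYM", "/": "SYM",
    "-": "SYM", "%": "SYM", "+": "SYM", "=": "SYM",
}


def _tag_word(word: str) -> str:
    lower = word.lower()
    if lower in _CLOSED:
        return _CLOSED[lower]
    if any(c.isdigit() for c in word) and not any(c.isalpha() for c in word):
        return "CD"
    if not any(c.isalnum() for c in word):
        return "SYM"
    if any(c.isdigit() for c in word):
        return "NN"  # alphanumeric biomedical identifiers behave like nouns
    if lower.endswith("ly"):
        return "RB"
    if lower.endswith("ing"):
        return "VBG"
    if lower.endswith("ed"):
        return "VBD"
    if lower.endswith(("ous", "ive", "ic", "al", "able", "ible")):
        return "JJ"
    if word[0].isupper() and len(word) > 1 and not word.isupper():
        return "NNP"
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def rule_pos_tagger(words: Sequence[str]) -> list[str]:
    """Tag each word independently by closed-class lookup then suffix rules."""
    return [_tag_word(w) for w in words]
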