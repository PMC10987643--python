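"""Symbol inventories for the POS one-hot feature and character-level models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["PosVocab", "CharVocab"]

UNK_SYMBOL = "<unk>"
PAD_SYMBOL = "<pad>"


@dataclass(frozen=True)
class PosVocab:
    """Ordered POS symbol inventory with a reserved unknown bucket.

    The one-hot dimension equals ``len(vocab)``; unseen symbols map to the
    unknown bucket rather than failing.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate POS symbols")
        if UNK_SYMBOL not in self.symbols:
            raise ValueError("unk symbol missing from PosVocab")

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "PosVocab":
        ordered: dict[str, None] = {UNK_SYMBOL: None}
        for s in symbols:
            ordered.setdefault(s, None)
        return cls(tuple(ordered))

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            return self.symbols.index(UNK_SYMBOL)

    def encode(self, symbols: Sequence[str]) -> list[int]:
        return [self.index(s) for s in symbols]


@dataclass(frozen=True)
class CharVocab:
    """Ordered character inventory with reserved unknown and padding entries."""

    chars: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.chars)) != len(self.chars):
            raise ValueError("duplicate characters")
        if UNK_SYMBOL in self.chars or PAD_SYMBOL in self.chars:
            raise ValueError("reserved symbols must not appear in chars")

    @classmethod
    def from_text(cls, texts: Iterable[str]) -> "CharVocab":
        ordered: dict[str, None] = {}
        for text in texts:
            for c in text:
                ordered.setdefault(c, None)
        return cls(tuple(ordered))

    def __len__(self) -> int:
        # +2 for the unk and pad entries appended after the observed chars
        return len(self.chars) + 2

    @property
    def unk_index(self) -> int:
        return len(self.chars)

    @property
    def pad_index(self) -> int:
        return len(self.chars) + 1

    def index(self, char: str) -> int:
        try:
            return self.chars.index(char)
        except ValueError:
            return self.unk_index

    def encode(self, text: str) -> list[int]:
        lookup = {c: i for i, c in enumerate(self.chars)}
        return [lookup.get(c, self.unk_index) for c in text]
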