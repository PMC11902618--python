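"""Strong (timed) and weak (order-only) labels.

Eating-behavior recordings are annotated with strong labels — onset/offset
times per chew or swallow — against synchronized video. Training supervision
uses weak labels: the event/character sequence with the times removed. Strong
labels are kept for evaluation, where temporal accuracy matters.

Reserved symbols: ``_`` is the CTC blank, ``#`` marks a chewing event, ``$``
marks a swallowing event (configurable through :class:`Vocabulary`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

BLANK_SYMBOL = "_"
CHEW_SYMBOL = "#"
SWALLOW_SYMBOL = "$"
SPACE_SYMBOL = " "

_RESERVED_KINDS = {
    BLANK_SYMBOL: "blank",
    CHEW_SYMBOL: "chew",
    SWALLOW_SYMBOL: "swallow",
    SPACE_SYMBOL: "space",
}


@dataclass(frozen=True)
class Token:
    """One vocabulary item: a transcript character, an event mark, or blank."""

    symbol: str
    kind: str = "character"

    def __post_init__(self) -> None:
        if len(self.symbol) < 1:
            raise ValueError("token symbol must be non-empty")
        expected = _RESERVED_KINDS.get(self.symbol)
        if expected is not None and self.kind != expected:
            raise ValueError(
                f"symbol {self.symbol!r} is reserved for kind {expected!r}"
            )
        if expected is None and self.kind in ("blank", "chew", "swallow", "space"):
            raise ValueError(f"kind {self.kind!r} requires its reserved symbol")

    def __str__(self) -> str:
        return self.symbol


def make_token(symbol: str) -> Token:
    """Build a token, inferring the reserved kind from the symbol."""
    return Token(symbol, _RESERVED_KINDS.get(symbol, "character"))


BLANK = make_token(BLANK_SYMBOL)
CHEW = make_token(CHEW_SYMBOL)
SWALLOW = make_token(SWALLOW_SYMBOL)
SPACE = make_token(SPACE_SYMBOL)


@dataclass
class StrongLabelTrack:
    """Time-stamped event/transcript intervals; ground truth for evaluation."""

    entries: list[tuple[float, float, Token]] = field(default_factory=list)
    clip_id: str = ""

    def __post_init__(self) -> None:
        for start, end, token in self.entries:
            if not (0.0 <= start < end):
                raise ValueError(f"invalid interval ({start}, {end}) in {self.clip_id!r}")
            if token.kind == "blank":
                raise ValueError("strong label entries never carry the blank token")
        self.entries = sorted(self.entries, key=lambda e: (e[0], e[1]))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[float, float, Token]]:
        return iter(self.entries)


@dataclass
class WeakLabelSeq:
    """Ordered token sequence without times; the CTC training target."""

    tokens: list[Token] = field(default_factory=list)
    clip_id: str = ""

    def __post_init__(self) -> None:
        if any(t.kind == "blank" for t in self.tokens):
            raise ValueError("weak label sequences contain no blank tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def symbols(self) -> list[str]:
        return [t.symbol for t in self.tokens]

    def text(self) -> str:
        return "".join(self.symbols())


def weak_from_strong(track: StrongLabelTrack) -> WeakLabelSeq:
    """Project a strong track to its weak label: tokens in start-time order."""
    return WeakLabelSeq([tok for _, _, tok in track.entries], clip_id=track.clip_id)


def shift_track(track: StrongLabelTrack, offset_s: float) -> StrongLabelTrack:
    """Shift every interval later by ``offset_s`` (>= 0)."""
    if offset_s < 0:
        raise ValueError("offset_s must be non-negative")
    return StrongLabelTrack(
        [(s + offset_s, e + offset_s, tok) for s, e, tok in track.entries],
        clip_id=track.clip_id,
    )


def read_track(path: str | os.PathLike) -> StrongLabelTrack:
    """Read an Audacity-style TSV label track: ``start<TAB>end<TAB>symbol``."""
    path = os.fspath(path)
    entries: list[tuple[float, float, Token]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric time") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            entries.append((start, end, make_token(parts[2])))
    clip_id = os.path.splitext(os.path.basename(path))[0]
    return StrongLabelTrack(entries, clip_id=clip_id)


def write_track(track: StrongLabelTrack, path: str | os.PathLike) -> None:
    """Write a track in canonical 6-decimal TSV form (round-trips with read)."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for start, end, tok in track.entries:
            fh.write(f"{start:.6f}\t{end:.6f}\t{tok.symbol}\n")


class Vocabulary:
    """Token inventory with the blank fixed at index 0.

    The on-disk format is one symbol per line, first line ``_``.
    """

    def __init__(self, symbols: Sequence[str]):
        symbols = list(symbols)
        if not symbols or symbols[0] != BLANK_SYMBOL:
            raise ValueError("vocabulary must start with the blank symbol '_'")
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate symbols in vocabulary")
        self._symbols = symbols
        self._index = {s: i for i, s in enumerate(symbols)}
        self.tokens = [make_token(s) for s in symbols]

    def __len__(self) -> int:
        return len(self._symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    @property
    def blank_id(self) -> int:
        return 0

    @property
    def symbols(self) -> list[str]:
        return list(self._symbols)

    def index(self, symbol: str) -> int:
        return self._index[symbol]

    def encode(self, seq: WeakLabelSeq | Iterable[Token]) -> list[int]:
        return [self._index[t.symbol] for t in seq]

    def decode(self, ids: Iterable[int]) -> list[Token]:
        return [self.tokens[i] for i in ids]

    def extend(self, symbols: Iterable[str]) -> "Vocabulary":
        """New vocabulary with extra symbols appended (existing ids preserved)."""
        new = [s for s in symbols if s not in self._index]
        return Vocabulary(self._symbols + new)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "Vocabulary":
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            symbols = [line.rstrip("\n") for line in fh if line.rstrip("\n") != ""]
        return cls(symbols)

    def write(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            for s in self._symbols:
                fh.write(s + "\n")
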