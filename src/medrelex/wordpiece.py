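"""WordPiece tokenization and sentence-pair encoding.

A word is segmented greedily, longest vocabulary match first; non-initial
pieces carry the ``##`` prefix ("suxamethonium" -> su, ##xa, ##met, ##hon,
##ium with a suitable vocabulary).  Sentence pairs are laid out as
``[CLS] A [SEP] B [SEP] [PAD]...`` with segment ids 0 over ``[CLS] A
[SEP]`` and 1 over the rest, padded to a fixed length; over-long pairs are
truncated token-by-token from the end of whichever side is currently
longer.

Basic tokenization (before WordPiece) lowercases, splits on whitespace,
makes punctuation stand-alone and isolates every CJK character, matching
the conventions of the uncased English models.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PAD", "UNK", "CLS", "SEP", "MASK", "SPECIALS",
    "Vocabulary", "basic_tokenize", "wordpiece_tokenize",
    "TokenSequence", "encode_pair", "build_vocab",
]

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIALS = (PAD, UNK, CLS, SEP, MASK)

_MAX_WORD_CHARS = 100  # longer words map straight to [UNK]


def _is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return (
        0x4E00 <= cp <= 0x9FFF
        or 0x3400 <= cp <= 0x4DBF
        or 0xF900 <= cp <= 0xFAFF
        or 0x20000 <= cp <= 0x2A6DF
    )


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


class Vocabulary:
    """Token -> contiguous id mapping with the five special tokens."""

    def __init__(self, tokens: Sequence[str]):
        self.tokens = list(tokens)
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            dupes = len(self.tokens) - len(self.token_to_id)
            raise ValueError(f"vocabulary contains {dupes} duplicate token(s)")
        missing = [s for s in SPECIALS if s not in self.token_to_id]
        if missing:
            raise ValueError(f"vocabulary is missing special tokens: {missing}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, self.token_to_id[UNK])

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[s] for s in SPECIALS)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("".join(t + "\n" for t in self.tokens), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([ln for ln in lines if ln])


def basic_tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Whitespace split with stand-alone punctuation and per-character CJK."""
    if lowercase:
        text = text.lower()
    out: list[str] = []
    word: list[str] = []

    def flush() -> None:
        if word:
            out.append("".join(word))
            word.clear()

    for ch in text:
        if ch.isspace():
            flush()
        elif _is_punct(ch) or _is_cjk(ch):
            flush()
            out.append(ch)
        else:
            word.append(ch)
    flush()
    return out


def wordpiece_tokenize(word: str, vocab: Vocabulary) -> list[str]:
    """Greedy longest-match-first segmentation of a single pre-split word.

    Returns ``[UNK]`` for the whole word when no vocabulary piece matches
    at some position (or the word is pathologically long).
    """
    if not word:
        raise ValueError("cannot tokenize an empty word")
    if len(word) > _MAX_WORD_CHARS:
        return [UNK]
    pieces: list[str] = []
    start = 0
    while start < len(word):
        end = len(word)
        piece = None
        while end > start:
            candidate = word[start:end]
            if start > 0:
                candidate = "##" + candidate
            if candidate in vocab:
                piece = candidate
                break
            end -= 1
        if piece is None:
            return [UNK]
        pieces.append(piece)
        start = end
    return pieces


def tokenize_text(text: str, vocab: Vocabulary, lowercase: bool = True) -> list[str]:
    """Basic tokenization followed by WordPiece over each word."""
    pieces: list[str] = []
    for word in basic_tokenize(text, lowercase=lowercase):
        pieces.extend(wordpiece_tokenize(word, vocab))
    return pieces


@dataclass(frozen=True)
class TokenSequence:
    """An encoded sentence pair: pieces, ids, segments, positions, mask."""

    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    segment_ids: tuple[int, ...]
    positions: tuple[int, ...]
    mask: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        for name in ("ids", "segment_ids", "positions", "mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from token count {n}")
        if self.tokens[0] != CLS:
            raise ValueError("sequence must start with [CLS]")
        if sum(1 for t in self.tokens if t == SEP) != 2:
            raise ValueError("a sentence pair carries exactly two [SEP] tokens")
        for tok, m in zip(self.tokens, self.mask):
            if (tok == PAD) != (m == 0):
                raise ValueError("attention mask must be 0 exactly on [PAD]")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def seq_len(self) -> int:
        """Number of real (non-padding) tokens."""
        return int(sum(self.mask))


def _truncate_pair(a: list[str], b: list[str], budget: int) -> None:
    """Drop tokens from the end of the currently longer side until they fit."""
    while len(a) + len(b) > budget:
        longer = a if len(a) >= len(b) else b
        longer.pop()


def encode_pair(sentence_a: str, sentence_b: str, vocab: Vocabulary,
                max_len: int, lowercase: bool = True) -> TokenSequence:
    """Encode a sentence pair to a fixed-length :class:`TokenSequence`."""
    if max_len < 5:
        raise ValueError(f"max_len must be at least 5, got {max_len}")
    if not sentence_a.strip():
        raise ValueError("sentence_a is empty: an instance always names two entities")
    a = tokenize_text(sentence_a, vocab, lowercase=lowercase)
    b = tokenize_text(sentence_b, vocab, lowercase=lowercase)
    _truncate_pair(a, b, max_len - 3)
    tokens = [CLS, *a, SEP, *b, SEP]
    seg_split = len(a) + 2  # [CLS] A [SEP] -> segment 0
    n_pad = max_len - len(tokens)
    segment_ids = [0] * seg_split + [1] * (len(tokens) - seg_split) + [0] * n_pad
    mask = [1] * len(tokens) + [0] * n_pad
    tokens = tokens + [PAD] * n_pad
    return TokenSequence(
        tokens=tuple(tokens),
        ids=tuple(vocab.id(t) for t in tokens),
        segment_ids=tuple(segment_ids),
        positions=tuple(range(max_len)),
        mask=tuple(mask),
    )


def build_vocab(corpus: Iterable[str], target_size: int, lowercase: bool = True) -> Vocabulary:
    """Build a WordPiece vocabulary from raw text lines.

    Layout: the five specials, one entry per corpus character (plus its
    ``##`` continuation, so any in-alphabet word segments without [UNK]),
    then whole words by descending frequency (frequency ties broken
    lexicographically) until ``target_size`` is reached.
    """
    freq: dict[str, int] = {}
    alphabet: set[str] = set()
    for line in corpus:
        for word in basic_tokenize(line, lowercase=lowercase):
            freq[word] = freq.get(word, 0) + 1
            alphabet.update(word)
    chars = sorted(alphabet)
    floor = len(SPECIALS) + 2 * len(chars)
    if target_size < floor:
        raise ValueError(
            f"target_size {target_size} too small: need at least {floor} "
            f"(5 specials + 2 x {len(chars)} alphabet entries) for full coverage"
        )
    tokens = list(SPECIALS) + chars + ["##" + c for c in chars]
    have = set(tokens)
    for word, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])):
        if len(tokens) >= target_size:
            break
        if word not in have:
            tokens.append(word)
            have.add(word)
    return Vocabulary(tokens)
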