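"""Non-overlapping k-mer tokenization of DNA sequences.

The vocabulary contains every k-mer over the nucleotide alphabet
(lexicographic order), the five standalone tokens A, C, G, T, N, and four
special tokens [PAD], [MASK], [CLS], [UNK] — 4**6 + 5 + 4 = 4105 entries at
the default hexamer size. Tokenization is a greedy left-to-right scan:
whenever a full k-mer over the alphabet fits at the cursor it is emitted and
the cursor advances k; otherwise a single standalone nucleotide token is
emitted. An N therefore can never sit inside an emitted k-mer, and
concatenating the emitted tokens always reproduces the input sequence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STANDALONE_TOKENS = ("A", "C", "G", "T", "N")
PAD, MASK, CLS, UNK = "[PAD]", "[MASK]", "[CLS]", "[UNK]"
SPECIAL_TOKENS = (PAD, MASK, CLS, UNK)
_NUCLEOTIDES = frozenset("ACGT")
_VALID_CHARS = frozenset("ACGTN")


class InvalidAlphabetError(ValueError):
    pass


class InvalidCharacterError(ValueError):
    pass


class InvalidTokenError(ValueError):
    pass


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TokenVocabulary:
    """Immutable id <-> token mapping: k-mers, standalone bases, specials."""

    kmer_size: int
    alphabet: tuple[str, ...]
    tokens: tuple[str, ...]
    id_of: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.id_of[PAD]

    @property
    def mask_id(self) -> int:
        return self.id_of[MASK]

    @property
    def cls_id(self) -> int:
        return self.id_of[CLS]

    @property
    def unk_id(self) -> int:
        return self.id_of[UNK]

    @property
    def special_ids(self) -> tuple[int, ...]:
        return tuple(self.id_of[t] for t in SPECIAL_TOKENS)

    @property
    def nonspecial_ids(self) -> np.ndarray:
        """Ids of all sequence tokens (k-mers and standalone bases)."""
        special = set(self.special_ids)
        return np.array([i for i in range(len(self)) if i not in special])

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    def save(self, path) -> None:
        """One token per line; line number (0-based) is the id."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "TokenVocabulary":
        with open(path) as fh:
            tokens = tuple(line.strip() for line in fh if line.strip())
        kmers = [t for t in tokens if t not in STANDALONE_TOKENS and t not in SPECIAL_TOKENS]
        k = len(kmers[0])
        alphabet = tuple(sorted({c for t in kmers for c in t}))
        return cls(kmer_size=k, alphabet=alphabet, tokens=tokens,
                   id_of={t: i for i, t in enumerate(tokens)})


def build_vocab(kmer_size: int = 6,
                alphabet: Sequence[str] = ("A", "C", "G", "T")) -> TokenVocabulary:
    """Build the deterministic k-mer vocabulary.

    Token order is fixed: all k-mers in lexicographic order, then the five
    standalone tokens, then the special tokens — so ids are stable across
    runs. Size is ``|alphabet|**kmer_size + 5 + 4``.
    """
    if kmer_size < 1:
        raise InvalidConfigError(f"kmer_size must be >= 1, got {kmer_size}")
    alphabet = tuple(alphabet)
    if not alphabet:
        raise InvalidAlphabetError("alphabet must be non-empty")
    if len(set(alphabet)) != len(alphabet):
        raise InvalidAlphabetError(f"alphabet symbols must be unique: {alphabet}")
    bad = [a for a in alphabet if a not in _NUCLEOTIDES]
    if bad:
        raise InvalidAlphabetError(f"non-nucleotide alphabet symbols: {bad}")
    kmers = ["".join(p) for p in itertools.product(sorted(alphabet), repeat=kmer_size)]
    tokens = tuple(kmers) + STANDALONE_TOKENS + SPECIAL_TOKENS
    return TokenVocabulary(kmer_size=kmer_size, alphabet=alphabet, tokens=tokens,
                           id_of={t: i for i, t in enumerate(tokens)})


def tokenize(sequence: str, vocab: TokenVocabulary) -> list[str]:
    """Greedy left-to-right k-mer scan with standalone-base fallback.

    Lowercase (soft-masked) input is uppercased first. Raises
    InvalidCharacterError naming the offset of the first character outside
    {A,C,G,T,N}.
    """
    seq = sequence.upper()
    for i, c in enumerate(seq):
        if c not in _VALID_CHARS:
            raise InvalidCharacterError(
                f"invalid character {c!r} at offset {i} (expected A/C/G/T/N)")
    k = vocab.kmer_size
    alpha = set(vocab.alphabet)
    out: list[str] = []
    i, n = 0, len(seq)
    while i < n:
        window = seq[i:i + k]
        if len(window) == k and all(c in alpha for c in window):
            out.append(window)
            i += k
        else:
            out.append(seq[i])
            i += 1
    return out


def detokenize(tokens: Iterable[str]) -> str:
    """Concatenate k-mer/standalone tokens back to a sequence; specials skipped."""
    parts = []
    for t in tokens:
        if t in SPECIAL_TOKENS:
            continue
        if not t or not all(c in _VALID_CHARS for c in t):
            raise InvalidTokenError(f"unknown token {t!r}")
        parts.append(t)
    return "".join(parts)


@dataclass
class TokenSequence:
    """Model-ready id sequence: CLS first, PAD-completed to a fixed length."""

    ids: np.ndarray
    is_special: np.ndarray
    source_span: tuple[str, int, int] | None = None
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_nonspecial(self) -> int:
        return int((~self.is_special).sum())


def token_ids(sequence: str, vocab: TokenVocabulary) -> np.ndarray:
    return np.array([vocab.id_of[t] for t in tokenize(sequence, vocab)], dtype=np.int64)


def encode_for_model(sequence: str, vocab: TokenVocabulary, max_tokens: int,
                     source_span: tuple[str, int, int] | None = None) -> TokenSequence:
    """[CLS] + token ids, right-truncated if over-long, PAD-filled to max_tokens."""
    if max_tokens < 2:
        raise InvalidConfigError(f"max_tokens must be >= 2, got {max_tokens}")
    ids = token_ids(sequence, vocab)
    truncated = False
    if len(ids) > max_tokens - 1:
        logger.warning("sequence of %d tokens truncated to %d", len(ids), max_tokens - 1)
        ids = ids[:max_tokens - 1]
        truncated = True
    n_pad = max_tokens - 1 - len(ids)
    full = np.concatenate([[vocab.cls_id], ids,
                           np.full(n_pad, vocab.pad_id, dtype=np.int64)])
    is_special = np.zeros(max_tokens, dtype=bool)
    is_special[0] = True
    if n_pad:
        is_special[-n_pad:] = True
    return TokenSequence(ids=full.astype(np.int64), is_special=is_special,
                         source_span=source_span, truncated=truncated)


def token_spans(sequence: str, vocab: TokenVocabulary) -> list[tuple[int, int]]:
    """0-based half-open nucleotide span of each emitted token."""
    spans = []
    pos = 0
    for t in tokenize(sequence, vocab):
        spans.append((pos, pos + len(t)))
        pos += len(t)
    return spans
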