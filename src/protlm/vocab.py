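"""Amino-acid vocabulary and tokenization.

The vocabulary covers the 20 standard amino acids plus the 6 non-standard
symbols that occur in curated protein databases (B, J, O, U, X, Z), together
with two special tokens: ``<PAD>`` (index 0) and ``<BOS>``, which marks the
beginning of every tokenized sequence.  Token indices are fixed once here and
shared by the language model, the classifiers and the one-hot encoder of the
CNN baseline: ``<PAD>`` = 0, ``<BOS>`` = 1, the 20 standard residues in
alphabetical order at 2..21, then B, J, O, U, X, Z at 22..27.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

STANDARD_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
NONSTANDARD_RESIDUES = tuple("BJOUXZ")
PAD, BOS = "<PAD>", "<BOS>"

FORWARD = "forward"
BACKWARD = "backward"


class UnknownResidueError(ValueError):
    """A sequence contains a symbol outside the residue vocabulary."""

    def __init__(self, symbol: str, position: int, seq_id: str | None = None):
        self.symbol = symbol
        self.position = position
        self.seq_id = seq_id
        where = f" in sequence {seq_id!r}" if seq_id else ""
        super().__init__(
            f"unknown residue symbol {symbol!r} at position {position}{where}"
        )


@dataclass(frozen=True)
class AminoAcidVocabulary:
    """Residue vocabulary with fixed integer ids.

    26 residue symbols (20 standard + 6 non-standard, including X) plus the
    special tokens <PAD> and <BOS>.
    """

    residue_tokens: tuple[str, ...] = STANDARD_RESIDUES + NONSTANDARD_RESIDUES
    special_tokens: tuple[str, ...] = (PAD, BOS)
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.residue_tokens) != 26:
            raise ValueError("vocabulary requires exactly 26 residue symbols")
        if set(self.special_tokens) & set(self.residue_tokens):
            raise ValueError("special tokens must be disjoint from residues")
        index = {tok: i for i, tok in enumerate(self.special_tokens)}
        for i, tok in enumerate(self.residue_tokens):
            index[tok] = len(self.special_tokens) + i
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.special_tokens) + len(self.residue_tokens)

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    @property
    def bos_id(self) -> int:
        return self._index[BOS]

    @property
    def x_id(self) -> int:
        return self._index["X"]

    def index_of(self, symbol: str) -> int:
        return self._index[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def token_of(self, index: int) -> str:
        tokens = self.special_tokens + self.residue_tokens
        return tokens[index]

    def residue_index(self, symbol: str) -> int:
        """0-based index of a residue among the 26 residues (one-hot column)."""
        i = self._index[symbol]
        if i < len(self.special_tokens):
            raise KeyError(symbol)
        return i - len(self.special_tokens)


@dataclass
class ProteinRecord:
    """A protein sequence with an optional task-dependent label payload."""

    id: str
    sequence: str
    labels: object | None = None

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TokenSequence:
    """Direction-aware encoded sequence: <BOS> followed by L residue ids."""

    ids: tuple[int, ...]
    direction: str

    def __len__(self) -> int:
        return len(self.ids)


def tokenize(
    record: ProteinRecord,
    vocab: AminoAcidVocabulary,
    direction: str = FORWARD,
) -> TokenSequence:
    """Encode a record as <BOS> followed by its residue ids.

    ``direction="backward"`` reverses the residue order while keeping <BOS>
    first, so forward and backward models see mirrored contexts.
    """
    if direction not in (FORWARD, BACKWARD):
        raise ValueError(f"direction must be forward|backward, got {direction!r}")
    seq = record.sequence
    ids = [vocab.bos_id]
    residues = seq if direction == FORWARD else seq[::-1]
    for i, ch in enumerate(residues):
        if ch not in vocab or ch in vocab.special_tokens:
            pos = i if direction == FORWARD else len(seq) - 1 - i
            raise UnknownResidueError(ch, pos, record.id)
        ids.append(vocab.index_of(ch))
    return TokenSequence(tuple(ids), direction)


def detokenize(tokens: TokenSequence, vocab: AminoAcidVocabulary) -> str:
    """Recover the original residue string from a TokenSequence."""
    if tokens.ids[0] != vocab.bos_id:
        raise ValueError("token sequence does not start with <BOS>")
    seq = "".join(vocab.token_of(i) for i in tokens.ids[1:])
    return seq[::-1] if tokens.direction == BACKWARD else seq


def normalize_sequence(
    seq: str, vocab: AminoAcidVocabulary, permissive: bool = False
) -> str:
    """Uppercase a raw sequence; unknown symbols map to X only if permissive."""
    out = []
    for i, ch in enumerate(seq.upper()):
        if ch in vocab and ch not in vocab.special_tokens:
            out.append(ch)
        elif permissive:
            out.append("X")
        else:
            raise UnknownResidueError(ch, i)
    return "".join(out)


def encode_ids(
    sequences: Sequence[str], vocab: AminoAcidVocabulary, direction: str = FORWARD
) -> list[tuple[int, ...]]:
    """Tokenize plain residue strings (convenience for LM corpora)."""
    return [
        tokenize(ProteinRecord(id=str(i), sequence=s), vocab, direction).ids
        for i, s in enumerate(sequences)
    ]
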