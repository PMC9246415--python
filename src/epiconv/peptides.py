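"""Peptide tokenization, padding and dense embedding.

MHC-II ligands are 9–25 residues long.  Sequences are right-padded to 25
with the pad symbol ``J`` (not a standard amino-acid letter), tokenized
against a fixed 21-symbol vocabulary and embedded through a trainable
21 x dim table initialized from a seeded normal distribution.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, embedding_lookup

__all__ = [
    "VOCAB",
    "PAD",
    "MIN_LEN",
    "MAX_LEN",
    "PeptideVocab",
    "pad_peptide",
    "tokenize",
    "detokenize",
    "validate_peptide",
]

PAD = "J"
VOCAB = [PAD, "A", "C", "D", "E", "F", "G", "H", "I", "K", "L",
         "M", "N", "P", "Q", "R", "S", "T", "V", "W", "Y"]
_SYM_INDEX = {s: i for i, s in enumerate(VOCAB)}
AMINO_ACIDS = "".join(VOCAB[1:])

MIN_LEN = 9
MAX_LEN = 25


def validate_peptide(seq: str) -> str:
    """Check length 9–25 and standard uppercase residues; return seq."""
    if not isinstance(seq, str) or not seq:
        raise ValueError("empty peptide")
    if not (MIN_LEN <= len(seq) <= MAX_LEN):
        raise ValueError(
            f"peptide length {len(seq)} outside [{MIN_LEN}, {MAX_LEN}]: {seq!r}"
        )
    for pos, ch in enumerate(seq):
        if ch == PAD or ch not in _SYM_INDEX:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} in {seq!r}"
            )
    return seq


def pad_peptide(seq: str) -> str:
    """Right-pad a validated 9–25-mer with 'J' to exactly 25 characters."""
    validate_peptide(seq)
    return seq + PAD * (MAX_LEN - len(seq))


def tokenize(seq: str) -> np.ndarray:
    """Validated sequence -> length-25 integer token array."""
    padded = pad_peptide(seq)
    return np.array([_SYM_INDEX[c] for c in padded], dtype=np.int64)


def detokenize(tokens: np.ndarray) -> str:
    """Inverse of :func:`tokenize`: strips trailing pad symbols."""
    s = "".join(VOCAB[int(t)] for t in tokens)
    return s.rstrip(PAD)


class PeptideVocab:
    """The 21-symbol vocabulary plus its trainable embedding table."""

    def __init__(self, dim: int = 128, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self.symbols = list(VOCAB)
        rng = np.random.default_rng(seed)
        self.table = Tensor(
            rng.standard_normal((len(VOCAB), dim)) * 0.1, requires_grad=True
        )
        # a seeded continuous table has pairwise-distinct rows w.p. 1;
        # assert rather than assume so lookup stays injective on the vocab
        d = self.table.data
        gram_distinct = not np.any(
            [np.allclose(d[i], d[j]) for i in range(len(d)) for j in range(i)]
        )
        if not gram_distinct:
            raise RuntimeError("degenerate embedding table: duplicate rows")

    def embed(self, seqs: list[str] | str) -> Tensor:
        """Peptide(s) -> (25, dim) or (B, 25, dim) embedding matrix."""
        if isinstance(seqs, str):
            return embedding_lookup(self.table, tokenize(seqs))
        toks = np.stack([tokenize(s) for s in seqs])
        return embedding_lookup(self.table, toks)

    def params(self) -> list[Tensor]:
        return [self.table]


def embed_peptide(seq: str, vocab: PeptideVocab) -> Tensor:
    """Single validated peptide -> 25 x dim matrix (pad rows all equal)."""
    return vocab.embed(seq)
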