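"""Elution-negative decoy generation from source proteins.

For every eluted (positive) peptide P, all same-length windows of its
source protein are enumerated; each candidate is scored for dissimilarity
against the *entire* positive set (negated best ungapped BLOSUM62
similarity over all offsets), optionally screened by a pluggable binding
filter, and the k most dissimilar survivors become the negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "SourceProtein",
    "DecoySet",
    "slide_windows",
    "dissimilarity_score",
    "select_negatives",
    "build_ratio_dataset",
    "null_filter",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class SourceProtein:
    """A full-length source protein addressed by accession."""

    accession: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty protein sequence")


@dataclass
class DecoySet:
    """Ranked decoy candidates for one positive peptide."""

    positive: str
    ranked: list[tuple[str, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)


def slide_windows(F: str, w: int) -> list[str]:
    """All |F|-w+1 contiguous length-w windows of F, N->C order."""
    if w < 1:
        raise ValueError("window length must be >= 1")
    if len(F) < w:
        raise ValueError(
            f"protein length {len(F)} shorter than window {w}"
        )
    return [F[i : i + w] for i in range(len(F) - w + 1)]


def _pair_similarity(a: str, b: str, matrix) -> float:
    """Best ungapped alignment score of a against b over all offsets.

    Equal lengths compare position-by-position at offset 0 as a special
    case of sliding the shorter sequence along the longer one.
    """
    if len(a) > len(b):
        a, b = b, a
    best = -np.inf
    for off in range(len(b) - len(a) + 1):
        s = 0.0
        for x, y in zip(a, b[off : off + len(a)]):
            try:
                s += matrix[x, y]
            except (KeyError, IndexError):
                s += -4.0  # non-standard symbol: gap-like penalty
        best = max(best, s)
    return best


def dissimilarity_score(
    candidate: str, positive_set: list[str], matrix=None
) -> float:
    """Negated maximum substitution-matrix similarity to any positive.

    Higher = more dissimilar.  Deterministic; BLOSUM62 by default.
    """
    if not positive_set:
        raise ValueError("empty positive set")
    matrix = _BLOSUM62 if matrix is None else matrix
    best = max(_pair_similarity(candidate, p, matrix) for p in positive_set)
    return -best


def null_filter(candidate: str) -> bool:
    """Binding filter that passes everything."""
    return True


def select_negatives(
    candidates: list[str],
    positive_set: list[str],
    binding_filter=null_filter,
    k: int = 10,
    matrix=None,
) -> DecoySet:
    """Rank filter-surviving candidates by dissimilarity and keep the top k.

    Exact duplicates of any positive are removed; ties at any rank break
    lexicographically by sequence so the selection is order-independent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    positives = set(positive_set)
    survivors = sorted(
        {c for c in candidates if c not in positives and binding_filter(c)}
    )
    scored = [
        (c, dissimilarity_score(c, list(positive_set), matrix=matrix))
        for c in survivors
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    ds = DecoySet(positive="", ranked=scored, selected=[c for c, _ in scored[:k]])
    if len(ds.selected) < k:
        warnings.warn(
            f"only {len(ds.selected)} decoy candidates survive "
            f"(requested {k})",
            stacklevel=2,
        )
    return ds


def negatives_for_positive(
    positive: str,
    protein: SourceProtein,
    positive_set: list[str],
    binding_filter=null_filter,
    k: int = 10,
    matrix=None,
) -> DecoySet:
    """Full per-positive pipeline: windows of the source protein -> top-k."""
    try:
        cands = slide_windows(protein.sequence, len(positive))
    except ValueError as exc:
        warnings.warn(f"{protein.accession}: {exc}", stacklevel=2)
        return DecoySet(positive=positive)
    ds = select_negatives(
        cands, positive_set, binding_filter=binding_filter, k=k, matrix=matrix
    )
    ds.positive = positive
    return ds


def build_ratio_dataset(
    positives: pd.DataFrame,
    decoy_pool: pd.DataFrame,
    ratio: str = "1:1",
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble a labelled dataset at a positive:negative ratio.

    ``ratio`` is "P:N" (e.g. "1:1", "1:5"); negatives are drawn from the
    pool without replacement, seeded.  Output columns: allele, peptide,
    label (1 positive / 0 negative).
    """
    try:
        p_part, n_part = ratio.split(":")
        p_w, n_w = int(p_part), int(n_part)
        if p_w < 1 or n_w < 1:
            raise ValueError
    except ValueError:
        raise ValueError(f"malformed ratio {ratio!r}; expected like '1:5'")
    n_pos = len(positives)
    n_needed = (n_pos * n_w) // p_w
    if len(decoy_pool) < n_needed:
        raise ValueError(
            f"decoy pool too small: {n_needed} negatives required for "
            f"ratio {ratio} with {n_pos} positives, only "
            f"{len(decoy_pool)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(decoy_pool), size=n_needed, replace=False)
    neg = decoy_pool.iloc[np.sort(idx)].copy()
    pos = positives.copy()
    pos["label"] = 1
    neg["label"] = 0
    cols = ["allele", "peptide", "label"]
    return pd.concat([pos[cols], neg[cols]], ignore_index=True)
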