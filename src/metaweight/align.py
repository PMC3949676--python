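"""Pairwise protein similarity backends.

The sequence-similarity weight needs a symmetric similarity in [0, 1] for a
pair of amino-acid sequences.  The default backend is an affine-gap
Smith-Waterman (Gotoh) local aligner scored with BLOSUM62, gap existence 11
and extension 1 (a gap of length L costs 11 + L), returning

    similarity = identities / alignment length

over the optimal local alignment.  Traceback ties are resolved
deterministically (diagonal, then vertical, then horizontal; the end cell is
the first maximum in row-major order), and the pair is canonically ordered
before aligning, so the similarity is exactly symmetric.

Users who ran an external aligner can instead supply precomputed pair scores
via :class:`PrecomputedSimilarity`; any callable ``(seq_a, seq_b) -> float``
is accepted wherever a similarity backend is expected.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = ["pairwise_similarity", "PrecomputedSimilarity", "GAP_OPEN",
           "GAP_EXTEND"]

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_SUBMAT = np.asarray(_BLOSUM62, dtype=np.float64)
_X_INDEX = _ALPHABET.index("X")
_CHAR_TO_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as BLOSUM62 row indices (unknown -> X)."""
    return np.asarray(
        [_CHAR_TO_INDEX.get(c, _X_INDEX) for c in seq.upper()],
        dtype=np.int64)


@njit(cache=True)
def _gotoh_local(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    m, n = a.shape[0], b.shape[0]
    neg = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), neg)
    F = np.full((m + 1, n + 1), neg)
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 open, 1 extend
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.int8)
    open_cost = gap_open + gap_extend
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] - open_cost
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptr_e[i, j] = 0
            else:
                E[i, j] = ee
                ptr_e[i, j] = 1
            fo = H[i - 1, j] - open_cost
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptr_f[i, j] = 0
            else:
                F[i, j] = fe
                ptr_f[i, j] = 1
            val = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            p = 1
            if F[i, j] > val:
                val = F[i, j]
                p = 2
            if E[i, j] > val:
                val = E[i, j]
                p = 3
            if val <= 0.0:
                H[i, j] = 0.0
                ptr_h[i, j] = 0
            else:
                H[i, j] = val
                ptr_h[i, j] = p
                if val > best:
                    best = val
                    bi = i
                    bj = j
    # traceback
    ident = 0
    length = 0
    i, j = bi, bj
    state = 0  # 0 = H, 2 = F (vertical), 3 = E (horizontal)
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                length += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            length += 1
            p = ptr_f[i, j]
            i -= 1
            state = 0 if p == 0 else 2
        else:
            length += 1
            p = ptr_e[i, j]
            j -= 1
            state = 0 if p == 0 else 3
    return best, ident, length


def local_alignment(seq_a: str, seq_b: str) -> tuple[float, int, int]:
    """Optimal local alignment of two sequences.

    Returns ``(score, identities, alignment_length)``; all zero when no
    positive-scoring local alignment exists.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    score, ident, length = _gotoh_local(
        encode(seq_a), encode(seq_b), _SUBMAT, GAP_OPEN, GAP_EXTEND)
    return float(score), int(ident), int(length)


def pairwise_similarity(seq_a: str, seq_b: str) -> float:
    """Identity fraction of the optimal local alignment, in [0, 1].

    Symmetric by construction (the pair is canonically ordered first);
    exactly 1.0 for identical sequences, 0.0 when nothing aligns.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 1.0
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    _, ident, length = local_alignment(seq_a, seq_b)
    if length == 0:
        return 0.0
    return min(1.0, max(0.0, ident / length))


class PrecomputedSimilarity:
    """Similarity backend backed by an externally computed pair-score table.

    ``scores`` maps unordered sequence pairs to similarities; construct with
    :meth:`from_records` when scores are keyed by protein id.  Scores are
    clamped to [0, 1].  Missing pairs raise ``KeyError``.
    """

    def __init__(self, scores: Mapping[frozenset, float]):
        self._scores = {frozenset(k): float(v) for k, v in scores.items()}

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str, float]],
        sequences: Mapping[str, str],
    ) -> "PrecomputedSimilarity":
        scores = {}
        for id_a, id_b, s in records:
            scores[frozenset((sequences[id_a], sequences[id_b]))] = s
        return cls(scores)

    def __call__(self, seq_a: str, seq_b: str) -> float:
        if seq_a == seq_b:
            return 1.0
        s = self._scores[frozenset((seq_a, seq_b))]
        return min(1.0, max(0.0, s))
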