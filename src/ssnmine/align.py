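"""Pairwise local alignment, Karlin-Altschul statistics and the SSN
alignment score.

Alignment is optimal Smith-Waterman under affine gaps (no heuristic
seeding), scored with a substitution matrix (BLOSUM62 by default, with
``X`` scoring 0 against everything).  E-values use the per-pair search
space ``m * n`` of the two sequences rather than a database-wide
length, which makes them symmetric, deterministic and independent of
dataset size; the resulting alignment score AS = -log10(E) is therefore
on its own scale and thresholds must be tuned on the data at hand
rather than transplanted from BLAST-based services.

Gap cost convention: a gap of length ``k`` costs
``gap_open + k * gap_extend`` (the BLAST convention, so the default
11/1 behaves like ``blastp -gapopen 11 -gapextend 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices as _submat

from ssnmine.seqio import ALPHABET, AMINO20, SeqRecord

_LN2 = math.log(2.0)
_LN10 = math.log(10.0)

#: Robinson & Robinson background amino-acid frequencies, order = ALPHABET
#: without X.  Used for matrix sanity checks and BLOSUM-derived
#: substitution models elsewhere in the package.
BACKGROUND_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def _blosum62_x0():
    """BLOSUM62 restricted to the package alphabet, with X scoring 0."""
    m = _submat.load("BLOSUM62").select(ALPHABET).copy()
    for a in ALPHABET:
        m[a, "X"] = 0
        m["X", a] = 0
    return m


def _validate_matrix(matrix) -> None:
    arr = np.asarray(matrix)
    if not np.array_equal(arr, arr.T):
        raise ValueError("substitution matrix must be symmetric")
    # expected score under background frequencies must be negative,
    # otherwise Karlin-Altschul statistics are undefined
    letters = [a for a in matrix.alphabet if a in BACKGROUND_FREQS]
    exp = 0.0
    for a in letters:
        for b in letters:
            exp += BACKGROUND_FREQS[a] * BACKGROUND_FREQS[b] * matrix[a, b]
    if exp >= 0:
        raise ValueError(f"expected substitution score is nonnegative ({exp:.3f})")


@dataclass(frozen=True, eq=False)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul
    parameters.

    ``gap_open``/``gap_extend`` are positive penalties; a gap of length
    k costs ``gap_open + k * gap_extend``.  ``ka_lambda`` and
    ``ka_kappa`` are the Karlin-Altschul scale and prefactor used in
    ``E = kappa * m * n * exp(-lambda * S)``; the defaults are the
    standard gapped BLOSUM62/11/1 values.
    """

    matrix: object = None
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_kappa: float = 0.041

    def __post_init__(self) -> None:
        if self.matrix is None:
            object.__setattr__(self, "matrix", _blosum62_x0())
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.ka_lambda <= 0 or self.ka_kappa <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @classmethod
    def from_matrix_file(cls, path: str | Path, **kwargs) -> "ScoringScheme":
        """Load a substitution matrix in NCBI text format and validate it."""
        with open(path) as fh:
            matrix = _submat.read(fh)
        _validate_matrix(matrix)
        return cls(matrix=matrix, **kwargs)

    def aligner(self) -> _BioAlign.PairwiseAligner:
        """A configured Smith-Waterman (local, affine-gap) aligner."""
        cached = self.__dict__.get("_aligner")
        if cached is None:
            cached = _make_aligner(self.matrix, self.gap_open, self.gap_extend)
            object.__setattr__(self, "_aligner", cached)
        return cached

    def score_lookup(self) -> np.ndarray:
        """Matrix as a dense array indexed by ALPHABET positions."""
        n = len(ALPHABET)
        out = np.zeros((n, n))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                out[i, j] = self.matrix[a, b]
        return out


def _make_aligner(matrix, gap_open: int, gap_extend: int) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap residue and
    # extend_gap_score thereafter; our convention charges open + k*extend
    # for a length-k gap, hence the offset.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise local alignment.

    ``span_a``/``span_b`` are 1-based inclusive residue intervals of the
    reported optimal alignment; an empty alignment (raw_score 0) has
    ``aligned_columns`` 0 and no spans.  ``log10_evalue`` is carried so
    the alignment score can be formed without underflow even when
    ``evalue`` rounds to 0.
    """

    raw_score: int
    bit_score: float
    evalue: float
    log10_evalue: float
    percent_identity: float
    aligned_columns: int
    span_a: Optional[Tuple[int, int]]
    span_b: Optional[Tuple[int, int]]


def log10_evalue(raw_score: float, len_a: int, len_b: int, scheme: ScoringScheme) -> float:
    """log10 of the Karlin-Altschul E-value, computed in log space."""
    if len_a < 1 or len_b < 1:
        raise ValueError("sequence lengths must be >= 1")
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    # single log of the product keeps the value exactly symmetric in
    # the two lengths
    return (
        math.log10(scheme.ka_kappa)
        + math.log10(float(len_a) * float(len_b))
        - scheme.ka_lambda * raw_score / _LN10
    )


def evalue(raw_score: float, len_a: int, len_b: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation ``kappa * m * n * exp(-lambda * S)``.

    Strictly decreasing in ``raw_score`` and linear in each length.
    May underflow to 0.0 for very high scores; use
    :func:`log10_evalue` where that matters.
    """
    return 10.0 ** log10_evalue(raw_score, len_a, len_b, scheme)


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalised score ``(lambda*S - ln kappa) / ln 2``."""
    return (scheme.ka_lambda * raw_score - math.log(scheme.ka_kappa)) / _LN2


def alignment_score(result: AlignmentResult) -> float:
    """SSN alignment score AS = -log10(E-value), clamped below at 0.

    Computed from the stored log10 E-value, so an underflowed
    ``evalue == 0.0`` still yields a finite AS.
    """
    return max(0.0, -result.log10_evalue)


def blosum_joint_probs() -> np.ndarray:
    """Implied BLOSUM62 joint substitution probabilities.

    Reconstructed from the half-bit score matrix via
    ``p(a,b) ∝ bg(a) * bg(b) * 2**(s(a,b)/2)`` — adequate for
    pseudocounts and simulation, where the rounding error of the
    integer score matrix is immaterial.  Order follows :data:`AMINO20`.
    """
    m = _blosum62_x0()
    bg = np.array([BACKGROUND_FREQS[a] for a in AMINO20])
    s = np.array([[m[a, b] for b in AMINO20] for a in AMINO20])
    joint = bg[:, None] * bg[None, :] * np.power(2.0, s / 2.0)
    return joint / joint.sum()


def blosum_conditional() -> np.ndarray:
    """Row-stochastic conditional substitution matrix P(b | a)."""
    joint = blosum_joint_probs()
    return joint / joint.sum(axis=1, keepdims=True)


def anchored_residues(
    anchor: SeqRecord, other: SeqRecord, scheme: Optional["ScoringScheme"] = None
) -> list:
    """Project *other* onto *anchor* coordinates via local alignment.

    Returns a list of length ``anchor.length``: at each anchor
    position, the residue of *other* aligned to it, or ``None`` where
    the position is unaligned or gapped.  Insertions in *other*
    relative to the anchor are dropped (anchor coordinates only).
    """
    scheme = scheme or ScoringScheme()
    out: list = [None] * anchor.length
    if not other.residues:
        return out
    aligner = scheme.aligner()
    swapped = other.residues < anchor.residues
    first, second = (
        (other.residues, anchor.residues) if swapped else (anchor.residues, other.residues)
    )
    alignments = aligner.align(first, second)
    if alignments.score <= 0 or len(alignments) == 0:
        return out
    blocks_a, blocks_b = alignments[0].aligned
    anchor_blocks, other_blocks = (blocks_b, blocks_a) if swapped else (blocks_a, blocks_b)
    for (a_start, a_end), (o_start, _) in zip(anchor_blocks, other_blocks):
        for off in range(a_end - a_start):
            out[a_start + off] = other.residues[o_start + off]
    return out


def residue_indices(seq: str) -> np.ndarray:
    """Map residues to ALPHABET positions (X = index 20)."""
    lut = {a: i for i, a in enumerate(ALPHABET)}
    return np.fromiter((lut[c] for c in seq), dtype=np.int64, count=len(seq))


def sw_score_positional(
    pssm: np.ndarray, seq_indices: np.ndarray, gap_open: int, gap_extend: int
) -> float:
    """Optimal local-alignment raw score of a sequence against a
    position-specific scoring matrix.

    ``pssm`` has shape (m, 21): one row per profile position, columns
    indexed like :data:`ALPHABET` (last column = X).  Affine gaps with
    the same ``open + k*extend`` convention as :func:`align_local`.

    The row recursion is vectorised: within a row, the best
    insertion-extended value is a running maximum of
    ``H - open - (gap length)*extend``, which a prefix maximum over
    ``G[j] + j*extend`` computes exactly (re-opening a gap is never
    cheaper than extending the one already open).
    """
    m = pssm.shape[0]
    n = seq_indices.shape[0]
    go, ge = float(gap_open), float(gap_extend)
    idx = np.arange(1, n + 1, dtype=float)
    h_prev = np.zeros(n + 1)
    f_prev = np.full(n + 1, -np.inf)
    best = 0.0
    for i in range(m):
        scores = pssm[i, seq_indices]
        m_row = h_prev[:-1] + scores
        f_row = np.maximum(f_prev[1:] - ge, h_prev[1:] - go - ge)
        g = np.maximum.reduce([m_row, f_row, np.zeros(n)])
        run = np.maximum.accumulate(g + idx * ge)
        e_row = np.empty(n)
        e_row[0] = -np.inf
        e_row[1:] = run[:-1] - go - idx[1:] * ge
        h_row = np.maximum(g, e_row)
        best = max(best, float(h_row.max(initial=0.0)))
        h_prev = np.concatenate(([0.0], h_row))
        f_prev = np.concatenate(([-np.inf], f_row))
    return float(best)


def _empty_result(len_a: int, len_b: int, scheme: ScoringScheme) -> AlignmentResult:
    lg = log10_evalue(0, len_a, len_b, scheme)
    return AlignmentResult(
        raw_score=0,
        bit_score=bit_score(0, scheme),
        evalue=10.0 ** lg,
        log10_evalue=lg,
        percent_identity=0.0,
        aligned_columns=0,
        span_a=None,
        span_b=None,
    )


def align_local(a: SeqRecord, b: SeqRecord, scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two records.

    Returns the optimal raw score, its E-value/bit score, and percent
    identity over the aligned columns (matches, mismatches and gap
    columns) of one reported optimal alignment.  Symmetric: swapping
    the inputs leaves every scalar field unchanged (internally the pair
    is ordered canonically before traceback so tie-broken alignments do
    not depend on argument order).
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequence")
    swapped = b.residues < a.residues
    first, second = (b, a) if swapped else (a, b)
    aligner = scheme.aligner()
    alignments = aligner.align(first.residues, second.residues)
    raw = int(alignments.score)
    if raw <= 0 or len(alignments) == 0:
        return _empty_result(a.length, b.length, scheme)
    best = alignments[0]
    counts = best.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    pid = 100.0 * counts.identities / cols if cols else 0.0
    blocks_a, blocks_b = best.aligned
    span_first = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    span_second = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    if swapped:
        span_first, span_second = span_second, span_first
    lg = log10_evalue(raw, a.length, b.length, scheme)
    return AlignmentResult(
        raw_score=raw,
        bit_score=bit_score(raw, scheme),
        evalue=10.0 ** lg,
        log10_evalue=lg,
        percent_identity=pid,
        aligned_columns=int(cols),
        span_a=span_first,
        span_b=span_second,
    )
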