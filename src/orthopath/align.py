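"""Local protein alignment with bit scores and E-values.

The orthology search needs only alignment *scores*, so the default backend
wraps Biopython's ``PairwiseAligner`` in local (Smith–Waterman) mode with a
substitution matrix and affine gaps, then converts raw scores to bits and
E-values with the Karlin–Altschul statistics

    bits = (lambda * S - ln K) / ln 2,      E = m * n * 2**(-bits)

using the conventional ungapped BLOSUM62 constants (lambda = 0.3176,
K = 0.134) and a caller-supplied search space m*n (query length times total
subject residues).  Any backend producing :class:`AlignmentHit` records with
the same semantics can be substituted (e.g. a wrapper around an external
search tool); the rest of the pipeline only consumes hits.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .types import VALID_RESIDUES


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, affine gap costs and Karlin–Altschul constants."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.3176  # ungapped BLOSUM62
    ka_k: float = 0.134

    def bit_score(self, raw_score: float) -> float:
        return (self.ka_lambda * raw_score - math.log(self.ka_k)) / math.log(2)

    def e_value(self, raw_score: float, search_space: float) -> float:
        return search_space * 2.0 ** (-self.bit_score(raw_score))


@dataclass(frozen=True)
class AlignmentHit:
    """Score triple for one query/subject pair."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # first gap position costs open+extend, each further position costs extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"{label}: unknown residue character(s) {sorted(bad)} "
            "(expected the 20 amino acids or X)"
        )


def local_score(seq_a: str, seq_b: str, params: ScoringParams = ScoringParams()) -> float:
    """Raw Smith–Waterman score of the best local alignment of two proteins."""
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend)
    return float(aligner.score(seq_a, seq_b))


def local_align(
    seq_a: str,
    seq_b: str,
    params: ScoringParams = ScoringParams(),
    search_space: float | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Score one pair and attach bit score and E-value.

    ``search_space`` defaults to ``len(seq_a) * len(seq_b)``; callers
    searching a whole proteome pass query length times total database
    residues instead, as BLAST does.
    """
    raw = local_score(seq_a, seq_b, params)
    if search_space is None:
        search_space = float(len(seq_a) * len(seq_b))
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=params.bit_score(raw),
        e_value=params.e_value(raw, search_space),
    )


def self_score(seq: str, params: ScoringParams = ScoringParams()) -> float:
    """Sum of diagonal matrix entries — the score of aligning *seq* to itself."""
    m = substitution_matrices.load(params.matrix)
    return float(sum(m[c, c] for c in seq))
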