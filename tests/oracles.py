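"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (plain-Python
dynamic programming, exhaustive enumeration, naive set arithmetic) so the
package implementation is checked against code that shares nothing with it.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_gotoh(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0,
                   matrix=_B62) -> float:
    """Smith-Waterman score with affine gaps (gap of length L costs
    open + L*extend), computed with an explicit three-state Gotoh DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1], H[i][j - 1] - gap_open) - gap_extend
            F[i][j] = max(F[i - 1][j], H[i - 1][j] - gap_open) - gap_extend
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def enumerate_assignment_optimum(candidates, operon_of, operon_penalty):
    """Exhaustive optimum of the operon-constrained selection objective.

    candidates: {member: [(target_gene, bit_score), ...]}
    operon_of: {target_gene: operon_id or None}
    Returns the best objective value over every combination of one
    candidate (or None) per member.
    """
    members = sorted(candidates)
    options = [list(candidates[m]) + [None] for m in members]
    best = float("-inf")
    for combo in itertools.product(*options):
        total = 0.0
        covered = set()
        for choice in combo:
            if choice is None:
                continue
            gene, bits = choice
            total += bits
            op = operon_of.get(gene)
            covered.add(("op", op) if op is not None else ("single", gene))
        best = max(best, total - operon_penalty * len(covered))
    return best


def naive_precision_recall(predicted: set, gold: set):
    """Membership-counting precision/recall, element by element."""
    tp = sum(1 for g in predicted if g in gold)
    fp = sum(1 for g in predicted if g not in gold)
    fn = sum(1 for g in gold if g not in predicted)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return tp, fp, fn, precision, recall
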