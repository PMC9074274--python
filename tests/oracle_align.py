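"""Independent dynamic-programming oracle used only by the tests.

A straightforward O(nm) Gotoh affine-gap Smith-Waterman computing the
optimal local alignment score with full matrices and no shortcuts.  It
shares no code with the package's alignment path.  The optimal score is
unique (unlike the traceback, which may have co-optimal paths), so score
agreement is asserted exactly; identity and coverage are cross-checked on
constructed cases where the optimal alignment is unambiguous.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = float("-inf")


def local_alignment_score(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Optimal local affine-gap alignment score by exhaustive DP."""
    matrix = substitution_matrices.load(matrix_name)
    n, m = len(seq_a), len(seq_b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a gap in seq_b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a gap in seq_a
    best = 0.0
    for i in range(1, n + 1):
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            sub = matrix[ai, seq_b[j - 1]]
            diag = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1], 0.0)
            row_m[j] = diag + sub
            row_x[j] = max(prev_m[j] - gap_open - gap_extend, prev_x[j] - gap_extend)
            row_y[j] = max(row_m[j - 1] - gap_open - gap_extend, row_y[j - 1] - gap_extend)
            here = max(row_m[j], row_x[j], row_y[j])
            if here > best:
                best = here
    return best
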