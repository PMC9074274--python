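"""Pairwise protein alignment used by the clustering criterion.

Cluster membership asks two questions of a candidate *member* protein against
the (longer) cluster *representative*:

* identity — exact-match columns divided by all aligned columns (gap columns
  included) of the optimal local alignment;
* member coverage — fraction of the member's length spanned by the alignment
  (the "coverage of the shorter/target sequence" criterion, which lets
  assembly fragments join the cluster of their full-length homolog).

Scoring is BLOSUM62 with affine gaps (open 11, extend 1) by default; both the
matrix and the penalties are configurable and deterministic.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning a member protein against a representative."""

    identity: float
    member_coverage: float
    score: float
    rep_range: tuple[int, int]
    member_range: tuple[int, int]
    n_columns: int

    def passes(self, min_seq_id: float, min_member_cov: float) -> bool:
        return (
            self.identity >= min_seq_id and self.member_coverage >= min_member_cov
        )


@functools.lru_cache(maxsize=8)
def _get_aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST-style affine costs: a gap of length k costs gap_open + k*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str, alphabet: str, which: str) -> None:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{which} sequence has illegal residues: {sorted(bad)}")


def align_pair(
    rep_seq: str,
    member_seq: str,
    *,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal local alignment of *member_seq* against *rep_seq*.

    Returns identity over aligned columns and the fraction of the member
    covered by the aligned span.  Deterministic: Bio.Align's traceback order
    is fixed, and only the first optimal alignment is used.
    """
    aligner = _get_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_protein(rep_seq, alphabet, "representative")
    _check_protein(member_seq, alphabet, "member")

    alignments = aligner.align(rep_seq, member_seq)
    try:
        aln = alignments[0]
    except IndexError:
        return AlignmentResult(0.0, 0.0, 0.0, (0, 0), (0, 0), 0)
    identities, n_columns, rep_span, member_span = alignment_stats(
        aln, rep_seq, member_seq
    )
    identity = identities / n_columns if n_columns else 0.0
    member_coverage = (member_span[1] - member_span[0]) / len(member_seq)
    return AlignmentResult(
        identity=identity,
        member_coverage=member_coverage,
        score=float(aln.score),
        rep_range=rep_span,
        member_range=member_span,
        n_columns=n_columns,
    )


def alignment_stats(
    aln, seq_a: str, seq_b: str
) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """(identities, aligned columns, span on a, span on b) of an alignment.

    Columns count matches, mismatches and internal gap columns; a local
    alignment has no terminal gap columns.  Walking the aligned blocks
    directly keeps this on the hot path cheap.
    """
    blocks_a, blocks_b = aln.aligned
    identities = 0
    n_columns = 0
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            n_columns += (a0 - prev_a) + (b0 - prev_b)  # gap columns
        n_columns += a1 - a0
        identities += sum(
            x == y for x, y in zip(seq_a[a0:a1], seq_b[b0:b1])
        )
        prev_a, prev_b = a1, b1
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return identities, n_columns, span_a, span_b
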