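"""Read mapping evaluation: subsampling, counting, coverage estimation.

Gene catalogues are evaluated by mapping a fixed random subset of each
sample's forward reads against the catalogue's nucleotide sequences.  A read
is accepted when its best local alignment covers at least ``min_read_cov`` of
the read at ``min_read_identity`` identity or better; matching is
strand-insensitive (the reverse complement is always tried).  A read whose
best score is achieved by two or more genes is *ambiguous* and is not counted
to any gene, but is tallied separately — the convention of feature-count
tools that drop ambiguous overlaps.

Per-gene read-depth coverage in the total metagenome is the rough scale-up

    coverage = count * (mean_read_pair_length / gene_length)
                     * (total_read_pairs / n_sampled_reads)

and genes are binned as low (0-50x), median (50-500x), high (500-5000x) and
very high (5000-250,000x) coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .catalogue import Catalogue
from .align import alignment_stats
from .normalize import reverse_complement
from .records import Read, ReadSet

logger = logging.getLogger(__name__)

COVERAGE_BIN_EDGES = (0.0, 50.0, 500.0, 5000.0, 250000.0)
COVERAGE_BIN_LABELS = ("low", "median", "high", "very_high")


@dataclass(frozen=True)
class MappingConfig:
    """Read-assignment parameters.

    Defaults: 10,000 forward reads per sample with RNG seed 100; a hit needs
    a local alignment covering >= 80% of the read at >= 90% identity
    (approximating local-mode mapper sensitivity); scoring is the classic
    local-mapping scheme (match +2, mismatch -6, gap open -5, extend -3).
    """

    n_subsample: int = 10_000
    seed: int = 100
    min_read_cov: float = 0.8
    min_read_identity: float = 0.9
    match_score: int = 2
    mismatch_score: int = -6
    gap_open: int = -5
    gap_extend: int = -3
    seed_kmer: int = 11
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.n_subsample < 1:
            raise ValueError("n_subsample must be >= 1")


def subsample_reads(readset: ReadSet, config: MappingConfig) -> ReadSet:
    """Uniform random subset (without replacement) of the forward reads.

    Deterministic given the seed; input order is preserved.  If the sample
    has fewer forward reads than requested, all are returned with a warning.
    """
    forward = readset.forward_reads()
    if not forward:
        raise ValueError(f"sample {readset.sample_id}: no forward reads")
    if len(forward) <= config.n_subsample:
        if len(forward) < config.n_subsample:
            logger.warning(
                "sample %s: only %d forward reads (< %d requested); using all",
                readset.sample_id,
                len(forward),
                config.n_subsample,
            )
        return ReadSet(sample_id=readset.sample_id, reads=list(forward))
    rng = np.random.default_rng(config.seed)
    idx = np.sort(rng.choice(len(forward), size=config.n_subsample, replace=False))
    return ReadSet(
        sample_id=readset.sample_id, reads=[forward[i] for i in idx]
    )


@dataclass
class MappingResult:
    """Per-sample outcome of assigning reads to catalogue genes."""

    sample_id: str
    counts: dict[str, int]
    n_total: int
    n_assigned: int
    n_ambiguous: int
    n_unmapped: int

    def __post_init__(self) -> None:
        assert self.n_assigned + self.n_ambiguous + self.n_unmapped == self.n_total

    @property
    def mapped_fraction(self) -> float:
        """Fraction of reads counted to a unique gene."""
        return self.n_assigned / self.n_total if self.n_total else 0.0

    @property
    def mapped_fraction_incl_ambiguous(self) -> float:
        """Fraction of reads with an accepted alignment, ambiguous included
        (a mapper would report these as mapped even though feature counting
        discards them)."""
        return (
            (self.n_assigned + self.n_ambiguous) / self.n_total if self.n_total else 0.0
        )


class _GeneIndex:
    """Exact k-mer index over catalogue genes used to shortlist candidates.

    For every candidate (gene, read strand) it also returns the diagonal
    range of the seed hits, so the alignment can be restricted to the gene
    window the read could plausibly align in.
    """

    def __init__(self, genes: Mapping[str, str], k: int) -> None:
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for gid, seq in genes.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((gid, i))

    def candidates(
        self, read_seq: str, rc_seq: str
    ) -> dict[tuple[str, int], tuple[int, int]]:
        """(gene_id, strand) -> (min_diagonal, max_diagonal) seed offsets."""
        k = self.k
        out: dict[tuple[str, int], tuple[int, int]] = {}
        for strand, seq in enumerate((read_seq, rc_seq)):
            for i in range(len(seq) - k + 1):
                for gid, gpos in self.index.get(seq[i : i + k], ()):
                    diag = gpos - i
                    key = (gid, strand)
                    if key in out:
                        lo, hi = out[key]
                        out[key] = (min(lo, diag), max(hi, diag))
                    else:
                        out[key] = (diag, diag)
        return out


def _make_aligner(config: MappingConfig) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=config.match_score,
        mismatch_score=config.mismatch_score,
        open_gap_score=config.gap_open,
        extend_gap_score=config.gap_extend,
    )


def _read_alignment_stats(aligner, read_seq: str, gene_seq: str) -> tuple[float, float]:
    """(read_coverage, identity) of the best local alignment."""
    aln = aligner.align(gene_seq, read_seq)[0]
    identities, n_columns, _, read_span = alignment_stats(aln, gene_seq, read_seq)
    identity = identities / n_columns if n_columns else 0.0
    return (read_span[1] - read_span[0]) / len(read_seq), identity


def assign_and_count(
    reads: ReadSet | Sequence[Read],
    catalogue: Catalogue,
    config: MappingConfig = MappingConfig(),
) -> MappingResult:
    """Assign each read to its best-scoring gene and count.

    Strand-insensitive; no score cutoff other than the coverage/identity
    acceptance rule; exact best-score ties across distinct genes are counted
    as ambiguous.  ``config.exhaustive`` aligns every read against every gene
    (reference behaviour); the default shortlists genes through an exact
    k-mer index, which can only miss alignments of reads with a mismatch in
    every index-length window.
    """
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)
    sample_id = reads.sample_id if isinstance(reads, ReadSet) else "reads"
    genes = {
        r.gene_id: r.nt_seq for r in catalogue.representatives if r.nt_seq is not None
    }
    if not genes:
        raise ValueError(f"catalogue {catalogue.name} has no nucleotide sequences")

    aligner = _make_aligner(config)
    index = None if config.exhaustive else _GeneIndex(genes, config.seed_kmer)

    margin = 25  # gene window slack beyond the seed diagonals
    counts: dict[str, int] = {}
    n_assigned = n_ambiguous = n_unmapped = 0
    for read in read_list:
        rc = reverse_complement(read.sequence)
        read_len = len(read.sequence)
        if index is None:
            cand = {
                (gid, strand): None
                for gid in sorted(genes)
                for strand in (0, 1)
            }
        else:
            cand = index.candidates(read.sequence, rc)
        best_score = 0.0
        best_ids: list[str] = []
        best_aln: tuple[str, str] | None = None  # (strand seq, gene window)
        for (gid, strand) in sorted(cand):
            gene_seq = genes[gid]
            diag = cand[(gid, strand)]
            if diag is not None:
                lo = max(0, diag[0] - margin)
                hi = min(len(gene_seq), diag[1] + read_len + margin)
                gene_seq = gene_seq[lo:hi]
            strand_seq = read.sequence if strand == 0 else rc
            score = aligner.score(gene_seq, strand_seq)
            if score > best_score:
                best_score, best_ids = score, [gid]
                best_aln = (strand_seq, gene_seq)
            elif score == best_score and best_score > 0 and gid not in best_ids:
                best_ids.append(gid)
        accepted = False
        if best_aln is not None:
            cov, ident = _read_alignment_stats(aligner, best_aln[0], best_aln[1])
            accepted = cov >= config.min_read_cov and ident >= config.min_read_identity
        if not accepted:
            n_unmapped += 1
        elif len(best_ids) > 1:
            n_ambiguous += 1
        else:
            n_assigned += 1
            counts[best_ids[0]] = counts.get(best_ids[0], 0) + 1
    return MappingResult(
        sample_id=sample_id,
        counts=counts,
        n_total=len(read_list),
        n_assigned=n_assigned,
        n_ambiguous=n_ambiguous,
        n_unmapped=n_unmapped,
    )


@dataclass(frozen=True)
class CoverageEstimate:
    """Estimated read-depth coverage of one gene in the total metagenome."""

    gene_id: str
    raw_count: int
    gene_length: int
    estimate: float
    bin: str


def bin_coverage(estimate: float) -> str:
    """Coverage bin of an estimate; intervals are half-open on the left edge."""
    if estimate < 0:
        raise ValueError(f"negative coverage estimate: {estimate}")
    if estimate > COVERAGE_BIN_EDGES[-1]:
        warnings.warn(
            f"coverage estimate {estimate:.1f} above top bin edge "
            f"{COVERAGE_BIN_EDGES[-1]:.0f}; labelled very_high"
        )
        return "very_high"
    for lo, hi, label in zip(
        COVERAGE_BIN_EDGES[:-1], COVERAGE_BIN_EDGES[1:], COVERAGE_BIN_LABELS
    ):
        if lo <= estimate < hi:
            return label
    return "very_high"  # exactly the top edge


def estimate_coverage(
    counts: Mapping[str, int],
    gene_lengths: Mapping[str, int],
    avg_read_pair_len: float,
    total_read_pairs: int,
    n_sampled: int,
) -> dict[str, CoverageEstimate]:
    """Scale sampled per-gene counts up to total-metagenome read depth.

    ``estimate = count * avg_read_pair_len / gene_length * total_read_pairs / n_sampled``
    """
    if n_sampled <= 0:
        raise ValueError("n_sampled must be > 0")
    out: dict[str, CoverageEstimate] = {}
    for gene_id, length in gene_lengths.items():
        if length <= 0:
            raise ValueError(f"gene {gene_id}: non-positive length {length}")
        c = counts.get(gene_id, 0)
        est = c * (avg_read_pair_len / length) * (total_read_pairs / n_sampled)
        out[gene_id] = CoverageEstimate(
            gene_id=gene_id,
            raw_count=c,
            gene_length=length,
            estimate=est,
            bin=bin_coverage(est),
        )
    return out


def mapping_rate_curves(
    result: MappingResult, catalogue: Catalogue, by: str = "completeness"
) -> pd.DataFrame:
    """Cumulative mapped fraction as a function of the minimum gene length.

    At cutoff L the value is the fraction of all reads counted to genes of
    length >= L; monotone non-increasing in L, equal to the overall mapped
    fraction at cutoff 0.  Stratified by completeness class or provenance.
    """
    recs = {r.gene_id: r for r in catalogue.representatives}
    rows = []
    for gene_id, count in result.counts.items():
        rec = recs[gene_id]
        group = (
            rec.completeness.value
            if by == "completeness"
            else catalogue.provenance.get(gene_id, "unknown")
        )
        rows.append((rec.nt_length, group, count))
    total = result.n_total
    lengths = sorted({r.nt_length for r in catalogue.representatives})
    cutoffs = [0] + lengths + [max(lengths) + 1] if lengths else [0]
    df = pd.DataFrame(rows, columns=["length", "group", "count"])
    out: dict[str, list] = {"length_cutoff": cutoffs}
    groups = ["all"] + sorted(df["group"].unique()) if len(df) else ["all"]
    for group in groups:
        sub = df if group == "all" else df[df["group"] == group]
        out[group] = [
            (sub.loc[sub["length"] >= c, "count"].sum() / total if total else 0.0)
            for c in cutoffs
        ]
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PairedRateTest:
    statistic: float
    p_value: float
    n: int
    degenerate: bool


def paired_rate_test(
    rates_a: Sequence[float], rates_b: Sequence[float]
) -> PairedRateTest:
    """Two-sided Wilcoxon signed-rank test on paired per-sample rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedRateTest(statistic=0.0, p_value=1.0, n=len(a), degenerate=True)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return PairedRateTest(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(a),
        degenerate=False,
    )
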