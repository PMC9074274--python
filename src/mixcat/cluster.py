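"""Greedy length-sorted protein clustering and the two-stage cascade.

Redundancy removal works on protein sequences.  Sequences are sorted by
length (ties broken by lexicographically smallest id, for bit-reproducible
runs); the longest unassigned sequence seeds a cluster, and every unassigned
sequence that aligns to it at >= ``min_seq_id`` identity with >=
``min_member_cov`` of the member covered joins the cluster.  Seeding clusters
with the longest sequences means that when a fragment and a full-length
version of a gene meet, the full-length protein represents the cluster —
this is the mechanism by which merging individual-assembly and co-assembly
gene sets enriches for complete genes.

The cascade runs the greedy pass twice: first over all individual-assembly
proteins (collapsing cross-sample redundancy), then over the stage-1
representatives pooled with the co-assembly proteins.  Each final
representative records whether it came from an individual assembly or from
the co-assembly.

``brute_force_cluster`` executes the same greedy rule with exhaustive
all-vs-all alignment and no shortcuts; it exists as a desk-scale oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import AlignmentResult, align_pair



@dataclass(frozen=True)
class ClusterParams:
    """Thresholds and scoring for the clustering criterion.

    Defaults implement clustering at >= 95% amino-acid identity with >= 95%
    of the member sequence covered by the alignment — the species-level
    grain, since conspecific prokaryotic strains generally exceed 95%
    average amino-acid identity.
    """

    min_seq_id: float = 0.95
    min_member_cov: float = 0.95
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    prefilter: bool = True
    prefilter_k: int = 6
    prefilter_min_len: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.min_seq_id <= 1:
            raise ValueError("min_seq_id must be in (0, 1]")
        if not 0 < self.min_member_cov <= 1:
            raise ValueError("min_member_cov must be in (0, 1]")

    def align(self, rep_seq: str, member_seq: str) -> AlignmentResult:
        return align_pair(
            rep_seq,
            member_seq,
            matrix=self.matrix,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )


@dataclass
class Cluster:
    """A representative protein and the members it absorbed."""

    representative_id: str
    member_ids: list[str]  # includes the representative
    alignments: dict[str, AlignmentResult] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _sorted_ids(proteins: Mapping[str, str]) -> list[str]:
    # longest first; equal lengths broken by smallest id
    return sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))


def _seq_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _check_unique_ids(proteins: Mapping[str, str]) -> None:
    # mappings are unique by construction; guard sequences of pairs upstream
    for pid, seq in proteins.items():
        if not seq:
            raise ValueError(f"protein {pid}: empty sequence")


def as_protein_mapping(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]]
) -> dict[str, str]:
    if isinstance(proteins, Mapping):
        return dict(proteins)
    out: dict[str, str] = {}
    for pid, seq in proteins:
        if pid in out:
            raise ValueError(f"duplicate protein id: {pid}")
        out[pid] = seq
    return out


def greedy_cluster(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """Greedy length-sorted clustering; returns clusters in seeding order.

    The optional k-mer prefilter (on by default) skips candidate pairs that
    share no exact amino-acid k-mer.  A member passing both thresholds must
    contain an exact run of >= ``prefilter_k`` matching residues whenever its
    length is at least ``prefilter_min_len`` (pigeonhole: at most ~5% of
    aligned columns are non-identical and at most 5% of the member is
    unaligned), so the prefilter can only skip pairs the full alignment would
    reject; shorter members are always aligned.
    """
    prot = as_protein_mapping(proteins)
    _check_unique_ids(prot)
    order = _sorted_ids(prot)
    unassigned = dict.fromkeys(order)  # insertion-ordered set
    kmer_cache: dict[str, set[str]] = {}

    def kmers(pid: str) -> set[str]:
        if pid not in kmer_cache:
            kmer_cache[pid] = _seq_kmers(prot[pid], params.prefilter_k)
        return kmer_cache[pid]

    clusters: list[Cluster] = []
    while unassigned:
        rep_id = next(iter(unassigned))
        del unassigned[rep_id]
        rep_seq = prot[rep_id]
        cluster = Cluster(representative_id=rep_id, member_ids=[rep_id])
        rep_kmers = kmers(rep_id) if params.prefilter else None
        for cand_id in list(unassigned):
            cand_seq = prot[cand_id]
            if (
                rep_kmers is not None
                and len(cand_seq) >= max(params.prefilter_min_len, params.prefilter_k)
                and rep_kmers.isdisjoint(kmers(cand_id))
            ):
                continue
            result = params.align(rep_seq, cand_seq)
            if result.passes(params.min_seq_id, params.min_member_cov):
                cluster.member_ids.append(cand_id)
                cluster.alignments[cand_id] = result
                del unassigned[cand_id]
        clusters.append(cluster)
    return clusters


def brute_force_cluster(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """The greedy rule executed naively: all-vs-all alignment, no prefilter.

    Desk-scale reference implementation (n up to a few hundred) against which
    the production path is checked.
    """
    prot = as_protein_mapping(proteins)
    _check_unique_ids(prot)
    remaining = _sorted_ids(prot)
    clusters: list[Cluster] = []
    while remaining:
        rep_id, rest = remaining[0], remaining[1:]
        cluster = Cluster(representative_id=rep_id, member_ids=[rep_id])
        keep: list[str] = []
        for cand_id in rest:
            result = align_pair(
                prot[rep_id],
                prot[cand_id],
                matrix=params.matrix,
                gap_open=params.gap_open,
                gap_extend=params.gap_extend,
            )
            if result.passes(params.min_seq_id, params.min_member_cov):
                cluster.member_ids.append(cand_id)
                cluster.alignments[cand_id] = result
            else:
                keep.append(cand_id)
        clusters.append(cluster)
        remaining = keep
    return clusters


@dataclass
class CascadeResult:
    """Outcome of the two-stage mix-assembly clustering."""

    stage1: list[Cluster]
    stage2: list[Cluster]
    # final representative id -> "from_individual" | "from_coassembly"
    provenance: dict[str, str]
    # final representative id -> every original protein id it stands for
    # (stage-2 members expanded through their stage-1 clusters)
    final_members: dict[str, list[str]]

    @property
    def representative_ids(self) -> list[str]:
        return [c.representative_id for c in self.stage2]


def cascade_cluster(
    individual_proteins_by_sample: Mapping[str, Mapping[str, str]],
    coassembly_proteins: Mapping[str, str],
    params: ClusterParams = ClusterParams(),
) -> CascadeResult:
    """Two-stage cascaded clustering of individual- and co-assembly proteins.

    Stage 1 clusters the pooled individual-assembly proteins; stage 2
    clusters the stage-1 representatives together with the co-assembly
    proteins.  ID spaces must be disjoint across sources.
    """
    pooled_individual: dict[str, str] = {}
    for sample_id, prots in individual_proteins_by_sample.items():
        for pid, seq in prots.items():
            if pid in pooled_individual:
                raise ValueError(
                    f"protein id {pid} occurs in more than one sample ({sample_id})"
                )
            pooled_individual[pid] = seq
    collisions = set(pooled_individual) & set(coassembly_proteins)
    if collisions:
        raise ValueError(
            f"protein ids shared between individual and co-assembly sets: "
            f"{sorted(collisions)[:5]}"
        )

    stage1 = greedy_cluster(pooled_individual, params)
    stage1_by_rep = {c.representative_id: c for c in stage1}

    stage2_input = {
        c.representative_id: pooled_individual[c.representative_id] for c in stage1
    }
    stage2_input.update(coassembly_proteins)
    stage2 = greedy_cluster(stage2_input, params)

    provenance: dict[str, str] = {}
    final_members: dict[str, list[str]] = {}
    for cluster in stage2:
        rep = cluster.representative_id
        provenance[rep] = (
            "from_coassembly" if rep in coassembly_proteins else "from_individual"
        )
        members: list[str] = []
        for mid in cluster.member_ids:
            if mid in stage1_by_rep:
                members.extend(stage1_by_rep[mid].member_ids)
            else:
                members.append(mid)
        final_members[rep] = members
    return CascadeResult(
        stage1=stage1, stage2=stage2, provenance=provenance, final_members=final_members
    )
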