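"""Gene catalogues: assembly, summaries, rRNA removal, cross-catalogue comparison.

A catalogue is a nonredundant set of representative genes with provenance
(which assembly strategy each representative came from), optional functional
annotations, and the cluster membership that produced it.  Summaries mirror
the standard reporting for assembly-strategy comparisons: total bp, gene
counts overall and >= 100 bp, counts per completeness class, and annotated
gene counts per database stratified by completeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster import ClusterParams, _seq_kmers
from .records import ANNOTATION_DATABASES, AnnotationTable, Completeness, GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class Catalogue:
    """A nonredundant gene set with provenance and annotations."""

    name: str
    representatives: list[GeneRecord]
    # representative id -> "from_individual" | "from_coassembly"
    provenance: dict[str, str] = field(default_factory=dict)
    # representative id -> all original member gene ids
    membership: dict[str, list[str]] = field(default_factory=dict)
    annotations: AnnotationTable = field(default_factory=AnnotationTable)
    removed_rrna_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.representatives]
        if len(ids) != len(set(ids)):
            raise ValueError(f"catalogue {self.name}: duplicate representative ids")
        overlap = set(ids) & self.removed_rrna_ids
        if overlap:
            raise ValueError(
                f"catalogue {self.name}: removed rRNA ids still present: "
                f"{sorted(overlap)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.representatives)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.representatives]

    def get(self, gene_id: str) -> GeneRecord:
        return self._by_id()[gene_id]

    def _by_id(self) -> dict[str, GeneRecord]:
        if not hasattr(self, "_index") or len(self._index) != len(self.representatives):
            self._index = {r.gene_id: r for r in self.representatives}
        return self._index

    def proteins(self) -> dict[str, str]:
        return {
            r.gene_id: r.aa_seq for r in self.representatives if r.aa_seq is not None
        }


@dataclass
class CatalogueSummary:
    """Headline statistics of a catalogue (assembly-approach comparison rows)."""

    name: str
    total_bp: int
    n_genes: int
    n_genes_ge_100bp: int
    n_complete: int
    n_partial: int
    n_incomplete: int
    median_gene_length: float

    def __post_init__(self) -> None:
        assert self.n_complete + self.n_partial + self.n_incomplete == self.n_genes
        assert self.n_genes_ge_100bp <= self.n_genes

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(catalogue: Catalogue) -> CatalogueSummary:
    """Exact integer summary counts; invariant to gene order."""
    lengths = []
    n_by_class = {c: 0 for c in Completeness}
    for rec in catalogue.representatives:
        if rec.nt_seq is None and (rec.start is None or rec.end is None):
            raise ValueError(f"gene {rec.gene_id}: no nucleotide length for summary")
        lengths.append(rec.nt_length)
        n_by_class[rec.completeness] += 1
    return CatalogueSummary(
        name=catalogue.name,
        total_bp=int(sum(lengths)),
        n_genes=len(lengths),
        n_genes_ge_100bp=sum(1 for l in lengths if l >= 100),
        n_complete=n_by_class[Completeness.COMPLETE],
        n_partial=n_by_class[Completeness.PARTIAL],
        n_incomplete=n_by_class[Completeness.INCOMPLETE],
        median_gene_length=float(np.median(lengths)) if lengths else 0.0,
    )


def annotation_summary(catalogue: Catalogue) -> pd.DataFrame:
    """Annotated-gene counts per completeness class x database.

    A gene counts once per database no matter how many accessions it carries
    (gene counts, not hit counts).  Rows: complete/partial/incomplete plus a
    total row; columns: the annotation databases.
    """
    classes = [c.value for c in Completeness]
    table = pd.DataFrame(0, index=classes + ["total"], columns=list(ANNOTATION_DATABASES))
    for rec in catalogue.representatives:
        for db in catalogue.annotations.databases_for(rec.gene_id):
            table.loc[rec.completeness.value, db] += 1
            table.loc["total", db] += 1
    return table


def attach_annotations(catalogue: Catalogue, annotations: AnnotationTable) -> None:
    """Attach an annotation table; rows for genes outside the catalogue stay
    in the table (so it can serve several catalogues) but are logged."""
    present = set(catalogue.gene_ids())
    missing = annotations.gene_ids() - present
    if missing:
        logger.info(
            "catalogue %s: %d annotated gene ids not in catalogue (kept in table)",
            catalogue.name,
            len(missing),
        )
    catalogue.annotations = annotations


def remove_rrna(
    catalogue: Catalogue, barrnap_ids: set[str], rfam_rrna_ids: set[str]
) -> Catalogue:
    """Drop the union of rRNA screen hits from the catalogue (idempotent).

    Genes flagged by either screen are falsely predicted as protein-coding
    and are removed; other structural-RNA flags are annotation-only and do
    not remove genes.  IDs absent from the catalogue are ignored with a log
    line.
    """
    to_remove = barrnap_ids | rfam_rrna_ids
    present = set(catalogue.gene_ids())
    ignored = to_remove - present
    if ignored:
        logger.info(
            "remove_rrna: %d screen ids not in catalogue %s (ignored)",
            len(ignored),
            catalogue.name,
        )
    removed = to_remove & present
    return Catalogue(
        name=catalogue.name,
        representatives=[
            r for r in catalogue.representatives if r.gene_id not in removed
        ],
        provenance={
            k: v for k, v in catalogue.provenance.items() if k not in removed
        },
        membership={
            k: v for k, v in catalogue.membership.items() if k not in removed
        },
        annotations=catalogue.annotations,
        removed_rrna_ids=catalogue.removed_rrna_ids | removed,
    )


def _has_match(
    query: str,
    targets: Mapping[str, str],
    target_kmers: Mapping[str, set[str]],
    params: ClusterParams,
    threshold: float,
    min_cov: float | None,
) -> bool:
    # the prefilter's skip guarantee derives from the coverage+identity
    # criterion; with an identity-only rule (min_cov=None) it must stay off
    use_prefilter = params.prefilter and min_cov is not None
    qk = _seq_kmers(query, params.prefilter_k) if use_prefilter else None
    for tid, tseq in targets.items():
        if (
            qk is not None
            and len(query) >= max(params.prefilter_min_len, params.prefilter_k)
            and qk.isdisjoint(target_kmers[tid])
        ):
            continue
        # member-coverage convention: the tested (query) protein must be
        # covered, with the longer sequence acting as representative
        if len(tseq) >= len(query):
            res = params.align(tseq, query)
            cov = res.member_coverage
        else:
            res = params.align(query, tseq)
            span = res.rep_range
            cov = (span[1] - span[0]) / len(query)
        if res.identity > threshold and (min_cov is None or cov >= min_cov):
            return True
    return False


def compare_catalogues(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    threshold: float = 0.95,
    min_cov: float | None = 0.95,
    params: ClusterParams = ClusterParams(),
) -> tuple[int, int]:
    """Count proteins in each set with a > *threshold*-identity partner in the
    other (the cross-catalogue novelty comparison).

    Coverage defaults to the clustering member-coverage rule applied to the
    tested protein; pass ``min_cov=None`` for an identity-only criterion.
    """
    a_kmers = {
        pid: _seq_kmers(s, params.prefilter_k) for pid, s in proteins_a.items()
    }
    b_kmers = {
        pid: _seq_kmers(s, params.prefilter_k) for pid, s in proteins_b.items()
    }
    n_a = sum(
        _has_match(seq, proteins_b, b_kmers, params, threshold, min_cov)
        for seq in proteins_a.values()
    )
    n_b = sum(
        _has_match(seq, proteins_a, a_kmers, params, threshold, min_cov)
        for seq in proteins_b.values()
    )
    return int(n_a), int(n_b)


def length_cumulative(
    catalogue: Catalogue, by: str = "completeness"
) -> pd.DataFrame:
    """Cumulative gene counts above each observed length (length-distribution
    comparison curves).  ``by`` is ``"completeness"`` or ``"provenance"``."""
    rows = []
    for rec in catalogue.representatives:
        group = (
            rec.completeness.value
            if by == "completeness"
            else catalogue.provenance.get(rec.gene_id, "unknown")
        )
        rows.append((rec.nt_length, group))
    df = pd.DataFrame(rows, columns=["length", "group"])
    cutoffs = np.sort(df["length"].unique())
    out = {"length_cutoff": cutoffs}
    for group in ["all"] + sorted(df["group"].unique()):
        sub = df if group == "all" else df[df["group"] == group]
        out[group] = [(sub["length"] >= c).sum() for c in cutoffs]
    return pd.DataFrame(out)
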