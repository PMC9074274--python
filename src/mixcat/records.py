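"""Domain records: predicted genes, reads, and functional annotations.

A metagenomic gene catalogue is built from genes predicted on assembled
contigs.  Each predicted gene carries a two-character *partial code* in the
Prodigal convention: the first character says whether the gene's 5' edge is
truncated by a contig boundary, the second whether the 3' edge is.  The code
determines the gene's *completeness class*:

``00``
    complete — predicted start codon and stop codon both present.
``01`` / ``10``
    partial — one of start/stop is missing (gene runs off a contig edge).
``11``
    incomplete — neither start nor stop codon predicted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

VALID_PARTIAL_CODES = ("00", "01", "10", "11")

ANNOTATION_DATABASES = ("Pfam", "EggNOG", "dbCAN")


class Completeness(str, enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    INCOMPLETE = "incomplete"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Source(str, enum.Enum):
    """Which assembly strategy a gene record stems from."""

    INDIVIDUAL = "individual"
    COASSEMBLY = "coassembly"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_completeness(partial_code: str) -> Completeness:
    """Map a Prodigal partial code to a completeness class.

    ``"00" -> complete``, ``"01"/"10" -> partial``, ``"11" -> incomplete``.

    Raises
    ------
    ValueError
        If *partial_code* is not one of the four valid codes.
    """
    if partial_code == "00":
        return Completeness.COMPLETE
    if partial_code in ("01", "10"):
        return Completeness.PARTIAL
    if partial_code == "11":
        return Completeness.INCOMPLETE
    raise ValueError(
        f"invalid partial code {partial_code!r}; expected one of {VALID_PARTIAL_CODES}"
    )


@dataclass
class GeneRecord:
    """One predicted gene.

    Coordinates are 1-based inclusive (GFF3/Prodigal convention).  For
    minus-strand genes the stored nucleotide sequence is the already-oriented
    coding sequence.  ``nt_seq``/``aa_seq`` may individually be ``None`` when
    only one representation is available (e.g. protein-only clustering input).
    """

    gene_id: str
    nt_seq: str | None = None
    aa_seq: str | None = None
    source: Source = Source.COASSEMBLY
    sample_id: str | None = None
    contig_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"
    partial_code: str = "00"

    def __post_init__(self) -> None:
        if self.partial_code not in VALID_PARTIAL_CODES:
            raise ValueError(
                f"gene {self.gene_id}: invalid partial code {self.partial_code!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.start is not None and self.end is not None:
            if self.end < self.start:
                raise ValueError(
                    f"gene {self.gene_id}: end {self.end} < start {self.start}"
                )
            if self.nt_seq is not None and len(self.nt_seq) != self.end - self.start + 1:
                raise ValueError(
                    f"gene {self.gene_id}: nt length {len(self.nt_seq)} does not "
                    f"match coordinates [{self.start}, {self.end}]"
                )
        if self.source is Source.INDIVIDUAL and self.sample_id is None:
            raise ValueError(f"gene {self.gene_id}: individual source needs sample_id")

    @property
    def completeness(self) -> Completeness:
        return classify_completeness(self.partial_code)

    @property
    def nt_length(self) -> int:
        if self.nt_seq is not None:
            return len(self.nt_seq)
        if self.start is not None and self.end is not None:
            return self.end - self.start + 1
        raise ValueError(f"gene {self.gene_id}: no nucleotide length available")


@dataclass
class Read:
    read_id: str
    sequence: str
    mate: int = 1


@dataclass
class ReadSet:
    """Shotgun reads from one sample."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for r in self.reads:
            key = (r.read_id, r.mate)
            if key in seen:
                raise ValueError(
                    f"sample {self.sample_id}: duplicate read id {r.read_id} mate {r.mate}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.reads)

    def forward_reads(self) -> list[Read]:
        return [r for r in self.reads if r.mate == 1]

    def mean_read_length(self) -> float:
        if not self.reads:
            raise ValueError(f"sample {self.sample_id}: empty read set")
        return sum(len(r.sequence) for r in self.reads) / len(self.reads)

    def mean_read_pair_length(self) -> float:
        """Mean forward length + mean reverse length.

        For single-end data this is 2 x the mean read length, so coverage
        arithmetic stays on the read-pair scale throughout.
        """
        fwd = [len(r.sequence) for r in self.reads if r.mate == 1]
        rev = [len(r.sequence) for r in self.reads if r.mate == 2]
        if not fwd:
            raise ValueError(f"sample {self.sample_id}: no forward reads")
        mean_fwd = sum(fwd) / len(fwd)
        mean_rev = sum(rev) / len(rev) if rev else mean_fwd
        return mean_fwd + mean_rev


class AnnotationTable:
    """gene_id -> set of (database, accession) functional assignments."""

    def __init__(
        self, entries: Mapping[str, Iterable[tuple[str, str]]] | None = None
    ) -> None:
        self._table: dict[str, set[tuple[str, str]]] = {}
        if entries:
            for gene_id, pairs in entries.items():
                for db, acc in pairs:
                    self.add(gene_id, db, acc)

    def add(self, gene_id: str, database: str, accession: str) -> None:
        if not gene_id:
            raise ValueError("empty gene_id in annotation table")
        if database not in ANNOTATION_DATABASES:
            raise ValueError(
                f"unknown annotation database {database!r}; "
                f"expected one of {ANNOTATION_DATABASES}"
            )
        self._table.setdefault(gene_id, set()).add((database, accession))

    def databases_for(self, gene_id: str) -> set[str]:
        return {db for db, _ in self._table.get(gene_id, ())}

    def get(self, gene_id: str) -> set[tuple[str, str]]:
        return set(self._table.get(gene_id, ()))

    def gene_ids(self) -> set[str]:
        return set(self._table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._table

    def __len__(self) -> int:
        return len(self._table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._table == other._table

    def items(self):
        return self._table.items()
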