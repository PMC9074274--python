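"""Reading and writing the pipeline's file formats.

FASTA/FASTQ go through Bio.SeqIO.  GFF3 records are the minimal gene-coordinate
subset (one ``CDS`` feature per gene, keyed by the ``ID`` attribute, optionally
carrying a ``partial`` attribute).  Annotation assignments are three-column TSV
(``gene_id  database  accession``); rRNA screen hits are plain-text ID lists.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    VALID_PARTIAL_CODES,
    AnnotationTable,
    GeneRecord,
    Read,
    ReadSet,
    Source,
)

logger = logging.getLogger(__name__)

_PARTIAL_RE = re.compile(r"partial=([01]{2})")
# Prodigal description: "<id> # <start> # <end> # <strand> # ID=...;partial=XY;..."
_PRODIGAL_COORD_RE = re.compile(r"#\s*(\d+)\s*#\s*(\d+)\s*#\s*(-?1)\s*#")

_NT_CHARS = frozenset("ACGTN")


def _looks_like_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq) <= _NT_CHARS


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff(gff_path: str | Path) -> dict[str, dict]:
    """Parse a minimal GFF3 file into ``ID -> feature dict``."""
    features: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF line (expected 9 columns): {line!r}")
            contig, _source, _ftype, start, end, _score, strand, _frame, attrs = fields
            attributes = _parse_gff_attributes(attrs)
            if "ID" not in attributes:
                raise ValueError(f"GFF feature without ID attribute: {line!r}")
            gene_id = attributes["ID"]
            if gene_id in features:
                raise ValueError(f"duplicate gene id in GFF: {gene_id}")
            features[gene_id] = {
                "contig_id": contig,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "partial": attributes.get("partial"),
            }
    return features


def read_genes(
    fasta_path: str | Path,
    gff_path: str | Path | None = None,
    *,
    source: Source = Source.COASSEMBLY,
    sample_id: str | None = None,
    default_partial: str | None = None,
) -> list[GeneRecord]:
    """Read predicted genes from FASTA (nt or aa), optionally joined with GFF3.

    The partial code is taken from a ``partial=XY`` token anywhere in the FASTA
    description line; a GFF ``partial`` attribute takes precedence, but a
    conflict between the two is an error (fail loud rather than guess).  A gene
    with no code anywhere gets *default_partial* if supplied, else raises.

    Sequences are upper-cased; ``*`` stop characters are stripped from protein
    termini.  Whether a sequence is nucleotide or protein is auto-detected from
    its alphabet (A/C/G/T/N only => nucleotide).
    """
    gff = read_gff(gff_path) if gff_path is not None else {}
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id in FASTA: {gene_id}")
        seen.add(gene_id)

        seq = str(entry.seq).upper()
        header_partial = None
        m = _PARTIAL_RE.search(entry.description)
        if m:
            header_partial = m.group(1)

        feature = gff.get(gene_id)
        gff_partial = feature["partial"] if feature else None
        if header_partial and gff_partial and header_partial != gff_partial:
            raise ValueError(
                f"gene {gene_id}: partial code conflict between FASTA header "
                f"({header_partial}) and GFF ({gff_partial})"
            )
        partial = gff_partial or header_partial or default_partial
        if partial is None:
            raise ValueError(
                f"gene {gene_id}: no partial= code in header or GFF and no default given"
            )
        if partial not in VALID_PARTIAL_CODES:
            raise ValueError(f"gene {gene_id}: invalid partial code {partial!r}")

        contig_id = feature["contig_id"] if feature else None
        start = feature["start"] if feature else None
        end = feature["end"] if feature else None
        strand = feature["strand"] if feature else "+"
        if feature is None:
            cm = _PRODIGAL_COORD_RE.search(entry.description)
            if cm:
                start, end = int(cm.group(1)), int(cm.group(2))
                strand = "+" if cm.group(3) == "1" else "-"

        is_nt = _looks_like_nucleotide(seq)
        if not is_nt:
            seq = seq.strip("*")
        kwargs = dict(
            gene_id=gene_id,
            source=source,
            sample_id=sample_id,
            contig_id=contig_id,
            strand=strand,
            partial_code=partial,
        )
        if is_nt:
            records.append(GeneRecord(nt_seq=seq, start=start, end=end, **kwargs))
        else:
            # protein input: coordinates still describe the gene on its contig
            records.append(GeneRecord(aa_seq=seq, start=start, end=end, **kwargs))
    return records


def write_genes_fasta(
    records: Iterable[GeneRecord], path: str | Path, *, kind: str = "nt"
) -> None:
    """Write gene records to FASTA, embedding the partial code in the header."""
    out = []
    for rec in records:
        seq = rec.nt_seq if kind == "nt" else rec.aa_seq
        if seq is None:
            raise ValueError(f"gene {rec.gene_id}: no {kind} sequence to write")
        desc = f"partial={rec.partial_code}"
        if rec.start is not None and rec.end is not None:
            strand = "1" if rec.strand == "+" else "-1"
            desc = f"# {rec.start} # {rec.end} # {strand} # partial={rec.partial_code}"
        out.append(SeqRecord(Seq(seq), id=rec.gene_id, description=desc))
    SeqIO.write(out, str(path), "fasta")


def write_gff(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            if rec.start is None or rec.end is None:
                continue
            attrs = f"ID={rec.gene_id};partial={rec.partial_code}"
            fh.write(
                "\t".join(
                    [
                        rec.contig_id or rec.gene_id,
                        "mixcat",
                        "CDS",
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_annotation_table(tsv_path: str | Path) -> AnnotationTable:
    """Read a ``gene_id  database  accession`` TSV (header optional)."""
    table = AnnotationTable()
    with open(tsv_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and [c.lower() for c in row[:2]] == ["gene_id", "database"]:
                continue
            if len(row) < 3:
                raise ValueError(f"annotation TSV row has <3 columns: {row!r}")
            table.add(row[0], row[1], row[2])
    return table


def write_annotation_table(table: AnnotationTable, tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("gene_id\tdatabase\taccession\n")
        for gene_id in sorted(table.gene_ids()):
            for db, acc in sorted(table.get(gene_id)):
                fh.write(f"{gene_id}\t{db}\t{acc}\n")


def read_id_list(path: str | Path) -> set[str]:
    """Plain-text ID list (one per line), e.g. an rRNA screen hit list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(ids):
            fh.write(gene_id + "\n")


def read_reads(path: str | Path, sample_id: str) -> ReadSet:
    """Read FASTQ or FASTA reads; ``/1`` / ``/2`` id suffixes set the mate."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads = []
    for entry in SeqIO.parse(str(path), fmt):
        read_id, mate = entry.id, 1
        if read_id.endswith("/1") or read_id.endswith("/2"):
            mate = int(read_id[-1])
            read_id = read_id[:-2]
        reads.append(Read(read_id, str(entry.seq).upper(), mate))
    return ReadSet(sample_id=sample_id, reads=reads)


def write_reads(readset: ReadSet, path: str | Path) -> None:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    out = []
    for r in readset.reads:
        rec = SeqRecord(Seq(r.sequence), id=f"{r.read_id}/{r.mate}", description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        out.append(rec)
    SeqIO.write(out, str(path), fmt)


def write_catalogue(
    catalogue, fasta_path: str | Path, tsv_path: str | Path, *, kind: str = "auto"
) -> None:
    """Export a catalogue: representatives FASTA plus a membership TSV.

    The TSV carries one row per (representative, member) with provenance, so
    ``read_catalogue(write_catalogue(x)) == x`` up to annotation content.
    ``kind`` picks the FASTA sequence ("nt", "aa", or "auto" = nt if present).
    """
    if kind == "auto":
        kind = "nt" if catalogue.representatives and catalogue.representatives[0].nt_seq else "aa"
    write_genes_fasta(catalogue.representatives, fasta_path, kind=kind)
    with open(tsv_path, "w") as fh:
        fh.write("rep_id\tmember_id\tprovenance\n")
        for rec in catalogue.representatives:
            prov = catalogue.provenance.get(rec.gene_id, "")
            for mid in catalogue.membership.get(rec.gene_id, [rec.gene_id]):
                fh.write(f"{rec.gene_id}\t{mid}\t{prov}\n")


def read_catalogue(fasta_path: str | Path, tsv_path: str | Path, name: str = "catalogue"):
    """Load a catalogue previously exported with :func:`write_catalogue`."""
    from .catalogue import Catalogue

    records = read_genes(fasta_path)
    provenance: dict[str, str] = {}
    membership: dict[str, list[str]] = {}
    with open(tsv_path) as fh:
        header = fh.readline()
        if not header.startswith("rep_id"):
            raise ValueError(f"{tsv_path}: missing rep_id header")
        for line in fh:
            rep_id, member_id, prov = line.rstrip("\n").split("\t")
            membership.setdefault(rep_id, []).append(member_id)
            if prov:
                provenance[rep_id] = prov
    return Catalogue(
        name=name,
        representatives=records,
        provenance=provenance,
        membership=membership,
    )
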