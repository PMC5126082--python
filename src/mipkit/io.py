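"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing/writing is delegated to :mod:`Bio.SeqIO`; GFF3 gene models
are parsed directly for the three-feature subset (gene/mRNA/exon linked by
ID/Parent) the pipeline consumes. All TSV writers emit UTF-8 with a header
row.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneModel, MipkitError, ProteinRecord

__all__ = ["read_fasta", "write_fasta", "read_nucleotide_fasta", "read_gff3", "write_tsv"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header;
    the remainder is retained as the description. Sequences are uppercased.
    Raises on an empty file, a duplicate id, or an illegal residue.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise MipkitError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    if not records:
        raise MipkitError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome/promoter FASTA as a plain {id: uppercase sequence} map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise MipkitError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise MipkitError(f"no FASTA records in {path}")
    return out


def _attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models: exons grouped per mRNA, sorted genomically.

    Genes with no mRNA/exon features yield a single exon spanning the gene.
    An exon whose Parent is unknown, or any feature with end < start, is an
    error.
    """
    genes: dict[str, tuple[str, str, int, int]] = {}  # id -> (chrom, strand, start, end)
    gene_order: list[str] = []
    mrna_parent: dict[str, str] = {}
    mrna_order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols[:9]
            start, end = int(start_s), int(end_s)
            if end < start:
                raise MipkitError(f"GFF3 feature with end < start: {line.strip()!r}")
            attrs = _attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID", "")
                genes[gid] = (chrom, strand, start, end)
                gene_order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                mid = attrs.get("ID", "")
                mrna_parent[mid] = attrs.get("Parent", "")
                mrna_order.append(mid)
            elif ftype == "exon":
                parent = attrs.get("Parent", "")
                for pid in parent.split(","):
                    exons.setdefault(pid, []).append((start, end))

    # exon parents must be known mRNAs (or genes, for mRNA-less annotations)
    for pid in exons:
        if pid not in mrna_parent and pid not in genes:
            raise MipkitError(f"exon Parent {pid!r} matches no gene or mRNA")

    models: list[GeneModel] = []
    covered_genes: set[str] = set()
    for mid in mrna_order:
        gid = mrna_parent[mid]
        chrom, strand, gstart, gend = genes.get(gid, ("", "", 0, 0))
        ex = exons.get(mid) or [(gstart, gend)]
        models.append(GeneModel(gene_id=gid or mid, chromosome=chrom, strand=strand,
                                exons=ex, mRNA_id=mid))
        covered_genes.add(gid)
    for gid in gene_order:
        if gid in covered_genes:
            continue
        chrom, strand, gstart, gend = genes[gid]
        ex = exons.get(gid) or [(gstart, gend)]
        models.append(GeneModel(gene_id=gid, chromosome=chrom, strand=strand, exons=ex))
    return models


def write_tsv(path: str | Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def format_tsv(header: list[str], rows: list[list]) -> str:
    buf = _io.StringIO()
    buf.write("\t".join(header) + "\n")
    for row in rows:
        buf.write("\t".join(str(c) for c in row) + "\n")
    return buf.getvalue()
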