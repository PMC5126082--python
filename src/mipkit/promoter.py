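"""Promoter extraction and IUPAC-consensus cis-element scanning.

Promoters are the 1-kb window upstream of the annotated gene start (taken
as the transcription start site), read on the coding strand; scanning
reports every match of an IUPAC consensus on either strand, with
minus-strand hits expressed in promoter coordinates. Position 1 is the
most upstream base of the extracted window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import GeneModel, MipkitError

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = ("light", "hormone", "stress", "circadian", "other")


@dataclass
class MotifDefinition:
    name: str
    consensus: str
    category: str = "other"

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        for ch in self.consensus:
            if ch not in IUPAC:
                raise MipkitError(f"motif {self.name}: invalid IUPAC letter {ch!r}")
        if self.category not in CATEGORIES:
            raise MipkitError(f"motif {self.name}: unknown category {self.category!r}")


@dataclass
class MotifHit:
    gene_id: str
    motif: str
    start: int  # 1-based in promoter coordinates
    strand: str
    matched: str


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_upstream(genome: dict[str, str], model: GeneModel,
                     length: int = 1000) -> str:
    """Upstream promoter window for a gene, on the gene's strand.

    Plus strand: bases [start−length, start−1]; minus strand: reverse
    complement of [end+1, end+length]. Truncated at chromosome edges with
    a logged warning.
    """
    if model.chromosome not in genome:
        raise MipkitError(f"chromosome {model.chromosome!r} absent from genome")
    chrom = genome[model.chromosome]
    gstart, gend = model.exons[0][0], model.exons[-1][1]
    if model.strand == "-":
        lo, hi = gend + 1, min(gend + length, len(chrom))
        window = chrom[lo - 1 : hi]
        if len(window) < length:
            logger.warning("%s: promoter truncated to %d bp at chromosome end",
                           model.gene_id, len(window))
        return reverse_complement(window)
    lo = max(1, gstart - length)
    window = chrom[lo - 1 : gstart - 1]
    if len(window) < length:
        logger.warning("%s: promoter truncated to %d bp at chromosome start",
                       model.gene_id, len(window))
    return window


def _matches_at(seq: str, pos: int, consensus: str) -> bool:
    return all(seq[pos + k] in IUPAC[c] for k, c in enumerate(consensus))


def iupac_scan(promoter: str, motif: MotifDefinition, both_strands: bool = True,
               gene_id: str = "") -> list[MotifHit]:
    """All (overlapping) matches of the consensus in a promoter.

    Minus-strand hits are found on the reverse complement and reported at
    the promoter coordinate of their leftmost base. Hits are sorted by
    start, plus strand first on ties.
    """
    promoter = promoter.upper()
    if not promoter:
        raise MipkitError("empty promoter")
    m = len(motif.consensus)
    n = len(promoter)
    hits: list[MotifHit] = []
    for pos in range(n - m + 1):
        if _matches_at(promoter, pos, motif.consensus):
            hits.append(MotifHit(gene_id, motif.name, pos + 1, "+",
                                 promoter[pos : pos + m]))
    if both_strands:
        rc = reverse_complement(promoter)
        for pos in range(n - m + 1):
            if _matches_at(rc, pos, motif.consensus):
                start = n - (pos + m) + 1  # leftmost base in promoter coords
                hits.append(MotifHit(gene_id, motif.name, start, "-",
                                     promoter[start - 1 : start - 1 + m]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def presence_matrix(promoters: dict[str, str], motifs: list[MotifDefinition],
                    both_strands: bool = True):
    """Gene × motif hit-count table plus a per-category gene summary.

    Returns ``(counts, category_summary)``: counts is
    {gene: {motif: n_hits}} with all-zero columns retained;
    category_summary counts genes with ≥1 hit in each motif category.
    """
    if not promoters or not motifs:
        raise MipkitError("need ≥1 promoter and ≥1 motif")
    counts: dict[str, dict[str, int]] = {}
    for gene in sorted(promoters):
        counts[gene] = {
            m.name: len(iupac_scan(promoters[gene], m, both_strands, gene_id=gene))
            for m in motifs
        }
    by_cat = {c: 0 for c in CATEGORIES}
    for gene in counts:
        hit_cats = {m.category for m in motifs if counts[gene][m.name] > 0}
        for c in hit_cats:
            by_cat[c] += 1
    return counts, by_cat
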