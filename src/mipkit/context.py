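"""Genomic organization: gene structure, chromosomal density,
tandem arrays and segmental-duplication calls.

Gene span is reported as end − start (the convention under which the
published per-gene lengths reproduce from the printed coordinates), not
the GFF3 end − start + 1. Tandem arrays chain same-chromosome,
same-subfamily neighbours within a distance cap; segmental calls look
for collinear anchor chains via longest-increasing-subsequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import GeneModel, MipkitError

UNPLACED = "unplaced"


@dataclass
class StructureStats:
    gene_id: str
    exon_count: int
    intron_count: int
    intron_lengths: list[int]
    gene_span: int


@dataclass
class DuplicationCall:
    array_id: str
    member_gene_ids: list[str]
    chromosome: str
    kind: str  # tandem | segmental


def structure_stats(model: GeneModel) -> StructureStats:
    """Exon/intron statistics; introns are the gaps between consecutive
    exons, span is last end − first start."""
    if not model.exons:
        raise MipkitError(f"gene {model.gene_id}: no exons")
    introns = [s2 - e1 - 1 for (_s1, e1), (s2, _e2) in zip(model.exons, model.exons[1:])]
    return StructureStats(
        gene_id=model.gene_id,
        exon_count=len(model.exons),
        intron_count=len(model.exons) - 1,
        intron_lengths=introns,
        gene_span=model.exons[-1][1] - model.exons[0][0],
    )


def chromosome_density(genes: list, chrom_lengths: dict[str, int]) -> dict:
    """Per-chromosome gene counts plus genome-wide density.

    ``genes`` need ``chromosome`` attributes; chromosomes absent from
    ``chrom_lengths`` are binned as unplaced scaffolds. Returns counts for
    every chromosome in ``chrom_lengths`` (zero included), the Mb-per-gene
    figure over placed chromosomes, and its reciprocal.
    """
    if not genes:
        raise MipkitError("no genes")
    counts = {c: 0 for c in chrom_lengths}
    counts[UNPLACED] = 0
    for g in genes:
        chrom = g.chromosome
        counts[chrom if chrom in chrom_lengths else UNPLACED] += 1
    total_mb = sum(chrom_lengths.values()) / 1e6
    n = len(genes)
    return {
        "counts": counts,
        "mb_per_gene": total_mb / n,
        "genes_per_mb": n / total_mb if total_mb else float("nan"),
    }


def detect_tandem_arrays(genes: list, max_gap_bp: int = 100_000,
                         max_intervening: int = 1) -> list[DuplicationCall]:
    """Chain same-chromosome, same-subfamily genes into tandem arrays.

    Consecutive members must start within ``max_gap_bp`` of each other with
    at most ``max_intervening`` non-family genes between them; maximal
    chains of ≥2 report as one array. ``genes`` need chromosome, start,
    end, subfamily and an id (``proposed_name`` or ``id``).
    """
    def gid(g):
        return getattr(g, "proposed_name", None) or getattr(g, "id", None) or g.locus_id

    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    calls: list[DuplicationCall] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, gid(g)))
        for fam in sorted({g.subfamily for g in ordered}):
            fam_positions = [(i, g) for i, g in enumerate(ordered) if g.subfamily == fam]
            chain: list = []
            chains: list[list] = []
            prev_idx = prev_gene = None
            for i, g in fam_positions:
                linked = (
                    prev_gene is not None
                    and g.start - prev_gene.start <= max_gap_bp
                    and (i - prev_idx - 1) <= max_intervening
                )
                if linked:
                    chain.append(g)
                else:
                    if len(chain) >= 2:
                        chains.append(chain)
                    chain = [g]
                prev_idx, prev_gene = i, g
            if len(chain) >= 2:
                chains.append(chain)
            for members in chains:
                ids = [gid(g) for g in members]
                calls.append(DuplicationCall(
                    array_id=f"{chrom}:{fam}:{ids[0]}",
                    member_gene_ids=ids, chromosome=chrom, kind="tandem"))
    return calls


@dataclass
class AnchorPair:
    """A homologous gene pair anchoring a candidate collinear block."""

    a_id: str
    a_chrom: str
    a_pos: int
    b_id: str
    b_chrom: str
    b_pos: int
    is_aqp: bool = False


def _lis_indices(values: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence."""
    best_len = [1] * len(values)
    prev = [-1] * len(values)
    for i in range(len(values)):
        for j in range(i):
            if values[j] < values[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not values:
        return []
    end = max(range(len(values)), key=lambda i: best_len[i])
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def detect_segmental_pairs(anchors: list[AnchorPair],
                           min_chain: int = 3) -> list[DuplicationCall]:
    """Flag AQP anchor pairs inside collinear chains of ≥ ``min_chain``
    anchors (ascending and descending passes, so inverted blocks count)."""
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        by_pair.setdefault((a.a_chrom, a.b_chrom), []).append(a)
    calls: list[DuplicationCall] = []
    for key in sorted(by_pair):
        group = sorted(by_pair[key], key=lambda a: (a.a_pos, a.b_pos))
        b_positions = [a.b_pos for a in group]
        for direction, series in (("+", b_positions), ("-", [-p for p in b_positions])):
            idx = _lis_indices(series)
            if len(idx) < min_chain:
                continue
            chain = [group[i] for i in idx]
            aqps = [a for a in chain if a.is_aqp]
            for a in aqps:
                calls.append(DuplicationCall(
                    array_id=f"{key[0]}|{key[1]}{direction}:{a.a_id}",
                    member_gene_ids=[a.a_id, a.b_id],
                    chromosome=f"{key[0]}|{key[1]}",
                    kind="segmental"))
    # deduplicate pairs found by both passes
    seen = set()
    unique = []
    for c in calls:
        k = tuple(c.member_gene_ids)
        if k not in seen:
            seen.add(k)
            unique.append(c)
    return unique
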