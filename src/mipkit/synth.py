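"""Synthetic data generators with ground-truth manifests.

Each generator is a pure function of (parameters, seed) and returns both
the synthetic inputs and a :class:`TruthManifest` sufficient to recompute
every expected downstream result. Element-level randomness derives from
per-element substreams (``default_rng([seed, *indices])``) so adding one
gene never perturbs the others.

Default settings emulate the shape of a small plant AQP family study:
proteins derived from the 12-member reference panel at moderate
divergence, a 40-gene four-cluster FPKM matrix over eight tissue
samples, 1-kb promoters, and multi-chromosome toy genomes with one-to-six
introns per gene and optional tandem arrays.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .records import AMINO_ACIDS, GeneModel, ProteinRecord, ReferenceAQP

#: Fixed most-frequent-codon choices (dicot-style usage) for reverse
#: translation; one codon per amino acid keeps genomes deterministic.
PREFERRED_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGA", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAG", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}
_CODON_TO_AA = {v: k for k, v in PREFERRED_CODON.items()}
STOP_CODON = "TAA"


@dataclass
class TruthManifest:
    """Ground truth for one generator call."""

    kind: str
    seed: int
    params: dict
    entries: dict[str, dict] = field(default_factory=dict)


def _protected_positions(ref: ReferenceAQP) -> set[int]:
    """0-based positions fixed by the annotation (NPA triplets + singles)."""
    fixed: set[int] = set()
    for name, pos in ref.position_map.items():
        if name.startswith("NPA"):
            fixed.update({pos - 1, pos, pos + 1})
        else:
            fixed.add(pos - 1)
    return fixed


def generate_proteins(panel: list[ReferenceAQP], n_per_subfamily: int = 5,
                      substitution_rate: float = 0.1, indel_rate: float = 0.0,
                      seed: int = 0) -> tuple[list[ProteinRecord], TruthManifest]:
    """Derive synthetic query proteins from panel templates.

    Point substitutions never land inside NPA triplets or mapped
    ar/R / Froger / SDP positions; indels (single-residue, at
    ``indel_rate`` per eligible position) stay ≥6 residues away from any
    mapped position so transferred coordinates shift but never vanish.
    """
    if not 0 <= substitution_rate < 0.5 or not 0 <= indel_rate < 0.5:
        raise ValueError("rates must be in [0, 0.5)")
    by_fam: dict[str, list[ReferenceAQP]] = {}
    for ref in panel:
        by_fam.setdefault(ref.subfamily, []).append(ref)
    records: list[ProteinRecord] = []
    manifest = TruthManifest(
        kind="proteins", seed=seed,
        params=dict(n_per_subfamily=n_per_subfamily,
                    substitution_rate=substitution_rate, indel_rate=indel_rate),
    )
    for fam_idx, fam in enumerate(sorted(by_fam)):
        refs = sorted(by_fam[fam], key=lambda r: r.id)
        for k in range(n_per_subfamily):
            template = refs[k % len(refs)]
            rng = np.random.default_rng([seed, fam_idx, k])
            protected = _protected_positions(template)
            indel_safe = {
                i for i in range(len(template.sequence))
                if all(abs(i - p) > 5 for p in protected)
            }
            seq = list(template.sequence)
            subs: list[int] = []
            for i in range(len(seq)):
                if i in protected:
                    continue
                if rng.random() < substitution_rate:
                    choices = [a for a in AMINO_ACIDS if a != seq[i]]
                    seq[i] = choices[rng.integers(len(choices))]
                    subs.append(i + 1)
            indels: list[tuple[str, int]] = []
            if indel_rate > 0:
                out: list[str] = []
                for i, aa in enumerate(seq):
                    if i in indel_safe and rng.random() < indel_rate:
                        if rng.random() < 0.5:
                            indels.append(("del", i + 1))
                            continue
                        ins = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                        out.append(aa)
                        out.append(ins)
                        indels.append(("ins", i + 1))
                    else:
                        out.append(aa)
                seq = out
            pid = f"syn{fam}-{k + 1}"
            records.append(ProteinRecord(id=pid, sequence="".join(seq)))
            manifest.entries[pid] = dict(
                template_id=template.id,
                subfamily=fam,
                substitution_positions=subs,
                indels=indels,
                NPA_LB=template.motif_at("NPA_LB"),
                NPA_LE=template.motif_at("NPA_LE"),
                arR=tuple(template.residue_at(n) for n in ("H2", "H5", "LE1", "LE2")),
                froger=tuple(template.residue_at(f"P{i}") for i in range(1, 6)),
                sdp=tuple(template.residue_at(f"SDP{i}") for i in range(1, 10)),
            )
    return records, manifest


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def reverse_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[aa] for aa in protein) + STOP_CODON


def translate_cds(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon == STOP_CODON:
            break
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def generate_genome(proteins: list[ProteinRecord],
                    introns_per_gene: dict[str, int] | int = 2,
                    tandem_arrays: list[list[str]] | None = None,
                    intergenic_length: int = 20_000,
                    tandem_gap: int = 4_000,
                    genes_per_chromosome: int = 8,
                    seed: int = 0) -> tuple[dict[str, str], str, TruthManifest]:
    """Build a toy multi-chromosome genome with the given proteins implanted.

    Coding sequences are reverse-translated with the fixed codon table and
    split by GT..AG introns (lengths 76–500 bp); tandem-array members are
    placed consecutively ``tandem_gap`` bp apart, everything else
    ``intergenic_length`` apart, every fourth gene on the minus strand.
    Returns (genome dict, GFF3 text, manifest).
    """
    tandem_arrays = tandem_arrays or []
    in_array = {g for arr in tandem_arrays for g in arr}
    order: list[tuple[str, bool]] = []
    for arr in tandem_arrays:
        order.extend((g, True) for g in arr)
    order.extend((p.id, False) for p in proteins if p.id not in in_array)
    by_id = {p.id: p for p in proteins}

    manifest = TruthManifest(
        kind="genome", seed=seed,
        params=dict(intergenic_length=intergenic_length, tandem_gap=tandem_gap,
                    genes_per_chromosome=genes_per_chromosome),
    )
    for arr_idx, arr in enumerate(tandem_arrays, start=1):
        for g in arr:
            manifest.entries.setdefault(g, {})["tandem_array"] = arr_idx

    genome: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    chrom_idx, placed_on_chrom = 1, 0
    chrom_seq: list[str] = []
    cursor = 0
    bases = "ACGT"

    def flush_chrom():
        nonlocal chrom_seq, cursor, placed_on_chrom, chrom_idx
        if chrom_seq:
            genome[f"chr{chrom_idx}"] = "".join(chrom_seq)
            chrom_idx += 1
        chrom_seq, cursor, placed_on_chrom = [], 0, 0

    for gene_pos, (gid, tandem) in enumerate(order):
        rng = np.random.default_rng([seed, 1, gene_pos])
        keep_together = tandem and placed_on_chrom > 0
        if placed_on_chrom >= genes_per_chromosome and not keep_together:
            flush_chrom()
        gap = tandem_gap if keep_together else intergenic_length
        filler = "".join(bases[b] for b in rng.integers(0, 4, size=gap))
        chrom_seq.append(filler)
        cursor += gap

        protein = by_id[gid]
        cds = reverse_translate(protein.sequence)
        n_introns = (introns_per_gene.get(gid, 2)
                     if isinstance(introns_per_gene, dict) else introns_per_gene)
        n_introns = min(n_introns, len(cds) // 50)
        cut_sites = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_introns,
                                      replace=False).tolist()) if n_introns else []
        pieces: list[str] = []
        exon_lens: list[int] = []
        intron_lens: list[int] = []
        prev = 0
        for cut in cut_sites:
            exon_lens.append(cut - prev)
            pieces.append(cds[prev:cut])
            ilen = int(rng.integers(76, 501))
            inner = "".join(bases[b] for b in rng.integers(0, 4, size=ilen - 4))
            pieces.append("GT" + inner + "AG")
            intron_lens.append(ilen)
            prev = cut
        exon_lens.append(len(cds) - prev)
        pieces.append(cds[prev:])
        gene_seq = "".join(pieces)

        strand = "-" if gene_pos % 4 == 3 else "+"
        if strand == "-":
            gene_seq = _reverse_complement(gene_seq)
        gstart = cursor + 1
        gend = cursor + len(gene_seq)
        chrom = f"chr{chrom_idx}"

        # exon coordinates in genomic (ascending) order
        exons: list[tuple[int, int]] = []
        offset = gstart
        if strand == "+":
            for elen, ilen in zip(exon_lens, intron_lens + [0]):
                exons.append((offset, offset + elen - 1))
                offset += elen + ilen
        else:
            rev_exons = list(reversed(exon_lens))
            rev_introns = list(reversed(intron_lens)) + [0]
            for elen, ilen in zip(rev_exons, rev_introns):
                exons.append((offset, offset + elen - 1))
                offset += elen + ilen

        gff_lines.append("\t".join([chrom, "mipkit_synth", "gene", str(gstart),
                                    str(gend), ".", strand, ".", f"ID={gid}"]))
        mid = f"{gid}.m1"
        gff_lines.append("\t".join([chrom, "mipkit_synth", "mRNA", str(gstart),
                                    str(gend), ".", strand, ".",
                                    f"ID={mid};Parent={gid}"]))
        for es, ee in exons:
            gff_lines.append("\t".join([chrom, "mipkit_synth", "exon", str(es),
                                        str(ee), ".", strand, ".", f"Parent={mid}"]))
        genomic_introns = intron_lens if strand == "+" else intron_lens[::-1]
        entry = manifest.entries.setdefault(gid, {})
        entry.update(chromosome=chrom, strand=strand, start=gstart, end=gend,
                     exons=exons, n_introns=len(intron_lens),
                     intron_lengths=genomic_introns, cds=cds)
        chrom_seq.append(gene_seq)
        cursor += len(gene_seq)
        placed_on_chrom += 1

    # trailing intergenic tail, then flush
    rng = np.random.default_rng([seed, 2])
    chrom_seq.append("".join(bases[b] for b in rng.integers(0, 4, size=2000)))
    flush_chrom()
    return genome, "\n".join(gff_lines) + "\n", manifest


def spliced_cds(genome: dict[str, str], model: GeneModel) -> str:
    """Concatenate exon sequence in transcript orientation."""
    chrom = genome[model.chromosome]
    parts = [chrom[s - 1 : e] for s, e in model.exons]
    cds = "".join(parts)
    if model.strand == "-":
        cds = _reverse_complement(cds)
    return cds


def _brute_force_motif_scan(seq: str, consensus: str) -> list[tuple[int, str]]:
    """Independent regex-based both-strand scan used as the generation-time
    oracle for chance matches; returns (1-based start, strand)."""
    from .promoter import IUPAC, reverse_complement

    pattern = "".join(f"[{IUPAC[c]}]" for c in consensus.upper())
    hits = [(m.start() + 1, "+") for m in re.finditer(f"(?=({pattern}))", seq)]
    rc = reverse_complement(seq)
    n, m = len(seq), len(consensus)
    hits += [(n - (mt.start() + m) + 1, "-")
             for mt in re.finditer(f"(?=({pattern}))", rc)]
    return sorted(hits)


def generate_promoters(gene_ids: list[str],
                       plantings: dict[str, list[tuple[str, str, int, str]]] | None = None,
                       motifs: list | None = None,
                       length: int = 1000, background_gc: float = 0.4,
                       seed: int = 0) -> tuple[dict[str, str], TruthManifest]:
    """i.i.d.-background promoters with motifs written at known positions.

    ``plantings`` maps gene id → list of (motif_name, concrete_sequence,
    position, strand); the concrete sequence must satisfy the motif
    consensus and is written on the stated strand. The manifest records
    plantings and, for each bundled motif, the total both-strand match
    count found by an independent regex oracle (so chance background
    matches are part of the truth).
    """
    from .fixtures import load_motif_table

    motifs = motifs if motifs is not None else load_motif_table()
    plantings = plantings or {}
    p_gc = background_gc / 2.0
    p_at = (1.0 - background_gc) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    promoters: dict[str, str] = {}
    manifest = TruthManifest(kind="promoters", seed=seed,
                             params=dict(length=length, background_gc=background_gc))
    motif_by_name = {m.name: m for m in motifs}
    for g_idx, gid in enumerate(gene_ids):
        rng = np.random.default_rng([seed, g_idx])
        seq = list("ACGT"[b] for b in rng.choice(4, size=length, p=probs))
        planted = []
        occupied: set[int] = set()
        for name, concrete, pos, strand in plantings.get(gid, []):
            concrete = concrete.upper()
            if pos < 1 or pos + len(concrete) - 1 > length:
                raise ValueError(f"{gid}: planting {name} at {pos} overflows promoter")
            span = set(range(pos, pos + len(concrete)))
            if span & occupied:
                raise ValueError(f"{gid}: planting {name} at {pos} overlaps another")
            occupied |= span
            from .promoter import reverse_complement
            written = concrete if strand == "+" else reverse_complement(concrete)
            seq[pos - 1 : pos - 1 + len(written)] = list(written)
            planted.append(dict(motif=name, position=pos, strand=strand,
                                sequence=concrete))
        promoters[gid] = "".join(seq)
        counts = {
            name: len(_brute_force_motif_scan(promoters[gid], m.consensus))
            for name, m in motif_by_name.items()
        }
        manifest.entries[gid] = dict(planted=planted, oracle_counts=counts)
    return promoters, manifest


def generate_expression(n_genes: int = 40, samples: list[str] | None = None,
                        k_clusters: int = 4, within_noise_sd: float = 0.05,
                        between_scale: float = 50.0,
                        seed: int = 0) -> tuple[ExpressionMatrix, TruthManifest]:
    """FPKM matrix with planted cluster structure.

    Cluster centroids are distinct non-negative tissue profiles (each
    cluster peaks in its own sample block at ``between_scale`` FPKM over a
    low baseline); each gene is its centroid times a positive gene scale
    plus truncated Gaussian noise (relative sd ``within_noise_sd``),
    clipped at zero.
    """
    samples = samples or ["young_leaves", "flower_bud", "shoot", "flower",
                          "root", "young_pod", "apical_meristem", "seedling"]
    if k_clusters > n_genes:
        raise ValueError("k_clusters must not exceed n_genes")
    n_samples = len(samples)
    centroids = np.full((k_clusters, n_samples), 2.0)
    block = max(1, n_samples // k_clusters)
    for k in range(k_clusters):
        lo = (k * block) % n_samples
        hi = min(lo + block, n_samples)
        centroids[k, lo:hi] = between_scale * (1.0 + 0.2 * k)
    manifest = TruthManifest(
        kind="expression", seed=seed,
        params=dict(n_genes=n_genes, samples=samples, k_clusters=k_clusters,
                    within_noise_sd=within_noise_sd, between_scale=between_scale,
                    centroids=centroids.tolist()),
    )
    rows = []
    gene_ids = []
    for g in range(n_genes):
        rng = np.random.default_rng([seed, g])
        label = g % k_clusters
        scale = float(rng.lognormal(mean=0.0, sigma=0.3))
        base = centroids[label] * scale
        noise = rng.normal(0.0, within_noise_sd * base.mean(), size=n_samples)
        row = np.clip(base + noise, 0.0, None)
        gid = f"gene{g + 1:03d}"
        gene_ids.append(gid)
        rows.append(row)
        manifest.entries[gid] = dict(cluster=label + 1, scale=scale)
    df = pd.DataFrame(np.array(rows), index=gene_ids, columns=samples)
    return ExpressionMatrix(df), manifest
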