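"""Candidate discovery by local-alignment homology screening.

Candidates are retained when their best local alignment against the
reference panel passes both an E-value cutoff (default 1e-5) and a
bit-score floor (default 100), the two filters used for BLASTp-style
family screens. Alignment itself is delegated to
:class:`Bio.Align.PairwiseAligner` (Smith–Waterman / Needleman–Wunsch with
affine gaps over BLOSUM62); this module owns scoring-scheme bookkeeping,
Karlin–Altschul statistics and the screening policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ALLOWED_RESIDUES, MipkitError, ProteinRecord, ReferenceAQP

# Gapped Karlin–Altschul parameters for BLOSUM62 with gap open 11 /
# extend 1, from the standard precomputed table shipped with NCBI BLAST
# (blast_stat.c, blosum62_values; also Altschul & Gish 1996 Table 5 region).
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


@dataclass
class ScoringScheme:
    """Substitution matrix + affine gap penalties + K-A statistics."""

    matrix: substitution_matrices.Array = field(
        default_factory=lambda: substitution_matrices.load("BLOSUM62")
    )
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = BLOSUM62_GAPPED_LAMBDA
    K: float = BLOSUM62_GAPPED_K

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise MipkitError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise MipkitError("Karlin–Altschul parameters must be positive")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix
        # BLAST convention: a gap of length k costs open + k*extend.
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_fraction: float
    query_span: tuple[int, int]  # 1-based inclusive; (0, 0) for empty alignment
    subject_span: tuple[int, int]


def _validate(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise MipkitError(f"{label}: empty sequence")
    for i, aa in enumerate(seq, start=1):
        if aa not in ALLOWED_RESIDUES:
            raise MipkitError(f"{label}: illegal residue {aa!r} at position {i}")
    return seq


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None,
                query_id: str = "query", subject_id: str = "subject") -> HomologyHit:
    """Optimal Smith–Waterman local alignment with affine gaps.

    Returns a hit whose raw score is the DP maximum (0 if no positive cell
    exists, with empty spans) and whose identity fraction is matches over
    aligned columns.
    """
    scheme = scheme or ScoringScheme()
    query = _validate(query, "query")
    subject = _validate(subject, "subject")
    aligner = scheme.aligner("local")
    alns = aligner.align(query, subject)
    score = float(alns.score)
    if score <= 0:
        return HomologyHit(query_id, subject_id, 0, scheme.bit_score(0), math.inf,
                           0.0, (0, 0), (0, 0))
    aln = alns[0]
    qa, sa = aln[0], aln[1]
    matches = sum(1 for x, y in zip(qa, sa) if x == y and x != "-")
    columns = len(qa)
    qs, qe = int(aln.aligned[0][0][0]) + 1, int(aln.aligned[0][-1][1])
    ss, se = int(aln.aligned[1][0][0]) + 1, int(aln.aligned[1][-1][1])
    bits = scheme.bit_score(score)
    return HomologyHit(query_id, subject_id, int(round(score)), bits,
                       evalue(bits, len(query), len(subject)),
                       matches / columns, (qs, qe), (ss, se))


def global_align(query: str, subject: str, scheme: ScoringScheme | None = None):
    """Needleman–Wunsch global alignment; returns (aligned_query, aligned_subject, score)."""
    scheme = scheme or ScoringScheme()
    query = _validate(query, "query")
    subject = _validate(subject, "subject")
    aligner = scheme.aligner("global")
    aln = aligner.align(query, subject)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def evalue(bit_score: float, m: int, n: int) -> float:
    """Expected chance hits: E = m·n·2^(−bit_score) for an m×n search space."""
    if m < 1 or n < 1:
        raise MipkitError("search-space dimensions must be ≥ 1")
    return m * n * 2.0 ** (-bit_score)


def screen_candidates(
    proteome: list[ProteinRecord],
    panel: list[ReferenceAQP],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
    bit_cutoff: float = 100.0,
) -> list[tuple[ProteinRecord, HomologyHit]]:
    """Retain proteome members whose best panel hit passes both cutoffs.

    The best hit is chosen by bit score (ties broken by lexicographically
    smallest subject id); E-values use the total panel residue count as the
    database length. Result order follows sorted query ids, independent of
    input order; duplicate query ids are an error.
    """
    if not panel:
        raise MipkitError("reference panel is empty")
    scheme = scheme or ScoringScheme()
    db_len = sum(len(r.sequence) for r in panel)
    seen: set[str] = set()
    retained: list[tuple[ProteinRecord, HomologyHit]] = []
    for rec in sorted(proteome, key=lambda r: r.id):
        if rec.id in seen:
            raise MipkitError(f"duplicate query id {rec.id!r}")
        seen.add(rec.id)
        best: HomologyHit | None = None
        for ref in sorted(panel, key=lambda r: r.id):
            hit = local_align(rec.sequence, ref.sequence, scheme,
                              query_id=rec.id, subject_id=ref.id)
            hit.e_value = evalue(hit.bit_score, len(rec.sequence), db_len)
            if best is None or hit.bit_score > best.bit_score:
                best = hit
        assert best is not None
        if best.e_value <= e_cutoff and best.bit_score >= bit_cutoff:
            retained.append((rec, best))
    return retained
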