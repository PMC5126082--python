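"""Progressive multiple sequence alignment.

A deliberately transparent progressive aligner: pairwise guide distances
are fractional shared k-mers (k=3), the guide tree is neighbor joining on
those distances, and profiles are merged leaf-to-root with affine-gap
profile–profile dynamic programming over the scoring scheme's substitution
matrix. This trades alignment polish for speed and determinism; the
downstream consumers (distance matrices, subfamily trees, residue
transfer) only need within-subfamily columns to align consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .homology import ScoringScheme
from .records import AMINO_ACIDS, MipkitError, ProteinRecord

GAP = "-"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_NSYM = len(AMINO_ACIDS) + 1  # + gap/unknown bucket (scores 0)


@dataclass
class Msa:
    """An alignment: equal-length gapped rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise MipkitError("MSA rows differ in length")
        if len(self.ids) != len(self.rows):
            raise MipkitError("MSA ids/rows mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def to_fasta(self) -> str:
        out = []
        for i, r in zip(self.ids, self.rows):
            out.append(f">{i}")
            out.extend(r[j : j + 60] for j in range(0, len(r), 60))
        return "\n".join(out) + "\n"


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 − (shared k-mers / k-mers of the shorter sequence)."""
    ka, kb = (
        {s[i : i + k] for i in range(len(s) - k + 1)} for s in (a, b)
    )
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0
    return 1.0 - len(ka & kb) / denom


def _score_table(scheme: ScoringScheme) -> np.ndarray:
    table = np.zeros((_NSYM, _NSYM))
    for a, i in _AA_INDEX.items():
        for b, j in _AA_INDEX.items():
            table[i, j] = scheme.score(a, b)
    return table


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue-frequency matrix (gaps and X share the zero bucket)."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, _NSYM))
    for row in rows:
        for j, ch in enumerate(row):
            prof[j, _AA_INDEX.get(ch, _NSYM - 1)] += 1
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    scheme: ScoringScheme, table: np.ndarray) -> tuple[list[str], list[str]]:
    """Affine-gap Gotoh DP on the profile–profile score matrix; returns
    the two row groups with gap columns inserted."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    m = (pa @ table @ pb.T).tolist()
    la, lb = len(rows_a[0]), len(rows_b[0])
    go, ge = float(scheme.gap_open + scheme.gap_extend), float(scheme.gap_extend)
    neg = -1e30
    h_prev = [0.0] + [-(go + ge * (j - 1)) for j in range(1, lb + 1)]
    e_prev = [neg] * (lb + 1)
    ptr = [bytearray(lb + 1) for _ in range(la + 1)]  # 1=diag 2=up(gap in B) 3=left(gap in A)
    for j in range(1, lb + 1):
        ptr[0][j] = 3
    f_row = [neg] * (lb + 1)
    for i in range(1, la + 1):
        h_cur = [0.0] * (lb + 1)
        e_cur = [neg] * (lb + 1)
        h_cur[0] = -(go + ge * (i - 1))
        ptr[i][0] = 2
        mi = m[i - 1]
        ptr_i = ptr[i]
        ecur = neg
        for j in range(1, lb + 1):
            # F: gap in B (consume A column) — vertical
            f = h_prev[j] - go
            fe = f_row[j] - ge
            if fe > f:
                f = fe
            f_row[j] = f
            # E: gap in A (consume B column) — horizontal
            e = h_cur[j - 1] - go
            ee = ecur - ge
            if ee > e:
                e = ee
            ecur = e
            d = h_prev[j - 1] + mi[j - 1]
            if d >= f and d >= e:
                h_cur[j] = d
                ptr_i[j] = 1
            elif f >= e:
                h_cur[j] = f
                ptr_i[j] = 2
            else:
                h_cur[j] = e
                ptr_i[j] = 3
        h_prev = h_cur
    # traceback
    i, j = la, lb
    take: list[int] = []
    while i > 0 or j > 0:
        p = ptr[i][j]
        take.append(p)
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    take.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for p in take:
        if p in (1, 2):
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            ia += 1
        else:
            for r in out_a:
                r.append(GAP)
        if p in (1, 3):
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
        else:
            for r in out_b:
                r.append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(sequences: list[ProteinRecord],
                      scheme: ScoringScheme | None = None) -> Msa:
    """Align ≥2 sequences progressively along a k-mer/NJ guide tree."""
    from .phylo import DistanceMatrix, nj_tree  # deferred: phylo imports Msa

    if len(sequences) < 2:
        raise MipkitError("progressive alignment needs ≥2 sequences")
    scheme = scheme or ScoringScheme()
    table = _score_table(scheme)
    ids = [r.id for r in sequences]
    seqs = {r.id: r.sequence for r in sequences}
    if len(sequences) == 2:
        order_tree = None
    else:
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = kmer_distance(sequences[i].sequence,
                                                  sequences[j].sequence)
        order_tree = nj_tree(DistanceMatrix(ids=ids, data=d)).root

    def merge(node) -> tuple[list[str], list[str]]:
        if not node.children:
            return [node.name], [seqs[node.name]]
        child_groups = [merge(c) for c in node.children]
        gid, grows = child_groups[0]
        for cid, crows in child_groups[1:]:
            a, b = _align_profiles(grows, crows, scheme, table)
            gid, grows = gid + cid, a + b
        return gid, grows

    if order_tree is None:
        a, b = _align_profiles([seqs[ids[0]]], [seqs[ids[1]]], scheme, table)
        out_ids, out_rows = ids, a + b
    else:
        out_ids, out_rows = merge(order_tree)

    msa = Msa(ids=out_ids, rows=out_rows)
    # reorder to input order
    perm = [msa.ids.index(i) for i in ids]
    return Msa(ids=ids, rows=[msa.rows[p] for p in perm])
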