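"""Physicochemical protein properties: GRAVY, molecular weight,
isoelectric point, and hydropathy-based transmembrane segment prediction.

pI is found by bisection on the Henderson–Hasselbalch net charge, which is
monotone non-increasing in pH; the default pKa set is the EMBOSS one and
the table is swappable, so recomputed pI values are comparable between
runs but not guaranteed to match any particular web tool to two decimals.
TM segments come from a transparent Kyte–Doolittle sliding-window rule,
not an HMM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import MISSING, MipkitError

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Average residue masses (Da); a peptide adds one water (18.0153 Da).
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153


@dataclass
class PKaTable:
    """Ionizable-group pKa values; positive groups protonate below their
    pKa, negative groups deprotonate above. Default: EMBOSS set."""

    n_terminus: float = 8.6
    c_terminus: float = 3.6
    positive: dict[str, float] = field(
        default_factory=lambda: {"K": 10.8, "R": 12.5, "H": 6.5}
    )
    negative: dict[str, float] = field(
        default_factory=lambda: {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
    )

    def __post_init__(self) -> None:
        for v in (self.n_terminus, self.c_terminus,
                  *self.positive.values(), *self.negative.values()):
            if not 0 < v < 14:
                raise MipkitError(f"pKa {v} outside (0,14)")


@dataclass
class PropertyReport:
    gene_id: str
    length: int
    MW: float
    pI: float
    GRAVY: float
    tm_segments: list[tuple[int, int]]
    subfamily: str = ""


def gravy(sequence: str) -> float:
    """Grand average of Kyte–Doolittle hydropathy; X is excluded from the
    mean (with a logged warning)."""
    sequence = sequence.upper()
    if not sequence:
        raise MipkitError("empty sequence")
    values = [KYTE_DOOLITTLE[aa] for aa in sequence if aa in KYTE_DOOLITTLE]
    if len(values) < len(sequence):
        logger.warning("GRAVY: %d residue(s) outside the hydropathy scale excluded",
                       len(sequence) - len(values))
    if not values:
        raise MipkitError("no scorable residues")
    return sum(values) / len(values)


def molecular_weight(sequence: str) -> float:
    """Peptide molecular weight in kD from average residue masses."""
    sequence = sequence.upper()
    if not sequence:
        raise MipkitError("empty sequence")
    total = WATER_MASS
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASS:
            raise MipkitError(f"mass undefined for residue {aa!r} at position {i}")
        total += RESIDUE_MASS[aa]
    return total / 1000.0


def net_charge(sequence: str, pH: float, table: PKaTable | None = None) -> float:
    """Henderson–Hasselbalch net charge at a given pH."""
    table = table or PKaTable()
    sequence = sequence.upper()
    if not sequence:
        raise MipkitError("empty sequence")
    charge = 1.0 / (1.0 + 10.0 ** (pH - table.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (table.c_terminus - pH))
    for aa in sequence:
        if aa in table.positive:
            charge += 1.0 / (1.0 + 10.0 ** (pH - table.positive[aa]))
        elif aa in table.negative:
            charge -= 1.0 / (1.0 + 10.0 ** (table.negative[aa] - pH))
    return charge


def isoelectric_point(sequence: str, table: PKaTable | None = None,
                      tolerance: float = 0.001) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    table = table or PKaTable()
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def predict_tm_segments(sequence: str, window: int = 19,
                        cutoff: float = 1.6) -> list[tuple[int, int]]:
    """Candidate transmembrane segments from sliding-window hydropathy.

    Window centers whose mean hydropathy exceeds ``cutoff`` are grouped
    into maximal runs; each run expands to its windows' extent, and
    overlapping extents merge. Sequences shorter than the window yield no
    segments.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < window:
        return []
    half = window // 2
    values = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence]
    total = sum(values[:window])
    centers = []
    for start in range(n - window + 1):
        if start > 0:
            total += values[start + window - 1] - values[start - 1]
        if total / window > cutoff:
            centers.append(start + half)  # 0-based center
    segments: list[list[int]] = []
    for c in centers:
        seg_start, seg_end = max(0, c - half), min(n - 1, c + half)
        if segments and seg_start <= segments[-1][1] + 1:
            segments[-1][1] = seg_end
        else:
            segments.append([seg_start, seg_end])
    return [(s + 1, e + 1) for s, e in segments]


def summarize_properties(rows: list) -> dict[str, dict[str, dict[str, float]]]:
    """Family-wide and per-subfamily mean/min/max of pI, MW and GRAVY.

    Accepts annotation-table rows or :class:`PropertyReport` objects (any
    object with pI/MW/GRAVY and a subfamily attribute). Values are
    unrounded; callers round to presentation precision.
    """
    if not rows:
        raise MipkitError("no rows to summarize")

    def stats(values: list[float]) -> dict[str, float]:
        return {"mean": sum(values) / len(values), "min": min(values), "max": max(values)}

    def block(subset) -> dict[str, dict[str, float]]:
        return {
            "pI": stats([r.pI for r in subset]),
            "MW": stats([r.MW for r in subset]),
            "GRAVY": stats([r.GRAVY for r in subset]),
        }

    out = {"family": block(rows)}
    for fam in sorted({getattr(r, "subfamily", "") for r in rows} - {""}):
        out[fam] = block([r for r in rows if getattr(r, "subfamily", "") == fam])
    return out
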