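"""Pore-selectivity residue extraction and substrate prediction.

Aquaporin substrate specificity is read from a handful of alignment
positions: the NPA triplets of loops B and E (channel constriction one),
the aromatic/arginine tetrad H2–H5–LE1–LE2 (constriction two), Froger's
positions P1–P5 (aquaglyceroporin discrimination) and nine
specificity-determining positions (SDPs) whose residue signatures are
associated with transport of urea, H2O2, boric acid or CO2. This module
formalizes the usual "visual inspection of the alignment" as automated
position transfer: the query is globally aligned to an annotated
reference and every mapped reference position is read off the aligned
query column, with NPA sites re-anchored to the nearest N-P-x triplet
within ±5 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology import ScoringScheme, global_align
from .msa import GAP
from .records import MISSING, MipkitError, ProteinRecord, ReferenceAQP

ARR_NAMES = ("H2", "H5", "LE1", "LE2")
FROGER_NAMES = ("P1", "P2", "P3", "P4", "P5")
SDP_NAMES = tuple(f"SDP{i}" for i in range(1, 10))


@dataclass
class ResidueReport:
    """Selectivity-residue extraction result for one protein."""

    gene_id: str
    NPA_LB: str = MISSING
    NPA_LE: str = MISSING
    npa_variant_flags: tuple[bool, bool] = (False, False)
    arR: tuple[str, str, str, str] = (MISSING,) * 4
    froger: tuple[str, str, str, str, str] = (MISSING,) * 5
    sdp: tuple[str, ...] = (MISSING,) * 9
    npa_lb_position: int | None = None
    npa_le_position: int | None = None
    source_reference_id: str = ""

    @property
    def npa_spacing(self) -> int | None:
        return npa_spacing(self)


@dataclass
class SubstrateSignature:
    """Allowed residue sets over the SDP position vector, in listed order."""

    substrate: str
    allowed: list[frozenset[str]]

    @classmethod
    def parse(cls, substrate: str, signature: str) -> "SubstrateSignature":
        """Parse a dash-separated signature; ``F/I/L`` and ``ILV`` both
        denote the allowed set {F,I,L} / {I,L,V}."""
        allowed = []
        for token in signature.split("-"):
            letters = frozenset(token.replace("/", ""))
            if not letters:
                raise MipkitError(f"{substrate}: empty signature position")
            allowed.append(letters)
        return cls(substrate=substrate, allowed=allowed)


#: Published substrate signatures over the SDP vector.
SUBSTRATE_SIGNATURES: list[SubstrateSignature] = [
    SubstrateSignature.parse("boric_acid", "T-I-H-P-E-L/M-L-T-P"),
    SubstrateSignature.parse("CO2", "ILV-I/M-C-A-I/V-D/H-W"),
    SubstrateSignature.parse("H2O2", "A/S-G/A-V/L-F/L/A/I-I/V-Q/H/I/L-F/Y-V/A-P"),
    SubstrateSignature.parse("urea", "H-P-F-F/I/L-L-P/A-G-G/S-N"),
]


def scan_npa(sequence: str) -> list[tuple[int, str]]:
    """All N-P-x triplets, as (1-based position of N, triplet)."""
    sequence = sequence.upper()
    out = []
    for i in range(len(sequence) - 2):
        if sequence[i] == "N" and sequence[i + 1] == "P":
            out.append((i + 1, sequence[i : i + 3]))
    return out


def npa_spacing(report: ResidueReport) -> int | None:
    """Residues strictly between the two NPA triplets
    (start-to-start offset minus the triplet length); None when either
    motif is missing."""
    if report.npa_lb_position is None or report.npa_le_position is None:
        return None
    return report.npa_le_position - report.npa_lb_position - 3


def _column_map(aligned_q: str, aligned_r: str) -> dict[int, int]:
    """reference position (1-based) → query position (1-based) for columns
    where both carry residues."""
    out: dict[int, int] = {}
    qi = ri = 0
    for qa, ra in zip(aligned_q, aligned_r):
        if qa != GAP:
            qi += 1
        if ra != GAP:
            ri += 1
            if qa != GAP:
                out[ri] = qi
    return out


def _anchor_npa(sequence: str, site: int | None) -> tuple[str, int | None]:
    """Validate/correct a transferred NPA site against the actual N-P-x
    triplets of the query; nearest within ±5 wins."""
    if site is None:
        return MISSING, None
    hits = scan_npa(sequence)
    near = [(abs(pos - site), pos, motif) for pos, motif in hits if abs(pos - site) <= 5]
    if near:
        _, pos, motif = min(near)
        return motif, pos
    if site + 2 <= len(sequence):
        return sequence[site - 1 : site + 2], site
    return MISSING, None


def transfer_positions(query: ProteinRecord, reference: ReferenceAQP,
                       scheme: ScoringScheme | None = None) -> ResidueReport:
    """Transfer every annotated reference position onto the query through
    a global alignment; positions aligned to gaps come back missing."""
    scheme = scheme or ScoringScheme()
    qa, ra, _score = global_align(query.sequence, reference.sequence, scheme)
    matches = sum(1 for x, y in zip(qa, ra) if x == y and x != GAP)
    identity = matches / len(qa)
    if identity < 0.15:
        raise MipkitError(
            f"reference {reference.id} too distant from {query.id} "
            f"(identity {identity:.2f} < 0.15)"
        )
    cmap = _column_map(qa, ra)

    def single(name: str) -> str:
        qpos = cmap.get(reference.position_map[name])
        return query.sequence[qpos - 1] if qpos else MISSING

    lb_motif, lb_pos = _anchor_npa(query.sequence, cmap.get(reference.position_map["NPA_LB"]))
    le_motif, le_pos = _anchor_npa(query.sequence, cmap.get(reference.position_map["NPA_LE"]))
    return ResidueReport(
        gene_id=query.id,
        NPA_LB=lb_motif,
        NPA_LE=le_motif,
        npa_variant_flags=(
            lb_motif != MISSING and not lb_motif.endswith("A"),
            le_motif != MISSING and not le_motif.endswith("A"),
        ),
        arR=tuple(single(n) for n in ARR_NAMES),
        froger=tuple(single(n) for n in FROGER_NAMES),
        sdp=tuple(single(n) for n in SDP_NAMES),
        npa_lb_position=lb_pos,
        npa_le_position=le_pos,
        source_reference_id=reference.id,
    )


def best_reference(query: ProteinRecord, panel: list[ReferenceAQP],
                   subfamily: str | None = None,
                   scheme: ScoringScheme | None = None) -> ReferenceAQP:
    """Highest global-alignment identity among panel members (optionally
    restricted to one subfamily); ties break on reference id."""
    scheme = scheme or ScoringScheme()
    pool = [r for r in panel if subfamily is None or r.subfamily == subfamily]
    if not pool:
        raise MipkitError(f"no panel members for subfamily {subfamily!r}")
    scored = []
    for ref in sorted(pool, key=lambda r: r.id):
        aq, ar, _ = global_align(query.sequence, ref.sequence, scheme)
        ident = sum(1 for x, y in zip(aq, ar) if x == y and x != GAP) / len(aq)
        scored.append((-ident, ref.id, ref))
    return min(scored)[2]


def predict_substrates(report: ResidueReport,
                       signatures: list[SubstrateSignature] | None = None
                       ) -> list[tuple[str, bool, float]]:
    """Match the report's SDP vector against each substrate signature.

    A substrate matches when every signature position with an available
    query residue is in its allowed set and at least 80% of signature
    positions are available; ``fraction_matched`` is the fraction of
    signature positions whose residue is present and allowed.
    """
    signatures = signatures if signatures is not None else SUBSTRATE_SIGNATURES
    if not signatures:
        raise MipkitError("no substrate signatures supplied")
    out = []
    for sig in signatures:
        npos = len(sig.allowed)
        residues = report.sdp[:npos]
        available = [(r, allowed) for r, allowed in zip(residues, sig.allowed) if r != MISSING]
        ok = sum(1 for r, allowed in available if r in allowed)
        fraction = ok / npos
        matched = (
            len(available) >= 0.8 * npos
            and all(r in allowed for r, allowed in available)
        )
        out.append((sig.substrate, matched, fraction))
    return out
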