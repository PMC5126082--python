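"""Core domain records for the aquaporin (MIP) family toolkit.

The plant MIP superfamily splits into subfamilies named for their typical
subcellular residence: plasma-membrane intrinsic proteins (PIP), tonoplast
intrinsic proteins (TIP), NOD26-like intrinsic proteins (NIP), small basic
intrinsic proteins (SIP) and the uncategorized X intrinsic proteins (XIP).
Records here carry the minimal annotation the pipeline needs: sequence,
genomic placement, and — for characterized reference channels — the 1-based
indices of the pore-lining diagnostic residues (the two NPA motifs of loops
B and E, the aromatic/arginine constriction tetrad H2/H5/LE1/LE2, Froger's
positions P1–P5 and nine specificity-determining positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = set(AMINO_ACIDS) | {"X"}
SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")

#: ASCII sentinel used wherever a printed table shows an en-dash for
#: "residue not present / not alignable".
MISSING = "-"


class MipkitError(ValueError):
    """Base error for malformed inputs."""


@dataclass
class ProteinRecord:
    """A candidate or identified AQP protein, optionally with locus coordinates."""

    id: str
    sequence: str
    description: str = ""
    locus_id: str = ""
    chromosome: str = ""
    start: int | None = None
    end: int | None = None
    strand: str = ""
    subfamily_annotation: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MipkitError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in ALLOWED_RESIDUES:
                raise MipkitError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {i}"
                )
        if self.start is not None and self.end is not None and self.end < self.start:
            raise MipkitError(f"record {self.id!r}: end < start")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene model: ordered, non-overlapping exons on one chromosome.

    Coordinates are GFF3-style 1-based inclusive; exons are stored in
    ascending genomic order regardless of strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    mRNA_id: str = ""

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if e < s:
                raise MipkitError(f"gene {self.gene_id!r}: exon end {e} < start {s}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise MipkitError(
                    f"gene {self.gene_id!r}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )


@dataclass
class AnnotationTableRow:
    """One row of the family annotation table (locus, placement, pI/MW/GRAVY)."""

    locus_id: str
    proposed_name: str
    subfamily: str
    chromosome: str
    start: int
    end: int
    pI: float
    MW: float
    GRAVY: float
    subcellular: str

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise MipkitError(f"{self.proposed_name}: unknown subfamily {self.subfamily!r}")
        if not 0.0 < self.pI < 14.0:
            raise MipkitError(f"{self.proposed_name}: pI {self.pI} outside (0,14)")
        if self.MW <= 0:
            raise MipkitError(f"{self.proposed_name}: non-positive MW")

    @property
    def span(self) -> int:
        """Gene length as printed in the source table: end − start."""
        return self.end - self.start


@dataclass
class ResiduePanelRow:
    """One row of the selectivity-residue table (NPA motifs, ar/R, Froger)."""

    gene_id: str
    NPA_LB: str
    NPA_LE: str
    arR: tuple[str, str, str, str]  # H2, H5, LE1, LE2
    froger: tuple[str, str, str, str, str]  # P1..P5

    def __post_init__(self) -> None:
        for motif in (self.NPA_LB, self.NPA_LE):
            if motif != MISSING and len(motif) != 3:
                raise MipkitError(f"{self.gene_id}: motif {motif!r} not length 3")
        for res in (*self.arR, *self.froger):
            if res != MISSING and len(res) != 1:
                raise MipkitError(f"{self.gene_id}: residue field {res!r} not one letter")


# Ordered names of the mapped positions a characterized reference must carry.
POSITION_NAMES = (
    "NPA_LB",
    "NPA_LE",
    "H2",
    "H5",
    "LE1",
    "LE2",
    "P1",
    "P2",
    "P3",
    "P4",
    "P5",
    "SDP1",
    "SDP2",
    "SDP3",
    "SDP4",
    "SDP5",
    "SDP6",
    "SDP7",
    "SDP8",
    "SDP9",
)


@dataclass
class ReferenceAQP:
    """A characterized AQP with hand-annotated selectivity-residue positions.

    ``position_map`` maps each name in :data:`POSITION_NAMES` to a 1-based
    index into ``sequence``; NPA_LB / NPA_LE index the first residue (the N)
    of the loop-B and loop-E triplets.
    """

    id: str
    species: str
    subfamily: str
    sequence: str
    position_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for name, idx in self.position_map.items():
            if not 1 <= idx <= n:
                raise MipkitError(
                    f"reference {self.id}: position {name}={idx} outside 1..{n}"
                )

    def residue_at(self, name: str) -> str:
        return self.sequence[self.position_map[name] - 1]

    def motif_at(self, name: str) -> str:
        i = self.position_map[name]
        return self.sequence[i - 1 : i + 2]
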