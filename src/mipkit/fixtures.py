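"""Bundled fixtures: the printed family tables, the synthetic reference
panel and the cis-element consensus table.

The two family tables are verbatim transcriptions of the published chickpea
aquaporin annotation (40 loci with coordinates, pI, MW, GRAVY, predicted
subcellular location) and selectivity-residue table (NPA motifs, ar/R
tetrad, Froger positions). They are data files guarded by SHA-256
checksums so silent edits fail loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

from .records import (
    MISSING,
    POSITION_NAMES,
    AnnotationTableRow,
    MipkitError,
    ReferenceAQP,
    ResiduePanelRow,
)

_DATA = resources.files("mipkit") / "data"

# sha256 of the fixture TSVs; recomputed on load to prevent silent edits.
TABLE1_SHA256 = "85cd1c2a0cb690d1fe5d8a75e1d78f7376b598f9ea7abbe09ce76c9e5d652d50"
TABLE2_SHA256 = "321b27274278a7d8603e64e2dc655511e7d8212a2cdc1f2949629db5d8409df3"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def _check(path: Path, expected: str) -> str:
    text = path.read_text(encoding="utf-8")
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != expected:
        raise MipkitError(f"fixture checksum mismatch for {path.name}: {digest}")
    return text


def load_fixture_tables() -> tuple[list[AnnotationTableRow], list[ResiduePanelRow]]:
    """Load the bundled annotation and selectivity-residue tables."""
    t1 = _check(_data_path("table1.tsv"), TABLE1_SHA256)
    rows1: list[AnnotationTableRow] = []
    for line in t1.splitlines()[1:]:
        f = line.split("\t")
        rows1.append(
            AnnotationTableRow(
                locus_id=f[2], proposed_name=f[1], subfamily=f[0], chromosome=f[3],
                start=int(f[4]), end=int(f[5]), pI=float(f[6]), MW=float(f[7]),
                GRAVY=float(f[8]), subcellular=f[9],
            )
        )

    t2 = _check(_data_path("table2.tsv"), TABLE2_SHA256)
    rows2: list[ResiduePanelRow] = []
    for line in t2.splitlines()[1:]:
        f = line.split("\t")
        rows2.append(
            ResiduePanelRow(
                gene_id=f[0], NPA_LB=f[1], NPA_LE=f[2],
                arR=(f[3], f[4], f[5], f[6]),
                froger=(f[7], f[8], f[9], f[10]),
            )
        )

    names = {r.proposed_name for r in rows1}
    for r in rows2:
        if r.gene_id not in names:
            raise MipkitError(f"residue-table gene {r.gene_id} missing from annotation table")
    return rows1, rows2


def load_reference_panel() -> list[ReferenceAQP]:
    """Load the bundled synthetic reference panel (sequences + position maps)."""
    pos_by_id: dict[str, tuple[str, dict[str, int]]] = {}
    for line in _data_path("synthetic_reference_panel_positions.tsv").read_text(
        encoding="utf-8"
    ).splitlines():
        if line.startswith("#") or line.startswith("id\t") or not line.strip():
            continue
        f = line.split("\t")
        pos_by_id[f[0]] = (f[1], dict(zip(POSITION_NAMES, map(int, f[2:]))))

    panel: list[ReferenceAQP] = []
    cur_id, chunks = None, []
    lines = _data_path("synthetic_reference_panel.fasta").read_text(encoding="utf-8").splitlines()
    lines.append(">")  # sentinel to flush last record
    for line in lines:
        if line.startswith(";"):
            continue
        if line.startswith(">"):
            if cur_id is not None:
                fam, pmap = pos_by_id[cur_id]
                panel.append(
                    ReferenceAQP(id=cur_id, species="synthetic", subfamily=fam,
                                 sequence="".join(chunks), position_map=pmap)
                )
            cur_id = line[1:].split()[0] if len(line) > 1 else None
            chunks = []
        else:
            chunks.append(line.strip())
    return panel


def load_motif_table() -> list:
    """Load the bundled IUPAC cis-element consensus table."""
    from .promoter import MotifDefinition

    motifs = []
    for line in _data_path("plantcare_motifs.tsv").read_text(encoding="utf-8").splitlines():
        if line.startswith("#") or line.startswith("name\t") or not line.strip():
            continue
        name, consensus, category = line.split("\t")
        motifs.append(MotifDefinition(name=name, consensus=consensus, category=category))
    return motifs
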