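"""Deterministic builder for the bundled SYNTHETIC reference AQP panel.

Real structure-resolved, functionally characterized aquaporins (the
Arabidopsis PIP/TIP/NIP/SIP members usually used to anchor subfamily calls
and residue transfer) cannot be redistributed here, so the bundled panel is
a synthetic construction: twelve sequences, three per subfamily, built on a
canonical 6-transmembrane MIP architecture with

* hydrophobic 21-residue TM blocks separated by hydrophilic loops,
* canonical NPA triplets in loops B and E (start-to-start offset 119,
  i.e. 116 residues strictly between the triplets),
* subfamily-consensus ar/R tetrad, Froger P1–P5 and SDP1–SDP9 residues
  written at fixed, hand-annotated coordinates.

Every mapped coordinate is therefore known by construction, which is what
a hand-annotated reference panel provides. Members within a subfamily
differ by ~8% residue-class-preserving substitutions outside the mapped
positions; subfamilies are drawn independently and share only the
architecture. Running ``python -m mipkit.panel_builder`` regenerates the
two data files bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .records import POSITION_NAMES, ReferenceAQP

# (kind, length): 6 hydrophobic TM blocks in a loop scaffold, 275 aa total.
ARCHITECTURE = (
    ("loop", 20),  # N-terminus          1-20
    ("tm", 21),    # TM1                21-41
    ("loop", 14),  # loop A             42-55
    ("tm", 21),    # TM2 (holds H2)     56-76
    ("loop", 29),  # loop B (NPA)       77-105
    ("tm", 21),    # TM3               106-126
    ("loop", 24),  # loop C            127-150
    ("tm", 21),    # TM4               151-171
    ("loop", 14),  # loop D            172-185
    ("tm", 21),    # TM5 (holds H5)    186-206
    ("loop", 29),  # loop E (NPA, ar/R)207-235
    ("tm", 21),    # TM6               236-256
    ("loop", 19),  # C-terminus        257-275
)

#: 1-based hand-annotated coordinates shared by every panel member.
PANEL_POSITION_MAP: dict[str, int] = {
    "NPA_LB": 90,
    "NPA_LE": 209,
    "H2": 66,
    "H5": 196,
    "LE1": 213,
    "LE2": 215,
    "P1": 222,
    "P2": 260,
    "P3": 262,
    "P4": 264,
    "P5": 266,
    "SDP1": 8,
    "SDP2": 12,
    "SDP3": 46,
    "SDP4": 50,
    "SDP5": 130,
    "SDP6": 136,
    "SDP7": 175,
    "SDP8": 226,
    "SDP9": 230,
}

# Subfamily consensus residues: ar/R (H2,H5,LE1,LE2), Froger P1–P5, SDP1–9.
# ar/R and Froger follow the within-subfamily consensus of the printed
# residue table; SDP vectors follow the published substrate signature the
# subfamily is associated with (PIP→urea, TIP→H2O2, NIP→boric acid; SIP is
# given a non-signature vector).
SUBFAMILY_RESIDUES: dict[str, dict[str, str]] = {
    "PIP": dict(H2="F", H5="H", LE1="T", LE2="R",
                P1="E", P2="S", P3="A", P4="F", P5="W",
                SDP="HPFFLPGGN"),
    "TIP": dict(H2="H", H5="I", LE1="A", LE2="V",
                P1="T", P2="S", P3="A", P4="Y", P5="W",
                SDP="AGVFIQFVP"),
    "NIP": dict(H2="W", H5="V", LE1="A", LE2="R",
                P1="F", P2="S", P3="A", P4="Y", P5="I",
                SDP="TIHPELLTP"),
    "SIP": dict(H2="L", H5="V", LE1="P", LE2="N",
                P1="I", P2="A", P3="A", P4="Y", P5="W",
                SDP="GDKSNESKD"),
}

TM_ALPHABET = "ILVFMA"
TM_WEIGHTS = np.array([0.25, 0.25, 0.2, 0.12, 0.09, 0.09])
LOOP_ALPHABET = "GSTNQDEKRAHY"
LOOP_WEIGHTS = np.array([0.14, 0.12, 0.1, 0.08, 0.07, 0.08, 0.08, 0.09, 0.07, 0.08, 0.05, 0.04])

_BASE_SEED = 20161129
MEMBERS_PER_SUBFAMILY = 3
WITHIN_SUBSTITUTION_RATE = 0.08


def _position_classes() -> list[str]:
    classes: list[str] = []
    for kind, length in ARCHITECTURE:
        classes.extend([kind] * length)
    return classes


def _mapped_positions() -> set[int]:
    """0-based indices fixed by the annotation (NPA triplets + singles)."""
    fixed: set[int] = set()
    for name, pos in PANEL_POSITION_MAP.items():
        if name.startswith("NPA"):
            fixed.update({pos - 1, pos, pos + 1})
        else:
            fixed.add(pos - 1)
    return fixed


def _draw(rng: np.random.Generator, kind: str) -> str:
    if kind == "tm":
        return TM_ALPHABET[rng.choice(len(TM_ALPHABET), p=TM_WEIGHTS)]
    return LOOP_ALPHABET[rng.choice(len(LOOP_ALPHABET), p=LOOP_WEIGHTS)]


def _write_annotation(seq: list[str], residues: dict[str, str]) -> None:
    pm = PANEL_POSITION_MAP
    for motif_name in ("NPA_LB", "NPA_LE"):
        i = pm[motif_name] - 1
        seq[i : i + 3] = list("NPA")
    for name in ("H2", "H5", "LE1", "LE2", "P1", "P2", "P3", "P4", "P5"):
        seq[pm[name] - 1] = residues[name]
    for k, aa in enumerate(residues["SDP"], start=1):
        seq[pm[f"SDP{k}"] - 1] = aa
    # Scrub accidental N-P pairs near the annotated motifs so the nearest
    # N-P-x to each transferred NPA site is the annotated triplet itself.
    for motif_name in ("NPA_LB", "NPA_LE"):
        start = pm[motif_name] - 1
        for i in range(max(0, start - 7), min(len(seq) - 1, start + 9)):
            if i != start and seq[i] == "N" and seq[i + 1] == "P":
                seq[i + 1] = "G"


def build_synthetic_panel() -> list[ReferenceAQP]:
    """Build the 12-member synthetic panel (pure function of its constants)."""
    classes = _position_classes()
    fixed = _mapped_positions()
    panel: list[ReferenceAQP] = []
    for fam_idx, (fam, residues) in enumerate(sorted(SUBFAMILY_RESIDUES.items())):
        rng = np.random.default_rng(_BASE_SEED + fam_idx)
        ancestor = [_draw(rng, k) for k in classes]
        _write_annotation(ancestor, residues)
        for member in range(1, MEMBERS_PER_SUBFAMILY + 1):
            seq = list(ancestor)
            for i, kind in enumerate(classes):
                if i in fixed:
                    continue
                if rng.random() < WITHIN_SUBSTITUTION_RATE:
                    seq[i] = _draw(rng, kind)
            _write_annotation(seq, residues)  # re-scrub after substitutions
            panel.append(
                ReferenceAQP(
                    id=f"ref{fam}-{member}",
                    species="synthetic",
                    subfamily=fam,
                    sequence="".join(seq),
                    position_map=dict(PANEL_POSITION_MAP),
                )
            )
    return panel


def write_panel_files(data_dir: str | Path) -> None:
    """Write the panel FASTA + position-map TSV into ``data_dir``."""
    data_dir = Path(data_dir)
    panel = build_synthetic_panel()
    with open(data_dir / "synthetic_reference_panel.fasta", "w", encoding="utf-8") as fh:
        fh.write(
            ";; SYNTHETIC reference AQP panel — constructed stand-in for a\n"
            ";; hand-annotated panel of characterized aquaporins; see\n"
            ";; mipkit.panel_builder for the construction. 3 members per\n"
            ";; subfamily (PIP, TIP, NIP, SIP).\n"
        )
        for ref in panel:
            fh.write(f">{ref.id} subfamily={ref.subfamily} species={ref.species}\n")
            for i in range(0, len(ref.sequence), 60):
                fh.write(ref.sequence[i : i + 60] + "\n")
    with open(data_dir / "synthetic_reference_panel_positions.tsv", "w", encoding="utf-8") as fh:
        fh.write("# SYNTHETIC panel position map (1-based; NPA_* index the N of the triplet)\n")
        fh.write("id\tsubfamily\t" + "\t".join(POSITION_NAMES) + "\n")
        for ref in panel:
            row = [ref.id, ref.subfamily] + [str(ref.position_map[n]) for n in POSITION_NAMES]
            fh.write("\t".join(row) + "\n")


if __name__ == "__main__":
    write_panel_files(Path(__file__).parent / "data")
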