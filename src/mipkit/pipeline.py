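"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — screen → classify → residues →
properties → genome context → promoters → expression — over whichever
inputs the config provides, skipping (with a logged notice) stages whose
inputs are absent. Outputs are deterministic given config + seed, and the
run log records per-stage record counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import context as ctx
from . import expression as expr
from . import io as mio
from . import phylo, promoter, residues
from . import properties as props
from .fixtures import load_motif_table, load_reference_panel
from .homology import ScoringScheme, screen_candidates
from .msa import progressive_align
from .records import MipkitError, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    proteome: str | None = None
    genome: str | None = None
    gff3: str | None = None
    promoters: str | None = None
    expression: str | None = None
    out_dir: str = "mipkit_out"
    e_cutoff: float = 1e-5
    bit_cutoff: float = 100.0
    bootstrap_replicates: int = 1000
    tandem_gap_bp: int = 100_000
    promoter_length: int = 1000
    fpkm_threshold: float = 0.0
    expression_clusters: int = 4
    seed: int = 0

    def validate(self) -> None:
        for cutoff in (self.e_cutoff, self.bit_cutoff, self.bootstrap_replicates,
                       self.tandem_gap_bp, self.promoter_length):
            if cutoff <= 0:
                raise MipkitError("cutoffs must be positive")
        for path in (self.proteome, self.genome, self.gff3,
                     self.promoters, self.expression):
            if path is not None and not Path(path).exists():
                raise MipkitError(f"input file not found: {path}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value (INI-style, no sections) config file."""
        kwargs: dict = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise MipkitError(f"unknown config key {key!r}")
            if key in ("e_cutoff", "bit_cutoff", "fpkm_threshold"):
                kwargs[key] = float(value)
            elif key in ("bootstrap_replicates", "tandem_gap_bp", "promoter_length",
                         "seed", "expression_clusters"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage the config has inputs for; returns {name: out path}."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    log_lines: list[str] = [f"seed={config.seed}"]
    scheme = ScoringScheme()
    panel = load_reference_panel()
    panel_labels = {r.subfamily + "|" + r.id: r.subfamily for r in panel}

    def emit(name: str, text: str) -> None:
        path = out_dir / name
        path.write_text(text, encoding="utf-8")
        outputs[name] = str(path)

    candidates: list[ProteinRecord] = []
    calls = []
    if config.proteome:
        stage = "screen"
        try:
            proteome = mio.read_fasta(config.proteome)
            retained = screen_candidates(proteome, panel, scheme,
                                         config.e_cutoff, config.bit_cutoff)
        except MipkitError as err:
            raise MipkitError(f"stage {stage}: {err}") from err
        candidates = [rec for rec, _hit in retained]
        rows = [[h.query_id, h.subject_id, f"{h.bit_score:.1f}", f"{h.e_value:.3g}",
                 f"{h.identity_fraction:.3f}", f"{h.query_span[0]}-{h.query_span[1]}",
                 f"{h.subject_span[0]}-{h.subject_span[1]}"]
                for _rec, h in retained]
        emit("candidates.tsv", mio.format_tsv(
            ["query", "subject", "bits", "evalue", "identity", "query_span",
             "subject_span"], rows))
        log_lines.append(f"screen: in={len(proteome)} retained={len(candidates)}")

        if len(candidates) >= 1:
            stage = "classify"
            try:
                ref_records = [ProteinRecord(id=f"{r.subfamily}|{r.id}", sequence=r.sequence)
                               for r in panel]
                msa = progressive_align(candidates + ref_records, scheme)
                tree = phylo.bootstrap_support(msa, config.bootstrap_replicates,
                                               seed=config.seed)
                calls = phylo.assign_subfamilies(tree, panel_labels)
            except MipkitError as err:
                raise MipkitError(f"stage {stage}: {err}") from err
            emit("tree.nwk", tree.to_newick())
            emit("alignment.fasta", msa.to_fasta())
            emit("subfamilies.tsv", mio.format_tsv(
                ["query", "subfamily", "support", "nearest_reference"],
                [[c.query_id, c.subfamily, f"{c.support:.2f}",
                  c.nearest_reference_id] for c in calls]))
            log_lines.append(f"classify: queries={len(calls)}")

            stage = "residues"
            try:
                fam_of = {c.query_id: c.subfamily for c in calls}
                reports = []
                for rec in candidates:
                    fam = fam_of.get(rec.id)
                    ref = residues.best_reference(
                        rec, panel, None if fam in (None, "unclassified") else fam,
                        scheme)
                    reports.append(residues.transfer_positions(rec, ref, scheme))
            except MipkitError as err:
                raise MipkitError(f"stage {stage}: {err}") from err
            res_rows = []
            for rep in reports:
                subs = [s for s, ok, _f in residues.predict_substrates(rep) if ok]
                res_rows.append([rep.gene_id, rep.NPA_LB, rep.NPA_LE, *rep.arR,
                                 *rep.froger,
                                 rep.npa_spacing if rep.npa_spacing is not None else "-",
                                 ",".join(subs) or "-"])
            emit("residues.tsv", mio.format_tsv(
                ["gene", "NPA_LB", "NPA_LE", "H2", "H5", "LE1", "LE2",
                 "P1", "P2", "P3", "P4", "P5", "npa_spacing", "substrates"],
                res_rows))
            log_lines.append(f"residues: reports={len(reports)}")

        stage = "properties"
        try:
            prop_rows = []
            for rec in candidates:
                prop_rows.append([
                    rec.id, len(rec), f"{props.molecular_weight(rec.sequence):.2f}",
                    f"{props.isoelectric_point(rec.sequence):.2f}",
                    f"{props.gravy(rec.sequence):.3f}",
                    len(props.predict_tm_segments(rec.sequence)),
                ])
        except MipkitError as err:
            raise MipkitError(f"stage {stage}: {err}") from err
        emit("properties.tsv", mio.format_tsv(
            ["gene", "length", "MW_kD", "pI", "GRAVY", "n_tm_segments"], prop_rows))
        log_lines.append(f"properties: rows={len(prop_rows)}")
    else:
        log_lines.append("screen/classify/residues/properties: skipped (no proteome)")
        logger.info("no proteome given; sequence stages skipped")

    if config.gff3:
        stage = "context"
        try:
            models = mio.read_gff3(config.gff3)
            stats = [ctx.structure_stats(m) for m in models]
        except MipkitError as err:
            raise MipkitError(f"stage {stage}: {err}") from err
        emit("gene_structure.tsv", mio.format_tsv(
            ["gene", "exons", "introns", "intron_lengths", "span"],
            [[s.gene_id, s.exon_count, s.intron_count,
              ",".join(map(str, s.intron_lengths)) or "-", s.gene_span]
             for s in stats]))
        fam_of = {c.query_id: c.subfamily for c in calls}

        @dataclass
        class _G:
            id: str
            chromosome: str
            start: int
            end: int
            subfamily: str

        genes = [_G(m.gene_id, m.chromosome, m.exons[0][0], m.exons[-1][1],
                    fam_of.get(m.gene_id, "unknown")) for m in models]
        arrays = ctx.detect_tandem_arrays(genes, max_gap_bp=config.tandem_gap_bp)
        emit("tandem_arrays.tsv", mio.format_tsv(
            ["array", "chromosome", "members"],
            [[a.array_id, a.chromosome, ",".join(a.member_gene_ids)] for a in arrays]))
        if config.genome:
            genome = mio.read_nucleotide_fasta(config.genome)
            density = ctx.chromosome_density(genes, {c: len(s) for c, s in genome.items()})
            emit("chromosome_density.tsv", mio.format_tsv(
                ["chromosome", "n_genes"],
                sorted([[c, n] for c, n in density["counts"].items()])))
        log_lines.append(f"context: genes={len(models)} tandem_arrays={len(arrays)}")
    else:
        log_lines.append("context: skipped (no GFF3)")
        logger.info("no GFF3 given; genome-context stage skipped")

    prom_seqs: dict[str, str] = {}
    if config.promoters:
        prom_seqs = mio.read_nucleotide_fasta(config.promoters)
    elif config.genome and config.gff3:
        genome = mio.read_nucleotide_fasta(config.genome)
        for m in mio.read_gff3(config.gff3):
            prom_seqs[m.gene_id] = promoter.extract_upstream(
                genome, m, config.promoter_length)
    if prom_seqs:
        stage = "promoters"
        try:
            motifs = load_motif_table()
            counts, by_cat = promoter.presence_matrix(prom_seqs, motifs)
        except MipkitError as err:
            raise MipkitError(f"stage {stage}: {err}") from err
        motif_names = [m.name for m in motifs]
        emit("promoter_counts.tsv", mio.format_tsv(
            ["gene"] + motif_names,
            [[g] + [counts[g][m] for m in motif_names] for g in sorted(counts)]))
        emit("promoter_categories.tsv", mio.format_tsv(
            ["category", "genes_with_hit"], sorted(by_cat.items())))
        log_lines.append(f"promoters: genes={len(counts)}")
    else:
        log_lines.append("promoters: skipped (no promoters/genome)")

    if config.expression:
        stage = "expression"
        try:
            matrix = expr.ExpressionMatrix.from_tsv(config.expression)
            presence = expr.call_expressed(matrix, config.fpkm_threshold)
            tree = expr.average_linkage(matrix)
            k = min(config.expression_clusters, len(tree.ids))
            clusters = expr.cut_clusters(tree, k)
        except MipkitError as err:
            raise MipkitError(f"stage {stage}: {err}") from err
        emit("expressed.tsv", presence.to_csv(sep="\t"))
        emit("clusters.tsv", mio.format_tsv(
            ["gene", "cluster"], [[g, c] for g, c in clusters.items()]))
        emit("linkage.tsv", expr.linkage_table(tree))
        emit("heatmap.txt", expr.text_heatmap(matrix, tree))
        log_lines.append(f"expression: genes={len(tree.ids)} clusters={k}")
    else:
        log_lines.append("expression: skipped (no matrix)")

    from . import __version__

    emit("run_log.txt", "\n".join([f"mipkit {__version__}"] + log_lines) + "\n")
    return outputs
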