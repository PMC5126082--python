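"""Synthetic-data generators: determinism, ground truth, round-trips."""

import numpy as np
import pytest

from mipkit.records import GeneModel
from mipkit.synth import (
    generate_expression,
    generate_genome,
    generate_promoters,
    generate_proteins,
    reverse_translate,
    spliced_cds,
    translate_cds,
)


class TestProteins:
    def test_rate_zero_reproduces_templates(self, panel):
        recs, manifest = generate_proteins(panel, n_per_subfamily=1,
                                           substitution_rate=0.0, seed=0)
        by_id = {r.id: r for r in panel}
        for rec in recs:
            assert rec.sequence == by_id[manifest.entries[rec.id]["template_id"]].sequence

    def test_same_seed_identical(self, panel):
        a, _ = generate_proteins(panel, n_per_subfamily=2, substitution_rate=0.1,
                                 seed=42)
        b, _ = generate_proteins(panel, n_per_subfamily=2, substitution_rate=0.1,
                                 seed=42)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_mapped_positions_never_substituted(self, panel):
        recs, manifest = generate_proteins(panel, n_per_subfamily=2,
                                           substitution_rate=0.3, seed=8)
        by_id = {r.id: r for r in panel}
        for rec in recs:
            e = manifest.entries[rec.id]
            template = by_id[e["template_id"]]
            protected = set()
            for name, pos in template.position_map.items():
                width = 3 if name.startswith("NPA") else 1
                protected.update(range(pos, pos + width))
            assert not protected & set(e["substitution_positions"])

    def test_invalid_rate_rejected(self, panel):
        with pytest.raises(ValueError):
            generate_proteins(panel, substitution_rate=0.7)


@pytest.fixture(scope="module")
def bundle(panel):
    recs, _ = generate_proteins(panel, n_per_subfamily=1,
                                substitution_rate=0.05, seed=6)
    genome, gff, manifest = generate_genome(
        recs, introns_per_gene=2,
        tandem_arrays=[[recs[0].id, recs[1].id]], seed=6)
    return recs, genome, gff, manifest


class TestGenome:
    def test_intron_spec_round_trip(self, bundle):
        from mipkit.context import structure_stats

        recs, genome, gff, manifest = bundle
        for rec in recs:
            e = manifest.entries[rec.id]
            model = GeneModel(gene_id=rec.id, chromosome=e["chromosome"],
                              strand=e["strand"], exons=e["exons"])
            stats = structure_stats(model)
            assert stats.intron_count == e["n_introns"] == 2
            assert stats.intron_lengths == e["intron_lengths"]
            assert all(ilen >= 76 for ilen in stats.intron_lengths)

    def test_spliced_cds_translates_back(self, bundle):
        recs, genome, _gff, manifest = bundle
        for rec in recs:
            e = manifest.entries[rec.id]
            model = GeneModel(gene_id=rec.id, chromosome=e["chromosome"],
                              strand=e["strand"], exons=e["exons"])
            assert translate_cds(spliced_cds(genome, model)) == rec.sequence

    def test_introns_have_canonical_bounds(self, bundle):
        recs, genome, _gff, manifest = bundle
        for rec in recs:
            e = manifest.entries[rec.id]
            chrom = genome[e["chromosome"]]
            for (s1, e1), (s2, _e2) in zip(e["exons"], e["exons"][1:]):
                intron = chrom[e1 : s2 - 1]
                if e["strand"] == "+":
                    assert intron.startswith("GT") and intron.endswith("AG")
                else:
                    assert intron.startswith("CT") and intron.endswith("AC")

    def test_gff_consistent_with_fasta(self, bundle, tmp_path):
        from mipkit.io import read_gff3

        recs, genome, gff, manifest = bundle
        path = tmp_path / "g.gff3"
        path.write_text(gff)
        models = {m.gene_id: m for m in read_gff3(path)}
        for rec in recs:
            e = manifest.entries[rec.id]
            assert models[rec.id].exons == e["exons"]
            assert e["end"] <= len(genome[e["chromosome"]])

    def test_tandem_spec_round_trips_through_detection(self, panel):
        from mipkit.context import detect_tandem_arrays

        recs, pman = generate_proteins(panel, n_per_subfamily=1,
                                       substitution_rate=0.05, seed=9)
        trio = [r.id for r in recs[:3]]
        _genome, _gff, manifest = generate_genome(
            recs, tandem_arrays=[trio], seed=9)

        class G:
            pass

        genes = []
        for rec in recs:
            g = G()
            e = manifest.entries[rec.id]
            g.id, g.chromosome, g.start, g.end = rec.id, e["chromosome"], e["start"], e["end"]
            g.subfamily = "ARRAY" if rec.id in trio else f"solo-{rec.id}"
            genes.append(g)
        arrays = detect_tandem_arrays(genes, max_gap_bp=10_000)
        assert [sorted(a.member_gene_ids) for a in arrays] == [sorted(trio)]

    def test_reverse_translate_inverse(self):
        assert translate_cds(reverse_translate("NPAVTWK")) == "NPAVTWK"


class TestPromoters:
    def test_same_seed_identical(self):
        a, _ = generate_promoters(["g1", "g2"], seed=3)
        b, _ = generate_promoters(["g1", "g2"], seed=3)
        assert a == b

    def test_planted_motif_found_at_position(self, motif_table):
        from mipkit.promoter import iupac_scan

        seqs, _ = generate_promoters(
            ["g"], plantings={"g": [("circadian", "CAATTTTATC", 101, "+")]},
            seed=1)
        motif = next(m for m in motif_table if m.name == "circadian")
        assert 101 in [h.start for h in iupac_scan(seqs["g"], motif)]

    def test_overflow_planting_rejected(self):
        with pytest.raises(ValueError):
            generate_promoters(["g"],
                               plantings={"g": [("circadian", "CAATTTTATC",
                                                 995, "+")]}, seed=1)

    def test_gc_content_near_requested(self):
        seqs, _ = generate_promoters(["g"], background_gc=0.6, length=5000, seed=2)
        gc = sum(c in "GC" for c in seqs["g"]) / 5000
        assert gc == pytest.approx(0.6, abs=0.03)


class TestExpression:
    def test_zero_noise_rows_are_exact_centroid_multiples(self):
        matrix, manifest = generate_expression(n_genes=8, k_clusters=2,
                                               within_noise_sd=0.0, seed=4)
        centroids = np.array(manifest.params["centroids"])
        for gid in matrix.genes:
            e = manifest.entries[gid]
            row = matrix.data.loc[gid].to_numpy()
            expected = centroids[e["cluster"] - 1] * e["scale"]
            assert np.allclose(row, expected)

    def test_same_seed_identical(self):
        a, _ = generate_expression(seed=10)
        b, _ = generate_expression(seed=10)
        assert a.data.equals(b.data)

    def test_values_nonnegative(self):
        matrix, _ = generate_expression(seed=1, within_noise_sd=0.5)
        assert (matrix.data.to_numpy() >= 0).all()


class TestManifestCoverage:
    """Every manifest field is consumed by a test somewhere in the suite;
    this guards the schema those tests rely on."""

    def test_protein_manifest_schema(self, panel):
        _recs, m = generate_proteins(panel, n_per_subfamily=1, seed=0)
        entry = next(iter(m.entries.values()))
        assert set(entry) == {"template_id", "subfamily", "substitution_positions",
                              "indels", "NPA_LB", "NPA_LE", "arR", "froger", "sdp"}

    def test_genome_manifest_schema(self, panel):
        recs, _ = generate_proteins(panel, n_per_subfamily=1, seed=0)
        _g, _gff, m = generate_genome(recs[:2], tandem_arrays=[[recs[0].id,
                                                                recs[1].id]],
                                      seed=0)
        entry = m.entries[recs[0].id]
        assert set(entry) == {"tandem_array", "chromosome", "strand", "start",
                              "end", "exons", "n_introns", "intron_lengths", "cds"}

    def test_promoter_manifest_schema(self):
        _s, m = generate_promoters(["g"], seed=0)
        assert set(m.entries["g"]) == {"planted", "oracle_counts"}

    def test_expression_manifest_schema(self):
        _x, m = generate_expression(n_genes=4, k_clusters=2, seed=0)
        assert set(next(iter(m.entries.values()))) == {"cluster", "scale"}
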