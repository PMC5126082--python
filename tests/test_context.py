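"""Gene structure, chromosome density and duplication detection."""

from dataclasses import dataclass

import numpy as np
import pytest

from mipkit.context import (
    AnchorPair,
    chromosome_density,
    detect_segmental_pairs,
    detect_tandem_arrays,
    structure_stats,
)
from mipkit.records import GeneModel, MipkitError


@dataclass
class Gene:
    id: str
    chromosome: str
    start: int
    end: int
    subfamily: str


class TestStructureStats:
    def test_two_exons_one_intron(self):
        m = GeneModel(gene_id="g", chromosome="c", strand="+",
                      exons=[(1, 100), (201, 300)])
        s = structure_stats(m)
        assert s.intron_count == 1
        assert s.intron_lengths == [100]
        assert s.gene_span == 299

    def test_single_exon_no_introns(self):
        s = structure_stats(GeneModel(gene_id="g", chromosome="c", strand="+",
                                      exons=[(10, 500)]))
        assert s.intron_count == 0 and s.intron_lengths == []

    def test_printed_span_convention(self):
        # one-exon span over the printed coordinates of the shortest gene
        s = structure_stats(GeneModel(gene_id="CaTIP3-1", chromosome="Ca4",
                                      strand="+", exons=[(3990175, 3991038)]))
        assert s.gene_span == 863

    def test_overlapping_exons_rejected(self):
        with pytest.raises(MipkitError):
            GeneModel(gene_id="g", chromosome="c", strand="+",
                      exons=[(1, 100), (50, 200)])

    def test_length_bookkeeping_on_random_models(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_exons = int(rng.integers(1, 6))
            pos = 1
            exons = []
            for _e in range(n_exons):
                length = int(rng.integers(50, 400))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(60, 500))
            s = structure_stats(GeneModel(gene_id="g", chromosome="c",
                                          strand="+", exons=exons))
            exon_total = sum(e - b + 1 for b, e in exons)
            assert exon_total + sum(s.intron_lengths) == s.gene_span + 1

    def test_fixture_span_extremes(self, tables):
        rows1, _ = tables
        spans = {r.proposed_name: r.span for r in rows1}
        assert min(spans, key=spans.get) == "CaTIP3-1"
        assert max(spans, key=spans.get) == "CaNIP2-1"
        assert spans["CaTIP3-1"] == 863 and spans["CaNIP2-1"] == 4382


class TestDensity:
    def test_definition(self):
        genes = [Gene(f"g{i}", "c1", i, i + 1, "PIP") for i in range(40)]
        out = chromosome_density(genes, {"c1": 532_000_000})
        assert out["mb_per_gene"] == pytest.approx(13.3)

    def test_fixture_chromosome_counts(self, tables):
        rows1, _ = tables
        genes = [Gene(r.proposed_name, r.chromosome, r.start, r.end, r.subfamily)
                 for r in rows1]
        lengths = {f"Ca{i}": 1 for i in range(1, 9)}
        out = chromosome_density(genes, lengths)
        counts = out["counts"]
        assert counts["Ca6"] == 10
        assert counts["Ca6"] == max(counts[c] for c in lengths)
        assert counts["Ca5"] == 2 and counts["Ca7"] == 0
        assert counts["unplaced"] == 2

    def test_empty_chromosome_reported_as_zero(self):
        genes = [Gene("g", "c1", 1, 2, "PIP")]
        out = chromosome_density(genes, {"c1": 100, "c2": 100})
        assert out["counts"]["c2"] == 0

    def test_zero_genes_error(self):
        with pytest.raises(MipkitError):
            chromosome_density([], {"c1": 100})


class TestTandem:
    def test_adjacent_pair_chains(self):
        genes = [Gene("a", "c1", 1000, 2000, "NIP"),
                 Gene("b", "c1", 6000, 7000, "NIP")]
        arrays = detect_tandem_arrays(genes)
        assert len(arrays) == 1 and arrays[0].member_gene_ids == ["a", "b"]

    def test_distance_cap_blocks_chain(self):
        genes = [Gene("a", "c1", 1000, 2000, "NIP"),
                 Gene("b", "c1", 501_000, 502_000, "NIP")]
        assert detect_tandem_arrays(genes) == []

    def test_intervening_gene_cap(self):
        genes = [Gene("a", "c1", 1_000, 2_000, "NIP"),
                 Gene("x1", "c1", 3_000, 4_000, "PIP"),
                 Gene("x2", "c1", 5_000, 6_000, "PIP"),
                 Gene("b", "c1", 7_000, 8_000, "NIP")]
        strict = detect_tandem_arrays(genes, max_intervening=1)
        assert not any("a" in a.member_gene_ids for a in strict)
        arrays = detect_tandem_arrays(genes, max_intervening=2)
        assert [a.member_gene_ids for a in arrays if a.member_gene_ids[0] == "a"] \
            == [["a", "b"]]

    def test_fixture_ca6_nip_block(self, tables):
        rows1, _ = tables
        genes = [Gene(r.proposed_name, r.chromosome, r.start, r.end, r.subfamily)
                 for r in rows1]
        arrays = detect_tandem_arrays(genes)
        members = {frozenset(a.member_gene_ids) for a in arrays}
        assert frozenset({"CaNIP1-3", "CaNIP1-4", "CaNIP1-5"}) in members

    def test_fixture_all_arrays(self, tables):
        rows1, _ = tables
        genes = [Gene(r.proposed_name, r.chromosome, r.start, r.end, r.subfamily)
                 for r in rows1]
        arrays = detect_tandem_arrays(genes)
        members = {frozenset(a.member_gene_ids) for a in arrays}
        assert members == {
            frozenset({"CaNIP1-6", "CaNIP1-7", "CaNIP1-8", "CaNIP1-9"}),
            frozenset({"CaTIP4-1", "CaTIP4-2"}),
            frozenset({"CaNIP1-3", "CaNIP1-4", "CaNIP1-5"}),
        }
        for a in arrays:
            assert len({g for g in a.member_gene_ids}) >= 2

    def test_invariant_to_input_order(self, tables):
        rows1, _ = tables
        genes = [Gene(r.proposed_name, r.chromosome, r.start, r.end, r.subfamily)
                 for r in rows1]
        fwd = {frozenset(a.member_gene_ids) for a in detect_tandem_arrays(genes)}
        rev = {frozenset(a.member_gene_ids)
               for a in detect_tandem_arrays(list(reversed(genes)))}
        assert fwd == rev

    def test_arrays_never_span_chromosomes(self, tables):
        rows1, _ = tables
        genes = [Gene(r.proposed_name, r.chromosome, r.start, r.end, r.subfamily)
                 for r in rows1]
        by_name = {g.id: g.chromosome for g in genes}
        for a in detect_tandem_arrays(genes):
            assert len({by_name[m] for m in a.member_gene_ids}) == 1


class TestSegmental:
    def _block(self, flip=False):
        anchors = []
        for i in range(5):
            b_pos = (5 - i) * 10_000 if flip else i * 10_000
            anchors.append(AnchorPair(f"a{i}", "c1", i * 10_000,
                                      f"b{i}", "c2", b_pos,
                                      is_aqp=(i == 2)))
        return anchors

    def test_collinear_block_flags_aqp_pair(self):
        calls = detect_segmental_pairs(self._block())
        assert len(calls) == 1
        assert calls[0].member_gene_ids == ["a2", "b2"]
        assert calls[0].kind == "segmental"

    def test_shuffled_anchors_no_call(self):
        anchors = self._block()
        positions = [30_000, 0, 40_000, 10_000, 20_000]
        for a, p in zip(anchors, positions):
            a.b_pos = p
        assert detect_segmental_pairs(anchors, min_chain=4) == []

    def test_inverted_block_found_by_descending_pass(self):
        calls = detect_segmental_pairs(self._block(flip=True))
        assert [c.member_gene_ids for c in calls] == [["a2", "b2"]]
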