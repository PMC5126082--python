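"""Progressive alignment, distance matrices, NJ trees, bootstrap and
subfamily assignment."""

import itertools
import math

import numpy as np
import pytest

from mipkit.msa import GAP, progressive_align
from mipkit.phylo import (
    DistanceMatrix,
    Msa,
    assign_subfamilies,
    bootstrap_support,
    distance_matrix,
    nj_tree,
)
from mipkit.records import MipkitError, ProteinRecord
from mipkit.synth import generate_proteins

from .oracles import enumerate_global_score, quartet_least_squares


def _msa_pair_identity(msa: Msa, a: str, b: str) -> float:
    ra, rb = msa.row(a), msa.row(b)
    comp = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
    return sum(1 for x, y in comp if x == y) / len(comp)


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self, scheme):
        recs = [ProteinRecord(id="a", sequence="NPAVTWK"),
                ProteinRecord(id="b", sequence="NPAVTWK")]
        msa = progressive_align(recs, scheme)
        assert msa.rows[0] == msa.rows[1] == "NPAVTWK"

    def test_single_sequence_rejected(self, scheme):
        with pytest.raises(MipkitError):
            progressive_align([ProteinRecord(id="a", sequence="NPA")], scheme)

    def test_ungapping_recovers_inputs(self, panel, scheme):
        recs = [ProteinRecord(id=r.id, sequence=r.sequence) for r in panel[:5]]
        msa = progressive_align(recs, scheme)
        for r in recs:
            assert msa.ungapped(r.id) == r.sequence

    def test_pair_score_matches_exhaustive_dp(self, scheme):
        a, b = "ACDEF", "ACEF"
        msa = progressive_align([ProteinRecord(id="a", sequence=a),
                                 ProteinRecord(id="b", sequence=b)], scheme)
        score = 0.0
        state = "m"
        for x, y in zip(msa.rows[0], msa.rows[1]):
            if GAP in (x, y):
                score -= scheme.gap_extend if state == "g" else \
                    scheme.gap_open + scheme.gap_extend
                state = "g"
            else:
                score += scheme.score(x, y)
                state = "m"
        oracle = enumerate_global_score(a, b, scheme.score,
                                        scheme.gap_open, scheme.gap_extend)
        assert score == pytest.approx(oracle)

    def test_within_subfamily_identity_exceeds_between(self, panel, scheme):
        recs, manifest = generate_proteins(panel, n_per_subfamily=2,
                                           substitution_rate=0.08, seed=9)
        subset = [r for r in recs if manifest.entries[r.id]["subfamily"]
                  in ("PIP", "TIP", "NIP")]
        msa = progressive_align(subset, scheme)
        fam = {r.id: manifest.entries[r.id]["subfamily"] for r in subset}
        within, between = [], []
        for a, b in itertools.combinations([r.id for r in subset], 2):
            (within if fam[a] == fam[b] else between).append(
                _msa_pair_identity(msa, a, b))
        assert min(within) > max(between)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = Msa(ids=["a", "b"], rows=["NPAVT", "NPAVT"])
        assert distance_matrix(msa).data[0, 1] == 0.0

    def test_p_distance_with_pairwise_deletion(self):
        # 12 columns, 2 gapped in one row -> 10 comparable, 2 mismatches
        msa = Msa(ids=["a", "b"],
                  rows=["ACDEFGHIKLMN", "ACDEFGHIY--W"])
        d = distance_matrix(msa)
        assert d.data[0, 1] == pytest.approx(2 / 10)

    def test_poisson_correction(self):
        msa = Msa(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAAAAACC"])
        d = distance_matrix(msa, model="poisson")
        assert d.data[0, 1] == pytest.approx(-math.log(0.8), abs=1e-9)

    def test_no_comparable_columns_names_pair(self):
        msa = Msa(ids=["x", "y"], rows=["AA--", "--CC"])
        with pytest.raises(MipkitError, match="x.*y|y.*x"):
            distance_matrix(msa)


def _tree_distances(tree):
    index, mat = tree.patristic_distances()
    return index, mat


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=ids, data=d))
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths["a"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["b"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["c"] == pytest.approx((6 + 8 - 4) / 2)

    def test_additive_four_taxon_matches_least_squares_oracle(self):
        # true tree: (a,b) cherry vs (c,d); internal 3, tips 1,2,4,5
        ids = ["a", "b", "c", "d"]
        tip = {"a": 1.0, "b": 2.0, "c": 4.0, "d": 5.0}
        internal = 3.0
        d = np.zeros((4, 4))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i == j:
                    continue
                cross = internal if {x, y} not in ({"a", "b"}, {"c", "d"}) else 0.0
                d[i, j] = tip[x] + tip[y] + cross
        split, lengths = quartet_least_squares(ids, d)
        assert split in (frozenset({"a", "b"}), frozenset({"c", "d"}))
        tree = nj_tree(DistanceMatrix(ids=ids, data=d))
        assert frozenset({"a", "b"}) in tree.bipartitions() or \
            frozenset({"c", "d"}) in tree.bipartitions()
        index, mat = _tree_distances(tree)
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                assert mat[index[x], index[y]] == pytest.approx(d[i, j], abs=1e-9)

    def test_additive_six_taxon_path_lengths_exact(self):
        # caterpillar tree with distinct branch lengths
        rng = np.random.default_rng(3)
        n = 6
        ids = [f"t{i}" for i in range(n)]
        # build additive distances from a random binary tree embedding:
        # chain internal nodes 0..3, tips hang off with random lengths
        tip_len = rng.uniform(0.5, 2.0, size=n)
        chain = rng.uniform(0.3, 1.0, size=3)
        node_of_tip = [0, 0, 1, 2, 3, 3]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ni, nj = node_of_tip[i], node_of_tip[j]
                path = chain[min(ni, nj):max(ni, nj)].sum()
                d[i, j] = d[j, i] = tip_len[i] + tip_len[j] + path
        tree = nj_tree(DistanceMatrix(ids=ids, data=d))
        index, mat = _tree_distances(tree)
        for i in range(n):
            for j in range(n):
                assert mat[index[ids[i]], index[ids[j]]] == \
                    pytest.approx(d[i, j], abs=1e-9)

    def test_ultrametric_pairs_join_first(self):
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0.0, 0.2, 1.0, 1.0],
            [0.2, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.2],
            [1.0, 1.0, 0.2, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(ids=ids, data=d))
        bps = set(tree.bipartitions())
        assert frozenset({"c", "d"}) in bps or frozenset({"a", "b"}) in bps

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MipkitError):
            DistanceMatrix(ids=["a", "b", "c"],
                           data=np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))


class TestBootstrap:
    def _toy_msa(self):
        # two clean clades (a vs b) plus two noisy tail columns
        return Msa(ids=["a1", "a2", "b1", "b2"],
                   rows=["AAAAAAAAAAAAAAAAAADD",
                         "AAAAAAAAAAAAAAAAAAEE",
                         "TTTTTTTTTTTTTTTTTTDD",
                         "TTTTTTTTTTTTTTTTTTEE"])

    def test_strong_split_high_support(self):
        tree = bootstrap_support(self._toy_msa(), n_replicates=100, seed=1)
        bps = tree.bipartitions()
        split = frozenset({"b1", "b2"})
        assert split in bps
        assert bps[split].support >= 95

    def test_same_seed_identical_supports(self):
        t1 = bootstrap_support(self._toy_msa(), n_replicates=30, seed=4)
        t2 = bootstrap_support(self._toy_msa(), n_replicates=30, seed=4)
        s1 = {bp: node.support for bp, node in t1.bipartitions().items()}
        s2 = {bp: node.support for bp, node in t2.bipartitions().items()}
        assert s1 == s2

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_support(self._toy_msa(), n_replicates=1, seed=0)
        for _bp, node in tree.bipartitions().items():
            assert node.support in (0.0, 100.0)


class TestAssignSubfamilies:
    def _tree_with_refs(self, panel, scheme, queries):
        refs = [ProteinRecord(id=r.id, sequence=r.sequence) for r in panel]
        msa = progressive_align(queries + refs, scheme)
        return nj_tree(distance_matrix(msa))

    def test_identical_query_called_pip(self, panel, scheme):
        pip = next(r for r in panel if r.subfamily == "PIP")
        q = ProteinRecord(id="query1", sequence=pip.sequence)
        tree = self._tree_with_refs(panel, scheme, [q])
        calls = assign_subfamilies(tree, {r.id: r.subfamily for r in panel})
        call = next(c for c in calls if c.query_id == "query1")
        assert call.subfamily == "PIP"

    def test_synthetic_queries_all_recovered(self, panel, scheme):
        recs, manifest = generate_proteins(panel, n_per_subfamily=2,
                                           substitution_rate=0.1, seed=21)
        tree = self._tree_with_refs(panel, scheme, recs)
        calls = assign_subfamilies(tree, {r.id: r.subfamily for r in panel})
        for c in calls:
            assert c.subfamily == manifest.entries[c.query_id]["subfamily"]

    def test_calls_invariant_under_leaf_permutation(self, panel, scheme):
        recs, _ = generate_proteins(panel, n_per_subfamily=1,
                                    substitution_rate=0.1, seed=13)
        labels = {r.id: r.subfamily for r in panel}
        t1 = self._tree_with_refs(panel, scheme, recs)
        t2 = self._tree_with_refs(list(reversed(panel)), scheme,
                                  list(reversed(recs)))
        c1 = {c.query_id: c.subfamily for c in assign_subfamilies(t1, labels)}
        c2 = {c.query_id: c.subfamily for c in assign_subfamilies(t2, labels)}
        assert c1 == c2

    def test_no_reference_leaves_errors(self, panel, scheme):
        recs = [ProteinRecord(id=r.id, sequence=r.sequence) for r in panel[:4]]
        msa = progressive_align(recs, scheme)
        tree = nj_tree(distance_matrix(msa))
        with pytest.raises(MipkitError):
            assign_subfamilies(tree, {"absent": "PIP"})

    def test_chimera_between_subfamilies_unclassified(self):
        # additive tree with cherries (refP,refT) and (chimera,other); the
        # chimera is exactly equidistant from the two subfamily references
        ids = ["chimera", "refP", "refT", "other"]
        d = np.array([
            [0.0, 1.0, 1.0, 0.2],
            [1.0, 0.0, 0.2, 1.0],
            [1.0, 0.2, 0.0, 1.0],
            [0.2, 1.0, 1.0, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(ids=ids, data=d))
        calls = assign_subfamilies(tree, {"refP": "PIP", "refT": "TIP"})
        call = next(c for c in calls if c.query_id == "chimera")
        assert call.subfamily == "unclassified"
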