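"""Distance matrices, neighbor-joining trees, bootstrap supports and
subfamily assignment.

The subfamily call for a query follows a clade rule on the NJ tree built
from candidates plus the annotated reference panel: the smallest edge
bipartition grouping the query with at least one reference decides its
subfamily when those references are unanimous; otherwise the nearest
reference by patristic distance decides, and a tie between subfamilies
leaves the query unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, Msa
from .records import MipkitError

_GAPCODE = 255


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, keyed by ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise MipkitError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise MipkitError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise MipkitError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise MipkitError("distance matrix has negative entries")
        self.data = d


class Node:
    """A tree node; leaves carry names, internal edges carry supports."""

    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def traverse(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def tips(self) -> list["Node"]:
        return [n for n in self.traverse() if not n.children]

    def tip_set(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tips())


@dataclass
class PhyloTree:
    """Unrooted NJ tree (stored with a trifurcating root node)."""

    root: Node
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = sorted(self.root.tip_set())
        names = [t.name for t in self.root.tips()]
        if len(names) != len(set(names)):
            raise MipkitError("duplicate leaf labels")

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Internal (non-trivial) bipartitions, keyed canonically by the
        side not containing the lexicographically smallest leaf."""
        anchor = min(self.ids)
        out: dict[frozenset[str], Node] = {}
        for node in self.root.traverse():
            if node is self.root or not node.children:
                continue
            side = node.tip_set()
            if anchor in side:
                side = frozenset(self.ids) - side
            if 1 < len(side) < len(self.ids) - 1:
                out[side] = node
        return out

    def patristic_distances(self) -> tuple[dict[str, int], np.ndarray]:
        """(leaf name → index, matrix of tip-to-tip path lengths)."""
        tips = sorted(self.root.tip_set())
        index = {t: i for i, t in enumerate(tips)}
        n = len(tips)
        dist = np.zeros((n, n))

        def below(node) -> dict[str, float]:
            if not node.children:
                return {node.name: 0.0}
            sub = [below(c) for c in node.children]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    ca, cb = node.children[a], node.children[b]
                    for ta, da in sub[a].items():
                        for tb, db in sub[b].items():
                            d = da + ca.length + db + cb.length
                            dist[index[ta], index[tb]] = dist[index[tb], index[ta]] = d
            merged: dict[str, float] = {}
            for c, s in zip(node.children, sub):
                for t, d in s.items():
                    merged[t] = d + c.length
            return merged

        below(self.root)
        return index, dist

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _encode(msa: Msa) -> np.ndarray:
    arr = np.frombuffer("".join(msa.rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(msa.rows), msa.n_columns).copy()
    arr[arr == ord(GAP)] = _GAPCODE
    return arr


def _pairwise_p(codes: np.ndarray, strict: bool = True,
                pair_ids: list[str] | None = None) -> np.ndarray:
    valid = codes != _GAPCODE
    comp = (valid[:, None, :] & valid[None, :, :])
    mism = comp & (codes[:, None, :] != codes[None, :, :])
    ncomp = comp.sum(axis=2)
    with np.errstate(invalid="ignore"):
        p = np.where(ncomp > 0, mism.sum(axis=2) / np.maximum(ncomp, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    if np.isnan(p).any():
        if strict:
            i, j = np.argwhere(np.isnan(p))[0]
            a = pair_ids[i] if pair_ids else str(i)
            b = pair_ids[j] if pair_ids else str(j)
            raise MipkitError(f"no comparable columns between {a} and {b}")
        p[np.isnan(p)] = np.nanmax(p) if np.isfinite(np.nanmax(p)) else 1.0
    return p


def distance_matrix(msa: Msa, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap columns.

    ``model`` is ``p-distance`` (mismatch fraction) or ``poisson``
    (−ln(1−p), the Poisson multiple-hit correction).
    """
    if len(msa.rows) < 2:
        raise MipkitError("need ≥2 aligned rows")
    p = _pairwise_p(_encode(msa), strict=True, pair_ids=msa.ids)
    if model in ("p", "p-distance"):
        d = p
    elif model in ("poisson", "Poisson-corrected"):
        if np.any(p >= 1.0):
            raise MipkitError("Poisson correction undefined for p ≥ 1")
        d = -np.log1p(-p)
    else:
        raise MipkitError(f"unknown distance model {model!r}")
    return DistanceMatrix(ids=list(msa.ids), data=d)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Ties in the Q matrix break to the lowest (row, column) index pair.
    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling branch.
    """
    n = len(d.ids)
    if n < 3:
        raise MipkitError("neighbor joining needs ≥3 taxa")
    mat = d.data.copy()
    nodes: list[Node] = [Node(name=i) for i in d.ids]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = (math.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = mat[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_row = 0.5 * (mat[i, :] + mat[j, :] - dij)
        mat = np.vstack([mat, new_row])
        new_col = np.append(new_row, 0.0)
        mat = np.column_stack([mat, new_col])
        nodes.append(parent)
        k = mat.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    # final trifurcation
    i, j, k = active
    root = Node()
    dij, dik, djk = mat[i, j], mat[i, k], mat[j, k]
    nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    for x in (i, j, k):
        root.add(nodes[x])
    return PhyloTree(root=root, ids=sorted(d.ids))


def _replicate_bipartitions(codes: np.ndarray, ids: list[str],
                            rng: np.random.Generator, model: str) -> set[frozenset[str]]:
    ncol = codes.shape[1]
    idx = rng.integers(0, ncol, size=ncol)
    p = _pairwise_p(codes[:, idx], strict=False)
    if model in ("poisson", "Poisson-corrected"):
        p = -np.log1p(-np.minimum(p, 0.999999))
    tree = nj_tree(DistanceMatrix(ids=ids, data=p))
    return set(tree.bipartitions().keys())


def bootstrap_support(msa: Msa, n_replicates: int = 1000, seed: int = 0,
                      model: str = "p-distance") -> PhyloTree:
    """NJ tree with internal-edge supports from column-resampling bootstrap.

    Replicate ``r`` uses its own generator seeded ``seed + r`` so the run
    is reproducible under any execution order.
    """
    if n_replicates < 1:
        raise MipkitError("need ≥1 bootstrap replicate")
    main = nj_tree(distance_matrix(msa, model))
    codes = _encode(msa)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in main.bipartitions()}
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        reps = _replicate_bipartitions(codes, list(msa.ids), rng, model)
        for bp in counts:
            if bp in reps:
                counts[bp] += 1
    for bp, node in main.bipartitions().items():
        node.support = 100.0 * counts[bp] / n_replicates
    return main


@dataclass
class SubfamilyCall:
    query_id: str
    subfamily: str
    support: float
    nearest_reference_id: str


def assign_subfamilies(tree: PhyloTree, panel_labels: dict[str, str]) -> list[SubfamilyCall]:
    """Call a subfamily for every non-reference leaf of ``tree``.

    ``panel_labels`` maps reference leaf ids to subfamily names. See the
    module docstring for the clade rule and its fallback.
    """
    leaves = set(tree.root.tip_set())
    refs = {r for r in panel_labels if r in leaves}
    if not refs:
        raise MipkitError("tree contains no reference leaves")
    queries = sorted(leaves - set(panel_labels))

    sides: list[tuple[frozenset[str], Node]] = []
    full = frozenset(leaves)
    for node in tree.root.traverse():
        if node is tree.root:
            continue
        s = node.tip_set()
        sides.append((s, node))
        sides.append((full - s, node))

    index, pat = tree.patristic_distances()
    calls: list[SubfamilyCall] = []
    for q in queries:
        ref_dists = sorted((pat[index[q], index[r]], r) for r in refs)
        nearest_d, nearest = ref_dists[0]
        candidates = [
            (len(s), s, node) for s, node in sides if q in s and s & refs
        ]
        candidates.sort(key=lambda t: t[0])
        subfamily = "unclassified"
        support = 0.0
        if candidates:
            min_size = candidates[0][0]
            minimal = [(s, node) for sz, s, node in candidates if sz == min_size]
            fams = {panel_labels[r] for s, _node in minimal for r in s & refs}
            if len(fams) == 1:
                subfamily = fams.pop()
                side, node = minimal[0]
                support = (node.support or 0.0) / 100.0
                nearest = min(side & refs, key=lambda r: pat[index[q], index[r]])
        if subfamily == "unclassified":
            tied = {panel_labels[r] for dd, r in ref_dists if dd <= nearest_d + 1e-9}
            if len(tied) == 1:
                subfamily = tied.pop()
        calls.append(SubfamilyCall(query_id=q, subfamily=subfamily,
                                   support=support, nearest_reference_id=nearest))
    return calls
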