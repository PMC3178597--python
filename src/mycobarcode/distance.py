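"""Kimura two-parameter distances, distance matrices, neighbor-joining trees.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over compared
sites.  Sites are compared under pairwise deletion: any column holding a
gap or a non-ACGT symbol in either sequence is excluded.  When the log
arguments are non-positive (observed divergence beyond the model's
measurable range) the distance is UNDEFINED, represented as ``d is None``
in :class:`K2PResult` and as NaN inside :class:`DistanceMatrix`; such
entries are never silently replaced here — downstream barcode-gap code
maps them to the capped value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_ACGT = b"ACGT"
#: purines / pyrimidines, used to classify substitution type
_PURINES = frozenset(b"AG")


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class K2PResult:
    """Transition/transversion proportions and the resulting K2P distance.

    ``d is None`` flags an UNDEFINED distance (saturated divergence or no
    comparable sites).
    """

    P: float
    Q: float
    sites: int
    d: float | None

    @property
    def defined(self) -> bool:
        return self.d is not None

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


def k2p_distance(aligned_a: str, aligned_b: str) -> K2PResult:
    """K2P-corrected distance between two rows of an alignment.

    Both strings must be equal length; columns with a gap or ambiguity
    code in either row are excluded (pairwise deletion).
    """
    if len(aligned_a) != len(aligned_b):
        raise DistanceError(
            f"aligned sequences differ in length ({len(aligned_a)} vs {len(aligned_b)})"
        )
    a = np.frombuffer(aligned_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(aligned_b.upper().encode(), dtype=np.uint8)
    good_a = np.isin(a, np.frombuffer(_ACGT, dtype=np.uint8))
    good_b = np.isin(b, np.frombuffer(_ACGT, dtype=np.uint8))
    keep = good_a & good_b
    sites = int(keep.sum())
    if sites == 0:
        return K2PResult(P=0.0, Q=0.0, sites=0, d=None)
    a, b = a[keep], b[keep]
    diff = a != b
    pur_a = (a == ord("A")) | (a == ord("G"))
    pur_b = (b == ord("A")) | (b == ord("G"))
    transitions = int((diff & (pur_a == pur_b)).sum())
    transversions = int((diff & (pur_a != pur_b)).sum())
    P = transitions / sites
    Q = transversions / sites
    w = 1.0 - 2.0 * P - Q
    z = 1.0 - 2.0 * Q
    if w <= 0.0 or z <= 0.0:
        return K2PResult(P=P, Q=Q, sites=sites, d=None)
    d = -0.5 * math.log(w * math.sqrt(z))
    return K2PResult(P=P, Q=Q, sites=sites, d=d)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; NaN entries mark UNDEFINED pairs."""

    ids: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DistanceError("distance matrix shape does not match ids")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())


def matrix_from_msa(msa) -> DistanceMatrix:
    """All-pairs K2P distances over the rows of a multiple alignment."""
    if len(msa) < 2:
        raise DistanceError("need at least 2 aligned records")
    length = len(msa[0].residues)
    for rec in msa:
        if len(rec.residues) != length:
            raise DistanceError(f"ragged alignment: record {rec.id!r}")
    n = len(msa)
    values = np.zeros((n, n), dtype=float)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(msa[i].residues, msa[j].residues)
            if res.defined:
                values[i, j] = values[j, i] = res.d
            else:
                values[i, j] = values[j, i] = np.nan
                undefined.append((msa[i].id, msa[j].id))
    return DistanceMatrix(ids=[r.id for r in msa], values=values, undefined_pairs=undefined)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label] if self.label is not None else [None]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


class Tree:
    """Unrooted tree stored with an arbitrary root node.

    Leaf labels are sequence ids; branch lengths are non-negative.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def _newick(self, node: TreeNode) -> str:
        if node.is_leaf:
            if not node.label:
                raise DistanceError("cannot serialize tree with an unlabeled leaf")
            if any(ch in node.label for ch in ";,():[]"):
                raise DistanceError(f"illegal character in leaf label {node.label!r}")
            return f"{node.label}:{node.length:g}"
        inner = ",".join(self._newick(c) for c in node.children)
        if node is self.root:
            return f"({inner})"
        return f"({inner}):{node.length:g}"

    def to_newick(self) -> str:
        return self._newick(self.root) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each given as the smaller-or-equal side's leaf set."""
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset[str]] = set()

        def walk(node):
            below = frozenset(node.leaf_labels())
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            for c in node.children:
                walk(c)

        walk(self.root)
        return splits

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (the additive distances of the tree)."""
        labels = sorted(self.leaf_labels())
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n), dtype=float)

        def walk(node) -> dict[str, float]:
            # distances from every leaf below `node` up to `node`
            if node.is_leaf:
                return {node.label: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                m = {lab: d + c.length for lab, d in walk(c).items()}
                child_maps.append(m)
            for ia in range(len(child_maps)):
                for ib in range(ia + 1, len(child_maps)):
                    for la, da in child_maps[ia].items():
                        for lb, db in child_maps[ib].items():
                            values[idx[la], idx[lb]] = values[idx[lb], idx[la]] = da + db
            for m in child_maps:
                below.update(m)
            return below

        walk(self.root)
        return DistanceMatrix(ids=labels, values=values)


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are broken by the lexicographically smallest
    joined pair (each cluster keyed by its smallest leaf label); negative
    branch-length estimates are clamped to zero.
    """
    if matrix.has_undefined:
        bad = matrix.undefined_pairs or ["(unknown pair)"]
        raise DistanceError(
            f"distance matrix contains UNDEFINED entries (e.g. {bad[0]}); "
            "cap or drop them before tree building"
        )
    n = len(matrix.ids)
    if n < 2:
        raise DistanceError("need at least 2 taxa")
    nodes = [TreeNode(label=i) for i in matrix.ids]
    keys = [i for i in matrix.ids]  # smallest leaf label per cluster
    D = matrix.values.astype(float).copy()
    if n == 2:
        d = float(D[0, 1])
        for node in nodes:
            node.length = d / 2.0
        return Tree(TreeNode(children=nodes))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                q = (m - 2) * sub[ai, bi] - r[ai] - r[bi]
                ka, kb = keys[active[ai]], keys[active[bi]]
                pair_key = (min(ka, kb), max(ka, kb))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, ai, bi)
        _, _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = dij / 2.0 + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new cluster to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the last three clusters around a central node
    i, j, k = active
    nodes[i].length = max((D[i, j] + D[i, k] - D[j, k]) / 2.0, 0.0)
    nodes[j].length = max((D[i, j] + D[j, k] - D[i, k]) / 2.0, 0.0)
    nodes[k].length = max((D[i, k] + D[j, k] - D[i, j]) / 2.0, 0.0)
    order = sorted((i, j, k), key=lambda x: keys[x])
    return Tree(TreeNode(children=[nodes[x] for x in order]))


def species_monophyly(tree: Tree, labels: dict[str, str]) -> dict[str, bool]:
    """Reciprocal monophyly of each species on an unrooted tree.

    A species with >= 2 leaves is monophyletic iff some edge separates
    exactly its leaves from all others; singleton species are
    monophyletic by convention.
    """
    leaf_ids = tree.leaf_labels()
    for leaf in leaf_ids:
        if leaf not in labels:
            raise DistanceError(f"unlabeled leaf {leaf!r}")
    by_species: dict[str, set[str]] = {}
    for leaf in leaf_ids:
        by_species.setdefault(labels[leaf], set()).add(leaf)
    all_leaves = frozenset(leaf_ids)

    sides: set[frozenset[str]] = set()

    def walk(node):
        below = frozenset(node.leaf_labels())
        if node is not tree.root:
            sides.add(below)
            sides.add(all_leaves - below)
        for c in node.children:
            walk(c)

    walk(tree.root)

    return {
        sp: (len(members) < 2 or frozenset(members) in sides)
        for sp, members in by_species.items()
    }
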