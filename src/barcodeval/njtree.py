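"""Neighbor-joining trees, column-bootstrap support, and monophyly calls.

Implements the Saitou–Nei neighbor-joining algorithm on a K2P distance
matrix: at each step join the pair minimising the rate-corrected Q criterion

    Q(i, j) = (m - 2) d(i, j) - r_i - r_j,        r_i = sum_k d(i, k)

with branch lengths from the standard formulas, until three nodes remain and
close with the three-point equations.  Taxa are processed in lexicographic
label order and Q ties are broken by the lexicographically smallest label
pair, so the tree is a deterministic function of the matrix, independent of
input row order.  Negative branch lengths are clamped to zero with the
deficit moved to the sibling edge and flagged.

Bootstrap support resamples alignment columns with replacement, recomputes
K2P + NJ per replicate, and attaches to each internal edge of the original
tree the percentage of replicate trees containing the same bipartition.
Replicates producing an undefined (saturated) distance are dropped and
counted; more than 10 % dropped is an error.

A species is monophyletic when some edge of the unrooted tree bipartitions
its leaves exactly; single-sample species are trivially monophyletic and
flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .k2p import k2p_matrix_encoded
from .seqdata import DistanceMatrix, InputError, MarkerAlignment

logger = logging.getLogger(__name__)

MAX_DROPPED_FRACTION = 0.10


class SaturatedBootstrapError(RuntimeError):
    """Too many bootstrap replicates had undefined distances."""


@dataclass
class Node:
    """Tree node; ``length`` is the edge to the parent (root edge unused)."""

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    support: float | None = None
    clamped: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (rooted at an arbitrary internal trifurcation for storage)."""

    root: Node
    labels: list[str]  # leaf labels, lexicographic

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def splits(self) -> dict[frozenset, Node]:
        """Non-trivial bipartitions, canonicalised to the side *not*
        containing the lexicographically smallest leaf, keyed to the child
        node under the defining edge."""
        n = len(self.labels)
        anchor = min(self.labels)
        out: dict[frozenset, Node] = {}

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = below if anchor not in below else frozenset(self.labels) - below
                out[side] = node
            return below

        walk(self.root)
        return out

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all leaf pairs."""
        paths: dict[str, dict] = {}

        def walk(node: Node, acc: dict):
            # acc maps edge-id -> edge length along the root-to-node path;
            # pair distance = total length of the symmetric difference
            if node.is_leaf:
                paths[node.name] = dict(acc)
                return
            for c in node.children:
                walk(c, acc | {id(c): c.length})

        walk(self.root, {})
        names = sorted(paths)
        m = len(names)
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                a, b = paths[names[i]], paths[names[j]]
                shared = set(a) & set(b)
                d = sum(v for k, v in a.items() if k not in shared)
                d += sum(v for k, v in b.items() if k not in shared)
                dist[i, j] = dist[j, i] = d
        return names, dist

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.{decimals}f}"
            kids = sorted(node.children, key=_min_leaf)
            inner = ",".join(fmt(c) for c in kids)
            label = "" if node.support is None else f"{node.support:g}"
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.{decimals}f}"

        return fmt(self.root) + ";"


def _min_leaf(node: Node) -> str:
    return min(l.name for l in node.leaves())


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a fully defined distance matrix."""
    if dm.n < 3:
        raise InputError("neighbor-joining needs at least 3 taxa")
    if not dm.is_fully_defined():
        raise InputError(
            "distance matrix has undefined entries; exclude or impute the "
            "affected samples upstream"
        )
    # canonical taxon order makes the result independent of input row order
    order = sorted(range(dm.n), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    D = dm.values[np.ix_(order, order)].astype(float).copy()

    nodes: list[Node] = [Node(name=l) for l in labels]
    # node "label" for tie-breaking = smallest leaf label in its cluster
    tags: list[str] = list(labels)
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-10 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        best = min(
            (tuple(sorted((tags[active[a]], tags[active[b]]))), a, b)
            for a, b in cand if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj, clamped = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        child_i.clamped = child_j.clamped = clamped
        parent = Node(children=[child_i, child_j])
        # reduction: d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        u = D.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for k, lk in zip((a, b, c), (la, lb, lc)):
        node = nodes[k]
        if lk < 0:
            node.clamped = True
            lk = 0.0
        node.length = lk
        root.children.append(node)
    return PhyloTree(root=root, labels=labels)


def _clamp_pair(li: float, lj: float) -> tuple[float, float, bool]:
    if li < 0:
        return 0.0, lj + li, True
    if lj < 0:
        return li + lj, 0.0, True
    return li, lj, False


def bootstrap_support(
    aln: MarkerAlignment,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """NJ tree of ``aln`` with column-bootstrap support on internal edges."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .k2p import k2p_matrix  # local import avoids cycle at module load

    original_dm = k2p_matrix(aln, deletion=deletion)
    tree = nj(original_dm)
    target_splits = tree.splits()
    counts = {s: 0 for s in target_splits}

    mat = aln.encoded_matrix()
    if deletion == "complete":
        from .seqdata import MISSING
        mat = mat[:, (mat != MISSING).all(axis=0)]
    L = mat.shape[1]
    rng = np.random.default_rng(seed)
    kept = dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep_dm = k2p_matrix_encoded(mat[:, cols], aln.sample_ids, aln.species)
        if not rep_dm.is_fully_defined():
            dropped += 1
            continue
        kept += 1
        rep_splits = nj(rep_dm).splits()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if dropped:
        logger.warning("bootstrap: dropped %d/%d replicates with undefined "
                       "distances", dropped, replicates)
    if dropped > MAX_DROPPED_FRACTION * replicates:
        raise SaturatedBootstrapError(
            f"{dropped}/{replicates} bootstrap replicates undefined"
        )
    if kept == 0:
        raise SaturatedBootstrapError("no usable bootstrap replicates")
    for split, node in target_splits.items():
        node.support = 100.0 * counts[split] / kept
    return tree


@dataclass(frozen=True)
class MonophylyCall:
    species: str
    n_leaves: int
    monophyletic: bool
    trivial: bool           # single-sample species
    support: float | None   # bootstrap % of the defining edge, if computed


def monophyly(tree: PhyloTree, species_map: dict[str, str]) -> list[MonophylyCall]:
    """Assess monophyly of every species under ``species_map`` (label → species)."""
    leaves = set(tree.leaf_names())
    missing = [l for l in species_map if l not in leaves]
    extra = leaves - set(species_map)
    if missing or extra:
        raise KeyError(
            f"species_map does not match tree leaves (missing={missing}, "
            f"unmapped={sorted(extra)})"
        )
    splits = tree.splits()
    sides = {s: node for s, node in splits.items()}
    full = frozenset(leaves)
    calls = []
    for sp in sorted(set(species_map.values())):
        members = frozenset(l for l, s in species_map.items() if s == sp)
        if len(members) == 1:
            calls.append(MonophylyCall(sp, 1, True, True, None))
            continue
        node = sides.get(members) or sides.get(full - members)
        if len(members) == len(leaves):  # single-species tree: trivially a clade
            calls.append(MonophylyCall(sp, len(members), True, True, None))
        elif node is not None:
            calls.append(MonophylyCall(sp, len(members), True, False, node.support))
        else:
            calls.append(MonophylyCall(sp, len(members), False, False, None))
    return calls


def reroot(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Re-root on the edge above ``outgroup`` (reporting convenience only)."""
    if outgroup not in tree.leaf_names():
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    adj: dict[int, list[tuple[int, float, float | None]]] = {}
    info: dict[int, Node] = {}

    def collect(node: Node):
        info[id(node)] = node
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length, c.support))
            adj.setdefault(id(c), []).append((id(node), c.length, c.support))
            collect(c)

    collect(tree.root)
    og = next(l for l in tree.root.leaves() if l.name == outgroup)
    (nbr, length, support) = adj[id(og)][0]

    new_root = Node()

    def build(nid: int, parent: int, length: float, support: float | None) -> Node:
        orig = info[nid]
        node = Node(name=orig.name, length=length, support=support,
                    clamped=orig.clamped)
        for cid, clen, csup in adj[nid]:
            if cid != parent:
                node.children.append(build(cid, nid, clen, csup))
        return node

    new_root.children = [
        build(id(og), nbr, length / 2.0, None),
        build(nbr, id(og), length / 2.0, support),
    ]
    return PhyloTree(root=new_root, labels=tree.labels)
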