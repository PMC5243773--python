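"""Distance phylogeny: p-distances, neighbour joining, column bootstrap.

Neighbour joining is implemented here rather than delegated because its
tie-breaking and branch-length conventions are part of the package
contract: ties in the join criterion resolve to the lowest node indices,
negative branch lengths are clamped to zero, and when three nodes remain
(where the Q criterion is constant) the closest pair is joined, so the
final cherry is the closest pair. The tree is returned rooted at the last
join with a zero-length edge to the remaining node; on additive matrices
the unrooted topology and path lengths are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .compare import DifferenceMatrix, difference_matrix
from .errors import ValidationError

_N = ord("N")


def p_distance_matrix(genomes) -> DifferenceMatrix:
    """Pairwise difference counts and p-distances (N-columns pairwise
    excluded) for equal-length genomes."""
    return difference_matrix(genomes)


def _validate_square(d: np.ndarray, taxa) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if taxa is None or len(taxa) != d.shape[0]:
        raise ValidationError("taxa labels must match the matrix dimension")
    if d.shape[0] < 3:
        raise ValidationError("neighbour joining needs at least 3 taxa")
    if (d < 0).any():
        raise ValidationError("distance matrix has negative entries")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix is not symmetric")
    return d


def nj_tree(matrix, taxa=None) -> TreeNode:
    """Neighbour-joining tree from a distance (or count) matrix.

    ``matrix`` may be a :class:`DifferenceMatrix` (its p-distances are
    used) or a square array with explicit ``taxa``. Branch lengths are on
    the scale of the input matrix.
    """
    if isinstance(matrix, DifferenceMatrix):
        d = matrix.p_distances.copy()
        taxa = list(matrix.taxa)
    else:
        d = np.asarray(matrix, dtype=float).copy()
        taxa = list(taxa) if taxa is not None else None
    d = _validate_square(d, taxa).copy()

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 2:
        n = len(nodes)
        if n > 3:
            r = d.sum(axis=1)
            q = (n - 2) * d - r[:, None] - r[None, :]
            np.fill_diagonal(q, np.inf)
            i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        else:
            sel = d.copy()
            np.fill_diagonal(sel, np.inf)
            i, j = np.unravel_index(int(np.argmin(sel)), sel.shape)
        if i > j:
            i, j = j, i
        r = d.sum(axis=1)
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(vi)
        child_j.length = float(vj)
        parent = TreeNode(children=[child_i, child_j])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        du = np.clip(np.delete(du, [i, j]), 0.0, None)
        keep = [k for k in range(n) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = du
        nodes = [nodes[k] for k in keep] + [parent]

    a, b = nodes
    a.length = float(d[0, 1])
    b.length = 0.0
    return TreeNode(children=[a, b])


def tree_clades(tree: TreeNode) -> set[frozenset]:
    """Internal bipartitions of a tree, as leaf-name sets normalized to the
    side not containing the lexicographically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(leaves) - side
        if 0 < len(side) < len(leaves):
            out.add(side)
    return out


@dataclass
class BootstrapResult:
    tree: TreeNode                  # full-data tree, supports on node.support
    supports: dict                  # frozenset(leaf names) -> support in [0,1]
    replicates: int
    seed: int

    def support_of(self, *names: str) -> float:
        leaves = sorted(t.name for t in self.tree.tips())
        side = frozenset(names)
        if leaves[0] in side:
            side = frozenset(leaves) - side
        return self.supports.get(side, 0.0)


def bootstrap_support(genomes, replicates: int = 1000,
                      seed: int = 0) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Alignment columns are resampled with replacement per replicate (as a
    multinomial over the distinct column patterns, which is equivalent and
    fast), the NJ tree recomputed, and each internal edge of the full-data
    tree reported with the fraction of replicates containing it. If the
    genomes are all identical the supports are undefined and reported as 0.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    full = difference_matrix(genomes)
    taxa = list(full.taxa)
    arr = np.vstack([np.frombuffer(g.seq.encode(), dtype=np.uint8)
                     for g in genomes])
    length = arr.shape[1]
    patterns, counts = np.unique(arr, axis=1, return_counts=True)
    n = len(taxa)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.array([
        (patterns[i] != patterns[j]) & (patterns[i] != _N) & (patterns[j] != _N)
        for i, j in pairs
    ])
    valid = np.array([
        (patterns[i] != _N) & (patterns[j] != _N) for i, j in pairs
    ])

    tree = nj_tree(full)
    clades = tree_clades(tree)
    if full.counts.sum() == 0:
        supports = {c: 0.0 for c in clades}
    else:
        rng = np.random.default_rng(seed % (2 ** 31))
        hits = {c: 0 for c in clades}
        probs = counts / length
        for _ in range(replicates):
            w = rng.multinomial(length, probs)
            dcounts = diff @ w
            dvalid = valid @ w
            m = np.zeros((n, n))
            for (i, j), c, v in zip(pairs, dcounts, dvalid):
                m[i, j] = m[j, i] = c / v if v else 0.0
            rep = nj_tree(m, taxa=taxa)
            rep_clades = tree_clades(rep)
            for c in clades:
                if c in rep_clades:
                    hits[c] += 1
        supports = {c: hits[c] / replicates for c in clades}

    leaves = sorted(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if leaves[0] in side:
            side = frozenset(leaves) - side
        # supports become internal node labels in the newick output; the
        # skbio-reserved 'support' attribute is left alone
        node.name = f"{supports.get(side, 0.0):g}"
    return BootstrapResult(tree, supports, replicates, seed)


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()
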