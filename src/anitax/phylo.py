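"""Neighbour-joining trees with column-resampling bootstrap support.

Distances are uncorrected p-distances by default (differences per compared
site, gap/ambiguity columns dropped pairwise), matching the raw-identity
framing of the rest of the package; a Jukes–Cantor correction is available
by flag. The joining step is the classic agglomeration on the Q-criterion
with a documented deterministic tie-break (lowest index pair in current
matrix order), negative branch-length estimates clamped to zero and
flagged. Trees are returned as scikit-bio ``TreeNode`` objects (unrooted,
trifurcating root) so Newick round-trips and topology comparisons use the
standard machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .seqio import SymMatrix

__all__ = [
    "PhyloTree",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "random_tree",
    "tree_distance_matrix",
]

_UNAMBIGUOUS = frozenset(b"ACGT")


@dataclass
class PhyloTree:
    """An unrooted NJ tree plus bookkeeping from its construction."""

    tree: TreeNode
    clamped_edges: int = 0
    tie_joins: int = 0
    supports: dict[frozenset, float] | None = None

    def newick(self) -> str:
        return str(self.tree).strip()

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def _seq_arrays(seqs: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must share one length, got {sorted(lengths)}")
    mat = np.array([np.frombuffer(seqs[l].upper().encode(), dtype=np.uint8) for l in labels])
    return labels, mat


def p_distance_matrix(
    seqs: Mapping[str, str],
    jukes_cantor: bool = False,
) -> SymMatrix:
    """Pairwise p-distance (or JC69-corrected distance) over an alignment.

    Columns where either member of a pair carries a gap or ambiguity code
    are excluded for that pair (pairwise deletion). A pair with zero
    comparable columns is an error.
    """
    labels, mat = _seq_arrays(seqs)
    ok = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ok[i] & ok[j]
            compared = int(keep.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            p = float((mat[i, keep] != mat[j, keep]).sum()) / compared
            if jukes_cantor:
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {labels[i]} and {labels[j]} "
                        "exceeds the Jukes–Cantor limit of 0.75"
                    )
                p = -0.75 * np.log(1 - 4.0 * p / 3.0)
            values[i, j] = values[j, i] = p
    return SymMatrix(labels, values, kind="distance")


def nj_tree(d: SymMatrix) -> PhyloTree:
    """Neighbour joining on a distance matrix.

    Standard Q-criterion agglomeration; at each step the pair minimizing
    Q is joined, ties resolved to the lowest (row, column) index in the
    current matrix order. Negative branch-length estimates are clamped to
    zero and counted. The final three nodes attach to a trifurcating root
    by the three-point formulas, giving an unrooted binary tree.
    """
    if d.kind != "distance":
        raise ValueError(f"expected a distance matrix, got kind={d.kind!r}")
    if d.n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(d.values)):
        raise ValueError("non-finite distances")

    D = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in d.labels]
    clamped = 0
    ties = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        pairs = sorted((min(i, j), max(i, j)) for i, j in candidates)
        if len(set(pairs)) > 1:
            ties += 1
        i, j = pairs[0]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = clamp(float(li)), clamp(float(lj))
        parent = TreeNode(children=[ni, nj_])
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]

    # three-point formulas for the final trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(float(0.5 * (dab + dac - dbc)))
    b.length = clamp(float(0.5 * (dab + dbc - dac)))
    c.length = clamp(float(0.5 * (dac + dbc - dab)))
    root = TreeNode(children=[a, b, c])
    return PhyloTree(tree=root, clamped_edges=clamped, tie_joins=ties)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree as canonical leaf sets.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf is the canonical representative.
    """
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = all_leaves - side
        parts.add(side)
    return parts


def bootstrap_support(
    seqs: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    jukes_cantor: bool = False,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the original tree is the percentage
    of replicate trees containing the same bipartition. Supports are
    written as internal node names (so they appear as internal labels in
    Newick output). ``n_reps=0`` returns the plain tree with no supports.
    """
    if len(seqs) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    labels, mat = _seq_arrays(seqs)
    base = nj_tree(p_distance_matrix(seqs, jukes_cantor=jukes_cantor))
    if n_reps == 0:
        return base

    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(base.tree)}
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = {l: mat[k, cols].tobytes().decode() for k, l in enumerate(labels)}
        try:
            rep = nj_tree(p_distance_matrix(resampled, jukes_cantor=jukes_cantor))
        except ValueError:
            continue  # e.g. resample with zero comparable columns for a pair
        n_ok += 1
        rep_parts = bipartitions(rep.tree)
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed")
    supports = {bp: 100.0 * k / n_ok for bp, k in counts.items()}

    anchor = sorted(t.name for t in base.tree.tips())[0]
    all_leaves = frozenset(t.name for t in base.tree.tips())
    for node in base.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        key = all_leaves - side if anchor in side else side
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    base.supports = supports
    return base


def random_tree(
    taxa: Sequence[str],
    seed: int = 0,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
) -> TreeNode:
    """A random unrooted binary topology with uniform branch lengths.

    Built by random sequential joining; useful for generating additive
    distance matrices on which NJ is provably consistent.
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(min_branch, max_branch))
    return TreeNode(children=list(nodes))


def tree_distance_matrix(tree: TreeNode) -> SymMatrix:
    """Leaf-to-leaf path-length (additive) distances of a tree."""
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    return SymMatrix(labels, np.asarray(dm.data, dtype=float), kind="distance")
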