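"""Distance-based phylogenetics: p/JC distance matrices, neighbor-joining,
bootstrap support, and newick I/O (trees are :class:`dendropy.Tree` objects).

Distances over aligned sequences use pairwise deletion: for each pair, only
positions where both sequences carry an unambiguous base (or residue) are
compared.  Neighbor joining follows Saitou & Nei's Q-criterion with ties
broken at the lowest index pair, and negative branch-length estimates are
clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from dupsel.core_io import SequenceRecord

_AMBIGUOUS = {"-", "N", "?", "X", "."}


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix entries must be finite")
        object.__setattr__(self, "d", d)


def pairwise_distance_matrix(
    seqs: Sequence[SequenceRecord], model: str = "p_distance"
) -> DistanceMatrix:
    """p-distance or Jukes–Cantor distance matrix with pairwise deletion."""
    if model not in ("p_distance", "jukes_cantor"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(seqs)
    length = len(seqs[0])
    for s in seqs:
        if len(s) != length:
            raise ValueError("sequences must be aligned (equal length)")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i].residues, seqs[j].residues
            compared = mismatches = 0
            for x, y in zip(a, b):
                if x in _AMBIGUOUS or y in _AMBIGUOUS:
                    continue
                compared += 1
                if x != y:
                    mismatches += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {seqs[i].id!r} and {seqs[j].id!r}"
                )
            p = mismatches / compared
            if model == "jukes_cantor":
                if p >= 0.75:
                    raise ValueError(
                        f"JC distance undefined for pair ({seqs[i].id!r}, "
                        f"{seqs[j].id!r}): p = {p:.3f} >= 3/4"
                    )
                p = -0.75 * math.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=tuple(s.id for s in seqs), d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(list(dm.ids))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    nodes = []
    for label in dm.ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair among minima for determinism
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                if best is None or q[ii, jj] < best[0] - 1e-12:
                    best = (q[ii, jj], ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        vi = 0.5 * d[i, j] + (row_sums[ii] - row_sums[jj]) / (2.0 * (r - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(vi, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(vj, 0.0)
        new_index = d.shape[0]
        new_row = np.zeros((1, d.shape[0]))
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.zeros((d.shape[0], 1))])
        for kk in active:
            if kk in (i, j):
                continue
            d[new_index, kk] = d[kk, new_index] = 0.5 * (
                d[i, kk] + d[j, kk] - d[i, j]
            )
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    root = tree.seed_node
    bi = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    bj = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    bk = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    for idx, length in ((i, bi), (j, bj), (k, bk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = length
    return tree


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial splits, each as the tip-label set not containing the
    lexicographically first taxon (a rooting-free normalization)."""
    all_labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = all_labels[0]
    out: dict[frozenset, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if anchor in side:
            side = frozenset(all_labels) - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out[side] = nd
    return out


def bootstrap_support(
    seqs: Sequence[SequenceRecord],
    model: str = "p_distance",
    n_replicates: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with internal-edge bootstrap support (percent of replicates).

    Alignment columns are resampled with replacement ``n_replicates`` times;
    the support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it, stored as the internal node
    label.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    full = nj_tree(pairwise_distance_matrix(seqs, model))
    splits = _bipartitions(full)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    length = len(seqs[0])
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(id=s.id, residues="".join(s.residues[i] for i in idx))
            for s in seqs
        ]
        rep_tree = nj_tree(pairwise_distance_matrix(resampled, model))
        rep_splits = set(_bipartitions(rep_tree))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for split, node in splits.items():
        node.label = f"{100.0 * counts[split] / n_replicates:g}"
    return full


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths and internal-node (support) labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; malformed input raises a parse error."""
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
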