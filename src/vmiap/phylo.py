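"""Neighbor-joining phylogeny of solo-LTR sequences and VM-clade testing.

Distances are raw p-distances with pairwise gap deletion (Jukes-Cantor
correction optional).  The tree is built with the Saitou-Nei
neighbor-joining algorithm using the Studier-Keppler Q-criterion, a
deterministic lowest-index tie break, and standard limb-length formulas
with negative estimates clamped to zero.  Whether variably methylated
elements concentrate in one clade is quantified by hypergeometric
enrichment over all clades plus a label-permutation p-value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "length_filter",
    "p_distance_matrix",
    "neighbor_joining",
    "subtree_enrichment",
    "EnrichmentResult",
    "tree_to_newick",
    "tree_from_newick",
]


def length_filter(
    seqs: Mapping[str, str], len_min: int = 200, len_max: int = 800
) -> Dict[str, str]:
    """Retain sequences with length in [len_min, len_max] (inclusive)."""
    return {k: v for k, v in seqs.items() if len_min <= len(v) <= len_max}


def p_distance_matrix(
    aligned: Mapping[str, str], jukes_cantor: bool = False
) -> DistanceMatrix:
    """Pairwise p-distances over columns where both rows are ungapped
    (and non-N).  Raises on pairs with no comparable columns."""
    ids = list(aligned)
    rows = [aligned[i] for i in ids]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(r) for r in rows])
    valid = (arr != "-") & (arr != "N")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            p = float(np.sum(arr[i, both] != arr[j, both])) / m
            if jukes_cantor:
                if p >= 0.75:
                    raise ValueError("p-distance too large for Jukes-Cantor correction")
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j; the minimal pair joins first
    (ties broken by lowest index pair); limb lengths from the standard
    formulas with negatives clamped to 0 (flagged via the node attribute
    ``clamped``).  The root of the returned tree is the final trifurcation
    (unrooted semantics).
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: List[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        fi, fj = np.unravel_index(np.argmin(q), q.shape)  # argmin is first minimum
        if fi > fj:
            fi, fj = fj, fi
        i_glob, j_glob = active[fi], active[fj]
        dij = sub[fi, fj]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (k - 2))
        lj = dij - li
        child_i, child_j = nodes[i_glob], nodes[j_glob]
        child_i.length, child_i.clamped = max(0.0, li), li < 0
        child_j.length, child_j.clamped = max(0.0, lj), lj < 0
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i_glob, :] + d[j_glob, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i_glob, j_glob)] + [len(nodes) - 1]
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    limbs = {
        a: 0.5 * (dab + dac - dbc),
        b: 0.5 * (dab + dbc - dac),
        c: 0.5 * (dac + dbc - dab),
    }
    children = []
    for idx in (a, b, c):
        nd = nodes[idx]
        nd.length, nd.clamped = max(0.0, limbs[idx]), limbs[idx] < 0
        children.append(nd)
    return TreeNode(children=children)


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def tree_from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


@dataclass(frozen=True)
class EnrichmentResult:
    clade_leaves: Tuple[str, ...]
    n_vm_in_clade: int
    clade_size: int
    hypergeom_p: float
    permutation_p: float
    n_permutations: int


def _best_clade(tree: TreeNode, vm: Set[str]) -> Tuple[float, Tuple[str, ...], int, int]:
    """Minimal hypergeometric tail p over all clades of the midpoint-rooted
    tree.  Ties resolve to the smaller clade, then lexicographically."""
    leaves = [t.name for t in tree.tips()]
    n = len(leaves)
    k_total = len(vm & set(leaves))
    best = (np.inf, (), 0, 0)
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._leafset = (node.name,)
        else:
            node._leafset = tuple(l for ch in node.children for l in ch._leafset)
        size = len(node._leafset)
        if size == n:  # the whole tree is not an informative clade
            continue
        hits = sum(1 for l in node._leafset if l in vm)
        if hits == 0:
            continue
        p = float(stats.hypergeom.sf(hits - 1, n, k_total, size))
        key = (p, size, tuple(sorted(node._leafset)))
        if key < (best[0], best[3], tuple(sorted(best[1]))):
            best = (p, node._leafset, hits, size)
    return best


def subtree_enrichment(
    tree: TreeNode,
    vm_labels: Iterable[str],
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Find the clade most enriched for VM-labelled leaves.

    The tree is midpoint-rooted solely to enumerate clades; the reported
    clade should be read as an unrooted bipartition.  The permutation p
    (labels shuffled across leaves, clade search repeated) is the primary
    statistic; the hypergeometric tail p is descriptive.
    """
    vm = set(vm_labels)
    if not vm:
        raise ValueError("at least one VM label required")
    rng = rng if rng is not None else np.random.default_rng()
    rooted = tree.copy()
    try:
        rooted = rooted.root_at_midpoint()
    except Exception:  # zero-length or degenerate trees: use as-is
        pass
    leaves = [t.name for t in rooted.tips()]
    obs_p, clade, hits, size = _best_clade(rooted, vm)
    k = len(vm & set(leaves))
    count = 0
    leaves_arr = np.array(leaves)
    for _ in range(n_permutations):
        perm_vm = set(rng.choice(leaves_arr, size=k, replace=False))
        perm_p, _, _, _ = _best_clade(rooted, perm_vm)
        if perm_p <= obs_p:
            count += 1
    perm_pvalue = (1 + count) / (n_permutations + 1)
    return EnrichmentResult(
        clade_leaves=tuple(sorted(clade)),
        n_vm_in_clade=hits,
        clade_size=size,
        hypergeom_p=obs_p,
        permutation_p=perm_pvalue,
        n_permutations=n_permutations,
    )
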