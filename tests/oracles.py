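"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms in the package: likelihoods are
computed by explicit enumeration of internal-state assignments, soft-LCA
scores by scoring every node directly, rooting by a fine grid scan, and
Mann-Whitney p-values by counting permutations.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"


def enumeration_site_loglik(tree, alignment, model) -> np.ndarray:
    """Per-site log-likelihood by summing over every assignment of states
    to internal nodes (outer-product enumeration, no pruning)."""
    seq = dict(zip(alignment.ids, alignment.seqs))
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    axis = {id(n): k for k, n in enumerate(internals)}
    n_int = len(internals)
    pi = model.frequencies

    def place_vec(v, a):
        shape = [1] * n_int
        shape[a] = 20
        return v.reshape(shape)

    def place_mat(M, row_axis, col_axis):
        # broadcast M so M[s_row, s_col] sits on the two grid axes
        arr = M if row_axis < col_axis else M.T
        shape = [1] * n_int
        shape[min(row_axis, col_axis)] = 20
        shape[max(row_axis, col_axis)] = 20
        return arr.reshape(shape)

    out = []
    for s in range(alignment.n_sites):
        grid = place_vec(pi, axis[id(tree.seed_node)])
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            P = model.transition_matrix(node.edge.length or 0.0)
            pa = axis[id(node.parent_node)]
            if node.is_leaf():
                state = AA.index(seq[node.taxon.label][s])
                grid = grid * place_vec(P[:, state], pa)
            else:
                grid = grid * place_mat(P, pa, axis[id(node)])
        out.append(math.log(grid.sum()))
    return np.array(out)


def exhaustive_soft_lca(tree, taxonomy, label) -> dict[int, float]:
    """Score every node containing the label directly from the formula."""
    total = sum(
        1
        for leaf in tree.leaf_node_iter()
        if taxonomy.label(leaf.taxon.label) == label
    )
    scores = {}
    for node in tree.preorder_node_iter():
        leaves = [l.taxon.label for l in node.leaf_iter()]
        n_label = sum(1 for l in leaves if taxonomy.label(l) == label)
        if n_label > 0:
            scores[id(node)] = (n_label / len(leaves)) * (n_label / total)
    return scores


def exhaustive_root_balance(tree, n_offsets: int = 400) -> float:
    """Minimum achievable side-imbalance over every edge and a fine
    offset grid."""
    below = {}
    for node in tree.postorder_node_iter():
        below[id(node)] = sum(
            (c.edge.length or 0.0) + below[id(c)] for c in node.child_nodes()
        )
    total = below[id(tree.seed_node)]
    best = math.inf
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        for frac in np.linspace(0.0, 1.0, n_offsets):
            side = below[id(node)] + frac * bl
            best = min(best, abs(2.0 * side - total))
    return best


def permutation_mwu_pvalue(a, b) -> float:
    """Two-sided Mann-Whitney p by direct permutation counting, written
    with rank sums rather than pairwise comparisons."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na, n = len(a), len(pooled)

    def u_from_indices(idx):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in set(idx)]
        # rank-sum formulation: U = R_a - na(na+1)/2 with midranks
        ranks = _midranks(chosen + rest)
        r_a = sum(ranks[: len(chosen)])
        return r_a - na * (na + 1) / 2.0

    center = na * (n - na) / 2.0
    obs = abs(u_from_indices(tuple(range(na))) - center)
    hits = count = 0
    for idx in combinations(range(n), na):
        count += 1
        if abs(u_from_indices(idx) - center) >= obs - 1e-12:
            hits += 1
    return hits / count


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def column_entropy_bits(column: str) -> float:
    """Direct Shannon computation for the information oracle."""
    counts = Counter(c for c in column.upper() if c in AA)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = -sum((v / total) * math.log2(v / total) for v in counts.values())
    return math.log2(20) - h
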