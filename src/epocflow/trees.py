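"""Tree curation and taxonomic clade detection.

Covers log-normal branch-length outlier removal, weighted midpoint
rooting, the soft-LCA purity x scope score, clade validity rules and the
topological distance used to rank candidate sisters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.stats import norm

from .taxonomy import EUKARYOTE, TaxonomyTable

DISCARD_OUTLIER_OVERPRUNE = "outlier_overprune"
DISCARD_NO_EUK_CLADE = "no_euk_clade"
DISCARD_NO_PROK_CLADE = "no_prok_clade"
DISCARD_PARAPHYLY = "paraphyly"


class EpocDiscarded(Exception):
    """A gene family failed a QC rule; .reason is machine readable."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or @path) preserving leaf label spelling."""
    if source.startswith("@"):
        return dendropy.Tree.get(
            path=source[1:], schema="newick", preserve_underscores=True
        )
    return dendropy.Tree.get(
        data=source, schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def leaf_ids(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def all_leaf_ids(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def mrca(tree: dendropy.Tree, ids) -> dendropy.Node:
    """Most recent common ancestor of the given leaf ids.

    Safe after manual topology surgery (no cached bipartitions)."""
    wanted = set(ids)
    if not wanted:
        raise ValueError("empty leaf id set")
    counts: dict[int, int] = {}
    target = len(wanted)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[id(node)] = 1 if node.taxon.label in wanted else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.child_nodes())
        if counts[id(node)] == target:
            return node
    raise ValueError("leaf ids not all present in tree")


# ----------------------------------------------------------------- outliers


@dataclass(frozen=True)
class OutlierModel:
    mu: float
    sigma: float
    upper_cut: float
    n_branches: int


def maximal_monophyletic_groups(
    tree: dendropy.Tree, is_member
) -> list[set[str]]:
    """Leaf-id sets of maximal clades whose leaves all satisfy the predicate."""
    pure: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[id(node)] = bool(is_member(node.taxon.label))
        else:
            pure[id(node)] = all(pure[id(c)] for c in node.child_nodes())
    groups = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if pure[id(node)] and (parent is None or not pure[id(parent)]):
            groups.append(leaf_ids(node))
    return groups


def fit_lognormal_prune(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable | None = None,
    quantile: float = 0.995,
    max_removed_fraction: float = 0.30,
    min_branches: int = 10,
) -> tuple[dendropy.Tree, list[set[str]], OutlierModel | None]:
    """Remove subtrees hanging on implausibly long branches.

    A log-normal is fitted by maximum likelihood to every positive branch
    length (leaf and internal); any branch strictly above the ``quantile``
    point is cut, taking its whole subtree.  Zero-length branches never
    enter the fit and are never removed.

    Raises EpocDiscarded when pruning would delete more than 30% of the
    leaves or an entire eukaryotic clade (requires ``taxonomy``).
    """
    work = tree.clone(depth=1)
    lengths = np.array(
        [
            n.edge.length
            for n in work.preorder_node_iter()
            if n.parent_node is not None and (n.edge.length or 0.0) > 0
        ],
        dtype=float,
    )
    if lengths.size < min_branches:
        return work, [], None

    logs = np.log(lengths)
    mu = float(logs.mean())
    sigma = float(logs.std())
    upper_cut = float(math.exp(mu + sigma * norm.ppf(quantile)))
    model = OutlierModel(mu, sigma, upper_cut, int(lengths.size))

    removed: list[set[str]] = []
    removed_leaves: set[str] = set()

    def visit(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            if bl > 0 and bl > upper_cut:
                ids = leaf_ids(child)
                removed.append(ids)
                removed_leaves.update(ids)
            else:
                visit(child)

    visit(work.seed_node)

    if not removed:
        return work, [], model

    n_total = len(all_leaf_ids(work))
    if len(removed_leaves) / n_total > max_removed_fraction:
        raise EpocDiscarded(
            DISCARD_OUTLIER_OVERPRUNE,
            f"pruning removes {len(removed_leaves)}/{n_total} leaves",
        )
    if taxonomy is not None:
        euk_groups = maximal_monophyletic_groups(
            work, lambda lid: taxonomy.is_eukaryote(lid)
        )
        for group in euk_groups:
            if group <= removed_leaves:
                raise EpocDiscarded(
                    DISCARD_OUTLIER_OVERPRUNE,
                    "pruning removes a whole eukaryotic clade",
                )

    keep = all_leaf_ids(work) - removed_leaves
    work.retain_taxa_with_labels(sorted(keep))
    return work, removed, model


# ------------------------------------------------------------------ rooting


def _subtree_lengths(tree: dendropy.Tree) -> dict[int, float]:
    """Sum of edge lengths strictly below each node (node's own edge excluded)."""
    below: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        total = 0.0
        for child in node.child_nodes():
            total += (child.edge.length or 0.0) + below[id(child)]
        below[id(node)] = total
    return below


def weighted_midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Re-root so the total branch length on either side is as equal as possible.

    The root point on edge e at offset x gives sides of length
    S_below(e) + x and L - S_below(e) - x; the closed-form optimum per edge
    is clamped to the edge, and the globally best edge wins (ties broken by
    the smallest leaf id below the edge).  Already balanced trees are
    returned unchanged.
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("need at least 2 leaves to root")
    work = tree.clone(depth=1)
    below = _subtree_lengths(work)
    total = below[id(work.seed_node)]

    best = None  # (balance, min_leaf_id, node, x)
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        s = below[id(node)]
        x = min(max(total / 2.0 - s, 0.0), bl)
        balance = abs(2.0 * (s + x) - total)
        key = (balance, min(leaf_ids(node)))
        if best is None or key < (best[0], best[1]):
            best = (balance, key[1], node, x)

    assert best is not None
    balance, _, node, x = best

    # fixed point: keep the current root when it is already optimal
    root_children = work.seed_node.child_nodes()
    if len(root_children) == 2:
        sides = [
            below[id(c)] + (c.edge.length or 0.0) for c in root_children
        ]
        if abs(sides[0] - sides[1]) <= balance + 1e-12:
            return work

    work.reroot_at_edge(
        node.edge,
        length1=(node.edge.length or 0.0) - x,  # parent side
        length2=x,  # child side
        update_bipartitions=False,
    )
    work.suppress_unifurcations()
    return work


def root_balance(tree: dendropy.Tree) -> float:
    """|T_left - T_right| at the current (bifurcating) root."""
    below = _subtree_lengths(tree)
    sides = [
        below[id(c)] + (c.edge.length or 0.0)
        for c in tree.seed_node.child_nodes()
    ]
    if len(sides) != 2:
        raise ValueError("root is not bifurcating")
    return abs(sides[0] - sides[1])


# ------------------------------------------------------- topological distance


def topological_distance(
    tree: dendropy.Tree, node_a: dendropy.Node, node_b: dendropy.Node
) -> int:
    """Number of non-root internal nodes strictly between two nodes."""
    if node_a is node_b:
        return 0
    ancestors_a = []
    n = node_a
    while n is not None:
        ancestors_a.append(n)
        n = n.parent_node
    index_a = {id(n): i for i, n in enumerate(ancestors_a)}
    path_b = []
    n = node_b
    while id(n) not in index_a:
        path_b.append(n)
        n = n.parent_node
    lca = n
    path = ancestors_a[1 : index_a[id(lca)]] + [lca] + path_b[1:]
    root = tree.seed_node
    return sum(1 for n in path if n is not root and not n.is_leaf())


# ----------------------------------------------------------------- soft LCA


@dataclass
class CladeCall:
    node: dendropy.Node = field(repr=False)
    label: str
    size: int
    n_label: int
    purity: float
    soft_lca_score: float
    valid: bool
    leaf_ids: frozenset[str]
    clade_id: str = ""


def _label_counts(tree: dendropy.Tree, matches) -> dict[int, tuple[int, int]]:
    """Per node: (leaves matching predicate, total leaves)."""
    counts: dict[int, tuple[int, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[id(node)] = (1 if matches(node.taxon.label) else 0, 1)
        else:
            m = s = 0
            for c in node.child_nodes():
                cm, cs = counts[id(c)]
                m += cm
                s += cs
            counts[id(node)] = (m, s)
    return counts


def soft_lca_scan(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    label: str,
    domain_mode: bool = False,
) -> list[tuple[dendropy.Node, float]]:
    """Score candidate soft-LCA nodes for one label.

    Every node on a path from a maximal monophyletic label-clade root to
    the tree root gets purity x scope =
    (n_label_in_clade / clade_size) * (n_label_in_clade / total_label).
    Sorted by descending score; ties by smaller clade, then smallest leaf id.
    """
    if domain_mode:
        matches = lambda lid: taxonomy.domain(lid) == label  # noqa: E731
    else:
        matches = lambda lid: taxonomy.label(lid) == label  # noqa: E731
    counts = _label_counts(tree, matches)
    total = counts[id(tree.seed_node)][0]
    if total == 0:
        return []
    scored: dict[int, tuple[dendropy.Node, float]] = {}
    for node in tree.postorder_node_iter():
        m, s = counts[id(node)]
        if m == s and m > 0:
            parent = node.parent_node
            if parent is not None:
                pm, ps = counts[id(parent)]
                if pm == ps:
                    continue  # not a maximal monophyletic clade root
            walker = node
            while walker is not None:
                wm, ws = counts[id(walker)]
                scored[id(walker)] = (
                    walker,
                    (wm / ws) * (wm / total),
                )
                walker = walker.parent_node
    ranked = sorted(
        scored.values(),
        key=lambda item: (
            -item[1],
            counts[id(item[0])][1],
            min(leaf_ids(item[0])),
        ),
    )
    return [(n, round(s, 15)) for n, s in ranked]


def _make_call(
    node: dendropy.Node,
    label: str,
    score: float,
    counts: dict[int, tuple[int, int]],
    min_size: int,
    purity_threshold: float,
) -> CladeCall:
    m, s = counts[id(node)]
    purity = m / s
    return CladeCall(
        node=node,
        label=label,
        size=s,
        n_label=m,
        purity=purity,
        soft_lca_score=score,
        valid=(s >= min_size and purity > purity_threshold),
        leaf_ids=frozenset(leaf_ids(node)),
    )


@dataclass
class CladeSet:
    eukaryotic: list[CladeCall]
    prokaryotic: list[CladeCall]

    def valid_eukaryotic(self) -> list[CladeCall]:
        return [c for c in self.eukaryotic if c.valid]

    def valid_prokaryotic(self) -> list[CladeCall]:
        return [c for c in self.prokaryotic if c.valid]

    def to_frame(self, epoc_id: str = ""):
        import pandas as pd

        rows = [
            {
                "epoc_id": epoc_id,
                "clade_id": c.clade_id,
                "label": c.label,
                "size": c.size,
                "n_label": c.n_label,
                "purity": c.purity,
                "score": c.soft_lca_score,
                "valid": c.valid,
            }
            for c in self.eukaryotic + self.prokaryotic
        ]
        return pd.DataFrame(rows)


def detect_clades(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    prok_min_size: int = 3,
    euk_min_size: int = 5,
    purity_threshold: float = 0.8,
    max_euk_clades: int = 3,
) -> CladeSet:
    """Call the best soft-LCA clade per prokaryotic label and disjoint
    eukaryotic clades, applying the validity and paraphyly rules.

    Prokaryotic clades are valid at >= 3 sequences with purity > 0.8;
    eukaryotic at >= 5 with purity > 0.8.  Raises EpocDiscarded when no
    valid clade exists on either side, or when more than
    ``max_euk_clades`` valid eukaryotic clades indicate paraphyly.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in taxonomy:
            raise ValueError(f"leaf {leaf.taxon.label!r} missing from taxonomy")

    prok_calls: list[CladeCall] = []
    prok_labels = sorted(
        {
            taxonomy.label(leaf.taxon.label)
            for leaf in tree.leaf_node_iter()
            if not taxonomy.is_eukaryote(leaf.taxon.label)
        }
    )
    for label in prok_labels:
        ranked = soft_lca_scan(tree, taxonomy, label)
        if not ranked:
            continue
        counts = _label_counts(
            tree, lambda lid, lab=label: taxonomy.label(lid) == lab
        )
        calls = [
            _make_call(node, label, score, counts, prok_min_size, purity_threshold)
            for node, score in ranked
        ]
        # prefer the best-scoring valid clade; otherwise report the top
        # scorer flagged invalid
        chosen = next((c for c in calls if c.valid), calls[0])
        prok_calls.append(chosen)

    euk_counts = _label_counts(tree, lambda lid: taxonomy.is_eukaryote(lid))
    ranked = soft_lca_scan(tree, taxonomy, EUKARYOTE, domain_mode=True)
    euk_calls: list[CladeCall] = []
    taken: set[str] = set()
    for node, score in ranked:
        call = _make_call(
            node, EUKARYOTE, score, euk_counts, euk_min_size, purity_threshold
        )
        if not call.valid:
            continue
        if call.leaf_ids & taken:
            continue
        taken.update(call.leaf_ids)
        euk_calls.append(call)

    valid_euk = [c for c in euk_calls if c.valid]
    valid_prok = [c for c in prok_calls if c.valid]
    if not valid_euk:
        raise EpocDiscarded(DISCARD_NO_EUK_CLADE)
    if not valid_prok:
        raise EpocDiscarded(DISCARD_NO_PROK_CLADE)
    if len(valid_euk) > max_euk_clades:
        raise EpocDiscarded(
            DISCARD_PARAPHYLY, f"{len(valid_euk)} valid eukaryotic clades"
        )

    for i, call in enumerate(euk_calls):
        call.clade_id = f"euk_{i + 1}"
    for call in prok_calls:
        call.clade_id = call.label
    return CladeSet(eukaryotic=euk_calls, prokaryotic=prok_calls)
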