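"""Candidate-sister enumeration, constrained topologies and expected
likelihood weights (ELW) via RELL site resampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .likelihood import optimize_branch_lengths
from .msa import Alignment
from .substitution import SubstitutionModel
from .taxonomy import TaxonomyTable
from .trees import (
    CladeCall,
    CladeSet,
    detect_clades,
    mrca,
    topological_distance,
)

MIN_STEM_LENGTH = 0.01


def enumerate_candidates(
    tree: dendropy.Tree,
    euk_clade: CladeCall,
    valid_prok_clades: list[CladeCall],
    k: int = 12,
) -> list[CladeCall]:
    """The k prokaryotic clades closest to the eukaryotic clade root by
    topological distance; ties break lexicographically by label."""
    if not valid_prok_clades:
        raise ValueError("need at least one valid prokaryotic clade")
    ranked = sorted(
        valid_prok_clades,
        key=lambda c: (
            topological_distance(tree, euk_clade.node, c.node),
            c.label,
        ),
    )
    return ranked[:k]


@dataclass
class ConstraintHypothesis:
    euk_leaf_ids: frozenset[str]
    candidate_label: str
    candidate_leaf_ids: frozenset[str]
    topology: dendropy.Tree
    stem_init: float


def _detach_clade(tree: dendropy.Tree, node: dendropy.Node) -> float:
    """Remove the subtree at node, healing the resulting unifurcation.
    Returns the removed stem branch length."""
    stem = node.edge.length or 0.0
    parent = node.parent_node
    parent.remove_child(node)
    if parent.parent_node is None:
        # parent is the root; promote its surviving child
        kids = parent.child_nodes()
        if len(kids) == 1:
            new_root = kids[0]
            parent.remove_child(new_root)
            new_root.parent_node = None
            tree.seed_node = new_root
            new_root.edge.length = None
    elif len(parent.child_nodes()) == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        merged = (parent.edge.length or 0.0) + (only.edge.length or 0.0)
        grand.remove_child(parent)
        grand.add_child(only)
        only.edge.length = merged
    return stem


def build_constraint_topology(
    master: dendropy.Tree,
    euk_clade: CladeCall,
    candidate: CladeCall,
) -> ConstraintHypothesis:
    """Regraft the eukaryotic clade as sister to the candidate clade root.

    The new stem and attachment branch start at the pruned stem length
    (floored at 0.01); all other branch lengths carry over.
    """
    if candidate.leaf_ids <= euk_clade.leaf_ids:
        raise ValueError("candidate clade nested inside the eukaryotic clade")
    if candidate.leaf_ids & euk_clade.leaf_ids:
        raise ValueError("clades overlap")

    work = master.clone(depth=1)
    euk_node = mrca(work, euk_clade.leaf_ids)
    stem0 = max(_detach_clade(work, euk_node), MIN_STEM_LENGTH)

    cand_node = mrca(work, candidate.leaf_ids)
    parent = cand_node.parent_node
    attach = dendropy.Node()
    if parent is None:
        work.seed_node = attach
    else:
        carried = cand_node.edge.length or 0.0
        parent.remove_child(cand_node)
        parent.add_child(attach)
        attach.edge.length = carried
    attach.add_child(cand_node)
    cand_node.edge.length = stem0
    attach.add_child(euk_node)
    euk_node.edge.length = stem0

    n_master = len(master.leaf_nodes())
    n_new = len(work.leaf_nodes())
    if n_master != n_new:
        raise RuntimeError("leaf count changed during regraft")
    return ConstraintHypothesis(
        euk_leaf_ids=euk_clade.leaf_ids,
        candidate_label=candidate.label,
        candidate_leaf_ids=candidate.leaf_ids,
        topology=work,
        stem_init=stem0,
    )


def rell_elw(
    site_logliks: np.ndarray, B: int = 1000, seed: int = 0
) -> np.ndarray:
    """Expected likelihood weights by RELL site bootstrap.

    For each replicate, site indices are resampled with replacement (the
    same indices for every topology); replicate weights are the softmax
    of replicate log-likelihoods, and the ELW is their mean over
    replicates.  Sums to 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sll = np.asarray(site_logliks, dtype=float)
    if sll.ndim != 2 or sll.shape[0] < 2 or sll.shape[1] < 1:
        raise ValueError("need >= 2 topologies and >= 1 site")
    ntopo, nsites = sll.shape
    rng = np.random.default_rng(seed)
    elw = np.zeros(ntopo)
    chunk = max(1, int(2_000_000 / max(nsites, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, nsites, size=(b, nsites))
        rep = sll[:, idx].sum(axis=2)  # (ntopo, b)
        w = np.exp(rep - logsumexp(rep, axis=0, keepdims=True))
        elw += w.sum(axis=1)
        done += b
    return elw / B


@dataclass
class ELWResult:
    epoc_id: str
    euk_clade_id: str
    euk_leaf_ids: frozenset[str]
    candidates: list[str]
    elw: np.ndarray
    n_sites: int
    alpha: float | None
    topologies: dict[str, dendropy.Tree] = field(default_factory=dict, repr=False)
    logliks: dict[str, float] = field(default_factory=dict)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.elw))

    @property
    def best_label(self) -> str:
        return self.candidates[self.best_index]

    @property
    def best_elw(self) -> float:
        return float(self.elw[self.best_index])

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.elw, kind="stable")
        rows = []
        for rank, i in enumerate(order, start=1):
            rows.append(
                {
                    "epoc_id": self.epoc_id,
                    "euk_clade_id": self.euk_clade_id,
                    "candidate_label": self.candidates[i],
                    "elw": float(self.elw[i]),
                    "rank": rank,
                    "n_sites": self.n_sites,
                    "alpha": self.alpha,
                }
            )
        return pd.DataFrame(rows)


def assign_sisters(
    tree: dendropy.Tree,
    alignment: Alignment,
    taxonomy: TaxonomyTable,
    model: SubstitutionModel,
    epoc_id: str = "epoc",
    clades: CladeSet | None = None,
    k: int = 12,
    B: int = 1000,
    seed: int = 0,
    opt_tol: float = 0.05,
    opt_max_rounds: int = 3,
) -> list[ELWResult]:
    """Full constrained-topology ELW pipeline, one result per valid
    eukaryotic clade: enumerate candidates, regraft, re-optimize branch
    lengths, collect per-site log-likelihoods and average RELL weights."""
    if clades is None:
        clades = detect_clades(tree, taxonomy)
    valid_prok = clades.valid_prokaryotic()
    results = []
    for euk in clades.valid_eukaryotic():
        candidates = enumerate_candidates(tree, euk, valid_prok, k=k)
        labels = []
        rows = []
        topologies = {}
        logliks = {}
        for cand in candidates:
            hyp = build_constraint_topology(tree, euk, cand)
            opt = optimize_branch_lengths(
                hyp.topology, alignment, model,
                tol=opt_tol, max_rounds=opt_max_rounds,
            )
            labels.append(cand.label)
            rows.append(opt.site_logliks)
            topologies[cand.label] = opt.tree
            logliks[cand.label] = opt.loglik
        if len(rows) == 1:
            elw = np.ones(1)
        else:
            elw = rell_elw(np.vstack(rows), B=B, seed=seed)
        results.append(
            ELWResult(
                epoc_id=epoc_id,
                euk_clade_id=euk.clade_id,
                euk_leaf_ids=euk.leaf_ids,
                candidates=labels,
                elw=elw,
                n_sites=alignment.n_sites,
                alpha=model.gamma_alpha,
                topologies=topologies,
                logliks=logliks,
            )
        )
    return results
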