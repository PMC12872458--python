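"""Alignment column statistics, information-based trimming and
taxonomy-aware prune-and-align data reduction."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import AA, GAP_CHARS, MISSING_CHARS
from .taxonomy import TaxonomyTable

MAX_INFORMATION_BITS = math.log2(20.0)


@dataclass
class Alignment:
    """Ordered amino-acid alignment; all rows share one length."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("rows have unequal length")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def column(self, site: int) -> str:
        return "".join(s[site] for s in self.seqs)

    def subset_rows(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        pairs = [(i, s) for i, s in zip(self.ids, self.seqs) if i in keep]
        return Alignment([p[0] for p in pairs], [p[1] for p in pairs])

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq).upper() for r in records])


def column_information(column: str | Sequence[str]) -> float:
    """Information content of one alignment column in bits.

    Defined as log2(20) minus the Shannon entropy of the residue
    distribution, gaps excluded.  An all-gap column carries 0 bits.
    """
    if len(column) < 1:
        raise ValueError("column must contain at least one character")
    counts: Counter[str] = Counter()
    for ch in column:
        c = ch.upper()
        if c in GAP_CHARS or c in MISSING_CHARS:
            continue
        if c not in AA:
            raise ValueError(f"unknown residue {ch!r} in column")
        counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    entropy = -sum(
        (n / total) * math.log2(n / total) for n in counts.values()
    )
    return MAX_INFORMATION_BITS - entropy


def trim_alignment(
    aln: Alignment, threshold_bits: float = 0.15
) -> tuple[Alignment, pd.DataFrame]:
    """Keep columns with strictly more than ``threshold_bits`` of information.

    Returns the trimmed alignment plus a per-site report
    (columns: site, information, kept).
    """
    if threshold_bits < 0:
        raise ValueError("threshold must be >= 0")
    info = [column_information(aln.column(j)) for j in range(aln.n_sites)]
    kept = [j for j, b in enumerate(info) if b > threshold_bits]
    report = pd.DataFrame(
        {
            "site": range(aln.n_sites),
            "information": info,
            "kept": [j in set(kept) for j in range(aln.n_sites)],
        }
    )
    new_seqs = ["".join(s[j] for j in kept) for s in aln.seqs]
    return Alignment(list(aln.ids), new_seqs), report


# ---------------------------------------------------------------- reduction


def _root_distances(tree: dendropy.Tree) -> dict:
    dist = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dist[node] = 0.0
        else:
            dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
    return dist


def prune_and_align_reduce(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    target_n: int,
) -> set[str]:
    """Select ``min(target_n, n_leaves)`` representative leaves.

    Iteratively collapses same-label cherries (the closest pair first),
    keeping the leaf nearest the root and crediting it with the pruned
    relatives.  If collapsing converges above the target, leaves with the
    fewest pruned relatives are deleted until the target is reached.
    Deterministic: all ties break lexicographically by leaf id.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")

    work = tree.clone(depth=1)
    leaves = list(work.leaf_node_iter())
    for leaf in leaves:
        if leaf.taxon.label not in taxonomy:
            raise ValueError(f"leaf {leaf.taxon.label!r} missing from taxonomy")

    pruned_count = {leaf.taxon.label: 0 for leaf in leaves}
    n_leaves = len(leaves)
    if target_n >= n_leaves:
        return set(pruned_count)

    def same_label_cherries():
        """(distance, id_a, id_b, node_a, node_b) for same-label cherries."""
        out = []
        for node in work.preorder_internal_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                a, b = sorted(kids, key=lambda k: k.taxon.label)
                la, lb = a.taxon.label, b.taxon.label
                if taxonomy.label(la) == taxonomy.label(lb):
                    d = (a.edge.length or 0.0) + (b.edge.length or 0.0)
                    out.append((d, la, lb, a, b))
        return out

    remaining = n_leaves
    while remaining > target_n:
        cherries = same_label_cherries()
        if not cherries:
            break
        cherries.sort(key=lambda c: (c[0], c[1], c[2]))
        _, _, _, a, b = cherries[0]
        rdist = _root_distances(work)
        # keep the leaf closest to the root; tie -> lexicographically smaller id
        if (rdist[a], a.taxon.label) <= (rdist[b], b.taxon.label):
            keep, drop = a, b
        else:
            keep, drop = b, a
        pruned_count[keep.taxon.label] += 1 + pruned_count.pop(drop.taxon.label)
        work.prune_taxa([drop.taxon], suppress_unifurcations=True)
        remaining -= 1

    if remaining > target_n:
        # fallback: delete leaves with the fewest pruned relatives
        order = sorted(pruned_count.items(), key=lambda kv: (kv[1], kv[0]))
        for leaf_id, _ in order[: remaining - target_n]:
            del pruned_count[leaf_id]

    return set(pruned_count)
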