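"""End-to-end per-family processing: curation, clade detection,
constrained-topology ELW testing and stem metrics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .elw import ELWResult, assign_sisters
from .likelihood import DEFAULT_ALPHA_GRID, estimate_gamma_alpha
from .msa import Alignment, trim_alignment
from .stems import StemRecord, StemUndefined, make_stem_record
from .substitution import load_model
from .taxonomy import TaxonomyTable
from .trees import (
    CladeSet,
    EpocDiscarded,
    detect_clades,
    fit_lognormal_prune,
    weighted_midpoint_root,
)


@dataclass
class RunConfig:
    model_name: str = "LG"
    gamma_alpha: float | None = None  # None -> estimate on the master tree
    n_rate_categories: int = 4
    trim_threshold_bits: float = 0.15
    k_candidates: int = 12
    rell_replicates: int = 1000
    opt_tol: float = 0.05
    opt_max_rounds: int = 3
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class EpocOutcome:
    epoc_id: str
    status: str  # "ok" or a discard reason code
    detail: str = ""
    alpha: float | None = None
    elw_results: list[ELWResult] = field(default_factory=list)
    stem_records: list[StemRecord] = field(default_factory=list)
    clades: CladeSet | None = None


def curate_tree(
    tree: dendropy.Tree, taxonomy: TaxonomyTable
) -> dendropy.Tree:
    """Outlier pruning followed by weighted midpoint rooting."""
    pruned, _, _ = fit_lognormal_prune(tree, taxonomy)
    return weighted_midpoint_root(pruned)


def process_epoc(
    tree: dendropy.Tree,
    alignment: Alignment,
    taxonomy: TaxonomyTable,
    config: RunConfig | None = None,
    epoc_id: str = "epoc",
    category: str = "",
    curate: bool = True,
) -> EpocOutcome:
    """Run one family through the full pipeline; discards become an
    EpocOutcome whose status is the machine-readable reason code."""
    config = config or RunConfig()
    try:
        work = curate_tree(tree, taxonomy) if curate else tree
        alignment = alignment.subset_rows(
            [leaf.taxon.label for leaf in work.leaf_node_iter()]
        )
        trimmed, _ = trim_alignment(alignment, config.trim_threshold_bits)
        if trimmed.n_sites == 0:
            return EpocOutcome(epoc_id, "empty_alignment")
        clades = detect_clades(work, taxonomy)

        base = load_model(
            config.model_name, n_rate_categories=config.n_rate_categories
        )
        if config.gamma_alpha is None:
            alpha = estimate_gamma_alpha(work, trimmed, base, DEFAULT_ALPHA_GRID)
        else:
            alpha = config.gamma_alpha
        model = base.with_alpha(alpha)

        results = assign_sisters(
            work,
            trimmed,
            taxonomy,
            model,
            epoc_id=epoc_id,
            clades=clades,
            k=config.k_candidates,
            B=config.rell_replicates,
            seed=config.seed,
            opt_tol=config.opt_tol,
            opt_max_rounds=config.opt_max_rounds,
        )
    except EpocDiscarded as exc:
        return EpocOutcome(epoc_id, exc.reason, detail=exc.detail)

    stem_records = []
    for result in results:
        best = result.best_label
        topology = result.topologies[best]
        # the sister is the euk clade's sibling in the regrafted topology
        try:
            record = make_stem_record(
                topology,
                result.euk_leaf_ids,
                _sister_clade_ids(topology, result.euk_leaf_ids),
                epoc_id=epoc_id,
                euk_clade_id=result.euk_clade_id,
                sister_label=best,
                category=category,
                best_elw=result.best_elw,
            )
        except StemUndefined:
            continue
        stem_records.append(record)
    return EpocOutcome(
        epoc_id,
        "ok",
        alpha=alpha,
        elw_results=results,
        stem_records=stem_records,
        clades=clades,
    )


def _sister_clade_ids(topology: dendropy.Tree, euk_leaf_ids) -> set[str]:
    from .trees import leaf_ids, mrca

    euk_node = mrca(topology, euk_leaf_ids)
    parent = euk_node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not euk_node]
    out: set[str] = set()
    for sib in siblings:
        out |= leaf_ids(sib)
    return out


def results_frames(
    outcomes: list[EpocOutcome],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(elw table, stems table, discard log) across a run."""
    elw_frames = [
        r.to_frame() for o in outcomes for r in o.elw_results
    ]
    elw = (
        pd.concat(elw_frames, ignore_index=True)
        if elw_frames
        else pd.DataFrame(
            columns=[
                "epoc_id",
                "euk_clade_id",
                "candidate_label",
                "elw",
                "rank",
                "n_sites",
                "alpha",
            ]
        )
    )
    from .stems import stem_records_frame

    stems = stem_records_frame(
        [rec for o in outcomes for rec in o.stem_records]
    )
    discards = pd.DataFrame(
        [
            {"epoc_id": o.epoc_id, "reason": o.status, "detail": o.detail}
            for o in outcomes
            if o.status != "ok"
        ],
        columns=["epoc_id", "reason", "detail"],
    )
    return elw, stems, discards
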