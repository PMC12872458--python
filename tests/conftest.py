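import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from epocflow.msa import Alignment  # noqa: E402
from epocflow.substitution import load_model  # noqa: E402
from epocflow.synthetic import (  # noqa: E402
    PROK_CLASSES,
    SimConfig,
    generate_epoc,
)
from epocflow.taxonomy import TaxonomyTable  # noqa: E402
from epocflow.trees import read_newick  # noqa: E402


@pytest.fixture(scope="session")
def lg():
    return load_model("LG")


@pytest.fixture(scope="session")
def lg_g4():
    return load_model("LG", gamma_alpha=1.0)


@pytest.fixture(scope="session")
def poisson():
    return load_model("poisson")


def random_tree(rng: np.random.Generator, n_leaves: int, scale: float = 0.2):
    """Random topology with exponential-ish branch lengths, labels t0..tn."""
    labels = [f"t{i}" for i in range(n_leaves)]
    parts = [f"{l}:{rng.uniform(0.05, scale):.6f}" for l in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        a, b = parts[i], parts[j]
        merged = f"({a},{b}):{rng.uniform(0.05, scale):.6f}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(merged)
    newick = parts[0].rsplit(":", 1)[0] + ";"
    return read_newick(newick)


def random_alignment(rng: np.random.Generator, ids, n_sites: int):
    from epocflow._alphabet import AA

    seqs = [
        "".join(AA[k] for k in rng.integers(0, 20, size=n_sites)) for _ in ids
    ]
    return Alignment(list(ids), seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def taxonomy_for(prefix_map: dict) -> TaxonomyTable:
    """prefix_map: leaf id -> (label, domain, supergroup) shortcuts."""
    table = TaxonomyTable()
    for leaf, (label, domain, sg) in prefix_map.items():
        table.add(leaf, label, domain, sg)
    return table


# ------------------------------------------------- shared recovery experiment


@dataclass
class RecoveryRun:
    n_families: int
    hits: int
    truth_elws: list
    outcomes: list
    donors: list


def run_recovery(
    n_families: int,
    seed: int = 42,
    n_prok_classes: int = 10,
    n_sites: int = 160,
    leaves_per_class=(4, 6),
    n_euk_leaves=(8, 12),
    stem_range=(0.2, 0.5),
    gamma_alpha: float = 1.0,
    B: int = 1000,
) -> RecoveryRun:
    """End-to-end seeded sister-recovery experiment used by the
    acceptance suite; curation + trimming + ELW assignment per family."""
    from epocflow.pipeline import RunConfig, process_epoc

    rng = np.random.default_rng(seed)
    hits = 0
    truth_elws = []
    outcomes = []
    donors = []
    for i in range(n_families):
        donor = PROK_CLASSES[int(rng.integers(len(PROK_CLASSES)))]
        stem = float(rng.uniform(*stem_range))
        cfg = SimConfig(
            n_prok_classes=n_prok_classes,
            leaves_per_class=leaves_per_class,
            n_euk_leaves=n_euk_leaves,
            donor_label=donor,
            stem_length=stem,
            n_sites=n_sites,
            gamma_alpha=gamma_alpha,
            seed=seed + 1000 * i,
        )
        epoc = generate_epoc(cfg, f"epoc_{i:03d}")
        outcome = process_epoc(
            epoc.tree,
            epoc.alignment,
            epoc.taxonomy,
            config=RunConfig(gamma_alpha=gamma_alpha, rell_replicates=B, seed=seed),
            epoc_id=epoc.epoc_id,
            category=epoc.category,
        )
        outcomes.append(outcome)
        donors.append(donor)
        if outcome.status != "ok" or not outcome.elw_results:
            truth_elws.append(0.0)
            continue
        result = outcome.elw_results[0]
        if result.best_label == donor:
            hits += 1
        if donor in result.candidates:
            truth_elws.append(float(result.elw[result.candidates.index(donor)]))
        else:
            truth_elws.append(0.0)
    return RecoveryRun(
        n_families=n_families,
        hits=hits,
        truth_elws=truth_elws,
        outcomes=outcomes,
        donors=donors,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """The 30-family recovery experiment (shared; takes a few minutes)."""
    return run_recovery(n_families=30, seed=42)


def run_nsl_grid(
    grid=(0.05, 0.1, 0.2, 0.4, 0.8), n_reps: int = 4, seed: int = 1000
):
    """Mean estimated NSL per truth stem: optimize branch lengths on the
    true topology from a simulated alignment, read the stem back off the
    estimated tree."""
    from epocflow.likelihood import optimize_branch_lengths
    from epocflow.stems import make_stem_record

    model = load_model("LG", gamma_alpha=1.0)
    mean_nsl = []
    for stem in grid:
        vals = []
        for rep in range(n_reps):
            cfg = SimConfig(
                n_prok_classes=6,
                leaves_per_class=(3, 4),
                n_euk_leaves=(6, 8),
                stem_length=stem,
                n_sites=300,
                gamma_alpha=1.0,
                seed=seed + rep,
            )
            epoc = generate_epoc(cfg, f"s{stem}_{rep}")
            opt = optimize_branch_lengths(
                epoc.tree, epoc.alignment, model, max_rounds=2
            )
            euk = epoc.truth.euk_clades[0]
            donor_ids = {
                i
                for i in epoc.taxonomy.entries
                if epoc.taxonomy.label(i) == epoc.truth.donors[0]
            }
            vals.append(make_stem_record(opt.tree, euk, donor_ids).NSL)
        mean_nsl.append(float(np.mean(vals)))
    return list(grid), mean_nsl


@pytest.fixture(scope="session")
def nsl_grid_run():
    return run_nsl_grid()
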