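"""Seeded generator of gene families with a known prokaryotic donor.

Trees are pure-birth within-class subtrees hung off a randomly joined
class backbone; eukaryotic clades attach as sister to their donor clade
by a stem branch of configurable length.  Sequences evolve under the
same substitution models used for inference, so recovery experiments are
well specified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._alphabet import AA, N_STATES
from .msa import Alignment
from .substitution import SubstitutionModel, load_model
from .trees import mrca as trees_mrca
from .taxonomy import (
    AMORPHEA,
    DIAPHORETICKES,
    EUKARYOTE,
    NOT_APPLICABLE,
    OTHER_SUPERGROUP,
    PROKARYOTE,
    TaxonomyTable,
)

PROK_CLASSES = (
    "Asgard",
    "Alphaproteobacteria",
    "Cyanobacteriota",
    "Actinomycetota",
    "Myxococcota",
    "Bacteroidia",
    "Clostridia",
    "Bacilli",
    "Gammaproteobacteria",
    "Thermococci",
    "Methanomicrobia",
    "Halobacteria",
    "Desulfobacteriota",
    "Spirochaetia",
    "Chlamydiia",
    "Planctomycetia",
    "Verrucomicrobiae",
    "Deinococci",
    "Chloroflexia",
    "Campylobacteria",
    "Fusobacteriia",
    "Aquificae",
    "Thermotogae",
    "Nitrososphaeria",
    "Archaeoglobi",
    "Thermoplasmata",
)

EUK_SUPERGROUP = {
    "Metazoa": AMORPHEA,
    "Fungi": AMORPHEA,
    "Amoebozoa": AMORPHEA,
    "Choanoflagellata": AMORPHEA,
    "Streptophyta": DIAPHORETICKES,
    "Chlorophyta": DIAPHORETICKES,
    "Stramenopiles": DIAPHORETICKES,
    "Alveolata": DIAPHORETICKES,
    "Rhizaria": DIAPHORETICKES,
    "Discoba": OTHER_SUPERGROUP,
    "Metamonada": OTHER_SUPERGROUP,
}
EUK_CLASSES = tuple(EUK_SUPERGROUP)
AMORPHEA_CLASSES = tuple(k for k, v in EUK_SUPERGROUP.items() if v == AMORPHEA)
DIAPHORETICKES_CLASSES = tuple(
    k for k, v in EUK_SUPERGROUP.items() if v == DIAPHORETICKES
)

CATEGORIES = (
    "ribosome",
    "oxidative_phosphorylation",
    "dna_replication",
    "transcription",
    "glycolysis",
    "lipid_metabolism",
    "protein_folding",
    "vesicle_traffic",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_prok_classes: int = 10
    leaves_per_class: tuple[int, int] = (4, 7)
    donor_label: str = "Asgard"
    stem_length: float = 0.3
    n_sites: int = 200
    gamma_alpha: float | None = 1.0
    n_euk_clades: int = 1
    n_euk_leaves: tuple[int, int] = (8, 12)
    hgt_rate: float = 0.0
    outlier_scale: float = 50.0
    n_outliers: int = 0
    model_name: str = "LG"
    backbone_scale: float = 0.16
    within_scale: float = 0.10
    length_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.donor_label not in PROK_CLASSES:
            raise ConfigurationError(f"unknown donor label {self.donor_label!r}")
        if not (1 <= self.n_prok_classes <= len(PROK_CLASSES)):
            raise ConfigurationError("n_prok_classes out of range")
        if self.stem_length < 0:
            raise ConfigurationError("stem_length must be >= 0")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if not (1 <= self.n_euk_clades <= 3):
            raise ConfigurationError("n_euk_clades must be in 1..3")
        if not (0.0 <= self.hgt_rate <= 1.0):
            raise ConfigurationError("hgt_rate must be a probability")


@dataclass
class Truth:
    donors: list[str]
    stem_length: float
    euk_clades: list[frozenset[str]]
    injected_outliers: list[str] = field(default_factory=list)
    injected_hgt: list[str] = field(default_factory=list)


@dataclass
class SyntheticEpoc:
    epoc_id: str
    tree: dendropy.Tree
    taxonomy: TaxonomyTable
    truth: Truth
    category: str
    alignment: Alignment | None = None


# ------------------------------------------------------------- tree builder


def _yule_subtree(
    ns: dendropy.TaxonNamespace,
    labels: list[str],
    rng: np.random.Generator,
    scale: float,
    sigma: float = 0.7,
) -> dendropy.Node:
    """Pure-birth subtree over the given leaf labels with log-normal-ish
    branch lengths of the given scale."""

    def new_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label)
        node.edge.length = _draw_length(rng, scale, sigma)
        return node

    tips = [new_leaf(labels[0])]
    for label in labels[1:]:
        split = tips[rng.integers(len(tips))]
        left = dendropy.Node()
        left.taxon = split.taxon
        left.edge.length = _draw_length(rng, scale, sigma)
        right = new_leaf(label)
        split.taxon = None
        split.add_child(left)
        split.add_child(right)
        tips.remove(split)
        tips.extend([left, right])
    root = tips[0]
    while root.parent_node is not None:
        root = root.parent_node
    return root


def _draw_length(rng: np.random.Generator, scale: float, sigma: float = 0.7) -> float:
    return float(np.exp(rng.normal(np.log(scale), sigma)))


def simulate_gene_tree(
    config: SimConfig,
) -> tuple[dendropy.Tree, TaxonomyTable, Truth]:
    """Rooted tree with monophyletic prokaryotic class clades and
    eukaryotic clades attached as sister to their donor clades."""
    rng = np.random.default_rng(config.seed)
    donor = config.donor_label
    others = [c for c in PROK_CLASSES if c != donor]
    labels = [donor] + others[: config.n_prok_classes - 1]

    ns = dendropy.TaxonNamespace()
    taxonomy = TaxonomyTable()
    class_roots: dict[str, dendropy.Node] = {}
    lo, hi = config.leaves_per_class
    for label in labels:
        k = int(rng.integers(lo, hi + 1))
        leaf_names = [f"{label}_{i:02d}" for i in range(k)]
        for name in leaf_names:
            taxonomy.add(name, label, PROKARYOTE, NOT_APPLICABLE)
        root = _yule_subtree(ns, leaf_names, rng, config.within_scale, config.length_sigma)
        class_roots[label] = root

    # random backbone: successively join random pairs of class subtrees
    subtrees = [class_roots[label] for label in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        joined = dendropy.Node()
        joined.add_child(a)
        joined.add_child(b)
        a.edge.length = _draw_length(rng, config.backbone_scale, config.length_sigma)
        b.edge.length = _draw_length(rng, config.backbone_scale, config.length_sigma)
        subtrees = [s for k_, s in enumerate(subtrees) if k_ not in (i, j)]
        subtrees.append(joined)
    backbone_root = subtrees[0]

    # eukaryotic clades, each sister to its own donor clade
    donors = [donor]
    extra_pool = [lab for lab in labels if lab != donor]
    for extra in range(config.n_euk_clades - 1):
        pick = extra_pool[int(rng.integers(len(extra_pool)))]
        extra_pool.remove(pick)
        donors.append(pick)

    truth_clades: list[frozenset[str]] = []
    elo, ehi = config.n_euk_leaves
    for ci, clade_donor in enumerate(donors, start=1):
        k = int(rng.integers(elo, ehi + 1))
        leaf_names = [f"Euk{ci}_{i:02d}" for i in range(k)]
        euk_labels = []
        for i in range(k):
            if i == 0:
                lab = AMORPHEA_CLASSES[int(rng.integers(len(AMORPHEA_CLASSES)))]
            elif i == 1 and k >= 2:
                lab = DIAPHORETICKES_CLASSES[
                    int(rng.integers(len(DIAPHORETICKES_CLASSES)))
                ]
            else:
                lab = EUK_CLASSES[int(rng.integers(len(EUK_CLASSES)))]
            euk_labels.append(lab)
        for name, lab in zip(leaf_names, euk_labels):
            taxonomy.add(name, lab, EUKARYOTE, EUK_SUPERGROUP[lab])
        euk_root = _yule_subtree(ns, leaf_names, rng, config.within_scale, config.length_sigma)
        euk_root.edge.length = config.stem_length

        target = class_roots[clade_donor]
        parent = target.parent_node
        attach = dendropy.Node()
        if parent is None:
            backbone_root = attach
        else:
            parent.remove_child(target)
            parent.add_child(attach)
            attach.edge.length = (target.edge.length or 0.0) / 2.0
            target.edge.length = (target.edge.length or 0.0) / 2.0
        attach.add_child(target)
        attach.add_child(euk_root)
        truth_clades.append(frozenset(leaf_names))

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = backbone_root
    backbone_root.edge.length = None
    truth = Truth(
        donors=donors, stem_length=config.stem_length, euk_clades=truth_clades
    )
    return tree, taxonomy, truth


# --------------------------------------------------------- sequence evolver


def evolve_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
) -> Alignment:
    """Evolve one amino-acid sequence per leaf down the tree.

    Site rates are i.i.d. continuous gamma (shape = model.gamma_alpha,
    mean 1); a None alpha means rate homogeneity.
    """
    rng = np.random.default_rng(seed)
    if model.gamma_alpha is not None:
        rates = rng.gamma(model.gamma_alpha, 1.0 / model.gamma_alpha, size=n_sites)
    else:
        rates = np.ones(n_sites)

    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(N_STATES, size=n_sites, p=pi)

    evals, right, left = model._evals, model._right, model._left
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        if not np.isfinite(t) or t < 0:
            raise ValueError("branch lengths must be finite and >= 0")
        parent_states = states[id(node.parent_node)]
        if t == 0:
            states[id(node)] = parent_states.copy()
            continue
        # per-site transition rows for the parent state
        expd = np.exp(evals[None, :] * (t * rates)[:, None])  # (sites, 20)
        rows = np.einsum(
            "sj,sj,jk->sk", right[parent_states], expd, left
        )
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)
        u = rng.random(n_sites)
        states[id(node)] = np.minimum(
            (rows.cumsum(axis=1) < u[:, None]).sum(axis=1), N_STATES - 1
        )

    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        seqs.append("".join(AA[s] for s in states[id(leaf)]))
    return Alignment(ids, seqs)


# ------------------------------------------------------------- perturbations


def inject_hgt_leaf(epoc: SyntheticEpoc, seed: int) -> SyntheticEpoc:
    """Graft one prokaryote-labeled leaf inside a eukaryotic clade.

    Modifies tree/taxonomy/truth in place (alignment must not exist yet);
    no-op with a warning when no eukaryotic clade can host a graft.
    """
    if epoc.alignment is not None:
        raise ValueError("inject before evolving the alignment")
    rng = np.random.default_rng(seed)
    hosts = [c for c in epoc.truth.euk_clades if len(c) >= 2]
    if not hosts:
        warnings.warn("no eukaryotic clade large enough to host an HGT graft")
        return epoc
    host = hosts[int(rng.integers(len(hosts)))]
    mrca = trees_mrca(epoc.tree, host)
    inside = [
        n for n in mrca.preorder_iter() if n is not mrca
    ]
    target = inside[int(rng.integers(len(inside)))]

    prok_labels = sorted(
        {
            r.class_label
            for r in epoc.taxonomy.entries.values()
            if r.domain == PROKARYOTE
        }
    )
    label = prok_labels[int(rng.integers(len(prok_labels)))]
    name = f"HGT_{len(epoc.truth.injected_hgt):02d}"

    parent = target.parent_node
    split = dendropy.Node()
    bl = target.edge.length or 0.0
    parent.remove_child(target)
    parent.add_child(split)
    split.edge.length = bl / 2.0
    split.add_child(target)
    target.edge.length = bl / 2.0
    graft = dendropy.Node()
    graft.taxon = epoc.tree.taxon_namespace.new_taxon(name)
    graft.edge.length = 0.1
    split.add_child(graft)

    epoc.taxonomy.add(name, label, PROKARYOTE, NOT_APPLICABLE)
    epoc.truth.injected_hgt.append(name)
    # the graft sits inside the eukaryotic clade
    epoc.truth.euk_clades = [
        frozenset(c | {name}) if c == host else c for c in epoc.truth.euk_clades
    ]
    return epoc


def inject_outlier(
    epoc: SyntheticEpoc, seed: int, scale: float | None = None, target: str = "leaf"
) -> SyntheticEpoc:
    """Stretch one branch by ``scale``; target 'leaf' picks a random
    prokaryotic tip branch, 'stem' stretches the first eukaryotic stem."""
    if scale is None:
        scale = 50.0
    rng = np.random.default_rng(seed)
    if target == "stem":
        mrca = trees_mrca(epoc.tree, epoc.truth.euk_clades[0])
        mrca.edge.length = (mrca.edge.length or 0.0) * scale
        epoc.truth.injected_outliers.append("euk_stem_1")
        return epoc
    euk_ids = set().union(*epoc.truth.euk_clades)
    leaves = sorted(
        (
            leaf
            for leaf in epoc.tree.leaf_node_iter()
            if leaf.taxon.label not in euk_ids
        ),
        key=lambda leaf: leaf.taxon.label,
    )
    victim = leaves[int(rng.integers(len(leaves)))]
    victim.edge.length = (victim.edge.length or 0.0) * scale
    epoc.truth.injected_outliers.append(victim.taxon.label)
    return epoc


# ---------------------------------------------------------------- generation


def generate_epoc(config: SimConfig, epoc_id: str = "epoc_000") -> SyntheticEpoc:
    """Full family: tree + perturbations + alignment + category label."""
    tree, taxonomy, truth = simulate_gene_tree(config)
    rng = np.random.default_rng(config.seed + 7)
    category = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
    epoc = SyntheticEpoc(
        epoc_id=epoc_id, tree=tree, taxonomy=taxonomy, truth=truth, category=category
    )
    if rng.random() < config.hgt_rate:
        inject_hgt_leaf(epoc, config.seed + 11)
    for i in range(config.n_outliers):
        inject_outlier(epoc, config.seed + 13 + i, scale=config.outlier_scale)
    model = load_model(config.model_name, gamma_alpha=config.gamma_alpha)
    epoc.alignment = evolve_alignment(
        epoc.tree, model, config.n_sites, seed=config.seed + 17
    )
    return epoc


def generate_epoc_set(
    config: SimConfig,
    n_families: int,
    out_dir: str | Path,
    seed: int | None = None,
) -> pd.DataFrame:
    """Serialize n families (FASTA + Newick + taxonomy TSV) with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if seed is None else seed
    rows = []
    for i in range(n_families):
        fam_config = replace(config, seed=base_seed + 1000 * i)
        epoc_id = f"epoc_{i:04d}"
        epoc = generate_epoc(fam_config, epoc_id=epoc_id)
        epoc.alignment.write_fasta(out / f"{epoc_id}.fasta")
        epoc.tree.write(
            path=str(out / f"{epoc_id}.nwk"),
            schema="newick",
            unquoted_underscores=True,
        )
        epoc.taxonomy.write_tsv(out / f"{epoc_id}.taxonomy.tsv")
        rows.append(
            {
                "epoc_id": epoc_id,
                "donor_label": ";".join(epoc.truth.donors),
                "stem_length": epoc.truth.stem_length,
                "category": epoc.category,
                "seed": fam_config.seed,
                "n_leaves": len(epoc.taxonomy),
                "injected_hgt": ";".join(epoc.truth.injected_hgt),
                "injected_outliers": ";".join(epoc.truth.injected_outliers),
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "epoc_id",
            "donor_label",
            "stem_length",
            "category",
            "seed",
            "n_leaves",
            "injected_hgt",
            "injected_outliers",
        ],
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
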