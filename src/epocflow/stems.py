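"""Stem-length extraction, normalization and distributional comparison.

The stem is the branch from the common ancestor of the eukaryotic clade
and its assigned sister down to the eukaryotic clade root; normalization
divides by the median root-to-leaf distance within the eukaryotic clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu as _scipy_mwu

from .trees import mrca

EXACT_MWU_MAX_N = 14


class StemUndefined(ValueError):
    """All eukaryotic leaf depths are zero; NSL has no value."""


def stem_length(
    tree: dendropy.Tree,
    euk_leaf_ids,
    sister_leaf_ids,
) -> float:
    """Branch length from the euk+sister common parent to the euk clade root."""
    euk_node = mrca(tree, euk_leaf_ids)
    sister_node = mrca(tree, sister_leaf_ids)
    if euk_node.parent_node is None or sister_node.parent_node is None:
        raise ValueError("clades are not sisters (one is the root)")
    if euk_node.parent_node is not sister_node.parent_node:
        raise ValueError("clades are not sisters in this topology")
    return float(euk_node.edge.length or 0.0)


def euk_leaf_depths(tree: dendropy.Tree, euk_leaf_ids) -> np.ndarray:
    """Path distances from the eukaryotic clade root to each of its leaves."""
    euk_node = mrca(tree, euk_leaf_ids)
    wanted = set(euk_leaf_ids)
    depths = {id(euk_node): 0.0}
    out = []
    for node in euk_node.preorder_iter():
        if node is euk_node:
            continue
        depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf() and node.taxon.label in wanted:
            out.append(depths[id(node)])
    return np.asarray(out)


@dataclass
class StemRecord:
    epoc_id: str
    euk_clade_id: str
    sister_label: str
    SL: float
    med_bl: float
    NSL: float
    category: str = ""
    best_elw: float = float("nan")


def make_stem_record(
    tree: dendropy.Tree,
    euk_leaf_ids,
    sister_leaf_ids,
    epoc_id: str = "epoc",
    euk_clade_id: str = "euk_1",
    sister_label: str = "",
    category: str = "",
    best_elw: float = float("nan"),
) -> StemRecord:
    """SL, med_bl and NSL for one assigned sister on its evaluated topology.

    Raises StemUndefined when every eukaryotic leaf depth is zero
    (the record is then dropped upstream with a reason code).
    """
    sl = stem_length(tree, euk_leaf_ids, sister_leaf_ids)
    depths = euk_leaf_depths(tree, euk_leaf_ids)
    if len(depths) < 2:
        raise StemUndefined("eukaryotic clade must have >= 2 leaves")
    med = float(np.median(depths))
    if med == 0.0:
        raise StemUndefined("all eukaryotic leaf depths are zero")
    return StemRecord(
        epoc_id=epoc_id,
        euk_clade_id=euk_clade_id,
        sister_label=sister_label,
        SL=sl,
        med_bl=med,
        NSL=sl / med,
        category=category,
        best_elw=best_elw,
    )


def stem_records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "epoc_id": r.epoc_id,
                "euk_clade_id": r.euk_clade_id,
                "sister_label": r.sister_label,
                "SL": r.SL,
                "med_bl": r.med_bl,
                "NSL": r.NSL,
                "category": r.category,
                "best_elw": r.best_elw,
            }
            for r in records
        ]
    )


# --------------------------------------------------------------- bootstraps


def cdf_grid(values, n_points: int = 200) -> np.ndarray:
    """200 even points from 0 to the 99th percentile of the pooled values."""
    values = np.asarray(values, dtype=float)
    upper = float(np.percentile(values, 99))
    if upper <= 0:
        upper = max(float(values.max()), 1e-12)
    return np.linspace(0.0, upper, n_points)


def empirical_cdf(values, grid) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return (values[:, None] <= grid[None, :]).mean(axis=0)


def bootstrap_cdf(
    nsl_values,
    B: int = 200,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical CDFs of B with-replacement resamples plus the point CDF.

    Returns (grid, point_cdf, replicate_cdfs) with replicate_cdfs of
    shape (B, len(grid)).
    """
    values = np.asarray(nsl_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if grid is None:
        grid = cdf_grid(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    reps = (values[idx][:, :, None] <= grid[None, None, :]).mean(axis=1)
    return grid, empirical_cdf(values, grid), reps


# ------------------------------------------------------------- Mann-Whitney


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null enumeration (conditional on the pooled values, so ties are
    handled) when n_a + n_b <= 14; otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    na, nb = a.size, b.size
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return u_obs, 1.0
    if na + nb <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([a, b])
        n = pooled.size
        center = na * nb / 2.0
        dev_obs = abs(u_obs - center)
        hits = total = 0
        for combo in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = _scipy_mwu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def compare_taxa_nsl(
    values_a,
    values_b,
    B: int = 200,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-grid-point Mann-Whitney p-values between two taxa's bootstrap
    CDF value distributions; grid shared (pooled 99th percentile)."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size < 2 or values_b.size < 2:
        raise ValueError("both taxa need >= 2 records")
    if grid is None:
        grid = cdf_grid(np.concatenate([values_a, values_b]))
    _, cdf_a, reps_a = bootstrap_cdf(values_a, B=B, seed=seed, grid=grid)
    _, cdf_b, reps_b = bootstrap_cdf(values_b, B=B, seed=seed, grid=grid)
    pvals = np.empty(grid.size)
    for j in range(grid.size):
        col_a, col_b = reps_a[:, j], reps_b[:, j]
        if np.all(col_a == col_a[0]) and np.all(col_b == col_b[0]) and (
            col_a[0] == col_b[0]
        ):
            pvals[j] = 1.0
        else:
            pvals[j] = mann_whitney_u(col_a, col_b)[1]
    return pd.DataFrame(
        {"nsl": grid, "cdf_a": cdf_a, "cdf_b": cdf_b, "p_value": pvals}
    )
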