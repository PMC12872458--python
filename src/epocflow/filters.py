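"""Soft-core pangenome filtering, core-set selection (with the late-HGT
guard), aELW aggregation by functional category and pathway-level
comparison against a reference taxon."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .taxonomy import DOMAINS, EUKARYOTE

REASON_NO_ANNOTATION = "no_annotation"
REASON_TOO_FEW_LABELS = "too_few_labels"
REASON_MISSING_SUPERGROUP = "missing_supergroup"
REASON_LOW_ELW = "low_elw"
REASON_HIGH_ELW = "high_elw"

ELW_EXCEPTION_SISTER = "Alphaproteobacteria"
ELW_EXCEPTION_PATHWAY = "oxidative_phosphorylation"


# -------------------------------------------------------- soft-core pangenome


def soft_core_pangenome(
    membership: pd.DataFrame,
    prok_frac: float = 0.5,
    euk_frac: float = 0.2,
) -> set[str]:
    """Clusters present in at least the stated fraction of a class's species.

    ``membership`` columns: cluster_id, species_id, class_label, domain.
    A cluster is retained when, for at least one class it contains, its
    distinct-species count reaches the domain's threshold (inclusive >=).
    """
    for frac in (prok_frac, euk_frac):
        if not (0.0 < frac <= 1.0):
            raise ValueError("fractions must be in (0, 1]")
    required = {"cluster_id", "species_id", "class_label", "domain"}
    if not required <= set(membership.columns):
        raise ValueError(f"membership table needs columns {sorted(required)}")
    bad = set(membership["domain"]) - set(DOMAINS)
    if bad:
        raise ValueError(f"unknown domain values: {sorted(bad)}")
    if membership["class_label"].isna().any():
        raise ValueError("missing class label")

    class_sizes = (
        membership.groupby("class_label")["species_id"].nunique().to_dict()
    )
    class_domain = (
        membership.drop_duplicates("class_label")
        .set_index("class_label")["domain"]
        .to_dict()
    )
    counts = (
        membership.groupby(["cluster_id", "class_label"])["species_id"]
        .nunique()
        .reset_index()
    )
    retained: set[str] = set()
    for row in counts.itertuples(index=False):
        threshold = (
            euk_frac if class_domain[row.class_label] == EUKARYOTE else prok_frac
        )
        if row.species_id / class_sizes[row.class_label] >= threshold:
            retained.add(row.cluster_id)
    return retained


# ------------------------------------------------------------------ core set


@dataclass(frozen=True)
class AssociationRecord:
    """One candidate-sister association for one eukaryotic clade."""

    epoc_id: str
    euk_clade_id: str
    sister_label: str
    elw: float
    category: str = ""
    pathway: str = ""
    euk_labels: frozenset[str] = frozenset()
    supergroups: frozenset[str] = frozenset()
    sister_size: int = 0
    max_elw: float = float("nan")  # max ELW over this clade's candidates


@dataclass
class RejectionLog:
    rows: list[dict] = field(default_factory=list)

    def add(self, record: AssociationRecord, reason: str, detail: str = "") -> None:
        self.rows.append(
            {
                "epoc_id": record.epoc_id,
                "euk_clade_id": record.euk_clade_id,
                "sister_label": record.sister_label,
                "reason": reason,
                "detail": detail,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["epoc_id", "euk_clade_id", "sister_label", "reason", "detail"],
        )

    def __len__(self) -> int:
        return len(self.rows)


def _elw_window_violation(
    record: AssociationRecord, elw_low: float, elw_high: float
) -> tuple[str, str] | None:
    max_elw = record.max_elw
    if np.isfinite(max_elw) and max_elw < elw_low:
        return REASON_LOW_ELW, "epoc_max_elw_below_window"
    if record.elw <= elw_low:
        return REASON_LOW_ELW, "candidate_elw_below_window"
    if record.elw >= elw_high:
        exempt = (
            record.sister_label == ELW_EXCEPTION_SISTER
            and record.pathway == ELW_EXCEPTION_PATHWAY
        )
        if not exempt:
            return REASON_HIGH_ELW, "candidate_elw_above_window"
    return None


def core_set_filter(
    records: Iterable[AssociationRecord],
    min_labels: int = 6,
    elw_low: float = 0.4,
    elw_high: float = 0.99,
    require_supergroups: tuple[str, str] = ("Amorphea", "Diaphoretickes"),
) -> tuple[list[AssociationRecord], RejectionLog]:
    """Core-set rules: an annotation, a LECA-spanning eukaryotic clade
    (more than five distinct labels, both deep supergroups) and an open
    ELW window, with the stated high-ELW exception for
    Alphaproteobacteria / oxidative phosphorylation.

    All rules are evaluated for every record, so the outcome is
    independent of rule order; the logged reason is the first violated
    rule in canonical order.
    """
    kept: list[AssociationRecord] = []
    log = RejectionLog()
    for record in records:
        violations: list[tuple[str, str]] = []
        if not record.category:
            violations.append((REASON_NO_ANNOTATION, ""))
        if len(record.euk_labels) < min_labels:
            violations.append(
                (REASON_TOO_FEW_LABELS, f"{len(record.euk_labels)} labels")
            )
        missing = [g for g in require_supergroups if g not in record.supergroups]
        if missing:
            violations.append((REASON_MISSING_SUPERGROUP, ";".join(missing)))
        elw_violation = _elw_window_violation(record, elw_low, elw_high)
        if elw_violation:
            violations.append(elw_violation)
        if violations:
            log.add(record, violations[0][0], violations[0][1])
        else:
            kept.append(record)
    return kept, log


def strict_subset_filter(
    records: Iterable[AssociationRecord],
    min_euk_labels: int = 15,
    min_sister_size: int = 20,
    min_elw: float = 0.7,
) -> list[AssociationRecord]:
    """Stricter subset: >= 15 eukaryotic labels, sister clade >= 20
    sequences, ELW strictly above 0.7."""
    return [
        r
        for r in records
        if len(r.euk_labels) >= min_euk_labels
        and r.sister_size >= min_sister_size
        and r.elw > min_elw
    ]


# ---------------------------------------------------------------- aggregation


@dataclass
class AELWTable:
    """category x taxon matrix of mean ELW with per-cell record counts."""

    aelw: pd.DataFrame
    counts: pd.DataFrame
    epocs_per_category: pd.Series

    def group_small(self, threshold: float = 0.01) -> pd.DataFrame:
        """Fold taxa whose aELW never reaches the threshold into 'other'."""
        strong = self.aelw.columns[(self.aelw.fillna(0) >= threshold).any(axis=0)]
        weak = [c for c in self.aelw.columns if c not in set(strong)]
        out = self.aelw[list(strong)].copy()
        if weak:
            out["other"] = self.aelw[weak].mean(axis=1)
        return out


def aelw_by_category(
    records: Iterable[AssociationRecord],
    by: str = "category",
) -> AELWTable:
    """Arithmetic mean of ELW per (category, sister taxon) cell."""
    rows = [
        {
            "epoc_id": r.epoc_id,
            "group": getattr(r, by),
            "taxon": r.sister_label,
            "elw": r.elw,
        }
        for r in records
    ]
    if not rows:
        empty = pd.DataFrame()
        return AELWTable(empty, empty, pd.Series(dtype=float))
    df = pd.DataFrame(rows)
    df = df[df["group"] != ""]
    aelw = df.pivot_table(index="group", columns="taxon", values="elw", aggfunc="mean")
    counts = df.pivot_table(
        index="group", columns="taxon", values="elw", aggfunc="count"
    ).fillna(0).astype(int)
    epocs = df.groupby("group")["epoc_id"].nunique()
    return AELWTable(aelw=aelw, counts=counts, epocs_per_category=epocs)


def relative_aelw_vs_reference(
    table: AELWTable,
    reference: str = "Asgard",
    min_epocs: int = 20,
) -> pd.DataFrame:
    """Per non-reference taxon: its best pathway (by own aELW) among
    pathways with at least ``min_epocs`` EPOCs, paired with the reference
    aELW on the same pathway and their ratio."""
    if reference not in table.aelw.columns:
        raise ValueError(f"reference taxon {reference!r} absent from table")
    qualifying = table.epocs_per_category[
        table.epocs_per_category >= min_epocs
    ].index
    rows = []
    for taxon in table.aelw.columns:
        if taxon == reference:
            continue
        series = table.aelw.loc[
            table.aelw.index.isin(qualifying), taxon
        ].dropna()
        if series.empty:
            rows.append(
                {
                    "taxon": taxon,
                    "pathway": None,
                    "taxon_aelw": np.nan,
                    "reference_aelw": np.nan,
                    "ratio": np.nan,
                    "note": "no qualifying pathway",
                }
            )
            continue
        best_pathway = series.idxmax()
        taxon_aelw = float(series.loc[best_pathway])
        ref_aelw = float(table.aelw.loc[best_pathway, reference])
        rows.append(
            {
                "taxon": taxon,
                "pathway": best_pathway,
                "taxon_aelw": taxon_aelw,
                "reference_aelw": ref_aelw,
                "ratio": taxon_aelw / ref_aelw if ref_aelw > 0 else np.inf,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
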