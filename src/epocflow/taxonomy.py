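"""Taxonomy table: sequence id -> (class label, domain, supergroup)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

PROKARYOTE = "prokaryote"
EUKARYOTE = "eukaryote"
DOMAINS = (PROKARYOTE, EUKARYOTE)

AMORPHEA = "Amorphea"
DIAPHORETICKES = "Diaphoretickes"
OTHER_SUPERGROUP = "other"
NOT_APPLICABLE = "not_applicable"
SUPERGROUPS = (AMORPHEA, DIAPHORETICKES, OTHER_SUPERGROUP, NOT_APPLICABLE)


@dataclass(frozen=True)
class TaxonRecord:
    class_label: str
    domain: str
    supergroup: str

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.supergroup not in SUPERGROUPS:
            raise ValueError(f"unknown supergroup {self.supergroup!r}")
        if (self.supergroup != NOT_APPLICABLE) != (self.domain == EUKARYOTE):
            raise ValueError(
                "supergroup must be 'not_applicable' iff domain is prokaryote"
            )


@dataclass
class TaxonomyTable:
    """Mapping of unique sequence ids to taxonomic annotations."""

    entries: dict[str, TaxonRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> TaxonRecord:
        return self.entries[seq_id]

    def add(self, seq_id: str, class_label: str, domain: str, supergroup: str) -> None:
        if seq_id in self.entries:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        self.entries[seq_id] = TaxonRecord(class_label, domain, supergroup)

    def label(self, seq_id: str) -> str:
        return self.entries[seq_id].class_label

    def domain(self, seq_id: str) -> str:
        return self.entries[seq_id].domain

    def is_eukaryote(self, seq_id: str) -> bool:
        return self.entries[seq_id].domain == EUKARYOTE

    def class_labels(self) -> set[str]:
        return {r.class_label for r in self.entries.values()}

    def ids_with_label(self, label: str) -> list[str]:
        return [i for i, r in self.entries.items() if r.class_label == label]

    def subset(self, ids: Iterable[str]) -> "TaxonomyTable":
        ids = set(ids)
        return TaxonomyTable({i: r for i, r in self.entries.items() if i in ids})

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, r.class_label, r.domain, r.supergroup)
            for i, r in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["id", "class_label", "domain", "supergroup"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, str, str]]) -> "TaxonomyTable":
        table = cls()
        for seq_id, (label, domain, supergroup) in mapping.items():
            table.add(seq_id, label, domain, supergroup)
        return table

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.id, row.class_label, row.domain, row.supergroup)
        return table
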