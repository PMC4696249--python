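"""Link FASTA sequences to tree leaves and extract the subset under any node.

Sequence ids are matched to leaf labels with the same exact-equality rule the
metadata join uses. Extraction returns records in tree (pre-order leaf) order,
not input-file order, so results are stable under store shuffling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import Node, Tree, subtree_leaves
from .datalink import _match_key

__all__ = [
    "SequenceStore",
    "SequenceLinkReport",
    "ExtractionResult",
    "link_sequences",
    "extract_subtree_sequences",
    "write_fasta",
]

_NUCLEOTIDE = set("ACGTUNRYSWKMBDHV-.")


class SequenceStore:
    """In-memory id → (description, residues) FASTA store with unique ids."""

    def __init__(self, records: Iterable[tuple[str, str, str]]):
        self.records: dict[str, tuple[str, str]] = {}
        for rid, description, residues in records:
            if rid in self.records:
                raise ValueError(f"duplicate sequence id {rid!r}")
            if not residues:
                raise ValueError(f"empty sequence for id {rid!r}")
            self.records[rid] = (description, residues.upper())

    @classmethod
    def from_fasta(cls, source) -> "SequenceStore":
        return cls(
            (rec.id, rec.description, str(rec.seq))
            for rec in SeqIO.parse(source, "fasta")
        )

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    @property
    def alphabet(self) -> str:
        """Heuristic, informational only: 'nucleotide' or 'amino acid'."""
        residues = set().union(*(set(s) for _, s in self.records.values()))
        return "nucleotide" if residues <= _NUCLEOTIDE else "amino acid"

    def __contains__(self, rid: str) -> bool:
        return rid in self.records

    def __len__(self) -> int:
        return len(self.records)

    def record(self, rid: str) -> SeqRecord:
        description, residues = self.records[rid]
        return SeqRecord(Seq(residues), id=rid, description=description)


@dataclass
class SequenceLinkReport:
    matched: list[str] = field(default_factory=list)
    leaves_without_sequence: list[str] = field(default_factory=list)
    orphan_ids: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(x, "matched") for x in self.matched]
            + [(x, "leaf_without_sequence") for x in self.leaves_without_sequence]
            + [(x, "orphan_sequence") for x in self.orphan_ids]
        )
        return pd.DataFrame(rows, columns=["entity", "status"])


def link_sequences(
    tree: Tree, store: SequenceStore, split_labels: bool = False
) -> SequenceLinkReport:
    """Report which leaves have a sequence and which sequence ids have no leaf."""
    report = SequenceLinkReport()
    used: set[str] = set()
    for leaf in tree.leaf_labels:
        key = _match_key(leaf, split_labels)
        if key in store:
            report.matched.append(leaf)
            used.add(key)
        else:
            report.leaves_without_sequence.append(leaf)
    report.orphan_ids = [rid for rid in store.ids if rid not in used]
    if not report.matched and len(store):
        warnings.warn("no sequence id matches any leaf label", stacklevel=2)
    return report


@dataclass
class ExtractionResult:
    records: list[SeqRecord]
    missing_leaves: list[str]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def extract_subtree_sequences(
    tree: Tree, node: Node | int, store: SequenceStore, split_labels: bool = False
) -> ExtractionResult:
    """FASTA records for the leaves under ``node``, in tree leaf order.

    Leaves without a stored sequence are listed in ``missing_leaves``.
    """
    records: list[SeqRecord] = []
    missing: list[str] = []
    for leaf in subtree_leaves(tree, node):
        key = _match_key(leaf, split_labels)
        if key in store:
            records.append(store.record(key))
        else:
            missing.append(leaf)
    return ExtractionResult(records=records, missing_leaves=missing)


def write_fasta(records: list[SeqRecord], handle_or_path) -> None:
    """Write records as FASTA, residues wrapped at 60 columns."""
    SeqIO.write(records, handle_or_path, "fasta")


def format_fasta(records: list[SeqRecord]) -> str:
    buf = StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
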