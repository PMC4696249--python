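"""Join tabular metadata onto tree leaves, classify leaves, cross-reference values.

Leaf labels are matched to a key column by exact, case-sensitive string
equality — an automated join with no fuzziness.  A documented fallback
(``split_labels=True``) strips everything after the first whitespace in the
leaf label, matching the common FASTA-header convention where the id is the
first token.

At most :data:`MAX_LINKED_FIELDS` (9) attribute columns may be linked at once,
a compatibility cap inherited from the desktop tool this library mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .tree import Tree

__all__ = [
    "MAX_LINKED_FIELDS",
    "UNLINKED",
    "DataTable",
    "LinkReport",
    "AnnotationSet",
    "Classification",
    "link_dataset",
    "classify",
    "cross_reference",
]

#: Maximum number of attribute columns linkable in one pass (compatibility cap).
MAX_LINKED_FIELDS = 9

#: Category assigned to leaves with no matching table row.
UNLINKED = "unlinked"


class DataTable:
    """A CSV-backed table with a designated key column matched to leaf labels.

    All values are carried as text.  Duplicate keys are detected and recorded
    (first occurrence wins on lookup).
    """

    def __init__(self, frame: pd.DataFrame, key_column: str):
        if key_column not in frame.columns:
            raise ValueError(f"key column {key_column!r} not in table columns")
        self.frame = frame.astype(str)
        self.key_column = key_column
        keys = self.frame[key_column]
        self.duplicate_keys: list[str] = sorted(keys[keys.duplicated()].unique())

    @classmethod
    def from_csv(cls, path, key_column: str, delimiter: str = ",") -> "DataTable":
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
        return cls(frame, key_column)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def keys(self) -> list[str]:
        return list(self.frame[self.key_column])

    def row_for_key(self, key: str) -> dict[str, str] | None:
        hits = self.frame[self.frame[self.key_column] == key]
        if hits.empty:
            return None
        return hits.iloc[0].to_dict()  # first occurrence wins

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LinkReport:
    matched: list[str] = field(default_factory=list)
    unmatched_leaves: list[str] = field(default_factory=list)
    unmatched_keys: list[str] = field(default_factory=list)
    duplicate_keys: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_unmatched_leaves(self) -> int:
        return len(self.unmatched_leaves)

    def to_frame(self) -> pd.DataFrame:
        """Report rows (entity, status) — CSV-writable."""
        rows = (
            [(x, "matched") for x in self.matched]
            + [(x, "unmatched_leaf") for x in self.unmatched_leaves]
            + [(x, "unmatched_key") for x in self.unmatched_keys]
            + [(x, "duplicate_key") for x in self.duplicate_keys]
        )
        return pd.DataFrame(rows, columns=["entity", "status"])


@dataclass
class AnnotationSet:
    """Per-leaf linked attribute records plus the link bookkeeping."""

    tree: Tree
    fields: list[str]
    records: dict[str, dict[str, str]]  # leaf label -> {field: value}
    link_report: LinkReport

    def value(self, leaf: str, field_name: str) -> str | None:
        rec = self.records.get(leaf)
        return None if rec is None else rec.get(field_name)


def _match_key(label: str, split_labels: bool) -> str:
    return label.split()[0] if split_labels and label.split() else label


def link_dataset(
    tree: Tree,
    table: DataTable,
    fields: list[str],
    split_labels: bool = False,
) -> AnnotationSet:
    """Join ``fields`` of ``table`` onto the leaves of ``tree`` by key.

    Matching is exact string equality between the leaf label and the key value
    (``split_labels`` truncates labels at the first whitespace first).  The
    report satisfies ``n_matched + n_unmatched_leaves == leaf count``.
    """
    fields = list(fields)
    if len(fields) > MAX_LINKED_FIELDS:
        raise ValueError(
            f"cannot link {len(fields)} fields: at most {MAX_LINKED_FIELDS} "
            f"fields may be integrated at once"
        )
    if table.key_column in fields:
        raise ValueError("the key column cannot itself be linked as a field")
    missing = [f for f in fields if f not in table.columns]
    if missing:
        raise ValueError(f"fields not in table: {missing}")

    if len(table) == 0:
        warnings.warn("empty table: all leaves unmatched", stacklevel=2)

    records: dict[str, dict[str, str]] = {}
    report = LinkReport(duplicate_keys=list(table.duplicate_keys))
    used_keys: set[str] = set()
    for leaf in tree.leaf_labels:
        key = _match_key(leaf, split_labels)
        row = table.row_for_key(key)
        if row is None:
            report.unmatched_leaves.append(leaf)
        else:
            records[leaf] = {f: row[f] for f in fields}
            report.matched.append(leaf)
            used_keys.add(key)
    report.unmatched_keys = sorted(set(table.keys) - used_keys)
    return AnnotationSet(tree=tree, fields=fields, records=records, link_report=report)


@dataclass
class Classification:
    """Leaf → category assignment for one categorical field.

    Unlinked leaves get the :data:`UNLINKED` category.  The legend lists the
    distinct assigned categories in lexicographic order with their color index.
    """

    field: str
    assignment: dict[str, str]  # every leaf appears exactly once
    legend: list[tuple[str, int]]

    @property
    def categories(self) -> list[str]:
        return [c for c, _ in self.legend]

    def members(self, category: str) -> set[str]:
        return {leaf for leaf, c in self.assignment.items() if c == category}


def classify(annotations: AnnotationSet, field_name: str) -> Classification:
    """Assign every leaf its value of ``field_name`` (or ``unlinked``)."""
    if field_name not in annotations.fields:
        raise ValueError(f"field {field_name!r} was not linked")
    assignment: dict[str, str] = {}
    for leaf in annotations.tree.leaf_labels:
        value = annotations.value(leaf, field_name)
        assignment[leaf] = UNLINKED if value is None else value
    categories = sorted(set(assignment.values()))
    legend = [(c, i) for i, c in enumerate(categories)]
    return Classification(field=field_name, assignment=assignment, legend=legend)


def cross_reference(annotations: AnnotationSet, field_name: str, value: str) -> set[str]:
    """Leaves whose linked ``field_name`` equals ``value`` (exact, case-sensitive).

    The search runs over the linked data, never over leaf labels; an empty
    result is valid.
    """
    if field_name not in annotations.fields:
        raise ValueError(f"field {field_name!r} was not linked")
    return {
        leaf
        for leaf, rec in annotations.records.items()
        if rec.get(field_name) == value
    }
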