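"""Readers and writers for curated interaction tables, SIF files, and edge lists.

A curated interaction table is a delimited text file with one row per
literature-reported molecular interaction and seven columns: the source
molecule (or event), the interaction kind, the target molecule, plus the
optional provenance columns alias, role, reference, and notes.  Molecule
labels are opaque identifiers; no synonym resolution is attempted (the alias
column is carried through, never applied).

SIF (Simple Interaction Format) is the tab-delimited Cytoscape exchange
format: ``source<TAB>interaction<TAB>target`` per edge, a bare label per
isolated node.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

__all__ = [
    "InteractionRecord",
    "SchemaError",
    "RowValidationError",
    "EdgeListParseError",
    "parse_interaction_table",
    "write_interaction_table",
    "read_edge_list",
    "read_sif",
    "write_sif",
]

#: Default interaction label for 2-token edge-list lines.
DEFAULT_INTERACTION = "interacts"

#: Case-insensitive header synonyms for the three mandatory columns and the
#: four optional provenance columns.  Curators name fields in prose, so each
#: canonical name accepts several spellings.
HEADER_SYNONYMS: dict[str, tuple[str, ...]] = {
    "source": ("source", "molecule involved in biochemical reaction (source)", "from"),
    "interaction": ("interaction", "interaction type", "kind of interaction"),
    "target": ("target", "molecule involved in biochemical reaction (target)", "to"),
    "alias": ("alias", "aliases"),
    "role": ("role",),
    "reference": ("reference", "ref", "citation"),
    "notes": ("notes", "note"),
}

MANDATORY_COLUMNS = ("source", "interaction", "target")


class SchemaError(ValueError):
    """A mandatory column is missing from the table header."""


class RowValidationError(ValueError):
    """A data row violates a field-level constraint (e.g. empty source)."""


class EdgeListParseError(ValueError):
    """An edge-list line has an unsupported token count."""


@dataclass(frozen=True)
class InteractionRecord:
    """One curated literature interaction.

    ``source`` and ``target`` are molecule/event labels and must be non-empty
    after whitespace trimming; ``interaction`` is a free-text kind label
    ("activates", "degrades", ...).  The remaining fields are optional
    provenance text and default to the empty string.
    """

    source: str
    interaction: str
    target: str
    alias: str = ""
    role: str = ""
    reference: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("source", "interaction", "target"):
            value = getattr(self, name)
            object.__setattr__(self, name, value.strip())
        if not self.source or not self.target:
            raise RowValidationError(
                f"source and target must be non-empty (got source={self.source!r}, "
                f"target={self.target!r})"
            )
        if not self.interaction:
            raise RowValidationError("interaction label must be non-empty")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.interaction, self.target)


def _resolve_header(columns: Sequence[str]) -> dict[str, str]:
    """Map canonical field names to actual column names, case-insensitively."""
    lowered = {str(c).strip().lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for canonical, synonyms in HEADER_SYNONYMS.items():
        for syn in synonyms:
            if syn in lowered:
                mapping[canonical] = lowered[syn]
                break
    missing = [c for c in MANDATORY_COLUMNS if c not in mapping]
    if missing:
        raise SchemaError(
            f"mandatory column(s) missing from header: {', '.join(missing)}; "
            f"found columns {list(columns)!r}"
        )
    return mapping


def parse_interaction_table(
    stream: IO[str] | str,
    dialect: str = "comma",
) -> list[InteractionRecord]:
    """Parse a delimited curated interaction table into records, in row order.

    Parameters
    ----------
    stream:
        Text stream (or a string holding the table) with a header row.
    dialect:
        ``"comma"`` for CSV, ``"tab"`` for TSV.

    Rows are never deduplicated or reordered; optional fields default to the
    empty string.  Raises :class:`SchemaError` if a mandatory column is
    absent and :class:`RowValidationError` (with the 1-based data-row number)
    if a source/target cell is empty.
    """
    if dialect not in ("comma", "tab"):
        raise ValueError(f"dialect must be 'comma' or 'tab', got {dialect!r}")
    sep = "," if dialect == "comma" else "\t"
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    frame = pd.read_csv(
        stream, sep=sep, dtype=str, keep_default_na=False, skip_blank_lines=True
    )
    mapping = _resolve_header(frame.columns)
    records: list[InteractionRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        values = dict(zip(frame.columns, row))
        fields = {
            canonical: str(values.get(col, "")).strip()
            for canonical, col in mapping.items()
        }
        try:
            records.append(InteractionRecord(**fields))
        except RowValidationError as exc:
            raise RowValidationError(f"row {i}: {exc}") from None
    return records


def write_interaction_table(
    records: Iterable[InteractionRecord],
    stream: IO[str],
    dialect: str = "comma",
) -> None:
    """Write records as a delimited table with the canonical seven-column header."""
    sep = "," if dialect == "comma" else "\t"
    frame = pd.DataFrame(
        [
            (r.source, r.interaction, r.target, r.alias, r.role, r.reference, r.notes)
            for r in records
        ],
        columns=["source", "interaction", "target", "alias", "role", "reference", "notes"],
    )
    frame.to_csv(stream, sep=sep, index=False)


def read_edge_list(stream: IO[str] | str) -> list[InteractionRecord]:
    """Read a plain edge list: 2 or 3 whitespace-separated tokens per line.

    Two-token lines ``A B`` get the interaction label ``"interacts"``;
    three-token lines carry their own label.  Lines starting with ``#`` and
    blank lines are skipped.  Raises :class:`EdgeListParseError` (with the
    line number) for any other token count.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    records: list[InteractionRecord] = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) == 2:
            records.append(InteractionRecord(tokens[0], DEFAULT_INTERACTION, tokens[1]))
        elif len(tokens) == 3:
            records.append(InteractionRecord(tokens[0], tokens[1], tokens[2]))
        else:
            raise EdgeListParseError(
                f"line {lineno}: expected 2 or 3 tokens, got {len(tokens)}: {stripped!r}"
            )
    return records


def read_sif(stream: IO[str] | str) -> tuple[list[InteractionRecord], list[str]]:
    """Read a SIF file; returns (edge records, isolated-node labels).

    SIF lines are tab-delimited ``source<TAB>interaction<TAB>target``; a line
    with a single token declares an isolated node.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    records: list[InteractionRecord] = []
    isolated: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.rstrip("\n")
        if not stripped.strip():
            continue
        tokens = stripped.split("\t")
        if len(tokens) == 1:
            isolated.append(tokens[0].strip())
        elif len(tokens) == 3:
            records.append(InteractionRecord(tokens[0], tokens[1], tokens[2]))
        else:
            raise EdgeListParseError(
                f"line {lineno}: SIF lines carry 1 or 3 tab-separated tokens, "
                f"got {len(tokens)}"
            )
    return records, isolated


def write_sif(network, stream: IO[str]) -> None:
    """Write a network in SIF: one line per edge, bare lines for isolated nodes.

    Node labels must not contain tab characters.  Re-reading the output
    reconstructs an identical node and edge set.
    """
    graph = getattr(network, "graph", network)
    for label in graph.nodes:
        if "\t" in str(label):
            raise ValueError(f"node label contains a tab character: {label!r}")
    for u, v, data in graph.edges(data=True):
        kind = data.get("interaction", DEFAULT_INTERACTION)
        stream.write(f"{u}\t{kind}\t{v}\n")
    for node in graph.nodes:
        if graph.degree(node) == 0:
            stream.write(f"{node}\n")
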