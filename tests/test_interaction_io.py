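"""Curated-table, SIF, and edge-list reading/writing."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capnet.interaction_io import (
    EdgeListParseError,
    InteractionRecord,
    RowValidationError,
    SchemaError,
    parse_interaction_table,
    read_edge_list,
    read_sif,
    write_interaction_table,
    write_sif,
)
from capnet.network_core import BuildPolicy, build_network

TABLE = """source,interaction,target,alias,role,reference,notes
HCO3-,activates,sAC,bicarbonate,input ion,PMID:1,
sAC,produces,cAMP,,,PMID:2,second messenger
"""


class TestParseInteractionTable:
    def test_basic_rows_in_order(self):
        records = parse_interaction_table(TABLE)
        assert [r.triple for r in records] == [
            ("HCO3-", "activates", "sAC"),
            ("sAC", "produces", "cAMP"),
        ]
        assert records[0].alias == "bicarbonate"
        assert records[1].notes == "second messenger"

    def test_header_only_gives_empty_collection(self):
        assert parse_interaction_table("source,interaction,target\n") == []

    def test_duplicate_rows_are_not_deduplicated(self):
        table = "source,interaction,target\nA,activates,B\nA,activates,B\n"
        assert len(parse_interaction_table(table)) == 2

    def test_header_synonyms_case_insensitive(self):
        table = (
            "Molecule involved in biochemical reaction (Source),Interaction,"
            "Molecule involved in biochemical reaction (Target)\nA,acts on,B\n"
        )
        [rec] = parse_interaction_table(table)
        assert rec.triple == ("A", "acts on", "B")

    def test_tab_dialect(self):
        table = "source\tinteraction\ttarget\nA\tdegrades\tB\n"
        [rec] = parse_interaction_table(table, dialect="tab")
        assert rec.triple == ("A", "degrades", "B")

    def test_missing_mandatory_column_names_it(self):
        with pytest.raises(SchemaError, match="target"):
            parse_interaction_table("source,interaction\nA,x\n")

    def test_empty_source_cell_reports_row_number(self):
        table = "source,interaction,target\nA,x,B\n ,x,C\n"
        with pytest.raises(RowValidationError, match="row 2"):
            parse_interaction_table(table)


class TestEdgeList:
    def test_two_token_line_gets_default_label(self):
        [rec] = read_edge_list("A B\n")
        assert rec.triple == ("A", "interacts", "B")

    def test_three_token_line_keeps_label(self):
        [rec] = read_edge_list("A\tactivates\tB\n")
        assert rec.triple == ("A", "activates", "B")

    def test_comments_and_blanks_skipped_counts_preserved(self):
        lines = "\n".join(f"n{i} n{i + 1}" for i in range(47))
        records = read_edge_list("# header comment\n\n" + lines + "\n")
        assert len(records) == 47

    def test_bad_token_count_reports_line_number(self):
        with pytest.raises(EdgeListParseError, match="line 2"):
            read_edge_list("A B\nA B C D\n")


class TestSif:
    def test_edge_line_format(self):
        net = build_network([InteractionRecord("A", "pp", "B")])
        out = io.StringIO()
        write_sif(net, out)
        assert out.getvalue() == "A\tpp\tB\n"

    def test_isolated_node_written_as_bare_label(self):
        net = build_network([InteractionRecord("A", "pp", "B")])
        net.graph.add_node("C")
        out = io.StringIO()
        write_sif(net, out)
        assert "C\n" in out.getvalue()
        records, isolated = read_sif(out.getvalue())
        assert isolated == ["C"]

    def test_tab_in_label_rejected(self):
        net = build_network([InteractionRecord("A", "pp", "B")])
        net.graph.add_node("bad\tlabel")
        with pytest.raises(ValueError, match="tab"):
            write_sif(net, io.StringIO())


labels = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789+-_",
    min_size=1,
    max_size=8,
)
record_strategy = st.builds(InteractionRecord, labels, labels, labels)


@settings(max_examples=50, derandomize=True)
@given(st.lists(record_strategy, min_size=1, max_size=30))
def test_table_round_trip_preserves_triples_in_order(records):
    """parse(write(records)) is the identity on (source, interaction, target)."""
    out = io.StringIO()
    write_interaction_table(records, out)
    parsed = parse_interaction_table(out.getvalue())
    assert [r.triple for r in parsed] == [r.triple for r in records]


@settings(max_examples=50, derandomize=True)
@given(st.lists(record_strategy, min_size=1, max_size=25))
def test_sif_round_trip_reconstructs_the_network(records):
    """write_sif then read_sif yields identical node and edge sets."""
    net = build_network(records, BuildPolicy())
    out = io.StringIO()
    write_sif(net, out)
    parsed, isolated = read_sif(out.getvalue())
    rebuilt = build_network(parsed, BuildPolicy()) if parsed else None
    if rebuilt is None:
        assert set(isolated) == set(net.graph.nodes)
        return
    rebuilt.graph.add_nodes_from(isolated)
    assert set(rebuilt.graph.nodes) == set(net.graph.nodes)
    assert set(rebuilt.graph.edges) == set(net.graph.edges)
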