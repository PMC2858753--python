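"""Readers, writers and domain-type invariants."""

import json

import pytest

from coremetnet.data_model import (
    GraphMetrics,
    MetabolicGraph,
    OrganismProfile,
    Reaction,
    SchemaError,
    ValidationError,
    read_graph,
    read_metrics_report,
    read_organism_profiles,
    read_reaction_table,
    write_graph,
    write_metrics_report,
    write_organism_profiles,
    write_reaction_table,
)
from coremetnet.graph_build import build_graph

REACTION_HEADER = "reaction_id\tec_numbers\teducts\tproducts\tmain_pairs\tspontaneous\tpathway_ids\n"


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReactionTable:
    def test_two_row_file_parses_with_cofactor_flags(self, tmp_path):
        p = write_tsv(
            tmp_path / "r.tsv",
            REACTION_HEADER
            + "R1\t1.1.1.1\tA;ATP\tB;ADP\tA>B\t0\tmap1\n"
            + "R2\t2.7.1.1;2.7.1.2\tC;NADH\tD\tC>D\t0\tmap1;map2\n",
        )
        reactions, compounds = read_reaction_table(p)
        assert len(reactions) == 2
        r1, r2 = reactions
        assert r1.uses_atp and not r1.uses_nad
        assert not r2.uses_atp and r2.uses_nad
        assert r2.ec_numbers == {"2.7.1.1", "2.7.1.2"}
        # participants registered once each, currency flagged
        assert set(compounds) == {"A", "ATP", "B", "ADP", "C", "NADH", "D"}
        assert compounds["ATP"].is_currency and not compounds["A"].is_currency

    def test_empty_main_pairs_row_is_kept_but_edgeless(self, tmp_path):
        p = write_tsv(
            tmp_path / "r.tsv", REACTION_HEADER + "R1\t1.1.1.1\tA\tB\t\t0\t\n"
        )
        reactions, _ = read_reaction_table(p)
        assert len(reactions) == 1
        graph = build_graph(reactions, "ALL")
        assert graph.n_edges == 0

    def test_main_pair_outside_participants_names_reaction(self, tmp_path):
        p = write_tsv(
            tmp_path / "r.tsv", REACTION_HEADER + "RX\t1.1.1.1\tA\tB\tA>Z\t0\t\n"
        )
        with pytest.raises(ValidationError, match="RX"):
            read_reaction_table(p)

    def test_missing_column_is_schema_error_naming_it(self, tmp_path):
        p = write_tsv(
            tmp_path / "r.tsv",
            "reaction_id\tec_numbers\teducts\tproducts\n" "R1\t1.1.1.1\tA\tB\n",
        )
        with pytest.raises(SchemaError, match="main_pairs"):
            read_reaction_table(p)

    def test_row_order_insensitive(self, tmp_path):
        rows = [
            "R1\t1.1.1.1\tA\tB\tA>B\t0\tmap1\n",
            "R2\t2.2.2.2\tB\tC\tB>C\t0\tmap1\n",
            "R3\t\tC\tD\tC>D\t1\tmap2\n",
        ]
        p1 = write_tsv(tmp_path / "a.tsv", REACTION_HEADER + "".join(rows))
        p2 = write_tsv(tmp_path / "b.tsv", REACTION_HEADER + "".join(rows[::-1]))
        ra, ca = read_reaction_table(p1)
        rb, cb = read_reaction_table(p2)
        assert set(ra) == set(rb)
        assert ca == cb

    def test_round_trip_on_synthetic_universe(self, tmp_path, default_study):
        path = tmp_path / "u.tsv"
        write_reaction_table(default_study.reactions, path)
        back, _ = read_reaction_table(path)
        assert set(back) == set(default_study.reactions)


class TestOrganismProfiles:
    def test_sixteen_organism_panel(self, tmp_path):
        codes = [
            ("Hsa", "F"), ("Eco", "FP"), ("Cal", "FP"), ("Sce", "F"),
            ("Spo", "F"), ("Ddi", "F"), ("Dme", "F"), ("Cel", "F"),
            ("Tcr", "OP"), ("Lma", "OP"), ("Tbr", "OP"), ("Pfa", "OP"),
            ("Ehi", "OP"), ("Tpa", "OP"), ("Cho", "OP"), ("Ecu", "OP"),
        ]
        body = "".join(
            f"{code}\tOrganism {code}\tclade\t{cat}\t1.1.1.{i}\n"
            for i, (code, cat) in enumerate(codes)
        )
        p = write_tsv(
            tmp_path / "o.tsv", "code\tname\tclassification\tcategory\tenzymes\n" + body
        )
        profiles = read_organism_profiles(p)
        assert len(profiles) == 16
        assert sum(1 for x in profiles if x.category == "OP") == 8
        assert [x.code for x in profiles] == [c for c, _ in codes]

    def test_duplicate_ec_collapses(self, tmp_path):
        p = write_tsv(
            tmp_path / "o.tsv",
            "code\tname\tclassification\tcategory\tenzymes\n"
            "Tbr\tx\ty\tOP\t1.1.1.1;1.1.1.1;2.2.2.2\n",
        )
        (profile,) = read_organism_profiles(p)
        assert profile.enzymes == {"1.1.1.1", "2.2.2.2"}

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = write_tsv(
            tmp_path / "o.tsv", "code\tname\tclassification\tcategory\tenzymes\n"
        )
        with caplog.at_level("WARNING"):
            assert read_organism_profiles(p) == []
        assert "empty" in caplog.text

    def test_bad_category_rejected(self, tmp_path):
        p = write_tsv(
            tmp_path / "o.tsv",
            "code\tname\tclassification\tcategory\tenzymes\nXxx\tx\ty\tZZ\t1.1.1.1\n",
        )
        with pytest.raises(ValidationError, match="category"):
            read_organism_profiles(p)

    def test_profile_round_trip(self, tmp_path, default_study):
        path = tmp_path / "o.tsv"
        write_organism_profiles(default_study.profiles, path)
        assert set(read_organism_profiles(path)) == set(default_study.profiles)


class TestDomainInvariants:
    def test_spontaneous_with_ec_rejected(self):
        with pytest.raises(ValidationError):
            Reaction(
                reaction_id="R1",
                ec_numbers=frozenset({"1.1.1.1"}),
                educts=frozenset("A"),
                products=frozenset("B"),
                spontaneous=True,
            )

    def test_profile_category_constrained(self):
        with pytest.raises(ValidationError):
            OrganismProfile(code="Xxx", category="parasite")


class TestGraphIO:
    @pytest.fixture()
    def triangle(self):
        return MetabolicGraph.from_edges(
            [("A", "B"), ("B", "C"), ("C", "A")],
            annotations={
                frozenset(("A", "B")): {"R1"},
                frozenset(("B", "C")): {"R2"},
                frozenset(("C", "A")): {"R3"},
            },
            label="triangle",
        )

    @pytest.mark.parametrize("fmt", ["graphml", "sif", "edgelist"])
    def test_round_trip_preserves_node_and_edge_sets(self, tmp_path, triangle, fmt):
        path = tmp_path / f"g.{fmt}"
        write_graph(triangle, path, fmt)
        back = read_graph(path, fmt)
        assert back.nodes == triangle.nodes
        assert back.edges == triangle.edges

    def test_sif_has_one_line_per_edge(self, tmp_path, triangle):
        path = tmp_path / "g.sif"
        write_graph(triangle, path, "sif")
        assert len(path.read_text().strip().splitlines()) == 3

    def test_graphml_round_trip_on_reference(self, tmp_path, reference_graph):
        path = tmp_path / "ref.graphml"
        write_graph(reference_graph, path, "graphml")
        back = read_graph(path, "graphml")
        assert back == reference_graph
        assert back.edge_annotations == reference_graph.edge_annotations

    def test_empty_graph_writes_valid_file(self, tmp_path):
        empty = MetabolicGraph(label="empty")
        path = tmp_path / "e.sif"
        write_graph(empty, path, "sif")
        assert read_graph(path, "sif").n_edges == 0

    def test_unknown_format_rejected(self, tmp_path, triangle):
        with pytest.raises(ValueError, match="format"):
            write_graph(triangle, tmp_path / "g.xyz", "xyz")


class TestMetricsReport:
    METRICS = GraphMetrics(
        n_nodes=4, n_edges=3, density=0.5, avg_connectivity=1.5,
        max_connectivity=2, avg_path_length=1.5, diameter=3,
        global_clustering=0.0, isolated_edges=0,
    )

    def test_tsv_with_group_summaries(self, tmp_path):
        rows = [(f"org{i}", self.METRICS) for i in range(4)]
        cats = {"org0": "OP", "org1": "OP", "org2": "F", "org3": "F"}
        path = tmp_path / "m.tsv"
        write_metrics_report(rows, path, "tsv", categories=cats)
        text = path.read_text()
        assert "mean[OP]" in text and "sd[F]" in text

    def test_single_row_no_summary(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_metrics_report([("only", self.METRICS)], path, "tsv")
        assert "mean[" not in path.read_text()

    def test_json_round_trip(self, tmp_path):
        rows = [("a", self.METRICS), ("b", self.METRICS)]
        path = tmp_path / "m.json"
        write_metrics_report(rows, path, "json")
        assert read_metrics_report(path) == rows
        payload = json.loads(path.read_text())
        assert payload["fields"][0] == "n_nodes"

    def test_empty_rows_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_metrics_report([], tmp_path / "m.tsv", "tsv")
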