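"""Interaction graph: SIF parsing, upstream rule, bounded expansion."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncomatch.catalog import DrugCatalog, DrugRecord, build_indexes
from oncomatch.mesh import NeoplasmVocabulary
from oncomatch.ppi import (
    COMPLEX_TYPE,
    UPSTREAM_IN_TYPES,
    UPSTREAM_OUT_TYPES,
    expand_search,
    parse_sif,
    upstream_interactors,
)

VOCAB = NeoplasmVocabulary.from_headings(["Neoplasms"])


def write_sif(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("".join("\t".join(l) + "\n" for l in lines), encoding="utf-8")
    return path


def tiny_catalog(targets_by_drug):
    """Indexed catalog where every drug is an eligible cancer drug."""
    records = [
        DrugRecord(
            drug_id=drug_id, molecule_type="small molecule", name=drug_id,
            indication="neoplasms", target_genes=tuple(targets),
        )
        for drug_id, targets in targets_by_drug.items()
    ]
    return build_indexes(DrugCatalog(records=records), VOCAB)


def brute_force_upstream(gene, edges):
    """Independent oracle: apply the upstream rule edge by edge."""
    gene = gene.upper()
    found = set()
    for source, itype, target in edges:
        if target == gene and (itype in UPSTREAM_IN_TYPES or itype == COMPLEX_TYPE):
            found.add(source)
        if source == gene and (itype in UPSTREAM_OUT_TYPES or itype == COMPLEX_TYPE):
            found.add(target)
    found.discard(gene)
    return found


class TestParseSif:
    def test_same_edge_in_two_files_collapses_to_one(self, tmp_path):
        line = ("CDK2", "controls-state-change-of", "BRCA1")
        f1 = write_sif(tmp_path, "a.sif", [line])
        f2 = write_sif(tmp_path, "b.sif", [line])
        assert len(parse_sif([f1, f2])) == 1

    def test_unknown_interaction_type_is_skipped_with_warning(self, tmp_path, caplog):
        f = write_sif(
            tmp_path, "a.sif",
            [("A", "binds", "B"), ("CDK2", "controls-state-change-of", "BRCA1")],
        )
        with caplog.at_level("WARNING"):
            graph = parse_sif(f)
        assert len(graph) == 1 and "unknown interaction type" in caplog.text

    def test_disjoint_files_merge_to_union(self, tmp_path):
        e1 = ("A1", "controls-expression-of", "B1")
        e2 = ("A2", "in-complex-with", "B2")
        graph = parse_sif(
            [write_sif(tmp_path, "a.sif", [e1]), write_sif(tmp_path, "b.sif", [e2])]
        )
        assert {(e.source, e.interaction_type, e.target) for e in graph.edges} == {e1, e2}

    def test_no_parseable_edges_is_fatal(self, tmp_path):
        f = write_sif(tmp_path, "a.sif", [("A", "binds", "B")])
        with pytest.raises(ValueError, match="no parseable"):
            parse_sif(f)


class TestUpstreamInteractors:
    def test_regulator_story_cdk_genes_control_brca1(self, tmp_path):
        f = write_sif(
            tmp_path, "a.sif",
            [
                ("CDK2", "controls-state-change-of", "BRCA1"),
                ("CDK7", "controls-expression-of", "BRCA1"),
                ("CDK9", "controls-expression-of", "BRCA1"),
            ],
        )
        assert upstream_interactors("BRCA1", parse_sif(f)) == {"CDK2", "CDK7", "CDK9"}

    def test_gene_absent_from_graph_has_no_interactors(self, graph):
        assert upstream_interactors("NOSUCHGENE", graph) == set()

    def test_downstream_edges_do_not_qualify(self, tmp_path):
        f = write_sif(tmp_path, "a.sif", [("BRCA1", "controls-expression-of", "X")])
        graph = parse_sif(f)
        assert upstream_interactors("BRCA1", graph) == set()
        assert upstream_interactors("X", graph) == {"BRCA1"}

    def test_complex_membership_is_undirected(self, tmp_path):
        f = write_sif(tmp_path, "a.sif", [("A", "in-complex-with", "B")])
        graph = parse_sif(f)
        assert upstream_interactors("A", graph) == {"B"}
        assert upstream_interactors("B", graph) == {"A"}

    def test_nonqualifying_types_are_ignored(self, tmp_path):
        f = write_sif(
            tmp_path, "a.sif",
            [("A", "reacts-with", "B"), ("C", "used-to-produce", "B")],
        )
        assert upstream_interactors("B", parse_sif(f)) == set()

    def test_matches_brute_force_oracle_on_default_graph(self, graph):
        edges = [(e.source, e.interaction_type, e.target) for e in graph.edges]
        for gene in ("BRCA1", "ATM", "TP53", "CDK2"):
            assert upstream_interactors(gene, graph) == brute_force_upstream(gene, edges)


class TestExpandSearch:
    def test_brca1_level1_reaches_flavopiridol_through_cdk7_and_cdk9(self, tmp_path):
        f = write_sif(
            tmp_path, "a.sif",
            [
                ("CDK2", "controls-state-change-of", "BRCA1"),
                ("CDK7", "controls-expression-of", "BRCA1"),
                ("CDK9", "controls-expression-of", "BRCA1"),
            ],
        )
        catalog = tiny_catalog({"DB03496": ["CDK7", "CDK9"]})
        result = expand_search("BRCA1", 1, parse_sif(f), catalog)
        level1 = {g: [r.drug_id for r in drugs] for g, drugs in result.levels[1].items()}
        assert level1 == {"CDK2": [], "CDK7": ["DB03496"], "CDK9": ["DB03496"]}

    def test_direct_hit_suppresses_expansion(self, graph):
        catalog = tiny_catalog({"DB05149": ["CHEK2"]})
        result = expand_search("CHEK2", 3, graph, catalog)
        assert set(result.levels) == {0}
        assert [r.drug_id for r in result.levels[0]["CHEK2"]] == ["DB05149"]

    def test_chain_requires_enough_levels(self, tmp_path):
        f = write_sif(
            tmp_path, "a.sif",
            [
                ("B", "controls-expression-of", "A"),
                ("C", "controls-expression-of", "B"),
            ],
        )
        graph = parse_sif(f)
        catalog = tiny_catalog({"DB00001": ["C"]})
        assert expand_search("A", 1, graph, catalog).all_drugs() == []
        result = expand_search("A", 2, graph, catalog)
        assert [r.drug_id for r in result.drugs_at(2)] == ["DB00001"]

    def test_level_zero_never_expands(self, graph):
        result = expand_search("BRCA1", 0, graph, tiny_catalog({}))
        assert set(result.levels) == {0} and result.levels[0]["BRCA1"] == []

    def test_level0_is_extensionally_direct_search(self, graph, catalog):
        from oncomatch.catalog import drugs_targeting

        for gene in ("EPCAM", "BRCA1", "ABL1", "NOSUCHGENE"):
            result = expand_search(gene, 0, graph, catalog)
            assert result.levels[0][gene.upper()] == drugs_targeting(gene, catalog)

    def test_queried_gene_never_its_own_interactor_and_levels_disjoint(
        self, graph, catalog
    ):
        result = expand_search("BRCA1", 3, graph, catalog)
        seen = set()
        for level, per_gene in result.levels.items():
            genes = set(per_gene)
            assert not (genes & seen), "a gene appeared at two levels"
            seen |= genes
            if level >= 1:
                assert "BRCA1" not in genes

    @given(st.data())
    def test_flattened_drugs_monotone_in_level_on_random_graphs(self, data):
        genes = [f"G{i}" for i in range(6)]
        edges = data.draw(
            st.lists(
                st.tuples(
                    st.sampled_from(genes),
                    st.sampled_from(
                        sorted(UPSTREAM_IN_TYPES) + [COMPLEX_TYPE, "reacts-with"]
                    ),
                    st.sampled_from(genes),
                ),
                min_size=1,
                max_size=12,
            )
        )
        targets = data.draw(
            st.dictionaries(
                st.sampled_from(["DB00001", "DB00002", "DB00003"]),
                st.lists(st.sampled_from(genes), min_size=1, max_size=3),
                max_size=3,
            )
        )
        from oncomatch.ppi import InteractionEdge, InteractionGraph

        graph = InteractionGraph()
        for s, t, o in edges:
            graph.add_edge(InteractionEdge(s, t, o))
        catalog = tiny_catalog(targets)
        previous: set[str] = set()
        for level in range(4):
            result = expand_search("G0", level, graph, catalog)
            current = {r.drug_id for r in result.all_drugs()}
            assert previous <= current
            previous = current
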