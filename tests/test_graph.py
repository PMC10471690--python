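"""Correlation graph construction, coverage and cascade ordering."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from qsynth import (
    build_graph,
    cascade_order,
    coverage,
    load_schema,
    pearson_matrix,
    score_subscales,
)
from qsynth.graph import SubscaleGraph, covered_nodes


def brute_pearson(x, y):
    """Textbook Pearson r on pairwise-complete entries."""
    m = ~(np.isnan(x) | np.isnan(y))
    x, y = x[m], y[m]
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestPearsonMatrix:
    def test_duplicate_and_negated_columns(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "dup": a.copy(), "neg": -a})
        corr = pearson_matrix(df)
        assert corr.loc["a", "dup"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self, schema):
        from qsynth.simulate import SyntheticCohortSpec, generate_cohort

        subjects = schema.subjects
        corr_mat = np.eye(len(subjects))
        spec = SyntheticCohortSpec(n_records=200, seed=42, subjects=subjects,
                                   subject_corr=corr_mat, item_loading=0.9,
                                   retention={q: 1.0 for q in schema.names})
        scores = score_subscales(generate_cohort(spec, schema))
        corr = pearson_matrix(scores)
        cols = list(scores.columns)
        rng = np.random.default_rng(3)
        for i, j in rng.choice(len(cols), size=(60, 2)):
            if i == j:
                continue
            expected = brute_pearson(scores[cols[i]].to_numpy(), scores[cols[j]].to_numpy())
            assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_records_gives_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan],
                           "b": [np.nan, np.nan, 1.0, 2.0]})
        corr = pearson_matrix(df)
        assert np.isnan(corr.loc["a", "b"])

    def test_constant_column_gives_nan(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        assert np.isnan(pearson_matrix(df).loc["a", "b"])


def _corr_frame(schema, mat):
    names = [s.name for s in schema.subscales]
    return pd.DataFrame(mat, index=names, columns=names)


class TestBuildGraph:
    def test_identity_matrix_gives_no_edges(self, schema):
        g = build_graph(_corr_frame(schema, np.eye(38)), schema)
        assert len(g.nodes) == 38 and len(g.edges) == 0

    def test_all_ones_gives_complete_graph(self, schema):
        g = build_graph(_corr_frame(schema, np.ones((38, 38))), schema)
        assert len(g.edges) == 38 * 37 // 2 == 703

    def test_negative_correlations_count(self, schema):
        mat = np.eye(38)
        mat[0, 1] = mat[1, 0] = -0.8
        g = build_graph(_corr_frame(schema, mat), schema)
        assert len(g.edges) == 1

    def test_invalid_threshold(self, schema):
        with pytest.raises(ValueError):
            build_graph(_corr_frame(schema, np.eye(38)), schema, tau=0.0)
        with pytest.raises(ValueError):
            build_graph(_corr_frame(schema, np.eye(38)), schema, tau=1.5)

    def test_raising_tau_never_adds_edges(self, schema, registry_cohort):
        corr = pearson_matrix(score_subscales(registry_cohort))
        edges = None
        for tau in (0.3, 0.5, 0.7, 0.9):
            new = set(map(frozenset, build_graph(corr, schema, tau=tau).edges))
            if edges is not None:
                assert new <= edges
            edges = new

    def test_invariance_to_affine_transform_and_permutation(self, schema, registry_cohort):
        scores = score_subscales(registry_cohort)
        base = set(map(frozenset, build_graph(pearson_matrix(scores), schema).edges))
        rng = np.random.default_rng(7)
        transformed = scores * rng.uniform(0.5, 3.0, size=scores.shape[1]) + rng.normal(size=scores.shape[1])
        transformed = transformed.iloc[rng.permutation(len(scores))]
        again = set(map(frozenset, build_graph(pearson_matrix(transformed), schema).edges))
        assert base == again

    def test_planted_block_recovery(self, schema):
        """Edges recovered at n=2000 match the planted structure's large-n
        oracle edges (>=95% recall, <=5% false discoveries), and the package
        edge set equals brute-force thresholding of its correlation matrix."""
        from qsynth.simulate import SyntheticCohortSpec, generate_cohort

        subjects = schema.subjects
        kwargs = dict(subjects=subjects, subject_corr=np.eye(len(subjects)),
                      item_loading=0.9, retention={q: 1.0 for q in schema.names})
        # independent oracle: large-n run defines the planted edge set
        oracle_scores = score_subscales(
            generate_cohort(SyntheticCohortSpec(n_records=100_000, seed=901, **kwargs), schema)
        )
        cols = list(oracle_scores.columns)
        planted = set()
        for i, j in itertools.combinations(range(len(cols)), 2):
            r = brute_pearson(oracle_scores[cols[i]].to_numpy(), oracle_scores[cols[j]].to_numpy())
            if abs(r) >= 0.5:
                planted.add(frozenset((cols[i], cols[j])))
        scores = score_subscales(
            generate_cohort(SyntheticCohortSpec(n_records=2000, seed=902, **kwargs), schema)
        )
        corr = pearson_matrix(scores)
        recovered = set(map(frozenset, build_graph(corr, schema).edges))
        # exact agreement with brute-force thresholding of the matrix itself
        brute = {
            frozenset((cols[i], cols[j]))
            for i, j in itertools.combinations(range(len(cols)), 2)
            if abs(corr.iloc[i, j]) >= 0.5
        }
        assert recovered == brute
        recall = len(recovered & planted) / len(planted)
        false_rate = len(recovered - planted) / max(len(recovered), 1)
        assert recall >= 0.95
        assert false_rate <= 0.05


def graph_from_edges(schema, edges, tau=0.5):
    g = nx.Graph()
    for s in schema.subscales:
        g.add_node(s.name, questionnaire=s.questionnaire, subject=s.subject)
    for a, b in edges:
        g.add_edge(a, b, weight=1.0)
    return SubscaleGraph(g, schema, tau)


@pytest.fixture()
def narrative_graph(schema):
    """Hand-built inter-questionnaire links mirroring the registry graph:
    SF-36 covers all HAD nodes, HAD covers all SCL-90-R nodes, SCL-90-R
    touches the single FIS8 node, FIS8 touches all four FIS40 nodes, PSQI
    is isolated."""
    sf36 = [s.name for s in schema.questionnaire("SF-36").subscales]
    had = [s.name for s in schema.questionnaire("HAD").subscales]
    scl = [s.name for s in schema.questionnaire("SCL 90 R").subscales]
    fis40 = [s.name for s in schema.questionnaire("FIS40").subscales]
    edges = [("Mental health (MH)", h) for h in had]
    edges += [(had[0], s) for s in scl]
    edges += [("Severity global index (GSI)", "FIS8")]
    edges += [("FIS8", f) for f in fis40]
    edges += [(sf36[0], sf36[1])]  # within-questionnaire edge, no effect on coverage
    return graph_from_edges(schema, edges)


class TestCoverage:
    def test_full_had_coverage(self, narrative_graph):
        assert coverage(narrative_graph, ["SF-36"], "HAD") == 1.0

    def test_partial_coverage_fraction(self, schema):
        scl = [s.name for s in schema.questionnaire("SCL 90 R").subscales]
        g = graph_from_edges(schema, [("Mental health (MH)", s) for s in scl[:3]])
        assert coverage(g, ["SF-36"], "SCL 90 R") == pytest.approx(3 / 12)

    def test_source_equals_target_rejected(self, narrative_graph):
        with pytest.raises(ValueError):
            coverage(narrative_graph, ["SF-36"], "SF-36")

    def test_matches_brute_force_adjacency_scan(self, schema, narrative_graph):
        for targets in (["SCL 90 R"], ["FIS8"], ["FIS40"], ["PSQI"]):
            t = targets[0]
            nodes_t = narrative_graph.nodes_of(t)
            src = {n for q in ("SF-36", "HAD")
                   for n in narrative_graph.nodes_of(q)}
            expected = [
                n for n in nodes_t
                if any(nb in src for nb in narrative_graph.g.neighbors(n))
            ]
            assert set(covered_nodes(narrative_graph, ["SF-36", "HAD"], t)) == set(expected)
            assert coverage(narrative_graph, ["SF-36", "HAD"], t) == pytest.approx(
                len(expected) / len(nodes_t)
            )


def greedy_order_oracle(graph, start):
    """Independent re-execution of the greedy coverage rule."""
    schema = graph.schema
    selected = [schema.questionnaire(start).name]
    remaining = [q.name for q in schema.questionnaires if q.name != selected[0]]
    while remaining:
        best = None
        for j in remaining:
            src = {n for q in selected for n in graph.nodes_of(q)}
            nodes_j = graph.nodes_of(j)
            cov = [n for n in nodes_j if any(nb in src for nb in graph.g.neighbors(n))]
            key = (len(cov) / len(nodes_j), len(cov), -len(nodes_j), j)
            if best is None:
                best = key
            else:
                if (key[0], key[1], key[2]) > (best[0], best[1], best[2]) or (
                    (key[0], key[1], key[2]) == (best[0], best[1], best[2]) and key[3] < best[3]
                ):
                    best = key
        selected.append(best[3])
        remaining.remove(best[3])
    return selected


class TestCascadeOrder:
    def test_narrative_graph_gives_published_order(self, narrative_graph):
        assert cascade_order(narrative_graph) == [
            "SF-36", "HAD", "SCL 90 R", "FIS8", "FIS40", "PSQI"
        ]

    def test_two_questionnaire_schema(self, toy_schema):
        g = nx.Graph()
        for s in toy_schema.subscales:
            g.add_node(s.name, questionnaire=s.questionnaire, subject=s.subject)
        sg = SubscaleGraph(g, toy_schema, 0.5)
        assert cascade_order(sg, start="QA") == ["QA", "QB"]

    def test_matches_independent_greedy_oracle_on_random_graphs(self, schema):
        rng = np.random.default_rng(99)
        names = [s.name for s in schema.subscales]
        for trial in range(20):
            edges = []
            for a, b in itertools.combinations(names, 2):
                if rng.random() < 0.05:
                    edges.append((a, b))
            g = graph_from_edges(schema, edges)
            assert cascade_order(g) == greedy_order_oracle(g, "SF-36")

    def test_isolated_questionnaires_go_last(self, schema):
        had = [s.name for s in schema.questionnaire("HAD").subscales]
        g = graph_from_edges(schema, [("Mental health (MH)", h) for h in had])
        order = cascade_order(g)
        assert order[1] == "HAD"
        assert set(order[2:]) == {"SCL 90 R", "FIS8", "FIS40", "PSQI"}


class TestExports:
    def test_edgelist_and_graphml_round_trip(self, schema, tmp_path, narrative_graph):
        edge_csv = tmp_path / "edges.csv"
        graphml = tmp_path / "g.graphml"
        narrative_graph.to_edgelist_csv(edge_csv)
        narrative_graph.to_graphml(graphml)
        back = pd.read_csv(edge_csv)
        assert set(map(frozenset, zip(back.node_a, back.node_b))) == set(
            map(frozenset, narrative_graph.edges)
        )
        g2 = nx.read_graphml(graphml)
        assert g2.number_of_nodes() == 38
        assert g2.number_of_edges() == len(narrative_graph.edges)

    def test_degree_table_matches_fig_convention(self, narrative_graph):
        table = narrative_graph.degree_table()
        assert len(table) == 38
        row = table.set_index("subscale").loc["FIS8"]
        assert row["degree"] == 5  # GSI + four FIS40 nodes
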