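import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import immetnet as im
from conftest import bfs_harmonic, fisher_enumeration, mini_atlas
from immetnet.fixtures import TOY_EXCLUSIVE_MET, TOY_PROCESS, TOY_SHARED_METS
from immetnet.metrics import ONE_SIDED, TWO_SIDED


def _network_from_graph(g):
    nodes = {str(n): "metabolite" for n in g.nodes}
    return im.InteractionNetwork.from_edgelist(
        nodes, [(str(a), str(b), im.MMI) for a, b in g.edges])


class TestHarmonicCloseness:
    def test_path_graph_values(self):
        net = im.InteractionNetwork.from_edgelist(
            {"A": "metabolite", "B": "metabolite", "C": "metabolite"},
            [("A", "B", im.MMI), ("B", "C", im.MMI)])
        mid = im.harmonic_closeness(net, "B")
        assert mid.raw == pytest.approx(2.0)
        assert mid.normalized == pytest.approx(1.0)
        end = im.harmonic_closeness(net, "A")
        assert end.raw == pytest.approx(1.5)
        assert end.normalized == pytest.approx(0.75)

    def test_disconnected_dyads(self):
        net = im.InteractionNetwork.from_edgelist(
            {k: "metabolite" for k in "ABCD"},
            [("A", "B", im.MMI), ("C", "D", im.MMI)])
        for node in "ABCD":
            score = im.harmonic_closeness(net, node)
            assert score.raw == pytest.approx(1.0)
            assert score.normalized == pytest.approx(1 / 3)

    def test_singleton_scores_zero(self):
        net = im.InteractionNetwork.from_edgelist({"A": "metabolite"}, [])
        score = im.harmonic_closeness(net, "A")
        assert score.raw == 0.0 and score.normalized == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        g = nx.gnp_random_graph(n, rng.uniform(0.02, 0.3), seed=seed)
        net = _network_from_graph(g)
        adj = {str(a): {str(b) for b in g.neighbors(a)} for a in g.nodes}
        for node in net.nodes:
            raw, normalized = bfs_harmonic(adj, node, len(g))
            score = im.harmonic_closeness(net, node)
            assert score.raw == pytest.approx(raw, abs=1e-12)
            assert score.normalized == pytest.approx(normalized, abs=1e-12)
            assert 0.0 <= score.normalized <= 1.0

    def test_identical_neighbor_sets_give_equal_scores(self, toy_atlas):
        network = im.build_process_network(toy_atlas, {TOY_PROCESS})
        scores = {im.harmonic_closeness(network, m).normalized
                  for m in TOY_SHARED_METS}
        assert len(scores) == 1


class TestPrecisionScore:
    def test_ratio_and_corrected_arithmetic(self):
        inputs = im.PrecisionInputs(N_ij=2, N_i=4, V_j=10)
        assert im.precision_score(inputs, "ratio") == pytest.approx(0.5)
        assert im.precision_score(inputs, "corrected") == pytest.approx(0.05)

    def test_zero_overlap_is_zero_in_both_modes(self):
        inputs = im.PrecisionInputs(N_ij=0, N_i=3, V_j=5)
        assert im.precision_score(inputs, "ratio") == 0.0
        assert im.precision_score(inputs, "corrected") == 0.0

    def test_undefined_without_interactions(self):
        with pytest.raises(ValueError, match="no interactions"):
            im.precision_score(im.PrecisionInputs(N_ij=0, N_i=0, V_j=5))

    def test_fully_committed_metabolite_scores_one(self, toy_atlas):
        inputs = im.precision_inputs(toy_atlas, TOY_EXCLUSIVE_MET,
                                     TOY_PROCESS)
        assert im.precision_score(inputs, "ratio") == pytest.approx(1.0)

    @given(st.integers(0, 20), st.integers(1, 20), st.integers(1, 30))
    @settings(derandomize=True, max_examples=60)
    def test_corrected_never_exceeds_ratio(self, n_ij, extra, v_j):
        inputs = im.PrecisionInputs(N_ij=n_ij, N_i=n_ij + extra, V_j=v_j)
        ratio = im.precision_score(inputs, "ratio")
        assert 0.0 <= ratio <= 1.0
        assert im.precision_score(inputs, "corrected") <= ratio


class TestFisherP:
    def test_most_extreme_table(self):
        p = im.fisher_p(im.ContingencyTable(5, 0, 0, 5), ONE_SIDED)
        assert p == pytest.approx(1 / 252, abs=1e-12)

    def test_least_enriched_table(self):
        assert im.fisher_p(im.ContingencyTable(0, 5, 5, 0), ONE_SIDED) == 1.0

    def test_all_zero_table_warns_p_one(self, caplog):
        with caplog.at_level("WARNING", logger="immetnet"):
            assert im.fisher_p(im.ContingencyTable(0, 0, 0, 0)) == 1.0
        assert any("all-zero" in r.message for r in caplog.records)

    @pytest.mark.parametrize("sided", [ONE_SIDED, TWO_SIDED])
    def test_matches_enumeration_oracle_small_margins(self, sided):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b + c + d == 0:
                            continue
                        got = im.fisher_p(im.ContingencyTable(a, b, c, d),
                                          sided)
                        want = fisher_enumeration(a, b, c, d, sided)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert im.fisher_p(im.ContingencyTable(a, b, c, d), ONE_SIDED) \
                == pytest.approx(
                    stats.fisher_exact(table, "greater").pvalue, rel=1e-9)

    def test_two_sided_symmetric_under_transpose(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            assert im.fisher_p(im.ContingencyTable(a, b, c, d), TWO_SIDED) \
                == pytest.approx(
                    im.fisher_p(im.ContingencyTable(a, c, b, d), TWO_SIDED),
                    abs=1e-12)


class TestContingencyTables:
    def test_toy_exclusive_metabolite_hand_count(self, toy_atlas):
        """Three target-annotated partners, two off-target annotation
        instances among them, nothing outside the network."""
        network = im.build_process_network(toy_atlas, {TOY_PROCESS})
        table = im.metabolite_contingency(
            toy_atlas, network, TOY_EXCLUSIVE_MET, TOY_PROCESS)
        assert (table.a, table.b, table.c, table.d) == (3, 2, 0, 3)

    def test_whole_atlas_network_complements(self, toy_atlas):
        """With the network equal to the atlas, the in-process complement c
        vanishes and d reduces to the database count of the process."""
        network = im.build_process_network(toy_atlas,
                                           toy_atlas.process_ids)
        db = im.inherit_processes(toy_atlas, None, 1)
        for met in ("M00001", "M00005", "M00007"):
            table = im.metabolite_contingency(toy_atlas, network, met,
                                              TOY_PROCESS)
            assert table.c == 0
            assert table.d == len(db.support(met, TOY_PROCESS))

    def test_absent_association_gives_p_one(self, toy_atlas):
        network = im.build_process_network(toy_atlas, {"GO:0019882"})
        table = im.metabolite_contingency(toy_atlas, network, "M00001",
                                          "GO:0006955")
        assert table.a == 0
        assert im.fisher_p(table, ONE_SIDED) == pytest.approx(1.0)

    def test_process_table_whole_atlas_is_balanced(self, toy_atlas):
        network = im.build_process_network(toy_atlas,
                                           toy_atlas.process_ids)
        for proc in toy_atlas.process_ids:
            table = im.process_contingency(toy_atlas, network, proc)
            assert table.a == table.b and table.c == table.d
            assert im.fisher_p(table, TWO_SIDED) == pytest.approx(1.0)

    def test_unannotated_process_raises(self):
        atlas = mini_atlas(proteins={"P1": {"GO:A"}},
                           metabolites={"M1": {"P1"}})
        atlas.ontology.terms["GO:B"] = im.ingest.Term(
            "GO:B", "empty", frozenset({atlas.ontology.root_id}))
        network = im.build_process_network(atlas, {"GO:A"})
        with pytest.raises(im.ValidationError, match="no annotations"):
            im.process_contingency(atlas, network, "GO:B")

    def test_enriched_process_has_minimum_p(self, toy_atlas):
        """Querying one process makes that process the most enriched."""
        network = im.build_process_network(toy_atlas, {TOY_PROCESS})
        pvals = {
            proc: im.fisher_p(
                im.process_contingency(toy_atlas, network, proc), ONE_SIDED)
            for proc in toy_atlas.process_ids
        }
        assert min(pvals, key=pvals.get) == TOY_PROCESS


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        assert im.adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert im.adjust_fdr([0.2]) == pytest.approx([0.2])

    def test_empty_list(self):
        assert im.adjust_fdr([]) == []

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=60)
    def test_q_at_least_p_and_order_preserved(self, pvals):
        qvals = im.adjust_fdr(pvals)
        for p, q in zip(pvals, qvals):
            assert q >= p - 1e-12
            assert 0.0 <= q <= 1.0
        order_p = np.argsort(np.argsort(pvals))
        for i in range(len(pvals)):
            for j in range(len(pvals)):
                if pvals[i] < pvals[j]:
                    assert qvals[i] <= qvals[j] + 1e-12


class TestRankAssociations:
    def test_toy_shared_centrality_and_exclusive_precision(self, toy_atlas):
        network = im.build_process_network(toy_atlas, {TOY_PROCESS})
        table = im.rank_associations(toy_atlas, network, 1)
        in_proc = table[table.process_id == TOY_PROCESS]
        shared = in_proc[in_proc.metabolite_id.isin(TOY_SHARED_METS)]
        assert shared.centrality.nunique() == 1
        best = in_proc.sort_values("precision", ascending=False).iloc[0]
        assert best.metabolite_id == TOY_EXCLUSIVE_MET
        assert best.precision == pytest.approx(1.0)

    def test_empty_network_gives_empty_table(self):
        atlas = mini_atlas(proteins={"P1": {"GO:A"}}, metabolites={})
        atlas.ontology.terms["GO:B"] = im.ingest.Term(
            "GO:B", "GO:B", frozenset({atlas.ontology.root_id}))
        network = im.build_process_network(atlas, {"GO:B"})
        table = im.rank_associations(atlas, network, 1)
        assert table.empty
        assert list(table.columns) == im.metrics.TABLE_COLUMNS

    def test_sorted_by_q_then_precision(self, default_scored):
        _, _, table = default_scored
        assert table.q.is_monotonic_increasing or \
            (table.q.diff().fillna(0) >= -1e-15).all()
        assert (table.q >= table.p - 1e-12).all()
        assert (table.significant == (table.q < 0.05)).all()

    def test_biomarker_implies_significant(self, default_scored):
        _, _, table = default_scored
        assert (~table.biomarker | table.significant).all()


class TestSelectBiomarkers:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["metabolite_id", "process_id",
                                           "centrality", "precision",
                                           "significant"])

    def test_identical_scores_flag_nothing(self):
        table = self._table([(f"M{i}", "GO:A", 0.5, 0.5, True)
                             for i in range(6)])
        assert im.select_biomarkers(table).empty

    def test_nonsignificant_extreme_row_never_flagged(self):
        rows = [(f"M{i}", "GO:A", 0.30 + 0.001 * i, 0.50 + 0.001 * i, True)
                for i in range(8)]
        rows.append(("M_EXTREME", "GO:B", 0.99, 0.99, False))
        flagged = im.select_biomarkers(self._table(rows))
        assert "M_EXTREME" not in set(flagged.metabolite_id)

    def test_planted_outlier_is_unique_flag(self, default_scored):
        _, truth, table = default_scored
        flagged = table[table.biomarker]
        assert len(flagged) == 1
        assert [flagged.metabolite_id.iloc[0],
                flagged.process_id.iloc[0]] == truth["outlier"]

    def test_fewer_than_two_significant_rows_warns(self, caplog):
        table = self._table([("M1", "GO:A", 0.9, 0.9, True),
                             ("M2", "GO:A", 0.1, 0.1, False)])
        with caplog.at_level("WARNING", logger="immetnet"):
            flagged = im.select_biomarkers(table)
        assert flagged.empty
        assert any("SD undefined" in r.message for r in caplog.records)


class TestSuperclassDistribution:
    def test_conservation_and_exclusion(self, toy_atlas):
        network = im.build_process_network(toy_atlas,
                                           toy_atlas.process_ids)
        table = im.rank_associations(toy_atlas, network, 1)
        group_map = {proc: "all immunity" for proc in toy_atlas.process_ids}
        summary = im.summarize_superclass_distribution(table, toy_atlas,
                                                       group_map)
        assert summary.n_metabolites.sum() == table.metabolite_id.nunique()
        excluded = im.summarize_superclass_distribution(
            table, toy_atlas, group_map,
            exclude_superclasses={"Organic nitrogen compounds"})
        assert "Organic nitrogen compounds" not in \
            set(excluded.superclass)

    def test_unmapped_processes_grouped_as_other(self, toy_atlas):
        network = im.build_process_network(toy_atlas, {TOY_PROCESS})
        table = im.rank_associations(toy_atlas, network, 1)
        summary = im.summarize_superclass_distribution(table, toy_atlas, {})
        assert set(summary.group) == {"other"}
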