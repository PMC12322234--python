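import numpy as np
import pandas as pd
import pytest

import metaboratio as mr
from metaboratio.containers import ScreenTable


def _screen(rows, direction="lower_is_more_sensitive"):
    return ScreenTable(
        pd.DataFrame(rows, columns=["cell_line", "target", "score", "database"]),
        score_direction=direction,
    )


def _kegg(pairs):
    return pd.DataFrame(pairs, columns=["target", "kegg_pathway"])


class TestJoinScreens:
    def test_keeps_only_labeled_cells_and_mapped_targets(self):
        screen = _screen([(f"c{i}", "T1", float(i), "db") for i in range(5)])
        labels = pd.Series([1, 1, 2], index=["c0", "c1", "c2"])
        filtered, counts = mr.join_screens(screen, labels, _kegg([("T1", "P")]))
        assert set(filtered.records["cell_line"]) == {"c0", "c1", "c2"}
        assert counts["records_kept"] == 3

    def test_unmapped_target_dropped_and_counted(self):
        screen = _screen([("c0", "T1", 1.0, "db"), ("c0", "T2", 2.0, "db")])
        labels = pd.Series([1], index=["c0"])
        filtered, counts = mr.join_screens(screen, labels, _kegg([("T1", "P")]))
        assert list(filtered.records["target"]) == ["T1"]
        assert counts["targets_dropped_no_pathway"] == 1

    def test_no_shared_cell_lines_errors(self):
        screen = _screen([("cX", "T1", 1.0, "db")])
        labels = pd.Series([1], index=["c0"])
        with pytest.raises(ValueError, match="overlap"):
            mr.join_screens(screen, labels, _kegg([("T1", "P")]))


class TestDifferentialResponse:
    def _four_cell_screen(self):
        screen = _screen(
            [("a1", "T1", -2.0, "db"), ("a2", "T1", -2.0, "db"),
             ("b1", "T1", 0.0, "db"), ("b2", "T1", 0.0, "db")]
        )
        labels = pd.Series([1, 1, 2, 2], index=["a1", "a2", "b1", "b2"])
        return screen, labels

    def test_hand_zscore_arithmetic(self):
        screen, labels = self._four_cell_screen()
        dt = mr.differential_response(screen, labels, 1, 2)
        assert dt.loc[0, "mean_z_a"] == pytest.approx(-0.8660, abs=1e-4)
        assert dt.loc[0, "differential"] == pytest.approx(-1.7321, abs=1e-4)

    def test_identical_scores_give_zero_differential(self):
        screen = _screen(
            [(c, "T1", 1.0 + 0.1 * i, "db") for i, c in enumerate(["a1", "a2", "b1", "b2"])]
            + [(c, "T2", 5.0, "db") for c in ["a1", "a2", "b1", "b2"]]
        )
        labels = pd.Series([1, 1, 2, 2], index=["a1", "a2", "b1", "b2"])
        dt = mr.differential_response(screen, labels, 1, 2)
        # T2 has zero variance -> excluded entirely
        assert list(dt["target"]) == ["T1"]

    def test_antisymmetry_under_cluster_swap(self, default_panel):
        *_, truth = default_panel
        screens, kegg = mr.generate_screens(truth, databases=["DEMETER"], seed=3)
        labels = truth.cluster_labels
        filtered, _ = mr.join_screens(screens["DEMETER"], labels, kegg)
        fwd = mr.differential_response(filtered, labels, 4, 3).set_index("target")
        rev = mr.differential_response(filtered, labels, 3, 4).set_index("target")
        np.testing.assert_array_equal(
            fwd["differential"].sort_index().to_numpy(),
            -rev["differential"].sort_index().to_numpy(),
        )

    def test_constant_shift_leaves_differential_unchanged(self):
        screen, labels = self._four_cell_screen()
        shifted = _screen(
            [(c, t, s + 100.0, d) for c, t, s, d in screen.records.itertuples(index=False)]
        )
        d0 = mr.differential_response(screen, labels, 1, 2).loc[0, "differential"]
        d1 = mr.differential_response(shifted, labels, 1, 2).loc[0, "differential"]
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_undersized_cluster_target_excluded_with_warning(self):
        screen = _screen(
            [("a1", "T1", 1.0, "db"), ("a2", "T1", 2.0, "db"), ("b1", "T1", 3.0, "db"),
             ("b2", "T1", 4.0, "db"),
             ("a1", "T2", 1.0, "db"), ("a2", "T2", 2.0, "db"), ("b1", "T2", 3.0, "db")]
        )
        labels = pd.Series([1, 1, 2, 2], index=["a1", "a2", "b1", "b2"])
        with pytest.warns(UserWarning, match="excluded 1"):
            dt = mr.differential_response(screen, labels, 1, 2)
        assert list(dt["target"]) == ["T1"]


class TestTopN:
    def _table(self):
        return pd.DataFrame(
            {"target": ["B", "A", "C"], "differential": [-2.0, -1.0, -1.0], "rank": [1, 2, 3]}
        )

    def test_n_larger_than_table_returns_all(self):
        assert len(mr.top_n_targets(self._table(), 10)) == 3

    def test_n_one_returns_most_differential(self):
        assert mr.top_n_targets(self._table(), 1)["target"].tolist() == ["B"]

    def test_ties_break_lexicographically(self):
        screen = _screen(
            [("a1", t, s, "db") for t, s in [("zz", -1.0), ("aa", -1.0)]]
            + [("a2", t, s, "db") for t, s in [("zz", -1.0), ("aa", -1.0)]]
            + [("b1", t, 0.0, "db") for t in ["zz", "aa"]]
            + [("b2", t, 0.001, "db") for t in ["zz", "aa"]]
        )
        labels = pd.Series([1, 1, 2, 2], index=["a1", "a2", "b1", "b2"])
        dt = mr.differential_response(screen, labels, 1, 2)
        assert mr.top_n_targets(dt, 2)["target"].tolist() == ["aa", "zz"]

    def test_non_positive_n_errors(self):
        with pytest.raises(ValueError, match="positive"):
            mr.top_n_targets(self._table(), 0)


class TestConsolidatePathways:
    def test_single_database_full_pathway(self):
        top = pd.DataFrame({"target": [f"T{i}" for i in range(20)]})
        kegg = _kegg([(f"T{i}", "P") for i in range(20)])
        scores = mr.consolidate_pathways({"db": top}, kegg)
        assert scores.loc[0, "kegg_pathway"] == "P"
        assert scores.loc[0, "score"] == pytest.approx(1.0)

    def test_two_databases_sum_normalized_counts(self):
        kegg = _kegg([(f"O{i}", "OXPHOS") for i in range(10)] + [(f"X{i}", "other") for i in range(10)])
        top1 = pd.DataFrame({"target": [f"O{i}" for i in range(10)] + [f"X{i}" for i in range(10)]})
        top2 = pd.DataFrame({"target": [f"O{i}" for i in range(10)] + [f"X{i}" for i in range(10)]})
        scores = mr.consolidate_pathways({"d1": top1, "d2": top2}, kegg).set_index("kegg_pathway")
        assert scores.loc["OXPHOS", "score"] == pytest.approx(1.0)  # 10/20 + 10/20

    def test_planted_pathway_ranks_first(self, default_panel):
        *_, truth = default_panel
        screens, kegg = mr.generate_screens(truth, seed=1)
        labels = truth.cluster_labels
        tops = {}
        for db, screen in screens.items():
            filtered, _ = mr.join_screens(screen, labels, kegg)
            tops[db] = mr.top_n_targets(
                mr.differential_response(filtered, labels, 4, 3, kegg=kegg), 20
            )
        scores = mr.consolidate_pathways(tops, kegg)
        assert scores.loc[0, "kegg_pathway"] == truth.vulnerable_pathways[4][0]

    def test_empty_top_lists_error(self):
        with pytest.raises(ValueError, match="at least one"):
            mr.consolidate_pathways({}, _kegg([("T", "P")]))
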