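"""Gene-table reading, ordinal assignment, QC filtering, dereplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanclust.io import (
    read_calls,
    read_gene_table,
    read_tree,
    write_calls,
)
from nanclust.model import AniMatrix, assign_ordinals, dereplicate, qc_filter


def _gene_frame(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "gene_uid", "start", "end", "strand"]
    )


class TestOrdinals:
    def test_ordinals_follow_start_coordinates(self, tmp_path):
        frame = _gene_frame(
            [
                ("G1", "c1", "g1", 100, 400, "+"),
                ("G1", "c1", "g2", 500, 800, "-"),
                ("G1", "c1", "g3", 900, 1200, "+"),
            ]
        )
        path = tmp_path / "genes.tsv"
        frame.to_csv(path, sep="\t", index=False)
        out = read_gene_table(path)
        assert list(out.sort_values("gene_uid")["ordinal"]) == [0, 1, 2]

    def test_row_order_is_irrelevant(self):
        frame = _gene_frame(
            [
                ("G1", "c1", "g3", 900, 1200, "+"),
                ("G1", "c1", "g1", 100, 400, "+"),
                ("G1", "c1", "g2", 500, 800, "-"),
            ]
        )
        out = assign_ordinals(frame).set_index("gene_uid")
        assert out.loc["g1", "ordinal"] == 0
        assert out.loc["g3", "ordinal"] == 2

    def test_ordinals_restart_per_contig(self):
        frame = _gene_frame(
            [
                ("G1", "c1", "a1", 100, 200, "+"),
                ("G1", "c1", "a2", 300, 400, "+"),
                ("G1", "c2", "b1", 100, 200, "+"),
                ("G1", "c2", "b2", 300, 400, "+"),
            ]
        )
        out = assign_ordinals(frame)
        per_contig = out.groupby("contig_id")["ordinal"].apply(list).to_dict()
        assert per_contig == {"c1": [0, 1], "c2": [0, 1]}

    def test_duplicate_gene_uid_rejected_with_uid(self):
        frame = _gene_frame(
            [("G1", "c1", "dup", 100, 200, "+"), ("G1", "c1", "dup", 300, 400, "+")]
        )
        with pytest.raises(ValueError, match="dup"):
            assign_ordinals(frame)

    @given(
        starts=st.lists(
            st.integers(min_value=1, max_value=10_000), min_size=1, max_size=30, unique=True
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_ordinal_assignment_is_a_bijection(self, starts):
        frame = _gene_frame(
            [("G1", "c1", f"g{i}", s, s + 10, "+") for i, s in enumerate(starts)]
        )
        out = assign_ordinals(frame)
        assert sorted(out["ordinal"]) == list(range(len(starts)))


class TestQcFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,markers,kept",
        [
            (96.0, 4.0, 0.80, True),
            (95.0, 4.0, 0.80, False),  # "more than 95%" is strict
            (96.0, 5.0, 0.80, False),  # "less than 5%" is strict
            (99.0, 1.0, 0.74, False),  # fewer than 75% of markers
            (99.0, 1.0, 0.75, True),  # exactly 75% is not "less than 75%"
        ],
    )
    def test_threshold_boundaries(self, completeness, contamination, markers, kept):
        metrics = pd.DataFrame(
            [{"genome_id": "G1", "completeness_pct": completeness,
              "contamination_pct": contamination, "marker_fraction": markers}]
        )
        assert (qc_filter(metrics) == {"G1"}) is kept

    def test_missing_metric_excluded_with_warning(self):
        metrics = pd.DataFrame(
            [
                {"genome_id": "G1", "completeness_pct": 99.0,
                 "contamination_pct": np.nan, "marker_fraction": 0.9},
                {"genome_id": "G2", "completeness_pct": 99.0,
                 "contamination_pct": 0.5, "marker_fraction": 0.9},
            ]
        )
        with pytest.warns(UserWarning, match="missing QC"):
            kept = qc_filter(metrics)
        assert kept == {"G2"}

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(0)
        metrics = pd.DataFrame(
            {
                "genome_id": [f"G{i}" for i in range(50)],
                "completeness_pct": rng.uniform(90, 100, 50),
                "contamination_pct": rng.uniform(0, 10, 50),
                "marker_fraction": rng.uniform(0.5, 1.0, 50),
            }
        )
        kept = qc_filter(metrics)
        again = qc_filter(metrics[metrics["genome_id"].isin(kept)])
        assert again == kept


def _ani(ids, values):
    return AniMatrix(pd.DataFrame(values, index=ids, columns=ids, dtype=float))


def _meta(ids, type_flags, genus="g1"):
    return pd.DataFrame(
        {"genome_id": ids, "is_type_strain": type_flags, "genus": [genus] * len(ids)}
    )


class TestDereplicate:
    def test_tight_cluster_collapses_to_one_representative(self):
        ids = ["b", "a", "c"]
        ani = _ani(ids, [[100, 99.9, 99.9], [99.9, 100, 99.9], [99.9, 99.9, 100]])
        kept = dereplicate(ani, _meta(ids, [False] * 3))
        assert kept == {"a"}  # lexicographically smallest

    def test_type_strain_exempt_from_dereplication(self):
        ids = ["t1", "n1"]
        ani = _ani(ids, [[100, 99.9], [99.9, 100]])
        kept = dereplicate(ani, _meta(ids, [True, False]))
        assert kept == {"t1", "n1"}

    def test_below_threshold_pair_kept(self):
        ids = ["n1", "n2"]
        ani = _ani(ids, [[100, 99.0], [99.0, 100]])
        kept = dereplicate(ani, _meta(ids, [False, False]))
        assert kept == {"n1", "n2"}

    def test_clustering_is_genus_restricted(self):
        ids = ["n1", "n2"]
        ani = _ani(ids, [[100, 99.9], [99.9, 100]])
        meta = pd.DataFrame(
            {"genome_id": ids, "is_type_strain": [False, False], "genus": ["g1", "g2"]}
        )
        assert dereplicate(ani, meta) == {"n1", "n2"}

    def test_asymmetric_matrix_rejected(self):
        frame = pd.DataFrame(
            [[100.0, 99.0], [98.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="asymmetric"):
            AniMatrix(frame)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_never_grows(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        ids = [f"G{i}" for i in range(n)]
        raw = rng.uniform(98.5, 100, (n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 100.0)
        ani = _ani(ids, sym)
        meta = _meta(ids, list(rng.random(n) < 0.3))
        kept = dereplicate(ani, meta)
        assert kept <= set(ids)
        sub = ani.frame.loc[sorted(kept), sorted(kept)]
        again = dereplicate(AniMatrix(sub), meta[meta["genome_id"].isin(kept)])
        assert again == kept
        assert set(meta.loc[meta["is_type_strain"], "genome_id"]) <= kept


class TestTreesAndRoundTrips:
    def test_newick_read_counts_nodes(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B),(C,D));\n")
        tree = read_tree(path)
        assert len(tree.leaf_nodes()) == 4
        assert sum(1 for n in tree if not n.is_leaf()) == 3

    def test_duplicate_leaf_label_rejected(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,A),B);\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_tree(path)

    def test_garbage_newick_rejected(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B(;\n")
        with pytest.raises(ValueError, match="Newick"):
            read_tree(path)

    def test_calls_table_round_trip(self, tmp_path):
        calls = pd.DataFrame(
            {
                "genome_id": ["G1", "G2"],
                "sac_positive": [True, False],
                "n_clusters": [1, 0],
                "paradigms": ["canonical", ""],
            }
        )
        path = tmp_path / "calls.tsv"
        write_calls(calls, path)
        back = read_calls(path)
        assert list(back["genome_id"]) == ["G1", "G2"]
        assert list(back["sac_positive"]) == [True, False]
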