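"""nan-cluster detection, typing, context annotation, genome verdicts."""

import numpy as np
import pandas as pd
import pytest
from oracles import enumerate_clusters

from nanclust.clusters import (
    DetectionParams,
    call_genome,
    call_genomes,
    classify_structure,
    find_bacteroidetes_clusters,
    find_canonical_clusters,
)
from conftest import make_genome, random_role_genome


class TestCanonicalDetection:
    def test_adjacent_triple_is_one_cluster(self):
        genes, a = make_genome({"c1": {5: "nanA", 6: "nanK", 7: "nanE"}})
        clusters = find_canonical_clusters(genes, a)
        assert len(clusters) == 1
        assert clusters[0].span == (5, 7)

    def test_window_is_max_minus_min(self):
        genes, a = make_genome({"c1": {0: "nanA", 5: "nanE", 11: "nanK"}})
        assert find_canonical_clusters(genes, a) == []  # span 11 > 10
        genes, a = make_genome({"c1": {0: "nanA", 5: "nanE", 10: "nanK"}})
        assert len(find_canonical_clusters(genes, a)) == 1

    def test_chain_rule_accepts_wider_spans(self):
        genes, a = make_genome({"c1": {0: "nanA", 8: "nanE", 16: "nanK"}})
        assert find_canonical_clusters(genes, a) == []
        chain = DetectionParams(rule="chain")
        assert len(find_canonical_clusters(genes, a, chain)) == 1

    def test_core_genes_never_span_contigs(self):
        genes, a = make_genome({"c1": {0: "nanA", 3: "nanK"}, "c2": {2: "nanE"}})
        assert find_canonical_clusters(genes, a) == []

    def test_two_disjoint_clusters_in_one_genome(self):
        genes, a = make_genome(
            {"c1": {2: "nanA", 3: "nanK", 4: "nanE", 30: "nanE", 31: "nanA", 33: "nanK"}}
        )
        clusters = find_canonical_clusters(genes, a)
        assert [c.span for c in clusters] == [(2, 4), (30, 33)]
        uids = [c.core_uids for c in clusters]
        assert not (uids[0] & uids[1])

    def test_detection_invariant_to_row_order_and_uid_relabeling(self):
        genes, a = make_genome({"c1": {4: "nanK", 9: "nanA", 12: "nanE"}})
        base = find_canonical_clusters(genes, a)
        shuffled = genes.sample(frac=1, random_state=1).reset_index(drop=True)
        assert [c.span for c in find_canonical_clusters(shuffled, a)] == [
            c.span for c in base
        ]
        mapping = {u: f"x_{u}" for u in genes["gene_uid"]}
        genes2 = genes.assign(gene_uid=genes["gene_uid"].map(mapping))
        a2 = a.assign(gene_uid=a["gene_uid"].map(mapping))
        assert [c.span for c in find_canonical_clusters(genes2, a2)] == [
            c.span for c in base
        ]

    def test_equivalence_with_enumeration_on_random_genomes(self):
        rng = np.random.default_rng(2024)
        for i in range(150):
            genes, a = random_role_genome(rng, genome_id=f"R{i}")
            call = call_genome(genes, a)
            det_spans = sorted((c.contig_id, *c.span) for c in call.clusters)
            verdict, spans = enumerate_clusters(genes, a)
            assert call.sac_positive == verdict
            assert det_spans == spans


class TestBacteroidetesDetection:
    def test_pair_with_rokA_elsewhere(self):
        genes, a = make_genome({"c1": {4: "nanA", 6: "nanE_II", 25: "rokA"}})
        clusters = find_bacteroidetes_clusters(genes, a)
        assert len(clusters) == 1
        assert clusters[0].span == (4, 6)
        assert clusters[0].paradigm == "bacteroidetes"

    def test_rokA_is_required(self):
        genes, a = make_genome({"c1": {4: "nanA", 6: "nanE_II"}})
        assert find_bacteroidetes_clusters(genes, a) == []

    def test_pair_distance_limit(self):
        genes, a = make_genome({"c1": {4: "nanA", 16: "nanE_II", 25: "rokA"}})
        assert find_bacteroidetes_clusters(genes, a) == []


class TestStructureTyping:
    @pytest.mark.parametrize(
        "ordinals,expected",
        [
            ({5: "nanE", 6: "nanA", 7: "nanK"}, "consecutive"),  # any role order
            ({5: "nanA", 7: "nanK", 8: "nanE"}, "inconsecutive"),
            ({5: "nanA", 6: "nagB", 7: "nanK", 8: "nanE"}, "inconsecutive"),
        ],
    )
    def test_consecutive_iff_interval_of_length_two(self, ordinals, expected):
        genes, a = make_genome({"c1": ordinals})
        (cluster,) = find_canonical_clusters(genes, a)
        assert classify_structure(cluster) == expected

    def test_bacteroidetes_cluster_has_no_structure_type(self):
        genes, a = make_genome({"c1": {4: "nanA", 6: "nanE_II", 25: "rokA"}})
        (cluster,) = find_bacteroidetes_clusters(genes, a)
        with pytest.raises(ValueError):
            classify_structure(cluster)


class TestContextAnnotation:
    def _call(self, layout, **kwargs):
        genes, a = make_genome(layout, **kwargs)
        return call_genome(genes, a)

    def test_abc_st3_transporter_in_flank(self):
        call = self._call({"c1": {5: "nanA", 6: "nanK", 7: "nanE", 9: "transporter_ABC_ST3"}})
        assert call.clusters[0].transporters == [("ABC", "ST3")]

    def test_abc_plus_mfs_reports_both_with_mfs_nd(self):
        call = self._call(
            {"c1": {5: "nanA", 6: "nanK", 7: "nanE",
                    9: "transporter_ABC_ST3", 10: "transporter_MFS"}}
        )
        assert set(call.clusters[0].transporters) == {("ABC", "ST3"), ("MFS", "ND")}

    def test_lone_mfs_is_st1_and_lone_partial_is_nd(self):
        call = self._call({"c1": {5: "nanA", 6: "nanK", 7: "nanE", 3: "transporter_MFS"}})
        assert call.clusters[0].transporters == [("MFS", "ST1")]
        call = self._call(
            {"c1": {5: "nanA", 6: "nanK", 7: "nanE", 3: "transporter_ABC_partial"}}
        )
        assert call.clusters[0].transporters == [("ABC_partial", "ND")]

    def test_transporter_outside_flank_not_counted(self):
        call = self._call({"c1": {15: "nanA", 16: "nanK", 17: "nanE",
                                  25: "transporter_ABC_ST3"}})
        assert call.clusters[0].transporters == []

    def test_regulator_within_three_orfs(self):
        call = self._call({"c1": {5: "nanA", 6: "nanK", 7: "nanE", 3: "regulator"}})
        assert call.clusters[0].regulator_cogs == ["TEST"]
        call = self._call({"c1": {5: "nanA", 6: "nanK", 7: "nanE", 1: "regulator"}})
        assert call.clusters[0].regulator_cogs == []

    def test_contig_boundary_flag(self):
        call = self._call({"c1": {5: "nanA", 6: "nanK", 7: "nanE"}}, contig_len=40)
        assert call.clusters[0].flags["contig_boundary"]  # 5 ordinals from start
        call = self._call({"c1": {15: "nanA", 16: "nanK", 17: "nanE"}}, contig_len=40)
        assert not call.clusters[0].flags["contig_boundary"]

    def test_pathway_flags_are_in_span_only(self):
        call = self._call(
            {"c1": {10: "nanA", 12: "nagB", 14: "nanK", 16: "nanE", 18: "nagA", 30: "nanOx"}},
            contig_len=50,
        )
        flags = call.clusters[0].flags
        assert flags["nagB_in_cluster"]
        assert not flags["nagA_in_cluster"]  # ordinal 18 is outside span (10, 16)
        assert not flags["nanOx_in_cluster"]
        assert flags["nanOx_in_genome"]

    def test_extra_core_copy_in_flank_counted(self):
        call = self._call({"c1": {10: "nanA", 11: "nanK", 12: "nanE", 14: "nanA"}},
                          contig_len=50)
        (cluster,) = call.clusters
        assert cluster.extra_core_copies == {"nanA": 1}
        assert cluster.span == (10, 12)


class TestGenomeVerdict:
    def test_scattered_nanA_nanK_only_is_negative(self):
        genes, a = make_genome({"c1": {2: "nanA", 30: "nanK"}, "c2": {5: "nanA"}})
        call = call_genome(genes, a)
        assert not call.sac_positive
        assert call.role_counts.get("nanA") == 2

    def test_single_canonical_cluster_positive(self, simple_cluster_genome):
        genes, a = simple_cluster_genome
        call = call_genome(genes, a)
        assert call.sac_positive
        assert call.paradigms == ("canonical",)

    def test_bacteroidetes_only_genome(self):
        genes, a = make_genome({"c1": {4: "nanA", 6: "nanE_II", 25: "rokA"}})
        call = call_genome(genes, a)
        assert call.sac_positive
        assert call.paradigms == ("bacteroidetes",)

    def test_batch_calls_match_single_genome_calls(self):
        g1, a1 = make_genome({"c1": {5: "nanA", 6: "nanK", 7: "nanE"}}, genome_id="G1")
        g2, a2 = make_genome({"c1": {2: "nanA", 30: "nanK"}}, genome_id="G2")
        genes = pd.concat([g1, g2], ignore_index=True)
        assigns = pd.concat([a1, a2], ignore_index=True)
        calls, clusters = call_genomes(genes, assigns)
        assert list(calls["sac_positive"]) == [True, False]
        assert list(clusters["genome_id"]) == ["G1"]
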