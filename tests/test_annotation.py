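"""Cluster classification, intron ordinals, event construction and
read-count filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apakit.annotation import (assign_intron_ordinal, build_events,
                               classify_pa, event_counts, min_read_filter)
from conftest import make_clusters


class TestIntronOrdinal:
    @pytest.mark.parametrize(
        "index,count,label",
        [
            (3, 6, "M"),
            (4, 5, "-2"),
            (1, 4, "+1"),
            (2, 4, "+2"),
            (3, 4, "-2"),
            (4, 4, "-1"),
            (5, 9, "M"),
        ],
    )
    def test_labels(self, index, count, label):
        assert assign_intron_ordinal(index, count) == label

    def test_short_genes_excluded(self):
        assert assign_intron_ordinal(1, 3) is None

    def test_no_middle_with_four_introns(self):
        labels = [assign_intron_ordinal(i, 4) for i in range(1, 5)]
        assert "M" not in labels

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            assign_intron_ordinal(5, 4)


class TestClassify:
    def test_ua_within_2kb(self, toy_annotation):
        cl = make_clusters([("chr1", "-", 300)])  # 700 nt upstream of gplus
        pa = classify_pa(cl, toy_annotation)
        assert pa.iloc[0]["pa_class"] == "uaRNA"
        assert pa.iloc[0]["gene_id"] == "gplus"
        assert pa.iloc[0]["tss_distance"] == -700

    def test_ua_beyond_2kb_is_intergenic(self, toy_annotation):
        cl = make_clusters([("chr1", "-", 10600 - 2500 - 10000)])
        cl = make_clusters([("chr1", "-", 1000 - 2500)])
        pa = classify_pa(cl, toy_annotation)
        assert pa.iloc[0]["pa_class"] == "intergenic"

    def test_sp_flag_in_first_intron(self, toy_annotation):
        # 500 nt downstream of the gplus TSS, inside intron 1
        cl = make_clusters([("chr1", "+", 1500)])
        pa = classify_pa(cl, toy_annotation)
        assert pa.iloc[0]["pa_class"] == "intron"
        assert pa.iloc[0]["intron_index"] == 1
        assert bool(pa.iloc[0]["sp_flag"])

    def test_last_exon_is_utr3_not_sp(self, toy_annotation):
        # gminus 3'-most exon is its left-most one
        cl = make_clusters([("chr1", "-", 20500)])
        pa = classify_pa(cl, toy_annotation)
        assert pa.iloc[0]["pa_class"] == "utr3"
        assert not bool(pa.iloc[0]["sp_flag"])

    def test_minus_strand_ua(self, toy_annotation):
        # sense '+' cluster upstream (right) of the gminus TSS at 22999
        cl = make_clusters([("chr1", "+", 23500)])
        pa = classify_pa(cl, toy_annotation)
        assert pa.iloc[0]["pa_class"] == "uaRNA"
        assert pa.iloc[0]["gene_id"] == "gminus"

    def test_partition_on_synthetic(self, classified):
        _, clusters, _, pa, _ = classified
        assert len(pa) == len(clusters)
        assert pa["pa_class"].notna().all()
        assert pa["cluster_id"].is_unique

    def test_planted_classes_recovered(self, classified):
        sim, clusters, _, pa, _ = classified
        truth = sim.pa_table.copy()
        # match clusters to truth by nearest position on same chrom/strand
        merged = pa.merge(clusters[["cluster_id", "position", "strand"]],
                          on="cluster_id")
        for rec in truth.itertuples(index=False):
            hits = merged[
                (merged["strand"] == rec.strand)
                & ((merged["position"] - rec.position).abs() <= 8)
            ]
            assert len(hits) == 1
            got = hits.iloc[0]["pa_class"]
            expect = {"utr3": "utr3", "intron": "intron", "ua": "uaRNA",
                      "sp": "intron"}[rec.pa_class]
            assert got == expect
            if rec.pa_class == "sp":
                assert bool(hits.iloc[0]["sp_flag"])


class TestEvents:
    def _counts(self, clusters, values):
        return pd.DataFrame({"s": values}, index=clusters["cluster_id"])

    def test_top2_ranking_and_autr(self, toy_annotation):
        cl = make_clusters([("chr1", "+", 8100), ("chr1", "+", 8600),
                            ("chr1", "+", 8900)])
        counts = self._counts(cl, [50, 30, 20])
        pa = classify_pa(cl, toy_annotation)
        ev = build_events(pa, cl, counts, "top2_abundant")
        assert len(ev) == 1
        assert ev.iloc[0]["set1"] == ("chr1:+:8100",)
        assert ev.iloc[0]["set2"] == ("chr1:+:8600",)
        assert ev.iloc[0]["autr_len"] == 500

    def test_top2_tie_breaks_threeward(self, toy_annotation):
        cl = make_clusters([("chr1", "+", 8100), ("chr1", "+", 8600),
                            ("chr1", "+", 8900)])
        counts = self._counts(cl, [50, 30, 30])
        pa = classify_pa(cl, toy_annotation)
        ev = build_events(pa, cl, counts, "top2_abundant")
        assert ev.iloc[0]["set2"] == ("chr1:+:8900",)

    def test_single_utr3_pa_yields_no_pair(self, toy_annotation):
        cl = make_clusters([("chr1", "+", 8100)])
        counts = self._counts(cl, [50])
        pa = classify_pa(cl, toy_annotation)
        ev = build_events(pa, cl, counts, "top2_abundant")
        assert len(ev) == 0

    def test_one_vs_rest_and_sets_disjoint(self, toy_annotation):
        cl = make_clusters([("chr1", "+", 8100), ("chr1", "+", 8600),
                            ("chr1", "+", 8900)])
        counts = self._counts(cl, [50, 30, 20])
        pa = classify_pa(cl, toy_annotation)
        ev = build_events(pa, cl, counts, "one_vs_rest")
        assert len(ev) == 3
        for row in ev.itertuples(index=False):
            assert set(row.set1).isdisjoint(row.set2)
            assert len(row.set2) == 2

    def test_cds_mode_combines_upstream(self, toy_annotation):
        cl = make_clusters([("chr1", "+", 3000), ("chr1", "+", 4100),
                            ("chr1", "+", 8100), ("chr1", "+", 8600)])
        counts = self._counts(cl, [5, 5, 50, 30])
        pa = classify_pa(cl, toy_annotation)
        ev = build_events(pa, cl, counts, "cds")
        assert len(ev) == 1
        assert set(ev.iloc[0]["set1"]) == {"chr1:+:3000", "chr1:+:4100"}
        assert set(ev.iloc[0]["set2"]) == {"chr1:+:8100", "chr1:+:8600"}

    def test_sp_events_on_synthetic(self, classified):
        sim, clusters, counts, pa, _ = classified
        ev = build_events(pa, clusters, counts, "spRNA")
        sp_genes = set(sim.pa_table.loc[sim.pa_table["pa_class"] == "sp",
                                        "gene_id"])
        # every planted TSS-proximal sense pA yields an event; any extra
        # event genes host another pA that genuinely sits within 2 kb of
        # the TSS (e.g. an early intronic pA)
        assert sp_genes <= set(ev["gene_id"])
        flagged = pa[pa["sp_flag"]]
        assert ((flagged["tss_distance"] > 0)
                & (flagged["tss_distance"] <= 2000)).all()
        # single-exon genes can never produce spRNA events
        for gid in ev["gene_id"]:
            assert sim.annotation[gid].n_introns >= 1

    def test_event_counts_collapse(self, toy_annotation):
        cl = make_clusters([("chr1", "+", 8100), ("chr1", "+", 8600)])
        counts = pd.DataFrame({"t": [10, 40], "c": [40, 10]},
                              index=pd.Index(cl["cluster_id"],
                                             name="cluster_id"))
        pa = classify_pa(cl, toy_annotation)
        ev = build_events(pa, cl, counts, "top2_abundant")
        ec = event_counts(ev, counts, "t", "c")
        assert ec.iloc[0][["a1", "a2", "b1", "b2"]].tolist() == [10, 40,
                                                                 40, 10]


class TestMinReadFilter:
    @pytest.mark.parametrize("counts,keep", [
        ((12, 0, 7, 0), False),   # 19 combined
        ((12, 0, 8, 0), True),    # 20 combined, boundary inclusive
        ((5, 5, 5, 5), True),
    ])
    def test_utr3_20_combined(self, counts, keep):
        a1, a2, b1, b2 = counts
        row = {"a1": a1, "a2": a2, "b1": b1, "b2": b2}
        assert min_read_filter(row, "utr3_20_combined") is keep

    def test_intronic_10_combined(self):
        assert min_read_filter({"a1": 5, "a2": 0, "b1": 5, "b2": 0},
                               "intronic_10_combined")
        assert not min_read_filter({"a1": 5, "a2": 0, "b1": 4, "b2": 0},
                                   "intronic_10_combined")

    def test_matrix_5_all(self):
        row = {"a1": 9, "a2": 0, "b1": 9, "b2": 0}
        assert min_read_filter(row, "matrix_5_all",
                               all_sample_counts=[5, 6, 7])
        assert not min_read_filter(row, "matrix_5_all",
                                   all_sample_counts=[5, 4, 7])

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            min_read_filter({"a1": 1, "a2": 1, "b1": 1, "b2": 1}, "bogus")
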