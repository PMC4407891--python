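"""aUTR binning, RED-profile clustering, gene groups, enrichment, RPM."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

from apakit.downstream import (assign_groups, autr_bin_red,
                               cluster_red_profiles, gene_expression_change,
                               geneset_enrichment, red_matrix)


class TestAutrBins:
    def test_equal_quintiles(self):
        ev = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "autr_len": np.arange(10) * 100 + 100,
            "red": np.zeros(10),
        })
        summary, _ = autr_bin_red(ev)
        assert summary["n"].tolist() == [2, 2, 2, 2, 2]

    def test_planted_trend_detected(self):
        rng = np.random.default_rng(0)
        autr = rng.integers(100, 5000, 300)
        ev = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(300)],
            "autr_len": autr,
            "red": np.log(autr) / 3 + rng.normal(0, 0.2, 300),
        })
        summary, p = autr_bin_red(ev)
        assert summary["mean_red"].is_monotonic_increasing
        assert p < 0.01

    def test_null_uniformity(self):
        rng = np.random.default_rng(1)
        ps = []
        for seed in range(20):
            ev = pd.DataFrame({
                "gene_id": [f"g{i}" for i in range(100)],
                "autr_len": rng.integers(100, 5000, 100),
                "red": rng.normal(size=100),
            })
            ps.append(autr_bin_red(ev)[1])
        assert min(ps) > 1e-4
        assert np.mean(np.array(ps) < 0.5) < 0.9

    def test_too_few_genes(self):
        ev = pd.DataFrame({"gene_id": list("abc"), "autr_len": [1, 2, 3],
                           "red": [0, 0, 0]})
        with pytest.raises(ValueError):
            autr_bin_red(ev)


class TestClusterProfiles:
    def _matrix(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        return pd.DataFrame({
            "f1": base + rng.normal(0, 0.3, 100),
            "f2": base + rng.normal(0, 0.3, 100),
            "f3": -base + rng.normal(0, 0.3, 100),
            "f4": -base + rng.normal(0, 0.3, 100),
        })

    def test_correlated_columns_cocluster(self):
        link, order = cluster_red_profiles(self._matrix())
        flat = hierarchy.fcluster(link, 2, criterion="maxclust")
        labels = dict(zip(["f1", "f2", "f3", "f4"], flat))
        assert labels["f1"] == labels["f2"]
        assert labels["f3"] == labels["f4"]
        assert labels["f1"] != labels["f3"]

    def test_duplicate_column_merges_first(self):
        mat = self._matrix()
        mat["f1b"] = mat["f1"]
        link, _ = cluster_red_profiles(mat)
        # first merge joins the two zero-distance leaves
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        mat = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        link, _ = cluster_red_profiles(mat)
        assert link[-1, 2] == pytest.approx(2.0)

    def test_row_permutation_invariance(self):
        mat = self._matrix()
        l1, o1 = cluster_red_profiles(mat)
        l2, o2 = cluster_red_profiles(mat.sample(frac=1, random_state=3))
        assert np.allclose(l1[:, 2], l2[:, 2])
        assert o1 == o2

    def test_zero_variance_column_dropped(self):
        mat = self._matrix()
        mat["flat"] = 0.0
        _, order = cluster_red_profiles(mat)
        assert "flat" not in order

    def test_red_matrix_zeroing(self):
        res = pd.DataFrame({"gene_id": ["a", "b"], "red": [1.5, -2.0],
                            "q": [0.01, 0.5]})
        mat = red_matrix({"kd": res})
        assert mat.loc["a", "kd"] == 1.5
        assert mat.loc["b", "kd"] == 0.0


class TestGroups:
    def _calls(self):
        return pd.DataFrame(
            {
                "cfi68": ["Sh", "Sh", "ns", "ns", "Le", "ns"],
                "pcf11": ["Le", "Sh", "ns", "Le", "Le", "ns"],
                "pabpn1": ["ns", "ns", "Le", "ns", "ns", "ns"],
                "pabpc1": ["ns"] * 6,
                "fip1": ["ns"] * 6,
            },
            index=[f"g{i}" for i in range(6)],
        )

    def test_printed_group_codes(self):
        g = assign_groups(self._calls(), "cfi68", "pcf11",
                          ["pabpn1", "pabpc1", "fip1"])
        assert g["g0"] == 3   # Sh by factor1, Le by factor2
        assert g["g1"] == 1   # Sh/Sh
        assert g["g2"] == 9   # only another factor
        assert g["g3"] == 5   # none/Le
        assert g["g4"] == 8   # Le/Le
        assert g["g5"] == 10  # detectable but unregulated

    def test_partition(self):
        g = assign_groups(self._calls(), "cfi68", "pcf11",
                          ["pabpn1", "pabpc1", "fip1"])
        assert len(g) == 6
        assert g.isin(range(1, 11)).all()

    def test_missing_factor_column(self):
        with pytest.raises(ValueError):
            assign_groups(self._calls(), "cfi68", "nope", [])


class TestEnrichment:
    def test_identical_set_most_significant(self):
        universe = {f"g{i}" for i in range(100)}
        group = {f"g{i}" for i in range(10)}
        sets = {"same": set(group), "random": {f"g{i}" for i in
                                               range(50, 60)},
                "big": {f"g{i}" for i in range(80)}}
        res = geneset_enrichment(group, sets, universe)
        assert res.iloc[0]["gene_set"] == "same"

    def test_disjoint_set_near_one(self):
        universe = {f"g{i}" for i in range(1000)}
        res = geneset_enrichment(
            {f"g{i}" for i in range(5)},
            {"far": {f"g{i}" for i in range(900, 905)}}, universe)
        assert res.iloc[0]["p"] > 0.9

    def test_matches_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(30)}
        group = {f"g{i}" for i in range(8)}
        gs = {f"g{i}" for i in range(4, 16)}
        res = geneset_enrichment(group, {"s": gs}, universe)
        k = len(group & gs)
        p_exact = hypergeom.sf(k - 1, 30, len(gs), len(group))
        assert res.iloc[0]["p"] == pytest.approx(p_exact, abs=1e-12)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            geneset_enrichment(set(), {"s": set()}, set())


class TestExpression:
    def _inputs(self):
        counts = pd.DataFrame(
            {"t": [100, 50, 11], "c": [100, 25, 10]},
            index=pd.Index(["u1", "u2", "u3"], name="cluster_id"),
        )
        # pad totals to 1e4 per sample via an extra gene
        counts.loc["pad"] = [10_000 - counts["t"].sum(),
                             10_000 - counts["c"].sum()]
        pa = pd.DataFrame({
            "cluster_id": ["u1", "u2", "u3", "pad"],
            "gene_id": ["gA", "gB", "gC", "gPad"],
            "pa_class": ["utr3"] * 4,
        })
        return counts, pa

    def test_rpm_and_log2(self):
        counts, pa = self._inputs()
        res = gene_expression_change(counts, pa, "t", "c")
        assert res.loc["gA", "rpm_test"] == pytest.approx(1e6 * 100 / 1e4)
        assert res.loc["gA", "log2_change"] == pytest.approx(0.0)
        assert res.loc["gB", "log2_change"] == pytest.approx(1.0)

    def test_strict_20_read_rule(self):
        counts, pa = self._inputs()
        res = gene_expression_change(counts, pa, "t", "c")
        # gC has 11 + 10 = 21 > 20 -> kept
        assert not np.isnan(res.loc["gC", "log2_change"])
        # exactly 20 reads fails the strict rule
        counts.loc["u3"] = [10, 10]
        counts.loc["pad"] = [10_000 - counts["t"].iloc[:3].sum() - 10,
                             10_000 - counts["c"].iloc[:3].sum() - 10]
        res = gene_expression_change(counts, pa, "t", "c")
        assert np.isnan(res.loc["gC", "log2_change"])

    def test_zero_total_rejected(self):
        counts, pa = self._inputs()
        counts["c"] = 0
        with pytest.raises(ValueError):
            gene_expression_change(counts, pa, "t", "c")
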