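"""Window geometry, k-mer enrichment and the distance/AATAAA grouping."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import fisher_exact, ks_2samp

from apakit.cis import (distance_pas_groups, extract_window, extract_windows,
                        has_downstream_aataaa, kmer_enrichment,
                        nucleotide_profile, window_coords)
from apakit.models import revcomp


class TestWindows:
    def test_plus_strand_coords(self):
        assert window_coords(1000, "+", "U40_1") == (960, 1000)
        assert window_coords(1000, "+", "U100_41") == (900, 960)
        assert window_coords(1000, "+", "D1_100") == (1001, 1101)

    def test_minus_strand_coords(self):
        assert window_coords(1000, "-", "U40_1") == (1001, 1041)
        assert window_coords(1000, "-", "U100_41") == (1041, 1101)
        assert window_coords(1000, "-", "D1_100") == (900, 1000)

    def test_window_lengths(self):
        for region, length in [("U100_41", 60), ("U40_1", 40),
                               ("D1_100", 100)]:
            s, e = window_coords(500, "+", region)
            assert e - s == length

    def test_minus_strand_reverse_complemented(self):
        genome = {"c": "A" * 1001 + "CCGT" + "A" * 100}
        w = extract_window(genome, "c", 1000, "-", "U40_1")
        # genomic 1001..1041 reverse-complemented: CCGT -> ACGG at the 3' end
        assert w == revcomp(genome["c"][1001:1041])
        assert w.endswith("ACGG" + "T" * 0) or "ACGG" in w

    def test_truncated_windows_flagged(self):
        genome = {"c": "A" * 200}
        tab = pd.DataFrame({"cluster_id": ["x"], "chrom": ["c"],
                            "position": [30], "strand": ["+"]})
        out = extract_windows(tab, genome)
        out = out.set_index("region")
        assert out.loc["U100_41", "truncated"]
        assert not out.loc["D1_100", "truncated"]

    def test_revcomp_mirror_roundtrip(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 600))
        genome = {"c": seq}
        mirrored = {"c": revcomp(seq)}
        for region in ("U100_41", "U40_1", "D1_100"):
            w1 = extract_window(genome, "c", 300, "+", region)
            w2 = extract_window(mirrored, "c", len(seq) - 1 - 300, "-",
                                region)
            assert w1 == w2


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher P by exhausting tables with the same margins,
    summing probabilities <= the observed table's (point-mass rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestKmer:
    def test_planted_enrichment_positive(self):
        rng = np.random.default_rng(1)
        def rand(n, L):
            return ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
        fg = [s[:10] + "TGTA" + s[14:] for s in rand(30, 60)]
        bg = rand(200, 60)
        res = kmer_enrichment(fg, bg, 4).set_index("kmer")
        assert res.loc["TGTA", "ss"] > 3

    def test_depletion_negative_sign(self):
        fg = ["ACAC" * 15] * 20
        bg = ["TGTA" + "ACAC" * 14] * 50
        res = kmer_enrichment(fg, bg, 4).set_index("kmer")
        assert res.loc["TGTA", "fg_with"] == 0
        assert res.loc["TGTA", "ss"] < 0

    def test_null_specificity(self):
        rng = np.random.default_rng(2)
        pool = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(600)]
        fg, bg = pool[:100], pool[100:]
        res = kmer_enrichment(fg, bg, 4)
        assert (res["p"] <= 0.001).sum() <= 2

    def test_ss_threshold_is_p_001(self):
        rng = np.random.default_rng(3)
        fg = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(40)]
        bg = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(80)]
        res = kmer_enrichment(fg, bg, 4)
        assert ((res["ss"].abs() >= 3) == (res["p"] <= 1e-3)).all()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment([], ["ACGT"], 4)

    @pytest.mark.parametrize("table", [(8, 2, 10, 90), (0, 10, 5, 5),
                                       (15, 15, 1, 29), (3, 3, 3, 3)])
    def test_fisher_matches_enumeration(self, table):
        a, b, c, d = table
        _, p_scipy = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p_enum = fisher_two_sided_enumeration(a, b, c, d)
        assert p_scipy == pytest.approx(p_enum, abs=1e-12)


class TestProfile:
    def _tab(self, positions, strand="+"):
        return pd.DataFrame({"cluster_id": [f"p{i}" for i in
                                            range(len(positions))],
                             "chrom": "c", "position": positions,
                             "strand": strand})

    def test_all_a_degenerate(self):
        genome = {"c": "A" * 400}
        prof = nucleotide_profile(self._tab([200]), genome, halfwidth=50)
        assert (prof["A"] == 1.0).all()

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(4)
        genome = {"c": "".join(rng.choice(list("ACGT"), 2000))}
        prof = nucleotide_profile(self._tab([500, 900, 1300]), genome, 100)
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_a_rich_peak(self):
        rng = np.random.default_rng(5)
        sites = list(range(300, 4300, 200))
        seq = list("".join(rng.choice(list("ACGT"), 5000)))
        for i, s in enumerate(sites):
            if i % 5 != 0:  # 80% of sites
                seq[s - 25 : s - 15] = "A" * 10
        genome = {"c": "".join(seq)}
        prof = nucleotide_profile(self._tab(sites), genome, 60)
        peak = prof.loc[-24:-16, "A"].mean()
        flank = prof.loc[20:60, "A"].mean()
        assert peak > 0.8 > flank + 0.3


class TestDistanceGroups:
    def _pairs(self, genome_len=50_000, n=40, seed=6):
        rng = np.random.default_rng(seed)
        seq = list("".join(rng.choice(list("ACGT"), genome_len)))
        rows = []
        for i in range(n):
            pos = 1000 + i * 1000
            autr = 119 if i % 2 == 0 else 120
            with_pas = i % 4 < 2
            if with_pas:
                seq[pos + 40 : pos + 46] = "AATAAA"
            else:  # scrub any chance AATAAA downstream
                window = "".join(seq[pos + 1 : pos + 101]).replace(
                    "AATAAA", "CCCCCC")
                seq[pos + 1 : pos + 101] = window
            rows.append((f"g{i}", autr, rng.normal(), "c", "+", pos))
        pairs = pd.DataFrame(rows, columns=["gene_id", "autr_len", "red",
                                            "chrom", "strand",
                                            "proximal_position"])
        return pairs, {"c": "".join(seq)}

    def test_group_assignment_boundaries(self):
        pairs, genome = self._pairs()
        out, summary, ks = distance_pas_groups(pairs, genome)
        out = out.set_index("gene_id")
        # i=0: autr 119 + AATAAA at +41..+46 -> group 1
        assert out.loc["g0", "group"] == 1
        # i=1: autr 120 + AATAAA -> group 3 (>=120 branch)
        assert out.loc["g1", "group"] == 3
        # i=2: autr 119, no AATAAA -> group 2
        assert out.loc["g2", "group"] == 2
        assert out.loc["g3", "group"] == 4

    def test_aataaa_detector(self):
        genome = {"c": "C" * 1000 + "C" + "AATAAA" + "C" * 500}
        assert has_downstream_aataaa(genome, "c", 1000, "+")
        assert not has_downstream_aataaa(genome, "c", 400, "+")

    def test_identical_samples_ks(self):
        x = np.arange(30.0)
        res = ks_2samp(x, x)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_ks_statistic_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=rng.integers(5, 50))
            y = rng.normal(0.4, 1.1, size=rng.integers(5, 50))
            d_scipy = ks_2samp(x, y).statistic
            grid = np.concatenate([x, y])
            cdf_x = np.array([(x <= g).mean() for g in grid])
            cdf_y = np.array([(y <= g).mean() for g in grid])
            assert d_scipy == pytest.approx(np.abs(cdf_x - cdf_y).max(),
                                            abs=1e-12)
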