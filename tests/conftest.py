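"""Shared fixtures: one moderately sized simulation reused across
modules, plus a tiny hand-built annotation for geometry tests."""

from __future__ import annotations

import pandas as pd
import pytest

from apakit import (GeneModel, GenomeAnnotation, PlantedEffect, SimConfig,
                    simulate_all)
from apakit.annotation import build_events, classify_pa
from apakit.processing import build_count_matrix, cluster_pa, filter_pass

PLANTED_SHORTEN = [f"g{i:05d}" for i in range(15)]


@pytest.fixture(scope="session")
def sim_bundle():
    """Simulation with 80 genes, 15 planted 3'UTR-shortening effects."""
    cfg = SimConfig(
        n_genes=80,
        depth_per_sample=60_000,
        seed=11,
        effect_table=[
            PlantedEffect(PLANTED_SHORTEN, "utr3_shift", 4.0, "proximal_up")
        ],
    )
    sim, usage, reads = simulate_all(cfg)
    return sim, usage, reads


@pytest.fixture(scope="session")
def processed(sim_bundle):
    sim, usage, reads = sim_bundle
    pass_reads = filter_pass(reads)
    clusters = cluster_pa(pass_reads)
    counts = build_count_matrix(clusters, pass_reads)
    return sim, pass_reads, clusters, counts


@pytest.fixture(scope="session")
def classified(processed):
    sim, pass_reads, clusters, counts = processed
    pa = classify_pa(clusters, sim.annotation)
    events = build_events(pa, clusters, counts, "top2_abundant")
    return sim, clusters, counts, pa, events


@pytest.fixture()
def toy_annotation() -> GenomeAnnotation:
    """Two genes on opposite strands with known geometry.

    gplus: 5 exons on '+' spanning [1000, 10600); TSS = 1000.
    gminus: 2 exons on '-' spanning [20000, 23000); TSS = 22999.
    """
    ann = GenomeAnnotation()
    exons_plus = ((1000, 1200), (2000, 2300), (4000, 4200), (6000, 6150),
                  (8000, 10600))
    ann.add(GeneModel("gplus", "chr1", "+", 1000, 10600, exons_plus))
    ann.add(GeneModel("gminus", "chr1", "-", 20000, 23000,
                      ((20000, 21000), (22000, 23000))))
    return ann


def make_clusters(rows: list[tuple[str, str, int]]) -> pd.DataFrame:
    """Cluster table from (chrom, strand, position) triples."""
    df = pd.DataFrame(rows, columns=["chrom", "strand", "position"])
    df["start"] = df["position"]
    df["end"] = df["position"] + 1
    df["n_reads"] = 10
    df.insert(0, "cluster_id",
              df["chrom"] + ":" + df["strand"] + ":"
              + df["position"].astype(str))
    return df
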