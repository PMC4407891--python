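"""Controlled simulation scenarios.

Each function builds one statistically controlled experiment used to
validate a pipeline stage: a calibration null for SAAP, a planted-effect
power design, GAAP exchangeability and recovery designs, a motif-planting
design for the k-mer scan, an intron-position design and a four-condition
RED-profile design. The scenarios deliberately switch off nuisance
variation that the stage under study is not responsible for (e.g. the
GAAP recovery design uses tandem-pair-only genes with balanced usage and
uniform abundance so the measured quantity is GAAP's counting behaviour,
not the depth limit of heterogeneous genes); the generator's realistic
defaults are unchanged elsewhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import (assign_intron_ordinal, build_events, classify_pa,
                         event_counts)
from .processing import build_count_matrix, cluster_pa, filter_pass
from .simulate import (PlantedEffect, PlantedMotif, SimConfig, Simulation,
                       simulate_all, simulate_annotation, simulate_pass_reads,
                       simulate_usage)


# ------------------------------------------------------------------- SAAP

def saap_null_events(seed: int, n_events: int = 2000,
                     min_reads: int = 50, max_reads: int = 300
                     ) -> pd.DataFrame:
    """Null event counts: both samples multinomial from one usage vector.

    Per event, a shared isoform-1 proportion is drawn uniformly in
    [0.2, 0.8] and both samples' counts are binomial splits of their own
    depths (>= ``min_reads`` each), so the two samples are exchangeable.
    """
    rng = np.random.default_rng([seed, 101])
    p = rng.uniform(0.2, 0.8, n_events)
    na = rng.integers(min_reads, max_reads + 1, n_events)
    nb = rng.integers(min_reads, max_reads + 1, n_events)
    a1 = rng.binomial(na, p)
    b1 = rng.binomial(nb, p)
    return pd.DataFrame(
        {"event_id": [f"null{i:05d}" for i in range(n_events)],
         "a1": a1, "a2": na - a1, "b1": b1, "b2": nb - b1}
    )


def saap_power_events(seed: int, n_null: int = 400, n_planted: int = 100,
                      fold_change: float = 4.0, depth: int = 600
                      ) -> pd.DataFrame:
    """Planted 4-fold odds shifts with >=100 reads per isoform per sample.

    Control usage is balanced (0.5/0.5) at ``depth`` reads per sample, so
    each isoform carries >=100 reads even after the shift (0.8/0.2 of
    600). Null events share the control proportions. Planted event ids
    start with 'shift'.
    """
    rng = np.random.default_rng([seed, 102])
    rows = []
    p_ctrl = 0.5
    p_test = fold_change * p_ctrl / (fold_change * p_ctrl + (1 - p_ctrl))
    for i in range(n_planted):
        rows.append((f"shift{i:04d}", rng.binomial(depth, p_test),
                     rng.binomial(depth, p_ctrl)))
    for i in range(n_null):
        rows.append((f"null{i:04d}", rng.binomial(depth, p_ctrl),
                     rng.binomial(depth, p_ctrl)))
    df = pd.DataFrame(rows, columns=["event_id", "a1", "b1"])
    df["a2"] = depth - df["a1"]
    df["b2"] = depth - df["b1"]
    return df[["event_id", "a1", "a2", "b1", "b2"]]


# ------------------------------------------------------------------- GAAP

def _gaap_sim_config(seed: int, n_genes: int, depth: int,
                     effects: list[PlantedEffect]) -> SimConfig:
    # tandem-pair-only genes, balanced usage, uniform abundance: the
    # measured quantity is GAAP's counting behaviour, not gene-depth
    # heterogeneity
    return SimConfig(
        n_genes=n_genes,
        depth_per_sample=depth,
        frac_intronic_pa=0.0,
        frac_ua_pa=0.0,
        frac_sp_pa=0.0,
        decoy_frac=0.0,
        abundance_sigma=0.0,
        utr3_dirichlet_alpha=1000.0,
        effect_table=effects,
        seed=seed,
    )


def gaap_readsets(seed: int, n_genes: int = 1000, depth: int = 500_000,
                  n_le: int = 0, n_sh: int = 0, fold_change: float = 4.0
                  ) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Cluster-count read sets (A=test, B=control) plus tandem-pair events.

    ``n_le`` genes get a 4-fold distal-up shift (3'UTR lengthening in the
    test set), the next ``n_sh`` genes a proximal-up shift.
    """
    le_genes = [f"g{i:05d}" for i in range(n_le)]
    sh_genes = [f"g{i:05d}" for i in range(n_le, n_le + n_sh)]
    effects = []
    if le_genes:
        effects.append(PlantedEffect(le_genes, "utr3_shift", fold_change,
                                     "distal_up"))
    if sh_genes:
        effects.append(PlantedEffect(sh_genes, "utr3_shift", fold_change,
                                     "proximal_up"))
    cfg = _gaap_sim_config(seed, n_genes, depth, effects)
    sim, _, reads = simulate_all(cfg)
    pass_reads = filter_pass(reads)
    clusters = cluster_pa(pass_reads)
    counts = build_count_matrix(clusters, pass_reads)
    pa = classify_pa(clusters, sim.annotation)
    events = build_events(pa, clusters, counts, "top2_abundant")
    return counts["test"], counts["control"], events


# ------------------------------------------------------------------ k-mer

def kmer_scenario(seed: int, n_fg: int = 200, n_bg: int = 1000,
                  fg_prob: float = 0.5, bg_prob: float = 0.1,
                  motif: str = "UGUA", window: str = "U100_41"
                  ) -> tuple[Simulation, pd.DataFrame, pd.DataFrame]:
    """Single-pA genes with a motif planted at different rates in a
    foreground and a background pA set.

    Returns the simulation plus foreground/background pA tables (columns
    cluster_id, chrom, position, strand) ready for window extraction.
    """
    n_genes = n_fg + n_bg
    cfg = SimConfig(n_genes=n_genes, utr3_pa_count=(1, 1),
                    frac_intronic_pa=0.0, frac_ua_pa=0.0, frac_sp_pa=0.0,
                    exons_per_gene=(1, 2), seed=seed)
    sim = simulate_annotation(cfg)
    pa_ids = sim.pa_table["pa_id"].tolist()
    rng = np.random.default_rng([seed, 103])
    order = rng.permutation(len(pa_ids))
    fg_ids = {pa_ids[i] for i in order[:n_fg]}
    bg_ids = {pa_ids[i] for i in order[n_fg:]}
    genome = sim.genome
    from .simulate import plant_motifs

    genome = plant_motifs(genome, sim.pa_table,
                          [PlantedMotif(motif, window, sorted(fg_ids), fg_prob),
                           PlantedMotif(motif, window, sorted(bg_ids), bg_prob)],
                          seed=seed)
    sim.genome = genome
    tab = sim.pa_table.rename(columns={"pa_id": "cluster_id"})
    fg = tab[tab["cluster_id"].isin(fg_ids)].reset_index(drop=True)
    bg = tab[tab["cluster_id"].isin(bg_ids)].reset_index(drop=True)
    return sim, fg, bg


# ----------------------------------------------------------------- introns

def intron_bias_scenario(seed: int, n_genes: int = 600,
                         fold_change: float = 2.0, depth: int = 400_000
                         ):
    """Genes with >=4 introns, one intronic pA each; pAs in the first two
    introns get a planted upregulation in the test condition.

    The planted gene subset is chosen by the truth table's intron index,
    so ordinal groups M/-2/-1 stay null. Returns (sim, counts, pa_ann).
    """
    cfg = SimConfig(n_genes=n_genes, exons_per_gene=(6, 9),
                    frac_intronic_pa=1.0, frac_ua_pa=0.0, frac_sp_pa=0.0,
                    decoy_frac=0.0, abundance_sigma=0.0, seed=seed)
    sim = simulate_annotation(cfg)
    truth = sim.pa_table
    intronic = truth[truth["pa_class"] == "intron"].copy()
    early = intronic[intronic["intron_index"] <= 2]["gene_id"].tolist()
    cfg.effect_table = [PlantedEffect(early, "intronic_up", fold_change,
                                      "up")]
    usage = simulate_usage(sim)
    reads = simulate_pass_reads(sim, usage, depth=depth)
    pass_reads = filter_pass(reads)
    clusters = cluster_pa(pass_reads)
    counts = build_count_matrix(clusters, pass_reads)
    pa_ann = classify_pa(clusters, sim.annotation)
    return sim, counts, pa_ann


# -------------------------------------------------------- RED profiles

def red_profile_scenario(seed: int, n_genes: int = 400, n_reg: int = 150,
                         depth: int = 150_000
                         ) -> dict[str, pd.DataFrame]:
    """Four knockdown-like conditions against a shared control: two
    shorten the 3'UTRs of one responsive gene set, two lengthen the same
    set (mimicking a shared cis-element-driven mechanism, where one
    factor class promotes and the other suppresses the proximal site of
    the same genes).

    Returns per-condition SAAP-ready event-count tables keyed by
    condition name, plus the shared events under key '_events'.
    """
    sh_genes = [f"g{i:05d}" for i in range(n_reg)]
    le_genes = sh_genes
    effects = []
    for cond in ("shortenA", "shortenB"):
        effects.append(PlantedEffect(sh_genes, "utr3_shift", 4.0,
                                     "proximal_up", condition=cond))
    for cond in ("lengthenA", "lengthenB"):
        effects.append(PlantedEffect(le_genes, "utr3_shift", 4.0,
                                     "distal_up", condition=cond))
    cfg = SimConfig(n_genes=n_genes, depth_per_sample=depth,
                    frac_intronic_pa=0.0, frac_ua_pa=0.0, frac_sp_pa=0.0,
                    decoy_frac=0.0, abundance_sigma=0.0,
                    utr3_dirichlet_alpha=20.0,
                    effect_table=effects, seed=seed)
    conditions = ["control", "shortenA", "shortenB", "lengthenA", "lengthenB"]
    sim = simulate_annotation(cfg)
    usage = simulate_usage(sim, conditions=conditions)
    reads = simulate_pass_reads(sim, usage,
                                samples={c: c for c in conditions})
    pass_reads = filter_pass(reads)
    clusters = cluster_pa(pass_reads)
    counts = build_count_matrix(clusters, pass_reads)
    pa = classify_pa(clusters, sim.annotation)
    events = build_events(pa, clusters, counts, "top2_abundant")
    out: dict[str, pd.DataFrame] = {"_events": events}
    for cond in conditions[1:]:
        out[cond] = event_counts(events, counts, cond, "control")
    return out
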