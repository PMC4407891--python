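"""End-to-end pipeline: simulate (optional) -> PASS filter -> cluster ->
count -> classify -> events -> SAAP/GAAP -> sequence and summary stages.

Every output TSV carries '#key=value' header lines with the tool
version, the global seed and a config hash, and identical config + seed
reruns are byte-identical. One global seed drives the run; per-stage
generators are derived deterministically from (seed, stage name) so
enabling or disabling one stage never perturbs another.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .annotation import build_events, classify_pa, event_counts
from .cis import extract_windows, kmer_enrichment_by_region
from .gaap import GAAPConfig, gaap_run
from .processing import build_count_matrix, cluster_pa, filter_pass
from .simulate import SimConfig, simulate_all
from .stats import SAAPConfig, call_direction, saap

log = logging.getLogger("apakit")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "apakit_out"
    seed: int = 0
    sample_test: str = "test"
    sample_ctrl: str = "control"
    sim: SimConfig | None = None          # None = read inputs from paths
    annotation_gtf: str | None = None
    genome_fasta: str | None = None
    reads_tsv: str | None = None
    saap: SAAPConfig = field(default_factory=SAAPConfig)
    gaap: GAAPConfig | None = None
    event_mode: str = "top2_abundant"
    run_kmer: bool = False
    kmer_k: int = 4

    def __post_init__(self) -> None:
        if self.sim is None:
            for name in ("annotation_gtf", "reads_tsv"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"either sim config or {name} required")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: {path}")
            if self.run_kmer and (self.genome_fasta is None
                                  or not Path(self.genome_fasta).exists()):
                raise FileNotFoundError(
                    "stage kmer requires an existing genome FASTA")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "apakit_version": __version__,
        "seed": config.seed,
        "config_hash": io.config_hash(
            {k: v for k, v in vars(config).items() if k != "out_dir"}),
    }

    def _fail(stage: str, exc: Exception) -> Exception:
        return RuntimeError(f"pipeline stage '{stage}' failed: {exc}")

    # --- inputs
    if config.sim is not None:
        sim_cfg = config.sim
        sim, usage, reads = simulate_all(sim_cfg)
        annotation, genome = sim.annotation, sim.genome
        io.write_gtf(annotation, out / "annotation.gtf")
        io.write_fasta(genome, out / "genome.fa")
        io.write_reads_tsv(reads, out / "reads.tsv")
        io.write_table(
            usage, out / "true_usage.tsv", header_meta=meta)
    else:
        annotation = io.read_gtf(config.annotation_gtf)
        genome = (io.read_fasta(config.genome_fasta)
                  if config.genome_fasta else None)
        reads = io.read_reads_tsv(config.reads_tsv)

    # --- processing
    try:
        pass_reads = filter_pass(reads)
        log.info("PASS filter: kept %d / dropped %d reads", len(pass_reads),
                 len(reads) - len(pass_reads))
        clusters = cluster_pa(pass_reads)
        counts = build_count_matrix(clusters, pass_reads)
    except Exception as exc:  # pragma: no cover - defensive
        raise _fail("processing", exc)
    io.write_clusters_bed(clusters, out / "clusters.bed")
    io.write_counts_tsv(counts, out / "counts.tsv")

    # --- classification and events
    try:
        pa_ann = classify_pa(clusters, annotation)
        events = build_events(pa_ann, clusters, counts, config.event_mode)
    except Exception as exc:
        raise _fail("classify/events", exc)
    io.write_table(pa_ann, out / "pa_annotation.tsv", header_meta=meta)
    ev_out = events.copy()
    ev_out["set1"] = ev_out["set1"].map(lambda s: ",".join(s))
    ev_out["set2"] = ev_out["set2"].map(lambda s: ",".join(s))
    io.write_table(ev_out, out / "events.tsv", header_meta=meta)

    # --- SAAP
    try:
        ec = event_counts(events, counts, config.sample_test,
                          config.sample_ctrl)
        keep = ec[["a1", "a2", "b1", "b2"]].sum(axis=1) >= 20
        saap_cfg = SAAPConfig(
            m=config.saap.m, seed=stage_seed(config.seed, "saap"),
            pseudocount=config.saap.pseudocount,
            q_threshold=config.saap.q_threshold,
        )
        res = saap(ec[keep], saap_cfg)
        res["direction"] = call_direction(res, "utr3_pair",
                                          saap_cfg.q_threshold)
    except Exception as exc:
        raise _fail("saap", exc)
    io.write_table(res, out / "saap.tsv", header_meta=meta)

    # --- GAAP
    if config.gaap is not None:
        try:
            A = counts[config.sample_test]
            B = counts[config.sample_ctrl]
            g_cfg = GAAPConfig(
                n=config.gaap.n, p=config.gaap.p,
                seed=stage_seed(config.seed, "gaap"),
                q_threshold=config.gaap.q_threshold,
                min_read_rule=config.gaap.min_read_rule,
            )
            g = gaap_run(A, B, events, saap_cfg, g_cfg)
        except Exception as exc:
            raise _fail("gaap", exc)
        io.write_table(g.rounds, out / "gaap_rounds.tsv", header_meta=meta)
        summary = pd.DataFrame(
            {
                "direction": list(g.mean_normalized),
                "mean_normalized": list(g.mean_normalized.values()),
                "sd_normalized": list(g.sd_normalized.values()),
                "log2_ratio": g.log2_ratio,
            }
        )
        io.write_table(summary, out / "gaap_summary.tsv", header_meta=meta)

    # --- k-mer stage
    if config.run_kmer:
        if genome is None:
            raise _fail("kmer", FileNotFoundError("genome FASTA missing"))
        try:
            sig = res[res["q"] < config.saap.q_threshold]
            sig_genes = set(sig["event_id"].str.split(":").str[0])
            pa_tab = pa_ann.merge(
                clusters[["cluster_id", "chrom", "position", "strand"]],
                on="cluster_id",
            )
            utr3 = pa_tab[pa_tab["pa_class"] == "utr3"]
            prox = utr3[utr3["rank_in_utr3"] == 1]
            fg = prox[prox["gene_id"].isin(sig_genes)]
            bg = prox[~prox["gene_id"].isin(sig_genes)]
            if len(fg) and len(bg):
                fg_w = extract_windows(fg, genome)
                bg_w = extract_windows(bg, genome)
                km = kmer_enrichment_by_region(fg_w, bg_w, config.kmer_k)
                io.write_table(km, out / "kmer.tsv", header_meta=meta)
        except Exception as exc:
            raise _fail("kmer", exc)

    return out
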