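"""Synthetic 3'READS-like data generator.

Produces multi-exon gene models on both strands, a random genome with
optionally planted sequence motifs, per-condition poly(A)-site usage
tables with planted knockdown effects, and per-sample tables of read
3'-end positions carrying an unaligned-T count, so the whole downstream
pipeline can be exercised under statistically controlled conditions.

The usage model is multinomial per gene: control proportions come from a
Dirichlet prior over the gene's pA repertoire; a planted effect
multiplies the odds of the targeted pA(s) by a fold change and
renormalizes, so a 4-fold effect on a 50/50 tandem pair yields 0.8/0.2.
Read counts are multinomial over genes (log-normal abundances) and then
over pAs given usage; 3'-end positions are jittered uniformly within
+/-8 nt of the true site so the 24-nt clustering rule is exercised. A
configurable fraction of reads are internal-priming decoys with fewer
than two unaligned Ts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cis import REGIONS, window_coords
from .models import GeneModel, GenomeAnnotation, revcomp

Selector = Sequence[str] | Callable[[str], bool] | str

EVENT_CLASSES = {"utr3_shift", "intronic_up", "ua_up", "sp_up"}
DIRECTIONS = {"proximal_up", "distal_up", "up", "down"}


@dataclass(frozen=True)
class PlantedEffect:
    """A condition-specific usage shift for a subset of genes.

    ``condition`` restricts the effect to one named non-control
    condition; None applies it to every non-control condition.
    """

    gene_subset: Selector
    event_class: str
    fold_change: float
    direction: str
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event_class {self.event_class!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be > 0")


@dataclass(frozen=True)
class PlantedMotif:
    """A motif written into a window around a subset of pAs."""

    motif: str
    window: str
    pa_subset: Selector = "all"
    insertion_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.window not in REGIONS:
            raise ValueError(f"window must be one of {sorted(REGIONS)}")
        if not set(self.motif.upper()) <= set("ACGTU"):
            raise ValueError("motif alphabet is ACGT(U)")
        if not 0 <= self.insertion_prob <= 1:
            raise ValueError("insertion_prob must be in [0,1]")

    @property
    def dna(self) -> str:
        return self.motif.upper().replace("U", "T")


@dataclass
class SimConfig:
    """Study conditions for the generator. Ranges are inclusive."""

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (1, 8)
    exon_len: tuple[int, int] = (120, 400)
    intron_len: tuple[int, int] = (200, 2000)
    utr3_pa_count: tuple[int, int] = (2, 2)
    autr_len: tuple[int, int] = (150, 1500)
    frac_intronic_pa: float = 0.3
    frac_ua_pa: float = 0.3
    frac_sp_pa: float = 0.2
    depth_per_sample: int = 100_000
    decoy_frac: float = 0.05
    jitter: int = 8
    gene_spacing: tuple[int, int] = (5000, 8000)
    ua_distance_mean: float = 700.0
    ua_distance_sd: float = 300.0
    abundance_sigma: float = 1.0
    utr3_dirichlet_alpha: float = 2.0
    effect_table: list[PlantedEffect] = field(default_factory=list)
    motif_table: list[PlantedMotif] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_intronic_pa", "frac_ua_pa", "frac_sp_pa",
                     "decoy_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "utr3_pa_count", "autr_len", "gene_spacing"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"range {name}=({lo},{hi}) is empty/invalid")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class Simulation:
    """Bundle of everything the generator knows about the truth."""

    config: SimConfig
    annotation: GenomeAnnotation
    genome: dict[str, str]
    pa_table: pd.DataFrame  # pa_id gene_id chrom strand position pa_class intron_index


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def resolve_subset(selector: Selector, universe: Sequence[str]) -> list[str]:
    if isinstance(selector, str):
        if selector == "all":
            return list(universe)
        raise ValueError(f"unknown selector string {selector!r}")
    if callable(selector):
        return [u for u in universe if selector(u)]
    chosen = set(selector)
    return [u for u in universe if u in chosen]


def _sample_range(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def simulate_annotation(config: SimConfig) -> Simulation:
    """Build gene models, the pA repertoire and a random genome.

    Genes are laid out sequentially on one chromosome with alternating
    strands and >=2 kb flanks so upstream-antisense pAs and +/-100 nt
    sequence windows never run off the contig. The pA repertoire per gene:
    tandem 3'UTR pAs in the 3'-most exon (count from ``utr3_pa_count``,
    spaced by ``autr_len``), optionally one intronic pA (uniform intron),
    one TSS-upstream antisense (ua) pA at ~Normal(700, 300) nt clipped to
    [100, 2000], and one TSS-proximal sense (sp) pA inside the first
    intron within 2 kb of the TSS.
    """
    rng = _rng(config, 0)
    ann = GenomeAnnotation()
    pa_rows = []
    chrom = "chr1"
    cursor = _sample_range(rng, config.gene_spacing)

    for gi in range(config.n_genes):
        gene_id = f"g{gi:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = _sample_range(rng, config.exons_per_gene)
        n_utr3 = _sample_range(rng, config.utr3_pa_count)

        # 3'-most exon sized to hold the tandem pAs with margins
        spacings = [_sample_range(rng, config.autr_len) for _ in range(n_utr3 - 1)]
        last_exon_len = 200 + sum(spacings) + 150
        exon_lens = [_sample_range(rng, config.exon_len) for _ in range(n_exons - 1)]
        exon_lens.append(last_exon_len)
        intron_lens = [_sample_range(rng, config.intron_len)
                       for _ in range(n_exons - 1)]
        if strand == "-":
            exon_lens = exon_lens[::-1]
            intron_lens = intron_lens[::-1]

        start = cursor
        exons = []
        pos = start
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += intron_lens[i]
        end = exons[-1][1]
        gene = GeneModel(gene_id, chrom, strand, start, end, tuple(exons))
        ann.add(gene)
        cursor = end + _sample_range(rng, config.gene_spacing)

        # --- tandem 3'UTR pAs, 5'->3' in transcript orientation
        ls, le = gene.last_exon
        if strand == "+":
            first = ls + 200
            positions = [first]
            for sp in spacings:
                positions.append(positions[-1] + sp)
        else:
            first = le - 1 - 200
            positions = [first]
            for sp in spacings:
                positions.append(positions[-1] - sp)
        for rank, p in enumerate(positions, start=1):
            pa_rows.append((f"{gene_id}:utr3:{rank}", gene_id, chrom, strand,
                            p, "utr3", None))

        # --- intronic pA
        introns = gene.introns
        if introns and rng.random() < config.frac_intronic_pa:
            usable = [iv for iv in introns if iv[1] - iv[0] >= 50]
            if usable:
                s, e = usable[rng.integers(len(usable))]
                p = int((s + e) // 2)
                idx = gene.intron_index(p)
                pa_rows.append((f"{gene_id}:intron:{idx}", gene_id, chrom,
                                strand, p, "intron", idx))

        # --- upstream antisense (ua) pA
        if rng.random() < config.frac_ua_pa:
            d = int(np.clip(rng.normal(config.ua_distance_mean,
                                       config.ua_distance_sd), 100, 2000))
            p = gene.tss - d if strand == "+" else gene.tss + d
            ua_strand = "-" if strand == "+" else "+"
            pa_rows.append((f"{gene_id}:ua:1", gene_id, chrom, ua_strand,
                            p, "ua", None))

        # --- TSS-proximal sense (sp) pA in intron 1 within 2 kb of the TSS
        if introns and rng.random() < config.frac_sp_pa:
            if strand == "+":
                s, e = introns[0]
            else:
                s, e = introns[-1]
            offset = min(200, (e - s) // 2)
            p = s + offset if strand == "+" else e - 1 - offset
            if 0 < gene.tss_distance(p) <= 2000:
                idx = gene.intron_index(p)
                pa_rows.append((f"{gene_id}:sp:1", gene_id, chrom, strand,
                                p, "sp", idx))

    contig_len = cursor + 2500
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=contig_len)].tobytes().decode("ascii")
    genome = {chrom: seq}
    pa_table = pd.DataFrame(
        pa_rows, columns=["pa_id", "gene_id", "chrom", "strand", "position",
                          "pa_class", "intron_index"]
    )
    if config.motif_table:
        genome = plant_motifs(genome, pa_table, config.motif_table,
                              seed=config.seed)
    return Simulation(config, ann, genome, pa_table)


def plant_motifs(genome: dict[str, str], pa_table: pd.DataFrame,
                 motif_table: Sequence[PlantedMotif], seed: int
                 ) -> dict[str, str]:
    """Write motifs into strand-aware windows around selected pAs.

    Each insertion overwrites the window at a uniformly chosen offset;
    sequence length never changes. Minus-strand pAs receive the reverse
    complement on the plus strand at mirrored coordinates.
    """
    rng = np.random.default_rng([seed, 99])
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    for spec in motif_table:
        t1, t2 = REGIONS[spec.window]
        window_len = t2 - t1 + 1
        if len(spec.dna) > window_len:
            raise ValueError(f"motif {spec.motif} longer than window "
                             f"{spec.window}")
        targets = resolve_subset(spec.pa_subset, pa_table["pa_id"].tolist())
        target_set = set(targets)
        rows = pa_table[pa_table["pa_id"].isin(target_set)]
        for rec in rows.itertuples(index=False):
            if rng.random() >= spec.insertion_prob:
                continue
            start, end = window_coords(rec.position, rec.strand, spec.window)
            offset = int(rng.integers(0, window_len - len(spec.dna) + 1))
            if rec.strand == "+":
                g0 = start + offset
                ins = spec.dna
            else:
                # offset measured from the transcript-5' edge of the window
                g0 = end - offset - len(spec.dna)
                ins = revcomp(spec.dna)
            buf = seqs[rec.chrom]
            if g0 < 0 or g0 + len(ins) > len(buf):
                continue
            buf[g0 : g0 + len(ins)] = ins.encode("ascii")
    return {c: bytes(b).decode("ascii") for c, b in seqs.items()}


# ---------------------------------------------------------------- usage

def simulate_usage(sim: Simulation, conditions: Sequence[str] = ("control",
                                                                 "test")
                   ) -> pd.DataFrame:
    """Per-pA usage proportions per condition; planted effects applied.

    Control proportions: the gene's tandem 3'UTR pAs share a Dirichlet(2)
    draw over 1 - (minor-class mass); an intronic pA takes weight 0.20, a
    ua pA 0.10 and an sp pA 0.10 before renormalization. Effects multiply
    the odds of targeted pAs by ``fold_change`` (direction ``down`` uses
    its reciprocal) and renormalize, leaving untargeted genes identical
    across conditions.
    """
    config = sim.config
    rng = _rng(config, 1)
    base_weight = {"intron": 0.20, "ua": 0.10, "sp": 0.10}
    records = []
    for gene_id, grp in sim.pa_table.groupby("gene_id", sort=True):
        utr3 = grp[grp["pa_class"] == "utr3"]
        minor = grp[grp["pa_class"] != "utr3"]
        minor_mass = sum(base_weight[c] for c in minor["pa_class"])
        w = {}
        if len(utr3):
            alloc = (1.0 - minor_mass) * rng.dirichlet(
                [config.utr3_dirichlet_alpha] * len(utr3))
            for pa_id, frac in zip(utr3["pa_id"], alloc):
                w[pa_id] = frac
        for pa_id, cls in zip(minor["pa_id"], minor["pa_class"]):
            w[pa_id] = base_weight[cls]
        total = sum(w.values())
        for pa_id in grp["pa_id"]:
            records.append((gene_id, pa_id, w[pa_id] / total))
    usage = pd.DataFrame(records, columns=["gene_id", "pa_id", "control"])

    for cond in conditions:
        if cond != "control":
            usage[cond] = usage["control"]

    for effect in config.effect_table:
        genes = set(resolve_subset(effect.gene_subset,
                                   sorted(sim.pa_table["gene_id"].unique())))
        for cond in conditions:
            if cond == "control":
                continue
            if effect.condition is not None and cond != effect.condition:
                continue
            usage[cond] = _apply_effect(usage[["gene_id", "pa_id", cond]]
                                        .rename(columns={cond: "p"}),
                                        sim, effect, genes)
    return usage


def _apply_effect(usage: pd.DataFrame, sim: Simulation, effect: PlantedEffect,
                  genes: set[str]) -> pd.Series:
    pa_info = sim.pa_table.set_index("pa_id")
    out = usage["p"].to_numpy(copy=True)
    fc = effect.fold_change
    if effect.direction == "down":
        fc = 1.0 / fc
    for gene_id, idx in usage.groupby("gene_id").groups.items():
        if gene_id not in genes:
            continue
        pa_ids = usage.loc[idx, "pa_id"]
        classes = pa_info.loc[pa_ids, "pa_class"].to_numpy()
        target = np.zeros(len(idx), dtype=bool)
        if effect.event_class == "utr3_shift":
            utr3_mask = classes == "utr3"
            if utr3_mask.sum() < 2:
                continue
            ranks = [int(p.split(":")[-1]) for p in pa_ids[utr3_mask]]
            if effect.direction == "proximal_up":
                chosen = int(np.argmin(ranks))
            elif effect.direction == "distal_up":
                chosen = int(np.argmax(ranks))
            else:
                raise ValueError("utr3_shift needs proximal_up/distal_up")
            target[np.flatnonzero(utr3_mask)[chosen]] = True
        elif effect.event_class == "intronic_up":
            target = classes == "intron"
        elif effect.event_class == "ua_up":
            target = classes == "ua"
        elif effect.event_class == "sp_up":
            target = classes == "sp"
        if not target.any():
            continue
        vals = out[np.asarray(idx)]
        vals = np.where(target, vals * fc, vals)
        out[np.asarray(idx)] = vals / vals.sum()
    return pd.Series(out, index=usage.index)


# ---------------------------------------------------------------- reads

def simulate_pass_reads(sim: Simulation, usage: pd.DataFrame,
                        samples: dict[str, str] | None = None,
                        depth: int | None = None) -> pd.DataFrame:
    """Emit per-sample read 3'-end tables.

    ``samples`` maps sample name -> condition column of ``usage``
    (default {"control": "control", "test": "test"}). Per sample exactly
    ``depth`` reads are emitted: gene totals are multinomial over
    log-normal gene abundances (shared across samples, so expression is
    condition-independent), pA counts multinomial given the condition's
    usage, positions jittered U[-jitter, +jitter], and a ``decoy_frac``
    fraction are internal-priming decoys with <2 unaligned Ts at uniform
    gene-body positions.
    """
    config = sim.config
    if samples is None:
        samples = {"control": "control", "test": "test"}
    if depth is None:
        depth = config.depth_per_sample
    rng = _rng(config, 2)

    gene_ids = sorted(sim.pa_table["gene_id"].unique())
    abund = rng.lognormal(0.0, config.abundance_sigma, size=len(gene_ids))
    abund /= abund.sum()
    genes = {g: sim.annotation[g] for g in gene_ids}

    usage_by_gene = {
        g: grp for g, grp in usage.groupby("gene_id", sort=True)
    }
    pa_pos = sim.pa_table.set_index("pa_id")[["chrom", "strand", "position"]]

    frames = []
    for sample, cond in samples.items():
        n_decoy = int(rng.binomial(depth, config.decoy_frac))
        n_true = depth - n_decoy
        gene_counts = rng.multinomial(n_true, abund)

        chroms, positions, strands, tcounts = [], [], [], []
        for g, n_g in zip(gene_ids, gene_counts):
            if n_g == 0:
                continue
            grp = usage_by_gene[g]
            props = grp[cond].to_numpy()
            pa_counts = rng.multinomial(n_g, props / props.sum())
            for pa_id, n_pa in zip(grp["pa_id"], pa_counts):
                if n_pa == 0:
                    continue
                chrom, strand, pos = pa_pos.loc[pa_id]
                jit = rng.integers(-config.jitter, config.jitter + 1,
                                   size=n_pa)
                positions.extend((pos + jit).tolist())
                chroms.extend([chrom] * n_pa)
                strands.extend([strand] * n_pa)
                tcounts.extend((2 + rng.poisson(3.0, size=n_pa)).tolist())

        # internal-priming decoys: <2 unaligned Ts, uniform gene-body position
        decoy_gene_idx = rng.choice(len(gene_ids), size=n_decoy, p=abund)
        for gi in decoy_gene_idx:
            gene = genes[gene_ids[gi]]
            positions.append(int(rng.integers(gene.start, gene.end)))
            chroms.append(gene.chrom)
            strands.append(gene.strand)
            tcounts.append(int(rng.integers(0, 2)))

        df = pd.DataFrame(
            {
                "chrom": chroms,
                "position": positions,
                "strand": strands,
                "sample": sample,
                "read_id": [f"{sample}:{i}" for i in range(len(positions))],
                "unaligned_T": tcounts,
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_all(config: SimConfig,
                 samples: dict[str, str] | None = None
                 ) -> tuple[Simulation, pd.DataFrame, pd.DataFrame]:
    """Convenience: annotation+genome, usage, reads in one call."""
    sim = simulate_annotation(config)
    conditions = ("control", "test") if samples is None else tuple(
        dict.fromkeys(samples.values()))
    usage = simulate_usage(sim, conditions=conditions)
    reads = simulate_pass_reads(sim, usage, samples=samples)
    return sim, usage, reads
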