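"""Sequence context around poly(A) sites: window extraction, k-mer
enrichment with signed significance scores, nucleotide profiles, and the
proximal-pA distance/AATAAA grouping.

All windows are reported in sense (transcript) orientation with the
cleaved nucleotide at position 0. The three canonical regions are
-100..-41, -40..-1 and +1..+100 relative to the pA.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .models import revcomp

#: region label -> inclusive transcript-coordinate bounds (pA = 0)
REGIONS: dict[str, tuple[int, int]] = {
    "U100_41": (-100, -41),
    "U40_1": (-40, -1),
    "D1_100": (1, 100),
}


def window_coords(position: int, strand: str, region: str) -> tuple[int, int]:
    """Genomic half-open interval for a named window around a pA.

    On the minus strand upstream means higher genomic coordinates; the
    extracted sequence must then be reverse-complemented to read 5'->3'.
    """
    t1, t2 = REGIONS[region]
    if strand == "+":
        return position + t1, position + t2 + 1
    return position - t2, position - t1 + 1


def extract_window(genome: dict[str, str], chrom: str, position: int,
                   strand: str, region: str) -> str | None:
    """Sense-orientation window sequence, or None if truncated at an edge."""
    start, end = window_coords(position, strand, region)
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        return None
    w = seq[start:end].upper()
    return revcomp(w) if strand == "-" else w


def extract_windows(pa_table: pd.DataFrame, genome: dict[str, str],
                    regions: tuple[str, ...] = ("U100_41", "U40_1", "D1_100"),
                    ) -> pd.DataFrame:
    """One row per pA per region: cluster_id, region, seq, truncated.

    ``pa_table`` needs columns cluster_id, chrom, position, strand.
    Truncated windows (running off a contig end) carry seq=None and are
    excluded from all downstream counting.
    """
    rows = []
    for rec in pa_table.itertuples(index=False):
        for region in regions:
            seq = extract_window(genome, rec.chrom, rec.position, rec.strand,
                                 region)
            rows.append((rec.cluster_id, region, seq, seq is None))
    return pd.DataFrame(rows, columns=["cluster_id", "region", "seq",
                                       "truncated"])


def _containment(seqs: list[str], k: int) -> dict[str, int]:
    """Number of sequences containing each k-mer at least once."""
    counts: dict[str, int] = {}
    for seq in seqs:
        present = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for kmer in present:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(fg_seqs: list[str], bg_seqs: list[str], k: int,
                    alphabet: str = "ACGT") -> pd.DataFrame:
    """Per-k-mer two-sided Fisher's exact test on sequence containment.

    The 2x2 table is (contains >=1 occurrence vs not) x (foreground vs
    background). SS = -log10(P) signed + for enrichment in the foreground,
    - for depletion. |SS| >= 3 corresponds to P <= 0.001.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    fg_with = _containment(fg_seqs, k)
    bg_with = _containment(bg_seqs, k)
    n_fg, n_bg = len(fg_seqs), len(bg_seqs)
    cache: dict[tuple[int, int], float] = {}
    rows = []
    for kmer_tuple in product(alphabet, repeat=k):
        kmer = "".join(kmer_tuple)
        a = fg_with.get(kmer, 0)
        b = bg_with.get(kmer, 0)
        key = (a, b)
        if key in cache:
            p = cache[key]
        else:
            _, p = stats.fisher_exact([[a, n_fg - a], [b, n_bg - b]],
                                      alternative="two-sided")
            cache[key] = p
        # direction from containment-rate comparison
        sign = 1.0 if a * n_bg >= b * n_fg else -1.0
        ss = -np.log10(max(p, 1e-300)) * sign
        rows.append((kmer, a, n_fg - a, b, n_bg - b, p, ss))
    return pd.DataFrame(
        rows, columns=["kmer", "fg_with", "fg_without", "bg_with",
                       "bg_without", "p", "ss"]
    ).sort_values("ss", ascending=False, ignore_index=True)


def kmer_enrichment_by_region(fg_windows: pd.DataFrame,
                              bg_windows: pd.DataFrame, k: int
                              ) -> pd.DataFrame:
    """Run kmer_enrichment per region on window tables from extract_windows."""
    out = []
    for region in REGIONS:
        fg = fg_windows.query("region == @region and ~truncated")["seq"].tolist()
        bg = bg_windows.query("region == @region and ~truncated")["seq"].tolist()
        res = kmer_enrichment(fg, bg, k)
        res.insert(1, "region", region)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def nucleotide_profile(pa_table: pd.DataFrame, genome: dict[str, str],
                       halfwidth: int = 100) -> pd.DataFrame:
    """Per-position base frequencies in [-halfwidth, +halfwidth] around pAs.

    Returns a frame indexed by transcript-relative position with columns
    A, C, G, U summing to 1 at every position (sites whose full window is
    not extractable are skipped).
    """
    width = 2 * halfwidth + 1
    counts = np.zeros((width, 4), dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = 0
    for rec in pa_table.itertuples(index=False):
        seq = genome[rec.chrom]
        start, end = rec.position - halfwidth, rec.position + halfwidth + 1
        if start < 0 or end > len(seq):
            continue
        w = seq[start:end].upper()
        if rec.strand == "-":
            w = revcomp(w)
        for i, base in enumerate(w):
            if base in base_idx:
                counts[i, base_idx[base]] += 1
        n += 1
    if n == 0:
        raise ValueError("no extractable windows")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        freqs, columns=["A", "C", "G", "U"],
        index=pd.RangeIndex(-halfwidth, halfwidth + 1, name="position"),
    )


def has_downstream_aataaa(genome: dict[str, str], chrom: str, position: int,
                          strand: str) -> bool:
    """Exact AATAAA match on the sense strand within +1..+100 of the pA."""
    seq = extract_window(genome, chrom, position, strand, "D1_100")
    return seq is not None and "AATAAA" in seq


def distance_pas_groups(pairs: pd.DataFrame, genome: dict[str, str],
                        distance_cutoff: int = 120) -> tuple[pd.DataFrame,
                                                             pd.DataFrame,
                                                             pd.DataFrame]:
    """Partition tandem 3'UTR pA pairs by aUTR size and downstream AATAAA.

    ``pairs`` needs columns: gene_id, autr_len, red, chrom, strand and the
    proximal pA coordinate as ``proximal_position``. Groups: 1 = short
    (< cutoff) with AATAAA within +1..+100 of the proximal pA, 2 = short
    without, 3 = long (>= cutoff) with, 4 = long without. Returns the
    pairs with a ``group`` column, a per-group summary (n, median RED)
    and two-sided Kolmogorov-Smirnov comparisons 1 vs 2 and 3 vs 4.
    """
    pairs = pairs.copy()
    pas = [
        has_downstream_aataaa(genome, r.chrom, r.proximal_position, r.strand)
        for r in pairs.itertuples(index=False)
    ]
    short = pairs["autr_len"] < distance_cutoff
    pas = np.asarray(pas)
    group = np.where(short, np.where(pas, 1, 2), np.where(pas, 3, 4))
    pairs["group"] = group

    summary = (
        pairs.groupby("group")["red"]
        .agg(n="size", median_red="median")
        .reindex([1, 2, 3, 4])
        .reset_index()
    )

    ks_rows = []
    for g1, g2 in [(1, 2), (3, 4)]:
        x = pairs.loc[pairs["group"] == g1, "red"].to_numpy()
        y = pairs.loc[pairs["group"] == g2, "red"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            ks_rows.append((g1, g2, np.nan, np.nan, True))
        else:
            res = stats.ks_2samp(x, y)
            ks_rows.append((g1, g2, res.statistic, res.pvalue, False))
    ks = pd.DataFrame(ks_rows, columns=["group_a", "group_b", "ks_stat",
                                        "p", "skipped"])
    return pairs, summary, ks
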