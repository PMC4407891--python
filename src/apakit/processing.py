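"""PASS filtering, 24-nt poly(A)-site clustering and count-matrix assembly.

A read is poly(A) site-supporting (PASS) when it carries >=2 unaligned Ts
at its 5' end, evidence that it spans the poly(A)-tail junction. Distinct
PASS 3'-end positions within 24 nt of each other on the same chromosome
and strand are chained into one cluster (single linkage, so a chain of
24-nt gaps can span more than 24 nt). The cluster representative is the
modal position by read count, ties broken toward the 3'-most position in
transcript orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLUSTER_GAP = 24


def filter_pass(reads: pd.DataFrame, min_t: int = 2) -> pd.DataFrame:
    """Retain reads with >= ``min_t`` unaligned 5' Ts, preserving order."""
    if "unaligned_T" not in reads.columns:
        raise ValueError("read table lacks an unaligned_T column")
    return reads[reads["unaligned_T"] >= min_t]


def cluster_pa(reads: pd.DataFrame) -> pd.DataFrame:
    """Chain distinct PASS 3'-end positions with gap <= 24 nt into clusters.

    Returns one row per cluster: cluster_id, chrom, strand, position
    (representative), start, end (half-open span over member positions),
    n_reads. Sorted by (chrom, strand, start).
    """
    rows = []
    grouped = reads.groupby(["chrom", "strand"], sort=True)
    for (chrom, strand), grp in grouped:
        pos_counts = grp.groupby("position").size().sort_index()
        positions = pos_counts.index.to_numpy()
        counts = pos_counts.to_numpy()
        if len(positions) == 0:
            continue
        breaks = np.flatnonzero(np.diff(positions) > CLUSTER_GAP) + 1
        for seg_pos, seg_cnt in zip(np.split(positions, breaks),
                                    np.split(counts, breaks)):
            best = seg_cnt == seg_cnt.max()
            candidates = seg_pos[best]
            rep = candidates.max() if strand == "+" else candidates.min()
            rows.append((chrom, strand, int(rep), int(seg_pos[0]),
                         int(seg_pos[-1]) + 1, int(seg_cnt.sum())))
    out = pd.DataFrame(rows, columns=["chrom", "strand", "position", "start",
                                      "end", "n_reads"])
    out = out.sort_values(["chrom", "strand", "start"], ignore_index=True)
    out.insert(0, "cluster_id",
               out["chrom"] + ":" + out["strand"] + ":"
               + out["position"].astype(str))
    return out


def assign_clusters(reads: pd.DataFrame, clusters: pd.DataFrame) -> pd.Series:
    """Map each read to the cluster whose span contains its 3'-end position.

    Raises if any read falls outside every cluster span on its
    chromosome/strand, which signals a clustering/counting mismatch.
    """
    out = pd.Series(pd.NA, index=reads.index, dtype="object")
    for (chrom, strand), cl in clusters.groupby(["chrom", "strand"]):
        cl = cl.sort_values("start")
        starts = cl["start"].to_numpy()
        ends = cl["end"].to_numpy()
        ids = cl["cluster_id"].to_numpy()
        mask = (reads["chrom"] == chrom) & (reads["strand"] == strand)
        pos = reads.loc[mask, "position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        if not ok.all():
            bad = pos[~ok][:3]
            raise ValueError(
                f"reads at {chrom}{strand}{bad.tolist()} fall outside all "
                "cluster spans"
            )
        out.loc[mask] = ids[idx]
    if out.isna().any():
        raise ValueError("reads on chrom/strand with no clusters")
    return out


def build_count_matrix(clusters: pd.DataFrame, reads: pd.DataFrame
                       ) -> pd.DataFrame:
    """Cluster x sample matrix of PASS read counts.

    Column sums equal per-sample PASS totals; samples with zero reads
    still appear as all-zero columns when present in the read table's
    sample categories.
    """
    assigned = assign_clusters(reads, clusters)
    tab = (
        pd.DataFrame({"cluster_id": assigned, "sample": reads["sample"]})
        .groupby(["cluster_id", "sample"], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    tab = tab.reindex(index=clusters["cluster_id"], fill_value=0)
    tab.columns.name = None
    tab.index.name = "cluster_id"
    return tab.astype(int)
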