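"""Classification of pA clusters against gene models and APA event
construction.

Structural classes partition the clusters: a sense cluster inside a gene
is ``utr3`` (in the 3'-most exon), ``internal_exon`` (any other exon) or
``intron``; an antisense cluster within 2 kb upstream of a TSS that does
not overlap a gene body on its own strand is ``uaRNA``; everything else
is ``intergenic``. Two non-exclusive flags ride along: ``sp_flag`` for
sense clusters within 2 kb downstream of the TSS of a multi-exon host
outside its 3'-most exon (TSS-proximal sense RNA), and ``ua_flag``
mirroring the uaRNA definition, so the TSS-proximal analyses can select
sites without disturbing the structural partition (an intron-1 pA close
to the TSS is legitimately both intronic and TSS-proximal).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GenomeAnnotation

TSS_WINDOW = 2000

ORDINAL_LABELS = ("+1", "+2", "M", "-2", "-1")


def assign_intron_ordinal(intron_index: int, intron_count: int) -> str | None:
    """Ordinal label for an intron: first two, last two, or middle.

    Defined only for genes with >= 4 introns; returns None (excluded)
    otherwise. ``intron_index`` is 1-based in transcript orientation.
    """
    if not 1 <= intron_index <= intron_count:
        raise ValueError("intron_index out of range")
    if intron_count < 4:
        return None
    if intron_index == 1:
        return "+1"
    if intron_index == 2:
        return "+2"
    if intron_index == intron_count:
        return "-1"
    if intron_index == intron_count - 1:
        return "-2"
    return "M"


def _gene_trees(annotation: GenomeAnnotation) -> dict[tuple[str, str],
                                                      IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in annotation:
        trees.setdefault((gene.chrom, gene.strand), IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id
        )
    return trees


def classify_pa(clusters: pd.DataFrame, annotation: GenomeAnnotation
                ) -> pd.DataFrame:
    """Assign every cluster exactly one structural class plus flags.

    Returns a frame with cluster_id, gene_id, pa_class, intron_index,
    intron_count, intron_ordinal, tss_distance, sp_flag, ua_flag,
    rank_in_utr3, utr3_len (distance from the 3'-most exon start to the
    pA, a 3'UTR-length proxy when the stop codon is not annotated).
    """
    if any(len(g.exons) == 0 for g in annotation):
        raise ValueError("annotation has genes without exons")
    trees = _gene_trees(annotation)
    rows = []
    for rec in clusters.itertuples(index=False):
        pos = rec.position
        sense_hits = sorted(
            iv.data for iv in trees.get((rec.chrom, rec.strand),
                                        IntervalTree()).at(pos)
        )
        gene_id = None
        pa_class = "intergenic"
        intron_index = intron_count = None
        ordinal = None
        tssd = None
        sp_flag = ua_flag = False

        if sense_hits:
            gene = annotation[sense_hits[0]]
            gene_id = gene.gene_id
            tssd = gene.tss_distance(pos)
            intron_count = gene.n_introns
            ls, le = gene.last_exon
            if ls <= pos < le:
                pa_class = "utr3"
            else:
                idx = gene.intron_index(pos)
                if idx is not None:
                    pa_class = "intron"
                    intron_index = idx
                    ordinal = assign_intron_ordinal(idx, gene.n_introns)
                else:
                    pa_class = "internal_exon"
            if (pa_class != "utr3" and gene.n_introns >= 1
                    and 0 < tssd <= TSS_WINDOW):
                sp_flag = True
        else:
            # antisense TSS-upstream candidate
            anti = "-" if rec.strand == "+" else "+"
            best = None
            for iv in trees.get((rec.chrom, anti), IntervalTree()):
                gene = annotation[iv.data]
                d = gene.tss_distance(pos)  # negative = upstream of the TSS
                if -TSS_WINDOW <= d < 0 and (best is None or d > best[0]):
                    best = (d, gene.gene_id)
            if best is not None:
                pa_class = "uaRNA"
                ua_flag = True
                gene_id = best[1]
                tssd = best[0]
        rows.append((rec.cluster_id, gene_id, pa_class, intron_index,
                     intron_count, ordinal, tssd, sp_flag, ua_flag))

    out = pd.DataFrame(
        rows, columns=["cluster_id", "gene_id", "pa_class", "intron_index",
                       "intron_count", "intron_ordinal", "tss_distance",
                       "sp_flag", "ua_flag"],
    )

    # 3'UTR geometry: rank 5'->3' and distance from the 3'-most exon start
    cl = clusters.set_index("cluster_id")
    rank = pd.Series(np.nan, index=out.index)
    utr3_len = pd.Series(np.nan, index=out.index)
    utr3_rows = out[out["pa_class"] == "utr3"]
    for gene_id, grp in utr3_rows.groupby("gene_id"):
        gene = annotation[gene_id]
        pos = cl.loc[grp["cluster_id"], "position"]
        order = pos.argsort() if gene.strand == "+" else (-pos).argsort()
        ranks = np.empty(len(grp), dtype=int)
        ranks[order.to_numpy()] = np.arange(1, len(grp) + 1)
        rank.loc[grp.index] = ranks
        ls, le = gene.last_exon
        anchor = ls if gene.strand == "+" else le - 1
        utr3_len.loc[grp.index] = (pos.to_numpy() - anchor) * (
            1 if gene.strand == "+" else -1)
    out["rank_in_utr3"] = rank
    out["utr3_len"] = utr3_len
    return out


# ------------------------------------------------------------------ events

EVENT_MODES = ("top2_abundant", "one_vs_rest", "cds", "uaRNA", "spRNA",
               "intronic_single")


def build_events(pa_annotation: pd.DataFrame, clusters: pd.DataFrame,
                 counts: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Construct APA events (set1 vs set2 of cluster ids) for a mode.

    top2_abundant: per gene, the two highest-total-count 3'UTR pAs;
      set1 = proximal, set2 = distal; autr_len = distance between the two
      representative positions. Abundance ties break toward the 3'-most pA.
    one_vs_rest: each 3'UTR pA vs the gene's other 3'UTR pAs.
    cds: all upstream-region pAs (introns + internal exons) combined vs
      all 3'-most-exon pAs.
    uaRNA / spRNA: the flagged class set vs the gene's sense pAs located
      beyond 2 kb downstream of the TSS.
    intronic_single: each intronic pA vs all other pAs of the gene.
    """
    if mode not in EVENT_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ann = pa_annotation.merge(
        clusters[["cluster_id", "position", "strand"]], on="cluster_id"
    )
    totals = counts.sum(axis=1)
    rows: list[tuple] = []

    for gene_id, grp in ann[ann["gene_id"].notna()].groupby("gene_id"):
        utr3 = grp[grp["pa_class"] == "utr3"]
        if mode == "top2_abundant":
            if len(utr3) < 2:
                continue
            strand = utr3["strand"].iloc[0]
            tot = totals.reindex(utr3["cluster_id"]).fillna(0)
            # tie toward the 3'-most pA: sort by (count, 3'-ward position)
            key = utr3.assign(
                total=tot.to_numpy(),
                threeward=utr3["position"] * (1 if strand == "+" else -1),
            ).sort_values(["total", "threeward"], ascending=False)
            top2 = key.head(2)
            proximal = top2.loc[top2["rank_in_utr3"].idxmin()]
            distal = top2.loc[top2["rank_in_utr3"].idxmax()]
            autr = abs(int(distal["position"]) - int(proximal["position"]))
            rows.append((f"{gene_id}:utr3_pair", gene_id, "utr3_pair",
                         (proximal["cluster_id"],), (distal["cluster_id"],),
                         autr))
        elif mode == "one_vs_rest":
            if len(utr3) < 2:
                continue
            ids = utr3.sort_values("rank_in_utr3")["cluster_id"].tolist()
            for cid in ids:
                rest = tuple(c for c in ids if c != cid)
                rows.append((f"{gene_id}:ovr:{cid}", gene_id, "utr3_pair",
                             (cid,), rest, np.nan))
        elif mode == "cds":
            upstream = grp[grp["pa_class"].isin(["intron", "internal_exon"])]
            if len(upstream) == 0 or len(utr3) == 0:
                continue
            rows.append((f"{gene_id}:cds", gene_id, "cds_vs_last_exon",
                         tuple(upstream["cluster_id"]),
                         tuple(utr3["cluster_id"]), np.nan))
        elif mode in ("uaRNA", "spRNA"):
            flag = "ua_flag" if mode == "uaRNA" else "sp_flag"
            focal = grp[grp[flag]]
            if len(focal) == 0:
                continue
            sense = grp[(~grp["ua_flag"])
                        & ((grp["tss_distance"] > TSS_WINDOW)
                           | (grp["pa_class"] == "utr3"))]
            sense = sense[~sense["cluster_id"].isin(focal["cluster_id"])]
            if len(sense) == 0:
                continue
            rows.append((f"{gene_id}:{mode}", gene_id, mode,
                         tuple(focal["cluster_id"]),
                         tuple(sense["cluster_id"]), np.nan))
        elif mode == "intronic_single":
            intronic = grp[grp["pa_class"] == "intron"]
            for cid in intronic["cluster_id"]:
                rest = tuple(c for c in grp["cluster_id"] if c != cid)
                if not rest:
                    continue
                rows.append((f"{gene_id}:intronic:{cid}", gene_id,
                             "intronic_single", (cid,), rest, np.nan))

    return pd.DataFrame(
        rows, columns=["event_id", "gene_id", "event_type", "set1", "set2",
                       "autr_len"],
    )


def event_counts(events: pd.DataFrame, counts: pd.DataFrame,
                 sample_a: str, sample_b: str) -> pd.DataFrame:
    """Collapse the count matrix to per-event a1,a2,b1,b2 totals.

    Sample ``a`` is the test condition, ``b`` the control; set1/set2
    columns follow the event definition (set2 = distal/reference).
    """
    ca = counts[sample_a]
    cb = counts[sample_b]
    rows = []
    for ev in events.itertuples(index=False):
        s1 = list(ev.set1)
        s2 = list(ev.set2)
        rows.append((ev.event_id,
                     int(ca.reindex(s1).fillna(0).sum()),
                     int(ca.reindex(s2).fillna(0).sum()),
                     int(cb.reindex(s1).fillna(0).sum()),
                     int(cb.reindex(s2).fillna(0).sum())))
    return pd.DataFrame(rows, columns=["event_id", "a1", "a2", "b1", "b2"])


MIN_READ_RULES = ("utr3_20_combined", "intronic_10_combined", "matrix_5_all")


def min_read_filter(event_counts_row: pd.Series | dict, rule: str,
                    all_sample_counts: Iterable[int] | None = None) -> bool:
    """Keep/drop decision for one event under the named read-count rule.

    utr3_20_combined: >= 20 PASS reads over both pAs and both samples.
    intronic_10_combined: the focal isoform (set1) has >= 10 reads over
      the two samples combined.
    matrix_5_all: the focal isoform has >= 5 reads in every sample
      (pass the per-sample counts via ``all_sample_counts``).
    """
    e = event_counts_row
    if rule == "utr3_20_combined":
        return e["a1"] + e["a2"] + e["b1"] + e["b2"] >= 20
    if rule == "intronic_10_combined":
        return e["a1"] + e["b1"] >= 10
    if rule == "matrix_5_all":
        if all_sample_counts is None:
            raise ValueError("matrix_5_all needs per-sample isoform counts")
        return all(c >= 5 for c in all_sample_counts)
    raise ValueError(f"unknown rule {rule!r}")
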