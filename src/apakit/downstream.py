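"""Downstream summaries: aUTR-size binning of RED, hierarchical
clustering of RED profiles, the ten-group gene partition over two focal
factors, gene-set enrichment and RPM gene-expression changes."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def autr_bin_red(events: pd.DataFrame, n_bins: int = 5) -> tuple[pd.DataFrame,
                                                                 float]:
    """Quintile-bin genes by aUTR size and compare extreme bins' REDs.

    ``events`` needs gene_id, autr_len, red (already read-filtered).
    Ties in aUTR size are resolved by stable sort on gene id so bins stay
    equal-sized. Returns the per-bin summary (n, mean aUTR, mean RED) and
    the two-sided Wilcoxon rank-sum P comparing bin 1 (shortest) with the
    last bin.
    """
    if len(events) < n_bins:
        raise ValueError(f"need >= {n_bins} genes")
    df = events.sort_values(["autr_len", "gene_id"],
                            kind="stable").reset_index(drop=True)
    df["bin"] = pd.qcut(np.arange(len(df)), n_bins, labels=False) + 1
    summary = (
        df.groupby("bin")
        .agg(n=("red", "size"), mean_autr=("autr_len", "mean"),
             mean_red=("red", "mean"), median_red=("red", "median"))
        .reset_index()
    )
    lo = df.loc[df["bin"] == 1, "red"]
    hi = df.loc[df["bin"] == n_bins, "red"]
    p = float(sps.mannwhitneyu(lo, hi, alternative="two-sided").pvalue)
    return summary, p


def red_matrix(results_by_contrast: dict[str, pd.DataFrame],
               q_threshold: float = 0.05) -> pd.DataFrame:
    """Genes x contrasts RED matrix with non-significant REDs set to 0.

    Each value is the event's RED when its q-value passes the threshold
    and 0 otherwise; the zeroing is applied before any distance
    computation.
    """
    cols = {}
    for name, res in results_by_contrast.items():
        r = res.set_index("gene_id") if "gene_id" in res.columns else res
        vals = r["red"].where(r["q"] < q_threshold, 0.0)
        cols[name] = vals
    return pd.DataFrame(cols).dropna()


def cluster_red_profiles(matrix: pd.DataFrame, axis: str = "columns"
                         ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering with 1 - Pearson distance.

    Zero-variance columns (or rows) are dropped with a warning-free flag;
    returns the scipy linkage matrix and the leaf order labels.
    """
    data = matrix.T if axis == "columns" else matrix
    variances = data.var(axis=1)
    kept = data[variances > 0]
    if len(kept) < 2:
        raise ValueError("need >= 2 non-degenerate profiles")
    corr = np.corrcoef(kept.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False),
                             method="average")
    order = hierarchy.leaves_list(link)
    return link, [kept.index[i] for i in order]


#: printed group order of the 3x3 (factor1, factor2) direction pairs,
#: excluding (ns, ns) which routes to groups 9/10
GROUP_CODES: dict[tuple[str, str], int] = {
    ("Sh", "Sh"): 1,
    ("Sh", "ns"): 2,
    ("Sh", "Le"): 3,
    ("ns", "Sh"): 4,
    ("ns", "Le"): 5,
    ("Le", "Sh"): 6,
    ("Le", "ns"): 7,
    ("Le", "Le"): 8,
}


def assign_groups(calls: pd.DataFrame, factor1: str, factor2: str,
                  other_factors: list[str],
                  group_codes: dict[tuple[str, str], int] | None = None
                  ) -> pd.Series:
    """Ten-group gene partition from per-factor direction calls.

    ``calls`` is genes x factors with entries 'Le', 'Sh' or 'ns'. Groups
    1-8 enumerate the (factor1, factor2) combinations; genes unregulated
    by both go to group 9 when regulated by any of ``other_factors``,
    else group 10.
    """
    if group_codes is None:
        group_codes = GROUP_CODES
    for col in [factor1, factor2, *other_factors]:
        if col not in calls.columns:
            raise ValueError(f"missing factor column {col!r}")
    out = pd.Series(10, index=calls.index, name="group")
    for (d1, d2), code in group_codes.items():
        out[(calls[factor1] == d1) & (calls[factor2] == d2)] = code
    none_none = (calls[factor1] == "ns") & (calls[factor2] == "ns")
    any_other = (calls[other_factors] != "ns").any(axis=1)
    out[none_none & any_other] = 9
    out[none_none & ~any_other] = 10
    return out


def geneset_enrichment(group_genes: set[str], gene_sets: dict[str, set[str]],
                       universe: set[str]) -> pd.DataFrame:
    """One-sided Fisher enrichment of a gene group in named gene sets.

    The universe is the full grouped-gene collection; sets are clipped to
    it. Reports P and -log10(P) per set.
    """
    if not universe:
        raise ValueError("empty universe")
    group = group_genes & universe
    rows = []
    for name, members in gene_sets.items():
        in_set = members & universe
        k = len(group & in_set)
        table = [[k, len(group) - k],
                 [len(in_set) - k, len(universe) - len(group) - len(in_set) + k]]
        _, p = sps.fisher_exact(table, alternative="greater")
        rows.append((name, k, len(in_set), len(group), p,
                     -np.log10(max(p, 1e-300))))
    return pd.DataFrame(
        rows, columns=["gene_set", "overlap", "set_size", "group_size", "p",
                       "neg_log10_p"],
    ).sort_values("p", ignore_index=True)


def gene_expression_change(counts: pd.DataFrame, pa_annotation: pd.DataFrame,
                           sample_test: str, sample_ctrl: str,
                           min_total: int = 20) -> pd.DataFrame:
    """Per-gene RPM (3'-most-exon PASS reads per million total PASS
    reads) and log2 change between two samples.

    Genes need strictly more than ``min_total`` PASS reads (both samples
    combined, 3'-most exon) to receive a log2 change; others get NaN.
    """
    tot_t = counts[sample_test].sum()
    tot_c = counts[sample_ctrl].sum()
    if tot_t <= 0 or tot_c <= 0:
        raise ValueError("per-sample totals must be > 0")
    utr3 = pa_annotation[pa_annotation["pa_class"] == "utr3"]
    joined = counts.loc[
        counts.index.intersection(utr3["cluster_id"])
    ].join(utr3.set_index("cluster_id")["gene_id"])
    per_gene = joined.groupby("gene_id")[[sample_test, sample_ctrl]].sum()
    rpm_t = 1e6 * per_gene[sample_test] / tot_t
    rpm_c = 1e6 * per_gene[sample_ctrl] / tot_c
    total = per_gene[sample_test] + per_gene[sample_ctrl]
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.log2(rpm_t / rpm_c)
    change = change.where(total > min_total)
    return pd.DataFrame(
        {"rpm_test": rpm_t, "rpm_ctrl": rpm_c, "total_reads": total,
         "log2_change": change}
    )
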