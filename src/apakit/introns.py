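"""Intron-position bias of intronic polyadenylation and signed
feature scores.

Intronic pA isoforms of genes with >= 4 introns are grouped by intron
ordinal (+1, +2, M, -2, -1). Expression changes are log2 ratios of
depth-normalized (RPM) PASS-read counts between a test and a control
sample; group means are mean-centered across the ordinal groups to
expose positional bias. Intron features (length, splice-site strengths,
consumed as numeric columns) of a foreground intron set are compared to
a background set with a two-sided Wilcoxon rank-sum test, reported as a
signed significance score SS = -log10(P) * S with S = +1 when the
foreground median is larger.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import ORDINAL_LABELS


def intronic_change(counts: pd.DataFrame, cluster_ids: list[str],
                    sample_test: str, sample_ctrl: str,
                    min_combined: int = 10,
                    pseudocount: str = "haldane") -> pd.Series:
    """Per-isoform log2 change of RPM between two samples.

    Isoforms with fewer than ``min_combined`` PASS reads summed over the
    two samples are excluded. RPM normalizes by each sample's total PASS
    reads (over the whole matrix); the Haldane policy adds 0.5 to both
    counts when either is zero.
    """
    tot_test = counts[sample_test].sum()
    tot_ctrl = counts[sample_ctrl].sum()
    if tot_test <= 0 or tot_ctrl <= 0:
        raise ValueError("per-sample totals must be > 0")
    sub = counts.loc[[c for c in cluster_ids if c in counts.index]]
    combined = sub[sample_test] + sub[sample_ctrl]
    sub = sub[combined >= min_combined]
    ct = sub[sample_test].to_numpy(float)
    cc = sub[sample_ctrl].to_numpy(float)
    zero = (ct == 0) | (cc == 0)
    if pseudocount == "haldane":
        ct = ct + 0.5 * zero
        cc = cc + 0.5 * zero
    elif zero.any():
        raise ZeroDivisionError("zero count with pseudocount policy 'none'")
    change = np.log2((ct / tot_test) / (cc / tot_ctrl))
    return pd.Series(change, index=sub.index, name="log2_change")


def position_bias(changes: pd.Series, ordinals: pd.Series) -> pd.DataFrame:
    """Mean-centered per-ordinal-group profile of expression changes.

    Returns one row per ordinal group in canonical order (+1, +2, M, -2,
    -1) with the group mean after subtracting the across-group mean of
    the group means, the SEM and n. Empty groups are flagged with n = 0;
    at least two non-empty groups are required.
    """
    df = pd.DataFrame({"change": changes, "ordinal": ordinals}).dropna()
    groups = df.groupby("ordinal")["change"]
    means = groups.mean().reindex(ORDINAL_LABELS)
    sems = groups.sem().reindex(ORDINAL_LABELS)
    ns = groups.size().reindex(ORDINAL_LABELS, fill_value=0)
    if (ns > 0).sum() < 2:
        raise ValueError("need >= 2 non-empty ordinal groups")
    center = means[ns > 0].mean()
    return pd.DataFrame(
        {
            "ordinal": ORDINAL_LABELS,
            "mean_centered": (means - center).to_numpy(),
            "sem": sems.to_numpy(),
            "n": ns.to_numpy(),
        }
    )


def background_introns(counts: pd.DataFrame, pa_annotation: pd.DataFrame,
                       control_samples: list[str],
                       min_ra: float = 0.05, min_reads: int = 2,
                       min_samples: int = 2) -> pd.DataFrame:
    """Detected intronic pAs in control samples.

    An intronic pA qualifies when its isoform relative abundance (reads
    for the pA over all reads of the gene in that sample) is >= 5% in at
    least two control samples and its read count is >= 2 in at least two
    control samples.
    """
    if len(control_samples) < 2:
        raise ValueError("need >= 2 control samples")
    intronic = pa_annotation[pa_annotation["pa_class"] == "intron"]
    gene_of = pa_annotation.set_index("cluster_id")["gene_id"]
    gene_totals = (
        counts.join(gene_of)
        .groupby("gene_id")[control_samples]
        .sum()
    )
    keep = []
    for rec in intronic.itertuples(index=False):
        if rec.cluster_id not in counts.index:
            continue
        reads = counts.loc[rec.cluster_id, control_samples]
        totals = gene_totals.loc[rec.gene_id]
        ra = reads / totals.replace(0, np.nan)
        if ((ra >= min_ra).sum() >= min_samples
                and (reads >= min_reads).sum() >= min_samples):
            keep.append(rec.cluster_id)
    return intronic[intronic["cluster_id"].isin(keep)].reset_index(drop=True)


def feature_score(fg: np.ndarray | pd.Series, bg: np.ndarray | pd.Series
                  ) -> tuple[float, float]:
    """Signed Wilcoxon significance score comparing a foreground to a
    background feature distribution.

    Returns (SS, P). SS = -log10(P) * S with S = +1 when the foreground
    median exceeds the background median, -1 otherwise; completely tied
    data yield P = 1, SS = 0. Exact enumeration is used for small
    tie-free samples, otherwise the normal approximation with continuity
    correction.
    """
    fg = np.asarray(fg, float)
    bg = np.asarray(bg, float)
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("foreground and background must be non-empty")
    pooled = np.concatenate([fg, bg])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    small = min(len(fg), len(bg)) <= 25
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(fg, bg, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(res.pvalue)
    s = 1.0 if np.median(fg) > np.median(bg) else -1.0
    return float(-np.log10(max(p, 1e-300)) * s), p


def feature_scores_by_ordinal(fg: pd.DataFrame, bg: pd.DataFrame,
                              feature: str) -> pd.DataFrame:
    """Per-ordinal-stratum signed feature scores plus a pooled score.

    Foreground introns are compared only against background introns with
    the same ordinal (relative location in the gene); the 'pooled' row
    restricts the background to ordinals present in the foreground and
    tests all values together.
    """
    rows = []
    fg_ords = set(fg["intron_ordinal"].dropna())
    for ordinal in ORDINAL_LABELS:
        f = fg.loc[fg["intron_ordinal"] == ordinal, feature].dropna()
        b = bg.loc[bg["intron_ordinal"] == ordinal, feature].dropna()
        if len(f) == 0 or len(b) == 0:
            rows.append((ordinal, np.nan, np.nan, len(f), len(b)))
            continue
        ss, p = feature_score(f, b)
        rows.append((ordinal, ss, p, len(f), len(b)))
    b_pool = bg.loc[bg["intron_ordinal"].isin(fg_ords), feature].dropna()
    f_pool = fg[feature].dropna()
    if len(f_pool) and len(b_pool):
        ss, p = feature_score(f_pool, b_pool)
        rows.append(("pooled", ss, p, len(f_pool), len(b_pool)))
    return pd.DataFrame(rows, columns=["stratum", "ss", "p", "n_fg", "n_bg"])


def intron_feature_table(annotation, pa_annotation: pd.DataFrame,
                         ss5: pd.Series | None = None,
                         ss3: pd.Series | None = None) -> pd.DataFrame:
    """Per-intron feature rows for every intron of every gene.

    Splice-site strengths are external numeric inputs keyed by intron id
    '<gene>:intron<k>'; absent values stay NaN. ``has_pa`` marks introns
    hosting at least one classified intronic pA.
    """
    with_pa = {
        (r.gene_id, int(r.intron_index))
        for r in pa_annotation[pa_annotation["pa_class"] == "intron"]
        .dropna(subset=["intron_index"]).itertuples(index=False)
    }
    rows = []
    for gene in annotation:
        n = gene.n_introns
        for i, (s, e) in enumerate(gene.introns):
            idx = i + 1 if gene.strand == "+" else n - i
            iid = f"{gene.gene_id}:intron{idx}"
            ordinal = assign_ordinal_safe(idx, n)
            rows.append(
                (iid, gene.gene_id, idx, n, ordinal, e - s,
                 ss5.get(iid, np.nan) if ss5 is not None else np.nan,
                 ss3.get(iid, np.nan) if ss3 is not None else np.nan,
                 (gene.gene_id, idx) in with_pa)
            )
    return pd.DataFrame(
        rows, columns=["intron_id", "gene_id", "intron_index", "intron_count",
                       "intron_ordinal", "length", "ss5_strength",
                       "ss3_strength", "has_pa"],
    )


def assign_ordinal_safe(intron_index: int, intron_count: int) -> str | None:
    from .annotation import assign_intron_ordinal

    return assign_intron_ordinal(intron_index, intron_count)
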