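"""RED and the SAAP randomization test.

RED (relative expression difference) for an event with isoform sets 1
(proximal/focal) and 2 (distal/reference), counted in test sample a and
control sample b:

    RED = log2(a2/a1) - log2(b2/b1)

so positive RED means the distal/reference isoform gained in the test
sample (3'UTR lengthening for tandem-pA events). RED is antisymmetric
under swapping the samples and invariant under per-sample depth scaling.

SAAP (significance analysis of alternative polyadenylation) tests each
event against the null that both samples share the isoforms' pooled
relative abundance. For each event, m bootstrap replicates redraw
(a1*, a2*) as a binomial split of a1+a2 at the pooled proportion, and
likewise for sample b; each replicate yields an expected RED. The
observed and expected REDs are standardized with the per-event mean and
SD of the expected REDs, giving Zo and Ze. The FDR at a cutoff Zc is
(#{|Ze| >= Zc}/m) / #{|Zo| >= Zc}, counting over the whole event
collection; an event's q-value is the FDR at Zc = |Zo|, capped at 1 and
made monotone non-increasing in |Zo|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SAAPConfig:
    m: int = 20
    seed: int = 0
    pseudocount: str = "haldane"  # add 0.5 to all four counts iff any is 0
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.pseudocount not in ("haldane", "none"):
            raise ValueError("pseudocount policy must be 'haldane' or 'none'")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0,1)")


def red(a1: float, a2: float, b1: float, b2: float,
        pseudocount: str = "haldane") -> float:
    """log2(a2/a1) - log2(b2/b1) with the Haldane zero-handling policy.

    When the policy is 'haldane' and any count is zero, 0.5 is added to
    all four counts; with policy 'none' a zero raises.
    """
    if pseudocount == "haldane":
        if min(a1, a2, b1, b2) == 0:
            a1, a2, b1, b2 = a1 + 0.5, a2 + 0.5, b1 + 0.5, b2 + 0.5
    elif min(a1, a2, b1, b2) == 0:
        raise ZeroDivisionError("zero count with pseudocount policy 'none'")
    return float(np.log2(a2 / a1) - np.log2(b2 / b1))


def _red_vec(a1, a2, b1, b2, pseudocount: str):
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if pseudocount == "haldane":
        zero = (a1 == 0) | (a2 == 0) | (b1 == 0) | (b2 == 0)
        a1 = a1 + 0.5 * zero
        a2 = a2 + 0.5 * zero
        b1 = b1 + 0.5 * zero
        b2 = b2 + 0.5 * zero
    elif ((a1 == 0) | (a2 == 0) | (b1 == 0) | (b2 == 0)).any():
        raise ZeroDivisionError("zero count with pseudocount policy 'none'")
    return np.log2(a2 / a1) - np.log2(b2 / b1)


def expected_red_samples(a1: int, a2: int, b1: int, b2: int, m: int,
                         seed: int, pseudocount: str = "haldane"
                         ) -> np.ndarray:
    """The m bootstrap-null RED replicates for a single event.

    Same sampling scheme as inside :func:`saap`: both samples redrawn as
    binomial splits of their own totals at the pooled relative abundance
    of isoform set 1.
    """
    na, nb = a1 + a2, b1 + b2
    if na <= 0 or nb <= 0:
        raise ValueError("both samples need reads")
    p1 = (a1 + b1) / (na + nb)
    rng = np.random.Generator(np.random.Philox(seed))
    a1_star = rng.binomial(na, p1, size=m)
    b1_star = rng.binomial(nb, p1, size=m)
    return np.asarray(
        _red_vec(a1_star, na - a1_star, b1_star, nb - b1_star, pseudocount)
    )


def saap(events: pd.DataFrame, config: SAAPConfig | None = None
         ) -> pd.DataFrame:
    """Run SAAP on an event-count table with columns event_id,a1,a2,b1,b2.

    Returns event_id, red, zo, q, testable. Events with an empty sample
    (a1+a2 == 0 or b1+b2 == 0) or with zero bootstrap SD are untestable
    and reported with q = 1. Events are processed in a canonical order
    (sorted by event_id) so results do not depend on input row order.
    """
    if config is None:
        config = SAAPConfig()
    ev = events.sort_values("event_id", kind="stable").reset_index(drop=True)
    n = len(ev)
    if n == 0:
        return pd.DataFrame(columns=["event_id", "red", "zo", "q", "testable"])
    a1 = ev["a1"].to_numpy(float)
    a2 = ev["a2"].to_numpy(float)
    b1 = ev["b1"].to_numpy(float)
    b2 = ev["b2"].to_numpy(float)
    na = a1 + a2
    nb = b1 + b2
    total = na + nb
    ok = (na > 0) & (nb > 0)

    red_obs = np.full(n, np.nan)
    red_obs[ok] = _red_vec(a1[ok], a2[ok], b1[ok], b2[ok], config.pseudocount)

    # pooled relative abundance of isoform set 1
    p1 = np.full(n, np.nan)
    p1[ok] = (a1[ok] + b1[ok]) / total[ok]

    m = config.m
    rng = np.random.Generator(np.random.Philox(config.seed))
    a1_star = rng.binomial(na[ok].astype(np.int64), p1[ok], size=(m, ok.sum()))
    b1_star = rng.binomial(nb[ok].astype(np.int64), p1[ok], size=(m, ok.sum()))
    red_exp = _red_vec(a1_star, na[ok] - a1_star, b1_star, nb[ok] - b1_star,
                       config.pseudocount)

    mean = red_exp.mean(axis=0)
    sd = red_exp.std(axis=0, ddof=1)
    testable = np.zeros(n, dtype=bool)
    testable[np.flatnonzero(ok)] = sd > 0

    zo = np.full(n, np.nan)
    ze_all: list[np.ndarray] = []
    ok_idx = np.flatnonzero(ok)
    good = sd > 0
    zo[ok_idx[good]] = (red_obs[ok_idx[good]] - mean[good]) / sd[good]
    ze = (red_exp[:, good] - mean[good]) / sd[good]

    q = _q_values(np.abs(zo), np.abs(ze), m)
    return pd.DataFrame(
        {"event_id": ev["event_id"], "red": red_obs, "zo": zo, "q": q,
         "testable": testable}
    )


def _q_values(abs_zo: np.ndarray, abs_ze: np.ndarray, m: int) -> np.ndarray:
    """Randomization FDR over the event collection, monotone in |Zo|.

    FDR(Zc) = (#{|Ze| >= Zc}/m) / #{|Zo| >= Zc}; an event's q uses its
    own |Zo| as the cutoff. Untestable events (NaN Zo) get q = 1.
    """
    n = len(abs_zo)
    q = np.ones(n)
    test_idx = np.flatnonzero(~np.isnan(abs_zo))
    if len(test_idx) == 0:
        return q
    zo_t = abs_zo[test_idx]
    ze_sorted = np.sort(abs_ze.ravel())
    zo_sorted = np.sort(zo_t)
    # counts with >= via searchsorted on the left edge
    n_ze = len(ze_sorted) - np.searchsorted(ze_sorted, zo_t, side="left")
    n_zo = len(zo_sorted) - np.searchsorted(zo_sorted, zo_t, side="left")
    fdr = (n_ze / m) / np.maximum(n_zo, 1)
    fdr = np.minimum(fdr, 1.0)
    # enforce q non-increasing in |Zo|: an event's q is the smallest FDR
    # attained at any cutoff at or below its own |Zo|
    order = np.argsort(zo_t)
    fdr_sorted = fdr[order]
    fdr_mono = np.minimum.accumulate(fdr_sorted)
    fdr[order] = fdr_mono
    q[test_idx] = fdr
    return q


def call_direction(results: pd.DataFrame, event_type: str = "utr3_pair",
                   q_threshold: float = 0.05) -> pd.Series:
    """Direction label per event: Le/Sh for 3'UTR events (positive RED =
    distal isoform up = lengthened), UP/DN for focal-class events; 'ns'
    when q >= threshold."""
    pos, neg = (("Le", "Sh") if event_type in ("utr3_pair",)
                else ("DN", "UP"))
    # for cds/uaRNA/spRNA, set1 is the focal class, so focal up = RED < 0
    sig = results["q"] < q_threshold
    lab = np.where(results["red"] > 0, pos, neg)
    return pd.Series(np.where(sig, lab, "ns"), index=results.index,
                     name="direction")


def top2_regulated(one_vs_rest: pd.DataFrame, pa_annotation: pd.DataFrame,
                   clusters: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the two most significantly regulated 3'UTR pAs.

    ``one_vs_rest`` is a SAAP result table whose event ids follow the
    '<gene>:ovr:<cluster_id>' convention. Ranking: smallest q, then
    largest |Zo|, then 3'-most position. Genes with fewer than two tested
    pAs are skipped.
    """
    res = one_vs_rest.copy()
    res["gene_id"] = res["event_id"].str.split(":ovr:").str[0]
    res["cluster_id"] = res["event_id"].str.split(":ovr:").str[1]
    pos = clusters.set_index("cluster_id")[["position", "strand"]]
    res = res.join(pos, on="cluster_id")
    res["threeward"] = res["position"] * np.where(res["strand"] == "+", 1, -1)
    res["abs_zo"] = res["zo"].abs().fillna(0.0)
    out = []
    for gene_id, grp in res.groupby("gene_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values(["q", "abs_zo", "threeward"],
                              ascending=[True, False, False])
        out.append(grp.head(2))
    if not out:
        return res.iloc[0:0]
    return pd.concat(out, ignore_index=True).drop(
        columns=["threeward", "abs_zo"])
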