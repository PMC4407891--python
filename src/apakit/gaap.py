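"""GAAP: global analysis of alternative polyadenylation.

Two read sets A and B (per-cluster PASS count vectors) are compared in n
rounds. Each round bootstraps p reads from each set (depth matching),
runs SAAP on the pair, and counts significantly regulated events per
direction — the observed counts. A label permutation of the pooled reads
(respecting |A| and |B|) followed by the same bootstrap and SAAP gives
the expected counts; one fresh permutation is drawn per round and paired
with that round's observed draw. The normalized count per direction is
mean(observed - expected) over rounds, floored at zero, with the SD over
rounds as the error estimate, and log2(Le/Sh) (or log2(UP/DN))
summarizing the global direction, with +/-inf sentinels when one
direction's floored mean is zero.

Read sets are represented as per-cluster count vectors; permutation is a
multivariate hypergeometric split of the pooled counts and bootstrap a
multinomial draw — exactly equivalent in distribution to shuffling and
resampling individual reads that carry cluster identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import min_read_filter
from .stats import SAAPConfig, call_direction, saap


@dataclass
class GAAPConfig:
    n: int = 20                 # bootstrap rounds (= permutations)
    p: int = 50_000             # PASS reads per bootstrap draw
    seed: int = 0
    q_threshold: float = 0.05
    min_read_rule: str = "utr3_20_combined"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.p <= 0:
            raise ValueError("p must be > 0")


@dataclass
class GAAPResult:
    contrast_id: str
    directions: tuple[str, str]          # (positive-RED label, negative)
    mean_normalized: dict[str, float]    # floored at 0
    sd_normalized: dict[str, float]
    log2_ratio: float                    # log2(first/second), +/-inf sentinel
    rounds: pd.DataFrame = field(repr=False)  # per-round obs/exp counts


def permute_readsets(A: pd.Series, B: pd.Series,
                     rng: np.random.Generator) -> tuple[pd.Series, pd.Series]:
    """Randomize sample labels: split the pooled per-cluster counts into
    sets of the original sizes, without replacement. The pooled count
    vector is preserved exactly."""
    A, B = A.align(B, fill_value=0)
    A, B = A.sort_index(), B.sort_index()
    pooled = (A + B).astype(np.int64)
    n_a = int(A.sum())
    if pooled.sum() == 0:
        return A.copy(), B.copy()
    a_new = rng.multivariate_hypergeometric(pooled.to_numpy(), n_a,
                                            method="marginals")
    a_ser = pd.Series(a_new, index=pooled.index)
    return a_ser, pooled - a_ser


def bootstrap_readset(X: pd.Series, p: int,
                      rng: np.random.Generator) -> pd.Series:
    """Draw exactly p reads with replacement from the set's count vector."""
    if p <= 0:
        raise ValueError("p must be > 0")
    total = X.sum()
    if total <= 0:
        raise ValueError("cannot bootstrap from an empty read set")
    probs = X.to_numpy(float) / total
    return pd.Series(rng.multinomial(p, probs), index=X.index)


def _event_index(events: pd.DataFrame, cluster_index: pd.Index
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat (event_row, cluster_row) index pairs for set1 and set2 sums."""
    lookup = {cid: i for i, cid in enumerate(cluster_index)}
    e1, c1, e2, c2 = [], [], [], []
    for row, ev in enumerate(events.itertuples(index=False)):
        for cid in ev.set1:
            if cid in lookup:
                e1.append(row)
                c1.append(lookup[cid])
        for cid in ev.set2:
            if cid in lookup:
                e2.append(row)
                c2.append(lookup[cid])
    return (np.asarray(e1, int), np.asarray(c1, int),
            np.asarray(e2, int), np.asarray(c2, int))


def _sum_counts(vec: np.ndarray, e_idx: np.ndarray, c_idx: np.ndarray,
                n_events: int) -> np.ndarray:
    return np.bincount(e_idx, weights=vec[c_idx], minlength=n_events)


def gaap_run(A: pd.Series, B: pd.Series, events: pd.DataFrame,
             saap_config: SAAPConfig | None = None,
             gaap_config: GAAPConfig | None = None,
             contrast_id: str = "utr3",
             event_type: str = "utr3_pair") -> GAAPResult:
    """Full GAAP for one contrast.

    A is the test read set, B the control (per-cluster counts on a shared
    or alignable index). ``events`` defines set1/set2 per event on the
    cluster universe.
    """
    if saap_config is None:
        saap_config = SAAPConfig()
    if gaap_config is None:
        gaap_config = GAAPConfig()
    # canonical cluster order so results are index-order invariant
    A, B = A.align(B, fill_value=0)
    A, B = A.sort_index(), B.sort_index()
    rng = np.random.default_rng(gaap_config.seed)
    n_events = len(events)
    e1, c1, e2, c2 = _event_index(events, A.index)
    event_ids = events["event_id"].to_numpy()
    pos_label, neg_label = (("Le", "Sh") if event_type == "utr3_pair"
                            else ("DN", "UP"))

    round_rows = []
    for i in range(gaap_config.n):
        a = bootstrap_readset(A, gaap_config.p, rng)
        b = bootstrap_readset(B, gaap_config.p, rng)
        A_perm, B_perm = permute_readsets(A, B, rng)
        a_exp = bootstrap_readset(A_perm, gaap_config.p, rng)
        b_exp = bootstrap_readset(B_perm, gaap_config.p, rng)

        counts = {}
        n_tested = {}
        for tag, (xa, xb) in {"obs": (a, b), "exp": (a_exp, b_exp)}.items():
            va, vb = xa.to_numpy(float), xb.to_numpy(float)
            ev = pd.DataFrame(
                {
                    "event_id": event_ids,
                    "a1": _sum_counts(va, e1, c1, n_events),
                    "a2": _sum_counts(va, e2, c2, n_events),
                    "b1": _sum_counts(vb, e1, c1, n_events),
                    "b2": _sum_counts(vb, e2, c2, n_events),
                }
            )
            rule = gaap_config.min_read_rule
            if rule == "utr3_20_combined":
                keep = ev[["a1", "a2", "b1", "b2"]].sum(axis=1) >= 20
            elif rule == "intronic_10_combined":
                keep = ev["a1"] + ev["b1"] >= 10
            else:
                keep = ev.apply(lambda r: min_read_filter(r, rule), axis=1)
            ev = ev[keep]
            sub_cfg = SAAPConfig(
                m=saap_config.m,
                seed=int(rng.integers(2**31)),
                pseudocount=saap_config.pseudocount,
                q_threshold=saap_config.q_threshold,
            )
            res = saap(ev, sub_cfg)
            direction = call_direction(res, event_type,
                                       gaap_config.q_threshold)
            counts[tag] = direction.value_counts()
            n_tested[tag] = len(res)
        round_rows.append(
            {
                "round": i,
                "obs_pos": int(counts["obs"].get(pos_label, 0)),
                "obs_neg": int(counts["obs"].get(neg_label, 0)),
                "exp_pos": int(counts["exp"].get(pos_label, 0)),
                "exp_neg": int(counts["exp"].get(neg_label, 0)),
                "n_tested_obs": n_tested["obs"],
                "n_tested_exp": n_tested["exp"],
            }
        )

    rounds = pd.DataFrame(round_rows)
    rounds["norm_pos"] = rounds["obs_pos"] - rounds["exp_pos"]
    rounds["norm_neg"] = rounds["obs_neg"] - rounds["exp_neg"]

    mean_pos = max(float(rounds["norm_pos"].mean()), 0.0)
    mean_neg = max(float(rounds["norm_neg"].mean()), 0.0)
    if mean_pos > 0 and mean_neg > 0:
        ratio = float(np.log2(mean_pos / mean_neg))
    elif mean_pos > 0:
        ratio = float("inf")
    elif mean_neg > 0:
        ratio = float("-inf")
    else:
        ratio = float("nan")
    return GAAPResult(
        contrast_id=contrast_id,
        directions=(pos_label, neg_label),
        mean_normalized={pos_label: mean_pos, neg_label: mean_neg},
        sd_normalized={
            pos_label: float(rounds["norm_pos"].std(ddof=1)),
            neg_label: float(rounds["norm_neg"].std(ddof=1)),
        },
        log2_ratio=ratio,
        rounds=rounds,
    )
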