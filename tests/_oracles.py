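"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: the enrichment-score
oracle walks the running sum position by position exactly as the statistic
is defined, and the BH oracle applies the step-up rule by hand.
"""

from __future__ import annotations

import numpy as np


def es_reference(rank_scores, membership, alpha) -> float:
    """Direct enumeration of ES = sum_i [P_in(i) - P_out(i)].

    Genes are walked in descending rank-score order; P_in accumulates
    weighted in-set mass, P_out the out-of-set count fraction.
    """
    r = np.asarray(rank_scores, dtype=float)
    member = np.asarray(membership, dtype=bool)
    n = r.size
    m = int(member.sum())
    order = np.argsort(-r, kind="stable")
    w_total = sum(r[j] ** alpha for j in order if member[j])
    es = 0.0
    in_mass = 0.0
    out_count = 0
    for j in order:
        if member[j]:
            in_mass += r[j] ** alpha
        else:
            out_count += 1
        es += in_mass / w_total - out_count / (n - m)
    return es


def bh_reference(pvalues) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up: p(i)*m/i with a cumulative
    minimum from the largest p downward, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
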