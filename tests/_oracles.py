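"""Independent reference implementations used as oracles by the tests.

Everything here is written from the method definitions directly — explicit
loops, per-quadrant marginals spelled out — and shares no code with the
package, so agreement is meaningful.
"""

import numpy as np
import pandas as pd

from boolimpl import HIGH, LOW, Relation
from boolimpl.stepminer import TritMatrix


def brute_force_step_fit(values):
    """Try every step position on the sorted values, recompute from scratch."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size
    best = None
    for k in range(1, n):
        lo, hi = xs[:k].mean(), xs[k:].mean()
        fitted = np.concatenate([np.full(k, lo), np.full(n - k, hi)])
        sse = float(np.sum((xs - fitted) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, lo, hi)
    sse, k, lo, hi = best
    return k, lo, hi, (lo + hi) / 2.0, sse


def oracle_relation(a00, a01, a10, a11, sthr=3.0, pthr=0.1):
    """Direct transcription of the six implication definitions."""
    total = a00 + a01 + a10 + a11
    n_a_low, n_a_high = a00 + a01, a10 + a11
    n_b_low, n_b_high = a00 + a10, a01 + a11

    def sparse(a, row, col):
        if total == 0 or row == 0 or col == 0:
            return False
        e = (row / total) * (col / total) * total
        s = (e - a) / np.sqrt(e)
        p = 0.5 * (a / row + a / col)
        return s > sthr and p < pthr

    s00 = sparse(a00, n_a_low, n_b_low)
    s01 = sparse(a01, n_a_low, n_b_high)
    s10 = sparse(a10, n_a_high, n_b_low)
    s11 = sparse(a11, n_a_high, n_b_high)
    flags = [s00, s01, s10, s11]
    if sum(flags) == 2 and s01 and s10:
        return Relation.EQUIVALENT
    if sum(flags) == 2 and s00 and s11:
        return Relation.OPPOSITE
    if sum(flags) == 1:
        return {0: Relation.LOHI, 1: Relation.LOLO,
                2: Relation.HIHI, 3: Relation.HILO}[flags.index(True)]
    return Relation.NONE


def pair_counting_auc(scores, labels):
    """ROC-AUC as explicit concordant-pair counting with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = scores[labels == 1]
    control = scores[labels == 0]
    wins = 0.0
    for c in case:
        for k in control:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case) * len(control))


def trits_from_binary(states):
    """Binary states mapped straight to LOW/HIGH trit codes."""
    return np.where(np.asarray(states) == 1, HIGH, LOW).astype(np.int8)


def make_trit_matrix(rows, genes=None):
    """Wrap raw trit rows in a TritMatrix with placeholder fit metadata."""
    rows = np.asarray(rows, dtype=np.int8)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    n = rows.shape[1]
    return TritMatrix(
        gene_ids=list(genes),
        sample_ids=[f"s{j}" for j in range(n)],
        trits=rows,
        thresholds=pd.Series(2.0, index=genes),
        stddevs=pd.Series(1.0, index=genes),
        fstats=pd.Series(10.0, index=genes),
    )
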