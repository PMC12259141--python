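"""StepMiner: single rising-step fits and three-level discretization.

Each gene's expression values are sorted ascending and a one-step function
(low plateau, then high plateau) is fitted by exhaustive search over the
step position, minimizing the residual sum of squares.  The midpoint of the
two plateau means is the StepMiner threshold separating "low" from "high"
expression.  A noise margin of +/-0.5 (a 2-fold band on the log2 scale)
around the threshold marks values as intermediate; those are excluded from
downstream Boolean pair analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

__all__ = [
    "LOW",
    "INTERMEDIATE",
    "HIGH",
    "StepFit",
    "TritMatrix",
    "fit_step",
    "discretize",
    "discretize_matrix",
]

# trit codes (also the on-disk TSV encoding)
LOW = 0
INTERMEDIATE = 1
HIGH = 2

# model degrees of freedom for the F statistic: two segment means plus the
# breakpoint position
DEFAULT_DF_MODEL = 3


@dataclass(frozen=True)
class StepFit:
    """Best single rising step fitted to one gene's sorted values.

    ``step_index`` k means the first k sorted values form the low segment.
    ``threshold`` is the midpoint of the two segment means.  ``fstat`` is
    the regression statistic
    ``(sum(fitted - mean)^2 / (m-1)) / (sse / (n-m))``; it is +inf when the
    fit is exact (sse == 0).  ``stddev`` is the sample (n-1) standard
    deviation of all values, reused by the composite-score normalization.
    """

    step_index: int
    mean_low: float
    mean_high: float
    threshold: float
    fstat: float
    sse: float
    stddev: float
    n: int
    m: int = DEFAULT_DF_MODEL


@dataclass
class TritMatrix:
    """Per-gene three-level discretization of an expression matrix."""

    gene_ids: list
    sample_ids: list
    trits: np.ndarray  # int8, genes x samples, values in {LOW, INTERMEDIATE, HIGH}
    thresholds: pd.Series  # gene -> StepMiner threshold
    stddevs: pd.Series  # gene -> sample standard deviation
    fstats: pd.Series  # gene -> step-fit F statistic
    margin: float = 0.5
    skipped_genes: list = field(default_factory=list)

    def subset_genes(self, genes) -> "TritMatrix":
        genes = list(genes)
        pos = pd.Index(self.gene_ids).get_indexer(genes)
        if (pos < 0).any():
            missing = genes[int(np.argmax(pos < 0))]
            raise KeyError(f"gene {missing!r} not in trit matrix")
        return TritMatrix(
            gene_ids=genes,
            sample_ids=list(self.sample_ids),
            trits=self.trits[pos],
            thresholds=self.thresholds.loc[genes],
            stddevs=self.stddevs.loc[genes],
            fstats=self.fstats.loc[genes],
            margin=self.margin,
            skipped_genes=list(self.skipped_genes),
        )


def _step_sse_profile(sorted_vals: np.ndarray) -> np.ndarray:
    """SSE of the two-plateau fit for every step position k = 1..n-1.

    For sorted x with prefix sums S_k, the SSE at step k is
    sum(x^2) - S_k^2/k - (S_n - S_k)^2/(n-k).
    """
    n = sorted_vals.size
    csum = np.cumsum(sorted_vals)
    k = np.arange(1, n)
    total = csum[-1]
    sq = float(np.sum(sorted_vals**2))
    sse = sq - csum[:-1] ** 2 / k - (total - csum[:-1]) ** 2 / (n - k)
    return np.maximum(sse, 0.0)  # guard tiny negative round-off


def fit_step(values, m: int = DEFAULT_DF_MODEL) -> StepFit:
    """Fit the best single rising step to a vector of expression values.

    Values are sorted ascending internally, so the threshold is invariant
    to the input order; only rising steps need to be considered.  SSE ties
    across step positions break toward the smallest step index.

    Raises ``ValueError`` for constant input or fewer than 3 values
    ("undefined threshold"): such a gene must be excluded upstream.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("fit_step expects a 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression value")
    n = x.size
    if n < 3:
        raise ValueError(f"undefined threshold: need >= 3 values, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("undefined threshold: constant expression vector")

    xs = np.sort(x, kind="stable")
    sse = _step_sse_profile(xs)
    k = int(np.argmin(sse)) + 1  # argmin takes the first (smallest k) on ties
    mean_low = float(xs[:k].mean())
    mean_high = float(xs[k:].mean())
    best_sse = float(sse[k - 1])

    xbar = float(xs.mean())
    fitted = np.concatenate([np.full(k, mean_low), np.full(n - k, mean_high)])
    ess = float(np.sum((fitted - xbar) ** 2))
    if best_sse <= 0.0 or n == m:
        fstat = float("inf")
    else:
        fstat = (ess / (m - 1)) / (best_sse / (n - m))

    return StepFit(
        step_index=k,
        mean_low=mean_low,
        mean_high=mean_high,
        threshold=(mean_low + mean_high) / 2.0,
        fstat=fstat,
        sse=best_sse,
        stddev=float(np.std(x, ddof=1)),
        n=n,
        m=m,
    )


def discretize(value: float, threshold: float, margin: float = 0.5) -> int:
    """Map one expression value to LOW / INTERMEDIATE / HIGH.

    LOW iff value < threshold - margin, HIGH iff value > threshold + margin;
    anything inside the closed noise band (boundaries included) is
    INTERMEDIATE.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not (np.isfinite(value) and np.isfinite(threshold)):
        raise ValueError("non-finite input")
    if value < threshold - margin:
        return LOW
    if value > threshold + margin:
        return HIGH
    return INTERMEDIATE


def discretize_matrix(matrix: ExpressionMatrix, margin: float = 0.5) -> TritMatrix:
    """Discretize every gene of a matrix with its own StepMiner threshold.

    Genes for which the step fit is undefined (constant vectors) are listed
    in ``skipped_genes`` rather than silently dropped.
    """
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("empty expression matrix")
    genes, thresholds, stddevs, fstats, rows, skipped = [], [], [], [], [], []
    vals = matrix.values
    for i, gene in enumerate(matrix.gene_ids):
        try:
            fit = fit_step(vals[i])
        except ValueError:
            skipped.append(gene)
            continue
        genes.append(gene)
        thresholds.append(fit.threshold)
        stddevs.append(fit.stddev)
        fstats.append(fit.fstat)
        row = np.full(vals.shape[1], INTERMEDIATE, dtype=np.int8)
        row[vals[i] < fit.threshold - margin] = LOW
        row[vals[i] > fit.threshold + margin] = HIGH
        rows.append(row)
    trits = np.vstack(rows) if rows else np.empty((0, matrix.n_samples), dtype=np.int8)
    return TritMatrix(
        gene_ids=genes,
        sample_ids=matrix.sample_ids,
        trits=trits,
        thresholds=pd.Series(thresholds, index=genes, name="threshold", dtype=float),
        stddevs=pd.Series(stddevs, index=genes, name="stddev", dtype=float),
        fstats=pd.Series(fstats, index=genes, name="fstat", dtype=float),
        margin=margin,
        skipped_genes=skipped,
    )
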