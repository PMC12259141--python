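"""BooleanNet implication statistics and network construction.

For a pair of discretized genes A and B, samples that are low or high in
both genes fall into four quadrants (a00 = A-low & B-low, a01 = A-low &
B-high, a10 = A-high & B-low, a11 = A-high & B-high); intermediates are
excluded.  A Boolean implication holds when a quadrant is sparsely
populated relative to independence.  Sparsity of quadrant ij is judged by

    S_ij = (n_hat - a_ij) / sqrt(n_hat),   n_hat = rowsum * colsum / total
    p_ij = (a_ij / rowsum + a_ij / colsum) / 2

where rowsum and colsum are the quadrant's two adjacent marginals (e.g.
for a00: nAlow = a00 + a01 and nBlow = a00 + a10).  A quadrant is sparse
when S_ij > sThr and p_ij < pThr (defaults 3 and 0.1).  One sparse
quadrant gives an asymmetric implication, the two diagonal pairs give the
symmetric equivalent / opposite relations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix
from .stepminer import HIGH, LOW, TritMatrix, discretize_matrix

__all__ = [
    "Relation",
    "QuadrantCounts",
    "BooleanRelation",
    "ImplicationNetwork",
    "quadrant_counts",
    "sparsity_stat",
    "classify_relation",
    "classify_tables",
    "RELATION_CODES",
    "swap_relation",
    "build_bin",
    "permutation_fdr",
]

DEFAULT_STHR = 3.0
DEFAULT_PTHR = 0.1

QUADRANTS = ("00", "01", "10", "11")


class Relation(str, enum.Enum):
    """The six Boolean implication relationship types, plus NONE."""

    NONE = "none"
    EQUIVALENT = "equivalent"  # 01 and 10 sparse: A high <=> B high
    OPPOSITE = "opposite"  # 00 and 11 sparse: A high <=> B low
    LOLO = "lolo"  # 01 sparse: A low  => B low
    LOHI = "lohi"  # 00 sparse: A low  => B high
    HIHI = "hihi"  # 10 sparse: A high => B high
    HILO = "hilo"  # 11 sparse: A high => B low

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# relation seen from B's side when the stored one is seen from A's side
_SWAP = {
    Relation.NONE: Relation.NONE,
    Relation.EQUIVALENT: Relation.EQUIVALENT,
    Relation.OPPOSITE: Relation.OPPOSITE,
    Relation.LOHI: Relation.LOHI,
    Relation.HILO: Relation.HILO,
    Relation.LOLO: Relation.HIHI,
    Relation.HIHI: Relation.LOLO,
}


def swap_relation(relation: Relation) -> Relation:
    """Relation from B to A given the relation from A to B."""
    return _SWAP[relation]


@dataclass(frozen=True)
class QuadrantCounts:
    """Sample counts in the four low/high quadrants of a gene pair."""

    a00: int
    a01: int
    a10: int
    a11: int

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    def quadrant(self, ij: str) -> int:
        return getattr(self, f"a{ij}")

    def marginals(self, ij: str) -> tuple[int, int]:
        """(rowsum, colsum) adjacent to quadrant ij: A in state i, B in state j."""
        i, j = ij
        rowsum = (self.a00 + self.a01) if i == "0" else (self.a10 + self.a11)
        colsum = (self.a00 + self.a10) if j == "0" else (self.a01 + self.a11)
        return rowsum, colsum

    def swapped(self) -> "QuadrantCounts":
        """Counts with the two genes' roles exchanged."""
        return QuadrantCounts(self.a00, self.a10, self.a01, self.a11)


@dataclass(frozen=True)
class BooleanRelation:
    """Classified Boolean implication between an ordered gene pair."""

    gene_a: object
    gene_b: object
    counts: QuadrantCounts
    stats: dict  # quadrant -> (S, p)
    relation: Relation


@dataclass
class ImplicationNetwork:
    """Genes as nodes, Boolean implication relationships as typed edges."""

    nodes: list
    edges: list  # of BooleanRelation, one per unordered pair, gene_a < gene_b order
    sthr: float = DEFAULT_STHR
    pthr: float = DEFAULT_PTHR
    margin: float = 0.5
    n_pairs_tested: int = 0
    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {(e.gene_a, e.gene_b): e.relation for e in self.edges}

    def relation(self, gene_a, gene_b) -> Relation:
        """Directed relation from gene_a to gene_b (NONE if no edge)."""
        rel = self._lookup.get((gene_a, gene_b))
        if rel is not None:
            return rel
        rel = self._lookup.get((gene_b, gene_a))
        if rel is not None:
            return swap_relation(rel)
        return Relation.NONE

    def equivalence_pairs(self) -> list:
        return [
            (e.gene_a, e.gene_b)
            for e in self.edges
            if e.relation is Relation.EQUIVALENT
        ]


def quadrant_counts(trits_a, trits_b) -> QuadrantCounts:
    """Count samples per quadrant, ignoring intermediates in either gene."""
    a = np.asarray(trits_a)
    b = np.asarray(trits_b)
    if a.shape != b.shape:
        raise ValueError(f"trit vector lengths differ: {a.shape} vs {b.shape}")
    use = (a != 1) & (b != 1)
    a_high = a[use] == HIGH
    b_high = b[use] == HIGH
    return QuadrantCounts(
        a00=int(np.sum(~a_high & ~b_high)),
        a01=int(np.sum(~a_high & b_high)),
        a10=int(np.sum(a_high & ~b_high)),
        a11=int(np.sum(a_high & b_high)),
    )


def sparsity_stat(counts: QuadrantCounts, quadrant: str) -> tuple[float, float]:
    """Sparsity statistic S and error rate p for one quadrant.

    A zero adjacent marginal makes the statistic undefined (the expected
    count is 0); such quadrants are reported as not-sparse with the
    sentinel (nan, 1.0) instead of raising.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    total = counts.total
    if total <= 0:
        raise ValueError("no usable samples: total quadrant count is 0")
    rowsum, colsum = counts.marginals(quadrant)
    if rowsum == 0 or colsum == 0:
        return float("nan"), 1.0
    n_obs = counts.quadrant(quadrant)
    n_hat = rowsum * colsum / total
    s = (n_hat - n_obs) / np.sqrt(n_hat)
    p = 0.5 * (n_obs / rowsum + n_obs / colsum)
    return float(s), float(p)


def _sparse_pattern(
    counts: QuadrantCounts, sthr: float, pthr: float
) -> tuple[dict, dict]:
    stats = {q: sparsity_stat(counts, q) for q in QUADRANTS}
    sparse = {
        q: (not np.isnan(s)) and s > sthr and p < pthr for q, (s, p) in stats.items()
    }
    return stats, sparse


def _pattern_to_relation(sparse: dict) -> Relation:
    n_sparse = sum(sparse.values())
    if n_sparse == 1:
        for q, rel in (
            ("00", Relation.LOHI),
            ("01", Relation.LOLO),
            ("10", Relation.HIHI),
            ("11", Relation.HILO),
        ):
            if sparse[q]:
                return rel
    if n_sparse == 2:
        if sparse["01"] and sparse["10"]:
            return Relation.EQUIVALENT
        if sparse["00"] and sparse["11"]:
            return Relation.OPPOSITE
    # zero sparse, an adjacent sparse pair, or >= 3 sparse quadrants:
    # no interpretable implication (degenerate marginals)
    return Relation.NONE


def classify_relation(
    counts: QuadrantCounts,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
    gene_a=None,
    gene_b=None,
) -> BooleanRelation:
    """Classify a gene pair into one of the six implication types or NONE."""
    stats, sparse = _sparse_pattern(counts, sthr, pthr)
    return BooleanRelation(
        gene_a=gene_a,
        gene_b=gene_b,
        counts=counts,
        stats=stats,
        relation=_pattern_to_relation(sparse),
    )


# ---------------------------------------------------------------------------
# vectorized pairwise engine
# ---------------------------------------------------------------------------

# integer codes used by the vectorized classifier
RELATION_CODES = {
    0: Relation.NONE,
    1: Relation.EQUIVALENT,
    2: Relation.OPPOSITE,
    3: Relation.LOLO,
    4: Relation.LOHI,
    5: Relation.HIHI,
    6: Relation.HILO,
}
_CODE_TO_RELATION = RELATION_CODES


def classify_tables(
    a00, a01, a10, a11, sthr: float = DEFAULT_STHR, pthr: float = DEFAULT_PTHR
) -> np.ndarray:
    """Vectorized relation classification of arrays of quadrant tables.

    Applies exactly the rules of ``classify_relation`` elementwise and
    returns int8 codes per ``RELATION_CODES``; empty tables (total 0)
    classify as NONE instead of raising.
    """
    a00 = np.asarray(a00, dtype=np.float64)
    a01 = np.asarray(a01, dtype=np.float64)
    a10 = np.asarray(a10, dtype=np.float64)
    a11 = np.asarray(a11, dtype=np.float64)

    a_low = a00 + a01
    a_high = a10 + a11
    b_low = a00 + a10
    b_high = a01 + a11
    total = a_low + a_high

    def sparse(a, rowm, colm):
        valid = (rowm > 0) & (colm > 0) & (total > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            n_hat = rowm * colm / total
            s = (n_hat - a) / np.sqrt(n_hat)
            p = 0.5 * (a / rowm + a / colm)
        return valid & (s > sthr) & (p < pthr)

    s00 = sparse(a00, a_low, b_low)
    s01 = sparse(a01, a_low, b_high)
    s10 = sparse(a10, a_high, b_low)
    s11 = sparse(a11, a_high, b_high)
    n_sparse = (
        s00.astype(np.int8) + s01.astype(np.int8) + s10.astype(np.int8) + s11
    )

    codes = np.zeros(a00.shape, dtype=np.int8)
    one = n_sparse == 1
    codes[one & s00] = 4  # LOHI
    codes[one & s01] = 3  # LOLO
    codes[one & s10] = 5  # HIHI
    codes[one & s11] = 6  # HILO
    two = n_sparse == 2
    codes[two & s01 & s10] = 1  # EQUIVALENT
    codes[two & s00 & s11] = 2  # OPPOSITE
    return codes


def _pairwise_relation_codes(
    trits: np.ndarray, sthr: float, pthr: float
) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Relation code for every ordered gene pair, computed with matmuls.

    Returns (codes, (a00, a01, a10, a11)); codes[i, j] encodes the relation
    from gene i to gene j per RELATION_CODES.  The diagonal is 0.
    """
    low = (trits == LOW).astype(np.float64)
    high = (trits == HIGH).astype(np.float64)
    # counts are exact: 0/1 matmuls of <= 2**53 samples
    a00 = low @ low.T
    a01 = low @ high.T
    a10 = high @ low.T
    a11 = high @ high.T
    codes = classify_tables(a00, a01, a10, a11, sthr, pthr)
    np.fill_diagonal(codes, 0)
    return codes, (a00, a01, a10, a11)


def build_bin(
    trits: TritMatrix,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
) -> ImplicationNetwork:
    """Evaluate every unordered gene pair and keep the non-NONE relations.

    The pairwise counting is done with matrix products over the low/high
    indicator matrices, so runtime is dominated by two dense matmuls even
    for thousands of genes; results are identical to pair-at-a-time
    classification and independent of gene order.
    """
    n = len(trits.gene_ids)
    if n < 2:
        raise ValueError("need at least 2 genes to build an implication network")
    codes, quads = _pairwise_relation_codes(trits.trits, sthr, pthr)
    genes = trits.gene_ids
    edges = []
    ii, jj = np.nonzero(np.triu(codes, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        counts = QuadrantCounts(
            a00=int(quads[0][i, j]),
            a01=int(quads[1][i, j]),
            a10=int(quads[2][i, j]),
            a11=int(quads[3][i, j]),
        )
        stats = {q: sparsity_stat(counts, q) for q in QUADRANTS}
        edges.append(
            BooleanRelation(
                gene_a=genes[i],
                gene_b=genes[j],
                counts=counts,
                stats=stats,
                relation=_CODE_TO_RELATION[int(codes[i, j])],
            )
        )
    return ImplicationNetwork(
        nodes=list(genes),
        edges=edges,
        sthr=sthr,
        pthr=pthr,
        margin=trits.margin,
        n_pairs_tested=n * (n - 1) // 2,
    )


def permutation_fdr(
    matrix: ExpressionMatrix,
    sthr: float = DEFAULT_STHR,
    pthr: float = DEFAULT_PTHR,
    seed: int = 0,
    margin: float = 0.5,
    trits: TritMatrix | None = None,
) -> float:
    """False discovery rate of implication calls under a permutation null.

    Each gene's values are independently permuted across samples, which
    preserves every per-gene threshold and marginal distribution while
    destroying all between-gene structure; the FDR is the fraction of gene
    pairs that still receive a non-NONE relation.  Deterministic for a
    fixed seed.
    """
    if trits is None:
        trits = discretize_matrix(matrix, margin=margin)
    n = len(trits.gene_ids)
    if n < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    permuted = trits.trits.copy()
    for row in permuted:
        rng.shuffle(row)
    codes, _ = _pairwise_relation_codes(permuted, sthr, pthr)
    n_hits = int(np.count_nonzero(np.triu(codes, k=1)))
    n_pairs = n * (n - 1) // 2
    return n_hits / n_pairs
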