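"""Composite scores and disease-signature training/evaluation.

A sample's composite score is a weighted sum, over gene sets, of the
per-set average of modified Z-normalized expression
``(x - t - 0.5) / (3 * sigma)``, where t is the gene's StepMiner threshold
and sigma its sample standard deviation in the evaluated dataset.  The
trained disease signature consists of an up-regulated and a down-regulated
gene list weighted +1 and -1; genes are selected by per-dataset ROC-AUC
filters and ranked by the Welch t statistic in a designated training
dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .bone_network import ClusteredNetwork
from .expression_io import ExpressionMatrix
from .stepminer import TritMatrix, discretize_matrix

__all__ = [
    "GeneSignature",
    "EvaluationResult",
    "normalize_expr",
    "composite_score",
    "roc_auc",
    "welch_ttest",
    "bh_adjust",
    "train_signature",
    "evaluate_signature",
]

SCORE_NOISE_MARGIN = 0.5  # same 2-fold band, carried onto the composite scale


@dataclass(frozen=True)
class GeneSignature:
    """Up/down gene lists with +/-1 weights driving the composite score."""

    up_genes: tuple
    down_genes: tuple
    weights: dict = field(default_factory=lambda: {"up": 1.0, "down": -1.0})
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            clash = sorted(set(self.up_genes) & set(self.down_genes))[0]
            raise ValueError(f"gene {clash!r} appears in both up and down lists")

    def swapped(self) -> "GeneSignature":
        return GeneSignature(self.down_genes, self.up_genes, dict(self.weights))


@dataclass
class EvaluationResult:
    """Classification performance of a signature on one labelled dataset."""

    scores: pd.Series  # sample -> composite score
    roc_auc: float
    t: float
    p: float
    p_adj: float | None = None
    score_margin: float = SCORE_NOISE_MARGIN

    def ordered_samples(self, labels: pd.Series | None = None) -> pd.DataFrame:
        """Samples ranked by score, for bar/violin-style exports."""
        df = pd.DataFrame({"score": self.scores.sort_values()})
        if labels is not None:
            df["label"] = labels.reindex(df.index)
        return df.reset_index(names="sample_id")


def normalize_expr(x: float, threshold: float, stddev: float):
    """Modified Z-score centred on the StepMiner threshold.

    ``(x - threshold - 0.5) / (3 * stddev)``: a value at the upper noise
    margin maps to 0, one three standard deviations above it to 1.
    """
    if stddev <= 0:
        raise ValueError("stddev must be > 0; gene unusable for scoring")
    return (np.asarray(x, dtype=float) - threshold - 0.5) / (3.0 * stddev)


def composite_score(
    matrix: ExpressionMatrix,
    trits: TritMatrix,
    sets: list,
    weights: list,
) -> pd.Series:
    """Weighted sum of per-set averages of normalized expression.

    Genes of a set missing from the matrix are skipped (the average runs
    over the genes present); a set with no overlap at all is an error.
    Thresholds and standard deviations come from ``trits``, i.e. they are
    local to the dataset being scored.
    """
    if len(sets) != len(weights):
        raise ValueError("sets and weights must have equal length")
    score = np.zeros(matrix.n_samples)
    gene_index = pd.Index(trits.gene_ids)
    for si, (gene_set, w) in enumerate(zip(sets, weights)):
        present = [
            g for g in gene_set if g in matrix.data.index and g in gene_index
        ]
        if not present:
            raise ValueError(f"gene set {si} has no overlap with the matrix")
        normed = np.vstack(
            [
                normalize_expr(
                    matrix.data.loc[g].to_numpy(),
                    trits.thresholds[g],
                    trits.stddevs[g],
                )
                for g in present
            ]
        )
        score = score + w * normed.mean(axis=0)
    return pd.Series(score, index=matrix.sample_ids, name="score")


def roc_auc(scores, labels) -> float:
    """ROC-AUC with the 'higher score = case (label 1)' orientation.

    Equals the Mann-Whitney estimate P(score_case > score_control) plus
    half the tie probability.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc needs exactly two classes in labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def welch_ttest(group1, group2) -> tuple[float, float]:
    """Welch's two-sample t-test (unpaired, unequal variance), two-sided."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(g1) == 0 and np.var(g2) == 0:
        if np.all(g1 == g2[0]) and np.all(g2 == g2[0]):
            return 0.0, 1.0  # identical constant groups
        raise ValueError("zero variance in both groups")
    t, p = sps.ttest_ind(g1, g2, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_by_label(values: np.ndarray, labels: np.ndarray):
    case = values[labels == 1]
    control = values[labels == 0]
    return case, control


def _gene_auc(matrix: ExpressionMatrix, gene) -> float:
    return roc_auc(matrix.data.loc[gene].to_numpy(), matrix.label_vector())


def train_signature(
    training: list,
    cbin: ClusteredNetwork,
    ranking_dataset: int = 0,
    auc_up: float = 0.6,
    auc_down: float = 0.3,
    top_k: int = 20,
    cluster_auc_cutoff: float = 0.6,
    candidate_clusters: tuple | None = None,
    margin: float = 0.5,
) -> GeneSignature:
    """Train the up/down disease signature from CBIN clusters.

    1. Candidate clusters: each cluster is scored (weight +1 composite) in
       every training dataset; clusters with AUC >= ``cluster_auc_cutoff``
       everywhere become up-candidates, those with AUC <=
       ``1 - cluster_auc_cutoff`` everywhere down-candidates.  Pass
       ``candidate_clusters=(up_ids, down_ids)`` to override with a
       curated choice.
    2. Gene filters: an up-gene must have single-gene ROC-AUC > ``auc_up``
       in ALL training datasets, a down-gene AUC < ``auc_down`` in all
       (always with the higher-expression-means-case orientation).
    3. Survivors are ranked by the Welch t statistic (case vs control) in
       ``training[ranking_dataset]`` — descending for up, ascending for
       down — and the top ``top_k`` per direction are kept with weights
       +1 / -1.

    Fewer than ``top_k`` survivors in a direction keeps them all with a
    warning; zero survivors in either direction is an error.
    """
    if not training:
        raise ValueError("need at least one training dataset")
    if not (0 <= ranking_dataset < len(training)):
        raise ValueError(f"ranking_dataset index {ranking_dataset} out of range")
    for d, m in enumerate(training):
        labs = np.unique(m.label_vector())
        if len(labs) != 2:
            raise ValueError(f"training dataset {d} does not have two classes")

    trits = [discretize_matrix(m, margin=margin) for m in training]

    if candidate_clusters is not None:
        up_ids, down_ids = (set(candidate_clusters[0]), set(candidate_clusters[1]))
    else:
        up_ids, down_ids = set(), set()
        for cluster in cbin.clusters:
            aucs = []
            for m, tr in zip(training, trits):
                members = [g for g in cluster.members if g in m.data.index]
                if not members:
                    break
                s = composite_score(m, tr, [members], [1.0])
                aucs.append(roc_auc(s.to_numpy(), m.label_vector()))
            else:
                if all(a >= cluster_auc_cutoff for a in aucs):
                    up_ids.add(cluster.cluster_id)
                elif all(a <= 1.0 - cluster_auc_cutoff for a in aucs):
                    down_ids.add(cluster.cluster_id)

    def _genes_of(ids):
        out = []
        for cluster in cbin.clusters:
            if cluster.cluster_id in ids:
                out.extend(cluster.members)
        return out

    up_candidates = _genes_of(up_ids)
    down_candidates = _genes_of(down_ids)

    def _passes(gene, low, high):
        for m in training:
            if gene not in m.data.index:
                return False
            a = _gene_auc(m, gene)
            if not (low < a < high):
                return False
        return True

    up_survivors = [g for g in up_candidates if _passes(g, auc_up, np.inf)]
    down_survivors = [g for g in down_candidates if _passes(g, -np.inf, auc_down)]
    if not up_survivors or not down_survivors:
        missing = "up" if not up_survivors else "down"
        raise ValueError(f"no {missing}-regulated genes survive the AUC filters")

    rank_m = training[ranking_dataset]
    labels = rank_m.label_vector()

    def _tstat(gene):
        case, control = _split_by_label(rank_m.data.loc[gene].to_numpy(), labels)
        t, _ = welch_ttest(case, control)
        return t

    up_ranked = sorted(up_survivors, key=lambda g: (-_tstat(g), str(g)))
    down_ranked = sorted(down_survivors, key=lambda g: (_tstat(g), str(g)))
    for name, ranked in (("up", up_ranked), ("down", down_ranked)):
        if len(ranked) < top_k:
            warnings.warn(
                f"only {len(ranked)} {name}-regulated survivors for top_k={top_k}; "
                "keeping all",
                stacklevel=2,
            )
    return GeneSignature(
        up_genes=tuple(up_ranked[:top_k]),
        down_genes=tuple(down_ranked[:top_k]),
        provenance={
            "up_clusters": sorted(up_ids),
            "down_clusters": sorted(down_ids),
            "auc_up": auc_up,
            "auc_down": auc_down,
            "top_k": top_k,
            "cluster_auc_cutoff": cluster_auc_cutoff,
            "ranking_dataset": ranking_dataset,
            "n_training_datasets": len(training),
        },
    )


def evaluate_signature(
    matrix: ExpressionMatrix,
    trits: TritMatrix,
    sig: GeneSignature,
) -> EvaluationResult:
    """Score a labelled dataset with a signature and test case/control split."""
    labels = matrix.label_vector()
    scores = composite_score(
        matrix,
        trits,
        [list(sig.up_genes), list(sig.down_genes)],
        [sig.weights.get("up", 1.0), sig.weights.get("down", -1.0)],
    )
    auc = roc_auc(scores.to_numpy(), labels)
    case, control = _split_by_label(scores.to_numpy(), labels)
    t, p = welch_ttest(case, control)
    return EvaluationResult(scores=scores, roc_auc=auc, t=t, p=p)
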