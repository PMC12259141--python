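"""Synthetic expression data with known Boolean ground truth.

Real transcriptomic cohorts are unavailable offline, so every other module
is exercised on generated matrices whose structure is planted: bimodal
genes are two-component Gaussian mixtures over a latent binary state,
implication relations are imposed by constraining a child gene's states
given its parent's (leaving the relation's forbidden quadrant empty up to
a chosen violation rate), and case/control effects are location shifts of
planted up/down genes between labelled sample groups.  All generators take
an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .booleannet import Relation
from .expression_io import ExpressionMatrix

__all__ = [
    "GroundTruth",
    "make_bimodal_gene",
    "states_to_values",
    "plant_relation",
    "make_null_bimodal_matrix",
    "make_case_control_trio",
]

# default mixture geometry: log2-scale modes 2 and 5 with sd 0.5 put the
# low/high components 6 sd apart, comfortably outside the +/-0.5 noise band
DEFAULT_MU_LOW = 2.0
DEFAULT_MU_HIGH = 5.0
DEFAULT_SD = 0.5


@dataclass
class GroundTruth:
    """What was planted, so recovery can be checked exactly."""

    seed: int
    latent_states: dict = field(default_factory=dict)  # gene -> binary vector
    planted_clusters: list = field(default_factory=list)  # list of gene lists
    planted_up: tuple = ()
    planted_down: tuple = ()
    effect: float = 0.0
    gene_models: dict = field(default_factory=dict)  # gene -> parameter dict


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_bimodal_gene(
    n: int,
    frac_high: float,
    mu_low: float = DEFAULT_MU_LOW,
    mu_high: float = DEFAULT_MU_HIGH,
    sd: float = DEFAULT_SD,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """One bimodal gene: values and the true binary state per sample.

    Exactly ``round(frac_high * n)`` samples are in the high state, at
    uniformly random positions; values are Gaussian around the state's
    mode.  ``mu_high - mu_low > 2 * sd`` is recommended so the StepMiner
    threshold can land between the modes.
    """
    if not (0.0 < frac_high < 1.0):
        raise ValueError("frac_high must be strictly between 0 and 1")
    if sd <= 0 or mu_high <= mu_low:
        raise ValueError("need sd > 0 and mu_high > mu_low")
    rng = _as_rng(seed)
    n_high = int(round(frac_high * n))
    states = np.zeros(n, dtype=np.int8)
    states[rng.permutation(n)[:n_high]] = 1
    values = states_to_values(states, mu_low, mu_high, sd, rng)
    return values, states


def states_to_values(
    states,
    mu_low: float = DEFAULT_MU_LOW,
    mu_high: float = DEFAULT_MU_HIGH,
    sd: float = DEFAULT_SD,
    seed=0,
) -> np.ndarray:
    """Gaussian expression values around the mode of each binary state."""
    rng = _as_rng(seed)
    states = np.asarray(states)
    mu = np.where(states == 1, mu_high, mu_low)
    return mu + rng.normal(0.0, sd, size=states.size)


def plant_relation(
    parent_states,
    relation: Relation,
    violation_rate: float = 0.0,
    seed=0,
) -> np.ndarray:
    """Child binary states satisfying a Boolean implication to the parent.

    The relation's forbidden quadrant stays empty except at
    ``violation_rate``: e.g. for LOHI (parent low => child high) every
    parent-low sample gets a high child state unless it is flipped as a
    violation; samples not constrained by the relation get fair-coin
    states.  Raises if the parent lacks the conditioning state entirely.
    """
    rng = _as_rng(seed)
    parent = np.asarray(parent_states).astype(bool)
    n = parent.size
    child = rng.integers(0, 2, size=n).astype(bool)

    if relation is Relation.EQUIVALENT:
        child = parent.copy()
        constrained = np.ones(n, dtype=bool)
    elif relation is Relation.OPPOSITE:
        child = ~parent
        constrained = np.ones(n, dtype=bool)
    elif relation in (Relation.LOHI, Relation.LOLO):
        constrained = ~parent
        if not constrained.any():
            raise ValueError("parent has no low samples for a low-conditioned relation")
        child[constrained] = relation is Relation.LOHI
    elif relation in (Relation.HIHI, Relation.HILO):
        constrained = parent
        if not constrained.any():
            raise ValueError("parent has no high samples for a high-conditioned relation")
        child[constrained] = relation is Relation.HIHI
    else:
        raise ValueError(f"cannot plant relation {relation}")

    if violation_rate > 0:
        flip = constrained & (rng.random(n) < violation_rate)
        child = child ^ flip
    return child.astype(np.int8)


def make_null_bimodal_matrix(
    n_genes: int,
    n_samples: int,
    mu_low: float = DEFAULT_MU_LOW,
    mu_high: float = DEFAULT_MU_HIGH,
    sd: float = DEFAULT_SD,
    frac_high_range: tuple = (0.2, 0.8),
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Independent bimodal genes with no between-gene structure.

    Each gene's high-state fraction is drawn uniformly from
    ``frac_high_range``.  This is the permutation-null test bed: any
    implication found between these genes (or their permuted versions) is
    a false discovery.
    """
    rng = _as_rng(seed)
    truth = GroundTruth(seed=seed)
    rows, genes = [], []
    for i in range(n_genes):
        gene = f"G{i:05d}"
        fh = float(rng.uniform(*frac_high_range))
        values, states = make_bimodal_gene(n_samples, fh, mu_low, mu_high, sd, rng)
        rows.append(values)
        genes.append(gene)
        truth.latent_states[gene] = states
        truth.gene_models[gene] = {
            "frac_high": fh, "mu_low": mu_low, "mu_high": mu_high, "sd": sd,
        }
    samples = [f"S{j:04d}" for j in range(n_samples)]
    data = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    return ExpressionMatrix(data), truth


def make_case_control_trio(
    n_datasets: int = 3,
    n_genes: int = 500,
    n_samples_per_class: int = 100,
    n_up: int = 30,
    n_down: int = 30,
    effect: float = 3.0,
    sd: float = DEFAULT_SD,
    mu_low: float = DEFAULT_MU_LOW,
    mu_high: float = DEFAULT_MU_HIGH,
    seed: int = 0,
) -> tuple[list, GroundTruth]:
    """Labelled training cohorts with shared planted up/down genes.

    Each dataset has ``n_samples_per_class`` controls (label 0) and cases
    (label 1) with independent noise.  Planted up-genes sit at
    ``mu_low`` in controls and ``mu_low + effect * sd`` in cases;
    down-genes mirror this.  The remaining genes are null bimodal genes
    whose states ignore the labels.  Because every planted gene of one
    direction shares the case/control latent state, the up set and the
    down set each form an exact equivalence clique (and are mutually
    opposite), emulating disease-driven gene clusters.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    if n_up < 1 or n_down < 1:
        raise ValueError("need at least one planted gene per direction")
    rng = _as_rng(seed)
    n = 2 * n_samples_per_class
    labels_vec = np.concatenate(
        [np.zeros(n_samples_per_class, np.int8), np.ones(n_samples_per_class, np.int8)]
    )
    up_genes = tuple(f"UP{i:04d}" for i in range(n_up))
    down_genes = tuple(f"DN{i:04d}" for i in range(n_down))
    null_genes = tuple(f"G{i:05d}" for i in range(n_genes - n_up - n_down))
    mu_case = mu_low + effect * sd

    matrices = []
    for d in range(n_datasets):
        rows, genes = [], []
        for g in up_genes:
            mu = np.where(labels_vec == 1, mu_case, mu_low)
            rows.append(mu + rng.normal(0.0, sd, size=n))
            genes.append(g)
        for g in down_genes:
            mu = np.where(labels_vec == 1, mu_low, mu_case)
            rows.append(mu + rng.normal(0.0, sd, size=n))
            genes.append(g)
        for g in null_genes:
            fh = float(rng.uniform(0.2, 0.8))
            values, _states = make_bimodal_gene(n, fh, mu_low, mu_high, sd, rng)
            rows.append(values)
            genes.append(g)
        samples = [f"D{d}S{j:04d}" for j in range(n)]
        data = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
        labels = pd.Series(labels_vec, index=samples, name="label")
        matrices.append(ExpressionMatrix(data, labels))

    truth = GroundTruth(
        seed=seed,
        planted_up=up_genes,
        planted_down=down_genes,
        planted_clusters=[list(up_genes), list(down_genes)],
        effect=effect,
    )
    return matrices, truth
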