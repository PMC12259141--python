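import itertools

import numpy as np
import pandas as pd
import pytest

from boolimpl import (
    ExpressionMatrix,
    GeneSignature,
    bh_adjust,
    build_bin,
    composite_score,
    evaluate_signature,
    extract_clusters,
    filter_dynamic_range,
    link_clusters,
    normalize_expr,
    roc_auc,
    train_signature,
    welch_ttest,
)
from boolimpl.stepminer import discretize_matrix
from boolimpl.synthetic_data import make_case_control_trio

from ._oracles import pair_counting_auc


class TestNormalizeExpr:
    @pytest.mark.parametrize(
        "x,t,sd,expected",
        [
            (2.5, 2.0, 1.0, 0.0),    # at the upper noise margin
            (5.5, 2.0, 1.0, 1.0),    # three sd above it
            (4.0, 2.0, 1.0, 0.5),
        ],
    )
    def test_modified_z(self, x, t, sd, expected):
        assert normalize_expr(x, t, sd) == pytest.approx(expected)

    def test_nonpositive_stddev_rejected(self):
        with pytest.raises(ValueError, match="stddev"):
            normalize_expr(1.0, 0.0, 0.0)


class TestCompositeScore:
    @staticmethod
    def _matrix(rows, genes):
        df = pd.DataFrame(
            rows, index=genes, columns=[f"s{i}" for i in range(len(rows[0]))]
        )
        return ExpressionMatrix(df)

    def test_single_gene_set_equals_normalized_value(self):
        m = self._matrix([[1.0, 1.0, 1.0, 4.0, 4.0, 4.0]], ["gA"])
        trits = discretize_matrix(m)
        scores = composite_score(m, trits, [["gA"]], [1.0])
        t, sd = trits.thresholds["gA"], trits.stddevs["gA"]
        expected = (m.values[0] - t - 0.5) / (3 * sd)
        np.testing.assert_allclose(scores.to_numpy(), expected)

    def test_identical_sets_with_opposite_weights_cancel(self):
        m = self._matrix([[1, 1, 4, 4, 1, 4]], ["gA"])
        trits = discretize_matrix(m)
        scores = composite_score(m, trits, [["gA"], ["gA"]], [1.0, -1.0])
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_up_and_down_sets_sum(self):
        # with t=2, sd=1 injected, values 5.5 / -0.5 normalize to exactly +/-1
        m = self._matrix([[5.5, -0.5, 2.0, 2.1], [-0.5, 5.5, 2.0, 2.1]], ["u", "d"])
        trits = discretize_matrix(m)
        trits.thresholds[:] = 2.0
        trits.stddevs[:] = 1.0
        scores = composite_score(m, trits, [["u"], ["d"]], [1.0, -1.0])
        np.testing.assert_allclose(scores.to_numpy()[:2], [2.0, -2.0])

    def test_empty_overlap_named(self):
        m = self._matrix([[1, 1, 4, 4]], ["gA"])
        trits = discretize_matrix(m)
        with pytest.raises(ValueError, match="set 1"):
            composite_score(m, trits, [["gA"], ["missing"]], [1.0, -1.0])

    def test_invariant_to_affine_rescaling(self):
        """Scaling a gene rescales threshold and sd; the modified Z cancels."""
        rng = np.random.default_rng(3)
        base = rng.normal(3, 1.2, size=40)
        base[:20] -= 3.0
        m1 = self._matrix([base], ["gA"])
        m2 = self._matrix([base * 2.5], ["gA"])
        s1 = composite_score(m1, discretize_matrix(m1), [["gA"]], [1.0])
        s2 = composite_score(m2, discretize_matrix(m2), [["gA"]], [1.0])
        # scale cancels except for the fixed 0.5 margin offset, which shifts
        # every sample equally -> identical ordering, equal differences
        np.testing.assert_allclose(
            np.diff(np.argsort(s1.to_numpy())), np.diff(np.argsort(s2.to_numpy()))
        )


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([2, 3, 0, 1], [1, 1, 0, 0], 1.0),
            ([1, 1, 1, 1], [1, 1, 0, 0], 0.5),
            ([3, 2, 1, 2.5], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_label_flip_complements(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, 1 - labels)
        )

    def test_matches_pair_counting_oracle_short_inputs(self, rng):
        for n in range(2, 13):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                if n > 8 and rng.random() > 0.05:
                    continue  # sample the larger label spaces
                scores = rng.integers(0, 4, size=n)  # ties likely
                assert roc_auc(scores, labels) == pytest.approx(
                    pair_counting_auc(scores, labels)
                )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            roc_auc([1, 2], [1, 1])


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_ttest([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, p = welch_ttest([1, 2, 3], [2, 3, 4])
        # equal variances of 1, n=3 each: t = -1 / sqrt(2/3), df = 4
        assert t == pytest.approx(-1.224745, abs=1e-6)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(1.224745, df=4), abs=1e-6)

    def test_antisymmetric_in_group_order(self, rng):
        g1, g2 = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        t12, p12 = welch_ttest(g1, g2)
        t21, p21 = welch_ttest(g2, g1)
        assert t12 == pytest.approx(-t21)
        assert p12 == pytest.approx(p21)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_ttest([1, 1, 1], [2, 2, 2])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_uniform_ladder(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def trio_with_cbin():
    matrices, truth = make_case_control_trio(
        n_genes=120, n_samples_per_class=60, n_up=25, n_down=25,
        effect=3.0, seed=42,
    )
    ref = matrices[0]
    trits = discretize_matrix(ref)
    filtered = filter_dynamic_range(ref.subset_genes(trits.gene_ids), trits)
    net = build_bin(trits.subset_genes(filtered.gene_ids))
    clusters = extract_clusters(net)
    cbin = link_clusters(net, clusters)
    return matrices, truth, cbin


class TestTrainSignature:
    def test_planted_trio_gives_top_k_per_direction(self, trio_with_cbin):
        matrices, truth, cbin = trio_with_cbin
        sig = train_signature(matrices, cbin, top_k=20)
        assert len(sig.up_genes) == 20 and len(sig.down_genes) == 20
        assert set(sig.up_genes) <= set(truth.planted_up)
        assert set(sig.down_genes) <= set(truth.planted_down)

    def test_shortfall_keeps_all_with_warning(self, trio_with_cbin):
        matrices, _truth, cbin = trio_with_cbin
        with pytest.warns(UserWarning, match="keeping all"):
            sig = train_signature(matrices, cbin, top_k=30)
        assert len(sig.up_genes) == 25  # only 25 planted up-genes exist

    def test_gene_flipped_in_one_dataset_is_excluded(self, trio_with_cbin):
        matrices, truth, cbin = trio_with_cbin
        flipped = truth.planted_up[0]
        tampered = []
        for d, m in enumerate(matrices):
            data = m.data.copy()
            if d == 1:  # reverse the effect direction in one training dataset
                row = data.loc[flipped].to_numpy()
                data.loc[flipped] = row[::-1]
            tampered.append(ExpressionMatrix(data, m.labels))
        sig = train_signature(tampered, cbin, top_k=25)
        assert flipped not in sig.up_genes

    def test_disjoint_up_down_enforced(self):
        with pytest.raises(ValueError, match="both up and down"):
            GeneSignature(("a", "b"), ("b", "c"))


class TestEvaluateSignature:
    def test_training_dataset_separates_cleanly(self, trio_with_cbin):
        matrices, _truth, cbin = trio_with_cbin
        sig = train_signature(matrices, cbin, top_k=20)
        m = matrices[0]
        res = evaluate_signature(m, discretize_matrix(m), sig)
        assert res.roc_auc > 0.9
        assert res.p < 1e-6

    def test_permuted_labels_near_chance(self, trio_with_cbin, rng):
        matrices, _truth, cbin = trio_with_cbin
        sig = train_signature(matrices, cbin, top_k=20)
        m = matrices[0]
        perm_labels = pd.Series(
            rng.permutation(m.labels.to_numpy()), index=m.labels.index
        )
        shuffled = ExpressionMatrix(m.data, perm_labels)
        res = evaluate_signature(shuffled, discretize_matrix(shuffled), sig)
        assert 0.3 < res.roc_auc < 0.7  # well within the null band at n=120

    def test_swapped_signature_complements_auc(self, trio_with_cbin):
        matrices, _truth, cbin = trio_with_cbin
        sig = train_signature(matrices, cbin, top_k=20)
        m = matrices[0]
        trits = discretize_matrix(m)
        auc = evaluate_signature(m, trits, sig).roc_auc
        auc_swapped = evaluate_signature(m, trits, sig.swapped()).roc_auc
        assert auc_swapped == pytest.approx(1.0 - auc)
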