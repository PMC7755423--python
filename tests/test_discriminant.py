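"""Frequency maps, PCA, feature selection, LDA and the SVM/LOOCV classifier."""

import numpy as np
import pytest

from cdrmatrix.discriminant import (
    TopDifferenceSelector,
    aa_frequency_difference,
    lda_fit_project,
    pca_project,
    scrambled_control,
    select_features,
    svm_loocv,
)
from cdrmatrix.property_masks import build_feature_matrix
from cdrmatrix.sequence_io import LABEL_NONPOLY, LABEL_POLY, encode_residue, encode_repertoire
from cdrmatrix.synthetic_fixtures import FixtureSpec, PropertyShift, generate_repertoire
from tests.conftest import make_records


def charge_shift_features(delta, n=50, seed=7, table=None, properties=("charge",)):
    """Fixture with an {R,K} enrichment across the CDR2H loop of one class."""
    from tests.conftest import STRONG_SIGNAL_LOOPS, STRONG_SIGNAL_POSITIONS
    shifts = ()
    if delta > 0:
        shifts = (PropertyShift(loop="cdr2h", positions=STRONG_SIGNAL_POSITIONS,
                                residues=("R", "K"), delta=delta),)
    spec = FixtureSpec(
        n_polyreactive=n, n_nonpolyreactive=n,
        loop_lengths=STRONG_SIGNAL_LOOPS, shifts=shifts, seed=seed,
    )
    records, _ = generate_repertoire(spec)
    matrix = encode_repertoire(records)
    return build_feature_matrix(matrix, list(properties), table)


class TestFrequencyDifference:
    def test_extreme_single_residue_columns(self):
        recs = make_records(
            [("L", "A", "A", "A", "A", "A")] * 3
            + [("F", "A", "A", "A", "A", "A")] * 3,
            [LABEL_POLY] * 3 + [LABEL_NONPOLY] * 3,
        )
        matrix = encode_repertoire(recs, buffer_width=1)
        fmap = aa_frequency_difference(matrix)
        col = matrix.layout.loop_spans["cdr1l"][0]
        assert fmap.delta[col, encode_residue("L") - 1] == pytest.approx(1.0)
        assert fmap.delta[col, encode_residue("F") - 1] == pytest.approx(-1.0)

    def test_identical_classes_all_zero(self, tiny_matrix):
        tiny_matrix.values[2:] = tiny_matrix.values[:2]
        fmap = aa_frequency_difference(tiny_matrix)
        assert np.all(fmap.delta == 0.0)

    def test_display_threshold_rule(self, null_repertoire):
        fmap = aa_frequency_difference(null_repertoire, display_threshold=0.10)
        small = np.abs(fmap.delta) <= 0.10
        assert np.all(fmap.filtered[small] == 0.0)
        kept = np.abs(fmap.delta) > 0.10
        np.testing.assert_array_equal(fmap.filtered[kept], fmap.delta[kept])
        # per-column frequency sums match in both classes, so each column's
        # differences sum to ~0 over all codes plus the gap share
        assert np.all(fmap.delta >= -1.0) and np.all(fmap.delta <= 1.0)


class TestPCA:
    def test_collinear_cloud_explained_by_pc1(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t])
        proj, ratio, _ = pca_project(X, n_components=2)
        assert ratio[0] >= 0.999

    def test_components_orthonormal(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        _, _, pca = pca_project(X, n_components=4)
        gram = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-9)

    def test_low_rank_distances_preserved(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((3, 10))
        X = rng.standard_normal((25, 3)) @ basis
        Xz = (X - X.mean(0)) / X.std(0)
        proj, _, _ = pca_project(X, n_components=3)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(proj), pdist(Xz), atol=1e-9)

    def test_all_constant_features_rejected(self):
        with pytest.raises(ValueError):
            pca_project(np.ones((10, 3)), n_components=1)


class TestFeatureSelection:
    def _features(self, X, names=None):
        from cdrmatrix.property_masks import FeatureMatrix
        names = names or [f"f{i}" for i in range(X.shape[1])]
        return FeatureMatrix(values=X, columns=names,
                             row_ids=[str(i) for i in range(X.shape[0])],
                             row_labels=["a"] * (X.shape[0] // 2)
                                        + ["b"] * (X.shape[0] - X.shape[0] // 2))

    def test_perfectly_separating_feature_ranked_first(self):
        rng = np.random.default_rng(3)
        n = 40
        X = rng.standard_normal((n, 6))
        X[:20, 4] += 10  # class a strongly shifted on feature 4
        fm = self._features(X)
        _, sel = select_features(fm, k=3)
        assert sel.indices[0] == 4

    def test_duplicate_feature_filtered(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(30)
        X = np.column_stack([base, base, rng.standard_normal(30)])
        X[:15, :2] += 2
        fm = self._features(X)
        _, sel = select_features(fm, k=3, correlation_threshold=0.75)
        assert not {0, 1} <= set(sel.indices)

    def test_identity_selection_at_full_k_and_unit_threshold(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 5))
        fm = self._features(X)
        reduced, sel = select_features(fm, k=5, correlation_threshold=1.0)
        assert sorted(sel.indices) == list(range(5))
        assert reduced.shape == (20, 5)

    def test_invalid_k_rejected(self):
        fm = self._features(np.ones((10, 3)))
        with pytest.raises(ValueError):
            select_features(fm, k=0)
        with pytest.raises(ValueError):
            select_features(fm, k=10)


class TestLDA:
    def test_separated_blobs_perfect_accuracy(self):
        rng = np.random.default_rng(6)
        a = rng.normal([0, 0], 0.3, (30, 2))
        b = rng.normal([5, 5], 0.3, (30, 2))
        X = np.vstack([a, b])
        y = np.array(["a"] * 30 + ["b"] * 30)
        res = lda_fit_project(X, y)
        assert res.accuracy == 1.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((200, 2))
        y = rng.permutation(np.array(["a", "b"] * 100))
        res = lda_fit_project(X, y)
        # binomial 99% CI around 0.5 for n=200 (plus training optimism)
        assert 0.4 <= res.accuracy <= 0.72

    def test_accuracy_at_least_half_by_orientation(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 3))
        y = np.array(["a", "b"] * 30)
        assert lda_fit_project(X, y).accuracy >= 0.5

    def test_top_weights_contract(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 12))
        y = np.array(["a", "b"] * 25)
        res = lda_fit_project(X, y)
        top = res.top_weights(10)
        assert len(top) == 10
        mags = top["weight"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)

    def test_overfit_guard(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((10, 12))
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError, match="overfit"):
            lda_fit_project(X, y)


class TestSVMClassifier:
    def test_strong_signal_high_loocv(self, table):
        fm = charge_shift_features(0.5, n=50, seed=7, table=table)
        rep = svm_loocv(fm, k=10, seed=7)
        assert rep.loocv_accuracy >= 0.85

    def test_deterministic_given_same_inputs(self, table):
        fm = charge_shift_features(0.5, n=15, seed=7, table=table)
        r1 = svm_loocv(fm, k=20, seed=3)
        r2 = svm_loocv(fm, k=20, seed=3)
        assert r1.predictions == r2.predictions
        assert r1.loocv_accuracy == r2.loocv_accuracy

    def test_no_leakage_from_held_out_row(self, table):
        fm = charge_shift_features(0.5, n=15, seed=2, table=table)
        X = fm.values
        y = fm.labels_array
        held_out = 4
        train = np.delete(np.arange(X.shape[0]), held_out)
        sel = TopDifferenceSelector(k=20).fit(X[train], y[train])
        X_inflated = X.copy()
        X_inflated[held_out] *= 1e6
        sel2 = TopDifferenceSelector(k=20).fit(X_inflated[train], y[train])
        assert sel.indices_ == sel2.indices_

    def test_scrambled_control_near_chance(self, table):
        fm = charge_shift_features(0.5, n=20, seed=5, table=table)
        ctrl = scrambled_control(fm, repeats=5, seed=1, k=20)
        assert 0.30 <= ctrl["mean"] <= 0.70
        assert len(ctrl["accuracies"]) == 5

    def test_zero_repeats_rejected(self, table):
        fm = charge_shift_features(0.0, n=10, seed=5, table=table)
        with pytest.raises(ValueError):
            scrambled_control(fm, repeats=0, seed=0)

    def test_too_few_sequences_rejected(self, table):
        fm = charge_shift_features(0.0, n=4, seed=5, table=table)
        with pytest.raises(ValueError):
            svm_loocv(fm)
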