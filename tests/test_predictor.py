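"""Balanced sampling, protein-grouped folds, and SVM cross-validation."""

import numpy as np
import pytest

from helpers import mkrec, random_annotated_records
from oglysite.exceptions import ValidationError
from oglysite.predictor import (
    cross_type_evaluate,
    cross_validate,
    make_protein_folds,
    sample_balanced_negatives,
    train_model,
    ws_sweep,
)
from oglysite.sites import negative_sites, typed_positive_sites


class TestBalancedSampling:
    def test_size_and_distinctness(self):
        negs = list(range(100))
        out = sample_balanced_negatives(list(range(5)), negs, seed=1)
        assert len(out) == 5 == len(set(out))

    def test_equal_pools_return_everything(self):
        negs = list(range(7))
        assert sorted(sample_balanced_negatives(list(range(7)), negs, seed=42)) == negs

    def test_deterministic_in_seed(self):
        negs = list(range(50))
        a = sample_balanced_negatives(list(range(10)), negs, seed=5)
        b = sample_balanced_negatives(list(range(10)), negs, seed=5)
        assert a == b

    def test_insufficient_negatives_error_states_counts(self):
        with pytest.raises(ValidationError, match="3.*2"):
            sample_balanced_negatives([1, 2, 3], [1, 2], seed=0)


class TestProteinFolds:
    def test_sizes_differ_by_at_most_one(self):
        recs = [mkrec("ATSA", (2,), protein_id=f"P{i}") for i in range(23)]
        folds = make_protein_folds(recs, k=10, seed=0)
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_every_protein_in_exactly_one_fold(self):
        recs = [mkrec("ATSA", (2,), protein_id=f"P{i}") for i in range(20)]
        folds = make_protein_folds(recs, k=10, seed=3)
        assert set(folds) == {r.protein_id for r in recs}

    def test_fold_membership_independent_of_other_proteins(self):
        # Grouping is by protein: all of a protein's sites share its fold
        # by construction, so the leakage check reduces to the map being
        # a function of protein id only.
        recs = [mkrec("ATSTSA", (2, 4), protein_id=f"P{i}") for i in range(12)]
        folds = make_protein_folds(recs, k=10, seed=1)
        sites = typed_positive_sites(recs, "clustered") + negative_sites(recs)
        fold_of_site = {}
        for rec, pos in sites:
            fold_of_site.setdefault(rec.protein_id, set()).add(folds[rec.protein_id])
        assert all(len(v) == 1 for v in fold_of_site.values())

    def test_too_few_proteins_raises(self):
        recs = [mkrec("ATSA", (2,), protein_id=f"P{i}") for i in range(5)]
        with pytest.raises(ValidationError):
            make_protein_folds(recs, k=10, seed=0)


class TestCrossValidate:
    def test_planted_deterministic_motif_is_learned(self, separable_dataset):
        """Isolated positives all carry Pro at −1, negatives never do:
        the sparse Ws=3 problem is linearly separable and CV accuracy
        must be near-perfect."""
        res = cross_validate(
            separable_dataset.records, "isolated", "sparse", 3,
            c_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), seed=3,
        )
        assert res.mean_accuracy >= 0.95
        # independent check: the single-feature rule "P at -1" itself
        # classifies the balanced data perfectly
        from oglysite.sites import excise_window

        for rec, pos in typed_positive_sites(separable_dataset.records, "isolated"):
            assert excise_window(rec, pos, 3).symbols[0] == "P"

    def test_best_accuracy_bounds_every_grid_point(self, separable_dataset):
        res = cross_validate(
            separable_dataset.records, "isolated", "sparse", 3,
            c_grid=(0.1, 1.0), gamma_grid=(0.001, 0.01), seed=0,
        )
        assert res.mean_accuracy >= max(res.grid_means.values()) - 1e-12
        assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies))

    def test_uninformative_labels_score_near_chance(self):
        res = cross_validate(
            random_annotated_records(0, n_proteins=40, length=300,
                                     positives_per_protein=12),
            "isolated", "sparse", 7, c_grid=(1.0,), gamma_grid=(0.01,), seed=0,
        )
        accs = np.array(res.fold_accuracies)
        se = max(accs.std(ddof=1) / np.sqrt(len(accs)), 0.01)
        assert abs(res.mean_accuracy - 0.5) <= 3 * se + 0.02

    def test_duplicated_training_data_same_accuracy(self, separable_dataset):
        """Duplicating every training point leaves the (separable)
        decision unchanged."""
        recs = separable_dataset.records
        model_a = train_model(recs, "isolated", "sparse", 3, c=10, gamma=0.1, seed=4)
        positives = typed_positive_sites(recs, "isolated")
        negs = sample_balanced_negatives(positives, negative_sites(recs), seed=4)
        labeled = [(r, p, 1) for r, p in positives] + [(r, p, -1) for r, p in negs]
        from oglysite.features import build_design_matrix
        from sklearn.svm import SVC

        X, y = build_design_matrix(labeled, 3, "sparse")
        doubled = SVC(kernel="rbf", C=10, gamma=0.1)
        doubled.fit(np.vstack([X, X]), np.concatenate([y, y]))
        acc_a = float(np.mean(model_a.svc.predict(X) == y))
        acc_b = float(np.mean(doubled.predict(X) == y))
        assert acc_a == pytest.approx(acc_b, abs=1e-6)

    def test_unknown_type_or_encoding_rejected(self, separable_dataset):
        with pytest.raises(ValidationError):
            cross_validate(separable_dataset.records, "sporadic", "sparse", 3)
        with pytest.raises(ValidationError):
            cross_validate(separable_dataset.records, "isolated", "onehot", 3)


class TestCrossTypeEvaluate:
    def test_models_specialize_to_their_training_type(self, separable_dataset):
        """The isolated-type signal (Pro at −1) and the clustered-type
        signal (adjacent Ser/Thr run mates, disorder composition) are
        disjoint, so each model beats the other on its own type."""
        recs = separable_dataset.records
        m_iso = train_model(recs, "isolated", "sparse", 3, c=10, gamma=0.1, seed=1)
        m_clu = train_model(recs, "clustered", "sparse", 3, c=10, gamma=0.1, seed=1)
        iso_on_iso = cross_type_evaluate(m_iso, recs, "isolated", seed=9)
        clu_on_iso = cross_type_evaluate(m_clu, recs, "isolated", seed=9)
        clu_on_clu = cross_type_evaluate(m_clu, recs, "clustered", seed=9)
        iso_on_clu = cross_type_evaluate(m_iso, recs, "clustered", seed=9)
        assert iso_on_iso > clu_on_iso
        assert clu_on_clu > iso_on_clu

    def test_own_training_distribution_consistency(self, separable_dataset):
        recs = separable_dataset.records
        m_iso = train_model(recs, "isolated", "sparse", 3, c=10, gamma=0.1, seed=1)
        acc = cross_type_evaluate(m_iso, recs, "isolated", seed=77)
        assert acc >= 0.95  # separable signal: fresh balanced sample stays high

    def test_empty_evaluation_set_raises(self, separable_dataset):
        recs = [mkrec("AAAA" + "T" + "AAAA")]  # no positives at all
        m = train_model(
            separable_dataset.records, "isolated", "sparse", 3, c=1, gamma=0.1
        )
        with pytest.raises(ValidationError):
            cross_type_evaluate(m, recs, "isolated")


class TestWsSweep:
    def test_even_ws_rejected(self, separable_dataset):
        with pytest.raises(ValidationError):
            ws_sweep(separable_dataset.records, "isolated", "sparse", [4])

    def test_single_ws_single_row(self, separable_dataset):
        df = ws_sweep(
            separable_dataset.records, "isolated", "sparse", [3],
            c_grid=(1.0,), gamma_grid=(0.01,), seed=2,
        )
        assert len(df) == 1
        assert df.loc[0, "ws"] == 3

    def test_local_signal_flat_in_ws(self, separable_dataset):
        """All isolated-type signal sits at −1, so accuracy is already
        maximal at Ws=3 and does not degrade at a wider window."""
        df = ws_sweep(
            separable_dataset.records, "isolated", "sparse", [3, 9],
            c_grid=(10.0,), gamma_grid=(0.01,), seed=2,
        )
        accs = df["mean_accuracy"].to_numpy()
        assert accs[0] >= 0.95
        assert abs(accs[1] - accs[0]) <= 0.05
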