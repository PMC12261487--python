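"""Estimator behaviour: determinism, plumbing, interpretability surfaces.

The heavier learnability runs live in the acceptance suite; here training
is kept to a handful of epochs to exercise the machinery.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from dgsyn.evaluate import ABLATION_TOGGLES, order_independence, train_fold
from dgsyn.model import DualGranularitySynergyClassifier
from dgsyn.splits import split_random

COLS = ["drug1", "drug2", "cell_line"]


@pytest.fixture(scope="module")
def short_kwargs(small_model_kwargs):
    return dict(small_model_kwargs, gin_hidden=(16, 16, 16), cell_hidden=(32, 24),
                coarse_dims=(48, 24, 24, 24), mlp_hidden=32, max_epochs=6, patience=10)


@pytest.fixture(scope="module")
def fitted(short_kwargs, samples_frame):
    manifest = split_random(samples_frame, seed=0)[0]
    est, report, preds = train_fold(
        DualGranularitySynergyClassifier(**short_kwargs), samples_frame, manifest)
    return est, report, preds


class TestFitBasics:
    def test_history_and_attributes(self, fitted):
        est, _, _ = fitted
        assert est.n_epochs_ <= 6
        assert list(est.classes_) == [0, 1]
        assert {"total", "classification", "val_loss"} <= set(est.history_.columns)

    def test_same_seed_reproduces_epoch_log(self, short_kwargs, samples_frame):
        manifest = split_random(samples_frame, seed=0)[0]
        kwargs = dict(short_kwargs, max_epochs=3)
        _, _, preds_a = train_fold(
            DualGranularitySynergyClassifier(**kwargs), samples_frame, manifest)
        est_a = DualGranularitySynergyClassifier(**kwargs)
        est_b = DualGranularitySynergyClassifier(**kwargs)
        train = samples_frame.iloc[manifest.train]
        val = samples_frame.iloc[manifest.val]
        eval_set = (val[COLS], val["label"].to_numpy())
        est_a.fit(train[COLS], train["label"].to_numpy(), eval_set=eval_set)
        est_b.fit(train[COLS], train["label"].to_numpy(), eval_set=eval_set)
        pd.testing.assert_frame_equal(est_a.history_, est_b.history_)

    def test_loss_breakdown_identity_every_epoch(self, fitted):
        _, _, _ = fitted
        est = fitted[0]
        h = est.history_
        recomposed = (h["w_cls"] * h["classification"] + h["w_rec"] * h["reconstruction"]
                      + h["w_con"] * h["contrastive"])
        assert np.abs(h["total"] - recomposed).max() < 1e-6

    def test_probabilities_well_formed(self, fitted, samples_frame):
        est, _, _ = fitted
        probs = est.predict_proba(samples_frame.head(10)[COLS])
        assert probs.shape == (10, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.array_equal(est.predict(samples_frame.head(10)[COLS]),
                              (probs[:, 1] >= 0.5).astype(int))

    def test_evaluation_never_adds_hyperedges(self, fitted, samples_frame):
        est, _, _ = fitted
        before = est.incidence_.H.sum()
        est.predict_proba(samples_frame.head(50)[COLS])
        assert est.incidence_.H.sum() == before


class TestValidation:
    def test_missing_inputs_rejected(self, samples_frame):
        est = DualGranularitySynergyClassifier()
        with pytest.raises(ValueError, match="drug_smiles"):
            est.fit(samples_frame[COLS], samples_frame["label"])

    def test_unknown_entities_rejected(self, short_kwargs, samples_frame):
        est = DualGranularitySynergyClassifier(**dict(short_kwargs, max_epochs=1))
        bad = samples_frame.head(4)[COLS].copy()
        bad.loc[bad.index[0], "drug1"] = "NOT_A_DRUG"
        with pytest.raises(ValueError, match="NOT_A_DRUG"):
            est.fit(bad, np.array([0, 1, 0, 1]))

    def test_both_modules_off_rejected(self, short_kwargs, samples_frame):
        est = DualGranularitySynergyClassifier(
            **dict(short_kwargs, use_coarse=False, use_fine=False))
        with pytest.raises(ValueError):
            est.fit(samples_frame.head(4)[COLS], np.array([0, 1, 0, 1]))

    def test_non_binary_labels_rejected(self, short_kwargs, samples_frame):
        est = DualGranularitySynergyClassifier(**short_kwargs)
        with pytest.raises(ValueError, match="binary"):
            est.fit(samples_frame.head(3)[COLS], np.array([0, 1, 2]))

    def test_sklearn_clone_roundtrip(self, short_kwargs):
        est = DualGranularitySynergyClassifier(**short_kwargs)
        cloned = clone(est)
        assert cloned.get_params()["gin_hidden"] == (16, 16, 16)


class TestInterpretability:
    def test_explain_maps_normalized(self, fitted):
        est, _, _ = fitted
        maps = est.explain(est.drug_ids_[0])
        assert len(maps) == 3  # one per message-passing layer
        for m in maps:
            values = np.array(list(m.values()))
            assert np.all((values >= 0) & (values <= 1))
            assert values.max() == pytest.approx(1.0)

    def test_explain_single_atom_molecule(self, samples_frame):
        drugs = pd.DataFrame({"drug_id": ["A", "B", "C"], "smiles": ["C", "CCO", "CCN"]})
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 5)),
                            index=["X", "Y"], columns=list("abcde"))
        X = pd.DataFrame({"drug1": ["A", "B", "A", "C"], "drug2": ["B", "A", "C", "A"],
                          "cell_line": ["X", "X", "Y", "Y"]})
        est = DualGranularitySynergyClassifier(
            drug_smiles=drugs, expression=expr, gin_hidden=(8, 8, 8),
            cell_hidden=(8, 6), coarse_dims=(12, 8, 8, 8), mlp_hidden=8,
            max_epochs=2, patience=5, random_state=0)
        est.fit(X, np.array([1, 1, 0, 0]))
        maps = est.explain("A")
        assert all(m == {0: 1.0} for m in maps)
        with pytest.raises(ValueError, match="unknown drug"):
            est.explain("ZZZ")

    def test_attention_maps_exported(self, fitted, samples_frame):
        est, _, _ = fitted
        maps = est.attention_maps(samples_frame.head(3)[COLS])
        assert set(maps) == {"a_from_b", "b_from_a", "a_from_cell", "cell_from_a",
                             "b_from_cell", "cell_from_b", "self"}

    def test_embedding_export_tags(self, fitted, samples_frame):
        est, _, _ = fitted
        frame = est.export_embeddings(samples_frame.head(4)[COLS])
        assert set(frame["module"]) == {"init", "coarse", "fine", "final"}
        assert len(frame) == 16


class TestScreen:
    def test_candidates_exclude_training_and_sort(self, fitted):
        est, _, _ = fitted
        drugs = est.drug_ids_[:6]
        cells = est.cell_ids_[:3]
        table = est.screen(drugs, cells)
        assert (table["prob"].diff().dropna() <= 1e-12).all()
        for row in table.itertuples():
            assert (row.drug1, row.drug2, row.cell_line) not in est.train_triples_
        n_candidates = 15 * 3 - sum(
            1 for (a, b, c) in est.train_triples_
            if a in drugs and b in drugs and c in cells)
        assert len(table) == n_candidates


class TestOrderIndependence:
    def test_antithetic_toy_predictions(self):
        # direct PCC sanity check on constructed anti-correlated predictions
        forward = np.array([0.1, 0.9])
        backward = np.array([0.9, 0.1])
        assert np.corrcoef(forward, backward)[0, 1] == pytest.approx(-1.0)

    def test_pcc_computed_on_model(self, fitted, samples_frame):
        est, _, preds = fitted
        pcc, scatter = order_independence(est, preds)
        assert -1.0 <= pcc <= 1.0
        assert {"prob_d1_d2", "prob_d2_d1"} == set(scatter.columns)
        with pytest.raises(ValueError):
            order_independence(est, preds.head(1))


def test_shuffled_labels_give_chance_level(short_kwargs, samples_frame):
    manifest = split_random(samples_frame, seed=1)[0]
    shuffled = samples_frame.copy()
    shuffled["label"] = np.random.default_rng(0).permutation(shuffled["label"].to_numpy())
    kwargs = dict(short_kwargs, max_epochs=30, patience=30)
    _, report, _ = train_fold(
        DualGranularitySynergyClassifier(**kwargs), shuffled, manifest)
    assert 0.3 <= report.auc_roc <= 0.7


def test_ablation_toggle_table_structure():
    assert {"no_coarse", "no_fine", "no_highway", "no_residual",
            "no_reconstruction", "no_contrastive", "classification_only"} \
        == set(ABLATION_TOGGLES)
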