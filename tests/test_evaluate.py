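"""Metrics, the training pipeline, cross-validation and external scoring."""

import json

import numpy as np
import pandas as pd
import pytest

from sensbn.data_model import CLASSES4, Dataset
from sensbn.evaluate import (HyperParams, accuracy_by_confidence,
                             balanced_accuracy, cross_validate,
                             evaluate_external, evaluate_test, grid_search,
                             train_full)
from sensbn.predict import ModelBundle, predict_from_posterior
from sensbn.synthetic import SimConfig, generate_dataset


def _recall_mean_oracle(y_true, y_pred):
    """Independent per-class recall average (hand-rolled)."""
    classes = sorted(set(y_true))
    recalls = []
    for c in classes:
        idx = [i for i, y in enumerate(y_true) if y == c]
        recalls.append(sum(y_pred[i] == c for i in idx) / len(idx))
    return 100.0 * sum(recalls) / len(recalls)


def test_balanced_accuracy_examples():
    assert balanced_accuracy(list(CLASSES4), list(CLASSES4)) == 100.0
    truth = ["non", "non", "weak", "moderate", "strong"]
    pred = ["non", "weak", "weak", "moderate", "moderate"]
    assert balanced_accuracy(truth, pred) == pytest.approx(62.5)
    # constant predictor on a balanced set: one recall of 1, three of 0
    balanced = [c for c in CLASSES4 for _ in range(5)]
    assert balanced_accuracy(balanced, ["weak"] * 20) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        balanced_accuracy([], [])


def test_balanced_accuracy_matches_recall_oracle():
    rng = np.random.default_rng(0)
    truth = list(rng.choice(CLASSES4, size=60))
    pred = list(rng.choice(CLASSES4, size=60))
    assert balanced_accuracy(truth, pred) == pytest.approx(
        _recall_mean_oracle(truth, pred))


def _pred(cls, conf_bf):
    prior = np.full(4, 0.25)
    post = np.full(4, (1 - 0.7) / 3)
    post[CLASSES4.index(cls)] = 0.7
    p = predict_from_posterior("x", post, prior, (-3.5, 1.0))
    p.predicted_class = cls
    p.confidence = conf_bf
    return p


def test_accuracy_by_confidence_strata():
    preds = [_pred("non", "weak") for _ in range(8)]
    truth = ["non"] * 4 + ["weak"] * 4  # 4 of 8 weak-confidence correct
    preds += [_pred("strong", "very strong") for _ in range(3)]
    truth += ["strong"] * 3
    table = accuracy_by_confidence(preds, truth)
    assert table["weak"] == {"accuracy": 50.0, "n": 8}
    assert table["very strong"] == {"accuracy": 100.0, "n": 3}
    assert sum(table[k]["n"] for k in
               ("weak", "substantial", "strong", "very strong")) == 11
    assert table["all"]["n"] == 11


# ---------------------------------------------------------------------------
# Training pipeline
# ---------------------------------------------------------------------------

def test_train_full_deterministic(realistic_train):
    hp = HyperParams.table1("A")
    b1 = train_full(realistic_train, "A", hp, seed=42)
    b2 = train_full(realistic_train, "A", hp, seed=42)
    assert json.dumps(b1.to_json()) == json.dumps(b2.to_json())


def test_train_full_separable_recovery(noiseless_train, noiseless_test):
    hp = HyperParams.table1("B")
    bundle = train_full(noiseless_train, "B", hp, seed=0)
    rep = evaluate_test(bundle, noiseless_test)
    assert rep.balanced_accuracy >= 95.0


def test_train_with_all_missing_assay_column(realistic_train):
    df = realistic_train.frame.copy()
    df["hclat_cv75"] = np.nan
    ds = Dataset(df, role="train")
    bundle = train_full(ds, "A", HyperParams.table1("A"), seed=1)
    # the unobservable node is dropped, the bundle still predicts
    assert "HCLAT_CV75" not in bundle.spec.nodes
    rep = evaluate_test(bundle, Dataset(df.head(10), role="test"))
    assert np.isfinite(rep.balanced_accuracy)


def test_bundle_json_roundtrip_predicts_identically(realistic_train,
                                                    realistic_test, tmp_path):
    bundle = train_full(realistic_train, "A", HyperParams.table1("A"), seed=3)
    path = tmp_path / "bundle.json"
    bundle.save(path)
    again = ModelBundle.load(path)
    r1 = evaluate_test(bundle, realistic_test)
    r2 = evaluate_test(again, realistic_test)
    assert r1.balanced_accuracy == pytest.approx(r2.balanced_accuracy)


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------

def test_cross_validate_partition():
    ds = generate_dataset(SimConfig(n=20, seed=31))
    rep = cross_validate(ds, "A", HyperParams.table1("A"), k=2, seed=5)
    assert rep.n == 20  # pooled predictions cover every row exactly once
    assert [f["n"] for f in rep.fold_results] == [10, 10]


def test_cross_validate_separable_recovery():
    ds = generate_dataset(SimConfig(n=120, seed=33, noiseless=True))
    rep = cross_validate(ds, "A", HyperParams.table1("A"), k=4, seed=7)
    assert rep.balanced_accuracy >= 95.0


def test_grid_search_contracts(realistic_train, realistic_test):
    singleton = {"CYTOX": [3], "CYSTEINE": [3], "HCLAT": [4], "BIOAV": [3],
                 "n_rep": [5], "pseudo_count": [1]}
    best, table = grid_search(realistic_train, realistic_test, "A",
                              grids=singleton, seed=0)
    assert len(table) == 1
    assert best.n_classes == {"CYTOX": 3, "CYSTEINE": 3, "HCLAT": 4,
                              "BIOAV": 3}

    small = {"CYTOX": [3, 4], "CYSTEINE": [3], "HCLAT": [4], "BIOAV": [3],
             "n_rep": [5], "pseudo_count": [1, 5]}
    best, table = grid_search(realistic_train, realistic_test, "A",
                              grids=small, seed=0)
    assert len(table) == 4  # product of grid sizes
    # argmax contract: the winner attains the table maximum
    hp_best = train_full(realistic_train, "A", best, seed=0)
    ba = evaluate_test(hp_best, realistic_test).balanced_accuracy
    assert ba == pytest.approx(table["balanced_accuracy"].max())


# ---------------------------------------------------------------------------
# External evaluation
# ---------------------------------------------------------------------------

def test_evaluate_external_excludes_structureless(realistic_train):
    bundle = train_full(realistic_train, "B", HyperParams.table1("B"), seed=2)
    ext = generate_dataset(SimConfig(n=128, seed=40, n_structureless=6),
                           role="external")
    rep = evaluate_external(ext, bundle, endpoint="llna4")
    assert rep.n == 122 and rep.n_excluded == 6


def test_evaluate_external_human3_mapping(realistic_train):
    """A compound predicted moderate with truth weak scores correct after
    the 4->3 collapse (moderate and weak merge)."""
    bundle = train_full(realistic_train, "B", HyperParams.table1("B"), seed=2)
    ext = generate_dataset(SimConfig(n=60, seed=41), role="external")
    rep4 = evaluate_external(ext, bundle, endpoint="llna4")
    rep3 = evaluate_external(ext, bundle, endpoint="human3")
    # collapsing classes can only help or keep accuracy
    assert rep3.overall_accuracy >= rep4.overall_accuracy - 1e-9
    assert rep3.confusion.shape == (3, 3)
    with pytest.raises(ValueError, match="endpoint"):
        evaluate_external(ext, bundle, endpoint="ghs")
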