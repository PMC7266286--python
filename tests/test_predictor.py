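"""Diagonal discriminant / shrunken-centroid classifiers and the
hierarchical subtype predictor."""

import numpy as np
import pandas as pd
import pytest

from mesohet.expression import delta_ct_normalize
from mesohet.panel import PREDICTOR_GENES, TASK_GENES
from mesohet.predictor import (DiagonalLDA, DiagonalQDA, EmptySelectionError,
                               SelectionConfig, ShrunkenCentroidClassifier,
                               SubtypePredictor, calls_to_frame,
                               select_marker_genes)


def _separable_toy(rng, n=40, gap=6.0):
    X = np.vstack([rng.normal(0.0, 1.0, size=(n, 3)),
                   rng.normal(gap, 1.0, size=(n, 3))])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


@pytest.mark.parametrize("cls", [DiagonalLDA, DiagonalQDA,
                                 lambda: ShrunkenCentroidClassifier(delta=0.0)])
def test_training_accuracy_on_separable_classes(cls):
    rng = np.random.default_rng(0)
    X, y = _separable_toy(rng)
    model = cls() if not isinstance(cls, type) else cls()
    model.fit(X, y)
    assert (model.predict(X) == y).all()
    proba = model.predict_proba(X)
    assert np.allclose(proba.sum(axis=1), 1.0)


def test_sample_at_class_mean_gets_that_class():
    rng = np.random.default_rng(1)
    X, y = _separable_toy(rng)
    for model in (DiagonalLDA(), DiagonalQDA(),
                  ShrunkenCentroidClassifier(delta=0.0)):
        model.fit(X, y)
        mean_a = X[y == "A"].mean(axis=0, keepdims=True)
        assert model.predict(mean_a)[0] == "A"
        assert model.predict_proba(mean_a)[0][0] > 0.5


def test_dlda_matches_full_lda_on_diagonal_data():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(2)
    X, y = _separable_toy(rng, gap=4.0)
    ours = DiagonalLDA().fit(X, y)
    full = LinearDiscriminantAnalysis().fit(X, y)
    Xnew = rng.normal(2.0, 2.0, size=(300, 3))
    assert (ours.predict(Xnew) == full.predict(Xnew)).mean() > 0.97


def test_shrunken_centroid_delta0_equals_standardized_centroid_oracle():
    rng = np.random.default_rng(3)
    n = 60
    X = np.vstack([rng.normal(0.0, 1.0, size=(n, 5)),
                   rng.normal(1.0, 1.5, size=(n, 5))])
    y = np.array(["A"] * n + ["B"] * n)   # balanced -> equal priors
    model = ShrunkenCentroidClassifier(delta=0.0).fit(X, y)
    # oracle: nearest centroid in (s_i + s0)-standardized coordinates
    centroids = np.vstack([X[y == k].mean(axis=0) for k in ("A", "B")])
    resid = X - centroids[(y == "B").astype(int)]
    s = np.sqrt((resid ** 2).sum(axis=0) / (len(y) - 2))
    s0 = np.median(s)
    Xnew = rng.normal(0.5, 2.0, size=(500, 5))
    d = (((Xnew[:, None, :] - centroids[None]) / (s + s0)) ** 2).sum(-1)
    oracle = np.array(["A", "B"])[np.argmin(d, axis=1)]
    assert (model.predict(Xnew) == oracle).all()


def test_shrunken_deviations_never_exceed_unshrunken():
    rng = np.random.default_rng(4)
    X, y = _separable_toy(rng, gap=2.0)
    model = ShrunkenCentroidClassifier(delta=0.5).fit(X, y)
    assert (np.abs(model.d_shrunk_) <= np.abs(model.d_) + 1e-12).all()
    assert model.delta_ == 0.5


def test_cv_delta_selection_is_deterministic_and_separates():
    rng = np.random.default_rng(5)
    X, y = _separable_toy(rng, gap=5.0)
    m1 = ShrunkenCentroidClassifier(delta="cv", random_state=7).fit(X, y)
    m2 = ShrunkenCentroidClassifier(delta="cv", random_state=7).fit(X, y)
    assert m1.delta_ == m2.delta_
    assert (m1.predict(X) == y).all()


def test_vote_symmetry_under_label_swap():
    rng = np.random.default_rng(6)
    X, y = _separable_toy(rng, gap=4.0)
    swapped = np.where(y == "A", "B", "A")
    Xnew = rng.normal(2.0, 2.0, size=(100, 3))
    for cls in (DiagonalLDA, DiagonalQDA):
        p1 = cls().fit(X, y).predict(Xnew)
        p2 = cls().fit(X, swapped).predict(Xnew)
        assert (p1 != p2).all()


def test_zero_variance_feature_floored_with_warning():
    X = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 5.0], [0.0, 6.0]])
    y = np.array(["A", "A", "B", "B"])
    with pytest.warns(RuntimeWarning):
        model = DiagonalLDA().fit(X, y)
    assert (model.predict(X) == y).all()


# ---------------------------------------------------------------------------
# marker-gene selection


def _selection_frame(rng, n=60, signal=4.0, n_noise=20):
    genes = [f"SIG_{i}" for i in range(3)] + [f"NOISE_{i}"
                                              for i in range(n_noise)]
    y = np.array(["C1"] * (n // 2) + ["C2"] * (n // 2))
    data = rng.normal(0.0, 1.0, size=(len(genes), n))
    data[:3, y == "C2"] += signal
    dct = pd.DataFrame(data, index=genes,
                       columns=[f"S{i:03d}" for i in range(n)])
    return dct, y


def test_planted_markers_are_selected():
    rng = np.random.default_rng(8)
    dct, y = _selection_frame(rng)
    cfg = SelectionConfig(n_trees=300)
    from mesohet.predictor import _select_binary
    selected = _select_binary(dct.T, y, cfg, seed=0)
    assert selected == ["SIG_0", "SIG_1", "SIG_2"]


def test_identical_distributions_raise_empty_selection():
    rng = np.random.default_rng(9)
    dct, y = _selection_frame(rng, signal=0.0)
    from mesohet.predictor import _select_binary
    with pytest.raises(EmptySelectionError):
        _select_binary(dct.T, y, SelectionConfig(n_trees=100), seed=0)


def test_auc_gate_excludes_weakly_separating_gene():
    # shift of 0.9 sd: p-value tiny at n=400 but AUC ~0.74 < 0.8
    rng = np.random.default_rng(10)
    n = 400
    y = np.array(["C1"] * (n // 2) + ["C2"] * (n // 2))
    x = rng.normal(0.0, 1.0, size=n)
    x[y == "C2"] += 0.9
    dct = pd.DataFrame(x[None, :], index=["WEAK"],
                       columns=[f"S{i}" for i in range(n)])
    from mesohet.predictor import _select_binary
    with pytest.raises(EmptySelectionError):
        _select_binary(dct.T, y, SelectionConfig(n_trees=100), seed=0)


def test_select_marker_genes_per_task(small_cohort):
    c = small_cohort
    dct = delta_ct_normalize(c.ct).dct.loc[list(PREDICTOR_GENES)]
    sel = select_marker_genes(dct, c.truth.subtype,
                              SelectionConfig(n_trees=200), random_state=0)
    # the planted class structure puts each task's markers among its genes
    assert set(sel["C1_vs_C2"]) <= set(PREDICTOR_GENES)
    assert sorted(sel) == ["C1A_vs_C1B", "C1_vs_C2", "C2A_vs_C2B"]
    assert set(sel["C1_vs_C2"]) == set(TASK_GENES["C1_vs_C2"])


# ---------------------------------------------------------------------------
# hierarchical predictor gates


def _trained_predictor(rng, n_per=20, gap=6.0):
    """Fully separable training data on the 9 predictor genes."""
    labels, cols = [], []
    data = []
    base = {"C1A": (-gap, -gap, 0), "C1B": (-gap, gap, 0),
            "C2A": (gap, 0, -gap), "C2B": (gap, 0, gap)}
    for sub, (t1, t2, t3) in base.items():
        for i in range(n_per):
            col = {}
            for g in TASK_GENES["C1_vs_C2"]:
                col[g] = rng.normal(t1, 1.0)
            for g in TASK_GENES["C1A_vs_C1B"]:
                col[g] = rng.normal(t2, 1.0)
            for g in TASK_GENES["C2A_vs_C2B"]:
                col[g] = rng.normal(t3, 1.0)
            data.append(col)
            labels.append(sub)
            cols.append(f"{sub}_{i}")
    dct = pd.DataFrame(data, index=cols).T
    labels = pd.Series(labels, index=cols)
    return SubtypePredictor(random_state=0).fit(dct, labels), dct


def test_confident_sample_gets_high_score():
    rng = np.random.default_rng(12)
    pred, dct = _trained_predictor(rng)
    call = pred.predict_one("x", dct["C1A_0"], tumor_content=80.0)
    assert call.level1 == "C1" and call.level2 == "C1A"
    assert call.score > 60 and call.score_ok
    assert call.votes["level1"] == {"dlda": "C1", "dqda": "C1", "pam": "C1"}


def test_tumor_content_gate():
    rng = np.random.default_rng(13)
    pred, dct = _trained_predictor(rng)
    call = pred.predict_one("x", dct["C1A_0"], tumor_content=25.0)
    assert call.level1 == "not_predicted"
    assert call.level2 == "not_predicted"
    assert not call.tumor_content_ok
    assert call.reason == "tumor_content_below_30"


def test_missing_marker_gene_gate():
    rng = np.random.default_rng(14)
    pred, dct = _trained_predictor(rng)
    col = dct["C1A_0"].copy()
    col["ADAM19"] = np.nan
    call = pred.predict_one("x", col, tumor_content=80.0)
    assert call.level1 == "not_predicted"
    assert call.reason == "missing_marker_gene"


def test_ambiguous_sample_is_unclassified_by_score_gate():
    rng = np.random.default_rng(15)
    pred, dct = _trained_predictor(rng)
    # a sample exactly between C1 and C2 has level-1 confidence ~0.5,
    # so the leaf score is ~50 <= 60
    mid = pd.Series(0.0, index=dct.index)
    call = pred.predict_one("x", mid, tumor_content=80.0)
    assert call.level2 == "unclassified"
    assert call.score <= 60
    assert call.reason == "score_below_60"
    assert call.level1 in ("C1", "C2")


def test_calls_frame_roundtrip():
    rng = np.random.default_rng(16)
    pred, dct = _trained_predictor(rng, n_per=5)
    content = pd.Series(80.0, index=dct.columns)
    frame = calls_to_frame(pred.predict(dct, content))
    assert len(frame) == dct.shape[1]
    assert (frame["level2"] == frame["sample_id"].str[:3]).all()


def test_unknown_labels_rejected():
    rng = np.random.default_rng(17)
    _, dct = _trained_predictor(rng, n_per=3)
    bad = pd.Series("C9X", index=dct.columns)
    with pytest.raises(ValueError):
        SubtypePredictor().fit(dct, bad)
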