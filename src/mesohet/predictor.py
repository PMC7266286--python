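"""Molecular-subtype prediction from qRT-PCR expression.

The hierarchical 9-gene predictor assigns each tumor to the two-subtype
(C1/C2) and four-subtype (C1A/C1B/C2A/C2B) transcriptomic classifications
by majority vote of three independently trained classifiers per binary
task: diagonal LDA, diagonal QDA, and a nearest-shrunken-centroid (PAM)
classifier.  Each task uses 3 marker genes.  Predictions are gated by tumor
content (>= 30%) and by a synthesized confidence score (> 60 on a 0-100
scale); the level-2 score is the mean across algorithms of the joint
posterior of the voted leaf, i.e. P(level-1 vote) x P(level-2 vote | branch).

Marker-gene selection reproduces the two-stage procedure used to build the
predictor: a differential-expression pre-filter (FDR, fold change and AUC
cutoffs) followed by backward elimination driven by random-forest
out-of-bag error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.stats.multitest import multipletests

from .panel import TASK_GENES

_VAR_FLOOR = 1e-6


class EmptySelectionError(RuntimeError):
    """No gene passes the differential-expression pre-filter."""


def _class_stats(X, y, classes):
    means = np.vstack([X[y == k].mean(axis=0) for k in classes])
    counts = np.array([(y == k).sum() for k in classes])
    return means, counts


def _floor_var(var):
    if np.any(var < _VAR_FLOOR):
        warnings.warn("zero-variance feature; variance floored",
                      RuntimeWarning, stacklevel=3)
    return np.maximum(var, _VAR_FLOOR)


class DiagonalLDA(ClassifierMixin, BaseEstimator):
    """Gaussian classifier with a pooled diagonal covariance matrix."""

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2 or np.min(
                [(y == k).sum() for k in self.classes_]) < 2:
            raise ValueError("need >=2 classes with >=2 samples each")
        self.means_, counts = _class_stats(X, y, self.classes_)
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        self.var_ = _floor_var(
            (resid ** 2).sum(axis=0) / (len(y) - len(self.classes_)))
        self.priors_ = counts / counts.sum()
        self.n_features_in_ = X.shape[1]
        return self

    def _log_posterior(self, X):
        d = ((X[:, None, :] - self.means_[None]) ** 2 / self.var_).sum(-1)
        return -0.5 * d + np.log(self.priors_)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return softmax(self._log_posterior(X), axis=1)

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]


class DiagonalQDA(ClassifierMixin, BaseEstimator):
    """Gaussian classifier with per-class diagonal covariance matrices."""

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2 or np.min(
                [(y == k).sum() for k in self.classes_]) < 2:
            raise ValueError("need >=2 classes with >=2 samples each")
        self.means_, counts = _class_stats(X, y, self.classes_)
        self.var_ = np.vstack([
            _floor_var(X[y == k].var(axis=0, ddof=1)) for k in self.classes_])
        self.priors_ = counts / counts.sum()
        self.n_features_in_ = X.shape[1]
        return self

    def _log_posterior(self, X):
        d = (((X[:, None, :] - self.means_[None]) ** 2 / self.var_[None])
             + np.log(self.var_)[None]).sum(-1)
        return -0.5 * d + np.log(self.priors_)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return softmax(self._log_posterior(X), axis=1)

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]


class ShrunkenCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest shrunken centroids (PAM).

    Standardized class-centroid deviations from the overall centroid are
    soft-thresholded at ``delta``; classification is by the shrunken-centroid
    discriminant with pooled within-class per-feature variances.  With
    ``delta="cv"`` the threshold is chosen by stratified cross-validation.

    ``selection_rule="one_se"`` (default) applies the parsimony rule of
    common shrunken-centroid practice: the largest delta whose CV error is
    within one standard error of the minimum.  ``"min"`` takes the smallest
    delta attaining the minimal CV error instead — with a handful of
    pre-selected marker genes the error curve is flat up to a cliff and
    shrinkage serves no gene-selection purpose, so the two rules give very
    similar ensemble behavior (one-SE deflates the confidence of this one
    voter rather than flipping votes).
    """

    def __init__(self, delta="cv", n_deltas: int = 30, cv: int = 5,
                 selection_rule: str = "one_se",
                 random_state: Optional[int] = None):
        self.delta = delta
        self.n_deltas = n_deltas
        self.cv = cv
        self.selection_rule = selection_rule
        self.random_state = random_state

    def _fit_at(self, X, y, delta):
        classes = unique_labels(y)
        means, counts = _class_stats(X, y, classes)
        n, n_k = len(y), counts
        resid = X - means[np.searchsorted(classes, y)]
        s = np.sqrt(_floor_var((resid ** 2).sum(axis=0) / (n - len(classes))))
        s0 = np.median(s)
        overall = X.mean(axis=0)
        m_k = np.sqrt(np.maximum(1.0 / n_k - 1.0 / n, 1e-12))
        d = (means - overall) / (m_k[:, None] * (s + s0))
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        shrunk_centroids = overall + m_k[:, None] * (s + s0) * d_shrunk
        return classes, counts, overall, s, s0, d, d_shrunk, shrunk_centroids

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = unique_labels(y)
        if len(classes) < 2 or np.min(
                [(y == k).sum() for k in classes]) < 2:
            raise ValueError("need >=2 classes with >=2 samples each")
        if self.delta == "cv":
            self.delta_ = self._select_delta(X, y)
        else:
            self.delta_ = float(self.delta)
        (self.classes_, counts, self.overall_centroid_, self.s_, self.s0_,
         self.d_, self.d_shrunk_, self.shrunken_centroids_) = self._fit_at(
            X, y, self.delta_)
        self.priors_ = counts / counts.sum()
        self.n_features_in_ = X.shape[1]
        return self

    def _select_delta(self, X, y):
        classes, counts = np.unique(y, return_counts=True)
        # candidate grid spans zero shrinkage to full shrinkage
        _, _, _, _, _, d, _, _ = self._fit_at(X, y, 0.0)
        deltas = np.linspace(0.0, np.abs(d).max(), self.n_deltas)
        n_splits = int(min(self.cv, counts.min()))
        if n_splits < 2:
            return 0.0
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=self.random_state)
        errs = np.zeros((n_splits, len(deltas)))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            for j, delta in enumerate(deltas):
                cls, cnt, _, s, s0, _, _, cent = self._fit_at(
                    X[tr], y[tr], delta)
                pred = cls[np.argmin(
                    ((X[te][:, None, :] - cent[None]) ** 2
                     / (s + s0) ** 2).sum(-1)
                    - 2 * np.log(cnt / cnt.sum()), axis=1)]
                errs[f, j] = np.mean(pred != y[te])
        mean_err = errs.mean(axis=0)
        j_min = int(np.argmin(mean_err))
        if self.selection_rule == "one_se":
            se = errs.std(axis=0, ddof=1) / np.sqrt(n_splits)
            ok = mean_err <= mean_err[j_min] + se[j_min]
            return float(deltas[np.max(np.where(ok))])
        if self.selection_rule != "min":
            raise ValueError("selection_rule must be 'min' or 'one_se'")
        # smallest delta attaining the minimum (np.argmin takes the first)
        return float(deltas[j_min])

    def _log_posterior(self, X):
        d = (((X[:, None, :] - self.shrunken_centroids_[None]) ** 2
              / (self.s_ + self.s0_) ** 2).sum(-1))
        return -0.5 * d + np.log(self.priors_)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return softmax(self._log_posterior(X), axis=1)

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]


# ---------------------------------------------------------------------------
# marker-gene selection


@dataclass(frozen=True)
class SelectionConfig:
    fdr_cutoff: float = 0.05
    abs_fold_change_cutoff: float = 1.5
    auc_cutoff: float = 0.8
    n_trees: int = 10_000
    drop_fraction: float = 0.2

    def __post_init__(self):
        for name in ("fdr_cutoff", "abs_fold_change_cutoff", "auc_cutoff",
                     "n_trees", "drop_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _select_binary(X: pd.DataFrame, y: np.ndarray, cfg: SelectionConfig,
                   seed: int) -> list[str]:
    """X: samples x genes; y: binary labels.  Returns selected gene names."""
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("binary task requires exactly two classes")
    a, b = (X[y == groups[0]], X[y == groups[1]])
    # stage 1: differential-expression pre-filter
    _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    dmean = a.mean(axis=0) - b.mean(axis=0)
    # dCt fold change: |2^(-ddCt)| > cutoff  <=>  |ddCt| > log2(cutoff)
    fc_ok = np.abs(dmean) > np.log2(cfg.abs_fold_change_cutoff)
    auc = np.array([roc_auc_score(y == groups[1], X[g]) for g in X.columns])
    auc_ok = np.maximum(auc, 1 - auc) > cfg.auc_cutoff
    keep = X.columns[(fdr < cfg.fdr_cutoff) & fc_ok & auc_ok].tolist()
    if not keep:
        raise EmptySelectionError(
            "no gene passes the FDR/fold-change/AUC pre-filter")
    # stage 2: random-forest backward elimination, one-SE smallest set
    candidates = []
    genes = list(keep)
    while True:
        rf = RandomForestClassifier(n_estimators=cfg.n_trees, oob_score=True,
                                    random_state=seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny sets can miss OOB coverage
            rf.fit(X[genes].to_numpy(), y)
        err = 1.0 - rf.oob_score_
        candidates.append((list(genes), err))
        if len(genes) <= 2:
            break
        order = np.argsort(rf.feature_importances_)
        n_drop = max(1, int(np.floor(cfg.drop_fraction * len(genes))))
        genes = [genes[i] for i in sorted(order[n_drop:])]
    n = len(y)
    best_err = min(err for _, err in candidates)
    se = np.sqrt(best_err * (1 - best_err) / n)
    eligible = [(g, e) for g, e in candidates if e <= best_err + se]
    return sorted(min(eligible, key=lambda ge: len(ge[0]))[0])


def select_marker_genes(
    dct: pd.DataFrame,
    labels: pd.Series,
    cfg: SelectionConfig = SelectionConfig(),
    random_state: Optional[int] = None,
) -> dict[str, list[str]]:
    """Marker genes per binary task from level-2 labels.

    ``dct`` is genes x samples; ``labels`` maps sample -> C1A/C1B/C2A/C2B.
    Tasks: C1 vs C2 on all samples, C1A vs C1B within C1, C2A vs C2B
    within C2.  Deterministic for a fixed ``random_state``.
    """
    seed = 0 if random_state is None else int(random_state)
    labels = labels.loc[dct.columns]
    X = dct.T
    level1 = labels.str[:2]
    out = {"C1_vs_C2": _select_binary(X, level1.to_numpy(), cfg, seed)}
    for task, branch in (("C1A_vs_C1B", "C1"), ("C2A_vs_C2B", "C2")):
        mask = (level1 == branch).to_numpy()
        out[task] = _select_binary(X[mask], labels.to_numpy()[mask], cfg,
                                   seed + 1)
    return out


# ---------------------------------------------------------------------------
# hierarchical predictor


@dataclass
class SubtypeCall:
    sample_id: str
    level1: str                  # C1 / C2 / not_predicted
    level2: str                  # C1A..C2B / unclassified / not_predicted
    score: float                 # synthesized confidence of the finest call, 0-100
    level1_score: float
    level2_score: float
    votes: dict = field(default_factory=dict)
    tumor_content_ok: bool = True
    score_ok: bool = True
    reason: str = ""


_ALGOS = ("dlda", "dqda", "pam")


class SubtypePredictor(BaseEstimator):
    """Hierarchical majority-vote subtype classifier over dCt expression.

    ``fit`` takes a genes x samples dCt matrix and level-2 labels; each of
    the three binary tasks trains DLDA, DQDA and shrunken-centroid models on
    its marker genes.  ``predict`` applies the tumor-content (>= 30%) and
    synthesized-score (> 60) gates.
    """

    def __init__(self, task_genes: Optional[dict] = None,
                 min_tumor_content: float = 30.0, min_score: float = 60.0,
                 nsc_delta="cv", random_state: Optional[int] = None):
        self.task_genes = task_genes
        self.min_tumor_content = min_tumor_content
        self.min_score = min_score
        self.nsc_delta = nsc_delta
        self.random_state = random_state

    def _fit_task(self, dct, genes, y):
        X = dct.loc[list(genes)].T.to_numpy()
        models = {
            "dlda": DiagonalLDA(),
            "dqda": DiagonalQDA(),
            "pam": ShrunkenCentroidClassifier(
                delta=self.nsc_delta, random_state=self.random_state),
        }
        for m in models.values():
            m.fit(X, y)
        return models

    def fit(self, dct: pd.DataFrame, labels: pd.Series):
        labels = labels.loc[dct.columns]
        bad = sorted(set(labels) - {"C1A", "C1B", "C2A", "C2B"})
        if bad:
            raise ValueError(f"unknown level-2 labels: {bad}")
        self.task_genes_ = dict(self.task_genes or TASK_GENES)
        level1 = labels.str[:2]
        self.models_ = {
            "C1_vs_C2": self._fit_task(dct, self.task_genes_["C1_vs_C2"],
                                       level1.to_numpy()),
        }
        for task, branch in (("C1A_vs_C1B", "C1"), ("C2A_vs_C2B", "C2")):
            mask = (level1 == branch).to_numpy()
            self.models_[task] = self._fit_task(
                dct.loc[:, dct.columns[mask]],
                self.task_genes_[task], labels.to_numpy()[mask])
        return self

    def _vote(self, task: str, x: np.ndarray) -> tuple[str, dict, dict]:
        """Majority vote; returns (label, per-algo labels, per-algo posteriors)."""
        votes, probs = {}, {}
        for name in _ALGOS:
            m = self.models_[task][name]
            p = m.predict_proba(x.reshape(1, -1))[0]
            votes[name] = str(m.classes_[int(np.argmax(p))])
            probs[name] = dict(zip((str(c) for c in m.classes_), p))
        labels, counts = np.unique(list(votes.values()), return_counts=True)
        return str(labels[np.argmax(counts)]), votes, probs

    def predict_one(self, sample_id: str, dct_col: pd.Series,
                    tumor_content: float) -> SubtypeCall:
        check_is_fitted(self, "models_")
        if tumor_content < self.min_tumor_content:
            return SubtypeCall(sample_id, "not_predicted", "not_predicted",
                               0.0, 0.0, 0.0, tumor_content_ok=False,
                               score_ok=False, reason="tumor_content_below_30")
        needed = {g for genes in self.task_genes_.values() for g in genes}
        if any(g not in dct_col.index or pd.isna(dct_col[g]) for g in needed):
            return SubtypeCall(sample_id, "not_predicted", "not_predicted",
                               0.0, 0.0, 0.0, score_ok=False,
                               reason="missing_marker_gene")
        x1 = dct_col[list(self.task_genes_["C1_vs_C2"])].to_numpy(float)
        level1, votes1, probs1 = self._vote("C1_vs_C2", x1)
        score1 = 100.0 * float(np.mean([probs1[a][level1] for a in _ALGOS]))
        task2 = "C1A_vs_C1B" if level1 == "C1" else "C2A_vs_C2B"
        x2 = dct_col[list(self.task_genes_[task2])].to_numpy(float)
        level2, votes2, probs2 = self._vote(task2, x2)
        # joint confidence of the leaf call along the hierarchy
        joint = [probs1[a][level1] * probs2[a][level2] for a in _ALGOS]
        score2 = 100.0 * float(np.mean(joint))
        score_ok = score2 > self.min_score
        return SubtypeCall(
            sample_id=sample_id, level1=level1,
            level2=level2 if score_ok else "unclassified",
            score=score2, level1_score=score1, level2_score=score2,
            votes={"level1": votes1, "level2": votes2},
            score_ok=score_ok,
            reason="" if score_ok else "score_below_60",
        )

    def predict(self, dct: pd.DataFrame,
                tumor_content: pd.Series) -> list[SubtypeCall]:
        return [
            self.predict_one(s, dct[s], float(tumor_content[s]))
            for s in dct.columns
        ]


def calls_to_frame(calls: Sequence[SubtypeCall]) -> pd.DataFrame:
    rows = [{
        "sample_id": c.sample_id, "level1": c.level1, "level2": c.level2,
        "score": round(c.score, 3), "level1_score": round(c.level1_score, 3),
        "level2_score": round(c.level2_score, 3),
        "tumor_content_ok": c.tumor_content_ok, "score_ok": c.score_ok,
        "reason": c.reason,
    } for c in calls]
    return pd.DataFrame(rows)
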