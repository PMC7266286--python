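"""Epithelioid/sarcomatoid component deconvolution (E.score, S.score).

Each tumor's signature-gene expression profile is modeled as a non-negative
mixture of fixed component centroids (epithelioid-like, sarcomatoid-like,
non-tumoral); the weights are the least-squares solution constrained to the
probability simplex.  Samples whose tumor components sum to 50% or less are
gated out; for the rest, the non-tumoral weight is removed and the scores
rescaled so E.score + S.score = 1.  S.score > 0.22 flags the
sarcomatoid-high stratum used by the survival models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import default_component_centroids


class DeconvolutionError(ValueError):
    pass


@dataclass
class MixtureEstimate:
    sample_id: str
    w_e: float
    w_s: float
    w_nt: float
    gate_passed: bool
    e_score: Optional[float]   # None when the gate fails
    s_score: Optional[float]
    s_high: Optional[bool]


def estimate_components(expr: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """argmin ||expr - centroids @ w||^2 s.t. w >= 0, sum(w) = 1.

    Solved as non-negative least squares on a sum-to-one-augmented system,
    then renormalized (exact for any profile inside the simplex hull).
    """
    centroids = np.asarray(centroids, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] < 2:
        raise DeconvolutionError("need >= 2 component centroids")
    if expr.shape[0] != centroids.shape[0]:
        raise DeconvolutionError("expression/centroid gene mismatch")
    if not (np.all(np.isfinite(expr)) and np.all(np.isfinite(centroids))):
        raise DeconvolutionError("non-finite values in deconvolution input")
    rho = 1e3 * max(np.abs(centroids).max(), 1e-12)
    a = np.vstack([centroids, rho * np.ones(centroids.shape[1])])
    b = np.concatenate([expr, [rho]])
    w, _ = nnls(a, b)
    total = w.sum()
    if total <= 0:
        raise DeconvolutionError("degenerate NNLS solution (all-zero weights)")
    return w / total


def gate_and_rescale(weights: Sequence[float],
                     sample_id: str = "",
                     gate_threshold: float = 0.5,
                     s_high_threshold: float = 0.22) -> MixtureEstimate:
    """Apply the cumulative tumor-content gate and rescale E/S scores.

    ``weights`` is (w_E, w_S, w_NT).  The gate requires w_E + w_S strictly
    above ``gate_threshold``; gated samples get E.score = w_E/(w_E+w_S) and
    S.score = w_S/(w_E+w_S).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-6:
        raise DeconvolutionError(
            f"weights must be 3 non-negative values summing to 1, got {w!r}")
    w_e, w_s, w_nt = (float(x) for x in w)
    tumor = w_e + w_s
    if tumor <= gate_threshold:
        return MixtureEstimate(sample_id, w_e, w_s, w_nt, False,
                               None, None, None)
    e_score = w_e / tumor
    s_score = w_s / tumor
    return MixtureEstimate(sample_id, w_e, w_s, w_nt, True, e_score, s_score,
                           s_score > s_high_threshold)


class MixtureDeconvolver(TransformerMixin, BaseEstimator):
    """Estimator wrapper: genes x samples expression -> per-sample scores.

    ``space="linear"`` (default) converts dCt input with 2**(-dCt) before
    fitting the mixture; ``space="dct"`` deconvolves on the dCt scale
    directly.  Samples missing more than ``max_missing_fraction`` of the
    signature genes are excluded with a reason.
    """

    def __init__(self, centroids: Optional[pd.DataFrame] = None,
                 space: str = "linear", input_scale: str = "dct",
                 gate_threshold: float = 0.5, s_high_threshold: float = 0.22,
                 max_missing_fraction: float = 0.2):
        self.centroids = centroids
        self.space = space
        self.input_scale = input_scale
        self.gate_threshold = gate_threshold
        self.s_high_threshold = s_high_threshold
        self.max_missing_fraction = max_missing_fraction

    def fit(self, X=None, y=None):
        if self.space not in ("linear", "dct"):
            raise ValueError("space must be 'linear' or 'dct'")
        cent = (self.centroids if self.centroids is not None
                else default_component_centroids())
        if cent.isna().any().any():
            raise DeconvolutionError("centroid table contains missing values")
        if set(cent.columns) != {"E", "S", "non_tumor"}:
            raise DeconvolutionError(
                "centroid columns must be named E, S, non_tumor")
        cent = cent[["E", "S", "non_tumor"]]
        self.components_ = list(cent.columns)
        if self.space == "dct":
            cent = -np.log2(cent.clip(lower=1e-12))
        self.centroids_ = cent
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        """``expr``: genes x samples, on the scale named by ``input_scale``."""
        if not hasattr(self, "centroids_"):
            self.fit()
        genes = self.centroids_.index
        rows = []
        for s in expr.columns:
            col = expr[s].reindex(genes)
            if self.input_scale == "dct" and self.space == "linear":
                col = 2.0 ** (-col)
            elif self.input_scale == "linear" and self.space == "dct":
                col = -np.log2(col.clip(lower=1e-12))
            present = col.notna()
            if (1.0 - present.mean()) > self.max_missing_fraction:
                rows.append({"sample_id": s, "excluded": True,
                             "reason": "missing_signature_genes"})
                continue
            w = estimate_components(col[present].to_numpy(),
                                    self.centroids_.loc[present.to_numpy()]
                                    .to_numpy())
            est = gate_and_rescale(w, s, self.gate_threshold,
                                   self.s_high_threshold)
            rows.append({
                "sample_id": s, "excluded": False, "reason": "",
                "w_E": est.w_e, "w_S": est.w_s, "w_NT": est.w_nt,
                "gate_passed": est.gate_passed,
                "E_score": est.e_score, "S_score": est.s_score,
                "s_high": est.s_high,
            })
        return pd.DataFrame(rows).set_index("sample_id")
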