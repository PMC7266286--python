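"""Association and survival statistics for cohort mutation analyses.

Covers the cohort-level analyses downstream of the mutation matrix:
pairwise co-occurrence/mutual-exclusivity (Fisher's exact test), mutation
vs E/S-score comparisons (two-sample t-test), TERT expression vs promoter
status (rank-based), Kaplan-Meier/log-rank survival comparisons, and
univariate/multivariate Cox proportional-hazards regression including the
combined TP53/NF2/TERT-promoter ("3-gene") mutation covariate.

Raw p-values are reported at the 0.05 level (an optional Benjamini-
Hochberg column is emitted by the pairwise scan); Cox models use Efron tie
handling (lifelines' default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    direction: str                 # co_occurring / mutually_exclusive / none
    haldane_corrected: bool = False
    locus_a: str = ""
    locus_b: str = ""


def fisher_exact(table, alpha: float = 0.05,
                 locus_a: str = "", locus_b: str = "") -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The odds ratio is the cross-product ratio, with a Haldane correction
    (+0.5 in every cell, flagged) when any cell is zero.  ``direction`` is
    set only when p < ``alpha``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table must hold non-negative integers")
        t = t.astype(int)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    haldane = bool(np.any(t == 0))
    a, b, c, d = (t + 0.5).ravel() if haldane else t.ravel().astype(float)
    orr = (a * d) / (b * c)
    direction = "none"
    if p < alpha:
        direction = "co_occurring" if orr > 1 else "mutually_exclusive"
    return ContingencyResult(table=t, odds_ratio=float(orr),
                             p_value=float(p), direction=direction,
                             haldane_corrected=haldane,
                             locus_a=locus_a, locus_b=locus_b)


def pairwise_cooccurrence(
    matrix: pd.DataFrame,
    loci: Optional[Sequence[str]] = None,
    focal: Optional[str] = "TERT_prom",
    all_pairs: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher tests of mutated/wild-type status between locus pairs.

    Default: each locus against the focal locus (self-pair excluded).
    ``all_pairs=True`` tests every unordered pair instead.  A BH-adjusted
    column is emitted alongside the raw p-values.
    """
    loci = list(loci) if loci is not None else list(matrix.columns)
    for locus in loci + ([focal] if focal and not all_pairs else []):
        if locus not in matrix.columns:
            raise KeyError(f"locus {locus!r} not in mutation matrix")
    mutated = matrix[loci + ([focal] if focal and focal not in loci
                             and not all_pairs else [])] != "WT"
    if all_pairs:
        pairs = list(itertools.combinations(loci, 2))
    else:
        pairs = [(focal, g) for g in loci if g != focal]
    rows = []
    for a, b in pairs:
        x, y = mutated[a], mutated[b]
        table = np.array([[int((x & y).sum()), int((x & ~y).sum())],
                          [int((~x & y).sum()), int((~x & ~y).sum())]])
        r = fisher_exact(table, alpha=alpha, locus_a=a, locus_b=b)
        rows.append({
            "locus_a": a, "locus_b": b,
            "n_both": table[0, 0], "n_a_only": table[0, 1],
            "n_b_only": table[1, 0], "n_neither": table[1, 1],
            "odds_ratio": r.odds_ratio, "p_value": r.p_value,
            "direction": r.direction,
            "haldane_corrected": r.haldane_corrected,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


@dataclass
class TTestResult:
    p_value: float
    t_statistic: float
    mean_mutated: float
    mean_wildtype: float
    n_mutated: int
    n_wildtype: int


def score_association_ttest(matrix: pd.DataFrame, scores: pd.Series,
                            locus: str, welch: bool = False) -> TTestResult:
    """Two-sample t-test of a per-sample score between mutated and WT tumors.

    ``scores`` (e.g. S.score or E.score) is aligned on sample id; samples
    absent from either input are dropped.  Student's equal-variance test by
    default, Welch optional.
    """
    if locus not in matrix.columns:
        raise KeyError(f"locus {locus!r} not in mutation matrix")
    common = matrix.index.intersection(scores.dropna().index)
    mut = (matrix.loc[common, locus] != "WT").to_numpy()
    vals = scores.loc[common].to_numpy(float)
    g_mut, g_wt = vals[mut], vals[~mut]
    if len(g_mut) < 2 or len(g_wt) < 2:
        raise ValueError("both groups need >= 2 samples")
    t, p = sps.ttest_ind(g_mut, g_wt, equal_var=not welch)
    return TTestResult(float(p), float(t), float(g_mut.mean()),
                       float(g_wt.mean()), len(g_mut), len(g_wt))


@dataclass
class KMResult:
    curves: dict                   # group label -> survival function DataFrame
    chi2: float
    p_value: float
    flagged: bool = False          # e.g. an all-censored group
    flag_reason: str = ""


def km_logrank(time, event, group) -> KMResult:
    """Kaplan-Meier curves per group plus the standard log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    curves = {}
    flagged, reason = False, ""
    for lab in labels:
        m = group == lab
        if event[m].sum() == 0:
            flagged, reason = True, f"group {lab!r} has no events"
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    res = multivariate_logrank_test(time, group, event)
    return KMResult(curves=curves, chi2=float(res.test_statistic),
                    p_value=float(res.p_value), flagged=flagged,
                    flag_reason=reason)


@dataclass
class SurvivalFit:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    flagged: bool = False
    flag_reason: str = ""


THREE_GENES = ("TP53", "NF2", "TERT_prom")


def three_gene_covariate(matrix: pd.DataFrame,
                         genes: Sequence[str] = THREE_GENES) -> pd.Series:
    """1 when the sample carries >= 1 mutation in TP53, NF2 or TERT_prom."""
    return (matrix[list(genes)] != "WT").any(axis=1).astype(int)


def build_survival_frame(
    clinical: pd.DataFrame,
    matrix: Optional[pd.DataFrame] = None,
    scores: Optional[pd.DataFrame] = None,
    mutation_covariate: Optional[str] = "three_gene",
    s_high_threshold: float = 0.22,
) -> pd.DataFrame:
    """Complete-case analysis frame for the Cox models.

    Columns: ``age`` when available, ``stage_iv`` (stage IV vs I-III),
    ``non_mme`` (MMB/MMS/MMD vs MME; lymphohistiocytoid excluded),
    ``s_high`` (S.score > 0.22) when scores are given, and a mutation
    indicator (a single locus name or ``"three_gene"``).
    """
    df = clinical.set_index("sample_id")
    out = pd.DataFrame(index=df.index)
    out["os_months"] = df["os_months"]
    out["os_event"] = df["os_event"]
    if "age" in df.columns:
        out["age"] = df["age"]
    out["stage_iv"] = (df["stage"] == "IV").astype(int)
    hist = df["histology"]
    out["non_mme"] = np.where(hist.isin(["MMB", "MMS", "MMD"]), 1,
                              np.where(hist == "MME", 0, np.nan))
    if scores is not None and "S_score" in scores.columns:
        s = scores["S_score"].reindex(df.index)
        out["s_high"] = (s > s_high_threshold).astype(float).where(s.notna())
    if matrix is not None and mutation_covariate is not None:
        m = matrix.reindex(df.index)
        if mutation_covariate == "three_gene":
            out["mut_3gene"] = three_gene_covariate(m).where(
                m.notna().all(axis=1))
        else:
            out[f"mut_{mutation_covariate}"] = (
                (m[mutation_covariate] != "WT").astype(float)
                .where(m[mutation_covariate].notna()))
    return out.dropna()


def cox_regression(
    frame: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    duration_col: str = "os_months",
    event_col: str = "os_event",
) -> dict[str, dict[str, SurvivalFit]]:
    """Univariate and multivariate Cox proportional-hazards fits.

    Returns ``{"univariate": {cov: fit}, "multivariate": {cov: fit}}`` with
    hazard ratios, Wald 95% CIs and p-values.  Non-convergence is flagged,
    never silently dropped.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in frame.columns if c not in (duration_col, event_col)]
    if frame[event_col].sum() < 1:
        raise ValueError("no events in the survival frame")

    def _fit(cols) -> dict[str, SurvivalFit]:
        sub = frame[[duration_col, event_col] + list(cols)]
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(sub, duration_col=duration_col, event_col=event_col)
        except (ConvergenceError, ValueError) as exc:
            return {c: SurvivalFit(c, float("nan"), float("nan"),
                                   float("nan"), float("nan"), len(sub),
                                   int(sub[event_col].sum()), True, str(exc))
                    for c in cols}
        s = cph.summary
        return {
            c: SurvivalFit(
                covariate=c,
                hazard_ratio=float(s.loc[c, "exp(coef)"]),
                ci_low=float(s.loc[c, "exp(coef) lower 95%"]),
                ci_high=float(s.loc[c, "exp(coef) upper 95%"]),
                p_value=float(s.loc[c, "p"]),
                n=len(sub), n_events=int(sub[event_col].sum()))
            for c in cols
        }

    uni = {}
    for c in covariates:
        uni.update(_fit([c]))
    multi = _fit(covariates) if len(covariates) > 1 else dict(uni)
    return {"univariate": uni, "multivariate": multi}


@dataclass
class TertExpressionResult:
    p_value: float
    median_dct_mutated: float
    median_dct_wildtype: float
    direction: str                 # higher expression side (lower dCt)
    n_mutated: int
    n_wildtype: int
    flagged: bool = False


def tert_expression_test(tert_dct: pd.Series,
                         tert_status: pd.Series) -> TertExpressionResult:
    """Rank-based two-sample test of TERT dCt by promoter mutation status.

    Lower dCt means higher expression; promoter-mutant tumors are expected
    to express more TERT.  Groups under 3 samples are flagged.
    """
    common = tert_dct.dropna().index.intersection(tert_status.dropna().index)
    x = tert_dct.loc[common].to_numpy(float)
    mut = tert_status.loc[common].astype(bool).to_numpy()
    g_mut, g_wt = x[mut], x[~mut]
    if len(g_mut) == 0 or len(g_wt) == 0:
        raise ValueError("both promoter-status groups must be non-empty")
    flagged = min(len(g_mut), len(g_wt)) < 3
    _, p = sps.mannwhitneyu(g_mut, g_wt, alternative="two-sided")
    med_m, med_w = float(np.median(g_mut)), float(np.median(g_wt))
    direction = ("higher_in_mutant" if med_m < med_w else
                 "higher_in_wildtype" if med_w < med_m else "none")
    return TertExpressionResult(float(p), med_m, med_w, direction,
                                len(g_mut), len(g_wt), flagged)
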