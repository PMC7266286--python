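"""Association and survival statistics against closed-form and
enumeration oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from mesohet.stats import (build_survival_frame, cox_regression, fisher_exact,
                           km_logrank, pairwise_cooccurrence,
                           score_association_ttest, tert_expression_test,
                           three_gene_covariate)


def oracle_fisher_p(a, b, c, d) -> float:
    """Exact two-sided p by hypergeometric enumeration in integer arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    wa = comb(r1, a) * comb(r2, c)
    s = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        # match the standard small relative slack for floating-point ties
        if w * 10**7 <= wa * (10**7 + 1):
            s += w
    return float(Fraction(s, comb(n, c1)))


def test_fisher_trivial_and_enumerated_examples():
    assert fisher_exact([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)
    r = fisher_exact([[5, 0], [0, 5]])
    assert r.p_value == pytest.approx(2 / 252, rel=1e-12)
    assert r.haldane_corrected
    assert r.direction == "co_occurring"
    r2 = fisher_exact([[0, 10], [10, 0]])
    assert r2.direction == "mutually_exclusive"


def test_fisher_matches_enumeration_oracle_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(300):
        t = rng.integers(0, 16, size=4)
        p = fisher_exact(t.reshape(2, 2)).p_value
        po = oracle_fisher_p(*t)
        assert p == pytest.approx(po, rel=1e-9, abs=1e-12)


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [0, 2]])
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 1], [0, 2]])
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])


def _matrix_from_bools(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.replace({True: "M1", False: "WT"})


def test_pairwise_cooccurrence_directions_and_self_exclusion():
    n = 60
    a = np.zeros(n, dtype=bool)
    a[:20] = True
    frame = pd.DataFrame({
        "TERT_prom": a,
        "NF2": a,                      # perfectly co-occurring
        "BAP1": ~a,                    # perfectly exclusive
    }, index=[f"S{i}" for i in range(n)])
    res = pairwise_cooccurrence(_matrix_from_bools(frame),
                                loci=["NF2", "BAP1", "TERT_prom"])
    assert set(res["locus_b"]) == {"NF2", "BAP1"}   # self-pair excluded
    by = res.set_index("locus_b")
    assert by.at["NF2", "direction"] == "co_occurring"
    assert by.at["BAP1", "direction"] == "mutually_exclusive"
    assert "p_bh" in res.columns
    with pytest.raises(KeyError):
        pairwise_cooccurrence(_matrix_from_bools(frame), loci=["GHOST"])


def test_ttest_matches_hand_computed_toy():
    # groups {1..5} vs {2..6}: means 3 and 4, pooled se = 1 -> t = -1, df = 8
    frame = pd.DataFrame({"G": [True] * 5 + [False] * 5},
                         index=[f"S{i}" for i in range(10)])
    scores = pd.Series([1, 2, 3, 4, 5, 2, 3, 4, 5, 6], dtype=float,
                       index=frame.index)
    r = score_association_ttest(_matrix_from_bools(frame), scores, "G")
    assert r.t_statistic == pytest.approx(-1.0)
    assert r.p_value == pytest.approx(2 * sps.t.sf(1.0, 8), rel=1e-12)
    assert (r.mean_mutated, r.mean_wildtype) == (3.0, 4.0)


def test_ttest_identical_groups_and_small_group_error():
    frame = pd.DataFrame({"G": [True] * 3 + [False] * 3},
                         index=[f"S{i}" for i in range(6)])
    scores = pd.Series([0.1, 0.2, 0.3] * 2, index=frame.index)
    r = score_association_ttest(_matrix_from_bools(frame), scores, "G")
    assert r.p_value == pytest.approx(1.0)
    small = pd.DataFrame({"G": [True] + [False] * 5},
                         index=[f"S{i}" for i in range(6)])
    with pytest.raises(ValueError):
        score_association_ttest(_matrix_from_bools(small), scores, "G")


def test_km_closed_form_no_censoring():
    # n distinct death times: survival after the k-th death is (n-k)/n
    time = np.array([3.0, 1.0, 4.0, 2.0, 5.0, 1.5, 2.5, 3.5, 4.5, 5.5])
    event = np.ones_like(time, dtype=int)
    group = np.array(["A"] * 5 + ["B"] * 5)
    res = km_logrank(time, event, group)
    surv = res.curves["A"].iloc[:, 0]
    n = 5
    expected = [(n - k) / n for k in range(1, n + 1)]
    assert surv.loc[surv.index > 0].tolist() == pytest.approx(expected)


def test_km_logrank_identical_groups_and_flag():
    time = np.array([2.0, 3.0, 5.0, 7.0] * 2)
    event = np.array([1, 1, 0, 1] * 2)
    group = np.array(["A"] * 4 + ["B"] * 4)
    res = km_logrank(time, event, group)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    # an all-censored group is flagged but still gets a curve
    res2 = km_logrank(np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 0]),
                      np.array(["A", "A", "B", "B"]))
    assert res2.flagged and "B" in res2.flag_reason
    with pytest.raises(ValueError):
        km_logrank(np.array([-1.0, 2]), np.array([1, 1]),
                   np.array(["A", "B"]))


def test_logrank_power_on_hazard_ratio_two():
    rng = np.random.default_rng(7)
    n = 200
    t1 = rng.exponential(1 / 0.05, size=n)
    t2 = rng.exponential(1 / 0.10, size=n)
    time = np.concatenate([t1, t2])
    event = np.ones(2 * n, dtype=int)
    group = np.array(["WT"] * n + ["M"] * n)
    assert km_logrank(time, event, group).p_value < 0.05


def _survival_df(rng, n=2000, beta=0.0, p_mut=0.3):
    x = (rng.random(n) < p_mut).astype(int)
    lam = 0.035 * np.exp(beta * x)
    T = rng.exponential(1 / lam)
    C = np.full(n, 80.0)
    return pd.DataFrame({
        "os_months": np.minimum(T, C),
        "os_event": (T <= C).astype(int),
        "mut": x.astype(float),
    })


def test_cox_null_hazard_ratio_near_one():
    df = _survival_df(np.random.default_rng(8), beta=0.0)
    fit = cox_regression(df, covariates=["mut"])["univariate"]["mut"]
    assert 0.8 <= fit.hazard_ratio <= 1.25
    assert fit.ci_low <= fit.hazard_ratio <= fit.ci_high


def test_cox_recovers_planted_hazard_ratio():
    df = _survival_df(np.random.default_rng(9), beta=np.log(2.0))
    fit = cox_regression(df, covariates=["mut"])["univariate"]["mut"]
    assert fit.ci_low <= 2.0 <= fit.ci_high


def test_cox_flags_degenerate_covariate():
    df = _survival_df(np.random.default_rng(10), n=50)
    df["flat"] = 1.0    # zero-variance covariate cannot converge
    fits = cox_regression(df, covariates=["flat"])
    assert fits["univariate"]["flat"].flagged


def test_three_gene_covariate_or_of_indicators():
    m = pd.DataFrame({"TP53": ["WT", "WT"], "NF2": ["M1", "WT"],
                      "TERT_prom": ["WT", "WT"]}, index=["A", "B"])
    cov = three_gene_covariate(m)
    assert cov.tolist() == [1, 0]


def test_build_survival_frame_complete_case():
    clinical = pd.DataFrame({
        "sample_id": ["A", "B", "C"],
        "histology": ["MME", "MMS", "lympho"],   # lympho excluded from binary
        "tumor_content_pct": [80, 60, 70],
        "asbestos": ["exposed"] * 3,
        "stage": ["II", "IV", "III"],
        "os_months": [10.0, 5.0, 8.0],
        "os_event": [1, 1, 0],
    })
    matrix = pd.DataFrame({"TP53": ["M1", "WT", "WT"],
                           "NF2": ["WT", "WT", "WT"],
                           "TERT_prom": ["WT", "M1", "WT"]},
                          index=["A", "B", "C"])
    scores = pd.DataFrame({"S_score": [0.1, 0.5, 0.3]},
                          index=["A", "B", "C"])
    frame = build_survival_frame(clinical, matrix, scores)
    assert list(frame.index) == ["A", "B"]
    assert frame.at["A", "mut_3gene"] == 1
    assert frame.at["B", "stage_iv"] == 1
    assert frame.at["B", "s_high"] == 1.0
    assert frame.at["A", "non_mme"] == 0


def test_tert_expression_rank_test_detects_planted_shift():
    rng = np.random.default_rng(11)
    idx = [f"S{i}" for i in range(260)]
    status = pd.Series([True] * 30 + [False] * 230, index=idx)
    dct = pd.Series(np.where(status, rng.normal(6.0, 1.0, 260),
                             rng.normal(8.0, 1.0, 260)), index=idx)
    r = tert_expression_test(dct, status)
    assert r.p_value < 1e-6
    assert r.direction == "higher_in_mutant"
    tiny = tert_expression_test(dct.iloc[28:40], status.iloc[28:40])
    assert tiny.flagged
    with pytest.raises(ValueError):
        tert_expression_test(dct, pd.Series(True, index=idx))
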