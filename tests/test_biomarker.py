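"""Biomarker statistics: CIs, quadrants, Fisher, AUC, DCB, survival."""

import math
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chaoscope import biomarker as bm


# ---------------------------------------------------------------------------
# proportion confidence intervals

# printed clinical intervals (percent, 2 dp) reproduced from their counts
PRINTED_CIS = [
    (5, 15, "wald", 9.48, 57.19),
    (1, 15, "wilson", 1.19, 29.82),
    (11, 16, "wald", 46.04, 91.46),
    (12, 16, "wald", 53.78, 96.22),
    (11, 12, "wald", 76.03, 107.30),
    (14, 44, "wald", 18.06, 45.58),
    (8, 45, "wald", 6.62, 28.94),
]


@pytest.mark.parametrize("k,n,method,lo,hi", PRINTED_CIS)
def test_response_rate_ci_reproduces_printed_bounds(k, n, method, lo, hi):
    ci = bm.response_rate_ci(k, n, method=method)
    _, lo_pct, hi_pct = ci.as_percent(2)
    assert lo_pct == pytest.approx(lo, abs=0.01)
    assert hi_pct == pytest.approx(hi, abs=0.01)


def test_wald_unclipped_wilson_bounded():
    # Wald can exceed [0, 1]; Wilson never does
    assert bm.response_rate_ci(11, 12, "wald").upper > 1.0
    assert bm.response_rate_ci(0, 11, "wald").lower <= 0.0
    assert bm.response_rate_ci(1, 11, "wald").lower < 0.0
    w = bm.response_rate_ci(0, 10, "wilson")
    assert w.lower == 0.0 and 0.0 <= w.upper <= 1.0


@pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (10, 10), (7, 30)])
@pytest.mark.parametrize("method", ["wald", "wilson"])
def test_ci_contains_point_estimate(k, n, method):
    ci = bm.response_rate_ci(k, n, method)
    assert ci.lower <= ci.p_hat <= ci.upper


def test_ci_width_shrinks_with_n():
    widths = [
        bm.response_rate_ci(n // 3, n, "wilson").upper
        - bm.response_rate_ci(n // 3, n, "wilson").lower
        for n in (10, 100, 1000, 10000)
    ]
    assert widths == sorted(widths, reverse=True)
    assert widths[-1] < 0.02


def test_ci_invalid_inputs():
    with pytest.raises(ValueError):
        bm.response_rate_ci(1, 0)
    with pytest.raises(ValueError):
        bm.response_rate_ci(5, 3)


# ---------------------------------------------------------------------------
# threshold derivation and quadrants

def test_group_threshold_linear_interpolation():
    # order-statistic interpolation on 1..100 at q=0.8
    assert bm.derive_group_threshold(range(1, 101), 0.8) == pytest.approx(80.2)


def test_group_threshold_edge_cases():
    assert bm.derive_group_threshold([7.0] * 6) == 7.0
    assert bm.derive_group_threshold([1, 5, 3, 9, 2], q=1.0) == 9.0
    with pytest.raises(ValueError):
        bm.derive_group_threshold([1, 2, 3, 4])  # too few healthy donors


NSCLC = bm.BiomarkerThresholds.for_disease("NSCLC")


@pytest.mark.parametrize("dn,dp,expected", [
    (30.0, 10.0, "Q4"),   # both low: predicted best responders
    (40.0, 10.0, "Q1"),
    (40.0, 20.0, "Q2"),
    (30.0, 20.0, "Q3"),
    (36.0, 17.2, "Q2"),   # boundary: >= threshold is hi
    (35.99, 17.2, "Q3"),
    (36.0, 17.19, "Q1"),
])
def test_quadrant_assignment(dn, dp, expected):
    assert bm.assign_quadrant(dn, dp, NSCLC) == expected


def test_quadrant_map_total_on_grid():
    # exactly one quadrant for every point of the plane
    for dn in np.linspace(0, 100, 21):
        for dp in np.linspace(0, 100, 21):
            assert bm.assign_quadrant(dn, dp, NSCLC) in bm.QUADRANTS


def test_disease_defaults():
    sclc = bm.BiomarkerThresholds.for_disease("SCLC")
    assert (sclc.dn_tem, sclc.dp_temra) == (42.0, 11.0)
    assert (NSCLC.dn_tem, NSCLC.dp_temra) == (36.0, 17.2)
    with pytest.raises(ValueError):
        bm.BiomarkerThresholds.for_disease("melanoma")


def test_assign_quadrants_drops_missing():
    df = pd.DataFrame({
        "donor_id": ["a", "b"],
        "dn_tem_pct": [30.0, np.nan],
        "dp_temra_pct": [10.0, 10.0],
    })
    with pytest.warns(UserWarning):
        q = bm.assign_quadrants(df, NSCLC)
    assert list(q) == ["Q4"]


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_oracle(a, b, c, d):
    """Two-sided p by exhaustive enumeration over fixed-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def test_fisher_no_association():
    assert bm.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_extreme_table_closed_form():
    # both extreme tables have probability 1/C(20,10)
    assert bm.fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
        2 / comb(20, 10), rel=1e-9
    )


def test_fisher_matches_enumeration_random_tables():
    rng = np.random.default_rng(7)
    for _ in range(200):
        t = rng.integers(0, 9, size=4)
        if t[:2].sum() == 0 or t[2:].sum() == 0 or t[0] + t[2] == 0 or t[1] + t[3] == 0:
            continue
        expected = fisher_oracle(*t)
        assert bm.fisher_exact_2x2(t.reshape(2, 2)) == pytest.approx(expected, rel=1e-9)


def test_fisher_zero_margin_warns():
    with pytest.warns(UserWarning):
        assert bm.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


# ---------------------------------------------------------------------------
# ROC AUC

def auc_pairwise_oracle(scores, labels):
    """O(n^2) count of concordant pairs, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_separation():
    scores = [10, 12, 14, 50, 55, 60]   # low DN-Tem -> responder
    labels = [True, True, True, False, False, False]
    assert bm.roc_auc(scores, labels) == pytest.approx(1.0)


def test_auc_matches_pairwise_oracle_with_ties():
    rng = np.random.default_rng(11)
    for _ in range(200):
        scores = rng.integers(0, 6, size=12).astype(float)  # heavy ties
        labels = rng.random(12) < 0.5
        if labels.all() or not labels.any():
            continue
        expected = auc_pairwise_oracle(-scores, labels)  # negated orientation
        assert bm.roc_auc(scores, labels) == pytest.approx(expected, rel=1e-12)


def test_auc_independent_scores_near_half():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=4000)
    labels = rng.random(4000) < 0.5
    assert bm.roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        bm.roc_auc([1.0, 2.0], [True, True])


def test_auc_hanley_mcneil_ci_brackets_estimate():
    auc, lo, hi = bm.roc_auc([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0], ci=True)
    assert lo < auc < hi


# ---------------------------------------------------------------------------
# DCB

@pytest.mark.parametrize("resp,expected", [
    ("PR", True), ("SD", True), ("CR", True), ("PD", False),
    ("NA", None), (None, None), (float("nan"), None),
])
def test_derive_dcb(resp, expected):
    assert bm.derive_dcb(resp) is expected


# ---------------------------------------------------------------------------
# Kaplan-Meier / Gehan-Breslow-Wilcoxon

def test_gbw_identical_groups_null():
    times = [5, 10, 15, 20, 5, 10, 15, 20]
    events = [1, 1, 1, 1, 1, 1, 1, 1]
    groups = ["a"] * 4 + ["b"] * 4
    stat, p, curves = bm.km_gehan_breslow_wilcoxon(times, events, groups,
                                                  permutation=False)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p > 0.99
    assert set(curves) == {"a", "b"}


def test_km_uncensored_equals_empirical_survival():
    times = [1, 2, 3, 4, 5]
    _, _, curves = bm.km_gehan_breslow_wilcoxon(
        times + [1, 2, 3, 4, 5], [1] * 10, ["a"] * 5 + ["b"] * 5, permutation=False
    )
    km = curves["a"].iloc[:, 0]
    for i, t in enumerate(times):
        assert km.loc[t] == pytest.approx(1.0 - (i + 1) / 5)


def test_gbw_exhaustive_permutation_extreme():
    """One group all early events, other all late-censored: only the two
    labelings splitting the samples exactly reach the observed statistic."""
    times = [1, 1, 1, 1, 10, 10, 10, 10]
    events = [1, 1, 1, 1, 0, 0, 0, 0]
    groups = ["a"] * 4 + ["b"] * 4
    stat, p, _ = bm.km_gehan_breslow_wilcoxon(times, events, groups,
                                              permutation=True)
    assert stat > 0
    # oracle: directly count arrangements with statistic >= observed
    ge = total = 0
    for pos in combinations(range(8), 4):
        lab = np.array(["b"] * 8); lab[list(pos)] = "a"
        s = bm._gbw_statistic(np.array(times, float), np.array(events, bool), lab)
        total += 1
        ge += s >= stat - 1e-12
    assert p == pytest.approx(ge / total)
    assert ge == 2  # the split and its mirror


def test_gbw_requires_events_and_groups():
    with pytest.raises(ValueError):
        bm.km_gehan_breslow_wilcoxon([1, 2], [1, 1], ["a", "a"])
    with pytest.raises(ValueError):
        bm.km_gehan_breslow_wilcoxon([1, 2], [0, 0], ["a", "b"])


# ---------------------------------------------------------------------------
# end-to-end evaluation

def _profiles_outcomes(n_per_quadrant, pr_rates, seed=0):
    """Synthetic donors placed at quadrant-representative frequencies."""
    rng = np.random.default_rng(seed)
    coords = {"Q1": (60, 5), "Q2": (60, 30), "Q3": (20, 30), "Q4": (20, 5)}
    prows, orows = [], []
    i = 0
    for q, (dn, dp) in coords.items():
        for _ in range(n_per_quadrant):
            donor = f"D{i:05d}"; i += 1
            prows.append({"donor_id": donor, "dn_tem_pct": dn + rng.normal(0, 2),
                          "dp_temra_pct": dp + rng.normal(0, 1)})
            pr = rng.random() < pr_rates[q]
            orows.append({"donor_id": donor, "best_response": "PR" if pr else "PD",
                          "response_6m": "PR" if pr else "PD"})
    return pd.DataFrame(prows), pd.DataFrame(orows)


def test_evaluate_biomarker_recovers_configured_rates():
    rates = {"Q1": 0.18, "Q2": 0.1, "Q3": 0.1, "Q4": 0.45}
    profiles, outcomes = _profiles_outcomes(300, rates, seed=3)
    res = bm.evaluate_biomarker(profiles, outcomes, NSCLC)
    for q in ("Q1", "Q4"):
        ci = res.pr_rates[q]["wilson"]
        assert ci.lower <= rates[q] <= ci.upper
    assert res.fisher_pr_q4_vs_q1 < 1e-3
    assert res.auc_dn_tem_pr > 0.5


def test_evaluate_biomarker_single_donor_quadrant():
    profiles = pd.DataFrame({
        "donor_id": ["a", "b"],
        "dn_tem_pct": [20.0, 60.0],
        "dp_temra_pct": [5.0, 5.0],
    })
    outcomes = pd.DataFrame({
        "donor_id": ["a", "b"],
        "best_response": ["PR", "PD"],
        "response_6m": ["PR", "PD"],
    })
    with pytest.warns(UserWarning):  # empty quadrants flagged
        res = bm.evaluate_biomarker(profiles, outcomes, NSCLC)
    ci = res.pr_rates["Q4"]["wilson"]
    assert ci.n == 1 and ci.p_hat == 1.0 and 0 <= ci.lower <= 1

def test_pooled_fisher_across_cohorts():
    rates = {"Q1": 0.18, "Q2": 0.1, "Q3": 0.1, "Q4": 0.45}
    results = []
    for seed in (1, 2, 3):
        profiles, outcomes = _profiles_outcomes(40, rates, seed=seed)
        results.append(bm.evaluate_biomarker(profiles, outcomes, NSCLC))
    pooled = bm.pooled_fisher_q4_vs_q1(results)
    assert 0 <= pooled <= 1
    # pooling three cohorts is at least as powerful as the weakest single one
    assert pooled <= max(r.fisher_pr_q4_vs_q1 for r in results)
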