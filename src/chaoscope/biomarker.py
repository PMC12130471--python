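"""Quadrant biomarker evaluation for ICI response prediction.

The biomarker uses two pre-treatment frequencies measured in peripheral
blood CD8+ T cells: the CD27-CD28- fraction of effector memory cells
(DN-Tem, within Tem) and the CD27+CD28+ fraction of Temra (DP-Temra,
within Temra).  Two thresholds split the (DN-Tem, DP-Temra) plane into
four quadrants; donors with both frequencies low (Q4) are predicted to
respond best to anti-PD-(L)1 therapy.

The module provides threshold derivation from a healthy reference
distribution, quadrant assignment, binomial proportion confidence
intervals (unclipped Wald and Wilson), Fisher's exact test, midrank ROC
AUC, durable-clinical-benefit derivation, Kaplan-Meier curves with the
Gehan-Breslow-Wilcoxon test, and a one-call evaluation that ties these
together.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BiomarkerThresholds",
    "ProportionCI",
    "BiomarkerResult",
    "derive_group_threshold",
    "assign_quadrant",
    "assign_quadrants",
    "response_rate_ci",
    "fisher_exact_2x2",
    "roc_auc",
    "derive_dcb",
    "km_gehan_breslow_wilcoxon",
    "evaluate_biomarker",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

#: Default thresholds (percent scale) per disease context.
DISEASE_DEFAULTS = {
    "NSCLC": (36.0, 17.2),
    "SCLC": (42.0, 11.0),
}


@dataclass(frozen=True)
class BiomarkerThresholds:
    """Positivity thresholds (percent, within-parent frequencies).

    ``dn_tem`` applies to the DN-Tem fraction of Tem; ``dp_temra`` to
    the DP fraction of Temra.  A donor is "hi" on an axis when its
    value is >= the threshold.
    """

    dn_tem: float
    dp_temra: float
    disease_context: str = "NSCLC"
    derivation: str = "fixed"

    def __post_init__(self) -> None:
        for name, v in (("dn_tem", self.dn_tem), ("dp_temra", self.dp_temra)):
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} threshold must be in (0, 100), got {v}")

    @classmethod
    def for_disease(cls, disease: str) -> "BiomarkerThresholds":
        try:
            dn, dp = DISEASE_DEFAULTS[disease]
        except KeyError:
            raise ValueError(
                f"unknown disease context {disease!r}; known: {sorted(DISEASE_DEFAULTS)}"
            ) from None
        return cls(dn, dp, disease_context=disease)


def derive_group_threshold(healthy_values, q: float = 0.8) -> float:
    """Empirical q-quantile of a healthy reference distribution.

    Donors at or above the returned value are called "hi", i.e. higher
    than most (a fraction q) of healthy individuals.  Linear
    interpolation between order statistics.
    """
    values = np.asarray(list(healthy_values), dtype=float)
    if values.size < 5:
        raise ValueError(
            f"need >= 5 healthy values to derive a stable threshold, got {values.size}"
        )
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be a probability, got {q}")
    return float(np.quantile(values, q, method="linear"))


def assign_quadrant(dn_tem: float, dp_temra: float, thr: BiomarkerThresholds) -> str:
    """Map one donor's (DN-Tem %, DP-Temra %) to a quadrant.

    Q1: DP-Temra lo / DN-Tem hi;  Q2: hi/hi;  Q3: DP-Temra hi / DN-Tem lo;
    Q4: lo/lo (predicted best responders).  Boundary rule: >= threshold
    is hi.
    """
    if not (0.0 <= dn_tem <= 100.0 and 0.0 <= dp_temra <= 100.0):
        raise ValueError("frequencies must be percentages in [0, 100]")
    dn_hi = dn_tem >= thr.dn_tem
    temra_hi = dp_temra >= thr.dp_temra
    if temra_hi:
        return "Q2" if dn_hi else "Q3"
    return "Q1" if dn_hi else "Q4"


def assign_quadrants(
    profiles: pd.DataFrame,
    thr: BiomarkerThresholds,
    dn_col: str = "dn_tem_pct",
    dp_col: str = "dp_temra_pct",
) -> pd.Series:
    """Vectorised quadrant assignment; donors with missing values dropped."""
    sub = profiles[[dn_col, dp_col]]
    ok = sub.notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} donor(s) excluded from quadrant assignment "
            "(missing frequency)"
        )
    out = sub.loc[ok].apply(lambda r: assign_quadrant(r[dn_col], r[dp_col], thr), axis=1)
    out.name = "quadrant"
    return out


# z for a 95% two-sided normal interval
_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its confidence interval.

    ``lower``/``upper`` are on the proportion (0-1) scale.  Wald bounds
    are deliberately not clipped to [0, 1] (the normal approximation
    can exceed them); Wilson bounds always lie inside [0, 1].
    """

    successes: int
    n: int
    p_hat: float
    lower: float
    upper: float
    method: str
    level: float = 0.95

    def as_percent(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(rate, lower, upper) on the 0-100 scale, rounded."""
        return (
            round(100.0 * self.p_hat, ndigits),
            round(100.0 * self.lower, ndigits),
            round(100.0 * self.upper, ndigits),
        )


def response_rate_ci(
    successes: int, n: int, method: str = "wald", level: float = 0.95
) -> ProportionCI:
    """Binomial proportion CI by the Wald (unclipped) or Wilson method."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError(f"successes must be in [0, n], got {successes}/{n}")
    p = successes / n
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    if method == "wald":
        half = z * math.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
        # guard against float round-off at the degenerate corners
        lo = min(max(float(lo), 0.0), p)
        hi = max(min(float(hi), 1.0), p)
    else:
        raise ValueError(f"unknown CI method {method!r} (use 'wald' or 'wilson')")
    return ProportionCI(successes, n, p, lo, hi, method, level)


def fisher_exact_2x2(table, method: str = "prob") -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    ``method='prob'`` (default) sums hypergeometric probabilities of
    all tables with the same margins that are no more probable than the
    observed one — the standard exact convention.  ``method='doubling'``
    doubles the smaller one-sided tail (capped at 1).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("a margin of the 2x2 table is zero; p set to 1")
        return 1.0
    if method == "prob":
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    if method == "doubling":
        p_less = stats.fisher_exact(t, alternative="less")[1]
        p_greater = stats.fisher_exact(t, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(p_less, p_greater)))
    raise ValueError(f"unknown method {method!r}")


def roc_auc(
    scores,
    labels,
    negate: bool = True,
    ci: bool = False,
    level: float = 0.95,
):
    """ROC AUC by the midrank (Mann-Whitney) formula.

    ``scores`` are per-donor DN-Tem frequencies and ``labels`` the PR
    flags.  Because a *lower* DN-Tem frequency predicts response, the
    scores are negated internally by default so that AUC > 0.5 means
    discriminative in the expected direction.  With ``ci=True`` the
    Hanley-McNeil standard-error interval is returned as
    ``(auc, lower, upper)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    if negate:
        s = -s
    ranks = stats.rankdata(s)  # midranks handle ties
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    auc = float(auc)
    if not ci:
        return auc
    # Hanley & McNeil (1982) SE
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = math.sqrt(
        (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
        / (n1 * n0)
    )
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return auc, auc - z * se, auc + z * se


_DCB_POSITIVE = {"CR", "PR", "SD"}


def derive_dcb(response_at_6m) -> bool | None:
    """Durable clinical benefit: PR or SD maintained at 6 months.

    CR counts as better-than-PR, hence benefit.  Missing 6-month
    response yields ``None`` (unknown), never ``False``.
    """
    if response_at_6m is None or (isinstance(response_at_6m, float) and math.isnan(response_at_6m)):
        return None
    r = str(response_at_6m).strip().upper()
    if r in ("", "NA", "NAN", "NONE"):
        return None
    if r in _DCB_POSITIVE:
        return True
    if r == "PD":
        return False
    raise ValueError(f"unrecognised 6-month response {response_at_6m!r}")


def _gbw_statistic(times, events, groups) -> float:
    """Gehan-Breslow-Wilcoxon chi-square statistic via lifelines."""
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(times, groups, events, weightings="wilcoxon")
    return float(res.test_statistic)


def km_gehan_breslow_wilcoxon(
    times,
    events,
    group_labels,
    permutation: bool | None = None,
    max_exact_permutations: int = 20000,
    n_random_permutations: int = 5000,
    seed: int = 0,
):
    """Kaplan-Meier curves and the Gehan-Breslow-Wilcoxon test.

    The test is the log-rank family member weighting each event time by
    the number at risk, making it sensitive to early differences.
    Returns ``(statistic, p, curves)`` where ``curves`` maps group
    label to a survival-function DataFrame.

    ``permutation=None`` picks a permutation p automatically for small
    samples (n < 30); the permutation distribution is enumerated
    exhaustively when the number of distinct label arrangements allows,
    otherwise sampled.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group_labels)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need >= 2 groups")
    if not e.any():
        raise ValueError("need >= 1 event")

    curves: dict = {}
    for lab in labels:
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == lab], event_observed=e[g == lab], label=str(lab))
        curves[lab] = kmf.survival_function_

    observed = _gbw_statistic(t, e, g)
    if permutation is None:
        permutation = t.size < 30

    if not permutation:
        p = float(stats.chi2.sf(observed, df=labels.size - 1))
        return observed, p, curves

    n = t.size
    counts = [int((g == lab).sum()) for lab in labels]
    n_arrangements = math.factorial(n)
    for c in counts:
        n_arrangements //= math.factorial(c)
    if n_arrangements <= max_exact_permutations:
        # enumerate all assignments of positions to groups
        ge = max_count = 0
        positions = range(n)
        base = np.empty(n, dtype=labels.dtype)
        for combo in _label_arrangements(positions, counts):
            for lab_idx, pos in enumerate(combo):
                base[list(pos)] = labels[lab_idx]
            stat = _gbw_statistic(t, e, base)
            max_count += 1
            if stat >= observed - 1e-12:
                ge += 1
        p = ge / max_count
    else:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_random_permutations):
            perm = rng.permutation(g)
            if _gbw_statistic(t, e, perm) >= observed - 1e-12:
                ge += 1
        p = (ge + 1) / (n_random_permutations + 1)
    return observed, float(p), curves


def _label_arrangements(positions, counts):
    """Yield tuples of index-sets, one per group, partitioning positions."""
    positions = tuple(positions)
    if len(counts) == 1:
        yield (positions,)
        return
    for head in itertools.combinations(positions, counts[0]):
        rest = tuple(p for p in positions if p not in set(head))
        for tail in _label_arrangements(rest, counts[1:]):
            yield (head,) + tail


def pooled_fisher_q4_vs_q1(results, endpoint: str = "pr") -> float:
    """Fisher p for Q4 vs Q1 with counts pooled over several cohorts."""
    attr = "pr_counts" if endpoint == "pr" else "dcb_counts"
    k4 = n4 = k1 = n1 = 0
    for res in results:
        counts = getattr(res, attr)
        k4 += counts["Q4"]["successes"]; n4 += counts["Q4"]["n"]
        k1 += counts["Q1"]["successes"]; n1 += counts["Q1"]["n"]
    return fisher_exact_2x2([[k4, n4 - k4], [k1, n1 - k1]])


@dataclass
class BiomarkerResult:
    """Full evaluation of the quadrant biomarker against outcomes."""

    thresholds: BiomarkerThresholds
    quadrant_counts: dict
    pr_counts: dict
    dcb_counts: dict
    pr_rates: dict = field(default_factory=dict)  # quadrant -> {method: ProportionCI}
    dcb_rates: dict = field(default_factory=dict)
    fisher_pr_q4_vs_q1: float | None = None
    fisher_dcb_q4_vs_q1: float | None = None
    auc_dn_tem_pr: float | None = None
    auc_ci: tuple | None = None

    def to_dict(self) -> dict:
        """JSON-ready summary (percent scale, provenance counts included)."""
        def rates_block(rates):
            return {
                q: {m: dict(zip(("rate_pct", "lower_pct", "upper_pct"), ci.as_percent()))
                    for m, ci in by_m.items()}
                for q, by_m in rates.items()
            }

        return {
            "thresholds": {
                "dn_tem_pct": self.thresholds.dn_tem,
                "dp_temra_pct": self.thresholds.dp_temra,
                "disease_context": self.thresholds.disease_context,
            },
            "quadrant_counts": self.quadrant_counts,
            "pr_counts": self.pr_counts,
            "dcb_counts": self.dcb_counts,
            "pr_rates": rates_block(self.pr_rates),
            "dcb_rates": rates_block(self.dcb_rates),
            "fisher_pr_q4_vs_q1": self.fisher_pr_q4_vs_q1,
            "fisher_dcb_q4_vs_q1": self.fisher_dcb_q4_vs_q1,
            "auc_dn_tem_pr": self.auc_dn_tem_pr,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
        }


def evaluate_biomarker(
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    thr: BiomarkerThresholds,
    dn_col: str = "dn_tem_pct",
    dp_col: str = "dp_temra_pct",
) -> BiomarkerResult:
    """Join profiles with outcomes and evaluate the quadrant biomarker.

    ``profiles`` needs one row per donor with the two percent-scale
    frequencies; ``outcomes`` needs ``donor_id``, ``best_response`` and
    (optionally) ``response_6m``/``dcb``.  Donors missing from either
    table are dropped from the evaluation.
    """
    prof = profiles.set_index("donor_id") if "donor_id" in profiles.columns else profiles
    out = outcomes.set_index("donor_id") if "donor_id" in outcomes.columns else outcomes
    out = out[out["best_response"].notna()]
    out = out.drop(columns=[c for c in out.columns if c in prof.columns])
    merged = prof.join(out, how="inner")
    if merged.empty:
        raise ValueError("no donors joinable across profiles and outcomes")

    merged = merged.copy()
    merged["quadrant"] = assign_quadrants(merged.reset_index(), thr, dn_col, dp_col).values
    merged["pr"] = merged["best_response"].isin(["PR", "CR"])
    if "dcb" in merged.columns and merged["dcb"].notna().any():
        merged["dcb_flag"] = merged["dcb"].astype("boolean")
    elif "response_6m" in merged.columns:
        merged["dcb_flag"] = pd.array(
            [derive_dcb(v) for v in merged["response_6m"]], dtype="boolean"
        )
    else:
        merged["dcb_flag"] = pd.array([None] * len(merged), dtype="boolean")

    quadrant_counts = {q: int((merged["quadrant"] == q).sum()) for q in QUADRANTS}
    pr_counts, dcb_counts, pr_rates, dcb_rates = {}, {}, {}, {}
    for q in QUADRANTS:
        sub = merged[merged["quadrant"] == q]
        n = len(sub)
        k_pr = int(sub["pr"].sum())
        pr_counts[q] = {"successes": k_pr, "n": n}
        sub_dcb = sub[sub["dcb_flag"].notna()]
        k_dcb = int(sub_dcb["dcb_flag"].sum())
        dcb_counts[q] = {"successes": k_dcb, "n": len(sub_dcb)}
        if n == 0:
            warnings.warn(f"quadrant {q} has no donors; rates missing")
            continue
        pr_rates[q] = {m: response_rate_ci(k_pr, n, m) for m in ("wald", "wilson")}
        if len(sub_dcb):
            dcb_rates[q] = {
                m: response_rate_ci(k_dcb, len(sub_dcb), m) for m in ("wald", "wilson")
            }

    def fisher_q4_q1(counts):
        a, b = counts["Q4"], counts["Q1"]
        if a["n"] == 0 or b["n"] == 0:
            return None
        return fisher_exact_2x2(
            [[a["successes"], a["n"] - a["successes"]],
             [b["successes"], b["n"] - b["successes"]]]
        )

    result = BiomarkerResult(
        thresholds=thr,
        quadrant_counts=quadrant_counts,
        pr_counts=pr_counts,
        dcb_counts=dcb_counts,
        pr_rates=pr_rates,
        dcb_rates=dcb_rates,
        fisher_pr_q4_vs_q1=fisher_q4_q1(pr_counts),
        fisher_dcb_q4_vs_q1=fisher_q4_q1(dcb_counts),
    )
    if merged["pr"].nunique() == 2:
        auc, lo, hi = roc_auc(
            merged[dn_col].to_numpy(), merged["pr"].to_numpy(), ci=True
        )
        result.auc_dn_tem_pr = auc
        result.auc_ci = (lo, hi)
    return result
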