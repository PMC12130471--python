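"""Threshold fitting, hierarchical subset classification, relative MFI."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from chaoscope import gating


def _thr(values: dict, cofactor=150.0) -> gating.MarkerThresholds:
    return gating.MarkerThresholds(
        cutoffs={(m, "__all__"): v for m, v in values.items()}, cofactor=cofactor
    )


# ---------------------------------------------------------------------------
# threshold derivation

def test_gmm2_threshold_separates_two_modes():
    rng = np.random.default_rng(0)
    x = np.concatenate([
        rng.lognormal(np.log(100), 0.4, 2000),
        rng.lognormal(np.log(10000), 0.4, 2000),
    ])
    cells = pd.DataFrame({"CCR7": x})
    thr = gating.derive_marker_thresholds(cells, markers=["CCR7"], seed=0)
    cut = thr.get("CCR7", None)
    assert 100 < cut < 10000
    # and most cells on each side gate correctly
    assert ((x[:2000] < cut).mean() > 0.95) and ((x[2000:] >= cut).mean() > 0.95)


def test_gmm2_matches_analytic_posterior_crossing():
    """With two well-separated Gaussian modes on the asinh scale, the
    fitted cutoff is within 10% of the analytic posterior-0.5 crossing."""
    rng = np.random.default_rng(1)
    cof = 150.0
    mu1, mu2, sd, w1 = 0.6, 4.2, 0.35, 0.5
    n = 20000
    t = np.concatenate([
        rng.normal(mu1, sd, int(n * w1)), rng.normal(mu2, sd, n - int(n * w1))
    ])
    x = np.sinh(t) * cof
    x = np.clip(x, 0, None)
    thr = gating.derive_marker_thresholds(
        pd.DataFrame({"CD27": x}), markers=["CD27"], cofactor=cof, seed=0
    )
    # analytic crossing of equal-variance, equal-weight posterior = midpoint
    def post_diff(z):
        a = w1 * norm.pdf(z, mu1, sd)
        b = (1 - w1) * norm.pdf(z, mu2, sd)
        return b / (a + b) - 0.5

    crossing_t = brentq(post_diff, mu1, mu2)
    fitted_t = np.arcsinh(thr.get("CD27", None) / cof)
    assert fitted_t == pytest.approx(crossing_t, rel=0.10)


def test_degenerate_data_falls_back_to_quantile(caplog):
    cells = pd.DataFrame({"CD28": np.full(200, 500.0)})
    with caplog.at_level(logging.WARNING):
        thr = gating.derive_marker_thresholds(cells, markers=["CD28"], seed=0)
    assert thr.get("CD28", None) == pytest.approx(500.0)
    assert any("collapsed" in r.message for r in caplog.records)


def test_gmm2_needs_enough_cells():
    cells = pd.DataFrame({"CCR7": np.arange(10.0)})
    with pytest.raises(ValueError, match="50 cells"):
        gating.derive_marker_thresholds(cells, markers=["CCR7"], seed=0)


def test_missing_marker_raises():
    cells = pd.DataFrame({"CCR7": np.ones(100)})
    with pytest.raises(ValueError, match="CD27"):
        gating.derive_marker_thresholds(cells, markers=["CD27"], seed=0)


# ---------------------------------------------------------------------------
# classification

THR = _thr({"CCR7": 1000.0, "CD45RA": 1000.0, "CD27": 1000.0, "CD28": 1000.0})


def _cell(ccr7, ra, cd27, cd28):
    return pd.DataFrame({
        "donor_id": ["d"], "CCR7": [ccr7], "CD45RA": [ra],
        "CD27": [cd27], "CD28": [cd28],
    })


@pytest.mark.parametrize("ccr7,ra,subset", [
    (5000, 5000, "Tn"), (5000, 10, "Tcm"), (10, 10, "Tem"), (10, 5000, "Temra"),
])
def test_four_subset_gate(ccr7, ra, subset):
    lab = gating.classify_subsets(_cell(ccr7, ra, 10, 10), THR)
    assert lab["subset"].iloc[0] == subset


@pytest.mark.parametrize("cd27,cd28,mem", [
    (5000, 5000, "DP"), (5000, 10, "SP27"), (10, 5000, "SP28"), (10, 10, "DN"),
])
def test_tem_memory_subgate(cd27, cd28, mem):
    lab = gating.classify_subsets(_cell(10, 10, cd27, cd28), THR)
    assert lab["subset"].iloc[0] == "Tem"
    assert lab["mem_subset"].iloc[0] == mem


def test_boundary_tie_rule_positive():
    # a cell exactly at every threshold is positive everywhere -> Tn
    lab = gating.classify_subsets(_cell(1000.0, 1000.0, 1000.0, 1000.0), THR)
    assert lab["subset"].iloc[0] == "Tn"
    assert pd.isna(lab["mem_subset"].iloc[0])  # Tn carries no memory subgate


def test_classification_partition_is_exhaustive(labeled_small_cohort):
    _, _, labeled, _ = labeled_small_cohort
    assert labeled["subset"].isin(gating.SUBSETS).all()
    memcells = labeled["subset"].isin(["Tem", "Temra"])
    assert labeled.loc[memcells, "mem_subset"].isin(gating.MEM_SUBSETS).all()
    assert labeled.loc[~memcells, "mem_subset"].isna().all()


def test_gating_recovers_generator_truth(labeled_small_cohort):
    _, _, labeled, _ = labeled_small_cohort
    full = np.where(
        labeled["mem_subset"].notna(),
        labeled["subset"] + "_" + labeled["mem_subset"].astype(str),
        labeled["subset"],
    )
    # GZMK+ DN-Tem cells carry a deliberately intermediate profile;
    # the recovery guarantee applies to the well-separated modes
    clean = ~labeled["gzmk_pos"].to_numpy()
    agreement = (full[clean] == labeled.loc[clean, "true_subset"]).mean()
    assert agreement >= 0.99


def test_missing_column_schema_error():
    with pytest.raises(ValueError, match="CD28"):
        gating.classify_subsets(
            _cell(10, 10, 10, 10).drop(columns=["CD28"]), THR
        )


# ---------------------------------------------------------------------------
# frequencies

def test_uniform_frequencies():
    cells = pd.DataFrame({
        "donor_id": ["d"] * 100,
        "CCR7": [5000] * 25 + [5000] * 25 + [10] * 25 + [10] * 25,
        "CD45RA": [5000] * 25 + [10] * 25 + [10] * 25 + [5000] * 25,
        "CD27": [5000] * 100,
        "CD28": [5000] * 100,
    })
    prof = gating.subset_frequencies(gating.classify_subsets(cells, THR))
    for s in gating.SUBSETS:
        assert prof[f"freq_{s}"].iloc[0] == pytest.approx(0.25)


def test_dn_tem_direct_count():
    # 10 Tem cells of which 6 DN
    cells = pd.DataFrame({
        "donor_id": ["d"] * 10,
        "CCR7": [10] * 10, "CD45RA": [10] * 10,
        "CD27": [10] * 6 + [5000] * 4,
        "CD28": [10] * 6 + [5000] * 4,
    })
    prof = gating.subset_frequencies(gating.classify_subsets(cells, THR))
    assert prof["tem_DN"].iloc[0] == pytest.approx(0.6)
    assert prof["dn_tem_pct"].iloc[0] == pytest.approx(60.0)
    assert np.isnan(prof["temra_DP"].iloc[0])  # no Temra cells -> flagged missing


def test_frequency_blocks_sum_to_one(labeled_small_cohort):
    _, _, _, profiles = labeled_small_cohort
    top = profiles[[f"freq_{s}" for s in gating.SUBSETS]].sum(axis=1)
    assert np.allclose(top, 1.0, atol=1e-9)
    for parent in ("tem", "temra"):
        block = profiles[[f"{parent}_{m}" for m in gating.MEM_SUBSETS]].sum(axis=1)
        ok = block.notna()
        assert np.allclose(block[ok], 1.0, atol=1e-9)
    # partition: subset counts sum to the donor total exactly
    counts = profiles[[f"n_{s}" for s in gating.SUBSETS]].sum(axis=1)
    assert (counts == profiles["n_cells"]).all()


def test_gated_frequencies_match_generator_composition(labeled_small_cohort):
    cfg, cohort, _, profiles = labeled_small_cohort
    for donor, info in cohort.truth["donors"].items():
        row = profiles[profiles["donor_id"] == donor].iloc[0]
        true_counts = info["subset_counts"]
        n = sum(true_counts.values())
        for s in gating.SUBSETS:
            true_frac = sum(
                v for k, v in true_counts.items() if k == s or k.startswith(s + "_")
            ) / n
            assert row[f"freq_{s}"] == pytest.approx(true_frac, abs=0.03)


# ---------------------------------------------------------------------------
# relative MFI

def _mfi_cells():
    rng = np.random.default_rng(2)
    rows = []
    for donor, batch, scale in (("ref", "b1", 1.0), ("ref", "b2", 1.0),
                                ("p1", "b1", 2.0), ("p2", "b2", 2.0)):
        for subset, ccr7, ra in (("Tn", 5000, 5000), ("Tem", 10, 10)):
            for _ in range(50):
                rows.append({
                    "donor_id": donor, "batch_id": batch,
                    "CCR7": ccr7 * scale, "CD45RA": ra if ra > 100 else ra,
                    "CD27": 2000.0 * scale, "CD28": 2000.0 * scale,
                })
    return pd.DataFrame(rows)


def test_reference_tn_normalizes_to_one():
    labeled = gating.classify_subsets(_mfi_cells(), THR)
    mfi = gating.relative_mfi(labeled, "ref", ["CD27", "CD28"])
    ref_tn = mfi[(mfi["donor_id"] == "ref") & (mfi["subset"] == "Tn")]
    assert np.allclose(ref_tn["relative_mfi"], 1.0)


def test_twofold_subset_gives_two():
    labeled = gating.classify_subsets(_mfi_cells(), THR)
    mfi = gating.relative_mfi(labeled, "ref", ["CD27"])
    p1 = mfi[(mfi["donor_id"] == "p1") & (mfi["marker"] == "CD27")]
    assert np.allclose(p1["relative_mfi"], 2.0)


def test_batch_invariance_under_multiplicative_distortion():
    cells = _mfi_cells()
    labeled = gating.classify_subsets(cells, THR)
    before = gating.relative_mfi(labeled, "ref", ["CD27", "CD28"])
    distorted = cells.copy()
    in_b2 = distorted["batch_id"] == "b2"
    for m in ("CCR7", "CD45RA", "CD27", "CD28"):
        distorted.loc[in_b2, m] *= 3.0
    # regate with per-batch thresholds scaled consistently (same labels)
    labeled2 = gating.classify_subsets(distorted, gating.MarkerThresholds(
        cutoffs={(m, b): (3000.0 if b == "b2" else 1000.0)
                 for m in gating.GATING_MARKERS for b in ("b1", "b2")}
    ))
    after = gating.relative_mfi(labeled2, "ref", ["CD27", "CD28"])
    merged = before.merge(after, on=["donor_id", "batch_id", "subset", "marker"])
    assert np.allclose(merged["relative_mfi_x"], merged["relative_mfi_y"])


def test_reference_missing_from_batch_errors():
    cells = _mfi_cells()
    cells = cells[~((cells["donor_id"] == "ref") & (cells["batch_id"] == "b2"))]
    labeled = gating.classify_subsets(cells, THR)
    with pytest.raises(ValueError, match="reference donor"):
        gating.relative_mfi(labeled, "ref", ["CD27"])


def test_geometric_mean_option():
    labeled = gating.classify_subsets(_mfi_cells(), THR)
    mfi = gating.relative_mfi(labeled, "ref", ["CD27"], stat="geometric")
    ref_tn = mfi[(mfi["donor_id"] == "ref") & (mfi["subset"] == "Tn")]
    assert np.allclose(ref_tn["relative_mfi"], 1.0)
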