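"""CD8+ T-cell subset gating, frequency profiling and relative MFI.

Cells are classified hierarchically from four marker intensities:
CCR7 x CD45RA define Tn (+/+), Tcm (+/-), Tem (-/-) and Temra (-/+);
within Tem and Temra, CD27 x CD28 define DP (+/+), SP27 (+/-),
SP28 (-/+) and DN (-/-).  Positivity thresholds are fit per marker and
batch by a two-component Gaussian mixture on asinh-transformed
intensities (the automated stand-in for manual gates), with a quantile
fallback for degenerate data.  The tie rule is intensity >= threshold
=> positive.

Relative MFI normalises batch effects by dividing each (donor, subset,
marker) mean intensity by the naive-subset mean of a reference healthy
donor measured in the same batch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "GATING_MARKERS",
    "SUBSETS",
    "MEM_SUBSETS",
    "MarkerThresholds",
    "derive_marker_thresholds",
    "classify_subsets",
    "subset_frequencies",
    "relative_mfi",
]

GATING_MARKERS = ("CCR7", "CD45RA", "CD27", "CD28")
SUBSETS = ("Tn", "Tcm", "Tem", "Temra")
MEM_SUBSETS = ("DP", "SP27", "SP28", "DN")

_NO_BATCH = "__all__"


@dataclass
class MarkerThresholds:
    """Positivity cutoffs on the raw intensity scale, per (marker, batch)."""

    cutoffs: dict = field(default_factory=dict)  # (marker, batch) -> float
    cofactor: float = 150.0
    method: str = "gmm2"

    def get(self, marker: str, batch) -> float:
        key = (marker, batch if batch is not None else _NO_BATCH)
        if key in self.cutoffs:
            return self.cutoffs[key]
        if (marker, _NO_BATCH) in self.cutoffs:
            return self.cutoffs[(marker, _NO_BATCH)]
        raise KeyError(f"no threshold for marker {marker!r} in batch {batch!r}")

    def covers(self, markers, batches) -> bool:
        try:
            for m in markers:
                for b in batches:
                    self.get(m, b)
        except KeyError:
            return False
        return True


def _gmm2_threshold(x_t: np.ndarray, seed: int) -> float | None:
    """Posterior-0.5 crossing of a 2-component GMM on transformed scale.

    Returns None when the components collapse (unimodal data).
    """
    q25, q75 = np.quantile(x_t, [0.25, 0.75])
    gm = GaussianMixture(
        n_components=2,
        means_init=np.array([[q25], [q75]]),
        random_state=seed,
        n_init=1,
    )
    gm.fit(x_t.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    sep = abs(means[hi] - means[lo])
    if sep < 0.5 * (sds[lo] + sds[hi]) or min(gm.weights_) < 1e-3:
        return None  # collapsed / effectively unimodal
    grid = np.linspace(means[lo], means[hi], 2001)
    post_hi = gm.predict_proba(grid.reshape(-1, 1))[:, hi]
    idx = np.searchsorted(post_hi >= 0.5, True)
    if idx == 0 or idx >= grid.size:
        return None
    # linear interpolation to the 0.5 crossing
    x0, x1 = grid[idx - 1], grid[idx]
    y0, y1 = post_hi[idx - 1], post_hi[idx]
    if y1 == y0:
        return float(x0)
    return float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))


def derive_marker_thresholds(
    cells: pd.DataFrame,
    markers=GATING_MARKERS,
    cofactor: float = 150.0,
    method: str = "gmm2",
    quantile: float = 0.5,
    seed: int = 0,
) -> MarkerThresholds:
    """Fit per-(marker, batch) positivity cutoffs.

    ``gmm2`` fits a two-component Gaussian mixture on asinh(x/cofactor)
    and places the cutoff where posterior membership of the upper
    component crosses 0.5, mapped back to the raw scale; degenerate
    (unimodal) data falls back to the ``quantile`` method with a
    logged warning.
    """
    if method not in ("gmm2", "quantile"):
        raise ValueError(f"unknown threshold method {method!r}")
    thr = MarkerThresholds(cofactor=cofactor, method=method)
    batches = (
        cells["batch_id"].unique() if "batch_id" in cells.columns else [_NO_BATCH]
    )
    for marker in markers:
        if marker not in cells.columns:
            raise ValueError(f"marker column {marker!r} missing from cell table")
        for batch in batches:
            if batch == _NO_BATCH:
                x = cells[marker].to_numpy(dtype=float)
            else:
                x = cells.loc[cells["batch_id"] == batch, marker].to_numpy(dtype=float)
            if not np.isfinite(x).all() or (x < 0).any():
                raise ValueError(f"non-finite or negative intensities for {marker!r}")
            x_t = np.arcsinh(x / cofactor)
            cut_t = None
            if method == "gmm2":
                if x.size < 50:
                    raise ValueError(
                        f"gmm2 needs >= 50 cells per (marker, batch); "
                        f"got {x.size} for ({marker}, {batch})"
                    )
                cut_t = _gmm2_threshold(x_t, seed)
                if cut_t is None:
                    logger.warning(
                        "GMM components collapsed for (%s, %s); falling back to "
                        "quantile threshold", marker, batch,
                    )
            if cut_t is None:
                cut_t = float(np.quantile(x_t, quantile))
            thr.cutoffs[(marker, batch)] = float(np.sinh(cut_t) * cofactor)
    return thr


def classify_subsets(cells: pd.DataFrame, thresholds: MarkerThresholds) -> pd.DataFrame:
    """Label every cell with its subset (and Tem/Temra memory subset).

    Adds ``subset`` in {Tn, Tcm, Tem, Temra} and, for Tem/Temra cells,
    ``mem_subset`` in {DP, SP27, SP28, DN} (NaN otherwise).  The
    partition is exhaustive and exclusive; >= threshold is positive.
    """
    for marker in GATING_MARKERS:
        if marker not in cells.columns:
            raise ValueError(f"marker column {marker!r} missing from cell table")

    out = cells.copy()
    batches = out["batch_id"] if "batch_id" in out.columns else pd.Series(
        [_NO_BATCH] * len(out), index=out.index
    )
    pos = {}
    for marker in GATING_MARKERS:
        cut = batches.map(lambda b, m=marker: thresholds.get(m, b)).to_numpy(dtype=float)
        pos[marker] = out[marker].to_numpy(dtype=float) >= cut

    ccr7, ra = pos["CCR7"], pos["CD45RA"]
    subset = np.where(
        ccr7, np.where(ra, "Tn", "Tcm"), np.where(ra, "Temra", "Tem")
    )
    cd27, cd28 = pos["CD27"], pos["CD28"]
    mem = np.where(
        cd27, np.where(cd28, "DP", "SP27"), np.where(cd28, "SP28", "DN")
    )
    out["subset"] = subset
    out["mem_subset"] = pd.Series(mem, index=out.index).where(
        pd.Series(np.isin(subset, ["Tem", "Temra"]), index=out.index)
    )
    return out


def subset_frequencies(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-donor subset-frequency profile.

    One row per donor: Tn/Tcm/Tem/Temra fractions of all CD8+ cells,
    DP/SP27/SP28/DN fractions within Tem and within Temra (plus the
    pooled SP fraction), and the raw counts behind each block.  Empty
    denominators yield NaN, never 0/0.  ``dn_tem_pct`` and
    ``dp_temra_pct`` (percent scale) are the biomarker axes.
    """
    if "subset" not in labeled.columns:
        raise ValueError("cells must be classified first (no 'subset' column)")
    rows = []
    for donor, grp in labeled.groupby("donor_id", observed=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"donor {donor} has zero cells; excluded")
            continue
        row: dict = {"donor_id": donor, "n_cells": n}
        for meta in ("group", "stage", "batch_id"):
            if meta in grp.columns:
                row[meta] = grp[meta].iloc[0]
        for s in SUBSETS:
            row[f"n_{s}"] = int((grp["subset"] == s).sum())
            row[f"freq_{s}"] = row[f"n_{s}"] / n
        for parent in ("Tem", "Temra"):
            sub = grp[grp["subset"] == parent]
            denom = len(sub)
            for m in MEM_SUBSETS:
                cnt = int((sub["mem_subset"] == m).sum())
                row[f"n_{parent}_{m}"] = cnt
                row[f"{parent.lower()}_{m}"] = cnt / denom if denom else np.nan
            row[f"{parent.lower()}_SP"] = (
                row[f"{parent.lower()}_SP27"] + row[f"{parent.lower()}_SP28"]
                if denom else np.nan
            )
        row["dn_tem_pct"] = 100.0 * row["tem_DN"] if not np.isnan(row["tem_DN"]) else np.nan
        row["dp_temra_pct"] = (
            100.0 * row["temra_DP"] if not np.isnan(row["temra_DP"]) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def relative_mfi(
    labeled: pd.DataFrame,
    reference_donor,
    markers,
    stat: str = "arithmetic",
) -> pd.DataFrame:
    """Batch-normalised relative MFI per (donor, subset, marker).

    Each subset's mean raw intensity is divided by the mean intensity
    of the reference healthy donor's naive (Tn) cells for the same
    marker in the same batch.  The reference donor must be present —
    with at least one Tn cell — in every batch (one healthy reference
    is included in all experiments by design).
    """
    if stat not in ("arithmetic", "geometric"):
        raise ValueError("stat must be 'arithmetic' or 'geometric'")

    def mfi(values: np.ndarray) -> float:
        if stat == "geometric":
            return float(np.exp(np.mean(np.log(np.maximum(values, 1e-12)))))
        return float(np.mean(values))

    df = labeled.copy()
    if "batch_id" not in df.columns:
        df["batch_id"] = _NO_BATCH

    ref_tn_mean: dict = {}
    for batch, grp in df.groupby("batch_id", observed=True):
        ref_cells = grp[(grp["donor_id"] == reference_donor) & (grp["subset"] == "Tn")]
        if ref_cells.empty:
            raise ValueError(
                f"reference donor {reference_donor!r} has no Tn cells in batch "
                f"{batch!r}; a reference healthy donor must be included in every batch"
            )
        ref_tn_mean[batch] = {m: mfi(ref_cells[m].to_numpy(dtype=float)) for m in markers}

    rows = []
    keys = ["donor_id", "batch_id", "subset"]
    sub_col = df["subset"].where(df["mem_subset"].isna(), df["subset"] + "_" + df["mem_subset"])
    df["_subset_full"] = sub_col
    for (donor, batch, subset), grp in df.groupby(
        ["donor_id", "batch_id", "_subset_full"], observed=True
    ):
        for m in markers:
            denom = ref_tn_mean[batch][m]
            rows.append({
                "donor_id": donor,
                "batch_id": batch,
                "subset": subset,
                "marker": m,
                "relative_mfi": mfi(grp[m].to_numpy(dtype=float)) / denom,
            })
    return pd.DataFrame(rows)
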