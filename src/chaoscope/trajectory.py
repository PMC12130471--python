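"""Deterministic pseudotime on protein-marker profiles.

Differentiation of peripheral CD8+ T cells is summarised as a single
ordering: markers are z-scored (scaled, not normalised), projected to
``d`` principal components, connected in a symmetric k-nearest-
neighbour graph with Euclidean edge weights, and pseudotime is the
single-source shortest-path distance from the medoid of the root
subset (naive T cells), min-max scaled to [0, 1].  The construction is
fully deterministic: no stochastic embedding is involved, and
neighbour ties are broken by cell index.

Group-level comparisons use per-(group, subset) histograms over B
equal-width pseudotime bins, patient-minus-healthy per-bin proportion
differences (which sum to zero by construction), and per-donor average
pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "scale_markers",
    "PseudotimeResult",
    "compute_pseudotime",
    "pseudotime_distributions",
    "proportion_difference",
    "average_pseudotime",
]

#: the default protein panel measured for the trajectory analysis
DEFAULT_MARKER_PANEL = (
    "CD8", "CD3", "CXCR4", "CD45RA", "CD95", "CD27", "CD28", "CD73", "CCR7", "CXCR3",
)


def scale_markers(cells: pd.DataFrame, markers) -> pd.DataFrame:
    """Per-marker z-score (mean 0, population sd 1) across all cells.

    Constant markers carry no ordering information and are dropped with
    a warning; an all-constant panel is an error.
    """
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise ValueError(f"markers missing from cell table: {missing}")
    if len(cells) < 2:
        raise ValueError("need >= 2 cells to scale")
    X = cells[list(markers)].astype(float)
    sd = X.std(axis=0, ddof=0)
    constant = sd.index[sd == 0.0].tolist()
    if constant:
        warnings.warn(f"constant marker(s) dropped: {constant}")
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] == 0:
        raise ValueError("all markers are constant; nothing to scale")
    return (X - X.mean(axis=0)) / sd


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime with its embedding and root bookkeeping."""

    t: pd.Series                    # scaled to [0, 1]; NaN = unreachable
    embedding: np.ndarray           # cells x d principal components
    root_index: int                 # positional index of the root medoid
    root_subset: str
    n_unreachable: int


def _medoid(points: np.ndarray) -> int:
    """Index of the point minimising total Euclidean distance (chunked)."""
    n = points.shape[0]
    totals = np.zeros(n)
    step = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, step):
        block = points[start:start + step]
        d = np.sqrt(((block[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        totals[start:start + step] = d.sum(axis=1)
    return int(np.argmin(totals))


def compute_pseudotime(
    scaled: pd.DataFrame,
    subset_labels: pd.Series,
    root_subset: str = "Tn",
    d: int = 5,
    k: int = 15,
    root_mask=None,
) -> PseudotimeResult:
    """PCA -> symmetric kNN graph -> shortest path from the root medoid.

    ``scaled`` is the z-scored marker matrix (cells x markers);
    ``subset_labels`` aligns with its rows.  The root is the medoid of
    the root-subset cells; ``root_mask`` narrows the candidate root
    cells further (e.g. to healthy naive cells, anchoring the origin at
    the healthy pole when comparing groups).  Cells disconnected from
    the root get NaN pseudotime and are counted in ``n_unreachable``.
    """
    labels = np.asarray(subset_labels)
    if labels.shape[0] != len(scaled):
        raise ValueError("subset_labels must align with the scaled matrix rows")
    root_mask_arr = labels == root_subset
    if root_mask is not None:
        root_mask_arr &= np.asarray(root_mask, dtype=bool)
    root_mask = root_mask_arr
    if not root_mask.any():
        raise ValueError(f"root subset {root_subset!r} is empty")
    n = len(scaled)
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")

    d_eff = min(d, scaled.shape[1], n)
    pca = PCA(n_components=d_eff, svd_solver="full")
    emb = pca.fit_transform(scaled.to_numpy(dtype=float))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
    graph = graph.maximum(graph.T)  # symmetrise

    root_points = emb[root_mask]
    root_index = int(np.flatnonzero(root_mask)[_medoid(root_points)])
    raw = dijkstra(graph, directed=False, indices=root_index)

    reachable = np.isfinite(raw)
    n_unreachable = int((~reachable).sum())
    if n_unreachable:
        warnings.warn(f"{n_unreachable} cell(s) unreachable from the root; t set missing")
    t = np.full(n, np.nan)
    fin = raw[reachable]
    span = fin.max() - fin.min()
    t[reachable] = (fin - fin.min()) / span if span > 0 else 0.0
    return PseudotimeResult(
        t=pd.Series(t, index=scaled.index, name="pseudotime"),
        embedding=emb,
        root_index=root_index,
        root_subset=root_subset,
        n_unreachable=n_unreachable,
    )


def pseudotime_distributions(
    t: pd.Series,
    groups: pd.Series,
    subsets: pd.Series,
    B: int = 50,
) -> pd.DataFrame:
    """Per-(group, subset) histogram of pseudotime over B equal bins.

    Rows are (group, subset); columns the B bins on [0, 1]; each
    non-empty row sums to 1.  Empty combinations are absent (flagged).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    edges = np.linspace(0.0, 1.0, B + 1)
    rows = {}
    frame = pd.DataFrame({"t": t, "group": np.asarray(groups), "subset": np.asarray(subsets)})
    frame = frame.dropna(subset=["t"])
    for (g, s), grp in frame.groupby(["group", "subset"], observed=True):
        hist, _ = np.histogram(grp["t"], bins=edges)
        total = hist.sum()
        if total == 0:
            warnings.warn(f"empty (group, subset) = ({g}, {s}); no distribution")
            continue
        rows[(g, s)] = hist / total
    out = pd.DataFrame.from_dict(rows, orient="index", columns=range(B))
    out.index = pd.MultiIndex.from_tuples(out.index, names=["group", "subset"])
    return out


def proportion_difference(dist_patient: np.ndarray, dist_healthy: np.ndarray) -> np.ndarray:
    """Per-bin patient minus healthy proportions; sums to 0 by construction."""
    p = np.asarray(dist_patient, dtype=float)
    h = np.asarray(dist_healthy, dtype=float)
    if p.shape != h.shape:
        raise ValueError(f"bin mismatch: {p.shape} vs {h.shape}")
    return p - h


def average_pseudotime(
    t: pd.Series,
    donors: pd.Series,
    subsets: pd.Series,
) -> pd.DataFrame:
    """Per-(donor, subset) mean pseudotime (NaN-aware, empty = missing)."""
    frame = pd.DataFrame({
        "t": t, "donor_id": np.asarray(donors), "subset": np.asarray(subsets)
    }).dropna(subset=["t"])
    out = (
        frame.groupby(["donor_id", "subset"], observed=True)["t"]
        .mean()
        .rename("mean_pseudotime")
        .reset_index()
    )
    return out
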