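"""Gene-set module scoring with expression-matched controls.

A module score for a gene set is, per cell, the mean expression of the
set's genes minus the mean expression of control genes drawn from the
same pooled-expression bins — so a random gene set scores zero in
expectation regardless of cell sequencing depth.  Donor-level averages
within a cluster (typically the CD27+CD28+ DP-Tem cluster), scores
relative to the healthy-group mean of the same dataset, and
correlation-based clustering of gene sets into gene-set clusters
(GSC1..k, ordered by decreasing patient-vs-healthy elevation) build on
the per-cell scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "module_score",
    "cluster_average_scores",
    "relative_module_score",
    "cluster_gene_sets",
]


@dataclass
class ExpressionMatrix:
    """A genes-x-cells expression matrix with per-cell metadata.

    ``values``: DataFrame indexed by gene id, columns = cell ids, with
    log-normalised (non-negative) values.  ``obs``: DataFrame indexed
    by cell id with at least ``donor_id``; ``group``, ``cluster_label``
    and ``dataset`` are used downstream when present.
    """

    values: pd.DataFrame
    obs: pd.DataFrame
    normalization: str = "lognorm"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not self.values.columns.equals(self.obs.index):
            if set(self.values.columns) != set(self.obs.index):
                raise ValueError("cell ids of values and obs differ")
            self.obs = self.obs.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in a declared-normalized matrix")


def module_score(
    expr: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    set_name: str = "module",
) -> pd.Series:
    """Per-cell module score with binned expression-matched controls.

    Genes are ranked by pooled mean expression and cut into ``n_bins``
    equal-size bins; for each target gene, up to ``n_ctrl`` control
    genes are drawn uniformly without replacement from its bin
    (excluding the target itself).  The score is
    mean(target genes) - mean(pooled control genes) per cell.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = pd.Index(gene_set)
    present = genes.intersection(expr.values.index)
    dropped = genes.difference(expr.values.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} gene(s) of set {set_name!r} absent from matrix; dropped"
        )
    if present.empty:
        raise ValueError(f"gene set {set_name!r} has no genes in the matrix")

    pooled_mean = expr.values.mean(axis=1)
    # equal-size bins on the rank of pooled mean expression
    ranks = pooled_mean.rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(ranks)), labels=False)
    bin_members = {b: idx for b, idx in pooled_mean.groupby(bins).groups.items()}

    rng = np.random.default_rng(seed)
    control: set = set()
    for g in present:
        members = bin_members[bins[g]].drop(g, errors="ignore")
        take = min(n_ctrl, len(members))
        if take == 0:
            continue
        chosen = rng.choice(np.asarray(members), size=take, replace=False)
        control.update(chosen)
    control -= set(present)
    if not control:
        raise ValueError(
            f"no control genes available for set {set_name!r}; matrix too small"
        )

    target_mean = expr.values.loc[present].mean(axis=0)
    ctrl_mean = expr.values.loc[sorted(control)].mean(axis=0)
    score = target_mean - ctrl_mean
    score.name = set_name
    return score


def cluster_average_scores(
    scores: pd.Series | pd.DataFrame,
    obs: pd.DataFrame,
    cluster: str,
) -> pd.DataFrame:
    """Per-donor mean score over cells of one cluster.

    Donors with no cells in the cluster appear with NaN (flagged via a
    log message), so cohort membership is preserved.
    """
    if "cluster_label" not in obs.columns:
        raise ValueError("obs lacks a 'cluster_label' column")
    if cluster not in set(obs["cluster_label"]):
        raise ValueError(f"cluster label {cluster!r} not present")
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    in_cluster = obs["cluster_label"] == cluster
    avg = df[in_cluster.to_numpy()].groupby(obs.loc[in_cluster, "donor_id"], observed=True).mean()
    all_donors = pd.Index(obs["donor_id"].unique(), name="donor_id")
    avg = avg.reindex(all_donors)
    missing = avg.index[avg.isna().all(axis=1)]
    if len(missing):
        logger.info("donors with no cells in cluster %r: %s", cluster, list(missing))
    return avg


def relative_module_score(
    donor_averages: pd.DataFrame,
    healthy_ids,
    dataset: pd.Series | None = None,
) -> pd.DataFrame:
    """Donor score minus the healthy-group mean, per set and dataset.

    By construction the healthy-group mean of the output is 0 for every
    set within every dataset.  ``dataset`` maps donor -> dataset label;
    omitted means a single dataset.
    """
    healthy = pd.Index(healthy_ids)
    if dataset is None:
        dataset = pd.Series("dataset0", index=donor_averages.index)
    out = donor_averages.copy().astype(float)
    for ds, donors in donor_averages.index.groupby(dataset.loc[donor_averages.index]).items():
        h = donors.intersection(healthy)
        if h.empty:
            raise ValueError(f"no healthy donors in dataset {ds!r}")
        out.loc[donors] = donor_averages.loc[donors] - donor_averages.loc[h].mean(axis=0)
    return out


def cluster_gene_sets(
    donor_averages: pd.DataFrame,
    k: int,
    patient_ids,
    healthy_ids,
) -> pd.Series:
    """Group gene sets into GSC1..GSCk by correlation clustering.

    ``donor_averages`` is sets x donors.  Distance = 1 - Pearson
    correlation across donors, average linkage, cut at ``k`` clusters.
    Labels are ordered by decreasing mean (patient - healthy) score, so
    GSC1 is the most patient-elevated cluster.  Missing values are
    imputed by the set mean (logged).
    """
    if k > len(donor_averages):
        raise ValueError(f"k={k} exceeds the number of gene sets ({len(donor_averages)})")
    X = donor_averages.copy().astype(float)
    if X.isna().any().any():
        logger.info("imputing %d missing values by set means", int(X.isna().sum().sum()))
        X = X.apply(lambda r: r.fillna(r.mean()), axis=1)

    if k == len(X):
        order_ids = np.arange(1, k + 1)
        raw = pd.Series(order_ids, index=X.index)
    else:
        corr = np.corrcoef(X.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        Z = linkage(squareform(dist, checks=False), method="average")
        raw = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=X.index)

    elevation = (
        X[list(patient_ids)].mean(axis=1) - X[list(healthy_ids)].mean(axis=1)
    )
    order = (
        elevation.groupby(raw).mean().sort_values(ascending=False).index.tolist()
    )
    remap = {old: f"GSC{i + 1}" for i, old in enumerate(order)}
    out = raw.map(remap)
    out.name = "gsc"
    return out
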