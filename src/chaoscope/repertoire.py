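"""TCR-repertoire statistics on paired-chain clonotypes.

A clonotype is the pair of CDR3 amino-acid sequences of the TCR alpha
and beta chains of a cell; cells sharing both sequences belong to one
clone.  The module builds clone summaries from per-cell tables,
computes Shannon diversity, Pielou evenness and clonality (1 - J),
counts unique clonotypes, decomposes clones into expansion classes
(barely: 1 cell; intermediate: 2-10; heavily: >10) and flags
virus-specific clones by dual-chain exact matching against a VDJdb
export.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "define_clonotypes",
    "shannon_diversity",
    "pielou_clonality",
    "DiversityResult",
    "unique_clonotype_count",
    "expansion_class_counts",
    "classify_expansion",
    "match_vdjdb",
    "diversity_by",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(rf"^[{_AA}]+$")

#: clone-size bounds of the expansion classes
BARELY_MAX = 1
HEAVILY_MIN_EXCLUSIVE = 10


@dataclass
class QCReport:
    """Row-level accounting of cells excluded from clone statistics."""

    n_cells_in: int = 0
    n_paired: int = 0
    n_missing_alpha: int = 0
    n_missing_beta: int = 0
    n_missing_both: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_missing_alpha + self.n_missing_beta + self.n_missing_both


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def define_clonotypes(
    table: pd.DataFrame,
    group_by: str | list[str] | None = "donor_id",
) -> tuple[pd.DataFrame, QCReport]:
    """Collapse a per-cell paired-CDR3 table into clones.

    ``table`` needs columns ``cdr3a_aa`` and ``cdr3b_aa`` (uppercase
    amino acids); cells missing either chain are excluded and counted
    in the QC report.  The clonotype key is the concatenation
    ``cdr3a|cdr3b``.  Returns ``(summary, qc)`` where ``summary`` has
    one row per clone (within ``group_by`` groups, default per donor)
    with its size and expansion class.
    """
    if table.empty:
        raise ValueError("clonotype table is empty")
    for col in ("cdr3a_aa", "cdr3b_aa"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")

    qc = QCReport(n_cells_in=len(table))
    miss_a = table["cdr3a_aa"].map(_is_missing)
    miss_b = table["cdr3b_aa"].map(_is_missing)
    qc.n_missing_both = int((miss_a & miss_b).sum())
    qc.n_missing_alpha = int((miss_a & ~miss_b).sum())
    qc.n_missing_beta = int((miss_b & ~miss_a).sum())
    paired = table[~miss_a & ~miss_b].copy()
    qc.n_paired = len(paired)
    if len(paired):
        bad = ~(
            paired["cdr3a_aa"].astype(str).str.match(_AA_RE)
            & paired["cdr3b_aa"].astype(str).str.match(_AA_RE)
        )
        if bad.any():
            offenders = paired.index[bad].tolist()[:20]
            raise ValueError(
                f"malformed CDR3 amino-acid strings in {int(bad.sum())} cell(s); "
                f"first offending rows: {offenders}"
            )

    paired["clonotype"] = paired["cdr3a_aa"].astype(str) + "|" + paired["cdr3b_aa"].astype(str)
    keys = []
    if group_by:
        keys = [group_by] if isinstance(group_by, str) else list(group_by)
        keys = [k for k in keys if k in paired.columns]
    summary = (
        paired.groupby(keys + ["clonotype"], observed=True)
        .size()
        .rename("size")
        .reset_index()
    )
    summary["expansion_class"] = classify_expansion(summary["size"])
    return summary, qc


def classify_expansion(sizes) -> pd.Series | np.ndarray:
    """Expansion class per clone size: barely (=1) / intermediate (2-10) / heavily (>10)."""
    s = np.asarray(sizes)
    out = np.where(
        s <= BARELY_MAX, "barely",
        np.where(s > HEAVILY_MIN_EXCLUSIVE, "heavily", "intermediate"),
    )
    if isinstance(sizes, pd.Series):
        return pd.Series(out, index=sizes.index, name="expansion_class")
    return out


def shannon_diversity(sizes) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of clone-size proportions."""
    s = np.asarray(list(sizes), dtype=float)
    if s.size == 0:
        raise ValueError("cannot compute diversity of an empty clone-size list")
    if (s <= 0).any():
        raise ValueError("clone sizes must be positive")
    p = s / s.sum()
    return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class DiversityResult:
    """Unique clonotypes S, Shannon H, Pielou evenness J and clonality 1-J."""

    S: int
    H: float
    J: float
    clonality: float


def pielou_clonality(sizes) -> DiversityResult:
    """Pielou evenness J = H / ln S and clonality = 1 - J.

    A repertoire of a single clone (S = 1) is maximally clonal by
    convention: J = 0, clonality = 1.
    """
    s = np.asarray(list(sizes), dtype=float)
    H = shannon_diversity(s)
    S = int(s.size)
    if S == 1:
        return DiversityResult(S=1, H=H, J=0.0, clonality=1.0)
    J = H / math.log(S)
    return DiversityResult(S=S, H=H, J=J, clonality=1.0 - J)


def unique_clonotype_count(summary: pd.DataFrame, cluster_label: str | None = None) -> int:
    """Number of distinct clonotypes (duplicated clonotypes counted once)."""
    sub = summary
    if cluster_label is not None:
        sub = summary[summary["cluster_label"] == cluster_label]
    return int(sub["clonotype"].nunique())


def expansion_class_counts(summary: pd.DataFrame) -> dict[str, int]:
    """Counts of clones per expansion class; classes partition all clones."""
    counts = {"barely": 0, "intermediate": 0, "heavily": 0}
    vc = classify_expansion(summary["size"]).value_counts()
    counts.update({str(k): int(v) for k, v in vc.items()})
    return counts


def match_vdjdb(summary: pd.DataFrame, vdjdb: pd.DataFrame) -> pd.DataFrame:
    """Flag virus-specific clones by dual-chain matching against VDJdb.

    A clone is virus-specific iff its CDR3-alpha exactly matches a TRA
    entry AND its CDR3-beta exactly matches a TRB entry AND the two
    matched entries share the same epitope.  All qualifying epitopes
    are reported (semicolon-joined).
    """
    for col in ("cdr3", "chain", "epitope"):
        if col not in vdjdb.columns:
            raise ValueError(f"VDJdb table missing required column {col!r}")
    bad_chain = ~vdjdb["chain"].isin(["TRA", "TRB"])
    if bad_chain.any():
        warnings.warn(f"{int(bad_chain.sum())} VDJdb rows with chain not in TRA/TRB ignored")
        vdjdb = vdjdb[~bad_chain]

    tra: dict[str, set] = {}
    trb: dict[str, set] = {}
    for chain, target in (("TRA", tra), ("TRB", trb)):
        sub = vdjdb[vdjdb["chain"] == chain]
        for cdr3, ep in zip(sub["cdr3"].astype(str).str.upper(), sub["epitope"]):
            target.setdefault(cdr3, set()).add(ep)

    out = summary.copy()
    parts = out["clonotype"].str.split("|", n=1, expand=True)
    epitopes, flags = [], []
    for a, b in zip(parts[0], parts[1]):
        shared = tra.get(a, set()) & trb.get(b, set())
        flags.append(bool(shared))
        epitopes.append(";".join(sorted(map(str, shared))) if shared else "")
    out["virus_specific"] = flags
    out["epitopes"] = epitopes
    return out


def diversity_by(summary: pd.DataFrame, by: str | list[str]) -> pd.DataFrame:
    """Per-group diversity table: S, H, J, clonality from clone sizes."""
    rows = []
    keys = [by] if isinstance(by, str) else list(by)
    for name, grp in summary.groupby(keys, observed=True):
        res = pielou_clonality(grp["size"].to_numpy())
        name = name if isinstance(name, tuple) else (name,)
        rows.append(dict(zip(keys, name)) | {
            "S": res.S, "H": res.H, "J": res.J, "clonality": res.clonality,
        })
    return pd.DataFrame(rows)
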