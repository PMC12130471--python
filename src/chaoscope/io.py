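"""Readers, writers and the pipeline driver.

Interchange formats are plain text: per-cell marker tables and donor
profiles as CSV, clonotypes as 10x-style contig-annotation TSV/CSV,
VDJdb exports as TSV, gene sets as GMT, expression as MatrixMarket
triplets (+ genes/barcodes TSV) or dense CSV, outcomes as CSV.  Every
writer emits a provenance header line (tool version, config hash,
seed) as a ``#`` comment; readers skip it.

Percentages live on the 0-100 scale in files (as printed clinically)
and on the 0-1 scale internally; converters sit at this boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

from . import __version__
from .scoring import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_cell_table", "write_cell_table",
    "read_contigs", "write_contigs",
    "read_vdjdb", "read_gmt", "write_gmt",
    "read_expression", "write_expression_mtx",
    "read_outcomes", "write_outcomes",
    "read_profiles", "write_profiles",
    "PipelineConfig", "run_pipeline",
]

REQUIRED_CELL_COLUMNS = ("donor_id", "group")
GATING_MARKERS = ("CCR7", "CD45RA", "CD27", "CD28")


def _provenance(seed=None, config_hash=None) -> str:
    parts = [f"chaoscope v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return "# " + " ".join(parts)


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path, seed=None, chash=None, sep=",") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, chash) + "\n")
        df.to_csv(fh, index=False, sep=sep)


def _schema_error(path, missing) -> ValueError:
    return ValueError(f"{path}: missing required column(s) {sorted(missing)}")


def read_cell_table(path) -> pd.DataFrame:
    """Per-cell marker-intensity CSV -> validated cell table."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty cell table")
    missing = set(REQUIRED_CELL_COLUMNS) - set(df.columns)
    missing |= set(GATING_MARKERS) - set(df.columns)
    if missing:
        raise _schema_error(path, missing)
    markers = [c for c in df.columns if c not in
               ("donor_id", "group", "stage", "batch_id", "cell_id",
                "true_subset", "gzmk_pos", "subset", "mem_subset")]
    bad = ~np.isfinite(df[markers].to_numpy(dtype=float))
    if bad.any():
        raise ValueError(f"{path}: non-finite marker intensities in {int(bad.sum())} entries")
    if (df[markers].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative marker intensities")
    return df


def write_cell_table(df, path, seed=None, chash=None) -> None:
    _write_csv(df, path, seed, chash)


def read_contigs(path, abundance_col: str = "reads") -> tuple[pd.DataFrame, dict]:
    """10x-style contig annotations -> per-cell paired-CDR3 table.

    Expects columns ``barcode``, ``chain`` (TRA/TRB), ``cdr3`` and
    optionally ``donor_id`` and an abundance column; when a cell has
    multiple contigs for one locus, the highest-abundance one is kept.
    Returns ``(table, qc)`` where ``qc`` counts unpaired cells.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty contig file")
    missing = {"barcode", "chain", "cdr3"} - set(df.columns)
    if missing:
        raise _schema_error(path, missing)
    df = df[df["chain"].isin(["TRA", "TRB"])]
    if abundance_col in df.columns:
        df = df.sort_values(abundance_col, ascending=False)
    df = df.drop_duplicates(["barcode", "chain"], keep="first")

    wide = df.pivot(index="barcode", columns="chain", values="cdr3")
    wide = wide.reindex(columns=["TRA", "TRB"])
    out = pd.DataFrame({
        "cell_id": wide.index,
        "cdr3a_aa": wide["TRA"].to_numpy(),
        "cdr3b_aa": wide["TRB"].to_numpy(),
    }).reset_index(drop=True)
    for extra in ("donor_id", "cluster_label"):
        if extra in df.columns:
            out[extra] = df.drop_duplicates("barcode").set_index("barcode").loc[
                out["cell_id"], extra
            ].to_numpy()
    qc = {
        "n_cells": len(out),
        "n_unpaired": int(out[["cdr3a_aa", "cdr3b_aa"]].isna().any(axis=1).sum()),
    }
    return out, qc


def write_contigs(clonotype_table: pd.DataFrame, path, seed=None, chash=None) -> None:
    """Per-cell paired table -> long 10x-style contig TSV (one row per chain)."""
    rows = []
    for _, r in clonotype_table.iterrows():
        for chain, col in (("TRA", "cdr3a_aa"), ("TRB", "cdr3b_aa")):
            if pd.notna(r[col]):
                rows.append({
                    "barcode": r["cell_id"], "chain": chain, "cdr3": r[col],
                    "donor_id": r.get("donor_id"),
                    "cluster_label": r.get("cluster_label"),
                    "reads": 100,
                })
    _write_csv(pd.DataFrame(rows), path, seed, chash, sep="\t")


_VDJDB_ALIASES = {
    "cdr3": ("cdr3", "cdr3_aa", "CDR3"),
    "chain": ("chain", "gene", "Gene"),
    "epitope": ("epitope", "antigen.epitope", "Epitope"),
}


def read_vdjdb(path) -> pd.DataFrame:
    """VDJdb export TSV -> (cdr3, chain, epitope) table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {}
    for canon, aliases in _VDJDB_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            raise _schema_error(path, {canon})
        cols[found] = canon
    out = df.rename(columns=cols)[list(_VDJDB_ALIASES)]
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file -> {set name: gene list}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_expression(path) -> ExpressionMatrix:
    """MTX triplet directory (matrix.mtx + genes.tsv + barcodes.tsv +
    optional obs.csv) or a dense CSV (genes x cells) -> ExpressionMatrix."""
    path = Path(path)
    if path.is_dir():
        mat = spio.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        values = pd.DataFrame(
            np.asarray(mat.todense() if sp.issparse(mat) else mat),
            index=genes, columns=barcodes,
        )
        obs_path = path / "obs.csv"
        if obs_path.exists():
            obs = pd.read_csv(obs_path, comment="#", index_col=0)
        else:
            obs = pd.DataFrame(index=values.columns)
    else:
        values = pd.read_csv(path, comment="#", index_col=0)
        obs = pd.DataFrame(index=values.columns)
    if values.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return ExpressionMatrix(values=values, obs=obs)


def write_expression_mtx(expr: ExpressionMatrix, outdir, seed=None, chash=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(expr.values.to_numpy()))
    expr.values.index.to_series().to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(expr.values.columns).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    with open(outdir / "obs.csv", "w") as fh:
        fh.write(_provenance(seed, chash) + "\n")
        expr.obs.to_csv(fh)


_RESPONSES = {"CR", "PR", "SD", "PD"}


def read_outcomes(path) -> pd.DataFrame:
    """Clinical outcome CSV -> validated table."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty outcome table")
    if "donor_id" not in df.columns or "best_response" not in df.columns:
        raise _schema_error(path, {"donor_id", "best_response"} - set(df.columns))
    known = df["best_response"].dropna()
    bad = ~known.isin(_RESPONSES)
    if bad.any():
        raise ValueError(
            f"{path}: unrecognised best_response values: {sorted(known[bad].unique())}"
        )
    return df


def write_outcomes(df, path, seed=None, chash=None) -> None:
    _write_csv(df, path, seed, chash)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "donor_id" not in df.columns:
        raise _schema_error(path, {"donor_id"})
    return df


def write_profiles(df, path, seed=None, chash=None) -> None:
    _write_csv(df, path, seed, chash)


# ---------------------------------------------------------------------------
# pipeline driver

_PIPELINE_KEYS = {
    "simulate", "cells", "contigs", "vdjdb", "expression", "gmt", "outcomes",
    "out_dir", "disease", "thresholds", "reference_donor", "trajectory",
    "scoring", "seed",
}


class PipelineConfig(dict):
    """Strict-schema pipeline configuration (unknown keys rejected)."""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _PIPELINE_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(raw)


def run_pipeline(config: PipelineConfig, seed: int = 0) -> dict:
    """Execute simulate (optional) -> gate -> repertoire -> score ->
    trajectory -> biomarker; returns (and writes) a results bundle.

    Stages whose inputs are absent are skipped with a logged notice;
    a stage failure halts with the stage name, earlier outputs kept.
    """
    from . import biomarker as bm
    from . import gating, repertoire, scoring, trajectory
    from . import synthetic

    out_dir = Path(config.get("out_dir", "chaoscope_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))
    chash = config_hash(dict(config))
    results: dict = {"version": __version__, "seed": seed, "config_hash": chash,
                     "stages": {}}
    stage = "setup"
    try:
        vdjdb_df = None
        expr = None
        gmt_sets = None
        outcomes = None

        if config.get("simulate"):
            stage = "simulate"
            sim_opts = config["simulate"] if isinstance(config["simulate"], dict) else {}
            cfg = synthetic.SimulationConfig(seed=seed, **sim_opts)
            cohort = synthetic.simulate_cohort(cfg)
            cells = cohort.cell_table
            clono = cohort.clonotype_table
            vdjdb_df = cohort.vdjdb
            expr = cohort.expression
            outcomes = cohort.outcomes
            write_cell_table(cells, out_dir / "cells.csv", seed, chash)
            write_outcomes(outcomes, out_dir / "outcomes.csv", seed, chash)
            with open(out_dir / "truth.yaml", "w") as fh:
                yaml.safe_dump(cohort.truth, fh, default_flow_style=False)
            results["stages"]["simulate"] = {
                "n_cells": len(cells), "n_donors": cells["donor_id"].nunique(),
            }
        else:
            if not config.get("cells"):
                raise ValueError("no cells input and simulate not requested")
            cells = read_cell_table(config["cells"])
            clono = None
            if config.get("contigs"):
                clono, contig_qc = read_contigs(config["contigs"])
                results["stages"]["contigs_qc"] = contig_qc
            if config.get("vdjdb"):
                vdjdb_df = read_vdjdb(config["vdjdb"])
            if config.get("expression"):
                expr = read_expression(config["expression"])
            if config.get("gmt"):
                gmt_sets = read_gmt(config["gmt"])
            if config.get("outcomes"):
                outcomes = read_outcomes(config["outcomes"])

        stage = "gate"
        thr = gating.derive_marker_thresholds(cells, seed=seed)
        labeled = gating.classify_subsets(cells, thr)
        profiles = gating.subset_frequencies(labeled)
        write_profiles(profiles, out_dir / "profiles.csv", seed, chash)
        results["stages"]["gate"] = {"n_donors": len(profiles)}

        if clono is not None:
            stage = "repertoire"
            summary, qc = repertoire.define_clonotypes(clono)
            if vdjdb_df is not None:
                summary = repertoire.match_vdjdb(summary, vdjdb_df)
            div = repertoire.diversity_by(summary, "donor_id")
            _write_csv(summary, out_dir / "clones.csv", seed, chash)
            _write_csv(div, out_dir / "diversity.csv", seed, chash)
            results["stages"]["repertoire"] = {
                "n_clones": len(summary), "qc_excluded": qc.n_excluded,
            }
        else:
            logger.info("repertoire stage skipped (no clonotype input)")

        if expr is not None:
            stage = "score"
            if gmt_sets is None:
                gmt_sets = {
                    "quiescence_like": [f"QUI{i:03d}" for i in range(30)],
                    "activation_like": [f"ACT{i:03d}" for i in range(30)],
                    "inflammation_like": [f"INF{i:03d}" for i in range(30)],
                }
            score_opts = config.get("scoring") or {}
            cluster = score_opts.get("cluster", "Tem_DP")
            scores = pd.DataFrame({
                name: scoring.module_score(expr, genes, seed=seed, set_name=name)
                for name, genes in gmt_sets.items()
            })
            avgs = scoring.cluster_average_scores(scores, expr.obs, cluster)
            healthy_ids = expr.obs.loc[
                expr.obs.get("group", pd.Series("", index=expr.obs.index)) == "healthy",
                "donor_id",
            ].unique() if "group" in expr.obs.columns else []
            if len(healthy_ids):
                rel = scoring.relative_module_score(avgs.dropna(), healthy_ids)
                _write_csv(rel.reset_index(), out_dir / "relative_scores.csv", seed, chash)
            _write_csv(avgs.reset_index(), out_dir / "module_scores.csv", seed, chash)
            results["stages"]["score"] = {"n_sets": scores.shape[1]}
        else:
            logger.info("scoring stage skipped (no expression input)")

        stage = "trajectory"
        traj_opts = config.get("trajectory") or {}
        panel = [m for m in trajectory.DEFAULT_MARKER_PANEL if m in labeled.columns]
        max_cells = int(traj_opts.get("max_cells", 20000))
        sub = labeled
        if len(sub) > max_cells:
            sub = sub.sample(max_cells, random_state=seed).sort_index()
        scaled = trajectory.scale_markers(sub, panel)
        pt = trajectory.compute_pseudotime(
            scaled, sub["subset"],
            root_subset=traj_opts.get("root", "Tn"),
            d=int(traj_opts.get("d", 5)), k=int(traj_opts.get("k", 15)),
        )
        avg_pt = trajectory.average_pseudotime(pt.t, sub["donor_id"], sub["subset"])
        _write_csv(avg_pt, out_dir / "pseudotime_by_donor.csv", seed, chash)
        results["stages"]["trajectory"] = {
            "n_cells": len(sub), "n_unreachable": pt.n_unreachable,
        }

        if outcomes is not None:
            stage = "biomarker"
            disease = config.get("disease", "NSCLC")
            if config.get("thresholds"):
                t = config["thresholds"]
                bthr = bm.BiomarkerThresholds(
                    t["dn_tem"], t["dp_temra"], disease_context=disease
                )
            else:
                bthr = bm.BiomarkerThresholds.for_disease(disease)
            res = bm.evaluate_biomarker(profiles, outcomes, bthr)
            results["stages"]["biomarker"] = res.to_dict()
        else:
            logger.info("biomarker stage skipped (no outcomes input)")

        with open(out_dir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=str)
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
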