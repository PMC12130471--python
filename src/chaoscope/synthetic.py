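"""Synthetic cohort generator for the CD8+ T-cell pipeline.

Emulates the statistical structure the downstream analysis assumes:
per-donor subset compositions (healthy vs patient, with a
stage-dependent DN-Tem shift), per-subset log-normal marker
intensities with multiplicative batch effects, clone-size
distributions mixing singletons with a power-law expanded tail, a
GZMK+-like DN-Tem subpopulation enriched in patients (barely expanded,
intermediate marker profile), block-structured gene programs
(quiescence / activation / inflammation), and clinical outcomes drawn
from a logistic response model applied to each donor's true biomarker
quadrant.

One root seed drives everything; per-donor substreams are derived from
(seed, donor index) so donor-level output is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .biomarker import BiomarkerThresholds, assign_quadrant
from .scoring import ExpressionMatrix

__all__ = [
    "ResponseModel",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_clone_sizes",
    "attach_outcomes",
    "synthetic_vdjdb",
]

_LN = math.log

FULL_SUBSETS = (
    "Tn", "Tcm",
    "Tem_DP", "Tem_SP27", "Tem_SP28", "Tem_DN",
    "Temra_DP", "Temra_SP27", "Temra_SP28", "Temra_DN",
)

MARKERS = ("CCR7", "CD45RA", "CD27", "CD28", "CD95", "CD73", "CXCR4", "CXCR3", "CD8", "CD3")

#: the differentiation chain used by the activation-drift model
NEXT_SUBSET = {
    "Tn": "Tcm", "Tcm": "Tem_DP",
    "Tem_DP": "Tem_DN", "Tem_SP27": "Tem_DN", "Tem_SP28": "Tem_DN",
    "Tem_DN": None,
    "Temra_DP": "Temra_DN", "Temra_SP27": "Temra_DN", "Temra_SP28": "Temra_DN",
    "Temra_DN": None,
}


def _default_marker_modes() -> dict:
    """Positive/negative mode per (full subset, marker).

    Encodes the gating definitions (Tn: CCR7+CD45RA+; DN: CD27-CD28-)
    plus a monotone differentiation axis for CD95 (rises), CD73 and
    CXCR3 (fall), so graph pseudotime can recover subset order.
    """
    modes = {}
    for s in FULL_SUBSETS:
        tem_like = s.startswith(("Tem_", "Temra_"))
        mem = s.split("_")[1] if tem_like else None
        modes[s] = {
            "CCR7": "pos" if s in ("Tn", "Tcm") else "neg",
            "CD45RA": "pos" if s == "Tn" or s.startswith("Temra") else "neg",
            "CD27": "pos" if (not tem_like or mem in ("DP", "SP27")) else "neg",
            "CD28": "pos" if (not tem_like or mem in ("DP", "SP28")) else "neg",
            "CD95": "neg" if s in ("Tn", "Tcm") else "pos",
            "CD73": "pos" if s in ("Tn", "Tcm", "Tem_DP", "Temra_DP") else "neg",
            "CXCR3": "pos" if s in ("Tn", "Tcm", "Tem_DP", "Temra_DP") else "neg",
            "CXCR4": "pos",
            "CD8": "pos",
            "CD3": "pos",
        }
    return modes


@dataclass
class ResponseModel:
    """Logistic response model on the donor's true quadrant.

    PR probability = logistic(intercept + log-odds of the quadrant).
    Defaults encode the configured Q4/Q1 partial-response rates of
    0.45 / 0.18 with slightly worse odds in the DP-Temra-hi quadrants.
    """

    intercept: float = _LN(0.18 / 0.82)  # logit of the Q1 PR rate
    quadrant_log_odds: dict = field(default_factory=lambda: {
        "Q1": 0.0,
        "Q2": -0.45,
        "Q3": -0.25,
        "Q4": _LN(0.45 / 0.55) - _LN(0.18 / 0.82),
    })
    cr_fraction: float = 0.05          # responders labelled CR rather than PR
    sd_fraction_nonresponder: float = 0.5
    dcb_given_sd: float = 0.5
    pfs_hazard_per_day: dict = field(default_factory=lambda: {
        "Q1": 1 / 150.0, "Q2": 1 / 120.0, "Q3": 1 / 140.0, "Q4": 1 / 320.0,
    })
    censoring_days: float = 730.0      # administrative censoring

    def pr_probability(self, quadrant: str) -> float:
        if quadrant not in self.quadrant_log_odds:
            raise ValueError(f"missing quadrant coefficient for {quadrant!r}")
        eta = self.intercept + self.quadrant_log_odds[quadrant]
        return 1.0 / (1.0 + math.exp(-eta))


def _check_probvec(vec: dict, name: str) -> None:
    total = float(sum(vec.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probability vector {name!r} sums to {total}, not 1")
    if any(v < 0 for v in vec.values()):
        raise ValueError(f"probability vector {name!r} has negative entries")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_healthy: int = 50
    n_patients: int = 50
    cells_per_donor: int = 5000
    stage_distribution: dict = field(default_factory=lambda: {
        "I": 0.2, "II": 0.2, "III": 0.3, "IV": 0.3,
    })
    subset_base_composition: dict = field(default_factory=lambda: {
        "Tn": 0.30, "Tcm": 0.20, "Tem": 0.35, "Temra": 0.15,
    })
    tem_composition_healthy: dict = field(default_factory=lambda: {
        "DP": 0.40, "SP27": 0.15, "SP28": 0.15, "DN": 0.30,
    })
    tem_composition_patient: dict = field(default_factory=lambda: {
        "DP": 0.22, "SP27": 0.14, "SP28": 0.14, "DN": 0.50,
    })
    temra_composition_healthy: dict = field(default_factory=lambda: {
        "DP": 0.15, "SP27": 0.20, "SP28": 0.15, "DN": 0.50,
    })
    temra_composition_patient: dict = field(default_factory=lambda: {
        "DP": 0.18, "SP27": 0.17, "SP28": 0.15, "DN": 0.50,
    })
    dn_shift_per_stage: dict = field(default_factory=lambda: {
        "I": 0.0, "II": 0.0, "III": 0.0, "IV": 0.0,
    })
    subset_concentration: float = 100.0   # Dirichlet concentration, donor variability
    tem_concentration: float = 100.0
    gzmk_pos_fraction_dn: float = 0.5     # patient DN-Tem cells that are GZMK+-like
    marker_modes: dict = field(default_factory=_default_marker_modes)
    mode_params: dict = field(default_factory=lambda: {
        # ln-scale (mu, sigma) of the log-normal intensity modes
        "neg": (_LN(100.0), 0.5),
        "pos": (_LN(10000.0), 0.5),
    })
    # mean per-cell interpolation of patient cells toward the next subset
    # on the differentiation chain (0 = no drift); emulates a continuous
    # flow of activation/differentiation
    activation_drift: float = 0.0
    batch_effects: dict = field(default_factory=lambda: {
        "B1": 1.0, "B2": 1.2, "B3": 0.85,
    })
    clone_singleton_fraction: float = 0.6
    clone_power_exponent: float = 2.5
    virus_specific_fraction: float = 0.05
    response_model: ResponseModel = field(default_factory=ResponseModel)
    thresholds: BiomarkerThresholds = field(default_factory=lambda: BiomarkerThresholds.for_disease("NSCLC"))
    n_expression_cells_per_donor: int = 150
    expression_effect: float = 0.5        # block shift of the gene programs
    inflamed_patient_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "stage_distribution", "subset_base_composition",
            "tem_composition_healthy", "tem_composition_patient",
            "temra_composition_healthy", "temra_composition_patient",
        ):
            _check_probvec(getattr(self, name), name)
        for name in ("n_healthy", "n_patients", "cells_per_donor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.clone_power_exponent <= 1.0:
            raise ValueError("clone_power_exponent must be > 1")
        if not (0.0 <= self.clone_singleton_fraction <= 1.0):
            raise ValueError("clone_singleton_fraction must be a probability")


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the generating truth."""

    cell_table: pd.DataFrame
    clonotype_table: pd.DataFrame
    expression: ExpressionMatrix
    outcomes: pd.DataFrame
    vdjdb: pd.DataFrame
    truth: dict


def _donor_rng(seed: int, donor_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, donor_index])


def _counts_from_composition(comp: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of comp * n to integers summing to n."""
    raw = comp * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def simulate_clone_sizes(
    n_cells: int,
    singleton_fraction: float,
    exponent: float,
    seed,
) -> np.ndarray:
    """Clone sizes mixing singletons with a power-law expanded tail.

    Sizes always sum exactly to ``n_cells``; the expected fraction of
    cells carried by size-1 clones is ~``singleton_fraction``.  The
    expanded tail is discrete power law P(s) ~ s^-exponent on s >= 2
    (the last drawn clone is truncated to fit).
    """
    if not (0.0 <= singleton_fraction <= 1.0):
        raise ValueError("singleton_fraction must be a probability")
    if exponent <= 1.0:
        raise ValueError("exponent must be > 1")
    if n_cells == 0:
        return np.array([], dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_single = int(round(singleton_fraction * n_cells))
    remaining = n_cells - n_single
    if remaining == 1:  # a lone leftover cell can only be a singleton
        n_single, remaining = n_single + 1, 0
    sizes = [1] * n_single
    if remaining:
        s_max = min(remaining, 10_000)
        support = np.arange(2, s_max + 1)
        if support.size == 0:
            sizes.append(remaining)
            remaining = 0
        else:
            pmf = support.astype(float) ** -exponent
            pmf /= pmf.sum()
            mean_size = float((support * pmf).sum())
            while remaining > 0:
                batch = max(16, int(1.5 * remaining / mean_size))
                draws = rng.choice(support, size=batch, p=pmf)
                cum = np.cumsum(draws)
                cut = int(np.searchsorted(cum, remaining))
                if cut < batch:  # batch covers the remainder; truncate last clone
                    kept = draws[:cut].tolist()
                    last = remaining - (cum[cut - 1] if cut else 0)
                    if last:
                        kept.append(int(last))
                    sizes.extend(kept)
                    remaining = 0
                else:
                    sizes.extend(draws.tolist())
                    remaining -= int(cum[-1])
    sizes = np.asarray(sizes, dtype=int)
    assert sizes.sum() == n_cells
    return sizes


_AA_POOL = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_cdr3(rng: np.random.Generator, n: int, prefix: str = "CA") -> np.ndarray:
    """n random CDR3-like amino-acid strings (synthetic, not biological)."""
    lengths = rng.integers(8, 14, size=n)
    flat = rng.integers(0, len(_AA_POOL), size=int(lengths.sum()))
    out = np.empty(n, dtype=object)
    pos = 0
    for i, L in enumerate(lengths):
        out[i] = prefix + "".join(_AA_POOL[flat[pos:pos + L]]) + "F"
        pos += L
    return out


def synthetic_vdjdb(n_epitopes: int = 40, pairs_per_epitope: int = 5, seed: int = 991) -> pd.DataFrame:
    """A small synthetic VDJdb-style reference (cdr3, chain, epitope).

    Purely synthetic stand-in for a VDJdb export: paired TRA/TRB rows
    sharing an epitope identifier, used to tag generator clones and to
    exercise the dual-chain matching rule.
    """
    rng = np.random.default_rng(seed)
    n = n_epitopes * pairs_per_epitope
    alphas = _random_cdr3(rng, n, prefix="CAV")
    betas = _random_cdr3(rng, n, prefix="CASS")
    epitopes = np.repeat([f"EP{i:03d}" for i in range(n_epitopes)], pairs_per_epitope)
    rows = []
    for a, b, ep in zip(alphas, betas, epitopes):
        rows.append({"cdr3": a, "chain": "TRA", "epitope": ep})
        rows.append({"cdr3": b, "chain": "TRB", "epitope": ep})
    return pd.DataFrame(rows)


def _shifted_tem_composition(comp: dict, shift: float) -> np.ndarray:
    """Additive logit shift of the DN component, others rescaled."""
    order = ("DP", "SP27", "SP28", "DN")
    vec = np.array([comp[k] for k in order], dtype=float)
    if shift != 0.0:
        dn = vec[3]
        dn_new = 1.0 / (1.0 + math.exp(-(math.log(dn / (1 - dn)) + shift)))
        vec[:3] *= (1.0 - dn_new) / (1.0 - dn)
        vec[3] = dn_new
    return vec


def attach_outcomes(
    profiles: pd.DataFrame,
    thresholds: BiomarkerThresholds,
    response_model: ResponseModel,
    seed: int,
) -> pd.DataFrame:
    """Draw clinical outcomes from the response model on true quadrants.

    ``profiles`` needs ``donor_id`` plus either a ``quadrant`` column
    or the two percent-scale frequencies.  Healthy donors (``group ==
    'healthy'``) receive rows with missing responses so every donor of
    a cohort is represented.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in profiles.iterrows():
        donor = r["donor_id"]
        group = r.get("group", "patient")
        if group == "healthy":
            rows.append({
                "donor_id": donor, "group": group, "quadrant": None,
                "best_response": None, "response_6m": None, "dcb": None,
                "pfs_time": np.nan, "pfs_event": None,
            })
            continue
        if "quadrant" in r and isinstance(r["quadrant"], str):
            q = r["quadrant"]
        else:
            q = assign_quadrant(r["dn_tem_pct"], r["dp_temra_pct"], thresholds)
        p_pr = response_model.pr_probability(q)
        is_pr = rng.random() < p_pr
        if is_pr:
            best = "CR" if rng.random() < response_model.cr_fraction else "PR"
            resp6 = "PR"
            dcb = True
        else:
            if rng.random() < response_model.sd_fraction_nonresponder:
                best = "SD"
                dcb = bool(rng.random() < response_model.dcb_given_sd)
                resp6 = "SD" if dcb else "PD"
            else:
                best, resp6, dcb = "PD", "PD", False
        hazard = response_model.pfs_hazard_per_day.get(q)
        if hazard is None:
            raise ValueError(f"missing PFS hazard for quadrant {q!r}")
        t_event = rng.exponential(1.0 / hazard)
        censored = t_event >= response_model.censoring_days
        rows.append({
            "donor_id": donor, "group": group, "quadrant": q,
            "best_response": best, "response_6m": resp6, "dcb": dcb,
            "pfs_time": float(min(t_event, response_model.censoring_days)),
            "pfs_event": not censored,
        })
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given the seed."""
    config.validate()
    cfg = config
    subset_order = ("Tn", "Tcm", "Tem", "Temra")
    base = np.array([cfg.subset_base_composition[s] for s in subset_order])
    mem_order = ("DP", "SP27", "SP28", "DN")
    batches = list(cfg.batch_effects)
    stages = list(cfg.stage_distribution)
    stage_p = np.array([cfg.stage_distribution[s] for s in stages])

    donors = (
        [(f"H{i + 1:03d}", "healthy") for i in range(cfg.n_healthy)]
        + [(f"P{i + 1:03d}", "patient") for i in range(cfg.n_patients)]
    )
    reference_donor = donors[0][0] if cfg.n_healthy else None

    cell_frames, clono_frames = [], []
    truth_donors = {}
    vdjdb = synthetic_vdjdb()
    vd_pairs = (
        vdjdb[vdjdb["chain"] == "TRA"].reset_index(drop=True)["cdr3"].to_numpy(),
        vdjdb[vdjdb["chain"] == "TRB"].reset_index(drop=True)["cdr3"].to_numpy(),
        vdjdb[vdjdb["chain"] == "TRA"].reset_index(drop=True)["epitope"].to_numpy(),
    )
    mu_neg, sd_neg = cfg.mode_params["neg"]
    mu_pos, sd_pos = cfg.mode_params["pos"]

    for donor_idx, (donor, group) in enumerate(donors):
        rng = _donor_rng(cfg.seed, donor_idx)
        stage = stages[rng.choice(len(stages), p=stage_p)] if group == "patient" else None

        comp = rng.dirichlet(base * cfg.subset_concentration)
        counts = _counts_from_composition(comp, cfg.cells_per_donor)

        tem_base = (
            cfg.tem_composition_patient if group == "patient" else cfg.tem_composition_healthy
        )
        temra_base = (
            cfg.temra_composition_patient if group == "patient" else cfg.temra_composition_healthy
        )
        shift = cfg.dn_shift_per_stage.get(stage, 0.0) if stage else 0.0
        tem_vec = _shifted_tem_composition(tem_base, shift)
        temra_vec = np.array([temra_base[k] for k in mem_order])
        tem_comp = rng.dirichlet(tem_vec * cfg.tem_concentration)
        temra_comp = rng.dirichlet(temra_vec * cfg.tem_concentration)

        # exact per-full-subset cell counts
        full_counts: dict[str, int] = {
            "Tn": counts[0], "Tcm": counts[1],
        }
        tem_counts = _counts_from_composition(tem_comp, counts[2])
        temra_counts = _counts_from_composition(temra_comp, counts[3])
        for m, c in zip(mem_order, tem_counts):
            full_counts[f"Tem_{m}"] = int(c)
        for m, c in zip(mem_order, temra_counts):
            full_counts[f"Temra_{m}"] = int(c)

        labels = np.repeat(
            [s for s in FULL_SUBSETS], [full_counts[s] for s in FULL_SUBSETS]
        )
        n = labels.size
        gzmk = np.zeros(n, dtype=bool)
        if group == "patient" and cfg.gzmk_pos_fraction_dn > 0:
            dn_idx = np.flatnonzero(labels == "Tem_DN")
            n_gz = int(round(cfg.gzmk_pos_fraction_dn * dn_idx.size))
            gzmk[rng.choice(dn_idx, size=n_gz, replace=False)] = False if n_gz == 0 else True

        # marker intensities; under activation drift, each patient cell is
        # interpolated part-way toward the mode profile of the next subset
        # on the differentiation chain (skewed: most cells stay near their
        # own mode, a tail is already en route)
        if group == "patient" and cfg.activation_drift:
            u = np.minimum(rng.exponential(cfg.activation_drift, size=n), 0.8)
        else:
            u = np.zeros(n)
        intensities = np.empty((n, len(MARKERS)))
        for s in FULL_SUBSETS:
            mask = labels == s
            if not mask.any():
                continue
            nxt = NEXT_SUBSET[s]
            for j, marker in enumerate(MARKERS):
                mode = cfg.marker_modes[s][marker]
                mu, sd = (mu_pos, sd_pos) if mode == "pos" else (mu_neg, sd_neg)
                if nxt is None:
                    mu_cells = np.full(int(mask.sum()), mu)
                else:
                    mu_next = (
                        mu_pos if cfg.marker_modes[nxt][marker] == "pos" else mu_neg
                    )
                    mu_cells = (1.0 - u[mask]) * mu + u[mask] * mu_next
                intensities[mask, j] = np.exp(rng.normal(mu_cells, sd))
        # GZMK+ DN-Tem: intermediate profile for the differentiation markers
        gz_idx = np.flatnonzero(gzmk)
        if gz_idx.size:
            for j, marker in enumerate(MARKERS):
                if marker in ("CD27", "CD28", "CD73"):
                    mu_mid = 0.5 * (mu_neg + mu_pos) - 0.8  # below threshold, above neg
                    intensities[gz_idx, j] = rng.lognormal(mu_mid, sd_neg, size=gz_idx.size)

        # batch assignment: reference donor spans all batches
        if donor == reference_donor:
            batch = np.array(batches)[np.arange(n) % len(batches)]
        else:
            batch = np.repeat(batches[donor_idx % len(batches)], n)
        factors = np.array([cfg.batch_effects[b] for b in batch])
        intensities *= factors[:, None]

        cell_ids = np.array([f"{donor}_c{i:05d}" for i in range(n)])
        cells = pd.DataFrame(intensities, columns=MARKERS)
        cells.insert(0, "donor_id", donor)
        cells.insert(1, "group", group)
        cells.insert(2, "stage", stage)
        cells.insert(3, "batch_id", batch)
        cells.insert(4, "cell_id", cell_ids)
        cells["true_subset"] = labels
        cells["gzmk_pos"] = gzmk
        cell_frames.append(cells)

        # clones: GZMK+ cells are forced singletons; the rest follow the mixture
        non_gz = np.flatnonzero(~gzmk)
        sizes = simulate_clone_sizes(
            non_gz.size, cfg.clone_singleton_fraction, cfg.clone_power_exponent, rng
        )
        order = rng.permutation(non_gz)
        clone_of = np.empty(n, dtype=int)
        pos = 0
        for cid, size in enumerate(sizes):
            clone_of[order[pos:pos + size]] = cid
            pos += size
        n_clones = sizes.size
        for extra, idx in enumerate(gz_idx):
            clone_of[idx] = n_clones + extra
        n_clones += gz_idx.size

        cdr3a = _random_cdr3(rng, n_clones, prefix="CAV")
        cdr3b = _random_cdr3(rng, n_clones, prefix="CASS")
        n_vs = min(int(round(cfg.virus_specific_fraction * n_clones)), vd_pairs[0].size)
        vs_clones = rng.choice(n_clones, size=n_vs, replace=False)
        vs_refs = rng.choice(vd_pairs[0].size, size=n_vs, replace=False)
        cdr3a[vs_clones] = vd_pairs[0][vs_refs]
        cdr3b[vs_clones] = vd_pairs[1][vs_refs]
        vs_flag = np.zeros(n_clones, dtype=bool)
        vs_flag[vs_clones] = True

        clono_frames.append(pd.DataFrame({
            "donor_id": donor,
            "cell_id": cell_ids,
            "cdr3a_aa": cdr3a[clone_of],
            "cdr3b_aa": cdr3b[clone_of],
            "cluster_label": labels,
            "true_clone_id": [f"{donor}_cl{c}" for c in clone_of],
            "true_virus_specific": vs_flag[clone_of],
        }))

        dn_tem_true = float(tem_comp[3])
        dp_temra_true = float(temra_comp[0])
        truth_donors[donor] = {
            "group": group,
            "stage": stage,
            "subset_composition": dict(zip(subset_order, map(float, comp))),
            "tem_composition": dict(zip(mem_order, map(float, tem_comp))),
            "temra_composition": dict(zip(mem_order, map(float, temra_comp))),
            "dn_tem_pct": 100.0 * dn_tem_true,
            "dp_temra_pct": 100.0 * dp_temra_true,
            "quadrant": assign_quadrant(
                100.0 * dn_tem_true, 100.0 * dp_temra_true, cfg.thresholds
            ) if group == "patient" else None,
            "subset_counts": {s: int(full_counts[s]) for s in FULL_SUBSETS},
        }

    cell_table = pd.concat(cell_frames, ignore_index=True)
    clonotype_table = pd.concat(clono_frames, ignore_index=True)

    profiles = pd.DataFrame([
        {
            "donor_id": d,
            "group": info["group"],
            "dn_tem_pct": info["dn_tem_pct"],
            "dp_temra_pct": info["dp_temra_pct"],
            "quadrant": info["quadrant"],
        }
        for d, info in truth_donors.items()
    ])
    outcomes = attach_outcomes(
        profiles, cfg.thresholds, cfg.response_model, seed=cfg.seed + 1
    )

    expression = _simulate_expression(cfg, cell_table)

    truth = {"config": _config_record(cfg), "donors": truth_donors}
    return SyntheticCohort(
        cell_table=cell_table,
        clonotype_table=clonotype_table,
        expression=expression,
        outcomes=outcomes,
        vdjdb=vdjdb,
        truth=truth,
    )


def _simulate_expression(cfg: SimulationConfig, cell_table: pd.DataFrame) -> ExpressionMatrix:
    """Block-structured gene programs on a per-donor cell subsample.

    Three 30-gene programs — quiescence-like (elevated in healthy
    cells), activation-like (elevated in patients) and inflammation-
    like (elevated in a random half of patients) — on top of 60
    background genes.  Values are clipped-at-zero Gaussian
    log-normalised expression.
    """
    rng = np.random.default_rng([cfg.seed, 10**6])
    genes = (
        [f"QUI{i:03d}" for i in range(30)]
        + [f"ACT{i:03d}" for i in range(30)]
        + [f"INF{i:03d}" for i in range(30)]
        + [f"BG{i:03d}" for i in range(60)]
    )
    chosen = []
    for donor, grp in cell_table.groupby("donor_id", observed=True):
        take = min(cfg.n_expression_cells_per_donor, len(grp))
        chosen.append(grp.iloc[
            rng.choice(len(grp), size=take, replace=False)
        ])
    cells = pd.concat(chosen)
    n_cells = len(cells)
    patients = set(
        cell_table.loc[cell_table["group"] == "patient", "donor_id"].unique()
    )
    inflamed = {
        d for d in sorted(patients)
        if rng.random() < cfg.inflamed_patient_fraction
    }

    base = rng.normal(1.0, 0.3, size=(len(genes), n_cells))
    is_patient = (cells["group"] == "patient").to_numpy()
    is_inflamed = cells["donor_id"].isin(inflamed).to_numpy()
    delta = cfg.expression_effect
    base[0:30, ~is_patient] += delta       # quiescence up in healthy
    base[30:60, is_patient] += delta       # activation up in patients
    base[60:90, is_inflamed] += delta      # inflammation in inflamed patients
    base = np.clip(base, 0.0, None)

    values = pd.DataFrame(base, index=genes, columns=cells["cell_id"].to_numpy())
    obs = pd.DataFrame({
        "donor_id": cells["donor_id"].to_numpy(),
        "group": cells["group"].to_numpy(),
        "cluster_label": cells["true_subset"].to_numpy(),
    }, index=cells["cell_id"].to_numpy())
    return ExpressionMatrix(values=values, obs=obs)


def _config_record(cfg: SimulationConfig) -> dict:
    rec = asdict(cfg)
    rec["thresholds"] = {
        "dn_tem": cfg.thresholds.dn_tem, "dp_temra": cfg.thresholds.dp_temra,
        "disease_context": cfg.thresholds.disease_context,
    }
    return rec
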