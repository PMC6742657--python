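"""Self-contained validation experiments for the whole pipeline.

Each function simulates data with known truth, runs the relevant part of the
package, and returns summary numbers. They are used by the test suite and by
``scripts/acceptance.py``; every experiment is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .downstream import fit_pathway_model, site_occupancy_changes
from .ingest import annotate_ptm_sites, log_and_normalize
from .morphometry import fit_group_donor_model
from .pipeline import RunConfig, run_differential
from .protein_model import (
    McmcConfig,
    build_design,
    fit_protein_model,
    moderate_variances,
    test_differential_batch,
)
from .simulate import (
    ProteomicsSimConfig,
    simulate_morphometry,
    simulate_null,
    simulate_proteomics,
    simulate_ptm_protein,
    simulate_timecourse_clusters,
)
from .stats import bh_adjust
from .summaries import cluster_timecourse, fit_gaussian_to_histogram

MAX_SEED = 2**31


def _sub(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % MAX_SEED)


def _fit_all(table, design, mcmc: McmcConfig, base_seed: int):
    fits = []
    for i, acc in enumerate(table.accessions):
        sub = table.copy()
        sub.df = table.df[table.df["accession"] == acc].reset_index(drop=True)
        cfg_i = dataclasses.replace(mcmc, seed=_sub(base_seed, i))
        fits.append(fit_protein_model(build_design(sub, design), cfg_i))
    return fits


def ols_limit_experiment(n_designs: int = 50, seed: int = 0) -> dict:
    """Weak-prior, unweighted Gibbs on random complete balanced designs
    (2-6 peptides, 2 groups, 2-3 donors) versus the normal-equations solve.

    Returns the largest deviation and the largest deviation in units of
    (3 MCSE + 1e-8)."""
    from mechanoprot.ingest import ExperimentDesign

    rng = np.random.default_rng(seed)
    max_dev, max_z = 0.0, 0.0
    for k in range(n_designs):
        F = int(rng.integers(2, 7))
        D = int(rng.integers(2, 4))
        donors = [f"d{j}" for j in range(D)]
        rows = [
            {"sample_id": f"{g}_{d}", "group": g, "donor": d}
            for g in ("control", "strain")
            for d in donors
        ]
        design = ExperimentDesign(pd.DataFrame(rows), "control")
        records = []
        for j in range(F):
            rec = {
                "peptide_id": f"p{j}",
                "sequence": "ACDEFGHIK",
                "modifications": "",
                "accession": "P1",
                "unique": True,
                "score": 50.0,
            }
            for s in design.sample_ids:
                rec[s] = float(rng.normal(0, 1))
            records.append(rec)
        from mechanoprot.ingest import PeptideTable, default_registry

        table = PeptideTable(pd.DataFrame(records), design.sample_ids, default_registry())
        table.log_scale = True
        pdz = build_design(table, design)
        cfg = McmcConfig(
            iterations=2000,
            burn_in=500,
            seed=_sub(seed, 7000 + k),
            robust_weighting=False,
            fixed_lambda1_sq=1e-10,
            fixed_lambda2=1e-10,
        )
        fit = fit_protein_model(pdz, cfg)
        ols = np.linalg.lstsq(pdz.X, pdz.y, rcond=None)[0]
        dev = np.abs(fit.coef_mean - ols)
        tol = 3.0 * np.maximum(fit.coef_mcse, 0.0) + 1e-8
        max_dev = max(max_dev, float(dev.max()))
        max_z = max(max_z, float((dev / tol).max()))
    return {"max_abs_deviation": max_dev, "max_z": max_z, "n": n_designs}


def recovery_experiment(
    n_proteins: int = 200,
    seed: int = 0,
    iterations: int = 1500,
    burn_in: int = 500,
) -> dict:
    """Treatment-effect recovery under the study design (20% differential,
    |beta_g| in [0.5, 1.5] log2, 3 donors)."""
    cfg = ProteomicsSimConfig(n_proteins=n_proteins, seed=_sub(seed, 1), ptm_fraction=0.0)
    table, design, truth = simulate_proteomics(cfg)
    table = log_and_normalize(table)
    fits = _fit_all(table, design, McmcConfig(iterations=iterations, burn_in=burn_in), _sub(seed, 2))
    tru = truth.proteins.set_index("accession")["beta_g"]
    est = np.array([f.beta_g["strain"] for f in fits])
    tr = np.array([tru.loc[f.accession] for f in fits])
    diff = tr != 0
    return {
        "spearman_all": float(spearmanr(tr, est).statistic),
        "spearman_differential": float(spearmanr(tr[diff], est[diff]).statistic),
        "rmse_differential": float(np.sqrt(np.mean((est[diff] - tr[diff]) ** 2))),
        "rmse_null": float(np.sqrt(np.mean(est[~diff] ** 2))),
        "n": int(len(fits)),
        "n_differential": int(diff.sum()),
    }


def null_calibration_experiment(
    n_seeds: int = 20,
    n_proteins: int = 300,
    seed: int = 0,
    iterations: int = 1000,
    burn_in: int = 300,
) -> dict:
    """Fraction of proteins called at q < 0.05 under the global null."""
    fractions = []
    for s in range(n_seeds):
        cfg = ProteomicsSimConfig(n_proteins=n_proteins, seed=_sub(seed, 100 + s), ptm_fraction=0.0)
        table, design, _ = simulate_null(cfg)
        table = log_and_normalize(table)
        fits = _fit_all(table, design, McmcConfig(iterations=iterations, burn_in=burn_in), _sub(seed, 300 + s))
        res = test_differential_batch(fits, moderate_variances(fits))
        fractions.append(float((res["q"] < 0.05).mean()))
    return {
        "mean_q05_fraction": float(np.mean(fractions)),
        "max_q05_fraction": float(np.max(fractions)),
        "n_seeds": n_seeds,
        "n_proteins": n_proteins,
    }


def ptm_recovery_experiment(n_reps: int = 100, seed: int = 0, effect: float = 1.0) -> dict:
    """Occupancy recovery for a +1 log2 interaction on the modified ions."""
    ests = []
    for rep in range(n_reps):
        table, design, truth, _ = simulate_ptm_protein(effect=effect, seed=_sub(seed, 500 + rep))
        tb = log_and_normalize(table)
        fit = fit_protein_model(
            build_design(tb, design),
            McmcConfig(iterations=1500, burn_in=500, seed=_sub(seed, 900 + rep)),
        )
        state = moderate_variances([fit])
        res = site_occupancy_changes([fit], annotate_ptm_sites(tb, truth.proteome), state)
        ests.append(float(res["occupancy_log2fc"].iloc[0]))
    ests = np.asarray(ests)
    lo, hi = effect - 0.2, effect + 0.2
    return {
        "in_band_fraction": float(np.mean((ests >= lo) & (ests <= hi))),
        "mean": float(ests.mean()),
        "sd": float(ests.std(ddof=1)),
        "n": n_reps,
    }


def bh_exactness_check(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Exact agreement of the BH adjustment with an O(n^2) transcription of
    the step-up definition."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 120))
        p = rng.uniform(size=n)
        order = np.argsort(p, kind="mergesort")
        q_sorted = np.empty(n)
        for i in range(n):
            m = np.inf
            for j in range(i, n):
                m = min(m, p[order[j]] * n / (j + 1))
            q_sorted[i] = min(m, 1.0)
        brute = np.empty(n)
        brute[order] = q_sorted
        exact += int(np.array_equal(bh_adjust(p), brute))
    return {"exact_fraction": exact / n_vectors, "n": n_vectors}


def gaussian_recovery_experiment(seed: int = 0, center: float = -0.11, width: float = 0.61, n: int = 5000) -> dict:
    rng = np.random.default_rng(seed)
    fit = fit_gaussian_to_histogram(rng.normal(center, width, size=n), bin_width=0.1)
    return {"center": fit.center, "width": fit.width, "n": n}


def pathway_experiment(
    n_reps: int = 50,
    seed: int = 0,
    shift: float = -0.4,
    n_members: int = 10,
    noise_sd: float = 0.2,
    n_null_pathways: int = 19,
) -> dict:
    """Detection of a pathway-level shift against null pathways at q < 0.05."""
    detected = 0
    null_flagged, null_total = 0, 0
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rows = []
        membership = {}
        acc = 0
        for pw in range(n_null_pathways + 1):
            members = [f"P{acc + i}" for i in range(n_members)]
            acc += n_members
            membership[f"pw{pw}"] = set(members)
            for m in members:
                rows.append({"accession": m, "group": "A",
                             "log2fc": float((shift if pw == 0 else 0.0) + rng.normal(0, noise_sd))})
                rows.append({"accession": m, "group": "B", "log2fc": float(rng.normal(0, noise_sd))})
        _, table = fit_pathway_model(pd.DataFrame(rows), membership)
        hit = table[(table["pathway_id"] == "pw0") & (table["group"] == "A")]
        detected += int((hit["q"] < 0.05).any())
        nulls = table[table["pathway_id"] != "pw0"]
        null_flagged += int((nulls.groupby("pathway_id")["q"].min() < 0.05).sum())
        null_total += n_null_pathways
    return {
        "detection_rate": detected / n_reps,
        "null_flag_rate": null_flagged / null_total,
        "n_reps": n_reps,
    }


def morphometry_oracle_experiment(n_instances: int = 100, seed: int = 0) -> dict:
    """Group/donor fit versus the normal-equations solution."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(20, 60))
        groups = rng.choice(["ctl", "a", "b"], n).tolist()
        donors = rng.choice(["d1", "d2", "d3"], n).tolist()
        if "ctl" not in groups or len(set(groups)) < 2:
            continue
        y = rng.normal(size=n)
        df = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(n)], "group": groups, "donor": donors, "m": y}
        )
        try:
            fit = fit_group_donor_model(df, "m", "ctl")
        except ValueError:
            continue
        nonref = [g for g in dict.fromkeys(groups) if g != "ctl"]
        dlev = list(dict.fromkeys(donors))
        cols = [np.ones(n)]
        for g in nonref:
            cols.append((np.array(groups) == g).astype(float))
        d_idx = np.array([dlev.index(d) for d in donors])
        for j in range(len(dlev) - 1):
            col = np.zeros(n)
            col[d_idx == j] = 1.0
            col[d_idx == len(dlev) - 1] = -1.0
            cols.append(col)
        X = np.column_stack(cols)
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        for k, g in enumerate(nonref):
            max_dev = max(max_dev, abs(fit.beta_g[g] - coef[1 + k]))
        done += 1
    return {"max_abs_deviation": float(max_dev), "n": n_instances}


def morphometry_recovery_experiment(
    n_seeds: int = 50,
    seed: int = 0,
    effect: float = 0.3,
    n_cells: int = 200,
    donor_sd: float = 0.2,
    cell_sd: float = 0.25,
) -> dict:
    """Donor-adjusted recovery of a log2 group effect on nuclear area.

    The per-cell noise is set to 0.25 log2 units: a +-0.05 recovery band at
    200 cells/group requires a standard error of ~0.025, i.e. within-group sd
    no larger than ~0.25 for any unbiased estimator."""
    hits = 0
    for s in range(n_seeds):
        records, _ = simulate_morphometry(
            n_cells_per_group=n_cells,
            donor_sd=donor_sd,
            cell_sd=cell_sd,
            group_effects={"nuclear_area": {"strain": effect}},
            seed=_sub(seed, 40 + s),
        )
        records["log2_nuclear_area"] = np.log2(records["nuclear_area"])
        fit = fit_group_donor_model(records, "log2_nuclear_area", "control")
        hits += int(abs(fit.beta_g["strain"] - effect) <= 0.05)
    return {"in_band_fraction": hits / n_seeds, "n_seeds": n_seeds, "n_cells": n_cells}


def cluster_selection_experiment(n_seeds: int = 100, seed: int = 0) -> dict:
    """Silhouette-selected k on three well-separated time-course blobs."""
    hits = 0
    for s in range(n_seeds):
        X, _ = simulate_timecourse_clusters(n_per_cluster=50, within_sd=0.2, seed=_sub(seed, 60 + s))
        res = cluster_timecourse(X, k_range=range(2, 9), restarts=10, seed=_sub(seed, 61 + s))
        hits += int(res.k_selected == 3)
    return {"k3_rate": hits / n_seeds, "n_seeds": n_seeds}


def determinism_check(seed: int = 0) -> dict:
    """Two full pipeline runs from one config must be byte-identical."""
    with tempfile.TemporaryDirectory() as tmp:
        hashes = []
        for name in ("a", "b"):
            cfg = RunConfig(
                out_dir=str(Path(tmp) / name),
                simulate=ProteomicsSimConfig(n_proteins=10, seed=_sub(seed, 3)),
                mcmc=McmcConfig(iterations=400, burn_in=100, seed=_sub(seed, 4)),
                seed=_sub(seed, 4),
            )
            manifest = run_differential(cfg)
            blob = hashlib.sha256()
            for fname in sorted(manifest["outputs"]):
                blob.update((Path(tmp) / name / fname).read_bytes())
            hashes.append(blob.hexdigest())
    return {"identical": float(hashes[0] == hashes[1])}
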