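"""Synthetic peptide-level proteomics experiments and per-cell morphometry
with known ground truth.

The proteomics generator is the generative mirror of the per-protein model:
log2 intensities are composed of protein baseline, peptide ionization
effects, treatment effects, donor effects at protein and peptide level, PTM
occupancy interactions and Gaussian residual noise; intensities are then
exponentiated to the raw scale, identification scores are drawn
intensity-correlated, and cells are masked missing. Defaults emulate the
source study design: 3 donors, a control and a strained condition, proteins
carrying 3-30 peptide ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import ExperimentDesign, PeptideTable, default_registry

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRVWY"))  # no S/T: PTM sites placed explicitly


@dataclass
class ProteomicsSimConfig:
    n_proteins: int = 200
    peptides_min: int = 3
    peptides_mode: int = 5
    peptides_max: int = 30
    n_donors: int = 3
    groups: tuple = ("control", "strain")
    reference: str = "control"
    fraction_differential: float = 0.2
    effect_low: float = 0.5  # |beta_g| range, log2
    effect_high: float = 1.5
    donor_sd_protein: float = 0.2
    donor_sd_peptide: float = 0.1
    peptide_sd: float = 1.5  # ionization-efficiency spread
    residual_sd: float = 0.3
    ptm_fraction: float = 0.05
    ptm_effect: float = 1.0  # log2 occupancy shift of modified peptides
    missing_rate: float = 0.1
    missing_mode: str = "mcar"  # or "censor" (intensity-dependent)
    score_base: float = 15.0
    score_slope: float = 5.0
    score_noise: float = 3.0
    base_log2_intensity: float = 25.0
    base_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for frac in (self.fraction_differential, self.ptm_fraction, self.missing_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for sd in (
            self.donor_sd_protein,
            self.donor_sd_peptide,
            self.peptide_sd,
            self.residual_sd,
            self.score_noise,
            self.base_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.n_donors < 1:
            raise ValueError("need >= 1 donor")
        if self.peptides_max < 3:
            raise ValueError("peptides_max < 3 would leave every protein filtered out")
        if not (self.peptides_min <= self.peptides_mode <= self.peptides_max):
            raise ValueError("peptide count distribution requires min <= mode <= max")
        if self.reference not in self.groups:
            raise ValueError("reference must be one of the groups")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a simulated dataset."""

    proteins: pd.DataFrame  # accession, group, beta_g, differential
    sites: pd.DataFrame  # accession, peptide_id, site, label, group, shift
    proteome: dict = field(default_factory=dict)  # accession -> sequence
    seed: int = 0


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _make_design(cfg: ProteomicsSimConfig) -> ExperimentDesign:
    rows = [
        {"sample_id": f"{g}_d{d + 1}", "group": g, "donor": f"d{d + 1}"}
        for g in cfg.groups
        for d in range(cfg.n_donors)
    ]
    return ExperimentDesign(pd.DataFrame(rows), cfg.reference)


def simulate_proteomics(cfg: ProteomicsSimConfig) -> tuple[PeptideTable, ExperimentDesign, SyntheticTruth]:
    """Generate a peptide-ion table, its design, and the generating truth.

    Pure function of the config (including its seed): identical configs give
    byte-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)
    nonref = [g for g in cfg.groups if g != cfg.reference]
    samples = design.sample_ids
    sample_group = dict(zip(design.samples["sample_id"], design.samples["group"]))
    sample_donor = dict(zip(design.samples["sample_id"], design.samples["donor"]))
    donors = design.donors

    rows = []
    truth_rows = []
    site_rows = []
    proteome = {}
    for i in range(cfg.n_proteins):
        acc = f"P{i + 1:05d}"
        n_pep = int(
            np.clip(
                np.floor(rng.triangular(cfg.peptides_min, cfg.peptides_mode, cfg.peptides_max + 1)),
                cfg.peptides_min,
                cfg.peptides_max,
            )
        )
        beta0 = rng.normal(cfg.base_log2_intensity, cfg.base_sd)
        beta_f = rng.normal(0.0, cfg.peptide_sd, size=n_pep)
        differential = rng.random() < cfg.fraction_differential
        beta_g = {}
        for g in nonref:
            if differential:
                mag = rng.uniform(cfg.effect_low, cfg.effect_high)
                beta_g[g] = float(mag * rng.choice([-1.0, 1.0]))
            else:
                beta_g[g] = 0.0
            truth_rows.append(
                {"accession": acc, "group": g, "beta_g": beta_g[g], "differential": differential}
            )
        beta_d = rng.normal(0.0, cfg.donor_sd_protein, size=cfg.n_donors)
        beta_fd = rng.normal(0.0, cfg.donor_sd_peptide, size=(n_pep, cfg.n_donors))

        peptides = []
        offset = 1  # protein starts with initiator M
        for j in range(n_pep):
            length = int(rng.integers(7, 19))
            seq = _random_peptide(rng, length)
            is_ptm = rng.random() < cfg.ptm_fraction
            mods = ""
            pid = f"{acc}_pep{j + 1:03d}"
            if is_ptm:
                site_off = int(rng.integers(2, length))  # internal residue
                seq = seq[: site_off - 1] + "S" + seq[site_off:]
                mods = f"{site_off}:phospho"
                for g in nonref:
                    site_rows.append(
                        {
                            "accession": acc,
                            "peptide_id": pid,
                            "site": f"S{offset + site_off}",
                            "label": "phospho",
                            "group": g,
                            "shift": cfg.ptm_effect,
                        }
                    )
            peptides.append((pid, seq, mods, is_ptm))
            offset += length
        proteome[acc] = "M" + "".join(seq for _, seq, _, _ in peptides)

        for j, (pid, seq, mods, is_ptm) in enumerate(peptides):
            intens = {}
            for sid in samples:
                g = sample_group[sid]
                d = donors.index(sample_donor[sid])
                y = (
                    beta0
                    + beta_f[j]
                    + (beta_g[g] if g != cfg.reference else 0.0)
                    + beta_d[d]
                    + beta_fd[j, d]
                    + (cfg.ptm_effect if (is_ptm and g != cfg.reference) else 0.0)
                    + rng.normal(0.0, cfg.residual_sd)
                )
                intens[sid] = 2.0**y
            rows.append(
                {
                    "peptide_id": pid,
                    "sequence": seq,
                    "modifications": mods,
                    "accession": acc,
                    "unique": True,
                    "score": np.nan,
                    **intens,
                }
            )

    df = pd.DataFrame(rows)
    # intensity-correlated identification scores
    mean_log2 = np.log2(df[samples].to_numpy(dtype=float)).mean(axis=1)
    z = (mean_log2 - mean_log2.mean()) / max(mean_log2.std(), 1e-12)
    scores = cfg.score_base + cfg.score_slope * z + rng.normal(0.0, cfg.score_noise, size=len(df))
    df["score"] = np.round(np.maximum(scores, 1.0), 2)

    # missingness
    if cfg.missing_rate > 0:
        vals = df[samples].to_numpy(dtype=float)
        if cfg.missing_mode == "mcar":
            mask = rng.random(vals.shape) < cfg.missing_rate
        elif cfg.missing_mode == "censor":
            logv = np.log2(vals)
            zc = (logv - logv.mean()) / max(logv.std(), 1e-12)
            p_miss = np.clip(cfg.missing_rate * 2.0 / (1.0 + np.exp(1.5 * zc)), 0.0, 0.95)
            mask = rng.random(vals.shape) < p_miss
        else:
            raise ValueError(f"unknown missing_mode {cfg.missing_mode!r}")
        vals[mask] = np.nan
        df[samples] = vals

    table = PeptideTable(df, list(samples), default_registry())
    truth = SyntheticTruth(
        proteins=pd.DataFrame(truth_rows),
        sites=pd.DataFrame(site_rows, columns=["accession", "peptide_id", "site", "label", "group", "shift"]),
        proteome=proteome,
        seed=cfg.seed,
    )
    return table, design, truth


def simulate_null(cfg: ProteomicsSimConfig) -> tuple[PeptideTable, ExperimentDesign, SyntheticTruth]:
    """Same generator with every treatment effect forced to zero."""
    return simulate_proteomics(replace(cfg, fraction_differential=0.0, ptm_effect=0.0))


def simulate_ptm_protein(
    n_peptides: int = 8,
    n_modified_ions: int = 2,
    effect: float = 1.0,
    residual_sd: float = 0.1,
    n_donors: int = 3,
    seed: int = 0,
) -> tuple[PeptideTable, ExperimentDesign, SyntheticTruth, str]:
    """One protein whose PTM site is covered by ``n_modified_ions`` peptide
    ions (the same modified sequence observed repeatedly, as with charge
    states); the modified ions carry an ``effect`` log2 occupancy shift under
    treatment. Low residual noise by design: this scenario isolates estimator
    bias. Returns (table, design, truth, site)."""
    cfg = ProteomicsSimConfig(
        n_proteins=1,
        residual_sd=residual_sd,
        n_donors=n_donors,
        ptm_fraction=0.0,
        fraction_differential=0.0,
        missing_rate=0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    design = _make_design(cfg)
    nonref = [g for g in cfg.groups if g != cfg.reference]
    acc = "P00001"
    donors = design.donors

    mod_seq = _random_peptide(rng, 11)
    site_off = 6
    mod_seq = mod_seq[: site_off - 1] + "S" + mod_seq[site_off:]
    seqs = [mod_seq] * n_modified_ions + [
        _random_peptide(rng, int(rng.integers(7, 19))) for _ in range(n_peptides - 1)
    ]
    is_mod = [True] * n_modified_ions + [False] * (n_peptides - 1)
    proteome = {acc: "M" + mod_seq + "".join(seqs[n_modified_ions:])}
    site = f"S{1 + site_off}"

    beta0 = rng.normal(cfg.base_log2_intensity, cfg.base_sd)
    beta_f = rng.normal(0.0, cfg.peptide_sd, size=len(seqs))
    beta_d = rng.normal(0.0, cfg.donor_sd_protein, size=n_donors)

    rows = []
    for j, (seq, mod) in enumerate(zip(seqs, is_mod)):
        pid = f"{acc}_ion{j + 1:03d}"
        beta_fd = rng.normal(0.0, cfg.donor_sd_peptide, size=n_donors)
        intens = {}
        for sid in design.sample_ids:
            g = design.samples.set_index("sample_id").loc[sid, "group"]
            d = donors.index(design.samples.set_index("sample_id").loc[sid, "donor"])
            y = (
                beta0
                + beta_f[j]
                + beta_d[d]
                + beta_fd[d]
                + (effect if (mod and g != cfg.reference) else 0.0)
                + rng.normal(0.0, residual_sd)
            )
            intens[sid] = 2.0**y
        rows.append(
            {
                "peptide_id": pid,
                "sequence": seq,
                "modifications": f"{site_off}:phospho" if mod else "",
                "accession": acc,
                "unique": True,
                "score": float(np.round(rng.uniform(20, 60), 2)),
                **intens,
            }
        )
    table = PeptideTable(pd.DataFrame(rows), design.sample_ids, default_registry())
    site_rows = [
        {
            "accession": acc,
            "peptide_id": f"{acc}_ion{j + 1:03d}",
            "site": site,
            "label": "phospho",
            "group": g,
            "shift": effect,
        }
        for j in range(n_modified_ions)
        for g in nonref
    ]
    truth = SyntheticTruth(
        proteins=pd.DataFrame(
            [{"accession": acc, "group": g, "beta_g": 0.0, "differential": False} for g in nonref]
        ),
        sites=pd.DataFrame(site_rows),
        proteome=proteome,
        seed=seed,
    )
    return table, design, truth, site


DEFAULT_BASELINES = {
    "nuclear_area": 170.0,
    "cytoplasmic_area": 1800.0,
    "ne_intensity": 1000.0,
    "texture_sum_variance": 50.0,
    "gH2AX_intensity": 120.0,
}


def simulate_morphometry(
    n_cells_per_group: int = 200,
    groups: tuple = ("control", "strain"),
    reference: str = "control",
    n_donors: int = 3,
    donor_sd: float = 0.2,
    cell_sd: float = 0.5,
    group_effects: dict | None = None,
    baselines: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell lognormal measures with additive log2-scale donor and group
    effects. ``group_effects`` maps measure -> {group: log2 shift}. Returns
    (records, truth dict)."""
    baselines = baselines or dict(DEFAULT_BASELINES)
    if any(v <= 0 for v in baselines.values()):
        raise ValueError("baselines must be positive")
    group_effects = group_effects or {}
    rng = np.random.default_rng(seed)
    donor_eff = {m: rng.normal(0.0, donor_sd, size=n_donors) for m in baselines}

    rows = []
    cell = 0
    for g in groups:
        for i in range(n_cells_per_group):
            d = i % n_donors
            cell += 1
            rec = {"cell_id": f"cell{cell:05d}", "donor": f"d{d + 1}", "group": g}
            for m, base in baselines.items():
                shift = group_effects.get(m, {}).get(g, 0.0) if g != reference else 0.0
                logv = np.log2(base) + donor_eff[m][d] + shift + rng.normal(0.0, cell_sd)
                rec[m] = 2.0**logv
            rows.append(rec)
    truth = {
        "group_effects": group_effects,
        "donor_effects": {m: v.tolist() for m, v in donor_eff.items()},
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


def simulate_timecourse_clusters(
    n_per_cluster: int = 50,
    centers: np.ndarray | None = None,
    within_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated synthetic log2FC time courses for cluster-count checks.
    Returns (matrix, true labels)."""
    if centers is None:
        centers = np.array([[-2.0, -2.0], [0.0, 2.0], [2.0, 0.0]])
    centers = np.asarray(centers, dtype=float)
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, c in enumerate(centers):
        blocks.append(c + rng.normal(0.0, within_sd, size=(n_per_cluster, centers.shape[1])))
        labels.extend([k + 1] * n_per_cluster)
    return np.vstack(blocks), np.asarray(labels)
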