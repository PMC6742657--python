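"""End-to-end orchestration: simulate/load -> filter -> normalize -> fit ->
moderate -> test -> PTM and pathway summaries, with a reproducibility
manifest.

Stage order is fixed: confidence filter, then unique-peptide count filter,
then normalization, then model fitting. Reruns with the same config are
byte-identical (per-protein chain seeds derive from the run seed)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .downstream import fit_pathway_model, site_occupancy_changes
from .ingest import (
    ExperimentDesign,
    annotate_ptm_sites,
    filter_by_confidence,
    filter_by_peptide_count,
    log_and_normalize,
    read_design,
    read_fasta,
    read_gmt,
    read_peptide_table,
    write_design,
    write_peptide_table,
)
from .protein_model import (
    McmcConfig,
    build_design,
    fit_protein_model,
    moderate_variances,
    test_differential_batch,
)
from .simulate import ProteomicsSimConfig, simulate_proteomics

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Whole-run configuration (paths, thresholds, chain settings, seed)."""

    out_dir: str
    peptides_path: str | None = None
    design_path: str | None = None
    reference_group: str | None = None
    proteome_path: str | None = None
    gmt_path: str | None = None
    simulate: ProteomicsSimConfig | None = None
    fdr_threshold: float = 0.2
    min_unique: int = 3
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.min_unique < 1:
            raise ValueError("min_unique must be >= 1")
        if self.simulate is None and (self.peptides_path is None or self.design_path is None):
            raise ValueError("either input paths or a simulate block are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        sim = raw.pop("simulate", None)
        sim_cfg = ProteomicsSimConfig(**sim) if sim is not None else None
        if sim_cfg is not None and isinstance(sim_cfg.groups, list):
            sim_cfg.groups = tuple(sim_cfg.groups)
        return cls(mcmc=mcmc, simulate=sim_cfg, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: Path, seed: int) -> None:
    """TSV with a header comment carrying tool version and seed."""
    with open(path, "w") as fh:
        fh.write(f"# mechanoprot {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def fit_all_proteins(table, design: ExperimentDesign, mcmc: McmcConfig, base_seed: int):
    """Fit every protein in a normalized table; returns fits and a count of
    skipped proteins (degenerate designs after missingness)."""
    fits, skipped = [], 0
    for i, acc in enumerate(table.accessions):
        sub = table.copy()
        sub.df = table.df[table.df["accession"] == acc].reset_index(drop=True)
        cfg_i = dataclasses.replace(mcmc, seed=int((base_seed + 1009 * (i + 1)) % (2**31)))
        try:
            pdesign = build_design(sub, design)
        except ValueError as exc:
            logger.warning("skipping %s: %s", acc, exc)
            skipped += 1
            continue
        fit = fit_protein_model(pdesign, cfg_i)
        logger.info(
            "fit %s: n_obs=%d rhat_max=%.3f",
            acc,
            fit.n_obs,
            max(fit.rhat.values()) if fit.rhat else float("nan"),
        )
        fits.append(fit)
    return fits, skipped


def run_differential(cfg: RunConfig) -> dict:
    """Run the full differential pipeline; returns the manifest (also written
    to ``out_dir/manifest.json``)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "mechanoprot", "version": __version__, "seed": cfg.seed, "stages": []}

    def stage(name: str, **counts):
        manifest["stages"].append({"stage": name, **counts})
        logger.info("stage %s: %s", name, counts)

    proteome = None
    if cfg.simulate is not None:
        table, design, truth = simulate_proteomics(cfg.simulate)
        proteome = truth.proteome
        write_peptide_table(table, out_dir / "peptides.csv")
        write_design(design, out_dir / "design.csv")
        write_tsv(truth.proteins, out_dir / "truth_proteins.tsv", cfg.seed)
        stage("simulate", peptide_ions=len(table), samples=len(design.sample_ids))
    else:
        design = read_design(cfg.design_path, cfg.reference_group)
        table = read_peptide_table(cfg.peptides_path, design)
        stage("ingest", peptide_ions=len(table), samples=len(design.sample_ids))
        if cfg.proteome_path:
            proteome = read_fasta(cfg.proteome_path)

    n0 = len(table)
    table = filter_by_confidence(table, cfg.fdr_threshold)
    stage("confidence_filter", kept=len(table), removed=n0 - len(table))

    n1, p1 = len(table), len(table.accessions)
    table = filter_by_peptide_count(table, cfg.min_unique)
    stage(
        "peptide_count_filter",
        kept=len(table),
        removed=n1 - len(table),
        proteins=len(table.accessions),
        proteins_removed=p1 - len(table.accessions),
    )

    table = log_and_normalize(table)
    stage("normalize", peptide_ions=len(table))

    fits, skipped = fit_all_proteins(table, design, cfg.mcmc, cfg.seed)
    stage("fit", proteins_fit=len(fits), proteins_skipped=skipped)
    if not fits:
        raise RuntimeError("fit stage produced no protein fits")

    state = moderate_variances(fits)
    stage("moderate", d0=float(state.d0), s0_2=float(state.s0_2))

    results = test_differential_batch(fits, state)
    write_tsv(results, out_dir / "proteins.tsv", cfg.seed)
    stage("test", contrasts=len(results), significant_q05=int((results["q"] < 0.05).sum()))

    outputs = {"proteins.tsv": str(out_dir / "proteins.tsv")}

    if proteome:
        annotations = annotate_ptm_sites(table, proteome)
        unambiguous = [a for a in annotations if not a.ambiguous]
        sites = site_occupancy_changes(fits, annotations, state)
        write_tsv(sites, out_dir / "ptm_sites.tsv", cfg.seed)
        ambiguous = [a for a in annotations if a.ambiguous]
        if ambiguous:
            amb_df = pd.DataFrame(
                [
                    {"accession": a.protein_accession, "site": a.site, "label": a.label, "peptide_id": a.peptide_id}
                    for a in ambiguous
                ]
            )
            write_tsv(amb_df, out_dir / "ptm_sites_ambiguous.tsv", cfg.seed)
            outputs["ptm_sites_ambiguous.tsv"] = str(out_dir / "ptm_sites_ambiguous.tsv")
        stage("ptm_sites", annotations=len(unambiguous), sites=len(sites))
        outputs["ptm_sites.tsv"] = str(out_dir / "ptm_sites.tsv")

    if cfg.gmt_path:
        membership = read_gmt(cfg.gmt_path)
        fc = results[["accession", "group", "log2fc"]]
        if fc["group"].nunique() >= 2:
            _, pathways = fit_pathway_model(fc, membership)
            write_tsv(pathways, out_dir / "pathways.tsv", cfg.seed)
            stage("pathways", pathways=pathways["pathway_id"].nunique() if len(pathways) else 0)
            outputs["pathways.tsv"] = str(out_dir / "pathways.tsv")
        else:
            logger.warning("pathway model skipped: fewer than 2 contrast groups")

    manifest["outputs"] = {name: _sha256(Path(p)) for name, p in outputs.items()}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
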