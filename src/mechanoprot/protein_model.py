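"""Per-protein hierarchical peptide-level model.

Each protein's log2 peptide-ion intensities are modeled as

    y_fgd = beta0 + Xf bf + Xg bg + Xd bd + XfXg b_fg + XfXd b_fd + eps

with peptide (f) and donor (d) effects coded sum-to-zero and treatment (g)
coded against the reference group, so ``beta_g`` is directly the log2 fold
change of the protein versus the reference. The fit is a confidence-weighted
Bayesian elastic net sampled by Gibbs (see ``_gibbs``); per-protein residual
variances are then shrunk by empirical-Bayes moderation and group effects are
tested with moderated t-statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._gibbs import gibbs_elastic_net
from .ingest import ExperimentDesign, PeptideTable
from .stats import batch_mcse, bh_adjust, fit_variance_prior, moderated_variance, split_rhat

logger = logging.getLogger(__name__)


@dataclass
class McmcConfig:
    """Chain settings and elastic-net hyperprior parameters.

    ``weight_c`` is the robustness scale in standardized-residual units;
    ``robust_weighting=False`` forces all observation weights to 1.
    ``fixed_lambda1_sq``/``fixed_lambda2`` freeze the penalties instead of
    sampling them (useful for the weak-prior/OLS limit).
    """

    iterations: int = 4000
    burn_in: int = 1000
    seed: int = 0
    lambda1_shape: float = 1.0
    lambda1_rate: float = 1.0
    lambda2_shape: float = 1.0
    lambda2_rate: float = 1.0
    weight_c: float = 3.0
    robust_weighting: bool = True
    fixed_lambda1_sq: float | None = None
    fixed_lambda2: float | None = None
    # identifiability floor for the peptide-by-treatment block: these
    # coefficients are the reported occupancy effect sizes, so they are left
    # essentially unpenalized rather than adaptively shrunk
    interaction_ridge: float = 0.01

    def __post_init__(self):
        if not (self.iterations > self.burn_in > 0):
            raise ValueError("require iterations > burn_in > 0")
        if self.weight_c <= 0:
            raise ValueError("weight_c must be positive")


def compute_observation_weights(residuals, scores, c: float = 3.0):
    """Blend identification confidence with a robustness kernel.

    w = qc + (1 - qc) / (1 + (r/c)^2), qc = 1 - 10^(-score/10) clipped to
    [0, 1). Monotone increasing in score at fixed |r|, decreasing in |r| at
    fixed score; w = 1 at r = 0.
    """
    if c <= 0:
        raise ValueError("scale constant c must be positive")
    r = np.asarray(residuals, dtype=float)
    qc = np.clip(1.0 - np.power(10.0, -np.asarray(scores, dtype=float) / 10.0), 0.0, 1.0 - 1e-12)
    return qc + (1.0 - qc) / (1.0 + (r / c) ** 2)


def _sum_code(index: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero coding: (n, L-1) matrix, last level coded -1."""
    out = np.zeros((index.size, n_levels - 1))
    for j in range(n_levels - 1):
        out[index == j, j] = 1.0
    out[index == n_levels - 1, :] = -1.0
    return out


@dataclass
class ProteinDesign:
    """Design structure for one protein: matrix, response, scores, and the
    level bookkeeping needed to reconstruct named effects."""

    accession: str
    X: np.ndarray
    y: np.ndarray
    scores: np.ndarray
    colnames: list[str]
    peptide_ids: list[str]
    nonref_groups: list[str]
    donors: list[str]
    reference_group: str
    row_meta: pd.DataFrame  # peptide_id, sample_id, group, donor

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)


def build_design(peptides: PeptideTable, design: ExperimentDesign, accession: str | None = None) -> ProteinDesign:
    """Build the model matrix for one protein from its (log-normalized)
    peptide subtable. Only unique peptides enter; rows exist only for
    observed intensities. Donor terms are dropped for single-donor designs."""
    df = peptides.df
    if accession is not None:
        df = df.loc[df["accession"] == accession]
    else:
        accs = df["accession"].unique()
        if len(accs) != 1:
            raise ValueError("build_design expects a single-protein subtable")
        accession = accs[0]
    df = df.loc[df["unique"]]
    if not peptides.log_scale:
        raise ValueError("intensities must be log-normalized before model fitting")

    sample_info = design.samples.set_index("sample_id")
    rows = []
    for _, row in df.iterrows():
        for sid in peptides.sample_ids:
            val = row[sid]
            if np.isfinite(val):
                rows.append(
                    (
                        row["peptide_id"],
                        sid,
                        sample_info.loc[sid, "group"],
                        sample_info.loc[sid, "donor"],
                        float(val),
                        float(row["score"]),
                    )
                )
    long = pd.DataFrame(rows, columns=["peptide_id", "sample_id", "group", "donor", "y", "score"])
    if long.empty:
        raise ValueError(f"protein {accession!r}: no observed intensities")

    groups = [design.reference_group] + [g for g in design.groups if g != design.reference_group]
    observed_groups = set(long["group"])
    for g in groups:
        if g not in observed_groups:
            raise ValueError(f"protein {accession!r}: group {g!r} has zero observations")

    peptide_ids = sorted(long["peptide_id"].unique())
    if len(peptide_ids) < 2:
        raise ValueError(f"protein {accession!r}: fewer than 2 unique peptides with data")
    donors = [d for d in design.donors if d in set(long["donor"])]

    f_idx = long["peptide_id"].map({p: i for i, p in enumerate(peptide_ids)}).to_numpy()
    g_idx = long["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    d_idx = long["donor"].map({d: i for i, d in enumerate(donors)}).to_numpy()

    F, G, D = len(peptide_ids), len(groups), len(donors)
    n = len(long)

    blocks = [np.ones((n, 1))]
    colnames = ["intercept"]

    pep = _sum_code(f_idx, F)
    blocks.append(pep)
    colnames += [f"pep[{peptide_ids[j]}]" for j in range(F - 1)]

    grp = np.zeros((n, G - 1))
    for j in range(1, G):
        grp[g_idx == j, j - 1] = 1.0
    blocks.append(grp)
    nonref = groups[1:]
    colnames += [f"group[{g}]" for g in nonref]

    if D > 1:
        don = _sum_code(d_idx, D)
        blocks.append(don)
        colnames += [f"donor[{donors[j]}]" for j in range(D - 1)]

    for jg, g in enumerate(nonref):
        inter = pep * grp[:, [jg]]
        blocks.append(inter)
        colnames += [f"pep[{peptide_ids[j]}]:group[{g}]" for j in range(F - 1)]

    if D > 1:
        for jd in range(D - 1):
            inter = pep * don[:, [jd]]
            blocks.append(inter)
            colnames += [f"pep[{peptide_ids[j]}]:donor[{donors[jd]}]" for j in range(F - 1)]

    X = np.hstack(blocks)
    return ProteinDesign(
        accession=accession,
        X=X,
        y=long["y"].to_numpy(),
        scores=long["score"].to_numpy(),
        colnames=colnames,
        peptide_ids=peptide_ids,
        nonref_groups=nonref,
        donors=donors,
        reference_group=design.reference_group,
        row_meta=long[["peptide_id", "sample_id", "group", "donor"]],
    )


@dataclass
class ProteinModelFit:
    """Posterior summaries of all model coefficients for one protein."""

    accession: str
    colnames: list[str]
    coef_mean: np.ndarray  # Rao-Blackwellized posterior means
    coef_sd: np.ndarray
    coef_cov: np.ndarray
    coef_mcse: np.ndarray
    beta0: float
    beta_f: np.ndarray  # full length-F, sums to zero
    beta_g: dict  # group -> posterior mean log2 FC vs reference
    beta_d: np.ndarray  # full length-D, sums to zero (empty if single donor)
    beta_fg: dict  # group -> full length-F interaction vector
    se_g: dict  # group -> posterior sd
    mcse_g: dict
    rhat: dict  # group -> split-Rhat of the beta_g chain
    sigma2: float
    df: float
    n_obs: int
    weights_mean: np.ndarray
    peptide_ids: list[str]
    nonref_groups: list[str]
    converged: bool = True
    _fg_maps: dict = field(default_factory=dict, repr=False)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    def fg_effect(self, group: str, peptide_id: str) -> float:
        f = self.peptide_ids.index(peptide_id)
        return float(self.beta_fg[group][f])

    def fg_contrast(
        self,
        group: str,
        target_peptides: list[str],
        sibling_peptides: list[str] | None = None,
    ) -> tuple[float, float]:
        """Posterior mean and variance of the contrast: average interaction
        effect of ``target_peptides`` minus the average over
        ``sibling_peptides`` (default: every other peptide). Falls back to
        the raw average interaction effect when no siblings remain."""
        M = self._fg_maps[group]  # (F, p) linear map coef -> full beta_fg
        F = len(self.peptide_ids)
        tgt = np.array(sorted({self.peptide_ids.index(p) for p in target_peptides}))
        if sibling_peptides is None:
            others = np.setdiff1d(np.arange(F), tgt)
        else:
            others = np.array(sorted({self.peptide_ids.index(p) for p in sibling_peptides} - set(tgt)))
        cvec = np.zeros(F)
        cvec[tgt] = 1.0 / tgt.size
        if others.size:
            cvec[others] = -1.0 / others.size
        c = cvec @ M
        est = float(c @ self.coef_mean)
        var = float(c @ self.coef_cov @ c)
        return est, var


def _fg_map(pdesign: ProteinDesign, group: str) -> np.ndarray:
    """Linear map from the coefficient vector to the full sum-to-zero
    peptide-by-group interaction vector for one group."""
    F = pdesign.n_peptides
    p = len(pdesign.colnames)
    M = np.zeros((F, p))
    for j in range(F - 1):
        col = pdesign.colnames.index(f"pep[{pdesign.peptide_ids[j]}]:group[{group}]")
        M[j, col] = 1.0
        M[F - 1, col] = -1.0
    return M


def fit_protein_model(pdesign: ProteinDesign, cfg: McmcConfig) -> ProteinModelFit:
    """Fit the weighted Bayesian elastic net for one protein.

    Identical config and inputs give identical output (the kernel RNG is
    seeded from ``cfg.seed``). Non-convergence (split-Rhat > 1.1 on any
    beta_g) flags the result rather than discarding it.
    """
    X = np.ascontiguousarray(pdesign.X, dtype=float)
    y = np.ascontiguousarray(pdesign.y, dtype=float)
    n, p = X.shape
    qc = np.clip(1.0 - np.power(10.0, -pdesign.scores / 10.0), 0.0, 1.0 - 1e-12)

    # penalty blocks: effects of one kind share adaptive shrinkage
    def _block_of(name: str) -> int:
        if name == "intercept":
            return -1
        if name.startswith("pep[") and ":group[" in name:
            return 3
        if name.startswith("pep[") and ":donor[" in name:
            return 4
        if name.startswith("pep["):
            return 0
        if name.startswith("group["):
            return 1
        return 2  # donor

    block = np.array([_block_of(c) for c in pdesign.colnames], dtype=np.int64)
    # interaction blocks are not sparse in sum-to-zero coordinates: ridge only;
    # the peptide-by-treatment ridge is pinned weak (reported effect sizes)
    ridge_only = np.array([False, False, False, True, True])
    lam2_fixed = np.array([0.0, 0.0, 0.0, cfg.interaction_ridge, 0.0])

    fix = cfg.fixed_lambda1_sq is not None or cfg.fixed_lambda2 is not None
    lam1_sq0 = cfg.fixed_lambda1_sq if cfg.fixed_lambda1_sq is not None else 1.0
    lam20 = cfg.fixed_lambda2 if cfg.fixed_lambda2 is not None else 1.0

    draws, cond_means, sigma2_draws, w_mean = gibbs_elastic_net(
        X,
        y,
        np.ascontiguousarray(qc),
        block,
        5,
        ridge_only,
        lam2_fixed,
        cfg.iterations,
        cfg.burn_in,
        cfg.weight_c,
        cfg.robust_weighting,
        cfg.lambda1_shape,
        cfg.lambda1_rate,
        cfg.lambda2_shape,
        cfg.lambda2_rate,
        fix,
        float(lam1_sq0),
        float(lam20),
        cfg.seed,
    )

    coef_mean = cond_means.mean(axis=0)
    coef_sd = draws.std(axis=0, ddof=1)
    coef_cov = np.cov(draws.T) if p > 1 else np.array([[float(np.var(draws, ddof=1))]])
    coef_mcse = np.array([batch_mcse(cond_means[:, j]) for j in range(p)])

    names = pdesign.colnames
    F = pdesign.n_peptides
    D = len(pdesign.donors)

    def full_sum_zero(prefix: str, levels: list[str]) -> np.ndarray:
        if len(levels) <= 1:
            return np.zeros(len(levels))
        idx = [names.index(f"{prefix}[{lev}]") for lev in levels[:-1]]
        vals = coef_mean[idx]
        return np.concatenate([vals, [-vals.sum()]])

    beta_f = full_sum_zero("pep", pdesign.peptide_ids)
    beta_d = (
        full_sum_zero("donor", pdesign.donors) if D > 1 else np.zeros(D)
    )

    beta_g, se_g, mcse_g, rhat = {}, {}, {}, {}
    for g in pdesign.nonref_groups:
        j = names.index(f"group[{g}]")
        beta_g[g] = float(coef_mean[j])
        se_g[g] = float(coef_sd[j])
        mcse_g[g] = float(coef_mcse[j])
        rhat[g] = split_rhat(draws[:, j])

    fg_maps = {g: _fg_map(pdesign, g) for g in pdesign.nonref_groups}
    beta_fg = {g: fg_maps[g] @ coef_mean for g in pdesign.nonref_groups}

    rank = int(np.linalg.matrix_rank(X))
    df = max(n - rank, 1)
    converged = all(not (r > 1.1) for r in rhat.values())
    if not converged:
        logger.warning("protein %s: split-Rhat > 1.1, flagged", pdesign.accession)

    return ProteinModelFit(
        accession=pdesign.accession,
        colnames=names,
        coef_mean=coef_mean,
        coef_sd=coef_sd,
        coef_cov=coef_cov,
        coef_mcse=coef_mcse,
        beta0=float(coef_mean[0]),
        beta_f=beta_f,
        beta_g=beta_g,
        beta_d=beta_d,
        beta_fg=beta_fg,
        se_g=se_g,
        mcse_g=mcse_g,
        rhat=rhat,
        sigma2=float(np.mean(sigma2_draws)),
        df=float(df),
        n_obs=n,
        weights_mean=w_mean,
        peptide_ids=pdesign.peptide_ids,
        nonref_groups=pdesign.nonref_groups,
        converged=converged,
        _fg_maps=fg_maps,
    )


@dataclass
class ModerationState:
    """Empirical-Bayes variance moderation across a batch of protein fits."""

    d0: float
    s0_2: float
    table: pd.DataFrame  # accession, s2, df, s_tilde2

    def s_tilde2(self, accession: str) -> float:
        return float(self.table.set_index("accession").loc[accession, "s_tilde2"])

    def row(self, accession: str) -> pd.Series:
        return self.table.set_index("accession").loc[accession]


def moderate_variances(fits: list[ProteinModelFit], min_proteins: int = 10) -> ModerationState:
    """Moment-match a scaled inverse-chi-square prior to the per-protein
    residual variances and shrink each variance toward it."""
    s2 = np.array([f.sigma2 for f in fits])
    df = np.array([f.df for f in fits])
    if len(fits) < min_proteins or np.unique(s2).size < 2:
        logger.warning("too few proteins/distinct variances for moderation; d0 = 0")
        d0, s0_2 = 0.0, float(np.mean(s2)) if s2.size else 1.0
    else:
        d0, s0_2 = fit_variance_prior(s2, df)
    st2 = moderated_variance(s2, df, d0, s0_2)
    table = pd.DataFrame(
        {"accession": [f.accession for f in fits], "s2": s2, "df": df, "s_tilde2": st2}
    )
    return ModerationState(d0=d0, s0_2=s0_2, table=table)


@dataclass(frozen=True)
class DifferentialResult:
    protein_accession: str
    group: str
    log2fc: float
    se: float
    moderated_t: float
    p: float
    q: float = np.nan


def _moderated_test(log2fc: float, se: float, s2: float, s_tilde2: float, df: float, d0: float):
    """Moderated t and two-tailed p for one contrast."""
    if se == 0:
        if log2fc == 0:
            return 0.0, 1.0
        raise ValueError("zero standard error with nonzero estimate")
    scale = np.sqrt(s_tilde2 / s2) if s2 > 0 else 1.0
    t = log2fc / (se * scale)
    dof = d0 + df
    if np.isinf(dof):
        pval = 2.0 * sps.norm.sf(abs(t))
    else:
        pval = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), float(min(pval, 1.0))


def test_differential(fit: ProteinModelFit, state: ModerationState) -> list[DifferentialResult]:
    """Moderated t-tests of every group effect of one protein (no q; BH is
    applied batch-wide by :func:`test_differential_batch`)."""
    row = state.row(fit.accession)
    out = []
    for g in fit.nonref_groups:
        t, p = _moderated_test(fit.beta_g[g], fit.se_g[g], row["s2"], row["s_tilde2"], row["df"], state.d0)
        out.append(
            DifferentialResult(
                protein_accession=fit.accession, group=g,
                log2fc=fit.beta_g[g], se=fit.se_g[g], moderated_t=t, p=p,
            )
        )
    return out


def test_differential_batch(fits: list[ProteinModelFit], state: ModerationState) -> pd.DataFrame:
    """All proteins x contrasts with BH q across the whole batch."""
    rows = []
    for fit in fits:
        for res in test_differential(fit, state):
            rows.append(
                {
                    "accession": res.protein_accession,
                    "group": res.group,
                    "log2fc": res.log2fc,
                    "se": res.se,
                    "t": res.moderated_t,
                    "p": res.p,
                    "n_peptides": fit.n_peptides,
                    "rhat_max": max(fit.rhat.values()) if fit.rhat else np.nan,
                    "n_obs": fit.n_obs,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = []
    return df
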