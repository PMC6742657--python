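"""PTM site-occupancy fold changes and pathway-level linear modeling.

A modified peptide tracks only the modified subpopulation of its protein, so
its peptide-by-treatment interaction carries the log2 fold change in site
occupancy. When several peptide ions cover one site their estimates are
combined by inverse-variance weighting. Pathway effects are estimated by a
least-squares fit of per-protein log2 fold changes on group and protein
factors (proteins coded sum-to-zero); because the responses are already fold
changes versus the reference condition, the group effect is directly the
pathway-level log2 fold change and is tested against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ingest import SiteAnnotation
from .protein_model import ModerationState, ProteinModelFit, _moderated_test
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PTMSiteResult:
    protein_accession: str
    site: str  # residue + protein position, e.g. "S21"
    label: str
    group: str
    occupancy_log2fc: float
    se: float
    p: float
    q: float = np.nan
    n_peptides: int = 1


def site_occupancy_changes(
    fits: list[ProteinModelFit],
    annotations: list[SiteAnnotation],
    state: ModerationState,
    include_ambiguous: bool = False,
) -> pd.DataFrame:
    """Per-(site, label, group) occupancy log2 fold changes.

    The occupancy change of a site is the contrast between the interaction
    effects of the peptides carrying the modification and their unmodified
    siblings; multiple covering peptides are combined by inverse-variance
    weighting. p-values use the protein's moderated variance; BH q is
    computed across all sites in the batch.
    """
    by_acc = {f.accession: f for f in fits}
    groups: dict[tuple, list[SiteAnnotation]] = {}
    modified_peptides: dict[str, set[str]] = {}
    for ann in annotations:
        modified_peptides.setdefault(ann.protein_accession, set()).add(ann.peptide_id)
        if ann.ambiguous and not include_ambiguous:
            logger.info("skipping ambiguous site %s on %s", ann.site, ann.protein_accession)
            continue
        groups.setdefault((ann.protein_accession, ann.site, ann.label), []).append(ann)

    rows = []
    for (acc, site, label), anns in sorted(groups.items()):
        fit = by_acc.get(acc)
        if fit is None:
            logger.info("site %s on %s: protein not fitted, skipped", site, acc)
            continue
        peptide_ids = sorted({a.peptide_id for a in anns if a.peptide_id in fit.peptide_ids})
        if not peptide_ids:
            logger.info("site %s on %s: no fitted interaction term, skipped", site, acc)
            continue
        # the occupancy baseline is the protein's unmodified peptides
        siblings = [p for p in fit.peptide_ids if p not in modified_peptides.get(acc, set())]
        mrow = state.row(acc)
        for g in fit.nonref_groups:
            # one estimate per covering peptide, inverse-variance combined
            ests, variances = [], []
            for pid in peptide_ids:
                est, var = fit.fg_contrast(g, [pid], siblings or None)
                if var > 0:
                    ests.append(est)
                    variances.append(var)
            if not ests:
                continue
            wts = 1.0 / np.asarray(variances)
            est = float(np.sum(wts * np.asarray(ests)) / np.sum(wts))
            se = float(np.sqrt(1.0 / np.sum(wts)))
            t, p = _moderated_test(est, se, mrow["s2"], mrow["s_tilde2"], mrow["df"], state.d0)
            rows.append(
                {
                    "accession": acc,
                    "site": site,
                    "label": label,
                    "group": g,
                    "occupancy_log2fc": est,
                    "se": se,
                    "t": t,
                    "p": p,
                    "n_peptides": len(peptide_ids),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df = pd.DataFrame(
            columns=["accession", "site", "label", "group", "occupancy_log2fc", "se", "t", "p", "n_peptides", "q"]
        )
    return df


@dataclass
class PathwayFit:
    pathway_id: str
    beta0: float
    beta_g: dict  # group -> pathway-level log2 fold change
    beta_p: np.ndarray  # per-protein effects, sum to zero
    proteins: list[str]
    sigma2: float
    n_proteins: int
    p: dict  # group -> two-tailed p
    se: dict


def _fit_one_pathway(pathway_id: str, sub: pd.DataFrame, groups: list[str]) -> PathwayFit:
    """Least-squares fit of fold changes on group (cell means) and protein
    (sum-to-zero) factors for one pathway."""
    proteins = sorted(sub["accession"].unique())
    P, G = len(proteins), len(groups)
    g_idx = sub["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    p_idx = sub["accession"].map({p: i for i, p in enumerate(proteins)}).to_numpy()
    n = len(sub)
    X = np.zeros((n, G + P - 1))
    for i in range(G):
        X[g_idx == i, i] = 1.0
    for j in range(P - 1):
        X[p_idx == j, G + j] = 1.0
    X[p_idx == P - 1, G:] = -1.0
    y = sub["log2fc"].to_numpy(dtype=float)

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - rank, 1)
    sigma2 = float(resid @ resid / dof)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_all = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))

    beta_g, pvals, ses = {}, {}, {}
    for i, g in enumerate(groups):
        est, se = float(coef[i]), float(se_all[i])
        if se == 0:
            pval = 1.0 if est == 0 else 0.0
        else:
            pval = float(2.0 * sps.t.sf(abs(est) / se, dof))
        beta_g[g] = est
        ses[g] = se
        pvals[g] = min(pval, 1.0)
    beta_p = np.concatenate([coef[G:], [-coef[G:].sum()]]) if P > 1 else np.zeros(1)
    return PathwayFit(
        pathway_id=pathway_id,
        beta0=0.0,
        beta_g=beta_g,
        beta_p=beta_p,
        proteins=proteins,
        sigma2=sigma2,
        n_proteins=P,
        p=pvals,
        se=ses,
    )


def fit_pathway_model(
    fold_changes: pd.DataFrame,
    membership: dict[str, set[str]],
    min_proteins: int = 3,
) -> tuple[list[PathwayFit], pd.DataFrame]:
    """Fit the pathway model for every pathway with >= ``min_proteins``
    quantified members.

    Parameters
    ----------
    fold_changes : long DataFrame with columns [accession, group, log2fc]
        (one row per quantified protein per contrast).
    membership : pathway id -> set of protein accessions.

    Returns the fits plus a tidy table with BH q across all
    pathway x group tests.
    """
    required = {"accession", "group", "log2fc"}
    if not required.issubset(fold_changes.columns):
        raise ValueError(f"fold_changes needs columns {sorted(required)}")
    groups = list(dict.fromkeys(fold_changes["group"]))
    if len(groups) < 2:
        raise ValueError("pathway model needs >= 2 groups of fold changes")
    quantified = set(fold_changes["accession"])

    fits = []
    for pw, members in sorted(membership.items()):
        members = members & quantified
        sub = fold_changes[fold_changes["accession"].isin(members)].dropna(subset=["log2fc"])
        complete = sub.groupby("accession")["group"].nunique()
        keep = set(complete.index[complete == len(groups)])
        sub = sub[sub["accession"].isin(keep)]
        if len(keep) < min_proteins:
            logger.info("pathway %s dropped: %d quantified member(s)", pw, len(keep))
            continue
        fits.append(_fit_one_pathway(pw, sub, groups))

    rows = []
    for fit in fits:
        for g in groups:
            rows.append(
                {
                    "pathway_id": fit.pathway_id,
                    "group": g,
                    "beta_g": fit.beta_g[g],
                    "se": fit.se[g],
                    "p": fit.p[g],
                    "n_proteins": fit.n_proteins,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table = pd.DataFrame(columns=["pathway_id", "group", "beta_g", "se", "p", "n_proteins", "q"])
    return fits, table
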