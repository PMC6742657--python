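"""Statistics on per-cell imaging measurements.

Per-cell morphometric readouts (nuclear area, cytoplasmic area, envelope
intensities, texture features) are modeled as y_gd = b0 + Xg bg + Xd bd + eps
with treatment coded against a reference group and donors sum-to-zero, so the
group effects are donor-adjusted shifts versus the unstrained control.
Log-log scaling between expression and a morphometric measure is summarized
by the simple-regression slope (the power-law exponent) with its standard
error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

RESERVED = {"cell_id", "donor", "group"}


@dataclass
class GroupModelFit:
    measure: str
    beta0: float
    beta_g: dict  # non-reference group -> donor-adjusted effect
    beta_d: dict  # donor -> sum-to-zero effect
    sigma2: float
    p: dict  # group -> two-tailed p
    se: dict
    n_obs: int
    reference_group: str


def _check_confounding(df: pd.DataFrame) -> None:
    donors_per_group = df.groupby("group")["donor"].agg(lambda s: frozenset(s))
    groups = list(donors_per_group.index)
    if len(set(df["donor"])) > 1:
        for g, donors in donors_per_group.items():
            if all(donors.isdisjoint(donors_per_group[h]) for h in groups if h != g):
                raise ValueError(
                    f"donor completely confounded with group: group {g!r} uses only "
                    f"donors {sorted(donors)} seen in no other group"
                )


def fit_group_donor_model(records: pd.DataFrame, measure: str, reference_group: str) -> GroupModelFit:
    """Least-squares fit of one measure on group and donor factors.

    ``beta_g`` are group effects versus ``reference_group`` after donor
    adjustment, with two-tailed p-values from the OLS t-statistics. With a
    single donor this reduces to a one-way group fit.
    """
    if measure not in records.columns:
        raise ValueError(f"measure {measure!r} not in records")
    df = records.dropna(subset=[measure])
    groups = list(dict.fromkeys(df["group"]))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    _check_confounding(df)

    nonref = [g for g in groups if g != reference_group]
    donors = list(dict.fromkeys(df["donor"]))
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for g in nonref:
        cols.append((df["group"] == g).to_numpy(dtype=float))
        names.append(f"group[{g}]")
    if len(donors) > 1:
        d_idx = df["donor"].map({d: i for i, d in enumerate(donors)}).to_numpy()
        for j in range(len(donors) - 1):
            col = np.zeros(n)
            col[d_idx == j] = 1.0
            col[d_idx == len(donors) - 1] = -1.0
            cols.append(col)
            names.append(f"donor[{donors[j]}]")
    X = np.column_stack(cols)
    y = df[measure].to_numpy(dtype=float)

    model = sm.OLS(y, X).fit()
    beta_g, pvals, ses = {}, {}, {}
    tiny = 1e-9 * max(1.0, float(np.abs(y).max()))
    for g in nonref:
        j = names.index(f"group[{g}]")
        beta = float(model.params[j])
        se = float(model.bse[j])
        if abs(beta) < tiny and (not np.isfinite(se) or se < tiny):
            beta, se = 0.0, 0.0  # numerically constant contrast
        beta_g[g] = beta
        ses[g] = se
        if se == 0 or not np.isfinite(se):
            pvals[g] = 1.0 if beta == 0 else 0.0
        else:
            pvals[g] = float(model.pvalues[j])
    beta_d = {}
    if len(donors) > 1:
        vals = [float(model.params[names.index(f"donor[{d}]")]) for d in donors[:-1]]
        vals.append(-sum(vals))
        beta_d = dict(zip(donors, vals))
    return GroupModelFit(
        measure=measure,
        beta0=float(model.params[0]),
        beta_g=beta_g,
        beta_d=beta_d,
        sigma2=float(model.mse_resid) if model.df_resid > 0 else 0.0,
        p=pvals,
        se=ses,
        n_obs=n,
        reference_group=reference_group,
    )


def ratio_metric(records: pd.DataFrame, numerator: str, denominator: str, name: str | None = None) -> pd.DataFrame:
    """Append a per-cell ratio measure; cells with zero denominator are
    excluded (logged)."""
    for col in (numerator, denominator):
        if col not in records.columns:
            raise ValueError(f"measure {col!r} not in records")
    name = name or f"{numerator}_over_{denominator}"
    out = records.copy()
    den = out[denominator].to_numpy(dtype=float)
    bad = den == 0
    if bad.any():
        logger.info("excluding %d cell(s) with zero %s", int(bad.sum()), denominator)
        out = out.loc[~bad].copy()
        den = den[~bad]
    out[name] = out[numerator].to_numpy(dtype=float) / den
    return out


def normalize_to_control(records: pd.DataFrame, measure: str, reference_group: str) -> pd.DataFrame:
    """Divide each cell's measure by its donor's control-group mean, then
    log2, so group effects read as log2 fold changes versus control."""
    df = records.copy()
    ref = df[df["group"] == reference_group]
    means = ref.groupby("donor")[measure].mean()
    if (means <= 0).any():
        raise ValueError("control means must be positive for log normalization")
    scaled = df[measure].to_numpy(dtype=float) / df["donor"].map(means).to_numpy(dtype=float)
    if (scaled <= 0).any():
        raise ValueError("values must be positive for log normalization")
    df[f"log2_{measure}"] = np.log2(scaled)
    return df


@dataclass(frozen=True)
class ScalingFit:
    slope: float  # power-law exponent b in log-log space
    slope_sd: float
    intercept: float
    r_value: float
    n: int


def loglog_scaling(x, y) -> ScalingFit:
    """Simple linear regression of per-cell log2 measure change on log2
    expression change; the slope is the power-law exponent."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return ScalingFit(
        slope=float(res.slope),
        slope_sd=float(res.stderr),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        n=int(x.size),
    )


def condition_means(records: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    """Per-(group, donor) means of two columns, for regressions on condition
    means rather than individual cells."""
    return records.groupby(["group", "donor"], as_index=False)[[x, y]].mean()
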