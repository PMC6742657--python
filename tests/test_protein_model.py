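"""Per-protein model: design coding, weighting, Gibbs fit, moderation, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanoprot.ingest import ExperimentDesign, log_and_normalize
from mechanoprot.protein_model import (
    McmcConfig,
    ModerationState,
    _moderated_test,
    build_design,
    compute_observation_weights,
    fit_protein_model,
    moderate_variances,
)
from mechanoprot.protein_model import test_differential_batch as differential_batch
from mechanoprot.simulate import ProteomicsSimConfig, simulate_proteomics

from conftest import make_table


def design_frame(groups, donors, reference="control"):
    rows = [
        {"sample_id": f"{g}_{d}", "group": g, "donor": d}
        for g in groups
        for d in donors
    ]
    return ExperimentDesign(pd.DataFrame(rows), reference)


def complete_table(n_pep, design, values=None, score=50.0, accession="P1"):
    sample_ids = design.sample_ids
    rows = []
    for j in range(n_pep):
        rec = {"peptide_id": f"p{j}", "sequence": "ACDEFGHIK", "score": score, "accession": accession}
        for i, s in enumerate(sample_ids):
            rec[s] = float(values[j, i]) if values is not None else 100.0
        rows.append(rec)
    table = make_table(rows, sample_ids)
    table.log_scale = True  # values are used as-is (already log scale)
    return table


class TestObservationWeights:
    def test_closed_forms(self):
        # score 20 (qc .99), r = 6, c = 3 -> 0.99 + 0.01/5
        assert np.isclose(compute_observation_weights([6.0], [20.0], 3.0)[0], 0.992)
        # score ~ 0 -> w ~ 1/5
        assert np.isclose(compute_observation_weights([6.0], [1e-9], 3.0)[0], 0.2, atol=1e-6)
        # zero residual -> weight 1 regardless of score
        assert np.allclose(compute_observation_weights([0.0, 0.0], [0.1, 90.0], 3.0), 1.0)

    @given(
        st.floats(0.0, 50.0),
        st.floats(0.0, 50.0),
        st.floats(-10.0, 10.0),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, s1, s2, r, c):
        lo, hi = sorted((s1, s2))
        w_lo, w_hi = compute_observation_weights([r, r], [lo, hi], c)
        assert w_hi >= w_lo - 1e-12  # increasing in score at fixed r
        w_near, w_far = compute_observation_weights([r, r * 2], [lo, lo], c)
        assert w_far <= w_near + 1e-12  # decreasing in |r| at fixed score

    def test_positive_scale_required(self):
        with pytest.raises(ValueError):
            compute_observation_weights([1.0], [10.0], 0.0)


class TestBuildDesign:
    def test_column_and_row_counts_complete_2x2x2(self):
        design = design_frame(["control", "strain"], ["d1", "d2"])
        table = complete_table(2, design)
        pdz = build_design(table, design)
        assert pdz.X.shape == (8, 6)  # 1 + 1 + 1 + 1 + 1 + 1

    def test_missing_observation_drops_row_only(self):
        design = design_frame(["control", "strain"], ["d1", "d2"])
        table = complete_table(2, design)
        table.df.loc[0, "strain_d2"] = np.nan
        pdz = build_design(table, design)
        assert pdz.X.shape == (7, 6)

    def test_single_donor_drops_donor_terms_and_stays_full_rank(self):
        design = design_frame(["control", "strain"], ["d1"])
        table = complete_table(3, design)
        rng = np.random.default_rng(0)
        for s in design.sample_ids:
            table.df[s] = rng.normal(size=3)
        pdz = build_design(table, design)
        assert not any("donor" in c for c in pdz.colnames)
        assert np.linalg.matrix_rank(pdz.X) == pdz.X.shape[1]

    def test_group_without_observations_is_error(self):
        design = design_frame(["control", "strain"], ["d1"])
        table = complete_table(3, design)
        table.df["strain_d1"] = np.nan
        with pytest.raises(ValueError, match="strain"):
            build_design(table, design)

    def test_non_unique_peptides_excluded(self):
        design = design_frame(["control", "strain"], ["d1", "d2"])
        table = complete_table(4, design)
        table.df.loc[3, "unique"] = False
        pdz = build_design(table, design)
        assert pdz.n_peptides == 3


def _simulated_design(seed, n_pep=4, donors=("d1", "d2", "d3"), sd=0.3, beta_strain=0.0, accession="P1"):
    design = design_frame(["control", "strain"], list(donors))
    rng = np.random.default_rng(seed)
    pep_eff = rng.normal(0, 1.5, n_pep)
    don_eff = rng.normal(0, 0.2, len(donors))
    vals = np.empty((n_pep, len(design.sample_ids)))
    for i, s in enumerate(design.sample_ids):
        g = design.samples.set_index("sample_id").loc[s, "group"]
        d = list(donors).index(design.samples.set_index("sample_id").loc[s, "donor"])
        vals[:, i] = pep_eff + don_eff[d] + (beta_strain if g == "strain" else 0.0)
    vals += rng.normal(0, sd, vals.shape)
    table = complete_table(n_pep, design, values=vals, accession=accession)
    return table, design


class TestFitProteinModel:
    def test_no_signal_case(self):
        table, design = _simulated_design(seed=1, sd=0.0)
        pdz = build_design(table, design)
        fit = fit_protein_model(pdz, McmcConfig(iterations=1500, burn_in=500, seed=3))
        mcse = max(fit.mcse_g["strain"], 1e-8)
        assert abs(fit.beta_g["strain"]) < 3 * mcse + 1e-6

    def test_ols_oracle_on_balanced_design(self):
        table, design = _simulated_design(seed=2, sd=0.3, beta_strain=0.7)
        pdz = build_design(table, design)
        cfg = McmcConfig(
            iterations=2000,
            burn_in=500,
            seed=11,
            robust_weighting=False,
            fixed_lambda1_sq=1e-10,
            fixed_lambda2=1e-10,
        )
        fit = fit_protein_model(pdz, cfg)
        ols = np.linalg.lstsq(pdz.X, pdz.y, rcond=None)[0]
        tol = 3 * np.maximum(fit.coef_mcse, 0) + 1e-8
        assert np.all(np.abs(fit.coef_mean - ols) <= tol)

    def test_seed_determinism_bit_identical(self):
        table, design = _simulated_design(seed=3, sd=0.3, beta_strain=0.5)
        pdz = build_design(table, design)
        cfg = McmcConfig(iterations=800, burn_in=200, seed=42)
        f1 = fit_protein_model(pdz, cfg)
        f2 = fit_protein_model(pdz, cfg)
        assert np.array_equal(f1.coef_mean, f2.coef_mean)
        assert np.array_equal(f1.coef_sd, f2.coef_sd)
        assert f1.sigma2 == f2.sigma2
        assert f1.beta_g == f2.beta_g

    def test_sum_to_zero_invariants(self):
        table, design = _simulated_design(seed=4, sd=0.2, beta_strain=0.4)
        pdz = build_design(table, design)
        fit = fit_protein_model(pdz, McmcConfig(iterations=800, burn_in=200, seed=5))
        assert abs(fit.beta_f.sum()) < 1e-10
        assert abs(fit.beta_d.sum()) < 1e-10
        assert abs(fit.beta_fg["strain"].sum()) < 1e-10
        assert fit.sigma2 > 0
        assert "strain" in fit.rhat

    def test_ridge_shrinkage_direction(self):
        """Enlarging the fixed L2 penalty never increases the norm of the
        penalized coefficient vector (individual coefficients may trade off
        in correlated designs, the overall shrinkage may not)."""
        rng = np.random.default_rng(9)
        for inst in range(8):
            table, design = _simulated_design(seed=100 + inst, sd=0.3, beta_strain=float(rng.uniform(-1, 1)))
            pdz = build_design(table, design)
            prev = None
            for lam2 in (1e-6, 0.1, 1.0, 10.0):
                cfg = McmcConfig(
                    iterations=1500, burn_in=500, seed=77,
                    robust_weighting=False, fixed_lambda1_sq=1e-10, fixed_lambda2=lam2,
                    interaction_ridge=lam2,
                )
                fit = fit_protein_model(pdz, cfg)
                cur = float(np.linalg.norm(fit.coef_mean[1:]))
                if prev is not None:
                    assert cur <= prev + 1e-4
                prev = cur


class TestModerationAndTests:
    def _fits(self, n=15, seed=0):
        fits = []
        rng = np.random.default_rng(seed)
        for i in range(n):
            table, design = _simulated_design(
                seed=1000 + i, sd=float(rng.uniform(0.2, 0.5)), accession=f"P{i}"
            )
            pdz = build_design(table, design)
            fits.append(fit_protein_model(pdz, McmcConfig(iterations=600, burn_in=200, seed=i)))
        return fits

    def test_moderation_state_bounds(self):
        fits = self._fits()
        state = moderate_variances(fits)
        s2 = state.table["s2"].to_numpy()
        st2 = state.table["s_tilde2"].to_numpy()
        lo = np.minimum(s2, state.s0_2)
        hi = np.maximum(s2, state.s0_2)
        assert np.all((st2 >= lo - 1e-12) & (st2 <= hi + 1e-12))

    def test_d0_zero_gives_ordinary_t(self):
        t_mod, p_mod = _moderated_test(0.5, 0.1, 0.09, 0.09, 10.0, 0.0)
        from scipy import stats as sps

        assert np.isclose(t_mod, 5.0)
        assert np.isclose(p_mod, 2 * sps.t.sf(5.0, 10.0))

    def test_null_point(self):
        t, p = _moderated_test(0.0, 0.1, 0.09, 0.12, 10.0, 4.0)
        assert t == 0.0 and p == 1.0
        t, p = _moderated_test(0.0, 0.0, 0.09, 0.12, 10.0, 4.0)
        assert t == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            _moderated_test(0.5, 0.0, 0.09, 0.12, 10.0, 4.0)

    def test_batch_q_is_bh_of_p(self):
        fits = self._fits(n=12, seed=3)
        state = moderate_variances(fits)
        res = differential_batch(fits, state)
        from mechanoprot.stats import bh_adjust

        assert np.array_equal(res["q"].to_numpy(), bh_adjust(res["p"].to_numpy()))

    def test_differential_spearman_over_differential_proteins(self):
        """True effects are ranked nearly perfectly where ranking is defined."""
        from scipy.stats import spearmanr

        cfg = ProteomicsSimConfig(n_proteins=60, seed=21, ptm_fraction=0.0, fraction_differential=0.5)
        table, design, truth = simulate_proteomics(cfg)
        table = log_and_normalize(table)
        est, tru = [], []
        for i, acc in enumerate(table.accessions):
            sub = table.copy()
            sub.df = table.df[table.df["accession"] == acc].reset_index(drop=True)
            fit = fit_protein_model(build_design(sub, design), McmcConfig(iterations=1000, burn_in=300, seed=i))
            est.append(fit.beta_g["strain"])
            tru.append(truth.proteins.set_index("accession").loc[acc, "beta_g"])
        est, tru = np.array(est), np.array(tru)
        diff = tru != 0
        assert spearmanr(tru[diff], est[diff]).statistic >= 0.9
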