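import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisfactor.effects import (
    EFFECTS,
    c4_correction,
    design_variance_factor,
    expected_null_calls,
    fit_all_genes,
    fit_gene_anova,
    normed_coefficients,
    pooled_sd,
    pvalues_and_fdr,
    rank_curve,
)
from cisfactor.preprocess import DesignError

from conftest import make_design, matrix_from_values


def _design_arrays(r=3):
    d = make_design(r)
    return d["genotype"].to_numpy(), d["treatment"].to_numpy()


def lstsq_oracle(y, genotype, treatment):
    """Independent least-squares fit of the same contrasts via the normal
    equations, with +-1/2 effect coding."""
    x = np.where(np.asarray(genotype) == "Wt", 0.5, -0.5)
    z = np.where(np.asarray(treatment) == "LPS", 0.5, -0.5)
    X = np.column_stack([np.ones_like(x), x, z, x * z])
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid / (len(y) - 4))


def test_noiseless_cell_means_give_exact_contrasts():
    g, t = _design_arrays()
    cells = {("Wt", "0"): 1.0, ("Wt", "LPS"): 3.0,
             ("KO", "0"): 0.0, ("KO", "LPS"): 1.0}
    y = np.array([cells[(gi, ti)] for gi, ti in zip(g, t)])
    fit = fit_gene_anova(y, g, t)
    assert fit.g_effect == pytest.approx(1.5)
    assert fit.t_effect == pytest.approx(1.5)
    assert fit.gt_effect == pytest.approx(1.0)
    assert fit.resid_var == pytest.approx(0.0)
    assert fit.df_resid == 8


def test_constant_gene_has_null_effects():
    g, t = _design_arrays()
    fit = fit_gene_anova(np.full(12, 2.5), g, t)
    assert (fit.g_effect, fit.t_effect, fit.gt_effect) == (0.0, 0.0, 0.0)
    assert fit.mu == pytest.approx(2.5)


def test_fit_matches_least_squares_oracle(rng):
    g, t = _design_arrays()
    for _ in range(20):
        y = rng.normal(size=12)
        fit = fit_gene_anova(y, g, t)
        beta, rv = lstsq_oracle(y, g, t)
        assert fit.mu == pytest.approx(beta[0], abs=1e-10)
        assert fit.g_effect == pytest.approx(beta[1], abs=1e-10)
        assert fit.t_effect == pytest.approx(beta[2], abs=1e-10)
        assert fit.gt_effect == pytest.approx(beta[3], abs=1e-10)
        assert fit.resid_var == pytest.approx(rv, abs=1e-10)


def test_vectorized_fit_agrees_with_single_gene(rng):
    vals = rng.normal(size=(30, 12))
    m = matrix_from_values(vals, scale_state="log_normalized")
    table = fit_all_genes(m)
    g, t = _design_arrays()
    for i in [0, 7, 29]:
        fit = fit_gene_anova(vals[i], g, t)
        row = table.iloc[i]
        assert row["g"] == pytest.approx(fit.g_effect, abs=1e-12)
        assert row["resid_var"] == pytest.approx(fit.resid_var, abs=1e-12)


def test_unbalanced_design_rejected(rng):
    g, t = _design_arrays()
    g = g.copy()
    g[0] = "KO"  # 2-4 split in one treatment arm
    with pytest.raises(DesignError):
        fit_gene_anova(rng.normal(size=12), g, t)


def test_pooled_sd_is_mean_of_root_variances():
    fits = pd.DataFrame({"resid_var": [1.0, 4.0, 9.0], "df_resid": [8, 8, 8]})
    assert pooled_sd(fits).sigma_bar == pytest.approx(2.0)
    fits = pd.DataFrame({"resid_var": [0.25] * 5, "df_resid": [8] * 5})
    assert pooled_sd(fits).sigma_bar == pytest.approx(0.5)


def test_pooled_sd_degenerate_error():
    fits = pd.DataFrame({"resid_var": [0.0, 0.0], "df_resid": [8, 8]})
    with pytest.raises(ValueError):
        pooled_sd(fits)


def test_normed_coefficients_divide_by_shared_scale():
    from cisfactor.effects import PooledScale

    fits = pd.DataFrame(
        {"mu": [0.0], "g": [1.5], "t": [1.5], "gt": [1.0],
         "resid_var": [0.25], "df_resid": [8]}
    )
    out = normed_coefficients(fits, PooledScale(0.5, 0.0, 1.0))
    assert out.loc[0, ["nc_g", "nc_t", "nc_gt"]].tolist() == [3.0, 3.0, 2.0]


def test_ncs_invariant_to_global_rescaling(rng):
    vals = rng.normal(size=(200, 12))
    m1 = matrix_from_values(vals, scale_state="log_normalized")
    m2 = matrix_from_values(vals * 7.0, scale_state="log_normalized")
    t1 = normed_coefficients(fit_all_genes(m1), pooled_sd(fit_all_genes(m1)))
    t2 = normed_coefficients(fit_all_genes(m2), pooled_sd(fit_all_genes(m2)))
    for eff in EFFECTS:
        np.testing.assert_allclose(t1[f"nc_{eff}"], t2[f"nc_{eff}"],
                                   atol=1e-10)


def test_design_variance_factors():
    assert design_variance_factor(3, "g") == pytest.approx(1 / 3)
    assert design_variance_factor(3, "t") == pytest.approx(1 / 3)
    assert design_variance_factor(3, "gt") == pytest.approx(4 / 3)
    assert design_variance_factor(5, "gt") == pytest.approx(4 / 5)


def test_zero_nc_gives_p_one_and_no_call():
    fits = pd.DataFrame(
        {"mu": [0.0], "g": [0.0], "t": [0.0], "gt": [0.0],
         "resid_var": [1.0], "df_resid": [8],
         "nc_g": [0.0], "nc_t": [0.0], "nc_gt": [0.0]}
    )
    out = pvalues_and_fdr(fits, 3)
    for eff in EFFECTS:
        assert out.loc[0, f"p_{eff}"] == pytest.approx(1.0)
        assert not out.loc[0, f"sig_fdr_{eff}"]
        assert not out.loc[0, f"sig_alpha_{eff}"]


def test_expected_chance_calls_closed_form():
    assert expected_null_calls(7546, 0.05) == pytest.approx(377.3)
    assert round(expected_null_calls(7546, 0.05)) == 377


def test_q_values_are_monotone_in_p(rng):
    n = 500
    fits = pd.DataFrame(
        {"nc_g": rng.normal(scale=np.sqrt(1 / 3), size=n),
         "nc_t": rng.normal(scale=np.sqrt(1 / 3), size=n),
         "nc_gt": rng.normal(scale=np.sqrt(4 / 3), size=n)}
    )
    out = pvalues_and_fdr(fits, 3)
    for eff in EFFECTS:
        order = np.argsort(out[f"p_{eff}"].to_numpy())
        q = out[f"q_{eff}"].to_numpy()[order]
        assert np.all(np.diff(q) >= -1e-12)


def test_null_ncs_scaled_by_design_factor_are_standard_normal(rng):
    """Under the global null nc_g / sqrt(1/3) is standard normal."""
    n = 10000
    vals = rng.normal(size=(n, 12))
    m = matrix_from_values(vals, scale_state="log_normalized")
    table = normed_coefficients(fit_all_genes(m), pooled_sd(fit_all_genes(m)))
    z = table["nc_g"] / np.sqrt(design_variance_factor(3, "g"))
    assert stats.kstest(z, "norm").pvalue > 0.01


def test_rank_curve_relative_ranks_and_sorting():
    rc = rank_curve([1.0, -1.0, 0.0], 3, "g")
    np.testing.assert_allclose(rc.relative_rank, [1 / 3, 2 / 3, 1.0])
    np.testing.assert_allclose(rc.nc_sorted, [-1.0, 0.0, 1.0])
    # null curve = Normal(0, 1/3) quantiles at (i - 0.5)/n
    expected = stats.norm.ppf((np.arange(1, 4) - 0.5) / 3,
                              scale=np.sqrt(1 / 3))
    np.testing.assert_allclose(rc.null_curve, expected)


def test_rank_curve_flat_for_equal_ncs():
    rc = rank_curve(np.full(50, 1.3), 3, "t")
    assert np.ptp(rc.nc_sorted) == 0.0


def test_c4_correction_matches_simulation(rng):
    df = 8
    sim = np.sqrt(rng.chisquare(df, size=200000) / df).mean()
    assert c4_correction(df) == pytest.approx(sim, rel=1e-3)
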