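"""Per-gene 2x2 factorial ANOVA, normed effect coefficients, p-values, FDR.

For every gene the model is

    y_gti = mu + g + t + gt + e

with genotype (Wt vs knockout) and treatment (LPS vs untreated control) as
fixed factors.  Effects are the natural cell-mean contrasts, oriented so
that positive ``g`` means higher in Wt (Wt minus KO), positive ``t`` means
higher after LPS (LPS minus control), and ``gt`` is the difference in LPS
induction between the genotypes (Wt minus KO).

Because all genes share a common error scale to good approximation, effects
are standardized not by each gene's own noisy residual SD but by the
study-wide average of per-gene residual SDs ("pooled scale", sigma_bar),
giving the normed effect coefficient NC = effect / sigma_bar.  Per-gene
significance uses a normal z-test with the analytic design variance factor
(1/r for main effects, 4/r for the interaction, r replicates per cell), and
multiplicity is handled per effect with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import DesignError, ExpressionMatrix

EFFECTS = ("g", "t", "gt")


@dataclass
class AnovaFit:
    mu: float
    g_effect: float
    t_effect: float
    gt_effect: float
    resid_var: float
    df_resid: int


@dataclass
class PooledScale:
    """Study-wide error scale: arithmetic mean over genes of sqrt(resid_var).

    ``chi2_ks_stat``/``chi2_ks_p`` report a Kolmogorov-Smirnov diagnostic of
    the equal-variance assumption: under it, df*s^2/sigma^2 follows a chi^2
    distribution with df_resid degrees of freedom.
    """

    sigma_bar: float
    chi2_ks_stat: float
    chi2_ks_p: float


def design_variance_factor(n_replicates: int, effect: str) -> float:
    """Variance of the effect contrast in units of the residual variance.

    Each of the four cell means has variance sigma^2/r; the main-effect
    contrasts average two cells against two (variance sigma^2/r) while the
    interaction sums four cell means with unit coefficients (4 sigma^2/r).
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    if n_replicates < 2:
        raise DesignError("need at least 2 replicates per cell")
    return (4.0 if effect == "gt" else 1.0) / n_replicates


def c4_correction(df: int) -> float:
    """E[sqrt(chi2_df / df)]: the downward bias of a root-mean-square SD."""
    from scipy.special import gammaln

    return float(
        np.sqrt(2.0 / df) * np.exp(gammaln((df + 1) / 2.0) - gammaln(df / 2.0))
    )


def _cell_labels(genotype, treatment):
    g = np.asarray(genotype)
    t = np.asarray([str(x) for x in np.asarray(treatment)])
    return g, t


def fit_gene_anova(y, genotype, treatment) -> AnovaFit:
    """Fit the full-factorial two-way ANOVA for one gene from cell means.

    Requires a balanced 2x2 design with >= 2 replicates per cell.
    """
    y = np.asarray(y, dtype=float)
    g, t = _cell_labels(genotype, treatment)
    if not (len(y) == len(g) == len(t)):
        raise DesignError("y, genotype, treatment must have equal length")
    cells = {}
    for gen in ("Wt", "KO"):
        for trt in ("0", "LPS"):
            sel = (g == gen) & (t == trt)
            cells[(gen, trt)] = y[sel]
    counts = {k: len(v) for k, v in cells.items()}
    if min(counts.values()) < 2 or len(set(counts.values())) != 1:
        raise DesignError(f"unbalanced or incomplete 2x2 design: {counts}")

    m = {k: v.mean() for k, v in cells.items()}
    mu = np.mean(list(m.values()))
    g_eff = (m[("Wt", "0")] + m[("Wt", "LPS")]) / 2 - (
        m[("KO", "0")] + m[("KO", "LPS")]
    ) / 2
    t_eff = (m[("Wt", "LPS")] + m[("KO", "LPS")]) / 2 - (
        m[("Wt", "0")] + m[("KO", "0")]
    ) / 2
    gt_eff = (m[("Wt", "LPS")] - m[("Wt", "0")]) - (
        m[("KO", "LPS")] - m[("KO", "0")]
    )
    sse = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df = len(y) - 4
    return AnovaFit(float(mu), float(g_eff), float(t_eff), float(gt_eff),
                    float(sse / df), int(df))


def fit_all_genes(m: ExpressionMatrix) -> pd.DataFrame:
    """Vectorized per-gene ANOVA over a whole matrix.

    Returns a DataFrame indexed by gene with columns
    ``mu, g, t, gt, resid_var, df_resid``.
    """
    g, t = _cell_labels(m.design["genotype"], m.design["treatment"])
    vals = m.values.to_numpy(dtype=float)
    cell_means = {}
    sse = np.zeros(vals.shape[0])
    n_per_cell = None
    for gen in ("Wt", "KO"):
        for trt in ("0", "LPS"):
            sel = (g == gen) & (t == trt)
            n = int(sel.sum())
            if n < 2:
                raise DesignError("need >= 2 replicates in every design cell")
            if n_per_cell is None:
                n_per_cell = n
            elif n != n_per_cell:
                raise DesignError("unbalanced 2x2 design")
            block = vals[:, sel]
            mean = block.mean(axis=1)
            cell_means[(gen, trt)] = mean
            sse += ((block - mean[:, None]) ** 2).sum(axis=1)
    df = vals.shape[1] - 4
    mu = sum(cell_means.values()) / 4.0
    g_eff = (cell_means[("Wt", "0")] + cell_means[("Wt", "LPS")]) / 2 - (
        cell_means[("KO", "0")] + cell_means[("KO", "LPS")]
    ) / 2
    t_eff = (cell_means[("Wt", "LPS")] + cell_means[("KO", "LPS")]) / 2 - (
        cell_means[("Wt", "0")] + cell_means[("KO", "0")]
    ) / 2
    gt_eff = (cell_means[("Wt", "LPS")] - cell_means[("Wt", "0")]) - (
        cell_means[("KO", "LPS")] - cell_means[("KO", "0")]
    )
    return pd.DataFrame(
        {
            "mu": mu,
            "g": g_eff,
            "t": t_eff,
            "gt": gt_eff,
            "resid_var": sse / df,
            "df_resid": df,
        },
        index=m.values.index,
    )


def pooled_sd(fits: pd.DataFrame) -> PooledScale:
    """sigma_bar = mean over genes of sqrt(resid_var), plus a chi^2 diagnostic."""
    rv = np.asarray(fits["resid_var"], dtype=float)
    if len(rv) == 0:
        raise ValueError("need at least one gene")
    if np.all(rv == 0):
        raise ValueError("degenerate scale: all residual variances are zero")
    sigma_bar = float(np.sqrt(rv).mean())
    df = int(fits["df_resid"].iloc[0])
    scaled = rv * df / rv.mean()
    ks = stats.kstest(scaled, "chi2", args=(df,))
    return PooledScale(sigma_bar, float(ks.statistic), float(ks.pvalue))


def normed_coefficients(fits: pd.DataFrame, scale: PooledScale) -> pd.DataFrame:
    """NC = effect / sigma_bar, appended as nc_g, nc_t, nc_gt columns."""
    if scale.sigma_bar <= 0:
        raise ValueError("sigma_bar must be positive")
    out = fits.copy()
    for eff in EFFECTS:
        out[f"nc_{eff}"] = out[eff] / scale.sigma_bar
    return out


def pvalues_and_fdr(
    table: pd.DataFrame,
    n_replicates: int,
    alpha: float = 0.05,
    fdr: float = 0.05,
    bias_correct: bool = True,
) -> pd.DataFrame:
    """Two-sided z-test per effect plus Benjamini-Hochberg q-values.

    z = NC / sqrt(v) with v the design variance factor.  Because sigma_bar
    (a mean of root residual variances) underestimates the true residual SD
    by the factor E[sqrt(chi2_df/df)], the z statistic applies the standard
    c4 bias correction by default; without it the type-I rate at alpha=0.05
    would be ~5.7% rather than nominal for the 3-replicate design.  Adds,
    per effect x in {g, t, gt}: ``p_x``, ``q_x``, and boolean calls
    ``sig_fdr_x`` (q <= fdr) and ``sig_alpha_x`` (p <= alpha).
    """
    if not (0 < alpha < 1) or not (0 < fdr < 1):
        raise ValueError("alpha and fdr must be in (0, 1)")
    out = table.copy()
    c4 = c4_correction(4 * n_replicates - 4) if bias_correct else 1.0
    for eff in EFFECTS:
        v = design_variance_factor(n_replicates, eff)
        z = out[f"nc_{eff}"] * c4 / np.sqrt(v)
        p = 2.0 * stats.norm.sf(np.abs(z))
        reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
        out[f"p_{eff}"] = p
        out[f"q_{eff}"] = q
        out[f"sig_fdr_{eff}"] = reject
        out[f"sig_alpha_{eff}"] = p <= alpha
    return out


def expected_null_calls(n_genes: int, alpha: float = 0.05) -> float:
    """Expected chance significant genes at level alpha under the global null."""
    return n_genes * alpha


@dataclass
class RankCurve:
    """Sorted NCs against relative ranks i/n, with the normal-theory null."""

    nc_sorted: np.ndarray
    relative_rank: np.ndarray
    null_curve: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_rank": self.relative_rank,
                "nc": self.nc_sorted,
                "null": self.null_curve,
            }
        )


def rank_curve(ncs, n_replicates: int, effect: str) -> RankCurve:
    """Diagnostic curve of sorted NCs vs relative rank.

    The null curve is the quantile function of Normal(0, v) evaluated at the
    plotting positions (i - 0.5)/n, v being the design variance factor of
    the chosen effect: the curve expected if no gene had any effect.
    """
    ncs = np.sort(np.asarray(ncs, dtype=float))
    n = len(ncs)
    if n < 1:
        raise ValueError("need at least one NC")
    v = design_variance_factor(n_replicates, effect)
    i = np.arange(1, n + 1)
    null = stats.norm.ppf((i - 0.5) / n, scale=np.sqrt(v))
    return RankCurve(ncs, i / n, null)
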