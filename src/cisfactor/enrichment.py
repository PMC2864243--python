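"""Competitive gene-class enrichment on normed effect coefficients.

A gene class (a GO biological-process category, the genes sharing a
conserved promoter TFBS or 3'UTR motif, the cognate genes of a miRNA, or a
curated list) is contrasted against all remaining analyzed genes: the class
statistic is the mean NC of its members, tested with a two-sample t-test
(classical pooled-variance form; Welch by flag) and a two-sample
Kolmogorov-Smirnov test.  The class mean NC is also expressed as an
enrichment ratio ER = exp(sigma_bar * NC): the geometric-mean expression
ratio implied by the class shift on the normalized natural-log scale.

A separate contingency route (`tfbs_set_enrichment`) asks whether a curated
gene set carries a motif more often than the rest of the universe (Fisher's
exact test, Haldane-Anscombe-corrected odds ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CLASS_SOURCES = (
    "GO_biological_process",
    "TFBS_5UR",
    "UTR3_motif",
    "miRNA_cognate",
    "curated_list",
)


class ClassSizeError(ValueError):
    pass


@dataclass
class GeneClassMap:
    """Named gene classes -> member gene sets, tagged with their source."""

    source: str
    classes: Dict[str, Set[str]]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in CLASS_SOURCES:
            raise ValueError(f"source must be one of {CLASS_SOURCES}")

    def restrict(self, universe: Iterable[str]) -> "GeneClassMap":
        """Intersect every class with the analyzed gene universe."""
        uni = set(universe)
        return GeneClassMap(
            self.source,
            {name: members & uni for name, members in self.classes.items()},
            dict(self.metadata),
        )


@dataclass
class ClassResult:
    class_name: str
    n_genes: int
    nc_class: float
    er: float
    p_t: float
    p_ks: float
    q: float = float("nan")


def class_stats(
    ncs: pd.Series,
    members: Set[str],
    sigma_bar: float,
    class_name: str = "",
    welch: bool = False,
) -> ClassResult:
    """Contrast the NCs of one class against all other genes.

    ``ncs`` is the per-gene NC vector for one effect over the full analyzed
    universe.  Degenerate comparisons (both groups constant and equal)
    yield p = NaN, treated downstream as no-call.
    """
    member_mask = ncs.index.isin(members)
    in_nc = ncs.to_numpy()[member_mask]
    out_nc = ncs.to_numpy()[~member_mask]
    if len(in_nc) < 2 or len(out_nc) < 2:
        raise ClassSizeError(
            f"class {class_name!r}: members and complement must each have >= 2 genes"
        )
    nc_class = float(in_nc.mean())
    er = float(np.exp(sigma_bar * nc_class))
    if np.ptp(in_nc) == 0 and np.ptp(out_nc) == 0:
        p_t = p_ks = float("nan")
    else:
        p_t = float(stats.ttest_ind(in_nc, out_nc, equal_var=not welch).pvalue)
        p_ks = float(stats.ks_2samp(in_nc, out_nc).pvalue)
    return ClassResult(class_name, int(len(in_nc)), nc_class, er, p_t, p_ks)


def enrichment_table(
    class_map: GeneClassMap,
    effect_table: pd.DataFrame,
    effect: str,
    sigma_bar: float,
    min_class_size: int = 10,
    alpha: float = 0.01,
    fdr: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """One row per class of sufficient size, sorted by class NC descending.

    The gene universe is the index of ``effect_table`` (classes are
    intersected with it first).  Columns: class, n_genes, er, nc, p_t, p_ks,
    q (BH across classes on the t-test p), sig_fdr05 / sig_alpha flags.
    """
    if effect not in ("g", "t", "gt"):
        raise ValueError("effect must be one of g, t, gt")
    col = f"nc_{effect}"
    if col not in effect_table.columns:
        raise ValueError(f"effect table lacks column {col!r}")
    ncs = effect_table[col]
    restricted = class_map.restrict(effect_table.index)
    results = []
    for name in sorted(restricted.classes):
        members = restricted.classes[name]
        if len(members) < min_class_size:
            continue
        if len(members) < 2 or len(ncs) - len(members) < 2:
            continue
        results.append(class_stats(ncs, members, sigma_bar, name, welch=welch))
    if not results:
        return pd.DataFrame(
            columns=["class", "n_genes", "er", "nc", "p_t", "p_ks", "q",
                     "sig_fdr", "sig_alpha"]
        )
    df = pd.DataFrame(
        {
            "class": [r.class_name for r in results],
            "n_genes": [r.n_genes for r in results],
            "er": [r.er for r in results],
            "nc": [r.nc_class for r in results],
            "p_t": [r.p_t for r in results],
            "p_ks": [r.p_ks for r in results],
        }
    )
    p = df["p_t"].to_numpy()
    ok = np.isfinite(p)
    q = np.full(len(p), np.nan)
    rej = np.zeros(len(p), dtype=bool)
    if ok.any():
        rej_ok, q_ok, _, _ = multipletests(p[ok], alpha=fdr, method="fdr_bh")
        q[ok] = q_ok
        rej[ok] = rej_ok
    df["q"] = q
    df["sig_fdr"] = rej
    df["sig_alpha"] = np.where(np.isfinite(p), p <= alpha, False)
    df = df.sort_values(["nc", "class"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def tfbs_set_enrichment(
    gene_set: Set[str],
    motif_presence: Mapping[str, Mapping[str, bool]],
    universe: Set[str],
) -> pd.DataFrame:
    """Is a motif over-represented in a curated gene set vs the rest?

    ``motif_presence`` maps motif id -> {gene: bool}; genes absent from the
    inner map count as motif-absent.  Returns one row per motif with the
    2x2 counts, the odds ratio (Haldane-Anscombe +0.5 correction applied
    when any cell is zero) and the two-sided Fisher exact p-value.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    complement = universe - gene_set
    for motif_id in sorted(motif_presence):
        present = {g for g, flag in motif_presence[motif_id].items() if flag}
        a = len(gene_set & present)
        b = len(gene_set) - a
        c = len(complement & present)
        d = len(complement) - c
        table = np.array([[a, b], [c, d]])
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            {
                "motif": motif_id,
                "set_present": a,
                "set_absent": b,
                "rest_present": c,
                "rest_absent": d,
                "odds_ratio": float(orr),
                "p_fisher": p,
            }
        )
    return pd.DataFrame(rows)


def fit_er_constant(er, nc) -> float:
    """Proportionality constant c of ln(ER) = c * NC from rounded table rows.

    Starts from the through-origin least-squares estimate and, because
    published ER/NC pairs are rounded to 2 decimals (interval-censored),
    refines it to the midpoint of the interval of c values consistent with
    every row's rounding, when that interval is nonempty.
    """
    er = np.asarray(er, dtype=float)
    nc = np.asarray(nc, dtype=float)
    if er.shape != nc.shape or er.size < 2:
        raise ValueError("need matching er/nc vectors with >= 2 rows")
    ls = float(np.sum(nc * np.log(er)) / np.sum(nc * nc))
    lo, hi = 0.0, np.inf
    for e, n in zip(er, nc):
        if n == 0:
            continue
        a = np.log(e - 0.005) / n
        b = np.log(e + 0.005) / n
        a, b = min(a, b), max(a, b)
        lo, hi = max(lo, a), min(hi, b)
    if lo < hi:
        if lo <= ls <= hi:
            return ls
        return float((lo + hi) / 2.0)
    return ls
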