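"""Microarray preprocessing: expression filter, log-normalization, deduplication.

The processing order mirrors the experimental protocol this package models:
genes are first filtered on *unnormalized* linear fluorescence intensity
(strictly greater than a threshold, default 25), the surviving genes are
natural-log transformed and standardized separately per array to mean 0 /
variance 1, and finally probes with missing annotation are dropped and
duplicate entries per gene are resolved by keeping a single randomly chosen
row.  State is tracked on the matrix so the steps cannot be run out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

RAW = "raw"
LOG_NORMALIZED = "log_normalized"

FILTER_RULES = ("all_arrays", "any_array", "median")


class StateError(RuntimeError):
    """Operation applied to a matrix in the wrong scale state."""


class DesignError(ValueError):
    """Array design labels are inconsistent or unbalanced."""


@dataclass
class ExpressionMatrix:
    """Genes x arrays expression values with the 2x2 factorial design labels.

    ``values`` is a DataFrame indexed by gene id with one column per array.
    ``design`` is indexed by array id and carries ``genotype`` (``Wt``/``KO``),
    ``treatment`` (``0``/``LPS``) and ``replicate``.  ``scale_state`` is
    ``"raw"`` (linear intensities) or ``"log_normalized"`` (per-array
    standardized natural-log values).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale_state: str = RAW

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design.index):
            raise DesignError("design rows must match value columns (array ids)")
        for col in ("genotype", "treatment", "replicate"):
            if col not in self.design.columns:
                raise DesignError(f"design is missing column {col!r}")
        bad_g = set(self.design["genotype"]) - {"Wt", "KO"}
        if bad_g:
            raise DesignError(f"unknown genotype labels: {sorted(bad_g)}")
        bad_t = set(map(str, self.design["treatment"])) - {"0", "LPS"}
        if bad_t:
            raise DesignError(f"unknown treatment labels: {sorted(bad_t)}")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def array_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_replicates(self) -> int:
        counts = self.design.groupby(
            [self.design["genotype"], self.design["treatment"].astype(str)]
        ).size()
        if len(counts) != 4 or counts.nunique() != 1:
            raise DesignError("design is not a balanced full 2x2 factorial")
        return int(counts.iloc[0])


def filter_expressed(
    m: ExpressionMatrix, threshold: float = 25.0, rule: str = "all_arrays"
) -> ExpressionMatrix:
    """Keep genes whose unnormalized intensity strictly exceeds ``threshold``.

    ``rule`` decides how many arrays must exceed the threshold:
    ``all_arrays`` (every array, the conservative default), ``any_array``
    (at least one), or ``median`` (the per-gene median exceeds it).
    A gene with all intensities exactly equal to the threshold is removed
    under every rule (the comparison is strict).
    """
    if m.scale_state != RAW:
        raise StateError("filter_expressed requires raw (unnormalized) intensities")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if rule not in FILTER_RULES:
        raise ValueError(f"rule must be one of {FILTER_RULES}")

    above = m.values.gt(threshold)
    if rule == "all_arrays":
        keep = above.all(axis=1)
    elif rule == "any_array":
        keep = above.any(axis=1)
    else:
        keep = m.values.median(axis=1).gt(threshold)
    return replace(m, values=m.values.loc[keep])


def log_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform, then standardize each array to mean 0, var 1.

    The variance uses the n-1 (sample) denominator.  Raises ``ValueError``
    naming the offending gene/array on nonpositive input.
    """
    if m.scale_state != RAW:
        raise StateError("log_normalize requires raw intensities")
    vals = m.values
    if (vals <= 0).any().any():
        bad = vals.le(0)
        gene = bad.any(axis=1).idxmax()
        array = bad.loc[gene].idxmax()
        raise ValueError(
            f"nonpositive intensity for gene {gene!r} on array {array!r}"
        )
    logged = np.log(vals)
    centered = logged - logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("array with zero variance cannot be standardized")
    return replace(m, values=centered / sd, scale_state=LOG_NORMALIZED)


def dedupe_annotations(
    m: ExpressionMatrix,
    annotation: Mapping[str, Optional[str]],
    seed: int,
) -> ExpressionMatrix:
    """Drop unannotated probes; keep one random row per annotated gene.

    ``annotation`` maps probe/row id to a gene identity; probes absent from
    the map or mapping to ``None`` are removed.  When several rows share one
    gene identity a single row is kept, chosen uniformly with ``seed``
    (deterministic), and the surviving row is re-labelled with the gene
    identity.
    """
    rng = np.random.default_rng(seed)
    genes = pd.Series(
        [annotation.get(g) for g in m.values.index], index=m.values.index
    )
    annotated = genes.dropna()
    keep_rows = []
    new_ids = []
    for gene_identity, grp in annotated.groupby(annotated, sort=True):
        rows = list(grp.index)
        pick = rows[rng.integers(len(rows))]
        keep_rows.append(pick)
        new_ids.append(gene_identity)
    out = m.values.loc[keep_rows].copy()
    out.index = new_ids
    return replace(m, values=out)
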