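"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the study conditions the pipeline was built for:

* a 2x2 factorial (genotype x LPS treatment, 3 replicates per cell)
  microarray experiment, emitted as linear-scale intensities so the >25
  expression filter is meaningfully exercised, with class-structured
  genotype/treatment/interaction effects on the log scale and residual
  noise of a common scale across genes;
* orthologous two-species sequence pairs with motifs planted at known,
  optionally conserved, alignment positions, emitted both as ground-truth
  alignments and as unaligned sequences;
* mature miRNA sets in which each target octamer has exactly one cognate
  miRNA by construction, plus decoys guaranteed not to match.

Every generator records a truth table; downstream tests read planted truth
exclusively from these outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conservation import (
    AlignedOrthologPair,
    IUPAC_MASKS,
    MotifDefinition,
    reverse_complement,
    scan_sequence,
)
from .mirna import MatureMirna
from .preprocess import ExpressionMatrix

_BASES = "ACGT"
_IUPAC_CHOICES = {
    code: [b for b in _BASES if IUPAC_MASKS[b] & mask]
    for code, mask in IUPAC_MASKS.items()
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ClassSpec:
    """One planted gene class: size and mean effects on the log scale."""

    name: str
    n_members: int
    g_mean: float = 0.0
    t_mean: float = 0.0
    gt_mean: float = 0.0
    effect_sd: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for the expression generator.

    Defaults mirror the modeled experiment: 3 replicates per design cell
    and residual noise of common SD across genes on the normalized log
    scale.  ``background_intensity`` is the linear-scale center of
    unexpressed-to-expressed signal (log-values are offsets from its log),
    chosen well above the >25 expression filter; ``frac_below_filter``
    genes are instead emitted entirely below the filter threshold.
    ``sigma_gene`` is the SD of per-gene baseline log-means, giving the
    between-gene spread that per-array standardization divides out.
    """

    n_genes: int
    n_replicates: int = 3
    sigma_resid: float = 0.1
    class_specs: Sequence[ClassSpec] = field(default_factory=tuple)
    background_intensity: float = 500.0
    frac_below_filter: float = 0.0
    sigma_gene: float = 0.5
    seed: int = 0
    filter_threshold: float = 25.0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ConfigError("need n_genes >= 1 and n_replicates >= 2")
        if self.sigma_resid <= 0:
            raise ConfigError("sigma_resid must be positive")
        if not 0 <= self.frac_below_filter <= 1:
            raise ConfigError("frac_below_filter must be in [0, 1]")
        if self.background_intensity <= self.filter_threshold:
            raise ConfigError(
                "background_intensity must exceed the filter threshold"
            )
        n_below = int(round(self.frac_below_filter * self.n_genes))
        n_class = sum(c.n_members for c in self.class_specs)
        if n_class + n_below > self.n_genes:
            raise ConfigError(
                "class member counts plus below-filter genes exceed n_genes"
            )


def generate_expression(
    cfg: SimulationConfig,
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a raw (linear-intensity) matrix plus its truth table.

    Cell means on the log scale are mu_gene + g*x + t*z + gt*x*z with
    genotype/treatment codes x, z = +-1/2 (so the fitted contrasts recover
    the planted g, t, gt exactly in expectation); observations add
    Normal(0, sigma_resid) noise and are exponentiated around the log of
    ``background_intensity``.  The designated below-filter genes get
    uniform intensities in (5, 25) on every array.

    The truth table records, per gene: class (empty string when none),
    g_true, t_true, gt_true, below_filter.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    r = cfg.n_replicates
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    n_below = int(round(cfg.frac_below_filter * n))
    order = rng.permutation(n)
    below_idx = np.sort(order[:n_below])
    eligible = order[n_below:]

    below = np.zeros(n, dtype=bool)
    below[below_idx] = True
    class_of = np.array([""] * n, dtype=object)
    g_true = np.zeros(n)
    t_true = np.zeros(n)
    gt_true = np.zeros(n)
    pos = 0
    for spec in cfg.class_specs:
        members = eligible[pos : pos + spec.n_members]
        pos += spec.n_members
        class_of[members] = spec.name
        g_true[members] = rng.normal(spec.g_mean, spec.effect_sd, len(members))
        t_true[members] = rng.normal(spec.t_mean, spec.effect_sd, len(members))
        gt_true[members] = rng.normal(
            spec.gt_mean, spec.effect_sd, len(members)
        )

    mu_gene = rng.normal(0.0, cfg.sigma_gene, n)

    arrays = []
    design_rows = []
    for gen, x in (("Wt", 0.5), ("KO", -0.5)):
        for trt, z in (("0", -0.5), ("LPS", 0.5)):
            for rep in range(1, r + 1):
                arrays.append(f"{gen}_{trt}_r{rep}")
                design_rows.append(
                    {"array_id": arrays[-1], "genotype": gen,
                     "treatment": trt, "replicate": rep, "_x": x, "_z": z}
                )
    design = pd.DataFrame(design_rows).set_index("array_id")

    log_bg = np.log(cfg.background_intensity)
    vals = np.empty((n, len(arrays)))
    for j, row in enumerate(design_rows):
        x, z = row["_x"], row["_z"]
        mean = mu_gene + g_true * x + t_true * z + gt_true * x * z
        vals[:, j] = np.exp(
            log_bg + mean + rng.normal(0.0, cfg.sigma_resid, n)
        )
    if n_below:
        vals[below, :] = rng.uniform(5.0, 25.0, size=(n_below, len(arrays)))

    values = pd.DataFrame(vals, index=gene_ids, columns=arrays)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "class": class_of,
            "g_true": g_true,
            "t_true": t_true,
            "gt_true": gt_true,
            "below_filter": below,
        }
    ).set_index("gene")
    matrix = ExpressionMatrix(
        values, design.drop(columns=["_x", "_z"]), scale_state="raw"
    )
    return matrix, truth


def truth_class_map(truth: pd.DataFrame, source: str = "GO_biological_process"):
    """GeneClassMap of the planted classes (above-filter genes only)."""
    from .enrichment import GeneClassMap

    usable = truth[(truth["class"] != "") & (~truth["below_filter"])]
    classes = {
        name: set(grp.index) for name, grp in usable.groupby("class", sort=True)
    }
    return GeneClassMap(source, classes)


# ---------------------------------------------------------------------------
# ortholog pairs with planted motifs


@dataclass
class MotifPlantConfig:
    """Conditions for the planted-motif ortholog-pair generator."""

    n_genes: int
    region: str
    region_length: int
    motifs: Sequence[MotifDefinition]
    plant_rate: float = 0.5
    conserve_rate: float = 0.7
    point_divergence: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("5UR", "3UTR"):
            raise ConfigError("region must be 5UR or 3UTR")
        if self.region == "5UR" and self.region_length > 8000:
            raise ConfigError("5UR regions are at most 8000 bp")
        if not self.motifs:
            raise ConfigError("need at least one motif")
        longest = max(m.max_form_length for m in self.motifs)
        if self.region_length < longest:
            raise ConfigError("region_length must be >= the longest motif form")
        for name in ("plant_rate", "conserve_rate", "point_divergence",
                     "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


def _instantiate_form(form: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_IUPAC_CHOICES[c.upper()]) for c in form)


def _scrub_background(
    seq: List[str],
    motifs: Sequence[MotifDefinition],
    protected: List[Tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Mutate chance motif occurrences outside the protected planted spans.

    Keeps planted truth exact: without scrubbing, random background produces
    occasional conserved-looking matches that are not in the truth table.
    """
    for _ in range(50):
        dirty = False
        s = "".join(seq)
        for motif in motifs:
            for start, form, strand in scan_sequence(s, motif):
                span = (start, start + len(form))
                if any(span[0] == p0 and span[1] == p1 for p0, p1 in protected):
                    continue
                # pick a position of the hit not inside any protected span
                candidates = [
                    i for i in range(*span)
                    if not any(p0 <= i < p1 for p0, p1 in protected)
                ]
                if not candidates:
                    continue
                i = int(rng.choice(candidates))
                seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motif matches")


def generate_ortholog_pairs(
    cfg: MotifPlantConfig,
) -> Tuple[List[AlignedOrthologPair], pd.DataFrame]:
    """Simulate aligned ortholog pairs with planted motif occurrences.

    Per gene and motif, with probability ``plant_rate`` a concrete
    realization of a random form is planted in species A; with probability
    ``conserve_rate`` it is planted at the homologous position in species B
    as well (a conserved occurrence), otherwise B keeps background sequence
    there.  Species B then diverges by per-site substitutions
    (``point_divergence``) and indels (``indel_rate``), applied after
    planting — so divergence can destroy planted occurrences, which is
    exactly how rising divergence lowers conserved-call counts.  Background
    is scrubbed of chance occurrences of the planted motifs so that at zero
    divergence the conservation caller reproduces the truth table exactly.

    The truth table lists one row per planted occurrence: gene, motif,
    alignment column (of the ground-truth alignment), start in each
    species (-1 when absent), conserved flag.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs: List[AlignedOrthologPair] = []
    rows = []
    for gi in range(cfg.n_genes):
        gene = f"gene{gi:05d}"
        L = cfg.region_length
        a = list(rng.choice(list(_BASES), L))
        # choose plants: (motif, realization, pos, conserved); planted spans
        # keep a buffer of one motif length between them so a junction of two
        # plants can never spell an unscrubable chance occurrence
        plants = []
        occupied: List[Tuple[int, int]] = []
        buffer = max(m.max_form_length for m in cfg.motifs)
        for motif in cfg.motifs:
            if rng.random() >= cfg.plant_rate:
                continue
            form = motif.forms[int(rng.integers(len(motif.forms)))]
            real = _instantiate_form(form, rng)
            for _ in range(20):  # find a non-overlapping slot
                pos = int(rng.integers(0, L - len(real) + 1))
                span = (pos, pos + len(real))
                if all(span[1] + buffer <= p0 or span[0] >= p1 + buffer
                       for p0, p1 in occupied):
                    occupied.append(span)
                    plants.append(
                        (motif, form, real, pos,
                         rng.random() < cfg.conserve_rate)
                    )
                    break
        for motif, form, real, pos, conserved in plants:
            a[pos : pos + len(real)] = list(real)
        # species B before divergence: conserved plants kept, others reverted
        b = list(a)
        for motif, form, real, pos, conserved in plants:
            if not conserved:
                b[pos : pos + len(real)] = list(
                    rng.choice(list(_BASES), len(real))
                )
        _scrub_background(a, cfg.motifs,
                          [(p, p + len(r)) for _, _, r, p, _ in plants], rng)
        # re-sync conserved spans and re-scrub B around reverted spans
        for motif, form, real, pos, conserved in plants:
            if conserved:
                b[pos : pos + len(real)] = a[pos : pos + len(real)]
        _scrub_background(
            b, cfg.motifs,
            [(p, p + len(r)) for _, _, r, p, c in plants if c], rng,
        )

        # diverge B along an explicit edit transcript over A's coordinates
        col_of_a_pos: Dict[int, int] = {}
        cols_a: List[str] = []
        cols_b: List[str] = []
        for i in range(L):
            if cfg.indel_rate and rng.random() < cfg.indel_rate / 2:
                # deletion in B
                col_of_a_pos[i] = len(cols_a)
                cols_a.append(a[i])
                cols_b.append("-")
                continue
            base_b = b[i]
            if cfg.point_divergence and rng.random() < cfg.point_divergence:
                base_b = rng.choice([x for x in _BASES if x != base_b])
            col_of_a_pos[i] = len(cols_a)
            cols_a.append(a[i])
            cols_b.append(base_b)
            if cfg.indel_rate and rng.random() < cfg.indel_rate / 2:
                cols_a.append("-")
                cols_b.append(rng.choice(list(_BASES)))

        pair = AlignedOrthologPair(
            gene, cfg.region, "".join(cols_a), "".join(cols_b)
        )
        pairs.append(pair)
        for motif, form, real, pos, conserved in plants:
            rows.append(
                {
                    "gene": gene,
                    "motif": motif.motif_id,
                    "form": form,
                    "alignment_column": col_of_a_pos[pos],
                    "start_a": pos,
                    "start_b": pos if conserved else -1,
                    "conserved": conserved,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=["gene", "motif", "form", "alignment_column",
                 "start_a", "start_b", "conserved"],
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# miRNA sets


def generate_mirnas(
    motifs: Sequence[MotifDefinition],
    n_decoys: int,
    seed: int,
    mature_length: int = 22,
) -> Tuple[List[MatureMirna], pd.DataFrame]:
    """One cognate miRNA per octamer motif, plus non-matching decoys.

    Each motif's first form must be an unambiguous DNA octamer; its miRNA
    starts with the reverse complement of the octamer (as RNA) so the
    distal-octamer rule associates them by construction.  Decoys are random
    mature sequences whose 5' octamer matches no motif.
    """
    rng = np.random.default_rng(seed)
    octamers = []
    for motif in motifs:
        form = motif.forms[0].upper()
        if len(form) != 8 or any(c not in _BASES for c in form):
            raise ConfigError(
                f"motif {motif.motif_id!r}: first form must be an unambiguous "
                "DNA octamer"
            )
        octamers.append((motif.motif_id, form))

    mirnas: List[MatureMirna] = []
    rows = []
    taken = {form for _, form in octamers}
    for k, (motif_id, form) in enumerate(octamers):
        head = reverse_complement(form).replace("T", "U")
        tail = "".join(rng.choice(list("ACGU"), mature_length - 8))
        mid = f"syn-miR-{k + 1}"
        mirnas.append(MatureMirna(mid, head + tail))
        rows.append({"motif": motif_id, "octamer": form, "mirna_id": mid})
    for k in range(n_decoys):
        while True:
            seq = "".join(rng.choice(list("ACGU"), mature_length))
            head = reverse_complement(seq[:8].replace("U", "T"))
            if head not in taken:
                break
        mirnas.append(MatureMirna(f"syn-decoy-{k + 1}", seq))
    truth = pd.DataFrame(rows, columns=["motif", "octamer", "mirna_id"])
    return mirnas, truth
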