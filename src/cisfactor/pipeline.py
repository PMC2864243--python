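"""End-to-end orchestration: simulate -> preprocess -> effects -> enrichment.

`run_pipeline` executes the stages in protocol order (expression filter,
log-normalization, deduplication, per-gene ANOVA and normed coefficients,
then class enrichment for each class source, with motif-conservation and
miRNA class construction feeding the sequence-based sources) and writes
every stage output plus a JSON manifest of parameters and seeds into a run
directory.  Reruns with identical configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from . import __version__
from .conservation import MotifDefinition, build_presence_map
from .effects import (
    fit_all_genes,
    normed_coefficients,
    pooled_sd,
    pvalues_and_fdr,
    rank_curve,
)
from .enrichment import enrichment_table
from .io import presence_to_gmt, write_expression, write_gmt
from .mirna import associate_octamers, build_mirna_classes
from .preprocess import dedupe_annotations, filter_expressed, log_normalize
from .synthetic import (
    ClassSpec,
    MotifPlantConfig,
    SimulationConfig,
    generate_expression,
    generate_mirnas,
    generate_ortholog_pairs,
    truth_class_map,
)


@dataclass
class PipelineConfig:
    """Tunable knobs of a full synthetic run; defaults are the study
    conditions the generators emulate."""

    out_dir: str = "run"
    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    sigma_resid: float = 0.1
    frac_below_filter: float = 0.05
    filter_threshold: float = 25.0
    filter_rule: str = "all_arrays"
    alpha: float = 0.05
    fdr: float = 0.05
    min_class_size: int = 10
    enrichment_alpha: float = 0.01
    n_ortholog_genes: int = 100
    region_length: int = 1000
    plant_rate: float = 0.5
    conserve_rate: float = 0.7
    point_divergence: float = 0.0
    indel_rate: float = 0.0
    n_decoy_mirnas: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


DEFAULT_CLASS_SPECS = (
    # immune classes down in KO at baseline and strongly LPS-induced;
    # metabolic classes up in KO and LPS-suppressed; interactions present
    ClassSpec("immune_response", 60, g_mean=0.4, t_mean=0.8,
              gt_mean=0.3, effect_sd=0.2),
    ClassSpec("defense_response", 40, g_mean=0.3, t_mean=0.5,
              gt_mean=0.2, effect_sd=0.2),
    ClassSpec("lipid_biosynthesis", 40, g_mean=-0.25, t_mean=-0.4,
              gt_mean=-0.2, effect_sd=0.15),
    ClassSpec("metabolism", 80, g_mean=-0.15, t_mean=-0.3,
              gt_mean=-0.1, effect_sd=0.1),
)

DEFAULT_5UR_MOTIFS = (
    MotifDefinition("IRF_ISRE", ("RAAASYGAAASY",), "5UR"),
    MotifDefinition("GAS", ("TTCNNNGAA",), "5UR"),
    MotifDefinition("TATA", ("TATAWAWR",), "5UR"),
)

DEFAULT_3UTR_MOTIFS = (
    MotifDefinition("m2_ARE", ("TATTTATT",), "3UTR"),
    MotifDefinition("m8_oct", ("GTGCCTTA",), "3UTR"),
    MotifDefinition("m9_oct", ("CAGTATTA",), "3UTR"),
)


def render_class_table(results: pd.DataFrame) -> str:
    """Tab-separated report with ER/NC at 2 decimals and p at 4, NC-descending.

    Ties in NC fall back to class name; an empty result renders headers only.
    """
    header = "class\t# genes\tER\tNC\tp-value"
    if len(results) == 0:
        return header + "\n"
    df = results.sort_values(
        ["nc", "class"], ascending=[False, True], kind="stable"
    )
    lines = [header]
    for _, row in df.iterrows():
        lines.append(
            f"{row['class']}\t{int(row['n_genes'])}\t{row['er']:.2f}\t"
            f"{row['nc']:.2f}\t{row['p_t']:.4f}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(
    cfg: PipelineConfig,
    class_specs: Sequence[ClassSpec] = DEFAULT_CLASS_SPECS,
    make_plots: bool = False,
) -> Dict[str, object]:
    """Full synthetic run; returns the in-memory stage products and writes
    all tables plus a manifest under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimulationConfig(
        n_genes=cfg.n_genes,
        n_replicates=cfg.n_replicates,
        sigma_resid=cfg.sigma_resid,
        class_specs=tuple(class_specs),
        frac_below_filter=cfg.frac_below_filter,
        filter_threshold=cfg.filter_threshold,
        seed=cfg.seed,
    )
    matrix, truth = generate_expression(sim_cfg)
    write_expression(matrix, out / "expression_raw.tsv", out / "arrays.tsv")
    truth.to_csv(out / "expression_truth.tsv", sep="\t")

    filtered = filter_expressed(matrix, cfg.filter_threshold, cfg.filter_rule)
    normalized = log_normalize(filtered)
    annotation = {g: g for g in normalized.gene_ids}  # synthetic ids unique
    deduped = dedupe_annotations(normalized, annotation, seed=cfg.seed + 1)

    fits = fit_all_genes(deduped)
    scale = pooled_sd(fits)
    table = normed_coefficients(fits, scale)
    table = pvalues_and_fdr(table, cfg.n_replicates, cfg.alpha, cfg.fdr)
    table.to_csv(out / "effects.tsv", sep="\t", index_label="gene")

    curves = {}
    for eff in ("g", "t", "gt"):
        rc = rank_curve(table[f"nc_{eff}"], cfg.n_replicates, eff)
        rc.to_frame().to_csv(out / f"rank_curve_{eff}.tsv", sep="\t",
                             index=False)
        curves[eff] = rc
        if make_plots:
            _plot_rank_curve(rc, eff, out / f"rank_curve_{eff}.svg")

    go_map = truth_class_map(truth)
    write_gmt(go_map, out / "classes_go.gmt")
    enrich = {}
    for eff in ("g", "t", "gt"):
        res = enrichment_table(
            go_map, table, eff, scale.sigma_bar,
            min_class_size=cfg.min_class_size, alpha=cfg.enrichment_alpha,
            fdr=cfg.fdr,
        )
        res.to_csv(out / f"enrichment_go_{eff}.tsv", sep="\t", index=False)
        (out / f"table_go_{eff}.txt").write_text(render_class_table(res))
        enrich[("GO", eff)] = res

    # sequence-based classes: 5'UR TFBSs and 3'UTR motifs on synthetic pairs
    presence_maps = {}
    for tag, motifs, region in (
        ("TFBS_5UR", DEFAULT_5UR_MOTIFS, "5UR"),
        ("UTR3_motif", DEFAULT_3UTR_MOTIFS, "3UTR"),
    ):
        plant_cfg = MotifPlantConfig(
            n_genes=min(cfg.n_ortholog_genes, cfg.n_genes),
            region=region,
            region_length=cfg.region_length,
            motifs=motifs,
            plant_rate=cfg.plant_rate,
            conserve_rate=cfg.conserve_rate,
            point_divergence=cfg.point_divergence,
            indel_rate=cfg.indel_rate,
            seed=cfg.seed + (2 if region == "5UR" else 3),
        )
        pairs, seq_truth = generate_ortholog_pairs(plant_cfg)
        seq_truth.to_csv(out / f"truth_{region}.tsv", sep="\t", index=False)
        presence = build_presence_map(pairs, motifs)
        presence_maps[tag] = presence
        pmap = presence_to_gmt(presence, tag)
        write_gmt(pmap, out / f"classes_{tag.lower()}.gmt")
        for eff in ("g", "t", "gt"):
            res = enrichment_table(
                pmap, table, eff, scale.sigma_bar,
                min_class_size=min(cfg.min_class_size, 2),
                alpha=cfg.enrichment_alpha, fdr=cfg.fdr,
            )
            res.to_csv(out / f"enrichment_{tag.lower()}_{eff}.tsv", sep="\t",
                       index=False)
            enrich[(tag, eff)] = res

    # miRNA cognate classes from the conserved 3'UTR octamers
    octamer_motifs = [m for m in DEFAULT_3UTR_MOTIFS
                      if len(m.forms[0]) == 8]
    mirnas, mirna_truth = generate_mirnas(
        octamer_motifs, cfg.n_decoy_mirnas, seed=cfg.seed + 4
    )
    mirna_truth.to_csv(out / "truth_mirna.tsv", sep="\t", index=False)
    octamer_presence = {
        m.motif_id: presence_maps["UTR3_motif"][m.motif_id]
        for m in octamer_motifs
    }
    associations = {m.forms[0]: [] for m in octamer_motifs}
    id_by_octamer = {m.forms[0]: m.motif_id for m in octamer_motifs}
    assoc = associate_octamers(list(associations), mirnas)
    octamer_presence_by_seq = {
        oct_seq: octamer_presence[id_by_octamer[oct_seq]]
        for oct_seq in associations
    }
    mirna_map = build_mirna_classes(octamer_presence_by_seq, assoc)
    write_gmt(mirna_map, out / "classes_mirna.gmt")
    for eff in ("g", "t", "gt"):
        res = enrichment_table(
            mirna_map, table, eff, scale.sigma_bar,
            min_class_size=min(cfg.min_class_size, 2),
            alpha=cfg.enrichment_alpha, fdr=cfg.fdr,
        )
        res.to_csv(out / f"enrichment_mirna_{eff}.tsv", sep="\t", index=False)
        enrich[("miRNA", eff)] = res

    manifest = {
        "cisfactor_version": __version__,
        "config": asdict(cfg),
        "n_genes_analyzed": int(len(table)),
        "sigma_bar": scale.sigma_bar,
        "chi2_ks_stat": scale.chi2_ks_stat,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {
        "matrix": matrix,
        "truth": truth,
        "effects": table,
        "scale": scale,
        "curves": curves,
        "enrichment": enrich,
        "manifest": manifest,
    }


def _plot_rank_curve(rc, effect: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(rc.relative_rank, rc.nc_sorted, lw=2, label="observed NC")
    ax.plot(rc.relative_rank, rc.null_curve, lw=0.8, label="null expectation")
    ax.set_xlabel("relative rank")
    ax.set_ylabel("NC")
    ax.set_title(f"effect: {effect}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
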