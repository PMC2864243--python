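"""Readers/writers for the pipeline's plain-text interchange formats.

Expression: TSV, genes as rows, header = array ids, plus a sidecar TSV of
array metadata (array_id, genotype, treatment, replicate).  Gene classes:
GMT.  Motifs: TSV (motif_id, region, comma-separated IUPAC forms).
Sequences: FASTA / aligned FASTA (two records per gene, '-' gaps) via
biopython.  Regions: BED-like TSV, 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .conservation import AlignedOrthologPair, MotifDefinition
from .enrichment import GeneClassMap
from .mirna import MatureMirna
from .preprocess import ExpressionMatrix


def write_expression(m: ExpressionMatrix, values_path, meta_path) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="gene")
    m.design.to_csv(meta_path, sep="\t", index_label="array_id")


def read_expression(values_path, meta_path, scale_state: str = "raw") -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    design = pd.read_csv(
        meta_path, sep="\t", index_col="array_id", dtype={"treatment": str}
    )
    return ExpressionMatrix(values, design, scale_state=scale_state)


def write_gmt(class_map: GeneClassMap, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(class_map.classes):
            members = sorted(class_map.classes[name])
            fh.write("\t".join([name, class_map.source] + members) + "\n")


def read_gmt(path, source: str = "GO_biological_process") -> GeneClassMap:
    classes: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            classes[fields[0]] = set(fields[2:])
    return GeneClassMap(source, classes)


def write_motifs(motifs: Sequence[MotifDefinition], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tregion\tforms\n")
        for m in motifs:
            fh.write(f"{m.motif_id}\t{m.region}\t{','.join(m.forms)}\n")


def read_motifs(path, max_mismatches: int = 0) -> List[MotifDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifDefinition(
            row["motif_id"],
            tuple(row["forms"].split(",")),
            row["region"],
            max_mismatches=max_mismatches,
        )
        for _, row in df.iterrows()
    ]


def write_mirnas(mirnas: Sequence[MatureMirna], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(m.sequence), id=m.mirna_id, description="")
        for m in mirnas
    ]
    seqio_write(records, str(path), "fasta")


def read_mirnas(path) -> List[MatureMirna]:
    from Bio import SeqIO

    return [
        MatureMirna(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_aligned_pairs(
    pairs: Sequence[AlignedOrthologPair], path,
    species: Tuple[str, str] = ("a", "b"),
) -> None:
    """Aligned FASTA with two records per gene, ids ``gene|species``."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for p in pairs:
        records.append(
            SeqRecord(Seq(p.seq_a), id=f"{p.gene_id}|{species[0]}",
                      description=p.region)
        )
        records.append(
            SeqRecord(Seq(p.seq_b), id=f"{p.gene_id}|{species[1]}",
                      description=p.region)
        )
    seqio_write(records, str(path), "fasta")


def read_aligned_pairs(path, region: str) -> List[AlignedOrthologPair]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError("aligned FASTA must contain two records per gene")
    pairs = []
    for first, second in zip(records[0::2], records[1::2]):
        gene_a = first.id.split("|")[0]
        gene_b = second.id.split("|")[0]
        if gene_a != gene_b:
            raise ValueError(
                f"consecutive records {first.id!r}, {second.id!r} are not "
                "the same gene"
            )
        pairs.append(
            AlignedOrthologPair(gene_a, region, str(first.seq), str(second.seq))
        )
    return pairs


def write_unaligned_pairs(
    pairs: Sequence[AlignedOrthologPair], path_a, path_b,
) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    for which, path in (("a", path_a), ("b", path_b)):
        records = [
            SeqRecord(Seq(p.ungapped(which)), id=p.gene_id, description=p.region)
            for p in pairs
        ]
        seqio_write(records, str(path), "fasta")


def presence_to_gmt(
    presence: Mapping[str, Mapping[str, bool]], source: str
) -> GeneClassMap:
    """Convert {motif: {gene: bool}} presence maps into a GeneClassMap."""
    classes = {
        motif: {g for g, flag in genes.items() if flag}
        for motif, genes in presence.items()
    }
    return GeneClassMap(source, classes)
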