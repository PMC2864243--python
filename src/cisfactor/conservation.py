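"""Phylogenetic footprinting of short regulatory motifs in ortholog pairs.

Regions scanned are the untranscribed region up to 8 kb upstream of the
transcription start site (5'UR) and the 3'UTR.  Orthologous regions from
two species are aligned (or ground-truth alignments ingested), each
ungapped sequence is scanned for degenerate IUPAC motifs — in any of a
motif's forms, including the reverse complement for 5'UR motifs — and an
occurrence is called *conserved* when both species carry one whose start
maps to the same alignment column.  A gene is positive for a motif if it
has at least one conserved occurrence; those presence maps feed the
class-enrichment statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

REGIONS = ("5UR", "3UTR")

# 4-bit encoding over {A, C, G, T}; an IUPAC code's mask has a bit per base
# it allows.  In a *sequence*, N is encoded as 0 so it can never support a
# match; in a motif form, N keeps its full mask (matches any base).
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}


class MotifDefinitionError(ValueError):
    pass


class RegionError(ValueError):
    pass


class AlignmentSizeError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (gap-preserving)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise MotifDefinitionError(f"invalid IUPAC character {exc.args[0]!r}")


@dataclass(frozen=True)
class MotifDefinition:
    """A motif as a set of IUPAC "forms", tagged with its region.

    Reverse-complement scanning defaults to on for 5'UR motifs (promoter
    elements act on either strand) and off for 3'UTR motifs (mRNA
    sequence elements are strand-specific).
    """

    motif_id: str
    forms: Tuple[str, ...]
    region: str
    allow_reverse_complement: Optional[bool] = None
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise MotifDefinitionError(f"region must be one of {REGIONS}")
        if not self.forms:
            raise MotifDefinitionError("motif needs at least one form")
        for form in self.forms:
            if not form or any(c not in IUPAC_MASKS for c in form.upper()):
                raise MotifDefinitionError(f"invalid IUPAC form {form!r}")
        if self.max_mismatches < 0:
            raise MotifDefinitionError("max_mismatches must be >= 0")
        if self.allow_reverse_complement is None:
            object.__setattr__(
                self, "allow_reverse_complement", self.region == "5UR"
            )

    @property
    def max_form_length(self) -> int:
        return max(len(f) for f in self.forms)


@dataclass
class AlignedOrthologPair:
    """A gapped two-species alignment of one gene's 5'UR or 3'UTR."""

    gene_id: str
    region: str
    seq_a: str
    seq_b: str
    tss_offset_a: Optional[int] = None
    tss_offset_b: Optional[int] = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise RegionError(f"region must be one of {REGIONS}")
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("gapped sequences must have equal length")
        sa, sb = self.seq_a.upper(), self.seq_b.upper()
        if any(a == "-" and b == "-" for a, b in zip(sa, sb)):
            raise ValueError("alignment has a column gapped in both rows")
        if not sa.replace("-", "") or not sb.replace("-", ""):
            raise ValueError("ungapped sequences must be nonempty")
        self.seq_a, self.seq_b = sa, sb

    def ungapped(self, which: str) -> str:
        seq = self.seq_a if which == "a" else self.seq_b
        return seq.replace("-", "")


@dataclass(frozen=True)
class ConservedHit:
    gene_id: str
    motif_id: str
    alignment_column: int
    form_a: str
    form_b: str
    strand_a: str
    strand_b: str


def _seq_bits(seq: str) -> np.ndarray:
    bits = np.zeros(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq.upper()):
        if c == "N":
            continue  # N in the subject sequence never supports a match
        mask = IUPAC_MASKS.get(c)
        if mask is None:
            raise ValueError(f"invalid sequence character {c!r}")
        bits[i] = mask
    return bits


def _form_bits(form: str) -> np.ndarray:
    return np.array([IUPAC_MASKS[c] for c in form.upper()], dtype=np.uint8)


def scan_sequence(seq: str, motif: MotifDefinition) -> List[Tuple[int, str, str]]:
    """All matches of any form of ``motif`` in an ungapped sequence.

    Returns (start, form, strand) triples, 0-based starts, sorted.  A minus-
    strand hit at start i means the reverse complement of the form occurs at
    i on the given strand, i.e. the physical site is the same stretch of
    DNA.  Up to ``max_mismatches`` mismatching positions are allowed.
    """
    bits = _seq_bits(seq)
    hits: List[Tuple[int, str, str]] = []
    patterns = [(form, "+", _form_bits(form)) for form in motif.forms]
    if motif.allow_reverse_complement:
        patterns += [
            (form, "-", _form_bits(reverse_complement(form)))
            for form in motif.forms
        ]
    for form, strand, pat in patterns:
        L = len(pat)
        if L > len(bits):
            continue
        windows = sliding_window_view(bits, L)
        mismatches = ((windows & pat) == 0).sum(axis=1)
        for start in np.nonzero(mismatches <= motif.max_mismatches)[0]:
            hits.append((int(start), form, strand))
    return sorted(set(hits))


def map_to_alignment_columns(
    gapped_seq: str, positions: Sequence[int]
) -> List[int]:
    """Column index in the gapped sequence of each ungapped position."""
    cols = [i for i, c in enumerate(gapped_seq) if c != "-"]
    out = []
    for p in positions:
        if p < 0 or p >= len(cols):
            raise IndexError(f"ungapped position {p} out of range")
        out.append(cols[p])
    return out


def strip_gaps_position(gapped_seq: str, column: int) -> int:
    """Inverse of `map_to_alignment_columns` for a non-gap column."""
    if gapped_seq[column] == "-":
        raise IndexError(f"column {column} is a gap")
    return sum(1 for c in gapped_seq[:column] if c != "-")


def call_conserved(
    pair: AlignedOrthologPair,
    motifs: Iterable[MotifDefinition],
    require_gapless: bool = False,
) -> Tuple[List[ConservedHit], Dict[str, bool]]:
    """Call motif occurrences conserved by the same-alignment-column rule.

    A motif is conserved in this gene when both species have an occurrence
    (any form, any permitted strand — the two species need not match the
    same form) whose start maps to the same alignment column.  With
    ``require_gapless`` the aligned span of the occurrence must additionally
    be free of gaps in both rows (strict mode); by default motif-internal
    gaps are tolerated since only start positions are compared.

    Returns the hits plus a presence map {motif_id: bool} marking genes
    with at least one conserved occurrence.
    """
    hits: List[ConservedHit] = []
    presence: Dict[str, bool] = {}
    ung_a = pair.ungapped("a")
    ung_b = pair.ungapped("b")
    for motif in motifs:
        if motif.region != pair.region:
            raise RegionError(
                f"motif {motif.motif_id!r} is a {motif.region} motif but the "
                f"pair is {pair.region}"
            )
        a_hits = scan_sequence(ung_a, motif)
        b_hits = scan_sequence(ung_b, motif)
        a_cols: Dict[int, Tuple[str, str]] = {}
        for start, form, strand in a_hits:
            col = map_to_alignment_columns(pair.seq_a, [start])[0]
            a_cols.setdefault(col, (form, strand))
        found = False
        for start, form_b, strand_b in b_hits:
            col = map_to_alignment_columns(pair.seq_b, [start])[0]
            if col not in a_cols:
                continue
            if require_gapless:
                span = slice(col, col + len(form_b))
                if "-" in pair.seq_a[span] or "-" in pair.seq_b[span]:
                    continue
            form_a, strand_a = a_cols[col]
            hits.append(
                ConservedHit(
                    pair.gene_id, motif.motif_id, col,
                    form_a, form_b, strand_a, strand_b,
                )
            )
            found = True
        presence[motif.motif_id] = found
    return hits, presence


def build_presence_map(
    pairs: Iterable[AlignedOrthologPair],
    motifs: Sequence[MotifDefinition],
    require_gapless: bool = False,
) -> Dict[str, Dict[str, bool]]:
    """Per-motif {gene: bool} presence maps over a collection of pairs."""
    presence: Dict[str, Dict[str, bool]] = {m.motif_id: {} for m in motifs}
    for pair in pairs:
        _, p = call_conserved(pair, motifs, require_gapless=require_gapless)
        for motif_id, flag in p.items():
            presence[motif_id][pair.gene_id] = flag
    return presence


def extract_5ur(
    annotations,
    genome: Mapping[str, str],
    max_len: int = 8000,
):
    """Extract up to ``max_len`` bp upstream of each gene's TSS.

    ``annotations`` is a DataFrame-like with columns gene, chrom, start,
    end, strand (0-based half-open).  The region is clipped at the
    chromosome boundary and truncated before the transcribed region of any
    adjacent gene on the same chromosome.  Sequences are returned 5'->3' in
    the gene's orientation, TSS-proximal end last; ``tss_distance`` is the
    achieved length.
    """
    import pandas as pd

    ann = pd.DataFrame(annotations)
    required = {"gene", "chrom", "start", "end", "strand"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    records = []
    for idx, row in ann.iterrows():
        chrom_seq = genome.get(row["chrom"])
        if chrom_seq is None:
            raise ValueError(f"unknown chromosome {row['chrom']!r}")
        clen = len(chrom_seq)
        tss = int(row["start"]) if row["strand"] == "+" else int(row["end"])
        if tss < 0 or tss > clen:
            raise ValueError(f"TSS of gene {row['gene']!r} outside sequence")
        others = ann.drop(index=idx)
        neighbors = others[others["chrom"] == row["chrom"]]
        if row["strand"] == "+":
            lo = max(0, tss - max_len)
            blocking = neighbors[
                (neighbors["end"] <= tss) & (neighbors["end"] > lo)
            ]
            if len(blocking):
                lo = int(blocking["end"].max())
            seq = chrom_seq[lo:tss]
            start, end = lo, tss
        else:
            hi = min(clen, tss + max_len)
            blocking = neighbors[
                (neighbors["start"] >= tss) & (neighbors["start"] < hi)
            ]
            if len(blocking):
                hi = int(blocking["start"].min())
            seq = reverse_complement(chrom_seq[tss:hi])
            start, end = tss, hi
        records.append(
            {
                "gene": row["gene"],
                "chrom": row["chrom"],
                "region_start": start,
                "region_end": end,
                "strand": row["strand"],
                "sequence": seq,
                "tss_distance": len(seq),
            }
        )
    return pd.DataFrame(records)


def truncate_to_common_tss_distance(
    seq_a: str,
    seq_b: str,
    region: str = "5UR",
) -> Tuple[str, str]:
    """Trim the distal end of the longer 5'UR so both span the same
    TSS-relative interval.

    Sequences must be oriented TSS-proximal end last (as `extract_5ur`
    emits them); the removed bases are the most upstream ones.  3'UTRs are
    deliberately left at different lengths, so calling this on them is a
    usage error.
    """
    if region != "5UR":
        raise RegionError("TSS-distance truncation applies to 5'UR regions only")
    n = min(len(seq_a), len(seq_b))
    return seq_a[-n:], seq_b[-n:]


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    gene_id: str = "",
    region: str = "5UR",
    max_len: int = 20000,
) -> AlignedOrthologPair:
    """Optimal affine-gap global alignment of one ortholog pair.

    A desk-scale pairwise aligner for the short regulatory regions handled
    here; pre-aligned input (aligned FASTA) bypasses it.  Tie-breaking is
    deterministic (first optimal alignment of the dynamic program).
    """
    from Bio import Align

    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    if len(seq_a) > max_len or len(seq_b) > max_len:
        raise AlignmentSizeError(
            f"sequence exceeds {max_len} bp; align externally and supply the "
            "aligned FASTA instead"
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    return AlignedOrthologPair(gene_id or "pair", region, gapped_a, gapped_b)
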