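"""miRNA re-annotation of conserved 3'UTR octamer motifs.

A conserved 3'UTR octamer is associated with a mature miRNA when the
miRNA's distal octamer matches it perfectly.  "Distal" is interpreted as
the 5'-terminal 8-mer of the mature miRNA, compared as a reverse
complement to the genomic octamer — the orientation under which a miRNA
seed pairs with its target site.  The alternative reading (3'-terminal
8-mer, direct match) is selectable via ``end="three_prime"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set

from .conservation import reverse_complement
from .enrichment import GeneClassMap

_DNA = set("ACGT")


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA sequence, 5'->3', RNA alphabet (T normalized to U)."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if len(seq) < 8:
            raise ValueError(f"miRNA {self.mirna_id!r} shorter than 8 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(f"miRNA {self.mirna_id!r} has a non-RNA character")
        object.__setattr__(self, "sequence", seq)

    def distal_octamer_dna(self, end: str = "five_prime") -> str:
        """The terminal 8-mer as DNA, oriented for comparison to a motif.

        five_prime: reverse complement of the 5'-terminal 8-mer (target-site
        orientation).  three_prime: the 3'-terminal 8-mer read directly.
        """
        if end == "five_prime":
            return reverse_complement(self.sequence[:8].replace("U", "T"))
        if end == "three_prime":
            return self.sequence[-8:].replace("U", "T")
        raise ValueError("end must be 'five_prime' or 'three_prime'")


def mirna_cognate(
    octamer: str,
    mirnas: Iterable[MatureMirna],
    end: str = "five_prime",
) -> List[str]:
    """ids of miRNAs whose distal octamer perfectly matches ``octamer``."""
    octamer = octamer.upper().replace("U", "T")
    if len(octamer) != 8 or set(octamer) - _DNA:
        raise ValueError(
            f"octamer must be 8 unambiguous DNA bases, got {octamer!r}"
        )
    return [m.mirna_id for m in mirnas if m.distal_octamer_dna(end) == octamer]


def associate_octamers(
    octamers: Iterable[str],
    mirnas: Iterable[MatureMirna],
    end: str = "five_prime",
) -> Dict[str, List[str]]:
    """Map each octamer to its associated miRNA ids (possibly empty)."""
    mirnas = list(mirnas)
    return {o: mirna_cognate(o, mirnas, end=end) for o in octamers}


def build_mirna_classes(
    presence: Mapping[str, Mapping[str, bool]],
    associations: Mapping[str, List[str]],
) -> GeneClassMap:
    """Gene classes of miRNA-cognate octamers from conserved-presence maps.

    ``presence`` maps octamer motif id -> {gene: bool} (from the 3'UTR
    conservation caller); ``associations`` maps octamer -> miRNA ids.  Only
    octamers with at least one associated miRNA become classes; class
    identity stays the octamer (distinct octamers are kept separate even
    when they share a miRNA), with the miRNA ids carried as metadata.
    """
    classes: Dict[str, Set[str]] = {}
    meta: Dict[str, object] = {}
    for octamer, mirna_ids in associations.items():
        if not mirna_ids or octamer not in presence:
            continue
        classes[octamer] = {g for g, flag in presence[octamer].items() if flag}
        meta[octamer] = list(mirna_ids)
    return GeneClassMap("miRNA_cognate", classes, {"associations": meta})
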