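import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cisfactor.conservation import (
    AlignedOrthologPair,
    MotifDefinition,
    MotifDefinitionError,
    RegionError,
    call_conserved,
    extract_5ur,
    global_align,
    map_to_alignment_columns,
    reverse_complement,
    scan_sequence,
    strip_gaps_position,
    truncate_to_common_tss_distance,
)
from cisfactor.synthetic import MotifPlantConfig, generate_ortholog_pairs

DNA = st.text(alphabet="ACGT", min_size=1, max_size=200)


def test_scan_finds_plain_matches():
    motif = MotifDefinition("m", ("TTTC",), "3UTR")
    hits = scan_sequence("AATTTCACTTTC", motif)
    assert [(h[0], h[2]) for h in hits] == [(2, "+"), (8, "+")]


def test_reverse_complement_scan_reports_same_physical_sites():
    motif = MotifDefinition("m", ("GAAA",), "5UR", allow_reverse_complement=True)
    hits = scan_sequence("AATTTCACTTTC", motif)
    minus = [(h[0], h[2]) for h in hits if h[2] == "-"]
    assert minus == [(2, "-"), (8, "-")]


def test_rc_scanning_defaults_by_region():
    assert MotifDefinition("a", ("ACGT",), "5UR").allow_reverse_complement
    assert not MotifDefinition("a", ("ACGT",), "3UTR").allow_reverse_complement


def test_n_in_sequence_never_matches():
    motif = MotifDefinition("m", ("TTNC",), "3UTR")
    # motif N is permissive, sequence N is not
    assert [h[0] for h in scan_sequence("ATTGCA", motif)] == [1]
    assert scan_sequence("ATTNCA", motif) == []


def test_mismatch_scan_equals_bruteforce_hamming(rng):
    seq = "".join(rng.choice(list("ACGT"), 2000))
    form = "".join(rng.choice(list("ACGT"), 8))
    motif = MotifDefinition("m", (form,), "3UTR", max_mismatches=1)
    hits = {h[0] for h in scan_sequence(seq, motif)}
    brute = {
        i
        for i in range(len(seq) - 7)
        if sum(a != b for a, b in zip(seq[i : i + 8], form)) <= 1
    }
    assert hits == brute


def test_invalid_iupac_form_rejected():
    with pytest.raises(MotifDefinitionError):
        MotifDefinition("m", ("ACGX",), "3UTR")


def test_alignment_column_mapping():
    assert map_to_alignment_columns("AC-GT", [0, 1, 2, 3]) == [0, 1, 3, 4]
    assert map_to_alignment_columns("ACGT", [0, 3]) == [0, 3]
    with pytest.raises(IndexError):
        map_to_alignment_columns("AC-GT", [4])


@given(seq=DNA, data=st.data())
@settings(max_examples=50, deadline=None)
def test_column_mapping_round_trips_through_gaps(seq, data):
    gaps = data.draw(st.sets(st.integers(0, len(seq)), max_size=10))
    gapped = ""
    for i, c in enumerate(seq):
        if i in gaps:
            gapped += "-"
        gapped += c
    pos = data.draw(st.integers(0, len(seq) - 1))
    col = map_to_alignment_columns(gapped, [pos])[0]
    assert strip_gaps_position(gapped, col) == pos


def test_truncation_keeps_tss_proximal_end():
    long = "A" * 3000 + "C" * 5000  # proximal 5 kb are C
    short = "G" * 5000
    a, b = truncate_to_common_tss_distance(long, short)
    assert len(a) == len(b) == 5000
    assert set(a) == {"C"}
    # symmetric in argument order
    b2, a2 = truncate_to_common_tss_distance(short, long)
    assert (a2, b2) == (a, b)
    same = truncate_to_common_tss_distance("ACGT", "TGCA")
    assert same == ("ACGT", "TGCA")


def test_truncation_refuses_3utr():
    with pytest.raises(RegionError):
        truncate_to_common_tss_distance("ACGT", "ACG", region="3UTR")


def test_global_align_identical_sequences():
    pair = global_align("ACGTACGT", "ACGTACGT")
    assert pair.seq_a == pair.seq_b == "ACGTACGT"


def test_global_align_single_gap():
    pair = global_align("ACGT", "AGT", match=1, mismatch=-1,
                        gap_open=-2, gap_extend=-1)
    assert pair.seq_a == "ACGT"
    assert pair.seq_b.count("-") == 1
    assert len(pair.seq_b) == 4


def test_global_align_degenerate_input_does_not_crash():
    pair = global_align("AAAA", "TTTT")
    assert len(pair.seq_a) == len(pair.seq_b)


def test_conserved_call_at_homologous_position():
    motif = MotifDefinition("m", ("TTTC",), "3UTR")
    pair = AlignedOrthologPair("g", "3UTR", "AATTTCAA", "AATTTCAA")
    hits, presence = call_conserved(pair, [motif])
    assert len(hits) == 1 and hits[0].alignment_column == 2
    assert presence == {"m": True}


def test_occurrence_in_one_species_only_is_not_conserved():
    motif = MotifDefinition("m", ("TTTC",), "3UTR")
    pair = AlignedOrthologPair("g", "3UTR", "AATTTCAA", "AAGGGGAA")
    hits, presence = call_conserved(pair, [motif])
    assert hits == [] and presence == {"m": False}


def test_species_may_match_different_forms():
    motif = MotifDefinition("m", ("TTTC", "TTCC"), "3UTR")
    pair = AlignedOrthologPair("g", "3UTR", "AATTTCAA", "AATTCCAA")
    hits, _ = call_conserved(pair, [motif])
    assert len(hits) == 1
    assert {hits[0].form_a, hits[0].form_b} == {"TTTC", "TTCC"}


def test_region_mismatch_is_a_usage_error():
    motif = MotifDefinition("m", ("TTTC",), "5UR")
    pair = AlignedOrthologPair("g", "3UTR", "AATTTCAA", "AATTTCAA")
    with pytest.raises(RegionError):
        call_conserved(pair, [motif])


def _planted_calls(pairs, motifs):
    calls = set()
    for p in pairs:
        hits, _ = call_conserved(p, motifs)
        calls |= {(h.gene_id, h.motif_id, h.alignment_column) for h in hits}
    return calls


def test_caller_reproduces_generator_truth_exactly():
    motifs = [
        MotifDefinition(f"m{i}", ("".join(np.random.default_rng(i).choice(
            list("ACGT"), 8)),), "3UTR")
        for i in range(5)
    ]
    cfg = MotifPlantConfig(
        n_genes=60, region="3UTR", region_length=400, motifs=motifs,
        plant_rate=0.5, conserve_rate=0.7, seed=42,
    )
    pairs, truth = generate_ortholog_pairs(cfg)
    planted = set(
        map(tuple, truth[truth["conserved"]][
            ["gene", "motif", "alignment_column"]].to_numpy())
    )
    assert _planted_calls(pairs, motifs) == planted


def test_conservation_calls_symmetric_in_species_order():
    motifs = [MotifDefinition("m", ("GTGCCTTA",), "3UTR")]
    cfg = MotifPlantConfig(
        n_genes=30, region="3UTR", region_length=300, motifs=motifs,
        plant_rate=0.8, conserve_rate=0.5, point_divergence=0.05, seed=9,
    )
    pairs, _ = generate_ortholog_pairs(cfg)
    swapped = [
        AlignedOrthologPair(p.gene_id, p.region, p.seq_b, p.seq_a)
        for p in pairs
    ]
    assert _planted_calls(pairs, motifs) == _planted_calls(swapped, motifs)


def test_extract_5ur_lengths_and_clipping():
    genome = {"chr1": "".join(
        np.random.default_rng(0).choice(list("ACGT"), 20000))}
    ann = pd.DataFrame(
        [
            {"gene": "free", "chrom": "chr1", "start": 10000, "end": 11000,
             "strand": "+"},
            {"gene": "upstream_neighbor", "chrom": "chr1", "start": 15000,
             "end": 16000, "strand": "+"},
            {"gene": "crowded", "chrom": "chr1", "start": 19000, "end": 19500,
             "strand": "+"},
            {"gene": "near_start", "chrom": "chr1", "start": 500, "end": 900,
             "strand": "+"},
        ]
    )
    regions = extract_5ur(ann, genome, max_len=8000).set_index("gene")
    assert regions.loc["free", "tss_distance"] == 8000
    # neighbor "upstream_neighbor" ends at 16000, 3 kb before crowded's TSS
    assert regions.loc["crowded", "tss_distance"] == 3000
    assert regions.loc["near_start", "tss_distance"] == 500


def test_extract_5ur_minus_strand_is_reverse_complemented():
    genome = {"chr1": "A" * 100 + "CCCC" + "A" * 100}
    ann = pd.DataFrame(
        [{"gene": "neg", "chrom": "chr1", "start": 50, "end": 100,
          "strand": "-"}]
    )
    out = extract_5ur(ann, genome, max_len=10).set_index("gene")
    assert out.loc["neg", "sequence"] == reverse_complement(
        genome["chr1"][100:110]
    )


@given(DNA)
@settings(max_examples=100, deadline=None)
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
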