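"""Sequence model: GC computation, QC flags, intron extraction, round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthointron import (
    GeneModel,
    dataset_summary,
    extract_internal_introns,
    gc_content,
    has_base_ambiguity,
    has_internal_stop,
    load_species_dataset,
    read_species_dataset,
    write_species_dataset,
)
from orthointron.errors import FormatError, UndefinedValueError
from orthointron.seqmodel import IntronicSequence, SpeciesDataset, reverse_complement

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "seq,expected",
    [("GCAT", 50.0), ("GGCC", 100.0), ("GCATNN", 50.0), ("aaGG", 50.0), ("AT", 0.0)],
)
def test_gc_content_definition(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_undefined_for_all_n():
    with pytest.raises(UndefinedValueError):
        gc_content("NNNN")


@settings(deadline=None, max_examples=100, derandomize=True)
@given(dna)
def test_gc_invariant_under_revcomp_and_case(seq):
    g = gc_content(seq)
    assert gc_content(reverse_complement(seq)) == pytest.approx(g)
    assert gc_content(seq.lower()) == pytest.approx(g)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(dna, dna)
def test_concatenation_identities(a, b):
    """bpi is additive and GC of a concatenation is the length-weighted mean."""
    cat = a + b
    assert len(cat) == len(a) + len(b)
    weighted = (len(a) * gc_content(a) + len(b) * gc_content(b)) / len(cat)
    assert gc_content(cat) == pytest.approx(weighted)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", False), ("ACRT", True), ("ACGN", True), ("acgt", False)],
)
def test_base_ambiguity(seq, expected):
    assert has_base_ambiguity(seq) is expected


def test_ambiguity_clean_long_sequence(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
    assert not has_base_ambiguity(seq)


@pytest.mark.parametrize(
    "cds,expected",
    [("ATGAAATAG", False), ("ATGTAAAAATAG", True), ("ATGAAA", False)],
)
def test_internal_stop_detection(cds, expected):
    assert has_internal_stop(cds) is expected


def test_malformed_cds_flagged():
    with pytest.raises(FormatError):
        has_internal_stop("ATGAA")


# ---------------------------------------------------------------------------
# intron extraction
# ---------------------------------------------------------------------------

def _toy_gene(exons, cds, strand="+", contig=None):
    return GeneModel(
        gene_id="g1",
        species_id="sp",
        strand=strand,
        seqid="chr1",
        exon_intervals=exons,
        cds_intervals=cds,
        sequence_source=contig,
    )


def test_single_exon_gene_has_empty_intronic_sequence():
    contig = "A" * 100
    gene = _toy_gene([(10, 40)], [(10, 40)], contig=contig)
    iseq = extract_internal_introns(gene)
    assert iseq.sequence == "" and iseq.bpi == 0 and iseq.n_introns == 0


def test_cds_internal_introns_concatenated_in_order():
    # exons 0-10, 20-30, 40-50, 60-70; all CDS-bearing -> 3 internal introns
    contig = "A" * 10 + "C" * 10 + "A" * 10 + "G" * 10 + "A" * 10 + "T" * 10 + "A" * 10
    gene = _toy_gene(
        [(0, 10), (20, 30), (40, 50), (60, 70)],
        [(0, 10), (20, 30), (40, 50), (60, 70)],
        contig=contig,
    )
    iseq = extract_internal_introns(gene)
    assert iseq.sequence == "C" * 10 + "G" * 10 + "T" * 10
    assert iseq.n_introns == 3


def test_utr_only_intron_is_disregarded():
    # first exon is pure 5' UTR: the intron before the CDS span is flanking
    contig = "ACGT" * 30
    gene = _toy_gene(
        [(0, 10), (20, 30), (40, 50)],
        [(22, 30), (40, 50)],  # CDS starts inside the second exon
        contig=contig,
    )
    iseq = extract_internal_introns(gene)
    assert iseq.sequence == contig[30:40]
    assert iseq.n_introns == 1


def test_utr_only_gene_yields_empty():
    contig = "ACGT" * 30
    gene = _toy_gene([(0, 10), (20, 30)], [(22, 30)], contig=contig)
    # single intron lies 5' of the CDS-bearing exon span start? span=[exon1] -> no internal
    assert extract_internal_introns(gene).sequence == ""


def test_minus_strand_intron_is_reverse_complement_of_gap():
    contig = "AAAAAAAAAACCCCCCCCCCGGGGGGGGGG"  # exons at [0,10) and [20,30)
    gene = _toy_gene(
        [(20, 30), (0, 10)],  # transcription order on '-' is descending
        [(20, 30), (0, 10)],
        strand="-",
        contig=contig,
    )
    iseq = extract_internal_introns(gene)
    assert iseq.sequence == reverse_complement(contig[10:20]) == "GGGGGGGGGG"


def test_bpi_additivity_three_introns(small_pair):
    _, ds_m, _, _ = small_pair
    for gid, gm in list(ds_m.genes.items())[:10]:
        iseq = extract_internal_introns(gm)
        assert iseq.bpi == len(iseq.sequence)
        assert iseq.sequence == ds_m.intronic_seqs[gid].sequence


# ---------------------------------------------------------------------------
# loader and round trips
# ---------------------------------------------------------------------------

def test_loader_round_trip_synthetic_bundle(tmp_path):
    from orthointron import SynthConfig, generate_species_pair
    from orthointron.synthetic import write_genome_files

    cfg = SynthConfig(seed=7, n_genes=10)
    ds, _, _ = generate_species_pair(cfg)
    fasta, gff = write_genome_files(ds, tmp_path)
    loaded = load_species_dataset(fasta, gff, species_id=ds.species_id)
    assert set(loaded.genes) == set(ds.genes)
    for gid in ds.genes:
        assert loaded.cds_seqs[gid] == ds.cds_seqs[gid]
        assert loaded.protein_seqs[gid] == ds.protein_seqs[gid]
        assert loaded.intronic_seqs[gid].sequence == ds.intronic_seqs[gid].sequence


def test_dataset_write_read_round_trip(tmp_path, small_pair):
    _, ds_m, _, _ = small_pair
    write_species_dataset(ds_m, tmp_path / "ds")
    back = read_species_dataset(tmp_path / "ds")
    assert back.species_id == ds_m.species_id
    assert back.cds_seqs == ds_m.cds_seqs
    assert back.protein_seqs == ds_m.protein_seqs
    for gid, iseq in ds_m.intronic_seqs.items():
        assert back.intronic_seqs[gid].sequence == iseq.sequence
        assert back.intronic_seqs[gid].n_introns == iseq.n_introns
    for gid, gm in ds_m.genes.items():
        assert back.genes[gid].exon_intervals == gm.exon_intervals
        assert back.genes[gid].strand == gm.strand


def test_loader_rejects_malformed_gff(tmp_path):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">chr1\nACGTACGT\n")
    gff = tmp_path / "bad.gff3"
    gff.write_text("this is not\tgff3\n")
    with pytest.raises(FormatError):
        load_species_dataset(fasta, gff)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _ds_from_introns(seqs):
    genes, intr = {}, {}
    for i, s in enumerate(seqs):
        gid = f"g{i}"
        genes[gid] = GeneModel(gid, "sp", "+", "chr1", [(0, 10), (20, 30)], [(0, 10), (20, 30)])
        intr[gid] = IntronicSequence(gid, "sp", s, 1)
    return SpeciesDataset("sp", genes, {}, {}, intr, gcg=50.0)


def test_summary_single_intron():
    s = dataset_summary(_ds_from_introns(["GCGC"]))
    assert s["mean_gci"] == 100.0 and s["mean_bpi"] == 4.0


def test_summary_mean_gci_of_two_equal_length_introns():
    # GC 40% and 60%, equal lengths -> mean GCi 50
    s = dataset_summary(_ds_from_introns(["GCGC" + "AT" * 3, "GCGCGC" + "AT" * 2]))
    assert s["mean_gci"] == pytest.approx(50.0)


def test_summary_recovers_generator_mean(small_pair):
    _, ds_m, _, truth = small_pair
    s = dataset_summary(ds_m)
    assert s["mean_gci"] == pytest.approx(truth.species_means[ds_m.species_id]["mean_gci"])
    assert s["mean_bpi"] == pytest.approx(truth.species_means[ds_m.species_id]["mean_bpi"])
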