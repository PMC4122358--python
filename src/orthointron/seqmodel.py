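"""Gene models, sequence I/O and base-composition primitives.

A :class:`SpeciesDataset` bundles, for one genome, the selected gene models
(one transcript per protein-coding gene) together with their coding,
protein and *internal-intron* sequences.  The quantity of interest
downstream is the concatenation of a gene's internal introns — introns
lying between CDS-containing exons — whose length (``bpi``) and GC content
(``gci``, percent) are compared between orthologous genes of two species.

Coordinates are 0-based half-open internally; GFF3 input is 1-based
inclusive and converted on load.  Exon and CDS intervals are stored in
transcription order (descending genomic coordinates on the minus strand).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FormatError, UndefinedValueError

UNAMBIGUOUS = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case; non-ACGTN letters go through Biopython."""
    try:
        return seq.translate(_COMPLEMENT)[::-1]
    except Exception:  # pragma: no cover - defensive
        return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# base-composition primitives
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """GC percent: 100*(G+C)/(A+C+G+T), case-insensitive.

    N and every other non-ACGT letter are excluded from both numerator and
    denominator, so hard-masked bases do not dilute the statistic.  Raises
    :class:`UndefinedValueError` when no unambiguous base remains.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        raise UndefinedValueError("GC content undefined: no unambiguous A/C/G/T bases")
    return 100.0 * gc / denom


def has_base_ambiguity(sequence: str) -> bool:
    """True iff any character falls outside {A,C,G,T} (case-insensitive).

    N counts as ambiguity here: this is the raw-input QC rule that discards
    sequences with uncertain base calls before any analysis.
    """
    return not UNAMBIGUOUS.issuperset(sequence.upper())


def has_internal_stop(cds: str, stop_codons: frozenset[str] = STOP_CODONS) -> bool:
    """True iff any codon before the final one is a stop (standard code).

    Raises :class:`FormatError` for a reading frame whose length is not a
    multiple of three; such CDS are treated as malformed and removed from
    the orthology input.
    """
    s = cds.upper()
    if len(s) % 3 != 0:
        raise FormatError(f"malformed CDS: length {len(s)} not divisible by 3")
    for i in range(0, len(s) - 3, 3):
        if s[i : i + 3] in stop_codons:
            return True
    return False


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One protein-coding gene: the selected transcript's exon/CDS structure.

    ``exon_intervals`` and ``cds_intervals`` are 0-based half-open genomic
    intervals listed in transcription order.  ``sequence_source`` is the
    contig sequence (a plain string) the intervals refer to, when available.
    """

    gene_id: str
    species_id: str
    strand: str
    seqid: str
    exon_intervals: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    transcript_id: str | None = None
    sequence_source: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exon_intervals:
            raise FormatError(f"gene {self.gene_id}: at least one exon required")
        for s, e in self.exon_intervals:
            if e <= s:
                raise CoordinateError(f"gene {self.gene_id}: empty/inverted exon ({s},{e})")

    @property
    def n_introns(self) -> int:
        return len(self.exon_intervals) - 1


@dataclass
class IntronicSequence:
    """Concatenation of a gene's internal introns with its summary measures.

    ``gci`` is None for an empty sequence (intronless gene or one whose only
    introns flank the CDS); such genes are excluded downstream.
    """

    gene_id: str
    species_id: str
    sequence: str
    n_introns: int

    @property
    def bpi(self) -> int:
        return len(self.sequence)

    @property
    def gci(self) -> float | None:
        if not self.sequence:
            return None
        try:
            return gc_content(self.sequence)
        except UndefinedValueError:
            return None


@dataclass
class SpeciesDataset:
    """All per-gene sequences of one species plus its genome GC (``gcg``)."""

    species_id: str
    genes: dict[str, GeneModel]
    cds_seqs: dict[str, str]
    protein_seqs: dict[str, str]
    intronic_seqs: dict[str, IntronicSequence]
    gcg: float | None = None

    def __post_init__(self) -> None:
        for gid in self.intronic_seqs:
            if gid not in self.genes:
                raise LookupError(f"intronic sequence {gid} has no gene model")


# ---------------------------------------------------------------------------
# intron extraction
# ---------------------------------------------------------------------------

def _intron_intervals(gene: GeneModel) -> list[tuple[int, int]]:
    """Genomic intervals of all introns, in transcription order."""
    out = []
    for (s1, e1), (s2, e2) in zip(gene.exon_intervals, gene.exon_intervals[1:]):
        if gene.strand == "+":
            gap = (e1, s2)
        else:
            gap = (e2, s1)
        if gap[1] < gap[0]:
            raise CoordinateError(f"gene {gene.gene_id}: exons overlap or are misordered")
        out.append(gap)
    return out


def _exon_has_cds(exon: tuple[int, int], cds_intervals: Sequence[tuple[int, int]]) -> bool:
    s, e = exon
    return any(cs < e and s < ce for cs, ce in cds_intervals)


def extract_internal_introns(
    gene: GeneModel,
    contig_seq: str | None = None,
    convention: str = "cds-span",
) -> IntronicSequence:
    """Concatenate the gene's internal introns in transcription order.

    Under the default ``cds-span`` convention an intron is internal when it
    lies between CDS-containing exons of the selected transcript; introns
    wholly within the 5'/3' UTRs are the flanking introns that are
    discarded.  ``drop-terminal`` is the alternative reading: discard the
    first and the last intron of the transcript unconditionally.
    """
    if contig_seq is None:
        contig_seq = gene.sequence_source
    if contig_seq is None:
        raise CoordinateError(f"gene {gene.gene_id}: no contig sequence available")
    introns = _intron_intervals(gene)
    n = len(introns)
    if convention == "cds-span":
        flags = [_exon_has_cds(ex, gene.cds_intervals) for ex in gene.exon_intervals]
        if any(flags):
            first = flags.index(True)
            last = len(flags) - 1 - flags[::-1].index(True)
            keep = [introns[i] for i in range(first, last)]
        else:
            keep = []
    elif convention == "drop-terminal":
        keep = introns[1 : n - 1] if n >= 3 else []
    else:
        raise ValueError(f"unknown internal-intron convention: {convention!r}")

    parts = []
    for s, e in keep:
        if s < 0 or e > len(contig_seq):
            raise CoordinateError(
                f"gene {gene.gene_id}: intron ({s},{e}) outside contig of length {len(contig_seq)}"
            )
        piece = contig_seq[s:e]
        parts.append(piece if gene.strand == "+" else reverse_complement(piece))
    return IntronicSequence(
        gene_id=gene.gene_id,
        species_id=gene.species_id,
        sequence="".join(parts),
        n_introns=len(keep),
    )


def extract_cds(gene: GeneModel, contig_seq: str | None = None) -> str:
    """Spliced CDS in reading-frame order (reverse-complemented on '-')."""
    if contig_seq is None:
        contig_seq = gene.sequence_source
    if contig_seq is None:
        raise CoordinateError(f"gene {gene.gene_id}: no contig sequence available")
    parts = []
    for s, e in gene.cds_intervals:
        if s < 0 or e > len(contig_seq):
            raise CoordinateError(
                f"gene {gene.gene_id}: CDS ({s},{e}) outside contig of length {len(contig_seq)}"
            )
        piece = contig_seq[s:e]
        parts.append(piece if gene.strand == "+" else reverse_complement(piece))
    return "".join(parts)


def translate_cds(cds: str) -> str:
    """Standard-code translation, trailing stop trimmed."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# loading from FASTA + GFF3
# ---------------------------------------------------------------------------

def _select_transcript(db: "gffutils.FeatureDB", gene) -> "gffutils.Feature | None":
    """Longest-CDS transcript; ties broken by lexicographic transcript id."""
    best = None
    best_key = None
    for t in db.children(gene, level=1):
        if t.featuretype not in {"mRNA", "transcript"}:
            continue
        cds_len = sum(c.end - c.start + 1 for c in db.children(t, featuretype="CDS"))
        if cds_len == 0:
            continue
        key = (-cds_len, t.id)
        if best_key is None or key < best_key:
            best, best_key = t, key
    return best


def load_species_dataset(
    genome_fasta: str | os.PathLike,
    annotation_gff: str | os.PathLike,
    species_id: str | None = None,
    intron_convention: str = "cds-span",
) -> SpeciesDataset:
    """Build a :class:`SpeciesDataset` from a genome FASTA and GFF3 annotation.

    One gene model per protein-coding gene (longest-CDS transcript); CDS,
    protein and internal-intron sequences are extracted with
    reverse-complementation on the minus strand.
    """
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    if not contigs:
        raise FormatError(f"no FASTA records in {genome_fasta}")
    if species_id is None:
        species_id = os.path.splitext(os.path.basename(str(genome_fasta)))[0]
    try:
        db = gffutils.create_db(
            str(annotation_gff),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"unparseable GFF3 {annotation_gff}: {exc}") from exc
    if next(iter(db.features_of_type("gene")), None) is None:
        raise FormatError(f"no parseable gene features in {annotation_gff}")

    genes: dict[str, GeneModel] = {}
    cds_seqs: dict[str, str] = {}
    protein_seqs: dict[str, str] = {}
    intronic_seqs: dict[str, IntronicSequence] = {}

    for gene in db.features_of_type("gene"):
        tr = _select_transcript(db, gene)
        if tr is None:
            continue
        if gene.seqid not in contigs:
            raise CoordinateError(f"gene {gene.id}: contig {gene.seqid} not in FASTA")
        contig = contigs[gene.seqid]
        exons = [(f.start - 1, f.end) for f in db.children(tr, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
        if not exons:
            exons = list(cds)
        reverse = gene.strand == "-"
        exons.sort(key=lambda iv: iv[0], reverse=reverse)
        cds.sort(key=lambda iv: iv[0], reverse=reverse)
        for s, e in exons:
            if s < 0 or e > len(contig):
                raise CoordinateError(
                    f"gene {gene.id}: exon ({s},{e}) outside contig {gene.seqid}"
                )
        gm = GeneModel(
            gene_id=gene.id,
            species_id=species_id,
            strand=gene.strand,
            seqid=gene.seqid,
            exon_intervals=exons,
            cds_intervals=cds,
            transcript_id=tr.id,
            sequence_source=contig,
        )
        genes[gene.id] = gm
        cds_seq = extract_cds(gm, contig)
        cds_seqs[gene.id] = cds_seq
        if len(cds_seq) % 3 == 0 and not has_base_ambiguity(cds_seq):
            protein_seqs[gene.id] = translate_cds(cds_seq)
        intronic_seqs[gene.id] = extract_internal_introns(gm, contig, intron_convention)

    gcg = None
    try:
        gcg = gc_content("".join(contigs.values()))
    except UndefinedValueError:
        pass
    return SpeciesDataset(
        species_id=species_id,
        genes=genes,
        cds_seqs=cds_seqs,
        protein_seqs=protein_seqs,
        intronic_seqs=intronic_seqs,
        gcg=gcg,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(ds: SpeciesDataset) -> tuple[SpeciesDataset, dict[str, int]]:
    """Drop genes with ambiguous CDS bases, malformed frames or internal stops.

    Returns a filtered copy plus a tally of removals by reason.  This is the
    gate in front of orthology inference.
    """
    report = {"ambiguous": 0, "malformed": 0, "internal_stop": 0, "kept": 0}
    keep: set[str] = set()
    for gid, cds in ds.cds_seqs.items():
        if has_base_ambiguity(cds):
            report["ambiguous"] += 1
            continue
        try:
            if has_internal_stop(cds):
                report["internal_stop"] += 1
                continue
        except FormatError:
            report["malformed"] += 1
            continue
        keep.add(gid)
        report["kept"] += 1
    filtered = SpeciesDataset(
        species_id=ds.species_id,
        genes={g: m for g, m in ds.genes.items() if g in keep},
        cds_seqs={g: s for g, s in ds.cds_seqs.items() if g in keep},
        protein_seqs={g: s for g, s in ds.protein_seqs.items() if g in keep},
        intronic_seqs={g: s for g, s in ds.intronic_seqs.items() if g in keep},
        gcg=ds.gcg,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# summaries and round-trip I/O
# ---------------------------------------------------------------------------

def dataset_summary(ds: SpeciesDataset) -> dict[str, float]:
    """Species-level means: genome GC, mean intronic GC and length."""
    measured = [iseq for iseq in ds.intronic_seqs.values() if iseq.gci is not None]
    if not measured:
        raise UndefinedValueError(f"{ds.species_id}: no gene with a measurable intronic sequence")
    return {
        "species_id": ds.species_id,
        "gcg": ds.gcg,
        "mean_gci": float(sum(i.gci for i in measured) / len(measured)),
        "mean_bpi": float(sum(i.bpi for i in measured) / len(measured)),
        "n_genes": len(ds.genes),
        "n_with_introns": len(measured),
    }


def _write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=i, description="") for i, s in records if s),
        path,
        "fasta",
    )


def write_species_dataset(ds: SpeciesDataset, outdir: str | os.PathLike) -> None:
    """Persist a dataset as plain-text FASTA/TSV/JSON under ``outdir``."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    _write_fasta(os.path.join(outdir, "cds.fasta"), ds.cds_seqs.items())
    _write_fasta(os.path.join(outdir, "proteins.fasta"), ds.protein_seqs.items())
    _write_fasta(
        os.path.join(outdir, "introns.fasta"),
        ((g, i.sequence) for g, i in ds.intronic_seqs.items()),
    )
    with open(os.path.join(outdir, "genes.tsv"), "w") as fh:
        fh.write("gene_id\ttranscript_id\tseqid\tstrand\texon_intervals\tcds_intervals\n")
        for g in sorted(ds.genes):
            gm = ds.genes[g]
            fh.write(
                f"{g}\t{gm.transcript_id or ''}\t{gm.seqid}\t{gm.strand}\t"
                f"{json.dumps(gm.exon_intervals)}\t{json.dumps(gm.cds_intervals)}\n"
            )
    with open(os.path.join(outdir, "intron_summary.tsv"), "w") as fh:
        fh.write("gene_id\tbpi\tgci\tn_introns\n")
        for g in sorted(ds.intronic_seqs):
            i = ds.intronic_seqs[g]
            gci = "" if i.gci is None else f"{i.gci:.6f}"
            fh.write(f"{g}\t{i.bpi}\t{gci}\t{i.n_introns}\n")
    manifest = {
        "species_id": ds.species_id,
        "gcg": ds.gcg,
        "n_genes": len(ds.genes),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_species_dataset(indir: str | os.PathLike) -> SpeciesDataset:
    """Inverse of :func:`write_species_dataset` (contig sequences not restored)."""
    indir = str(indir)
    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    species_id = manifest["species_id"]

    def read_fasta(name: str) -> dict[str, str]:
        path = os.path.join(indir, name)
        if not os.path.exists(path):
            return {}
        return {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}

    cds_seqs = read_fasta("cds.fasta")
    protein_seqs = read_fasta("proteins.fasta")
    intron_seqs = read_fasta("introns.fasta")

    genes: dict[str, GeneModel] = {}
    with open(os.path.join(indir, "genes.tsv")) as fh:
        header = fh.readline()
        for line in fh:
            gid, tid, seqid, strand, exons, cds = line.rstrip("\n").split("\t")
            genes[gid] = GeneModel(
                gene_id=gid,
                species_id=species_id,
                strand=strand,
                seqid=seqid,
                exon_intervals=[tuple(iv) for iv in json.loads(exons)],
                cds_intervals=[tuple(iv) for iv in json.loads(cds)],
                transcript_id=tid or None,
            )
    intronic: dict[str, IntronicSequence] = {}
    with open(os.path.join(indir, "intron_summary.tsv")) as fh:
        fh.readline()
        for line in fh:
            gid, bpi, gci, n_introns = line.rstrip("\n").split("\t")
            intronic[gid] = IntronicSequence(
                gene_id=gid,
                species_id=species_id,
                sequence=intron_seqs.get(gid, ""),
                n_introns=int(n_introns),
            )
    return SpeciesDataset(
        species_id=species_id,
        genes=genes,
        cds_seqs=cds_seqs,
        protein_seqs=protein_seqs,
        intronic_seqs=intronic,
        gcg=manifest.get("gcg"),
    )
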