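"""One-to-one orthology by reciprocal best hits (RBH) on protein sequences.

Orthologous coding sequences are inferred by scoring every protein of
species A against every protein of species B (and vice versa), keeping each
query's unique top-scoring subject, and retaining a pair only when the two
directions agree.  Orthology is then extended to the genes' internal-intron
sequences, which is where the downstream length/GC comparison happens.

The built-in scorer is Smith-Waterman local alignment with BLOSUM62 and
affine gaps (open 11, extend 1).  It reports raw scores, not e-values, so a
raw-score floor applies to built-in hits while the e-value threshold
applies to hits imported from an external aligner's 12-column tabular
output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FormatError, LookupMissError
from .seqmodel import IntronicSequence, SpeciesDataset

DEFAULT_SCORE_MIN = 50.0
DEFAULT_EVALUE_MAX = 1e-10


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue < 0:
            raise FormatError(f"negative e-value for {self.query_id}->{self.subject_id}")


@dataclass(frozen=True)
class OrthologPair:
    species_m: str
    species_z: str
    gene_m: str
    gene_z: str


class LocalProteinScorer:
    """BLOSUM62 local alignment score via Biopython's PairwiseAligner."""

    def __init__(self, open_gap: float = 11.0, extend_gap: float = 1.0) -> None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -open_gap
        aligner.extend_gap_score = -extend_gap
        self._aligner = aligner
        self._alphabet = set(str(aligner.substitution_matrix.alphabet))

    def _clean(self, seq: str) -> str:
        s = seq.upper()
        if set(s) <= self._alphabet:
            return s
        return "".join(c if c in self._alphabet else "X" for c in s)

    def __call__(self, a: str, b: str) -> float:
        if not a or not b:
            return 0.0
        return float(self._aligner.score(self._clean(a), self._clean(b)))


def _kmer_candidates(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    k: int,
    min_shared: int,
) -> dict[str, list[str]]:
    """Subjects sharing >= min_shared distinct k-mers with each query.

    A seeding shortcut in the spirit of word-based search tools: only
    seeded pairs are aligned, which keeps genome-scale all-vs-all feasible.
    """
    index: dict[str, set[str]] = {}
    for sid, seq in subjects.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(sid)
    out: dict[str, list[str]] = {}
    for qid, seq in queries.items():
        counts: dict[str, int] = {}
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            for sid in index.get(kmer, ()):
                counts[sid] = counts.get(sid, 0) + 1
        out[qid] = [sid for sid, c in counts.items() if c >= min_shared]
    return out


def all_vs_all_hits(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    scorer: Callable[[str, str], float] | None = None,
    score_min: float = DEFAULT_SCORE_MIN,
    kmer_prefilter: int | None = None,
    min_shared_kmers: int = 2,
) -> list[SimilarityHit]:
    """Score every A-protein against every B-protein; keep hits >= score_min.

    Hits are returned grouped by query, ranked by descending score (subject
    id breaks ties deterministically).  ``kmer_prefilter`` (a word size,
    e.g. 4) restricts alignment to seeded pairs; by default every pair is
    aligned, matching an exhaustive pairwise oracle exactly.
    """
    if scorer is None:
        scorer = LocalProteinScorer()
    if not proteins_a or not proteins_b:
        import warnings

        warnings.warn("all_vs_all_hits: empty input protein set", stacklevel=2)
        return []
    if kmer_prefilter is not None:
        candidates = _kmer_candidates(proteins_a, proteins_b, kmer_prefilter, min_shared_kmers)
    else:
        all_b = list(proteins_b)
        candidates = {qid: all_b for qid in proteins_a}

    hits: list[SimilarityHit] = []
    for qid in sorted(proteins_a):
        qseq = proteins_a[qid]
        qh = []
        for sid in candidates.get(qid, ()):
            score = scorer(qseq, proteins_b[sid])
            if score >= score_min:
                qh.append(SimilarityHit(qid, sid, score))
        qh.sort(key=lambda h: (-h.score, h.subject_id))
        hits.extend(qh)
    return hits


def best_hit_map(
    hits: Sequence[SimilarityHit],
    evalue_max: float | None = None,
    score_min: float | None = None,
) -> dict[str, str]:
    """Unique top-scoring subject per query; queries with tied tops are dropped.

    Dropping ties preserves the one-to-one guarantee of RBH pairing.
    """
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        if evalue_max is not None and h.evalue is not None and h.evalue > evalue_max:
            continue
        if score_min is not None and h.score < score_min:
            continue
        by_query.setdefault(h.query_id, []).append(h)
    best: dict[str, str] = {}
    for q, qh in by_query.items():
        top = max(h.score for h in qh)
        tops = {h.subject_id for h in qh if h.score == top}
        if len(tops) == 1:
            best[q] = next(iter(tops))
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[SimilarityHit],
    hits_ba: Sequence[SimilarityHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    species_m: str = "m",
    species_z: str = "z",
) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's unique best hit and a is b's, both passing QC.

    The e-value threshold applies where hits carry e-values (imported
    tables); built-in hits are already score-filtered upstream.
    """
    fwd = best_hit_map(hits_ab, evalue_max=evalue_max)
    rev = best_hit_map(hits_ba, evalue_max=evalue_max)
    pairs = [
        OrthologPair(species_m, species_z, a, b)
        for a, b in sorted(fwd.items())
        if rev.get(b) == a
    ]
    return pairs


# ---------------------------------------------------------------------------
# 12-column tabular import/export
# ---------------------------------------------------------------------------

_TAB_COLS = 12


def import_tabular_hits(path: str | os.PathLike) -> list[SimilarityHit]:
    """Parse 12-column tabular hits (query, subject, ..., evalue, bitscore)."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _TAB_COLS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {_TAB_COLS} columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric field: {exc}") from exc
            hits.append(SimilarityHit(fields[0], fields[1], bitscore, evalue))
    return hits


def export_tabular_hits(hits: Sequence[SimilarityHit], path: str | os.PathLike) -> None:
    """Write hits in the 12-column layout (unused columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            ev = h.evalue if h.evalue is not None else 0.0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{ev:g}\t{h.score:g}\n"
            )


def write_pairs_tsv(pairs: Sequence[OrthologPair], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("species_m\tgene_m\tspecies_z\tgene_z\n")
        for p in pairs:
            fh.write(f"{p.species_m}\t{p.gene_m}\t{p.species_z}\t{p.gene_z}\n")


# ---------------------------------------------------------------------------
# orthology extension to intronic sequences
# ---------------------------------------------------------------------------

def extend_to_introns(
    pairs: Sequence[OrthologPair],
    ds_m: SpeciesDataset,
    ds_z: SpeciesDataset,
) -> tuple[list[tuple[IntronicSequence, IntronicSequence]], int]:
    """Map each CDS ortholog pair to its two internal-intron sequences.

    Pairs where either member has an empty intronic sequence are dropped;
    the count of dropped pairs is returned alongside.
    """
    out: list[tuple[IntronicSequence, IntronicSequence]] = []
    dropped = 0
    for p in pairs:
        try:
            im = ds_m.intronic_seqs[p.gene_m]
            iz = ds_z.intronic_seqs[p.gene_z]
        except KeyError as exc:
            raise LookupMissError(f"ortholog pair references unknown gene: {exc}") from exc
        if not im.sequence or not iz.sequence:
            dropped += 1
            continue
        out.append((im, iz))
    return out, dropped
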