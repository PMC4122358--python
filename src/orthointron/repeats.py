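"""Masking of repetitive elements in intronic sequences and mask statistics.

Interspersed repeats inflate intron length and pull intronic GC toward the
repeat family's own composition, so the length/GC comparison is run both
before and after masking.  Two masking routes are provided:

* a built-in exact matcher — every exact occurrence (either strand) of a
  window of length >= ``min_match`` from any repeat-library consensus is
  hard-masked to N, plus single-base low-complexity runs.  This is a fast,
  fully testable matcher, not a drop-in for alignment-based repeat masking;
* an importer for externally produced masks (interval lists or soft-masked
  FASTA), the high-fidelity route when a dedicated masker has been run.

For the "after masking" analyses masked bases are removed from the intronic
sequence, so bpi shrinks and GCi is recomputed over the surviving bases.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from Bio import SeqIO

from .errors import CoordinateError, ParameterError, UndefinedValueError
from .seqmodel import (
    IntronicSequence,
    SpeciesDataset,
    gc_content,
    reverse_complement,
)

DEFAULT_MIN_MATCH = 15
DEFAULT_LOW_COMPLEXITY_RUN = 20

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class RepeatLibrary:
    """Named consensus sequences of the repeat families to mask."""

    elements: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for name, cons in self.elements:
            if not cons or not _ACGT.issuperset(cons.upper()):
                raise ParameterError(f"repeat consensus {name!r} must be non-empty A/C/G/T")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "RepeatLibrary":
        return cls(tuple((r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")))

    def to_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, cons in self.elements:
                fh.write(f">{name}\n{cons}\n")


@dataclass
class MaskResult:
    """Masked intervals on one intronic sequence, with composition of the cut."""

    gene_id: str
    masked_intervals: list[tuple[int, int]]
    masked_bp: int
    masked_gc: float | None
    masked_sequence: str

    @property
    def length(self) -> int:
        return len(self.masked_sequence)

    @property
    def masked_fraction(self) -> float:
        return self.masked_bp / self.length if self.length else 0.0


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted non-overlapping list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# rolling-hash window matching
# ---------------------------------------------------------------------------

_HASH_BASE = np.uint64(1099511628211)
_U64 = np.uint64


def _window_hashes(arr: np.ndarray, k: int) -> np.ndarray:
    """Polynomial hash of every length-k window (mod 2^64 by overflow wrap)."""
    n = arr.size - k + 1
    h = np.zeros(n, dtype=np.uint64)
    err = np.seterr(over="ignore")
    try:
        for j in range(k):
            h = h * _HASH_BASE + arr[j : j + n].astype(np.uint64)
    finally:
        np.seterr(**err)
    return h


def _hash_string(s: str) -> int:
    h = 0
    for c in s.encode():
        h = (h * 1099511628211 + c) % (1 << 64)
    return h


def _seed_windows(lib: RepeatLibrary, k: int) -> set[str]:
    """All length-k windows of every consensus, both strands."""
    seeds: set[str] = set()
    for _, cons in lib.elements:
        for s in (cons.upper(), reverse_complement(cons.upper())):
            seeds.update(s[i : i + k] for i in range(len(s) - k + 1))
    return seeds


def mask_with_library(
    seq: IntronicSequence | str,
    lib: RepeatLibrary,
    min_match: int = DEFAULT_MIN_MATCH,
    low_complexity_run: int = DEFAULT_LOW_COMPLEXITY_RUN,
    gene_id: str | None = None,
) -> MaskResult:
    """Hard-mask exact library matches (both strands) and low-complexity runs.

    Any target position covered by an exact occurrence of a library window
    of length >= ``min_match`` is masked; since every longer exact match
    contains a match of length exactly ``min_match``, scanning windows of
    that one length recovers the full masked footprint.
    """
    if min_match < 10:
        raise ParameterError("min_match must be >= 10")
    if isinstance(seq, IntronicSequence):
        target, gid = seq.sequence, seq.gene_id
    else:
        target, gid = seq, gene_id or ""
    upper = target.upper()
    intervals: list[tuple[int, int]] = []

    if len(upper) >= min_match and lib.elements:
        seeds = _seed_windows(lib, min_match)
        if seeds:
            arr = np.frombuffer(upper.encode(), dtype=np.uint8)
            hashes = _window_hashes(arr, min_match)
            seed_hashes = np.fromiter(
                {_hash_string(s) for s in seeds}, dtype=np.uint64
            )
            cand = np.nonzero(np.isin(hashes, seed_hashes))[0]
            for i in map(int, cand):
                if upper[i : i + min_match] in seeds:
                    intervals.append((i, i + min_match))

    if low_complexity_run:
        pat = "|".join(f"{b}{{{low_complexity_run},}}" for b in "ACGT")
        for m in re.finditer(pat, upper):
            intervals.append((m.start(), m.end()))

    merged = merge_intervals(intervals)
    return _build_result(gid, target, merged)


def _build_result(gene_id: str, target: str, merged: list[tuple[int, int]]) -> MaskResult:
    masked_bp = sum(e - s for s, e in merged)
    masked_bases = "".join(target[s:e] for s, e in merged)
    try:
        masked_gc = gc_content(masked_bases) if masked_bases else None
    except UndefinedValueError:
        masked_gc = None
    chars = list(target)
    for s, e in merged:
        chars[s:e] = "N" * (e - s)
    return MaskResult(
        gene_id=gene_id,
        masked_intervals=merged,
        masked_bp=masked_bp,
        masked_gc=masked_gc,
        masked_sequence="".join(chars),
    )


def import_external_mask(
    seq: IntronicSequence | str,
    intervals: Sequence[tuple[int, int]] | None = None,
    softmasked: str | None = None,
    gene_id: str | None = None,
) -> MaskResult:
    """Build a MaskResult from externally supplied intervals or soft-masking.

    Exactly one of ``intervals`` / ``softmasked`` must be given; lowercase
    letters in a soft-masked sequence are converted to intervals.
    """
    if isinstance(seq, IntronicSequence):
        target, gid = seq.sequence, seq.gene_id
    else:
        target, gid = seq, gene_id or ""
    if (intervals is None) == (softmasked is None):
        raise ParameterError("provide exactly one of intervals / softmasked")
    if softmasked is not None:
        if len(softmasked) != len(target):
            raise CoordinateError("soft-masked sequence length differs from target")
        intervals = [
            (m.start(), m.end()) for m in re.finditer("[a-z]+", softmasked)
        ]
    assert intervals is not None
    for s, e in intervals:
        if s < 0 or e > len(target) or e < s:
            raise CoordinateError(f"mask interval ({s},{e}) out of bounds for length {len(target)}")
    return _build_result(gid, target, merge_intervals(intervals))


def read_mask_intervals(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """3-column TSV (seq_id, start, end; 0-based half-open) -> intervals per id."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, s, e = line.split("\t")
            out.setdefault(sid, []).append((int(s), int(e)))
    return out


def write_mask_results(results: Sequence[MaskResult], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength\tmasked_bp\tmasked_gc\tintervals\n")
        for r in results:
            gc = "" if r.masked_gc is None else f"{r.masked_gc:.6f}"
            ivs = ";".join(f"{s}-{e}" for s, e in r.masked_intervals)
            fh.write(f"{r.gene_id}\t{r.length}\t{r.masked_bp}\t{gc}\t{ivs}\n")


# ---------------------------------------------------------------------------
# statistics and dataset-level application
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskStats:
    """Cohort means of masked length fraction and masked-base GC, with SEs."""

    mean_bp_pct: float
    se_bp_pct: float
    mean_gc_pct: float | None
    se_gc_pct: float | None
    n: int


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    se = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
    return float(a.mean()), se


def mask_stats(results: Sequence[MaskResult]) -> MaskStats:
    """Per-sequence masked bp% and masked-base GC%, averaged with standard errors.

    GC of masked bases is averaged over sequences that actually had masked
    bases; when nothing was masked anywhere it is reported as missing.
    """
    if not results:
        raise ParameterError("mask_stats requires at least one MaskResult")
    bp_pcts = [100.0 * r.masked_bp / r.length for r in results if r.length]
    mean_bp, se_bp = _mean_se(bp_pcts)
    gcs = [r.masked_gc for r in results if r.masked_gc is not None]
    if gcs:
        mean_gc, se_gc = _mean_se(gcs)
    else:
        mean_gc = se_gc = None
    return MaskStats(mean_bp, se_bp, mean_gc, se_gc, len(results))


def strip_masked(result: MaskResult) -> str:
    """Sequence with masked bases removed (the shortened, 'after masking' view)."""
    seq = result.masked_sequence
    keep = []
    prev = 0
    for s, e in result.masked_intervals:
        keep.append(seq[prev:s])
        prev = e
    keep.append(seq[prev:])
    return "".join(keep)


def apply_mask_to_dataset(
    ds: SpeciesDataset,
    lib: RepeatLibrary | None = None,
    external: dict[str, list[tuple[int, int]]] | None = None,
    min_match: int = DEFAULT_MIN_MATCH,
    low_complexity_run: int = DEFAULT_LOW_COMPLEXITY_RUN,
) -> tuple[SpeciesDataset, list[MaskResult]]:
    """Mask every intronic sequence and return the shortened, remeasured dataset."""
    if (lib is None) == (external is None):
        raise ParameterError("provide exactly one of lib / external")
    results: list[MaskResult] = []
    new_introns: dict[str, IntronicSequence] = {}
    for gid in sorted(ds.intronic_seqs):
        iseq = ds.intronic_seqs[gid]
        if lib is not None:
            res = mask_with_library(iseq, lib, min_match, low_complexity_run)
        else:
            res = import_external_mask(iseq, intervals=external.get(gid, []))
        results.append(res)
        new_introns[gid] = IntronicSequence(
            gene_id=gid,
            species_id=iseq.species_id,
            sequence=strip_masked(res),
            n_introns=iseq.n_introns,
        )
    masked_ds = SpeciesDataset(
        species_id=ds.species_id,
        genes=ds.genes,
        cds_seqs=ds.cds_seqs,
        protein_seqs=ds.protein_seqs,
        intronic_seqs=new_introns,
        gcg=ds.gcg,
    )
    return masked_ds, results
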