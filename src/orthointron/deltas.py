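"""Per-ortholog-pair differences in intron length and GC, and their statistics.

For each ortholog pair the signed differences are

    delta_bpi = bpi_m - bpi_z        (bases)
    delta_gci = GCi_m - GCi_z        (GC percentage points)

oriented as first species minus second.  Pairs carrying negligible signal on
either axis (|delta_gci| < 0.1 points or |delta_bpi| < 100 bases, strict)
are removed before any downstream statistic.  Each surviving pair falls in
one of four sign classes:

    N/P  shorter and GC-richer in species m   (delta_bpi < 0, delta_gci > 0)
    N/N  shorter and GC-poorer                (both negative)
    P/N  longer and GC-poorer                 (delta_bpi > 0, delta_gci < 0)
    P/P  longer and GC-richer                 (both positive)

Whether the top class dominates beyond chance is assessed with an exact
one-sided binomial test (upper tail, computed by direct pmf summation),
with Benjamini-Hochberg adjustment across the family of comparisons.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, UndefinedValueError
from .seqmodel import IntronicSequence

CLASS_LABELS = ("N/P", "N/N", "P/N", "P/P")
DEFAULT_GC_THRESHOLD = 0.1
DEFAULT_BP_THRESHOLD = 100.0


@dataclass(frozen=True)
class DeltaRecord:
    gene_m: str
    gene_z: str
    delta_bpi: float
    delta_gci: float
    masked_variant: str = "before"

    def reversed(self) -> "DeltaRecord":
        """Same pair seen from the other species' side (both deltas negated)."""
        return DeltaRecord(
            gene_m=self.gene_z,
            gene_z=self.gene_m,
            delta_bpi=-self.delta_bpi,
            delta_gci=-self.delta_gci,
            masked_variant=self.masked_variant,
        )


@dataclass
class ClassCounts:
    comparison_id: str
    counts: dict[str, int]
    n_filtered_out: int = 0

    def __post_init__(self) -> None:
        for lbl in CLASS_LABELS:
            self.counts.setdefault(lbl, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ParameterError("class counts must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        n = self.n_total
        if n == 0:
            raise UndefinedValueError("no classified records")
        return {lbl: 100.0 * self.counts[lbl] / n for lbl in CLASS_LABELS}

    @property
    def top_class(self) -> str:
        return max(CLASS_LABELS, key=lambda lbl: self.counts[lbl])


@dataclass(frozen=True)
class PairwiseSummary:
    comparison_id: str
    n: int
    pct_positive_gci: float
    pct_positive_bpi: float
    mean_delta_gci: float
    mean_delta_bpi: float


# ---------------------------------------------------------------------------
# deltas, filter, sign statistics
# ---------------------------------------------------------------------------

def compute_deltas(
    intron_pairs: Sequence[tuple[IntronicSequence, IntronicSequence]],
    masked_variant: str = "before",
) -> list[DeltaRecord]:
    """One DeltaRecord per ortholog intron pair, oriented (m, z) as given."""
    records = []
    for im, iz in intron_pairs:
        if im.gci is None or iz.gci is None:
            raise UndefinedValueError(
                f"pair ({im.gene_id},{iz.gene_id}): intronic GC undefined"
            )
        records.append(
            DeltaRecord(
                gene_m=im.gene_id,
                gene_z=iz.gene_id,
                delta_bpi=float(im.bpi - iz.bpi),
                delta_gci=im.gci - iz.gci,
                masked_variant=masked_variant,
            )
        )
    return records


def filter_deltas(
    records: Sequence[DeltaRecord],
    gc_threshold: float = DEFAULT_GC_THRESHOLD,
    bp_threshold: float = DEFAULT_BP_THRESHOLD,
    combine: str = "or",
) -> tuple[list[DeltaRecord], float]:
    """Remove pairs with negligible differences; report the removed fraction.

    A record is removed when |delta_gci| < gc_threshold OR |delta_bpi| <
    bp_threshold (default); boundary values are retained (strict
    inequalities).  ``combine="and"`` switches to removal only when both
    axes are sub-threshold.
    """
    if gc_threshold <= 0 or bp_threshold <= 0:
        raise ParameterError("filter thresholds must be positive")
    if combine not in {"or", "and"}:
        raise ParameterError("combine must be 'or' or 'and'")

    def negligible(r: DeltaRecord) -> bool:
        small_gc = abs(r.delta_gci) < gc_threshold
        small_bp = abs(r.delta_bpi) < bp_threshold
        return (small_gc or small_bp) if combine == "or" else (small_gc and small_bp)

    retained = [r for r in records if not negligible(r)]
    removed_fraction = (
        100.0 * (len(records) - len(retained)) / len(records) if records else 0.0
    )
    return retained, removed_fraction


def percent_positive(records: Sequence[DeltaRecord], variable: str) -> float:
    """100 * (#records with the chosen delta > 0) / n."""
    if variable not in {"delta_gci", "delta_bpi"}:
        raise ParameterError("variable must be 'delta_gci' or 'delta_bpi'")
    if not records:
        raise UndefinedValueError("percent_positive of an empty record set")
    k = sum(1 for r in records if getattr(r, variable) > 0)
    return 100.0 * k / len(records)


def classify(record: DeltaRecord) -> str:
    """Sign class of one filtered record (N/P, N/N, P/N or P/P)."""
    if record.delta_bpi == 0 or record.delta_gci == 0:
        raise ParameterError(
            f"pair ({record.gene_m},{record.gene_z}) has a zero delta; "
            "classify requires filtered records"
        )
    if record.delta_bpi < 0:
        return "N/P" if record.delta_gci > 0 else "N/N"
    return "P/P" if record.delta_gci > 0 else "P/N"


def class_frequencies(
    records: Sequence[DeltaRecord],
    comparison_id: str = "",
    n_filtered_out: int = 0,
) -> ClassCounts:
    counts = {lbl: 0 for lbl in CLASS_LABELS}
    for r in records:
        counts[classify(r)] += 1
    return ClassCounts(comparison_id=comparison_id, counts=counts, n_filtered_out=n_filtered_out)


def summarize_comparison(
    records: Sequence[DeltaRecord], comparison_id: str = ""
) -> PairwiseSummary:
    if not records:
        raise UndefinedValueError("cannot summarize an empty comparison")
    n = len(records)
    return PairwiseSummary(
        comparison_id=comparison_id,
        n=n,
        pct_positive_gci=percent_positive(records, "delta_gci"),
        pct_positive_bpi=percent_positive(records, "delta_bpi"),
        mean_delta_gci=sum(r.delta_gci for r in records) / n,
        mean_delta_bpi=sum(r.delta_bpi for r in records) / n,
    )


# ---------------------------------------------------------------------------
# exact binomial test and FDR
# ---------------------------------------------------------------------------

def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p) by pmf summation.

    Terms are evaluated through log-gamma and accumulated with compensated
    summation; no normal approximation at any n.
    """
    if not 0 < p < 1:
        raise ParameterError("binomial null probability must lie in (0,1)")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    lp, lq = math.log(p), math.log1p(-p)
    lbinom = math.lgamma(n + 1)
    terms = [
        math.exp(
            lbinom - math.lgamma(i + 1) - math.lgamma(n - i + 1) + i * lp + (n - i) * lq
        )
        for i in range(k, n + 1)
    ]
    return min(1.0, math.fsum(terms))


def binomial_test_top_class(
    counts: ClassCounts,
    null_p: float = 0.25,
    alternative: str = "top-vs-rest",
) -> float:
    """One-sided exact binomial p-value that the top class exceeds its null share.

    ``top-vs-rest`` (default): k = top-class count, n = all classified pairs,
    null probability ``null_p`` (1/4 for a uniform null over four classes).
    ``top-vs-second``: restrict to the top two classes and test the top one
    against p0 = 1/2 on their union.
    """
    n = counts.n_total
    if n < 1:
        raise ParameterError("binomial test requires at least one classified pair")
    ranked = sorted(CLASS_LABELS, key=lambda lbl: counts.counts[lbl], reverse=True)
    k_top = counts.counts[ranked[0]]
    if alternative == "top-vs-rest":
        return binomial_tail(k_top, n, null_p)
    if alternative == "top-vs-second":
        k_second = counts.counts[ranked[1]]
        return binomial_tail(k_top, k_top + k_second, 0.5)
    raise ParameterError("alternative must be 'top-vs-rest' or 'top-vs-second'")


def adjust_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone after sorting)."""
    if any(not 0 <= p <= 1 for p in pvalues):
        raise ParameterError("p-values must lie in [0,1]")
    if not pvalues:
        return []
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_delta_records(records: Sequence[DeltaRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_m\tgene_z\tdelta_bpi\tdelta_gci\tmasked_variant\n")
        for r in records:
            fh.write(
                f"{r.gene_m}\t{r.gene_z}\t{r.delta_bpi:g}\t{r.delta_gci:.6f}\t{r.masked_variant}\n"
            )
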