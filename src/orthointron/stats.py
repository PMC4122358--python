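"""Descriptive and inferential statistics for the comparative analysis.

Three tools are used downstream: the Fisher-Pearson skewness of intronic-GC
distributions (a proxy for compositional heterogeneity), Spearman rank
correlation between per-comparison mean deltas (length, GC, metabolic
rate), and the Student-Newman-Keuls (SNK) stepwise post hoc test for
between-species differences in metabolic rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .errors import ParameterError, UndefinedValueError


@dataclass(frozen=True)
class DistributionStats:
    n: int
    mean: float
    sd: float
    skewness: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "t-approximation"


def skewness(sample: Sequence[float], adjusted: bool = False) -> float:
    """Fisher-Pearson moment skewness g1 = m3 / m2^(3/2).

    ``adjusted=True`` applies the small-sample bias correction (G1).
    """
    a = np.asarray(sample, dtype=float)
    if a.size < 3:
        raise ParameterError("skewness requires n >= 3")
    if np.isclose(a.std(), 0.0):
        raise UndefinedValueError("skewness undefined for a zero-variance sample")
    return float(_sps.skew(a, bias=not adjusted))


def distribution_stats(sample: Sequence[float], bins: int = 20) -> DistributionStats:
    """Summary of one GC (or any) distribution: n, mean, sd, SK, histogram."""
    a = np.asarray(sample, dtype=float)
    counts, edges = np.histogram(a, bins=bins)
    return DistributionStats(
        n=int(a.size),
        mean=float(a.mean()),
        sd=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        skewness=skewness(a),
        bin_edges=tuple(map(float, edges)),
        bin_counts=tuple(map(int, counts)),
    )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t-approximation",
) -> CorrelationResult:
    """Tie-aware Spearman rho with a two-sided p-value.

    The default p-value comes from the t-approximation with n-2 degrees of
    freedom; ``method="permutation"`` enumerates all n! orderings exactly
    (restricted to n <= 10).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ParameterError("x and y must have equal length")
    n = xa.size
    if n < 4:
        raise ParameterError("spearman requires n >= 4")
    if np.isclose(xa.std(), 0) or np.isclose(ya.std(), 0):
        raise UndefinedValueError("spearman undefined for a constant vector")

    if method == "t-approximation":
        rho, p = _sps.spearmanr(xa, ya)
        return CorrelationResult(rho=float(rho), p_value=float(p), n=n, method=method)
    if method == "permutation":
        if n > 10:
            raise ParameterError("exact permutation p-value restricted to n <= 10")
        rx = _sps.rankdata(xa)
        ry = _sps.rankdata(ya)
        obs = float(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            hits += abs(r) >= abs(obs) - 1e-12
            total += 1
        return CorrelationResult(rho=obs, p_value=hits / total, n=n, method=method)
    raise ParameterError("method must be 't-approximation' or 'permutation'")


# ---------------------------------------------------------------------------
# Student-Newman-Keuls
# ---------------------------------------------------------------------------

@dataclass
class SNKResult:
    """Pairwise S/NS decisions plus the ANOVA quantities behind them."""

    group_names: list[str]
    means: dict[str, float]
    decisions: dict[tuple[str, str], str]
    mse: float
    df_error: int
    alpha: float

    def significant(self, a: str, b: str) -> bool:
        if a == b:
            return False
        key = (a, b) if (a, b) in self.decisions else (b, a)
        return self.decisions[key] == "S"


def snk_test(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> SNKResult:
    """Student-Newman-Keuls stepwise multiple comparison of group means.

    One-way ANOVA supplies the error mean square; group means are ranked and
    the extremes of each span are compared against studentized-range
    critical values whose argument is the number of means spanned.  A span
    found non-significant seals every comparison inside it.  Unequal group
    sizes use the harmonic pairwise standard error.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    if len(names) < 2:
        raise ParameterError("SNK needs at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ParameterError("each group needs n >= 2")

    n_total = sum(a.size for a in arrays.values())
    grand = np.concatenate(list(arrays.values()))
    df_error = n_total - len(names)
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values())
    mse = sse / df_error
    if mse <= 0 or np.isclose(grand.std(), 0):
        raise ParameterError("degenerate configuration: zero within-group variance")

    means = {g: float(a.mean()) for g, a in arrays.items()}
    order = sorted(names, key=lambda g: means[g])

    crit_cache: dict[int, float] = {}

    def crit(span: int) -> float:
        if span not in crit_cache:
            crit_cache[span] = float(_sps.studentized_range.ppf(1 - alpha, span, df_error))
        return crit_cache[span]

    decisions: dict[tuple[str, str], str] = {}
    sealed: list[tuple[int, int]] = []  # index spans declared NS

    for span in range(len(order), 1, -1):
        for i in range(0, len(order) - span + 1):
            j = i + span - 1
            gi, gj = order[i], order[j]
            key = (gi, gj)
            if key in decisions:
                continue
            if any(s <= i and j <= e for s, e in sealed):
                decisions[key] = "NS"
                continue
            ni, nj = arrays[gi].size, arrays[gj].size
            se = math.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
            q = (means[gj] - means[gi]) / se
            if q > crit(span):
                decisions[key] = "S"
            else:
                decisions[key] = "NS"
                sealed.append((i, j))

    return SNKResult(
        group_names=names,
        means=means,
        decisions=decisions,
        mse=mse,
        df_error=df_error,
        alpha=alpha,
    )


def snk_matrix_tsv(result: SNKResult, path) -> None:
    """Lower-triangular S/NS matrix, one row per group."""
    names = result.group_names
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for i, a in enumerate(names):
            cells = []
            for j, b in enumerate(names):
                if j >= i:
                    cells.append("-" if j == i else "")
                else:
                    cells.append("S" if result.significant(a, b) else "NS")
            fh.write(a + "\t" + "\t".join(cells) + "\n")
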