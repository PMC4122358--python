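"""Delta computation, filtering, classification, binomial and FDR machinery."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import special

from orthointron import (
    DeltaRecord,
    adjust_fdr,
    binomial_tail,
    binomial_test_top_class,
    class_frequencies,
    classify,
    compute_deltas,
    filter_deltas,
    percent_positive,
)
from orthointron.deltas import CLASS_LABELS, ClassCounts
from orthointron.errors import ParameterError, UndefinedValueError
from orthointron.seqmodel import IntronicSequence


def _iseq(gid, sp, seq):
    return IntronicSequence(gid, sp, seq, 1)


def test_identical_sequences_give_zero_deltas():
    a = _iseq("m1", "m", "GCAT" * 50)
    b = _iseq("z1", "z", "GCAT" * 50)
    (rec,) = compute_deltas([(a, b)])
    assert rec.delta_bpi == 0 and rec.delta_gci == 0


def test_delta_arithmetic():
    # bpi 1000 vs 800; GCi 40 vs 42 -> (+200, -2.0)
    a = _iseq("m1", "m", "GC" * 200 + "AT" * 300)  # 1000 bp, 40%
    b = _iseq("z1", "z", "GC" * 168 + "AT" * 232)  # 800 bp, 42%
    (rec,) = compute_deltas([(a, b)])
    assert rec.delta_bpi == 200
    assert rec.delta_gci == pytest.approx(-2.0)


def _rand_records(rng, n=50):
    return [
        DeltaRecord(f"m{i}", f"z{i}", float(rng.integers(-500, 500)), float(rng.normal(0, 3)))
        for i in range(n)
    ]


def test_orientation_swap_negates_both_deltas(rng):
    for r in _rand_records(rng):
        rev = r.reversed()
        assert rev.delta_bpi == -r.delta_bpi and rev.delta_gci == -r.delta_gci


# ---------------------------------------------------------------------------
# filter
# ---------------------------------------------------------------------------

def _rec(dbp, dgc):
    return DeltaRecord("m", "z", dbp, dgc)


@pytest.mark.parametrize(
    "dbp,dgc,kept",
    [
        (50.0, 5.0, False),     # bp below threshold
        (100.0, 0.1, True),     # boundary retained (strict <)
        (500.0, 0.05, False),   # gc below threshold
        (-100.0, -0.1, True),   # boundary on the negative side
        (99.0, 0.09, False),
    ],
)
def test_filter_threshold_semantics(dbp, dgc, kept):
    retained, _ = filter_deltas([_rec(dbp, dgc)])
    assert bool(retained) is kept


def test_filter_and_mode_requires_both_small():
    retained, _ = filter_deltas([_rec(50.0, 5.0)], combine="and")
    assert retained  # only one axis negligible -> kept under AND
    retained, _ = filter_deltas([_rec(50.0, 0.05)], combine="and")
    assert not retained


def test_filter_bookkeeping_constructed_fixture():
    records = [_rec(200.0 + i, 1.0) for i in range(90)] + [_rec(float(i), 1.0) for i in range(10)]
    retained, removed = filter_deltas(records)
    assert len(retained) == 90 and removed == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# percent positive / classes
# ---------------------------------------------------------------------------

def test_percent_positive_formula(rng):
    recs = [_rec(200, 1.0)] * 7 + [_rec(200, -1.0)] * 3
    assert percent_positive(recs, "delta_gci") == 70.0
    assert percent_positive([_rec(1, 1.0)] * 5, "delta_gci") == 100.0
    rand = [r for r in _rand_records(rng) if r.delta_gci != 0]
    pct_neg = 100.0 * sum(1 for r in rand if r.delta_gci < 0) / len(rand)
    assert percent_positive(rand, "delta_gci") + pct_neg == pytest.approx(100.0)


def test_percent_positive_empty_is_undefined():
    with pytest.raises(UndefinedValueError):
        percent_positive([], "delta_gci")


@pytest.mark.parametrize(
    "dbp,dgc,label",
    [(-200, 1.5, "N/P"), (-200, -1.5, "N/N"), (200, -1.5, "P/N"), (200, 1.5, "P/P")],
)
def test_sign_class_definitions(dbp, dgc, label):
    assert classify(_rec(dbp, dgc)) == label


def test_classify_rejects_zero_component():
    with pytest.raises(ParameterError):
        classify(_rec(0.0, 1.0))


def test_class_frequencies_uniform_and_degenerate():
    recs = [_rec(-200, 1.5), _rec(-200, -1.5), _rec(200, -1.5), _rec(200, 1.5)]
    cc = class_frequencies(recs)
    assert all(v == pytest.approx(25.0) for v in cc.percentages.values())
    cc2 = class_frequencies([_rec(-200, 1.5)] * 8)
    assert cc2.percentages["N/P"] == 100.0
    assert sum(cc2.percentages.values()) == pytest.approx(100.0)


def test_multinomial_fixture_recovery(rng):
    probs = (0.6, 0.2, 0.05, 0.15)
    n = 2000
    draws = rng.choice(4, size=n, p=probs)
    sign = {0: (-1, 1), 1: (-1, -1), 2: (1, -1), 3: (1, 1)}
    recs = [_rec(200 * sign[d][0], 1.5 * sign[d][1]) for d in draws]
    cc = class_frequencies(recs)
    for lbl, p in zip(CLASS_LABELS, probs):
        sd = 100 * math.sqrt(p * (1 - p) / n)
        assert abs(cc.percentages[lbl] - 100 * p) <= 3 * sd


def test_antisymmetry_of_classes_and_percentages(rng):
    recs = [r for r in _rand_records(rng, 200) if r.delta_bpi != 0 and r.delta_gci != 0]
    swap = {"N/P": "P/N", "P/N": "N/P", "N/N": "P/P", "P/P": "N/N"}
    for r in recs:
        assert classify(r.reversed()) == swap[classify(r)]
    fwd = class_frequencies(recs)
    rev = class_frequencies([r.reversed() for r in recs])
    for lbl in CLASS_LABELS:
        assert fwd.counts[lbl] == rev.counts[swap[lbl]]
    assert percent_positive([r.reversed() for r in recs], "delta_gci") == pytest.approx(
        100.0 - percent_positive(recs, "delta_gci")
    )


# ---------------------------------------------------------------------------
# exact binomial
# ---------------------------------------------------------------------------

def _fraction_tail(k, n, p_num, p_den):
    num = sum(math.comb(n, i) * p_num**i * (p_den - p_num) ** (n - i) for i in range(k, n + 1))
    return Fraction(num, p_den**n)


def test_binomial_tail_basic_values():
    assert binomial_tail(3, 3, 0.25) == pytest.approx(0.25**3, abs=1e-15)
    assert binomial_tail(0, 10, 0.25) == 1.0
    assert binomial_tail(11, 10, 0.25) == 0.0


def test_binomial_tail_matches_exact_summation():
    for n in (1, 7, 100):
        for k in range(0, n + 1, max(1, n // 10)):
            for pn, pd in ((1, 4), (1, 2)):
                exact = float(_fraction_tail(k, n, pn, pd))
                assert binomial_tail(k, n, pn / pd) == pytest.approx(exact, abs=1e-12)


def test_binomial_tail_beta_identity_and_monotonicity():
    n, p = 400, 0.25
    tails = [binomial_tail(k, n, p) for k in range(n + 1)]
    assert all(a >= b for a, b in zip(tails, tails[1:]))
    for k in (1, 50, 100, 399):
        assert tails[k] == pytest.approx(float(special.betainc(k, n - k + 1, p)), abs=1e-12)


def test_binomial_invalid_null_probability():
    with pytest.raises(ParameterError):
        binomial_tail(1, 10, 1.5)


def test_top_class_test_variants():
    cc = ClassCounts("c", {"N/P": 59, "N/N": 20, "P/N": 6, "P/P": 15})
    p_rest = binomial_test_top_class(cc, null_p=0.25)
    assert p_rest == pytest.approx(float(_fraction_tail(59, 100, 1, 4)), abs=1e-12)
    p_second = binomial_test_top_class(cc, alternative="top-vs-second")
    assert p_second == pytest.approx(float(_fraction_tail(59, 79, 1, 2)), abs=1e-12)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def _bh_oracle(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, ps[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def test_fdr_examples_and_bruteforce(rng):
    assert adjust_fdr([0.03]) == [pytest.approx(0.03)]
    assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    for _ in range(10):
        ps = list(rng.random(rng.integers(1, 20)))
        assert adjust_fdr(ps) == pytest.approx(_bh_oracle(ps))
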