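"""RBH orthology: scoring, reciprocity, tie handling, tabular I/O, extension."""

import numpy as np
import pytest

from orthointron import (
    SimilarityHit,
    all_vs_all_hits,
    extend_to_introns,
    import_tabular_hits,
    reciprocal_best_hits,
)
from orthointron.errors import FormatError
from orthointron.orthology import LocalProteinScorer, best_hit_map, export_tabular_hits
from orthointron.seqmodel import GeneModel, IntronicSequence, SpeciesDataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length=60):
    return "".join(AA[i] for i in rng.integers(0, len(AA), length))


def _mutate(rng, protein, rate):
    out = list(protein)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        out[i] = AA.replace(out[i], "")[rng.integers(0, 19)]
    return "".join(out)


def test_identical_sequence_is_self_best_hit(rng):
    p = _random_protein(rng, 50)
    scorer = LocalProteinScorer()
    hits = all_vs_all_hits({"a": p}, {"b1": p, "b2": _random_protein(rng, 50)}, scorer=scorer)
    assert hits[0].subject_id == "b1"
    assert hits[0].score == max(h.score for h in hits)
    # self-alignment score is the maximum achievable against any subject
    assert hits[0].score == pytest.approx(scorer(p, p))


def test_unrelated_sequences_fall_below_score_floor(rng):
    a = {"a": _random_protein(rng, 30)}
    b = {"b": _random_protein(rng, 30)}
    assert all_vs_all_hits(a, b, score_min=100.0) == []


def test_empty_input_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert all_vs_all_hits({}, {"b": "MKL"}) == []


def test_ranking_matches_exhaustive_pairwise_oracle(rng):
    """all_vs_all on a 5x5 toy set orders hits exactly as brute-force scoring."""
    scorer = LocalProteinScorer()
    pa = {f"a{i}": _random_protein(rng, 40) for i in range(5)}
    pb = {f"b{i}": _random_protein(rng, 40) for i in range(5)}
    hits = all_vs_all_hits(pa, pb, scorer=scorer, score_min=0.0)
    for qid in pa:
        got = [(h.subject_id, h.score) for h in hits if h.query_id == qid]
        oracle = sorted(
            ((sid, scorer(pa[qid], pb[sid])) for sid in pb),
            key=lambda t: (-t[1], t[0]),
        )
        assert got == oracle


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _hit(q, s, score, ev=1e-30):
    return SimilarityHit(q, s, score, ev)


def test_symmetric_best_hits_pair_up():
    ab = [_hit("a1", "b1", 100), _hit("a2", "b2", 90), _hit("a1", "b2", 10)]
    ba = [_hit("b1", "a1", 100), _hit("b2", "a2", 90)]
    pairs = reciprocal_best_hits(ab, ba)
    assert {(p.gene_m, p.gene_z) for p in pairs} == {("a1", "b1"), ("a2", "b2")}


def test_non_reciprocal_hit_is_rejected():
    ab = [_hit("a1", "b1", 100)]
    ba = [_hit("b1", "a2", 100)]
    assert reciprocal_best_hits(ab, ba) == []


def test_tied_top_hits_drop_the_query():
    ab = [_hit("a1", "b1", 100), _hit("a1", "b2", 100)]
    ba = [_hit("b1", "a1", 100)]
    assert best_hit_map(ab) == {}
    assert reciprocal_best_hits(ab, ba) == []


def test_evalue_threshold_applies_to_imported_hits():
    ab = [_hit("a1", "b1", 100, ev=1e-5)]
    ba = [_hit("b1", "a1", 100, ev=1e-30)]
    assert reciprocal_best_hits(ab, ba, evalue_max=1e-10) == []


def test_rbh_equals_bruteforce_argmax_intersection(rng):
    """On random score tables, RBH = intersection of the two argmax maps."""
    for _ in range(20):
        na, nb = rng.integers(2, 15, 2)
        scores = rng.integers(1, 1000, size=(na, nb))
        ab = [_hit(f"a{i}", f"b{j}", s) for i, row in enumerate(scores) for j, s in enumerate(row)]
        ba = [_hit(f"b{j}", f"a{i}", s) for i, row in enumerate(scores) for j, s in enumerate(row)]
        pairs = {(p.gene_m, p.gene_z) for p in reciprocal_best_hits(ab, ba)}
        oracle = set()
        for i in range(na):
            row = scores[i]
            if (row == row.max()).sum() != 1:
                continue
            j = int(row.argmax())
            col = scores[:, j]
            if (col == col.max()).sum() == 1 and int(col.argmax()) == i:
                oracle.add((f"a{i}", f"b{j}"))
        assert pairs == oracle
        assert len(pairs) <= min(na, nb)


def test_rbh_is_symmetric_under_species_swap(rng):
    na, nb = 8, 10
    scores = rng.integers(1, 500, size=(na, nb))
    ab = [_hit(f"a{i}", f"b{j}", s) for i, row in enumerate(scores) for j, s in enumerate(row)]
    ba = [_hit(f"b{j}", f"a{i}", s) for i, row in enumerate(scores) for j, s in enumerate(row)]
    fwd = {(p.gene_m, p.gene_z) for p in reciprocal_best_hits(ab, ba)}
    rev = {(p.gene_z, p.gene_m) for p in reciprocal_best_hits(ba, ab)}
    assert fwd == rev


def test_mutated_copy_proteomes_recover_true_pairing(rng):
    pa = {f"a{i}": _random_protein(rng, 80) for i in range(30)}
    pb = {f"b{i}": _mutate(rng, pa[f"a{i}"], 0.05) for i in range(30)}
    ab = all_vs_all_hits(pa, pb)
    ba = all_vs_all_hits(pb, pa)
    pairs = reciprocal_best_hits(ab, ba)
    assert {(p.gene_m, p.gene_z) for p in pairs} == {(f"a{i}", f"b{i}") for i in range(30)}


def test_kmer_prefilter_preserves_true_pairing(rng):
    pa = {f"a{i}": _random_protein(rng, 80) for i in range(20)}
    pb = {f"b{i}": _mutate(rng, pa[f"a{i}"], 0.04) for i in range(20)}
    ab = all_vs_all_hits(pa, pb, kmer_prefilter=4, min_shared_kmers=2)
    ba = all_vs_all_hits(pb, pa, kmer_prefilter=4, min_shared_kmers=2)
    pairs = reciprocal_best_hits(ab, ba)
    assert {(p.gene_m, p.gene_z) for p in pairs} == {(f"a{i}", f"b{i}") for i in range(20)}


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def test_import_single_row(tmp_path):
    f = tmp_path / "hits.tsv"
    f.write_text("q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t185\n")
    (hit,) = import_tabular_hits(f)
    assert hit.query_id == "q1" and hit.score == 185.0 and hit.evalue == 1e-50


def test_import_rejects_wrong_column_count(tmp_path):
    f = tmp_path / "bad.tsv"
    f.write_text("q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\n")
    with pytest.raises(FormatError, match="line 1"):
        import_tabular_hits(f)


def test_tabular_round_trip(tmp_path):
    hits = [SimilarityHit("q1", "s1", 185.0, 1e-50), SimilarityHit("q2", "s9", 44.0, 0.001)]
    path = tmp_path / "rt.tsv"
    export_tabular_hits(hits, path)
    assert import_tabular_hits(path) == hits


# ---------------------------------------------------------------------------
# extension to introns
# ---------------------------------------------------------------------------

def _mini_ds(species, intron_lengths):
    genes, intr = {}, {}
    for i, L in enumerate(intron_lengths):
        gid = f"{species}_g{i}"
        genes[gid] = GeneModel(gid, species, "+", "c", [(0, 5), (10, 15)], [(0, 5), (10, 15)])
        intr[gid] = IntronicSequence(gid, species, "GCAT" * (L // 4), 1 if L else 0)
    return SpeciesDataset(species, genes, {}, {}, intr)


def test_extension_drops_intronless_pairs_with_count():
    from orthointron.orthology import OrthologPair

    ds_m = _mini_ds("m", [100] * 90 + [0] * 10)
    ds_z = _mini_ds("z", [100] * 100)
    pairs = [OrthologPair("m", "z", f"m_g{i}", f"z_g{i}") for i in range(100)]
    intron_pairs, dropped = extend_to_introns(pairs, ds_m, ds_z)
    assert len(intron_pairs) == 90 and dropped == 10


def test_extension_missing_gene_raises():
    from orthointron.errors import LookupMissError
    from orthointron.orthology import OrthologPair

    ds = _mini_ds("m", [100])
    with pytest.raises(LookupMissError):
        extend_to_introns([OrthologPair("m", "m", "m_g0", "nope")], ds, ds)
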