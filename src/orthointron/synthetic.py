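"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates a two-species ortholog set with a controlled
concomitant-change structure: each gene pair draws one of the four sign
classes (N/P, N/N, P/N, P/P) for (delta_bpi, delta_gci), and the two
intronic sequences are then constructed so the drawn class is realised
*exactly* — intron lengths are set directly and GC is laid down with exact
integer G+C counts, with magnitudes kept above the analysis filter
(|delta_bpi| >= 100 bases, |delta_gci| >= 0.1 points) except for a
configured fraction of deliberately sub-threshold pairs (constructed with
|delta_bpi| < 100, which the OR-filter removes regardless of GC).

Species z intronic GC is drawn from a skew-normal truncated to (5, 95) and
intron length from a log-normal — mirroring the right-skewed GC histograms
and heavy-tailed intron lengths of real fish genomes — while species m is
z plus the class-signed delta, so its marginal distribution is induced.
Proteins are random sequences point-mutated between the species so
reciprocal-best-hit orthology can rediscover the true pairing.  Oxygen
traces are linear depletions with Gaussian noise.  Identical seed and
config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .errors import ParameterError
from .metabolism import (
    RespirometryTrace,
    freshwater_alpha,
    freshwater_svp_kpa,
    oxygen_concentration,
    partial_pressure_o2,
    write_trace_tsv,
)
from .repeats import RepeatLibrary
from .seqmodel import GeneModel, IntronicSequence, SpeciesDataset, gc_content, reverse_complement

CLASS_LABELS = ("N/P", "N/N", "P/N", "P/P")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SynthConfig:
    """Generating parameters of a synthetic two-species ortholog set.

    Defaults are the study conditions of the analysis this package
    reproduces: a dominant N/P class with the complementary classes in
    realistic proportions, zebrafish/medaka-like intronic GC means,
    kilobase-scale log-normal intron lengths, 5% proteome divergence, 5%
    repeat load at 60% GC, and 1%-noise linear oxygen traces.
    """

    seed: int = 0
    n_genes: int = 2000
    class_probs: tuple[float, float, float, float] = (0.60, 0.20, 0.05, 0.15)
    species_m: str = "spm"
    species_z: str = "spz"
    # intronic GC (percent), skew-normal; z is drawn, m is z + delta
    gci_mean_z: float = 36.5
    gci_sd_z: float = 6.0
    gci_skew_z: float = 4.0
    gci_mean_m: float = 39.6
    gci_sd_m: float = 6.0
    gci_skew_m: float = 4.0
    # intron length of species z, log-normal (bases)
    bpi_lognormal_mu: float = math.log(2500.0)
    bpi_lognormal_sigma: float = 0.8
    # class-signed delta magnitudes (guarantee filter survival)
    delta_bp_lognormal_mu: float = 5.5
    delta_bp_lognormal_sigma: float = 1.0
    delta_gc_exp_scale: float = 1.5
    sub_threshold_fraction: float = 0.05
    # gene structure
    n_introns_max: int = 6
    min_intron_len: int = 40
    minus_strand_fraction: float = 0.3
    flank_len: int = 100
    # proteome
    protein_length: int = 150
    mutation_rate: float = 0.05
    # repeats
    repeat_insertion_rate: float = 0.05
    repeat_gc: float = 60.0
    # respirometry
    mr_lognormal_mu_m: float = math.log(350.0)
    mr_lognormal_mu_z: float = math.log(250.0)
    mr_lognormal_sigma: float = 0.25
    trace_noise_sd: float = 0.01
    trace_n_points: int = 200
    trace_fall_target: float = 0.15

    def __post_init__(self) -> None:
        if len(self.class_probs) != 4 or any(p < 0 for p in self.class_probs):
            raise ParameterError("class_probs must be four non-negative numbers")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ParameterError("class_probs must sum to 1")
        for name in ("sub_threshold_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0,1]")
        if not 0.0 <= self.repeat_insertion_rate <= 0.5:
            raise ParameterError("repeat_insertion_rate must lie in [0, 0.5]")
        if self.trace_fall_target > 0.2 + 1e-12:
            # still generatable, but downstream QC will flag such traces
            pass


@dataclass
class PairTruth:
    gene_m: str
    gene_z: str
    label: str  # class label, or "sub" for a constructed sub-threshold pair
    delta_bpi: float
    delta_gci: float
    bpi_m: int
    bpi_z: int
    gci_m: float
    gci_z: float


@dataclass
class SynthTruth:
    """Everything needed to score each downstream stage of the pipeline."""

    config: SynthConfig
    pairs: list[PairTruth] = field(default_factory=list)
    species_means: dict[str, dict[str, float]] = field(default_factory=dict)
    repeat_insertions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_mr0: dict[str, list[float]] = field(default_factory=dict)
    true_trace_slopes: list[float] = field(default_factory=list)

    @property
    def pairing(self) -> dict[str, str]:
        return {p.gene_m: p.gene_z for p in self.pairs}

    def class_counts(self) -> dict[str, int]:
        counts = {lbl: 0 for lbl in CLASS_LABELS}
        for p in self.pairs:
            if p.label in counts:
                counts[p.label] += 1
        return counts

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "pairs": [dataclasses.asdict(p) for p in self.pairs],
            "species_means": self.species_means,
            "repeat_insertions": {
                g: [list(iv) for iv in ivs] for g, ivs in self.repeat_insertions.items()
            },
            "true_mr0": self.true_mr0,
            "true_trace_slopes": self.true_trace_slopes,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

_BASE_GC = np.frombuffer(b"GC", dtype=np.uint8)
_BASE_AT = np.frombuffer(b"AT", dtype=np.uint8)


def _seq_with_exact_gc(rng: np.random.Generator, length: int, n_gc: int) -> str:
    """Random A/C/G/T string of given length containing exactly n_gc G+C."""
    if not 0 <= n_gc <= length:
        raise ParameterError("n_gc outside [0, length]")
    arr = np.empty(length, dtype=np.uint8)
    arr[:n_gc] = _BASE_GC[rng.integers(0, 2, n_gc)]
    arr[n_gc:] = _BASE_AT[rng.integers(0, 2, length - n_gc)]
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    return _seq_with_exact_gc(rng, length, int(round(length * gc)))


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, min_part: int
) -> list[int]:
    """Random composition of `total` into `parts` pieces each >= min_part."""
    if parts * min_part > total:
        raise ParameterError("cannot split: total too small for min_part")
    extra = total - parts * min_part
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1)) if parts > 1 else np.array([], int)
    bounds = np.concatenate(([0], cuts, [extra]))
    return [min_part + int(b2 - b1) for b1, b2 in zip(bounds[:-1], bounds[1:])]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), length))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = _AA.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def _skewnorm_sample(
    rng: np.random.Generator, mean: float, sd: float, shape: float, size: int
) -> np.ndarray:
    """Skew-normal draws with the requested mean/sd, truncated to (5, 95)."""
    delta = shape / math.sqrt(1.0 + shape**2)
    omega = sd / math.sqrt(1.0 - 2.0 * delta**2 / math.pi)
    loc = mean - omega * delta * math.sqrt(2.0 / math.pi)
    draws = _sps.skewnorm.rvs(shape, loc=loc, scale=omega, size=size, random_state=rng)
    return np.clip(draws, 5.0, 95.0)


# ---------------------------------------------------------------------------
# gene-pair construction
# ---------------------------------------------------------------------------

_SIGNS = {"N/P": (-1, +1), "N/N": (-1, -1), "P/N": (+1, -1), "P/P": (+1, +1)}


def _realise_gc_counts(
    bpi_z: int,
    bpi_m: int,
    gci_z_target: float,
    d_gc: float,
    enforce: bool,
    gc_threshold: float = 0.1,
) -> tuple[int, int]:
    """Integer G+C counts whose realised delta matches sign(d_gc), |d| >= 0.1.

    Rounding a real-valued GC target to base counts can flip or shrink a
    small delta; the m-side count is nudged one base at a time until the
    realised difference honours the drawn class (skipped for sub-threshold
    pairs where only the length axis is constrained).
    """
    n_gc_z = min(max(int(round(bpi_z * gci_z_target / 100.0)), 1), bpi_z - 1)
    gci_z = 100.0 * n_gc_z / bpi_z
    target_m = min(max(gci_z + d_gc, 0.5), 99.5)
    n_gc_m = min(max(int(round(bpi_m * target_m / 100.0)), 1), bpi_m - 1)
    if enforce:
        step = 1 if d_gc > 0 else -1
        while True:
            realised = 100.0 * n_gc_m / bpi_m - gci_z
            if realised * d_gc > 0 and abs(realised) >= gc_threshold:
                break
            n_gc_m += step
            if not 0 < n_gc_m < bpi_m:
                raise ParameterError("infeasible GC delta for this intron length")
    return n_gc_z, n_gc_m


def _assemble_gene(
    rng: np.random.Generator,
    gene_id: str,
    species_id: str,
    cds: str,
    intron_seq: str,
    n_introns: int,
    min_intron_len: int,
    flank_len: int,
    minus_strand: bool,
) -> tuple[GeneModel, str, str]:
    """Lay CDS exons and introns on a fresh contig; returns (model, contig, seqid).

    The contig is gene-sized: 5' flank + alternating exons/introns + 3'
    flank, reverse-complemented wholesale for minus-strand genes.
    """
    exon_lens = _split_lengths(rng, len(cds), n_introns + 1, 3)
    intron_lens = (
        _split_lengths(rng, len(intron_seq), n_introns, min_intron_len) if n_introns else []
    )
    parts = []
    sense_intervals: list[tuple[int, int]] = []
    pos = flank_len
    parts.append(_random_dna(rng, flank_len))
    ci = ii = 0
    for k, el in enumerate(exon_lens):
        parts.append(cds[ci : ci + el])
        sense_intervals.append((pos, pos + el))
        pos += el
        ci += el
        if k < n_introns:
            il = intron_lens[k]
            parts.append(intron_seq[ii : ii + il])
            pos += il
            ii += il
    parts.append(_random_dna(rng, flank_len))
    sense = "".join(parts)

    if minus_strand:
        contig = reverse_complement(sense)
        L = len(sense)
        intervals = [(L - e, L - s) for s, e in sense_intervals]
        strand = "-"
    else:
        contig = sense
        intervals = sense_intervals
        strand = "+"

    seqid = f"ctg_{gene_id}"
    model = GeneModel(
        gene_id=gene_id,
        species_id=species_id,
        strand=strand,
        seqid=seqid,
        exon_intervals=intervals,
        cds_intervals=list(intervals),
        transcript_id=f"{gene_id}.t1",
        sequence_source=contig,
    )
    return model, contig, seqid


def generate_species_pair(cfg: SynthConfig) -> tuple[SpeciesDataset, SpeciesDataset, SynthTruth]:
    """Generate two orthologous SpeciesDatasets with fully recorded truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    labels = [CLASS_LABELS[i] for i in rng.choice(4, size=n, p=list(cfg.class_probs))]
    n_sub = int(round(n * cfg.sub_threshold_fraction))
    sub_idx = set(map(int, rng.permutation(n)[:n_sub]))

    gci_z_targets = _skewnorm_sample(rng, cfg.gci_mean_z, cfg.gci_sd_z, cfg.gci_skew_z, n)
    z_order = rng.permutation(n)  # shuffle z ids so pairing is non-trivial

    truth = SynthTruth(config=cfg)
    mk = lambda sp: dict(genes={}, cds_seqs={}, protein_seqs={}, intronic_seqs={})
    store_m, store_z = mk(cfg.species_m), mk(cfg.species_z)

    for i in range(n):
        label = labels[i]
        sign_bp, sign_gc = _SIGNS[label]
        sub = i in sub_idx
        n_introns = int(rng.integers(1, cfg.n_introns_max + 1))
        floor_len = max(400, n_introns * cfg.min_intron_len)

        bpi_z = max(floor_len, int(round(rng.lognormal(cfg.bpi_lognormal_mu, cfg.bpi_lognormal_sigma))))
        if sub:
            d_bp = int(rng.integers(0, 100)) * (1 if rng.random() < 0.5 else -1)
        else:
            d_bp = sign_bp * (100 + int(round(rng.lognormal(cfg.delta_bp_lognormal_mu, cfg.delta_bp_lognormal_sigma))))
        bpi_m = bpi_z + d_bp
        if bpi_m < floor_len:
            bpi_z += floor_len - bpi_m
            bpi_m = floor_len

        d_gc = sign_gc * (0.1 + rng.exponential(cfg.delta_gc_exp_scale))
        n_gc_z, n_gc_m = _realise_gc_counts(
            bpi_z, bpi_m, float(gci_z_targets[i]), d_gc, enforce=not sub
        )
        intron_z = _seq_with_exact_gc(rng, bpi_z, n_gc_z)
        intron_m = _seq_with_exact_gc(rng, bpi_m, n_gc_m)

        protein_m = _random_protein(rng, cfg.protein_length)
        protein_z = _mutate_protein(rng, protein_m, cfg.mutation_rate)
        cds_m = _back_translate(rng, protein_m)
        cds_z = _back_translate(rng, protein_z)

        gid_m = f"{cfg.species_m}_g{i:05d}"
        gid_z = f"{cfg.species_z}_g{int(z_order[i]):05d}"
        minus_m = rng.random() < cfg.minus_strand_fraction
        minus_z = rng.random() < cfg.minus_strand_fraction

        for gid, sp, cds, prot, intron, minus, store in (
            (gid_m, cfg.species_m, cds_m, protein_m, intron_m, minus_m, store_m),
            (gid_z, cfg.species_z, cds_z, protein_z, intron_z, minus_z, store_z),
        ):
            model, contig, seqid = _assemble_gene(
                rng, gid, sp, cds, intron, n_introns, cfg.min_intron_len, cfg.flank_len, minus
            )
            store["genes"][gid] = model
            store["cds_seqs"][gid] = cds
            store["protein_seqs"][gid] = prot
            store["intronic_seqs"][gid] = IntronicSequence(
                gene_id=gid, species_id=sp, sequence=intron, n_introns=n_introns
            )

        gci_m_real = 100.0 * n_gc_m / bpi_m
        gci_z_real = 100.0 * n_gc_z / bpi_z
        truth.pairs.append(
            PairTruth(
                gene_m=gid_m,
                gene_z=gid_z,
                label="sub" if sub else label,
                delta_bpi=float(bpi_m - bpi_z),
                delta_gci=gci_m_real - gci_z_real,
                bpi_m=bpi_m,
                bpi_z=bpi_z,
                gci_m=gci_m_real,
                gci_z=gci_z_real,
            )
        )

    ds_m = SpeciesDataset(species_id=cfg.species_m, **store_m)
    ds_z = SpeciesDataset(species_id=cfg.species_z, **store_z)
    for ds, side in ((ds_m, "m"), (ds_z, "z")):
        bpis = [getattr(p, f"bpi_{side}") for p in truth.pairs]
        gcis = [getattr(p, f"gci_{side}") for p in truth.pairs]
        truth.species_means[ds.species_id] = {
            "mean_bpi": float(np.mean(bpis)),
            "mean_gci": float(np.mean(gcis)),
        }
    return ds_m, ds_z, truth


# ---------------------------------------------------------------------------
# repeat insertion
# ---------------------------------------------------------------------------

def make_repeat_library(
    rng_or_seed: np.random.Generator | int,
    n_elements: int = 3,
    length: int = 300,
    gc: float = 60.0,
) -> RepeatLibrary:
    """Random repeat consensi with the requested GC percent."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    elements = tuple(
        (f"REP{i}", _seq_with_exact_gc(rng, length, int(round(length * gc / 100.0))))
        for i in range(n_elements)
    )
    return RepeatLibrary(elements)


def insert_repeats(
    ds: SpeciesDataset,
    lib: RepeatLibrary,
    rate: float,
    seed: int,
    truth: SynthTruth | None = None,
) -> SpeciesDataset:
    """Splice library elements into each intronic sequence to a target load.

    ``rate`` is the target masked-bp fraction of the *final* sequence.  The
    returned dataset carries the lengthened introns (gene-model genomic
    coordinates are left untouched: masking statistics operate on the
    intronic-sequence view).  Insertion intervals are recorded in ``truth``.
    """
    if not 0.0 <= rate <= 0.5:
        raise ParameterError("rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    new_introns: dict[str, IntronicSequence] = {}
    insertions: dict[str, list[tuple[int, int]]] = {}
    for gid in sorted(ds.intronic_seqs):
        iseq = ds.intronic_seqs[gid]
        seq = iseq.sequence
        if rate == 0.0 or not seq:
            new_introns[gid] = iseq
            insertions[gid] = []
            continue
        target = rate / (1.0 - rate) * len(seq)
        pieces: list[str] = []
        inserted = 0
        min_frag = 30  # keeps every fragment well above the matcher's window
        while inserted < target:
            _, cons = lib.elements[rng.integers(0, len(lib.elements))]
            remaining = target - inserted
            frag_len = int(min(len(cons), max(min_frag, math.ceil(remaining))))
            start = int(rng.integers(0, len(cons) - frag_len + 1))
            frag = cons[start : start + frag_len]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            pieces.append(frag)
            inserted += frag_len
        positions = np.sort(rng.integers(0, len(seq) + 1, size=len(pieces)))
        out: list[str] = []
        intervals: list[tuple[int, int]] = []
        prev = 0
        offset = 0
        for pos, piece in zip(positions, pieces):
            out.append(seq[prev : int(pos)])
            start = int(pos) + offset
            intervals.append((start, start + len(piece)))
            out.append(piece)
            offset += len(piece)
            prev = int(pos)
        out.append(seq[prev:])
        new_introns[gid] = IntronicSequence(
            gene_id=gid,
            species_id=iseq.species_id,
            sequence="".join(out),
            n_introns=iseq.n_introns,
        )
        insertions[gid] = intervals
    if truth is not None:
        truth.repeat_insertions.update(insertions)
    return SpeciesDataset(
        species_id=ds.species_id,
        genes=ds.genes,
        cds_seqs=ds.cds_seqs,
        protein_seqs=ds.protein_seqs,
        intronic_seqs=new_introns,
        gcg=ds.gcg,
    )


# ---------------------------------------------------------------------------
# respirometry traces
# ---------------------------------------------------------------------------

def generate_trace(
    true_rate_ug_per_h: float,
    cfg: SynthConfig,
    rng: np.random.Generator | int | None = None,
    temperature_c: float = 26.0,
    salinity_ppt: float = 0.0,
    chamber_volume_l: float = 0.2,
    animal_mass_kg: float = 0.003,
    ap_kpa: float = 101.325,
    fall_target: float | None = None,
    species_id: str = "",
) -> tuple[RespirometryTrace, float]:
    """Linear oxygen-depletion trace plus Gaussian noise; returns (trace, slope).

    The duration is set so the chamber loses ``fall_target`` of its oxygen
    at the true rate; noise sd is ``trace_noise_sd`` of the reading range.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    if fall_target is None:
        fall_target = cfg.trace_fall_target
    svp = freshwater_svp_kpa(temperature_c)
    alpha = freshwater_alpha(temperature_c)
    sat_conc = oxygen_concentration(partial_pressure_o2(ap_kpa, svp), alpha)
    o2_total_0 = sat_conc * chamber_volume_l * 1000.0  # ug
    duration_h = fall_target * o2_total_0 / true_rate_ug_per_h
    t = np.linspace(0.0, duration_h, cfg.trace_n_points)
    pct = 100.0 * (1.0 - true_rate_ug_per_h * t / o2_total_0)
    noise_sd = cfg.trace_noise_sd * (100.0 * fall_target)
    if cfg.trace_noise_sd > 0:
        pct = pct + rng.normal(0.0, noise_sd, size=t.size)
    trace = RespirometryTrace(
        timestamps=t,
        readings=pct,
        chamber_volume_l=chamber_volume_l,
        water_temperature_c=temperature_c,
        salinity_ppt=salinity_ppt,
        ap_kpa=ap_kpa,
        svp_kpa=svp,
        alpha=alpha,
        animal_mass_kg=animal_mass_kg,
        reading_kind="percent_saturation",
        species_id=species_id,
    )
    return trace, true_rate_ug_per_h


def generate_mr_samples(
    cfg: SynthConfig,
    species_id: str,
    n_specimens: int = 10,
    rng: np.random.Generator | None = None,
    temperature_c: float = 26.0,
    animal_mass_kg: float = 0.003,
    truth: SynthTruth | None = None,
) -> list[RespirometryTrace]:
    """Per-specimen traces whose true mass-specific rates are log-normal."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mu = cfg.mr_lognormal_mu_m if species_id == cfg.species_m else cfg.mr_lognormal_mu_z
    true_mr0 = rng.lognormal(mu, cfg.mr_lognormal_sigma, size=n_specimens)
    traces = []
    for mr0 in true_mr0:
        rate_ug_h = mr0 * 1000.0 * animal_mass_kg
        trace, slope = generate_trace(
            rate_ug_h,
            cfg,
            rng=rng,
            temperature_c=temperature_c,
            animal_mass_kg=animal_mass_kg,
            species_id=species_id,
        )
        traces.append(trace)
        if truth is not None:
            truth.true_trace_slopes.append(slope)
    if truth is not None:
        truth.true_mr0.setdefault(species_id, []).extend(map(float, true_mr0))
    return traces


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_genome_files(ds: SpeciesDataset, outdir: str | os.PathLike) -> tuple[str, str]:
    """Emit genome FASTA + GFF3 for a generated dataset (loader-compatible)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, f"{ds.species_id}.fasta")
    gff = os.path.join(outdir, f"{ds.species_id}.gff3")
    with open(fasta, "w") as fh:
        for gid in sorted(ds.genes):
            gm = ds.genes[gid]
            fh.write(f">{gm.seqid}\n")
            contig = gm.sequence_source or ""
            for i in range(0, len(contig), 70):
                fh.write(contig[i : i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(ds.genes):
            gm = ds.genes[gid]
            gstart = min(s for s, _ in gm.exon_intervals) + 1
            gend = max(e for _, e in gm.exon_intervals)
            tid = gm.transcript_id or f"{gid}.t1"
            fh.write(
                f"{gm.seqid}\tsynth\tgene\t{gstart}\t{gend}\t.\t{gm.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{gm.seqid}\tsynth\tmRNA\t{gstart}\t{gend}\t.\t{gm.strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            for s, e in sorted(gm.exon_intervals):
                fh.write(
                    f"{gm.seqid}\tsynth\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\tParent={tid}\n"
                )
            for s, e in sorted(gm.cds_intervals):
                fh.write(
                    f"{gm.seqid}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{gm.strand}\t0\t"
                    f"ID=cds_{tid};Parent={tid}\n"
                )
    return fasta, gff


def emit_run_dir(cfg: SynthConfig, outdir: str | os.PathLike) -> dict[str, object]:
    """Generate a complete input bundle under one directory named by the seed."""
    outdir = os.path.join(str(outdir), f"run_seed{cfg.seed}")
    os.makedirs(outdir, exist_ok=True)
    ds_m, ds_z, truth = generate_species_pair(cfg)
    lib = make_repeat_library(np.random.default_rng(cfg.seed + 1), gc=cfg.repeat_gc)
    paths: dict[str, object] = {"outdir": outdir}
    paths["fasta_m"], paths["gff_m"] = write_genome_files(ds_m, outdir)
    paths["fasta_z"], paths["gff_z"] = write_genome_files(ds_z, outdir)
    libpath = os.path.join(outdir, "repeat_library.fasta")
    lib.to_fasta(libpath)
    paths["repeat_library"] = libpath
    tracedir = os.path.join(outdir, "traces")
    os.makedirs(tracedir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 2)
    for sp in (cfg.species_m, cfg.species_z):
        for j, trace in enumerate(
            generate_mr_samples(cfg, sp, n_specimens=5, rng=rng, truth=truth)
        ):
            write_trace_tsv(trace, os.path.join(tracedir, f"{sp}_specimen{j}.tsv"))
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json())
    paths["truth"] = truth_path
    paths["datasets"] = (ds_m, ds_z, truth)
    return paths
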