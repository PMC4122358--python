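# Methods

## Problem and model

`orthointron` implements an inter-genome comparative analysis of intron
architecture.  For two species *m* and *z*, each one-to-one orthologous gene
pair contributes the signed differences of its concatenated internal
introns,

    Δbpi = bpi_m − bpi_z        (bases)
    ΔGCi = GCi_m − GCi_z        (GC percentage points),

where *internal* introns are those lying between CDS-containing exons of
the selected transcript (introns wholly within 5′/3′ UTR regions are
flanking and discarded).  The scientific question is whether the two
variables change concomitantly: each filtered pair falls into one of four
sign classes (N/P, N/N, P/N, P/P, first letter for Δbpi), and a dominant
N/P class — introns shorter *and* GC-richer in the first species — is the
signature of a joint constraint on intron length and composition.  The
species-level covariate is routine metabolic rate from closed-chamber
respirometry, temperature-corrected by the Boltzmann factor
MR = MR₀·e^{E/kT}.

## Pipeline stages and the choices behind them

**Gene models.**  One transcript per gene: the longest total CDS, ties
broken by lexicographic transcript id (determinism; annotation sources do
not mark a canonical transcript consistently).  Coordinates are 0-based
half-open internally; GFF3 is converted from 1-based inclusive on load.
The internal-intron rule is switchable (`convention="drop-terminal"`
drops the first and last intron of the transcript instead) because the
"flanking introns" reading admits both interpretations; the CDS-span rule
is the default since orthology is anchored on the CDS.

**GC content** is 100·(G+C)/(A+C+G+T), case-insensitive, with N and every
other non-ACGT symbol excluded from numerator and denominator — so
hard-masked bases never dilute the statistic.  Raw-input QC is stricter:
any non-ACGT character (including N) marks a sequence as ambiguous, and
CDS with frames not divisible by three or with internal stop codons are
removed before orthology.

**Orthology.**  Reciprocal best hits on proteins.  The built-in scorer is
Smith–Waterman local alignment, BLOSUM62, affine gaps (open 11, extend 1)
via Biopython's `PairwiseAligner`.  It reports raw scores, not e-values:
e-value calibration is deliberately out of scope, so a raw-score floor
(default 50) gates built-in hits while the conventional e ≤ 1e-10
threshold gates hits imported from an external aligner's 12-column
tabular format.  Ties for the best hit drop the gene, preserving the
one-to-one guarantee.  An optional shared-k-mer prefilter (word size 4,
≥ 2 shared words) restricts alignment to seeded pairs — the same idea as
word-based seeding in standard search tools — and makes genome-scale
all-vs-all feasible; it is off by default so that small-scale results
match the exhaustive pairwise oracle exactly.

**Repeat masking.**  The built-in matcher hard-masks every exact
occurrence, on either strand, of any window of length ≥ `min_match`
(default 15) from a repeat-library consensus, plus single-base runs
≥ 20 bp.  Because any longer exact match contains a window of exactly
`min_match`, scanning one window length recovers the full masked
footprint; candidate positions come from a vectorised 64-bit rolling
polynomial hash and are verified by string comparison, so there are no
hash-collision false positives.  This matcher does not claim
alignment-level fidelity to dedicated repeat-masking tools — the importer
for external interval lists or soft-masked FASTA is the high-fidelity
path.  For "after masking" analyses the masked bases are *removed*, so
bpi shrinks and GCi is recomputed over surviving bases; the exact
decomposition bpi·GCi_before = masked_bp·masked_GC + remaining_bp·GCi_after
is a tested identity.

**Filtering and classes.**  Pairs with |ΔGCi| < 0.1 points OR
|Δbpi| < 100 bases are removed (strict inequalities: boundary values are
retained).  The OR reading keeps only pairs informative on both axes,
which is what the joint four-class analysis needs; AND is available as a
switch.  Dominance of the top class is tested with an exact one-sided
binomial upper tail P(X ≥ k_top), computed by direct pmf summation in
log-gamma space with compensated summation (no normal approximation at
any n; verified against exact rational arithmetic to 1e-12 and against
the regularized-incomplete-beta identity).  The default null is a uniform
p₀ = 1/4 over the four classes; a top-vs-second alternative (p₀ = 1/2 on
the union of the two leading classes) is behind a flag.
Benjamini–Hochberg adjustment is applied across the whole family of
comparisons × masking variants.

**Respirometry.**  pO₂ = (AP − SVP)·0.2096; [O₂] = pO₂·α; total chamber
oxygen in µg is concentration × volume × 1000; the consumption rate is
the negated OLS slope of total oxygen vs time.  The first 10% of each
trace is trimmed by default (probe/animal adaptation period,
configurable).  Traces falling more than 20% are flagged invalid, and a
non-falling trace is a hard quality error.  The Boltzmann correction uses
E = 0.65 eV (the canonical activation energy of the metabolic-theory
framework, configurable) and k = 8.62e-5 eV/K, multiplying MR₀ by
e^{E/kT} exactly as written; the factor is numerically enormous (~1.5e11
at 20 °C) but cancels in every ratio, rank and significance statistic
downstream.  SVP and α should be supplied per measurement; the built-in
freshwater approximations are convenience only and not a calibration.

**Statistics.**  Skewness is the Fisher–Pearson moment coefficient
g1 = m₃/m₂^{3/2} (bias-corrected variant switchable).  Spearman's rho is
the Pearson correlation of mid-ranks (tie-aware); its p-value uses the
t-approximation with n−2 degrees of freedom by default, with an exact
permutation option for n ≤ 10 (the sample sizes at which the
approximation is weakest).  The SNK test ranks group means on a one-way
ANOVA error mean square and steps down the studentized range, sealing any
span found non-significant; critical values are computed numerically from
the studentized-range distribution rather than transcribed from tables,
and unequal group sizes use the harmonic pairwise standard error.  Under
the complete null the stepwise scheme rejects only if the full-range test
rejects, so the family-wise error stays at the nominal level (checked by
simulation: ≤ 0.08 at α = 0.05).

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes, with recorded
ground truth.  Its defaults are the study conditions used throughout the
tests: class probabilities (0.60, 0.20, 0.05, 0.15) for (N/P, N/N, P/N,
P/P); species-z intronic GC from a skew-normal (mean 36.5, sd 6, shape 4
— zebrafish-like, right-skewed as real GCi histograms are) truncated to
(5, 95); intron length log-normal with median 2.5 kb (sd of log 0.8);
delta magnitudes |Δbpi| = 100 + LogNormal(5.5, 1) bases and
|ΔGCi| = 0.1 + Exp(1.5) points, which guarantees filter survival; a 5%
sub-threshold fraction constructed with |Δbpi| < 100 (removed by the OR
filter regardless of GC); 150-aa proteins point-mutated at 5% between
species; 5% repeat load at 60% GC; oxygen traces of 200 points with
Gaussian noise at 1% of the reading range and a 15% oxygen fall.

Two construction details matter for exactness.  GC is laid down with
exact integer G+C counts, and the m-side count is nudged base by base
until the realised ΔGCi honours the drawn class sign and magnitude — so
drawn class labels are realised *by construction*, not just in
expectation.  Species m's GC is z's plus the signed delta, so its
marginal distribution is induced rather than drawn; the per-species
skew-normal parameters for m drive only standalone single-species
generation.

The generator does **not** simulate molecular evolution (uniform point
mutation only, no substitution model, no indels in proteins), intron gain
or loss, isochore spatial structure along chromosomes, alternative
splicing, or probe drift in respirometry beyond white noise.  Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims on data with known structure — not that real genomes satisfy the
generator's assumptions.

## Numerical choices

- Binomial tails: log-gamma term evaluation + `math.fsum`; max absolute
  error vs exact rational summation < 1e-12 over all n ≤ 200.
- Studentized-range quantiles from `scipy.stats.studentized_range.ppf`,
  cached per (span, df).
- Rolling-hash matching uses a 64-bit polynomial hash with explicit
  string verification of candidates.
- Degenerate inputs raise typed errors rather than returning sentinels:
  GC of an all-N sequence, skewness/Spearman of constant vectors,
  zero-variance SNK configurations, rising oxygen traces.
- Problem sizes in the tests and in `scripts/acceptance.py` (2000 gene
  pairs for class recovery, 200 genes for masking recovery, 1000 SNK
  null simulations, 20 toy proteomes for the RBH oracle) were chosen as
  the smallest sizes at which the binomial/Monte-Carlo tolerances are
  meaningful.

## Known limitations

- Pairwise deltas among more than two species are not phylogenetically
  independent; no independent-contrasts correction is applied (the
  Spearman correlations across comparisons must be read accordingly).
- The built-in repeat matcher finds exact copies only; diverged repeats
  require an external mask.
- The built-in aligner produces no e-values; the e-value threshold is
  meaningful only for imported hit tables.
- Whether "after masking" lengths should drop masked bases or whole
  masked sequences is a convention; this package drops bases.
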