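# Methods

This note documents the models and procedures `musaqc` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and conventions

All positions are 1-based; intervals are half-open `[start, end)` (the VCF
convention).  Depth windows and thresholds written "between x and y" or
"≥ x" are inclusive, matching the MIN()/MAX()-style filter expressions they
mirror.

## Synthetic allopolyploid generator

The generator emulates the data situation of resequenced *Musa* accessions
aligned to an A-genome reference.

* **Subgenomes.** The A reference is uniform random nucleotide sequence;
  the B subgenome substitutes each position independently with probability
  `divergence_rate` (default 0.005/bp — a free simulation parameter chosen
  to give the ~0.5% interspecific SNP density typical of congeneric plant
  genomes; it is not an empirical estimate for *Musa*), to one of the three
  other bases uniformly.  Short (1–3 bp) B-private indels are placed at
  `indel_rate` per bp; they are stored as annotations on a shared
  coordinate system rather than applied to the sequence, because the
  pipeline consumes per-position pileups in reference coordinates, where a
  B indel manifests only as indel read support.  Their sole purpose is to
  exercise the indel-gap and IDV filters.
* **Accessions.** A composition string over {A, B} (length 2–4) selects
  the subgenome of each chromosome copy.  Homeologous-exchange segments
  replace an interval of one copy with the homeologous sequence of the
  donor subgenome.  Per-site B dosage (always k/ploidy) is recorded as
  truth for every divergent site.
* **Reads.** Sequencing is simulated column-wise: depth is
  Poisson(`mean_depth`, default 30×, inside the 20–60× range the pipeline
  targets); each read draws its source copy uniformly, takes that copy's
  base and is miscalled to a uniformly chosen other base with probability
  `error_rate` (default 0.005).  There is no read-pair or fragment
  structure, no quality strings, no mapping ambiguity — every downstream
  stage consumes pileup columns, so fragment-level realism would add
  nothing testable.  Under this model the expected B-base fraction at a
  site of dosage d is `d(1−e) + (1−d)e/3`, which the tests verify
  empirically.
* **Het-site generator.** For ploidy work a direct generator produces
  heterozygous-site columns of a known ploidy p: dosage k/p with k uniform
  on 1..p−1, fixed depth (isolating the allele-frequency signal from
  coverage variation), binomial read support.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mapping errors and repeats (beyond the uniform
haze injected in de-noising tests), reference bias, within-subgenome
polymorphism (all A copies are identical, so simulated autopolyploids have
no heterozygous sites and their ploidy is reported as undetermined rather
than estimated; hybrid accessions do carry het sites at the A/B divergent
positions), GC or platform-specific error profiles, and structural
variation other than the simulated exchanges.

## Variant calling and QUAL

A pileup column becomes a substitution call when at least `min_alt_reads`
(default 2) non-reference bases are observed, and an indel record when any
read supports an indel (its credibility is judged downstream by the IDV
threshold).  QUAL is the phred-scaled probability that all alternate reads
are errors, `−10·log10 P(X ≥ n_alt)` with `X ~ Binomial(depth,
error_rate)`, capped at 999 so error-free simulations stay finite.  This is
deliberately *not* a re-implementation of the bcftools multiallelic caller:
it is monotone in the same quantities (more alternate support → higher
QUAL, higher assumed error → lower QUAL), fully specified, and checkable
against an exhaustive binomial-tail summation, which is what a
threshold-based filter chain needs.  A maximum-likelihood diploid genotype
is emitted for VCF completeness but never used: in polyploids the signal is
allele depth, not genotype.

## Filter chain and diagnostic SNPs

Filters: QUAL ≥ 35, DP ≥ 5, indel records excluded, and no credible indel
(IDV ≥ 2) within 100 bp.  "Within" is inclusive: a SNP exactly 100 bp from
an indel is excluded.  Distance is measured to the indel's anchor position,
ignoring its length — an approximation that errs by at most the 1–3 bp of
the simulated indels.  Low-support indels (IDV < 2) neither pass the filter
nor trigger the gap rule.  The pass is idempotent and monotone in every
threshold (property-tested).

A filtered SNP from the B accession becomes *diagnostic* when the major
alternate base makes up at least `hom_fraction` (default 0.9) of the called
bases — apparent homozygous divergence.  Sites segregating within
*M. balbisiana* fail this cut and are excluded, since they cannot attribute
reads to a subgenome.  Multiallelic sites contribute only their major
alternate as the B allele.

## Dosage painting

Percent-B is computed only at diagnostic sites with depth in [10, 50]
(inclusive); reads supporting a third allele are excluded from numerator
and denominator.  Smoothing is LOESS — locally weighted polynomial
regression with tricube weights over the nearest `ceil(span·n)` neighbours,
no robustness iterations — applied per chromosome, on the raw percentages,
unweighted by depth (a depth-weighted variant exists behind a flag).
Defaults: `span = 0.5`, `degree = 2`.  Span is the single most consequential
smoothing parameter: the effective bandwidth is roughly `span × chromosome
length`, which is also the breakpoint uncertainty to expect when an
exchange segment is painted; for breakpoint work on megabase chromosomes a
span of ~0.1 is more appropriate, and the CLI exposes it.  Smoothed values
are clamped to [0, 100] before painting into A-like (< 33), mixed (33–66)
and B-like (≥ 66) bands, half-open at the boundaries.

The implementation is an in-package local polynomial fit (no Python LOESS
with degree-2 support exists); it reproduces constants and collinear data
exactly, matches an independent weighted-least-squares oracle to 1e-8, and
matches `statsmodels` lowess (the degree-1 special case) to the same
tolerance.  When tricube weights leave fewer than `degree + 1` points with
positive weight, the local degree is reduced to keep the design matrix full
rank.

## Ploidy model

Heterozygous-site allele frequencies are extracted from columns whose two
best-supported bases each have ≥ `min_minor_reads` (default 3) reads and
depth ≥ `min_depth` (default 10, mirroring the dosage window's lower
bound).  The fraction is polarised against the reference — the non-reference
share of the top-two counts — so AAB-type sites sit near 1/3 and ABB-type
near 2/3.

De-noising fits a free three-Gaussian + uniform(0,1) mixture by EM and
drops sites whose posterior mass on the uniform component exceeds 0.5.
Limitation, measured on labelled simulations: because the Gaussian means
are free, the maximum-likelihood fit legitimately lets side components
absorb part of a uniform haze that overlaps the frequency clusters, so
~20% injected contamination is reduced to ~11% of the retained set, not
eliminated; clean sites are retained at ≥ 99%.  Even an oracle posterior
rule cannot do much better, since haze under a cluster is genuinely
indistinguishable site by site.

The ploidy fits are shared-σ Gaussian mixtures with means fixed at {1/2}
(diploid), {1/3, 2/3} (triploid), {1/4, 1/2, 3/4} (tetraploid), weights
free; the reference model frees the means too.  All fits are EM (tolerance
1e-7 on the log-likelihood, ≤ 500 iterations); the free model is restarted
from the canonical means, seeded data quantiles, and — crucially — an
exact-likelihood embedding of each converged fixed model, which guarantees
`logL(free) ≥ logL(fixed)` by EM monotonicity and keeps every
ΔlogL = logL(free) − logL(fixed) non-negative.  Gaussians are not
truncated to (0,1): for σ ≤ 0.15 (any depth ≥ ~10) the mass outside the
interval is negligible and the approximation keeps fixed and free models
exactly comparable.  σ is floored at 1e-4 with a warning.

**Model selection.** The inferred ploidy minimises ΔlogL.  The fixed models
are nested — the tetraploid mean set contains the diploid's — so with free
weights a higher-ploidy model can always tie a lower one and will typically
edge it out by a few nats of pure overfitting (its spare components absorb
sampling noise in the tails).  Genuine ploidy signal, by contrast,
separates models by hundreds to thousands of nats at realistic site counts.
Deltas within `ln(n_sites)` of the minimum (the BIC penalty scale for the
extra mixture weights) are therefore treated as ties and resolved toward
the lower ploidy, with a logged warning.  Without this margin, every clean
diploid would be called tetraploid on a sub-nat likelihood difference — a
bias this model family shares with the tooling it re-implements, which is
known to call highly heterozygous or noisy diploids as higher ploidies.
Fewer than 50 usable sites yields an explicit *undetermined* result, never
a default.

## Reconciliation

Genome-wide composition is inferred from the median of the smoothed %B
values: below `pure_threshold` (default 5%, a documented choice — "pure"
has no canonical operational definition) the accession is *exclusively A*,
above 95% *exclusively B*; otherwise the B copy number is
`round(ploidy · %B / 100)` (half rounds up), using the observed ploidy when
determined and the expected ploidy otherwise.  The verdict is `Yes` exactly
when the inferred composition matches one of the expected alternatives
("AAB or ABB" matches either; pure-A/B calls match expectations without the
other subgenome).  Ploidy disagreements alone never flip a verdict — a
correct composition at an unexpected ploidy still identifies the right
taxon — and are surfaced in a separate column instead.  A pure-A result
against a hybrid expectation produces the mis-identification verdict
`No: appears to be exclusively A`.

## Pipeline problem sizes and determinism

The packaged end-to-end runs use 2 × 150 kb chromosomes at 0.005
divergence (~1500 diagnostic sites), 30× depth and 0.005 error; the
acceptance checks use 1 Mb for SNP recovery, a 6 Mb chromosome for
exchange painting, and 100 × 5000-site accessions for ploidy recovery —
sizes at which every recovery statistic is comfortably estimated while a
full run stays around two minutes on one CPU.  Target-accession pileups
are simulated only at the diagnostic positions, which is exactly the
information the dosage and ploidy stages consume.  All stage seeds derive
from one root seed via seed-sequence spawning; identical configurations
reproduce every output file byte for byte.
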