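# Methods

`contamkit` quantifies and corrects cross-contamination in multi-sample
sequencing projects at three levels: a barcode-based screen for
between-species contamination, a read-count statistic for within-species
allele leakage, and a contamination-aware genotype caller whose output
feeds standard population-genomic estimators. A permutation-test layer
links detected contamination to laboratory metadata. This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic data do and do not establish.

## Between-species screen (barcode module)

Reads are aligned ungapped to an aligned panel of equal-length barcode
sequences (cox1-style, one or more sequences per species, headers
`id|species|component`). Every offset on both strands of every reference
is scanned; the best placement is the one with fewest mismatches, subject
to a mismatch tolerance of 1 for reads of at most 50 bp and 2 otherwise
(the tolerances of short-read mappers at these read lengths). Ambiguous
bases count as mismatches; ties among equally good placements are broken
uniformly with a caller-supplied seeded generator, so runs are exactly
reproducible (a deliberate difference from mappers that break ties with an
unseeded RNG). Reads shorter than 30 bp are uninformative at these
tolerances and are skipped. Ungapped alignment is a documented limitation:
indel-containing barcode reads are missed, which is acceptable for a
screen whose references are a few hundred base pairs.

Hits are tallied per species and normalized per million reads of the
sample. Two species are a *diagnostic* pair when the minimum p-distance
(pairwise deletion over unambiguous positions) between any two of their
panel sequences is at least the divergence threshold (default 5%,
robustness variant 10%); hits between non-diagnostic species are never
counted as contamination, because read mapping cannot attribute them
reliably. For each sample, hits split into expected (own species),
unexpected (diagnostic foreign species) and non-diagnostic; a sample whose
unexpected:expected prevalence ratio exceeds 1 is flagged dubious
(mislabeling or misidentification candidates).

The directed contamination matrix **M** has one row per potential
contaminant species and one column per sampled species; a cell is 1 when
at least `min_reads` (default 1, robustness variant 10) unexpected reads
from the column species hit references of the row species, 0 otherwise,
and missing for non-diagnostic pairs, self-pairs and unsampled columns.
The overall contamination proportion `p` is the share of ones among
non-missing cells.

## Within-species leakage (quartet and leakage modules)

The atomic observation is the *quartet*: the A/C/G/T read counts of one
individual at one position. A *homo-quartet* has exactly two observed
states, a major state with strictly more than 40 reads and a minor state
with exactly one read — a presumed homozygote carrying a single erroneous
or foreign read. Positions are classified from counts pooled over all
individuals (the focal individual included): *monoallelic* when the major
state strictly exceeds 95% of the pooled total, *biallelic* when the
second-ranked state strictly exceeds 10 reads per genotyped individual;
everything else is disregarded. Ties for the second rank are broken in
fixed base order A < C < G < T and counted.

At monoallelic positions the minor states of homo-quartets estimate the
error matrix **P** (row-normalized minor-state prevalence given the major
state); rows without observations are undefined and excluded downstream
with a logged counter. At biallelic positions, `q_obs` is the fraction of
homo-quartets whose minor state equals the other segregating allele z, and
`q_exp` is the error-matrix prediction of that fraction; since each
defined row of **P** sums to 1, `q_exp` equals the mean of P(a, z) over
scorable records (asserted as an exact identity in the tests). The allele
leakage index is λ = (q_obs − q_exp)/q_exp: zero in expectation without
contamination, positive when reads leak between individuals. Biallelic
homo-quartets whose major state is neither of the two segregating alleles
have no well-defined z and are excluded (counted); per-species λ is
reported when at least 50 biallelic homo-quartets exist (configurable).

The between-group variant λ′ restricts to homo-quartets at positions
biallelic in the whole sample but monoallelic — same 95% rule applied to
the group-restricted totals — within the focal individual's group (e.g.
shipment batch). There the coinciding minor allele can only have come from
outside the group, so λ′ isolates between-batch leakage. Numerators and
denominators pool across species, each record scored against its species'
own **P**.

The error-class summary pools complementary substitution classes (read
strand is unknown, so X→Y and its reverse complement are
indistinguishable) and reports a composition-corrected
transition:transversion ratio: observed counts are divided by their
expectation under uniform errors given the major-state composition, and
the ratio is rescaled so that random errors give 0.5 (every base has one
transition and two transversion partners, so the composition term cancels
for this particular ratio). The A→C|T→G share among transversions is
reported both as an enrichment (random = 1) and as a corrected count ratio
(random = 1/3). The correction formula is this package's own definition,
stated here because published analyses that correct such ratios for
composition rarely spell one out; it is unit-tested against its own
definition only.

## Contamination-aware genotyping (genotyping module)

The likelihood of a quartet R at a position with population allele
frequencies f is a multinomial mixture over the ten unordered diploid
genotypes with Hardy-Weinberg weights (f_y² for homozygotes, 2 f_y f_z for
heterozygotes — the factor 2 is switchable, and on by default). Per-read
state probabilities use a 4×4 error matrix E with distinct transition
(ε_ts) and transversion (ε_tv) rates: E[a,a] = 1 − (ε_ts + 2ε_tv). With
contamination probability γ, a read comes from the focal genotype with
probability 1 − γ and from the pool of the other individuals' reads with
probability γ:

    q_x[yz] = (1 − γ)·(E[y,x] + E[z,x])/2 + γ·Σ_w f′_w E[w,x]

where f′ is the read-frequency vector at the position excluding the focal
individual. Contaminant reads are themselves subject to sequencing error
(the E inside the sum). With a single ε this is the classical genotyping
model plus the contaminant term, and γ = 0 recovers it bit-for-bit
(regression-tested). Quartets with no non-focal reads fall back to γ = 0.

Allele frequencies f are the pooled read frequencies across individuals —
the simplest estimator consistent with read-count data; states without
reads get frequency 0. Error rates are estimated by bounded L-BFGS-B
maximization of the total log-likelihood (three fixed starting points,
ftol 1e-8, bounds [0, 0.2] per rate); the multinomial coefficient is
dropped during optimization (parameter-free) and added back for reporting
so likelihoods are proper and comparable across γ. Genotypes are called at
the posterior mode when it reaches the threshold (default 0.95, the usual
convention of genotype-calling pipelines for these data), otherwise
no-call; zero-coverage quartets are never called. A SNP is a position with
at least two distinct alleles among called genotypes. γ is selected on the
grid {0, 0.05, 0.1, 0.2} by profile likelihood with ε refit per value;
ties resolve to the smaller γ (parsimony) and are logged. An optional
numba JIT accelerates the likelihood kernel; a pure-numpy path computes
identical values (tested) when numba is unavailable.

The model assumes a single γ shared by all individuals, multinomial read
counts (no overdispersion), and independence across positions. Processes
such as hidden paralogy, allele-specific expression or error hotspots can
mimic leakage and inflate γ̂ on real data; the γ estimate should be read
as an upper bound on read-level contamination.

## Population-genomic statistics (popgen module)

From called genotypes over an in-frame coding reference: per-site
diversity is the unbiased heterozygosity (m/(m−1))(1 − Σp̂²) with m the
called allele copies at the site (equal to the mean pairwise difference
among copies; verified against an all-pairs oracle). Synonymous and
non-synonymous site counts follow Nei-Gojobori fractional counting under
the standard genetic code; mutations to stop codons count as
non-synonymous, reference stop codons are rejected by default and skipped
(with their SNPs) when summarizing synthetic references. π_S and π_N are
ratios of sums (Σ site-π over the class / class site count) — stable when
SNPs are few; F_IT = 1 − ΣH_obs/ΣH_exp across SNPs; Tajima's D uses the
textbook constants with m set to the median per-site called copy number
(per-site weighting available). Tri-allelic sites are classified against
the major allele and flagged.

### Sensitivity of the estimators to γ, and the role of coverage

On data simulated with leakage, calling at γ = 0 inflates observed
heterozygosity (F_IT biased negative) at every coverage tested, and
calling at the generating γ removes the excess — the F_IT direction is
robust. The π_S direction is coverage-dependent: at moderate coverage
(20-30×, typical of transcriptome-wide sites) uncorrected calling inflates
π_S and the correction deflates it monotonically in γ, together with the
SNP count; at deep coverage (≳60×) the dominant error mode flips —
rare-allele homozygotes are confidently miscalled as heterozygotes, which
skews allele frequencies toward the major allele and *deflates* the
frequency-based π̂ — so the sign of the π_S bias reverses. The diversity
sensitivity analyses in this package therefore run at coverage 25 with 80%
monomorphic sites; the acceptance checks state their problem sizes
explicitly.

## Metadata tests (labmeta module)

Per-species processing periods run from first entry to last shipment.
Five pair predictors — lab_overlap (days of period intersection),
same_technician, same_shipment (same day to the same center),
same_flowcell, same_lane — are nested by construction (lane ⊆ flowcell ⊆
shipment). The observed statistic of a predictor is its mean over
contaminated (value-1) cells of **M**. Nulls are cellwise Bernoulli
randomizations that never touch missing cells: unconditional with the
overall p, or conditional with stratum-specific probabilities (strata from
one or more predictors; the continuous lab_overlap is cut at its quartiles
— the conditioning scheme is this package's choice). Empirical p-values
use the add-one estimator (k+1)/(n+1), upper tail by default. The
LAB factor is positive when a pair shares a technician and overlaps more
than 200 days (the threshold direction is exposed as a flag because both
conventions appear in the literature of the motivating dataset); the
CENTER factor tiers same-shipment pairs by flowcell and lane sharing and
is reported cumulatively (same shipment ⊇ same flowcell ⊇ same lane), with
a disjoint-tier option. Pairs lacking flowcell/lane information are
excluded from tiered analyses. The one-species-per-(technician, shipment)
subsampling control removes the induced correlation between technician and
shipment sharing; species spanning several strata are assigned to their
earliest stratum by default.

Randomization on directed cells with symmetric pair predictors means a
mutually contaminating pair contributes twice to the statistic — the
natural weighting when each directed event is an observation.

## Synthetic data (simulate module)

`simulate_quartet_dataset` draws biallelic sites with minor-allele count
classes weighted 1/i (neutral-like folded spectrum), a configurable
monomorphic fraction (default 0.8), Hardy-Weinberg genotypes with optional
inbreeding F, Poisson coverage, and per-read errors with distinct ts/tv
rates. Leakage is simulated at the read level: with probability γ a read
is replaced by a state drawn from the pooled pre-leakage reads of the
other individuals — the generative mirror of the calling model's f′ term
(second-order leakage of already-leaked reads is not modeled).
`leak_groups` confines the donor pool to the focal individual's group to
emulate batch-restricted contamination. Default calibration sizes are 6
individuals × 20,000 positions at coverage 60 with ε_ts = 0.003,
ε_tv = 0.001 (coverage well above the 40-read homo-quartet cutoff, so the
leakage statistics have data to work with).

`simulate_barcode_experiment` builds a panel of species barcodes by
mutating a common ancestor (independent lineages ~12% diverged; optional
near-duplicate species below the 5% mask threshold to exercise
non-diagnostic handling), generates genuine barcode reads at a configured
per-million prevalence, and injects contaminant reads between species
according to metadata relations (same shipment/flowcell/lane/technician →
per-million injection rates). Only barcode-derived reads are materialized;
the nominal library size enters the per-million normalization.
`simulate_metadata` assigns species round-robin and independently to
shipments and technicians, with lanes nested in flowcells nested in
shipments.

What the simulations do not emulate: expression-level variation in
coverage, linkage between sites, overdispersed read counts, paralogy,
index-hopping structure, or panel gaps/ambiguity codes. Passing tests
therefore establish the internal consistency and calibration of the
statistics under their own model assumptions, not their behavior under
every real-data pathology; the known confounders of γ̂ are listed above.

## Numerical and interface conventions

Positions are 0-based half-open in memory and 1-based in all TSV I/O.
Thresholds are strict inequalities exactly as defined (major > 40, minor
== 1, major fraction > 0.95, second state > 10n, non-diagnostic < 5%).
All stochastic entry points take an explicit seed or generator; CLI runs
write a manifest with inputs, thresholds, seed and version. Undefined
statistics raise typed errors rather than returning silent NaNs, except
inside summary containers where NaN marks a signalled-undefined field.
Degenerate inputs (zero-coverage columns, empty tables, all-undefined
error-matrix rows) are hard errors where the operation's contract demands
data, and logged skips where a record-level fallback exists.
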