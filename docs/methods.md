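# Methods

## The problem

Transmission ratio distortion (TRD) is a deviation of offspring genotype
frequencies from Mendelian expectation given the parental genotypes.
`epitrd` detects *epistatic* TRD: distortion at a pair of unlinked
biallelic SNPs driven by their interaction rather than by either locus
alone, estimated from genotyped sire–dam–offspring trios. The unit of
observation is the trio; for a SNP pair, the data reduce to counts of
offspring two-locus genotype classes within each of the 81 ordered
parental mating configurations (65 of which are informative, i.e. can
produce more than one offspring class). Only inter-chromosomal pairs are
analyzed, so the two loci assort independently and linkage never
contributes to the Mendelian baseline.

## Genotypic model

Each of the nine offspring classes g receives an unnormalized weight

    w(g) = 16·M(g | mating) + c(g)·θ,

where M is the mating's Mendelian distribution, θ = (α_A, α_B, δ_A,
δ_B, αα_e, αδ_e, δα_e, δδ_e) are additive/dominance direct effects per
locus and four epistatic effects (additive×additive …
dominance×dominance), all on [−1, 1], and c(g) is a fixed integer
coefficient row per class. For the double-heterozygous mating the bases
are (1,2,1,2,4,2,1,2,1); for any other mating the base is 16 times that
mating's Mendelian vector with the coefficient rows unchanged and
Mendelian-infeasible classes held at zero — this generalization
reproduces the single-heterozygous worked case exactly (base 4 for AABB
under AaBB×AaBB, AABb impossible). Negative weights are clipped to zero
*first* and the vector is then normalized; if clipping zeroes an
observed class the likelihood is −∞ and the sampler simply rejects that
state, which keeps the chain well defined on the parameter boundary.
The coefficient table is a convention of the model, not the plain
product of contrast codes (several epistatic rows carry negated
products); it is stored verbatim and cross-checked in the tests by an
independent term-by-term transcription of the defining equations.

Two exact symmetries are enforced by tests: swapping the locus labels
(together with α_A↔α_B, δ_A↔δ_B, αδ_e↔δα_e) permutes the probability
vector by the genotype transpose, and flipping the allele labels at one
locus (negating α_A, αα_e, αδ_e) permutes it by the corresponding
reflection. Results are therefore independent of which allele the input
coding happens to count, and no frequency-based re-orientation is done.

## Allelic model

The allelic parameterization follows gametes ("artificial haplotypes"
AB, Ab, aB, ab). A heterozygous locus transmits its capital allele with
probability 0.5 + β (β_A, β_B ∈ [−0.5, 0.5]); a parent carrying exactly
the two gametes of a pair x/y multiplies the canonically earlier
gamete's weight by (1 + β_{x/y}) and the other by (1 − β_{x/y}), with
six pairwise parameters on [−1, 1] (double heterozygotes pair each
gamete with its double-flip complement). Homozygous loci contribute no
factor — any constant cancels under the per-parent normalization.
Offspring-class probabilities are the convolution of the two parents'
gamete distributions; the joint normalization factorizes into the
per-parent normalizations, which is verified numerically. Parental
origin (cis/trans heterozygotes) never enters the likelihood: the two
origin configurations of the double heterozygote sum to the class
probability.

### Simplified biallelic screen

As a cheap preliminary scan, the transmission of one designated gamete
j is modeled with a single parameter: P(transmit j) = 0.5 + α_j,
counted only from parents heterozygous at exactly one locus that carry
j. For such parents the Mendelian null is exactly 1/2; an unphased
double-heterozygous parent has a null of 1/4 for any specific gamete
and would bias α_j upward, so double heterozygotes are left to the full
model. Transmissions that cannot be deduced from the trio (both parents
heterozygous at the scored locus with a heterozygous offspring) are
skipped and tallied. Candidate promotion follows two configurable
rules: the haplotype's |TRD| must exceed the single SNP's by ≥ 0.05 and
the under/over-represented offspring count (≈ α_j × 2 × informative
transmissions) must be no smaller than the single SNP's.

## Inference

Flat priors over the boxed parametric spaces; a single-chain
Metropolis–Hastings sampler with per-parameter reflected Gaussian
random-walk proposals updated in fixed cyclic order within each
iteration. The chain starts at the all-zero Mendelian null (always
finite on clean data). Proposal scales default to 0.05 and are adapted
toward 20–40% acceptance during burn-in only, so the retained draws
come from a fixed kernel. Chain presets: preliminary 11,000 iterations
(1,000 burn-in), accurate 550,000 (50,000), simplified 110,000
(10,000). Identical seeds give bit-identical chains.

Per-parameter evidence is a Savage–Dickey Bayes factor: prior density
at 0 (1/width of the box) over the posterior density at 0, the latter a
Gaussian KDE with Silverman bandwidth (a histogram estimator is
available as a cross-check). A chain that never visits the neighborhood
of 0 yields +∞, which is the correct reading (overwhelming evidence
against the null) and propagates through the filter arithmetic. The KDE
is accurate to a few percent where the null lies within ~2–3 posterior
sds of the mass; deeper in the tail the smoothing bias grows, which
only strengthens already-decisive signals.

Model-level summaries: log10 likelihood ratio of the posterior-mean
parameters (clipped to bounds) against the all-zero null, and
DIC = 2·mean(D) − D(posterior mean) with deviance D = −2 log L,
averaged over at most 2,000 evenly spaced draws. Differences > 3 DIC
units are treated as relevant when comparing the genotypic and allelic
parameterizations on the same pair.

## Scan cascade

Ordered as: (1) pre-filter — ≥ 1,000 informative offspring and ≥ 20
heterozygous sires or ≥ 50 heterozygous dams (a parent counts as
heterozygous when heterozygous at ≥ 1 of the two loci; a stricter
"both-loci" mode exists); (2) deviation screen — some (mating, class)
cell deviates from Mendelian expectation by ≥ 1,000 offspring *and*
≥ 10% of expectation (percentages are reported relative to both the
expected and the observed count, since conventions differ); (3)
preliminary chains on survivors; (4) evidence filters — max epistatic
BF ≥ 1,000, epistatic/direct BF ratio > 1,000 (an underflowing direct
BF passes: direct effects are absent), CV = sd/|mean| ≤ 20% for every
significant epistatic parameter; (5) categorization by the strongest
epistatic BF (additive×additive, additive×dominance-or-reverse,
dominance×dominance); (6) top 0.1% per category, ceiling rule,
deterministic lexicographic tie-break; (7) accurate chains overwrite
the preliminary statistics for the selected pairs; (8) collapsing —
pairs sharing an anchor SNP whose partners lie on one chromosome within
10 Mb of each other (chained single-linkage; the window is configurable
since "physically linked" has no printed definition) keep only the
highest-BF member.

`ScanConfig.desk_scale()` keeps every threshold except the absolute
deviation cut, which drops from 1,000 to 50: the default presupposes
hundreds of thousands of trios per pair, while at the simulator's
20,000-trio scale the largest Mendelian cells hold ~300 offspring with
σ ≈ 15, so 50 ≈ 3.3σ plays the same screening role.

## Recessive screen

For each pair and each haplotype h, the expected number of offspring
double-homozygous for h is the sum over trios of the Mendelian product
of both parents transmitting h's allele at both loci (verified against
brute-force gamete enumeration to 1e−12). A hit requires expected ≥ 15,
zero observed, and Mendelian conformity of every other class within the
carrier matings: |obs − exp| ≤ max(0.10·exp, 3·√exp) — the 10% follows
the deviation-screen convention and the square-root floor protects
small cells from Poisson noise; both are configurable. Haplotype
frequency is reported as the product of the two per-locus parental
allele frequencies (independence holds by construction for unlinked
loci). The screen deliberately bypasses the BF cascade, whose
pre-filters would discard exactly this pattern.

## Synthetic data

The simulator emulates a livestock half-sib design: 50 sires × 2,000
dams × 1 offspring by default, sire usage drawn from a Dirichlet
(concentration 1 → strongly unbalanced families), parent genotypes from
Hardy–Weinberg at configurable frequencies (default 0.5, which
maximizes informative matings), two loci independent as befits an
inter-chromosomal pair. Mechanisms: Mendelian null; genotypic and
allelic sampling from the respective model distributions; viability
(Mendelian sampling then per-class survival) with two modes — `drop`
(default; a dead offspring means the trio is never genotyped, the
biologically faithful reading for a likelihood that conditions on
observed offspring) and `redraw` (trio count preserved; matings whose
every possible offspring is lethal are dropped even here, since no
survivor exists to genotype); and a recessive lethal (viability with
survival 1 − penetrance for one double-homozygote class). Viability
with survival proportional to the genotypic model's probability ratios
is distributionally equivalent to direct genotypic sampling, which the
tests use as a semi-independent check on the likelihood. All outputs
are bit-reproducible under a fixed seed, and every simulation writes a
truth record of its mechanism and parameters.

What the simulator does *not* emulate: genotyping or imputation error
(trios are internally consistent by construction, though the assembly
code excludes and logs Mendelian-inconsistent trios when given real
data), linkage disequilibrium with untyped causal variants, selection
across generations, and array-density heterogeneity. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative models, not robustness to those artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk scales chosen to keep the statistical
properties meaningful: parameter recovery uses 2,000 double-heterozygous
trios and 55,000-iteration chains (one tenth of the accurate preset)
over 20 seeds; null calibration uses 5,000-trio datasets and the
preliminary preset; the end-to-end scan uses 201 pairs × 20,000 trios.
Degenerate situations are handled explicitly: an all-zero clipped
weight vector raises a degenerate-mating error (treated as zero
likelihood by callers), a point-mass chain yields BF ±∞ by the
point-mass limit, CV is undefined (NaN) at mean 0, and ties in
selection and collapsing break lexicographically so scans are
deterministic.

## Known limitations

Single chain only (no Gelman–Rubin machinery), no adaptive MCMC beyond
burn-in tuning, no alternative priors. No intra-chromosomal pairs, no
three-locus interactions, no phasing, imputation or LD handling. The
"27 combined mating types" grouping referenced for the deviation screen
is not publicly specified; the 65 ordered informative matings are used
directly, with an optional user-supplied grouping table. The top-0.1%
selection treats SNP pairs as the unit ("regions" emerge only through
the post-selection collapsing step).
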