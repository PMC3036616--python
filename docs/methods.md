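# Methods

`rcdkit` implements a battery of population-genetic tests for reproductive
character displacement (RCD) between two deeply diverged, cryptic lineages
("Type A" and "Type B") sampled in sympatric and allopatric populations.  The
battery asks two questions: do candidate gamete-recognition genes (GRPs)
evolve faster than control genes, and do sympatric populations show stronger
signatures of positive selection than allopatric ones?  This note records the
models, conventions, parameter choices and known limitations.

## Codon-level divergence (NG86 with Jukes–Cantor correction)

Pairwise dN/dS uses Nei–Gojobori (1986) counting.  Each codon's three
positions are partitioned into fractional synonymous and nonsynonymous
*sites* by enumerating the nine single-base neighbours; changes producing a
stop codon are excluded from both numerator and denominator of the per-position
synonymous fraction (the common implementation convention; no sense codon has
a position whose every change is a stop, so the counts always sum to 3).
Observed *differences* between codons differing at d positions are averaged
with equal weight over the d! minimal pathways; pathways whose intermediates
are stops are excluded (all pathways are used if every one hits a stop).
Pathways are equal-weighted, not transition-favoured.  Codons containing a gap
or ambiguity in either sequence are skipped entirely (pairwise deletion at
codon granularity) — the input is assumed to be pre-aligned in-frame coding
sequence with frame fixed at 0.

Proportions pN, pS are corrected separately with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3).  p ≥ 3/4 saturates the correction: the result is
flagged and the raw proportion kept.  dS = 0 leaves ω *undefined*, which is
distinct from ω = 0.

Cross-type divergence for a gene averages all four A×B pairs of a 2+2 panel:
the arithmetic mean of dN, of dS and of the *defined* per-pair ω values (not
the ratio of mean dN to mean dS).  The candidate screen is strict ω > 0.5.
The GRP-vs-control comparison is a one-tailed Mann–Whitney U test (candidates
stochastically greater), exact for combined samples ≤ 12 without ties,
tie-corrected normal approximation otherwise.

This estimator is deliberately NG86, not a maximum-likelihood codon model:
NG86 is fully specified and testable against exhaustive enumeration oracles.
Printed dN/dS values obtained with ML estimators elsewhere are therefore not
numeric targets for this package.

## Polymorphism summaries

All per-site statistics are computed on the *clean codon region*: codon
columns in which every sequence is unambiguous ACGT.  Complete deletion at
codon granularity gives total and site-class statistics a single shared
denominator set, at the cost of discarding partially missing columns.
S counts segregating clean columns; Watterson's θ_w = S/(a_n·L) with
a_n = Σ_{i<n} 1/i; π is the mean pairwise difference proportion.  Site-class π
divides pathway-classified pairwise differences by NG86 class sites averaged
over the whole sample (not per-pair renormalization).  Hudson-style
F_ST = 1 − mean(π_within)/π_between over jointly clean codons; negative
estimates are reported as computed.  Note the plain estimator is biased
downward by ≈ 1/n for samples that are in fact panmictic.

## Neutrality statistics

Tajima's D follows Tajima (1989).  Fu & Li's outgroup-free D* and F* use the
total singleton count η_s (alleles observed in exactly one sequence) with the
published corrected variance coefficients (Simonsen et al. 1995 appendix, the
form used by the DnaSP/libsequence lineage of software).  Fay & Wu's
θ_H = Σ 2i²S_i/(n(n−1)) is computed from derived-allele counts; raw
H = π − θ_H is reported together with the Zeng et al. (2006) normalized form
(π − θ_L)/√Var, since raw and normalized H differ by an order of magnitude and
published tables are ambiguous about which is shown; neither is treated as a
numeric reproduction target.  Statistics are NA when S = 0 or n < 4 (no
extrapolated coefficients).

Polarization for H uses the consensus of the *other* lineage as outgroup
(Type B consensus polarizes Type A samples and vice versa).  Sites whose
outgroup character is ambiguous or whose outgroup allele is absent from the
sample are unpolarizable and excluded from both π and θ_H for this statistic
only.  This outgroup rule is a package convention and is carried verbatim in
every report row.

## Coalescent nulls

Significance of D, D*, F* and H is calibrated by neutral coalescent
simulation (default 1,000 replicates per gene × population).  The simulator
runs the ancestral recombination graph backwards over a continuous unit
interval: coalescence at rate k(k−1)/2, recombination at rate (ρ/2)×(breakable
span), infinite-sites mutation at rate (θ/2)×(ancestral material length),
with every mutation tagged by its carrier set, so derived-allele counts are
exact.  Only the embedded jump chain is simulated (event probabilities are
rate ratios), which is distributionally exact for mutation counts and
genealogy shape.  Simulations run at the observed per-gene θ_w; conditioning
on S is not implemented.  The per-gene recombination rate is accepted as
input (synthetic truth or user estimate) rather than estimated internally.

The empirical null yields 2.5/97.5 percentile bands and a one-tailed p on the
side of the observed deviation from the null median, floored at 1/(reps+1).
Replicates with S = 0 are dropped and counted; a null with > 50% NA is
refused.  The sympatric/allopatric decision is the conjunctive CI-overlap
rule: significant only if each population's 95% CI excludes the other's
observed value.

## Bayesian constant-ω comparison

Each population sample gets a posterior over (μ, κ, ω) under a pairwise
composite likelihood: every unordered haplotype pair is modelled as two
sequences at divergence t ~ Exponential(1) scaled by μ, evolving under an
NY98-style constant-ω codon model (κ-weighted transitions, ω-weighted
nonsynonymous changes, empirical codon frequencies with a 0.5 pseudocount,
generator normalized to one expected substitution per unit time).  The
t-integral uses 16-node Gauss–Laguerre quadrature (agreement to 1e−6 with a
10× finer rule on toy data).  ρ is not a parameter of this likelihood;
recombination is handled only by the coalescent-null machinery.

**Calibration.** The raw sum of pair log-likelihoods counts every mutation
O(n) times and produces spuriously sharp posteriors — in a truth-null
experiment most run pairs failed the combination check and an evaluable
comparison wrongly excluded zero.  The likelihood is therefore rescaled by
(n−1)/C(n,2), matching the information of n−1 effective pairs; the surface's
shape and point estimates are unchanged while interval magnitudes become
usable for interval-based decisions.  `calibrate=False` restores the raw sum.

Priors are reciprocal densities ∝ 1/x truncated to [1e−6, 1e3] (a proper
version of an improper inverse prior; bounds configurable).  Sampling is
Metropolis–Hastings with log-scale Gaussian random walks (sd 0.4) updated
per parameter; with a reciprocal prior the prior ratio exactly cancels the
log-normal proposal's Hastings ratio, so moves are accepted on the likelihood
ratio alone within the bounds.  Burn-in is an automatic fraction (default
20%) of retained draws rather than manual trace inspection.  Samples with no
haplotype variation are flagged "Not enough variation" and propagate NA
verdicts.

Two independent seeded runs are required to match (means and 95% CrI
endpoints within 0.5 pooled SD per parameter) before concatenation; the
pipeline retries once with fresh seeds, then reports an NA verdict.  The
sympatric/allopatric comparison resamples ω draws with replacement from each
combined posterior, differences them (sympatric − allopatric), and reports
the mean and equal-tailed 95% credible interval; an interval containing zero
means "not significantly different".

## Synthetic data generator

The generator defines the study conditions the tests are validated under.
Genealogies come from a structured coalescent (msprime, haploid samples,
branch lengths in standard coalescent units): Type A and B split at τ = 4.5,
each type's sympatric/allopatric deme pair splits at τ_pop = 0.5, with
optional symmetric A↔B migration between the sympatric demes.  Mutation is a
codon-aware process layered on the genealogy: attempts Poisson(θ/2 × branch
length) with θ_A = θ_B = 10 per gene by default, positions uniform over
3·L_codons sites (L_codons = 150 default), transitions favoured κ = 3,
stop-creating changes redrawn, and nonsynonymous changes retained with
probability ω_class (candidate GRP 0.6, control 0.1) — so realized dN/dS has
a known truth near ω_class.  Defaults were chosen to center the typical gene
inside the observed calibration bands — between-type p-distance ≈ 0.03–0.13
(measured medians 0.05–0.11 across ω_class) and within-population π ≈
0.002–0.05 per site (measured medians 0.009–0.019, matching the middle of the
observed diversity rather than its lower edge) — with cross-type NG86
recovery bias about −5% at ω_class ∈ {0.25, 0.6, 1.0}; individual genes
fluctuate with single-genealogy coalescent variance.  Samples are diploid (2n
haplotypes per population, default n = 10 individuals); an mtDNA-like mode
samples one haplotype per individual.  The 2+2 divergence panel reuses the
first two allopatric haplotypes of each type.  Optionally the 8-clone allele
discovery protocol is emulated (a heterozygote miscalled homozygous with
probability 2⁻⁷).

What the generator does *not* emulate: linked selection (selection enters
only as an acceptance filter per mutation), demographic history of real
invasions (growth, bottlenecks), intragenic recombination within simulated
genes, sequencing error, and alignment uncertainty.  Passing tests therefore
demonstrate correctness of the estimators and decision rules under a clean
neutral-plus-filter model, not robustness to those real-data features.

## Problem sizes and numerical conventions

Validation batteries use reduced sizes chosen to balance Monte-Carlo
resolution against runtime: coalescent calibration at 2,000 replicates;
null-specificity batches of 5–10 genes with 300 coalescent replicates per
null; ω parameter recovery over 20 replicates per truth value (n = 10
haplotypes, 300 codons, θ = 20) with single runs of 1,500 iterations thinned
by 10; pipeline null comparisons with 2,000 iterations thinned by 5.
Production analyses should use the defaults (250,000 iterations, thinning
1,000, two runs, 1,000 coalescent replicates).

Ties in consensus sequences break alphabetically.  Fractional MK counts are
rounded by largest remainder at the table level (raw fractional counts are
retained alongside).  Fisher's exact two-tailed p sums hypergeometric point
probabilities ≤ the observed one with relative tolerance 1e−7.  Seeds fan out
from a single global seed through `numpy.random.SeedSequence` keyed by
(global seed, stage id, gene index, …); every derived seed is below 2³¹.

## Known limitations

* The composite likelihood, even calibrated, is an approximation: posterior
  ω intervals are approximate and somewhat optimistic for highly structured
  samples; medians are reliable within roughly a factor of two at the
  validated sizes.
* The MK table's codon-context classification of polymorphisms uses the
  population consensus codon as context; dense multi-hit codons may be
  classified differently than by other software.
* Fu & Li and Fay & Wu statistics are validated against their defining
  formulas and simulation nulls, not against any external program's output.
* Hudson's F_ST uses the plain ratio estimator with its small-sample bias.
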