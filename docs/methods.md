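# Methods

This note documents the models, conventions and numerical choices behind
`mycoforage`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design and simulator

**Geometry.** A design enumerates `n_sites × cafeterias_per_site`
cafeterias, each holding one ingrowth bag per substrate (default: four
pre-incubated soils — two central-Swedish, one southern, one P-fertilised
southern — plus sand and sand + 1% apatite) and one central root sample.
The canonical design is 10 × 5 × 6 = 300 bags and 50 root samples. Field
loss of bags is independent Bernoulli per bag with default probability
23/300, matching the observed attrition of such experiments (277 of 300
bags recovered); root samples are never lost. Modelling loss as independent
Bernoulli ignores spatially correlated causes (animal disturbance taking a
whole cafeteria), which the analysis tolerates because cafeterias with
missing bags simply contribute means over fewer bags.

**Latent communities.** Each site draws a genus composition from a
Dirichlet with concentration `site_concentration` (default 30) weighted by
per-genus root affinities; each cafeteria's root community is a Dirichlet
draw around its site composition (`cafeteria_concentration`, default 100).
A bag community tilts the cafeteria's root composition multiplicatively by
the genus's `bag_enrichment` and its `substrate_preference[substrate]`,
then renormalises. Two consequences worth knowing:

* with all enrichments and preferences equal to 1, bag communities equal
  root communities exactly (neutral model);
* because compositions renormalise, the bags-vs-roots log ratio of a genus
  with enrichment *e* converges to `ln e − ln(1 + (e−1)q)` where *q* is the
  genus's share of the (renormalised) community — i.e. `ln e` is recovered
  exactly only for rare genera. The recovery studies therefore use a focal
  genus at ≈0.8% of the ectomycorrhizal community.

The quantitative link between root and bag communities is a simulator
construct: the field experiment measures both but does not specify a
generative relation. All downstream code is agnostic to it; the link only
matters for ground-truth parameter recovery.

**Counts.** Per-sample depth is negative binomial (mean `mean_depth`,
dispersion `depth_dispersion`; 0 = fixed depth). Taxon counts are
Dirichlet-multinomial with concentration `taxon_overdispersion` (∞ or 0 =
pure multinomial), the standard compositional count model for amplicon
data. Pre-incubated soil substrates carry residual ectomycorrhizal DNA:
each substrate has a background table of EMF relative abundances whose row
sums are the substrate's background fraction (defaults 5.6%, 4.5%, 0.6%,
3.1% for the four soils; 0 for sands, spanning the 0.6–5.6% range typical
of stored forest soils). Bag sample proportions are
`(1 − f) · latent + background_row`, so the residual DNA appears in the
post-incubation sample at exactly its pre-incubation relative abundance —
the same assumption the downstream subtraction makes. Root samples receive
no background. Sequencing a non-incubated substrate (its background profile
alone) realises an EMF read share equal to the configured fraction, which
is how an analyst would estimate the correction table.

**Reads.** Reads are simulated one per count unit (optionally subsampled):
`fwd_tag + fITS7 + template + revcomp(ITS4) + revcomp(rev_tag)`, with
substitution errors at `error_rate`, Gaussian-around-mean Phred+33
qualities, and an optional fraction of deliberately spoiled reads (short
template, low mean quality, a single very-low-quality base, broken primer,
broken tag) whose defect type is recorded — giving the filter a planted
ground truth. Reads are single-orientation and chimera-free; PacBio-style
indel-dominant error profiles are out of scope, so length-based filtering
behaves more sharply than on real long-read data.

## Amplicon processing

Filtering applies the classical thresholds as strict inequalities: template
length > 100 bp (after tag/primer removal), mean Phred > 20, every base
> 3, forward-primer identity > 0.90 (match fraction over the primer-length
window after the tag), and both tags intact. "Mean quality" is the
arithmetic mean of Phred scores — the simpler of the two readings
(error-probability averaging would be stricter) — and the rejection log
records the first failed criterion per read in the order above.

Demultiplexing is exact tag-pair lookup with no error correction ("intact"
tags); unmatched reads go to an explicit unassigned bin. Dereplication
collapses identical templates into genotypes and removes genotypes seen
exactly once in the whole data set (global singletons, the dominant error
class in amplicon data).

**Pairwise identity** is `1 − editDistance / max(|a|, |b|)` under unit-cost
global alignment (edlib). Fixing the denominator to the longer sequence
makes the value deterministic — equally optimal unit-cost alignments can
trade a substitution for an insertion/deletion pair and hence differ in
column count — while preserving the intuitive readings: 2 mismatches in
100 bp → 0.98; `ACGT` vs `ACG` → 0.75.

**Clustering** is single linkage at 98.5% identity: the species hypotheses
are exactly the connected components of the ≥-threshold identity graph.
The implementation (union–find with a length-ratio prescreen, since
`identity ≤ min(len)/max(len)`) is specified *by* that oracle; tests verify
equality with a brute-force connected-components computation on every
fixture up to 30 genotypes. Cluster representatives are the most abundant
member genotype, ties broken by lexicographically smallest sequence.
Taxonomy is best-identity assignment against a labelled reference at the
same 98.5% cutoff, exact ties going to the earlier reference in file order;
below-cutoff clusters are "unclassified" and non-ectomycorrhizal.

## Community tables

Counts → per-sample relative abundances (zero-depth samples dropped with a
warning) → per-substrate background subtraction for ectomycorrhizal taxa in
bag samples, clamped at zero (subtracting proportions can go negative; the
clamp is a documented choice preserving nonnegativity, applied at species
level before genus aggregation) → renormalisation of ectomycorrhizal taxa
to their share of the EMF community, summed within genus. EMF shares are
invariant to the total EMF read fraction, so bags and roots are comparable
even though their total EMF fractions differ. Genera enter the statistics
only if present (> 0 after correction; no detection threshold) on roots in
at least 10 of the 50 cafeterias.

## Log ratios

`μ = 1/(mean sequencing depth × n_substrates)` with `n_substrates = 6`;
"mean sequencing depth" is the mean total read count per retained sample.
μ is added to both numerator and denominator of both contrasts — the
symmetric form is the one that makes the ratio antisymmetric under swapping
groups, and it matches the explicit two-sided form of the soil-vs-sand
contrast. Natural logarithms throughout; the interpreted quantities (sign,
zero crossing) are base-invariant. Bag means run over recovered bags only;
soil = the four soil substrates, sand = sand and sand+apatite. A cafeteria
yields a record only when the genus is present on its roots, which also
bounds the damage of the (excluded) 0/0 case; when both group means are
zero the ratio is exactly `ln(μ/μ) = 0`.

## Mixed models

All per-genus tests are random-intercept linear mixed models fitted by
REML: `V(θ) = σ²_e I + Σ_k σ²_k Z_k Z_kᵀ` with indicator matrices for site,
cafeteria (globally unique ids, hence nested within site) and, for the
exploration-type model, genus. The profiled −2·REML criterion is minimised
by L-BFGS-B from a deterministic start (response variance split equally
across components) under nonnegativity bounds; fixed effects are the GLS
solution at the optimum. A component estimated at zero flags the fit as
singular but is not an error; a constant response returns the intercept
with all components zero. Test degrees of freedom use the **Satterthwaite
approximation**: `df = 2·Var(Lβ̂)² / gᵀA g` with `g` the central-difference
gradient of the contrast variance in θ and `A` the inverse observed REML
information (boundary components held fixed), clipped to `[1, n − p]`.
Multi-df F-tests decompose the contrast covariance into eigen-contrasts,
compute one-df Satterthwaite values and combine them
(`ddf = 2E/(E − q)`, `E = Σ νᵢ/(νᵢ − 2)`), the approach used by the
standard mixed-model testing packages. Tests verify the engine against
statsmodels' MixedLM (estimates, SEs, variance components), against the
OLS closed form at the zero-variance boundary, against the theoretical
`n_sites − 1` df in a between-site-dominated design, and against a
Kolmogorov–Smirnov check that F-test p-values are uniform under a null
where genus effects are independent of exploration type.

The engine is implemented in-package (dense matrices; designs here are a
few hundred observations) because the fixed-effect tests require
Satterthwaite denominator df, which the available Python mixed-model
implementations do not expose; statsmodels serves as an independent
cross-check, never as the implementation.

BH correction implements the step-up definition exactly (monotone, ≥ raw,
original order preserved) and is cross-checked against statsmodels'
`multipletests`. One BH family per test battery: the genus set within each
ratio type, and the genus set for substrate effects.

## PERMANOVA with restricted permutations

The pseudo-F is the classical among/within partition of squared
dissimilarities (equivalently the Gower-centred partition); on univariate
Euclidean data it equals the one-way ANOVA F to machine precision (tested
at 1e-8). The default distance is Bray–Curtis on Hellinger-transformed
(square-root) genus relative abundances — the conventional default for this
tool chain; the distance matrix is an explicit argument, so any metric can
be substituted. The permutation null shuffles group labels independently
and uniformly **within each cafeteria** (identity allowed), respecting the
blocked design; `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, which is
never zero. Blocks with a single sample contribute no permutations (logged);
a design in which every block is a singleton is an error. One structural
fact worth noting: with two groups, globally swapping the labels reproduces
the same partition and the same F, so at least two restricted labelings
always attain the observed maximum — with two blocks of two samples the
smallest attainable p is 1/2, and 1/4 first arises with three blocks.
Type-I error at α = 0.05 is verified by simulation (500 null runs at 199
permutations, tolerance ±0.03).

## Tukey HSD

Marginal means come from the treatment-coded substrate factor of the fitted
mixed model; each pairwise difference is tested on the studentized-range
distribution with `q = √2·|diff|/SE(diff)` and that contrast's
Satterthwaite df. With two levels this reduces exactly to the unadjusted
pairwise t-test; the three-group case is verified against a Monte-Carlo
estimate of the studentized-range tail (10⁵ draws, tolerance 0.01).

## Problem sizes and seeds

Every stochastic routine takes an explicit integer seed and is bit-for-bit
reproducible; the pipeline derives per-stage seeds from one master seed and
writes SHA-256 hashes of all outputs to its manifest. The replicated
studies use 20 end-to-end replicates of the full 10 × 5 design at depth
10⁴ for enrichment recovery, and 500 null runs at 199 permutations for
PERMANOVA calibration — sizes chosen so the whole validation suite runs in
a few minutes on a single CPU while keeping Monte-Carlo error comfortably
inside the stated tolerances.

## Known limitations

* The root↔bag latent link and the genus trait-to-parameter mapping in the
  default profiles are simulator constructs; passing tests demonstrate
  correctness of the estimator chain, not field realism.
* Read simulation is substitution-only and single-orientation; no chimeras,
  no indel-rich long-read error profiles, no UNITE-scale taxonomy.
* The background correction subtracts expected pre-incubation abundances;
  it is unbiased under the simulator's carry-over assumption but, like the
  field procedure, cannot distinguish residual DNA from genuine early
  colonisation.
* Satterthwaite df is an approximation; with very few sites the per-genus
  intercept tests are conservative (df near `n_sites − 1`).
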