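# Methods

This note documents the models and procedures implemented in
`introgrescan`, the parameter choices behind the synthetic-data
generator, the numerical conventions, and what the test suite does and
does not establish.

## The isolation-with-migration simulator

The generative model is a two-population isolation-with-migration (IM)
coalescent. All parameters are mutation-scaled per locus: θ₁, θ₂, θ_A =
4Nu for the two daughter populations and their ancestor, t = Tu the
split time, m₁, m₂ = m/u the migration rates *into* populations 1 and 2
(forward in time), and ρ = r/u the intra-locus recombination rate. Time
is measured in mutational units, so backwards in time a pair of
lineages in deme *i* coalesces at rate 2/θᵢ, a lineage in deme *i*
migrates at rate mᵢ/2, a lineage recombines at rate ρ/2 per unit of
ancestral span, and mutations fall at rate 1 per unit branch length.
Two identities anchor the scaling: a sample of two from one population
differs at θ sites on average, and the effective number of migrants per
generation is 2Nᵢmᵢ = θᵢmᵢ/2 (exactly invertible;
`convert_to_2Nm`/`invert_2Nm`). Demographic conversions assume the
*Heliconius* life history of roughly ten 35-day generations per year,
and per-locus mutation rates can be calibrated from divergence
(`mu_from_divergence`: u per year = d_xy / 2T_cal).

Two engines implement the model. `simulate_genealogy` returns a single
timed, deme-labelled tree (no recombination). `simulate_ancestry` is a
full segment-tracking ancestral-recombination-graph simulator (Hudson
style): lineages carry sorted ancestral-material intervals with
descendant bitmasks, recombination splits a lineage at a uniform
breakpoint within its span, coalescence merges segment lists with a
linear sweep, and material that reaches its marginal MRCA is pruned.
Its output is the list of mutation-bearing *pieces* — (lifetime × span,
descendant set) — from which mutations are dropped either at Poisson
rate (intensity = total piece weight) or conditionally on fixed counts.
A numba-compiled kernel (segment pool with linked lists, `uint64`
descendant masks, ≤ 64 haplotypes) runs ~20× faster than the
pure-Python reference; the two are cross-checked by
Kolmogorov–Smirnov tests against each other and against msprime's
segregating-site counts in the test suite.

Infinite-sites mutations render as binary columns (ancestral A, derived
T) at distinct positions, with a collision guard when the expected
mutation count approaches the locus length.

### The admixture pulse and the sweep approximation

Besides continuous migration, a locus may carry a single admixture
pulse: at `pulse_time` a fixed fraction of a population's lineages
traces its ancestry to the other deme. With `pulse_sweep=True` the
admixed lineages first coalesce into a single lineage — the star
genealogy of a hard selective sweep — so all introgressed material
descends from one donor haplotype. This is the model of *adaptive*
introgression: a wing-pattern allele crosses the species boundary once
and is driven to appreciable frequency in the matching phenotype class
by mimicry selection. Equilibrium continuous migration cannot produce
this signature: strong continuous flow (2Nm ≈ 10) simply homogenizes
the locus, the fitted isolation null tracks the reduced divergence, and
the LD gene-flow statistic loses essentially all power (we measured
~5% rejection — chance level — across a wide parameter grid). The
IM-style 2Nm estimates reported for colour loci in empirical studies
are best read as that model's summary of exactly such sweep-like
events.

### Default study design

`default_study_design()` fixes the conditions used throughout the tests
and the acceptance script: 20 haplotypes per species per locus, nine
500-bp loci, θ = 20 per locus (0.04/site — the high nuclear diversity
of *Heliconius*), t = 10 (one coalescent unit, 2t/θ — shallow species
divergence with extensive incomplete lineage sorting, matching the
pervasive allele sharing seen at real unlinked markers), ρ = 10 per
locus (ρ/θ = 0.5; enough recombination that ancestral shared
polymorphisms decorrelate while a young introgressed block stays
intact). The eight neutral loci exchange migrants at 2Nm = 0.1 per
direction. The colour locus adds the sweep pulse: at τ = 0.1 (1% of
the split time), 15% of the recipient's lineages (3 of 20) coalesce
into one donor haplotype. Phenotype labels mirror the mimicry classes:
the donor species splits arbitrarily into red-banded and rayed halves
(these markers carry no phenotype information within the donor), and a
recipient haplotype is labelled rayed when its colour-locus sequence is
closer to the donor pool than to its own population (donor-matched
introgressed phenotype), otherwise non-red. Regions and localities are
assigned per population half, so geography nests within species.

What the generator does *not* emulate: finite-sites homoplasy,
indels and alignment gaps, rate variation across sites, more than two
exchanging populations, gene conversion, and direct selection on the
sampled sites (selection enters only through the sweep approximation).
Passing tests therefore demonstrate correctness and calibration of the
*methods* under a clean coalescent world, not robustness to every
feature of real data.

## The shared-polymorphism LD gene-flow test

Sites are classified relative to a population pair as shared
polymorphisms, population-exclusive polymorphisms, fixed differences,
or monomorphic; columns with gaps/N in either population or more than
two pooled alleles are excluded (D′ is defined for biallelic pairs).
For population *p*, D̄_SS averages D′ over all shared–shared pairs and
D̄_SX over all shared–exclusive-*p* pairs, with D′ computed from *p*'s
haplotypes only; x_p = D̄_SS − D̄_SX, undefined (NA) when either pair
set is empty.

**Signed D′, minor-allele orientation.** D = p_AB − p_A p_B with A and
B the minor alleles (ties broken alphabetically), normalized by the
frequency-bound D_max, so D′ ∈ [−1, 1] keeps its sign: positive when
the rarer alleles travel together. x therefore spans [−2, 2]. The
magnitude-only variant (`signed=False`) is exposed, but it is
uninformative on recombination-poor data: under infinite sites any
tree-compatible site pair has at most three gametic types, which forces
|D′| = 1 regardless of the pair's age, so D̄_SS ≡ D̄_SX. Published
applications of this statistic report simulated means above 1, which is
only possible for the signed version — that settled the default.

**The simulation null.** Significance is the upper tail of x against a
zero-migration isolation model fitted to the locus: per-population θ by
Watterson's estimator, θ_A their mean, and t from net divergence
(d_a = d_xy − (π₁+π₂)/2, t = d_a/2 since E[d_a] = 2t under isolation),
with the null's ρ supplied by the caller (default 0, appropriate for
truly non-recombining blocks; pass the locus's ρ otherwise). Each null
replicate matches the sample sizes and the observed *site-class
counts*: mutations are placed class-by-class on genealogy branches
capable of producing them (genealogies lacking a required class are
resampled), so the comparison isolates the LD pattern from the class
counts themselves. Unconditional variants (total-S and Poisson) are
available; all three calibrate to nominal type-I error in our checks.
p = (1 + #{x_sim ≥ x_obs}) / (n_defined + 1), never exactly zero.
`infer_direction` names the population with the larger positive
significant x; exact ties and all-negative outcomes are
"undetermined".

## AMOVA

One-factor analysis of molecular variance from pairwise nucleotide
differences used as squared Euclidean distances (the standard
convention for haplotypic data): SSD_total and SSD_within give
σ²_within = SSD_within/(N−G) and σ²_among = (SSD_among/(G−1) −
σ²_within)/n_c with n_c the unequal-size correction; Φ_ST =
σ²_among/(σ²_among+σ²_within). Negative component estimates are
reported as computed (no truncation). Significance permutes whole
haplotypes among groups. Three separate one-factor analyses (phenotype,
species, geography) are run rather than one nested design, and the
outgroup is excluded. The decomposition is verified against a
definitional sums-of-squares oracle; the permutation test's type-I
error is checked at nominal level under exchangeable labels.

## Phylogenetics

*Distances and NJ.* Uncorrected p-distance with pairwise deletion of
gap/N columns. Saitou–Nei neighbour joining with deterministic
tie-breaking (first minimal Q entry in row-major order); negative
branch-length estimates are clamped to zero with the deficit moved to
the sister branch so the inter-child path length is preserved. NJ
exactly inverts additive distance matrices (tested for 4–8 taxa).
Bootstrap support resamples columns, rebuilds NJ trees, and reports the
percentage of replicates containing each internal bipartition of the
point-estimate tree.

*Likelihood.* GTR+I+Γ with the rate matrix scaled to mean rate 1 over
variable sites, discrete Gamma by mean-of-quantile (4 categories by
default), and site likelihood p_inv·[site constant]·π(base) +
(1−p_inv)·(mean over categories of the pruning likelihood). Felsenstein
pruning runs over unique site patterns with per-node rescaling against
underflow; t = 0 transition matrices are exact identities so
conflicting states at zero distance give −∞ (flagged with a warning).
Correctness is pinned to the two-taxon Jukes–Cantor closed form
(1/4 + 3/4·e^(−4t/3)) at 1e−10 and to exhaustive ancestral-state
summation on four-taxon instances. Branch lengths on a fixed topology
are optimized by cycling bounded univariate (Brent) passes until the
per-cycle improvement drops below 1e−6; the log-likelihood is
non-decreasing across cycles.

*SH test.* Fixed candidate topologies (no tree search — the alternative
histories are fixed hypotheses) are scored with optimized branch
lengths; RELL bootstrap resamples per-site log-likelihood vectors,
centers each topology's resampled totals on their own mean, and
p_i = Pr(max_j centered_j − centered_i ≥ lnL_best − lnL_i) with the
add-one rule. The best topology always receives p = 1, and p is
monotone non-increasing in the lnL deficit. The test is conservative by
construction; on data simulated under a known topology it rejected the
truth in 0–2% of replicates at α = 0.05.

## Simulation sizes in the test suite and acceptance script

The suite uses scaled Monte-Carlo sizes chosen for a minutes-scale run
with assertions carrying the matching standard-error slack: 200
replicates × 99 null simulations for gene-flow calibration, 150
replicates × 199 simulations for direction recovery (observed ≈ 0.9
against the ≥ 0.8 requirement), 200 replicates × 99 permutations for
AMOVA calibration, 100 datasets × 300 RELL resamples for SH
calibration, and 10⁴ genealogies for the Watterson check. The
acceptance script re-runs the same computations at comparable sizes
(e.g. 999 permutations, 499–999 null simulations for the single-study
tables) from a single command-line seed; every reported value is
computed at run time.

## Known limitations

- The compiled ancestry kernel supports at most 64 haplotypes per
  locus (descendant sets are `uint64` bitmasks); larger samples fall
  back to the slower reference engine.
- The gene-flow null fits θ and t per locus; a strongly introgressed
  locus therefore tests against a partially "contaminated" null, which
  is conservative. Passing a multilocus background estimate via
  `null_params` is supported but not automated.
- x is undefined for loci without shared or without exclusive
  polymorphisms (deep divergence, small samples) — reported as NA, as
  in real multi-locus tables.
- GTR exchangeability estimation is deliberately light (the package
  evaluates fixed topologies; model selection belongs to external
  tools). The SH demonstrations use Jukes–Cantor, which matches the
  generator.
- IM parameter *estimation* (MCMC fitting of θ, t, m) is out of scope;
  only the generative model and unit conversions are implemented.
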