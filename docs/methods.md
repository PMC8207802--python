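# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show.  Coordinates are 0-based
half-open everywhere inside the library; VCF/GFF3 (1-based) and BED
(0-based) conversions happen only in the I/O layer.

## Forward simulation (`simdata`)

**Model.** Discrete-generation Wright–Fisher with two diploid populations
descending from a common ancestor.  Per generation: viability selection
(per-locus genotype fitness 1, 1−hs, 1−s, multiplicative across loci),
migration (each offspring is drawn from the other population's parent pool
with probability m), random mating with multinomial resampling, uniform
crossover recombination (Poisson number of crossovers per gamete at
`rec_rate` per boundary), and infinite-sites mutation over the genome
layout.  Effect classes (noncoding / synonymous / missense / nonsense) are
assigned by translating the affected codon on the annotated strand.  The
simulator returns only sites segregating in the union of the two final
samples — the same ascertainment a variant-calling pipeline has.

**Initialization.** Instead of a long burn-in, the ancestral population is
initialized from the *stationary distribution of the same discrete chain*:
for each selection class the expected number of segregating sites per
derived-allele-count class under mutation–selection–drift balance is
obtained by solving the linear system `f = T'f + e₁` (T the one-generation
transition restricted to unabsorbed counts), and sites are then placed on
haplotypes at linkage equilibrium.  This is exact for all single-site
statistics; it omits standing linkage disequilibrium at the split (new LD
builds up during the simulated epochs).

**DFE and dominance.** Non-synonymous (missense and nonsense) mutations
draw a selection cost s from a gamma distribution (shape 0.2, configurable
mean, discretized into 16 equal-probability bins so the stationary solve
and the forward dynamics use identical point masses; s is capped at ~1 =
lethal).  Dominance is a single h = 0.25 for deleterious mutations
(partial recessivity).  No DFE or dominance was measured for this system;
these defaults are documented stand-ins chosen from the range typical of
nonsynonymous DFE estimates in vertebrates, and they are knobs, not claims.

**Demography preset** (`domestication_bottleneck`).  Split 12,300 generations before
present (one-year generations); wild: ancestral size → 257,000 by 10,300,
then linear decline to 154,000; domestic: 138,000 at the split → 52,000 by
6,990, then recovery to 152,000.  The pre-split ancestral size (default
180,000) and the migration rates (default 1×10⁻⁶ wild←domestic, 2×10⁻⁶
domestic←wild per generation, reflecting predominantly wild-into-domestic
gene flow) are user-set stand-ins with no published point estimates to
anchor them.  The preset is returned rescaled by Q (default 600):
sizes and times shrink by Q while μ, r, s and m grow by Q, preserving
θ = 4Nμ, Ns, Nm and t/N exactly (sizes and times stay floats; rounding to
whole individuals/generations happens only in the engine).  Rescaling
distorts strongly selected dynamics once s·Q approaches 1 (such mutations
become effectively lethal); weakly selected and neutral dynamics are
preserved.

**Outgroup.** Fixed substitutions dropped on an independent branch at
`outgroup_divergence` expected substitutions per site; shared ancestral
polymorphism is ignored, because the outgroup's only role is ancestral-
allele polarization.  Outgroup substitutions that strike a focal
segregating site produce realistic polarization errors and third-allele
(missing) outgroup genotypes.

**Hard sweeps.** An injected beneficial mutation enters at a
post-establishment frequency (default 5%), with all copies placed on a
single founder haplotype's background — the defining property of a hard
sweep, and what produces hitchhiking and a local diversity collapse as it
fixes.  The sweep keeps its own dominance (default ½).

**`coding_only` mode.** Restricts mutation and the stationary
initialization to coding sites.  Under multiplicative fitness without
epistasis, neutral noncoding sites never feed back on coding-site
dynamics, so this is exact for every coding-site statistic while making
multi-megabase contigs affordable for load experiments.

**What the generator does not emulate:** genotyping error and missing
data in the simulated output, more than two populations (hence no
introgression from divergent taxa), population structure or inbreeding
within either population, X/Z chromosomes, gene conversion, epistasis.
Conclusions that depend on those processes cannot be demonstrated here —
see "Expected load contrasts" below for the one place this matters.

## Expected load contrasts (`simdata.expectation`)

For each selection coefficient the full allele-frequency density is
propagated through the post-split epochs of each population separately
(exact transition matrices, influx of new mutations proportional to the
current population size, migration ignored at the preset's small rates).
This mean-field theory predicts the sign and size of the wild/domestic
load contrasts the stochastic simulator fluctuates around.

For the bottleneck preset it predicts: deleterious/synonymous ratio
slightly *higher* in the domestic population (≈ +0.4%), per-individual
deleterious allele count slightly *lower* (≈ −1.5%), and the heterozygous
fraction of deleterious genotypes *lower* by ≈ 0.8–2.5 percentage points —
robustly across DFE means, h ∈ [0, 0.25], ancestral sizes 60k–300k and
migration within the two-population geometry.  A closed two-population
model of this demography therefore does **not** reproduce the empirically
reported heterozygous-deleterious excess of domestic chickens; that
pattern plausibly requires introgression from divergent jungle-fowl taxa
and/or structure in the wild sample, both outside this model.  The
directional acceptance test encodes the original expectation and is left
failing by design; the package treats this as a result, not a bug.

## Variant annotation (`varianno`)

Effect classification translates the affected codon with the standard
genetic code (reverse-complement for minus-strand CDS); stop-gain →
nonsense.  The deleteriousness score is the mean, over a homolog set, of
the change in semi-global alignment score (BLOSUM62, gap open 10, extend
1, free terminal gaps) caused by the substitution; premature stops truncate
the protein before scoring.  A variant is a high-impact SNP (hSNP) when
its score is ≤ −2.5 (boundary included).  Unlike the original PROVEAN
workflow there is no database search and no 75%-identity clustering of
supporting sequences: the homolog set is an explicit input, and the
synthetic generator (substitution-only mutants of the reference protein at
a configurable divergence) is a stand-in adequate for testing the
alignment core, not a reproduction of any real homolog panel.
Polarization calls an allele ancestral only when the outgroup is fixed for
it; heterozygous, polymorphic, missing or third-allele outgroups leave the
site unpolarized, and unpolarized sites are excluded from all
derived-allele statistics.  Chromosome-class assignment (macro 1–5,
intermediate 6–10, micro 11–38) is a configurable lookup so synthetic
contigs default to "unassigned".

## Load statistics (`loadstats`)

Per individual: `n_del = n_het_del + 2·n_hom_del` over hSNP sites (the
additive-load convention), the synonymous analogue, their ratio, and the
heterozygous-deleterious fraction.  Missing genotypes are excluded site by
site.  Population summaries report the mean of per-individual fractions
(primary) and the pooled-count fraction.  Group contrasts use the
*unpaired* two-sided Wilcoxon–Mann–Whitney rank-sum test — the applicable
test for two independent groups, although comparisons of this kind are
sometimes labelled "signed-rank" in the applied literature — with exact
enumeration when n_A + n_B ≤ 12 without ties and the tie- and
continuity-corrected normal approximation otherwise.

## Windowed scans (`sweepscan`)

Site π is 2a(n−a)/(n(n−1)); window π divides summed site π by the full
window length (the convention of the common `--window-pi` tools), windows
50 kb sliding by 25 kb, only complete windows tiled.  F_ST is Hudson's
estimator combined as a ratio of averages and clamped to [0,1]; sites with
fewer than two called alleles in either population drop out of the sums.
LSBL = (d_AB + d_AC − d_BC)/2 floored at zero isolates the focal branch;
π-ratio is π_wild/π_domestic.  Sweep calls take windows at or above an
empirical quantile (default 0.99 — a knob; no canonical value exists) and
merge adjacent selections.  The hSNP-in-sweep contrast relocates sweep
regions uniformly at random (lengths preserved) for a two-sided
permutation p = (k+1)/(B+1).

## Joint-SFS demographic inference (`demofit`)

**Engine.** The expected sample joint SFS Phi[i,j] evolves under a closed
ODE: genetic drift closes exactly at sample order (x(1−x)B″ is tridiagonal
in the binomial-kernel basis), and migration terms — which need one extra
sampled chromosome in the source population — are closed with a quadratic
jackknife (exact for locally quadratic underlying densities).  New
mutations enter on the single-copy entries at rate n·θ/2.  The clean-split
initial condition is analytic (Beta moments of the θ/x stationary
density), and Crank–Nicolson steps (default ≤ 0.01 time units) integrate
through piecewise-linear size epochs.  The engine is linear in θ, exact in
the neutral constant-size limit, and agrees with an independent
Monte-Carlo coalescent average (msprime branch lengths, available as
`engine="coalescent"`) to ~2% of total mass at desk-scale sample sizes.
Fitting is practical up to n ≈ 15 chromosomes per population; larger
samples should be projected down (hypergeometric projection is built into
`joint_sfs`).

**Models.** Four nested parameterizations of a clean split: A (constant
sizes), B (+ asymmetric migration), C (+ linear size change from the split
to the present), D (C with the change confined to the last T2).  AIC uses
k = 3, 5, 7, 8.  D is deliberately a minimal one-epoch extension of C:
four-model ladders of this kind usually carry two growth variants whose
precise distinction varies between analyses, so D is defined here as the
smallest parameterization that nests C rather than as a reproduction of
any particular published pair.

**Likelihood and optimization.** Multinomial composite likelihood with θ
profiled out analytically (θ̂ = Σdata/Σmodel; Poisson mode by flag), the
invariant corners masked, and model cells floored at 10⁻¹⁰ of the total to
keep stray observations finite.  Optimization is Nelder–Mead in
log-parameter space in three rounds (coarse multi-start from log-uniform
draws or around a warm start; perturbed restarts around the round-1 best;
one tight polish).  The growth models have ridged likelihood surfaces on
which cold multi-starts stall, so `fit_models_nested` walks the nesting
chain A→B→C→D, seeding each model with the exact embedding of its parent
(guaranteeing non-decreasing likelihood along the chain) plus several
change-epoch fractions for D.  On noise-free self-generated spectra this
recovers every model's parameters to machine precision.

**Bootstrap and units.** Confidence intervals resample neutral regions
(blocks) with replacement, refit warm-started from the point estimate, and
take percentile intervals; region blocks rather than single sites keep the
resampling valid under linkage.  Physical units use
N_anc = θ̂/(4 μ_gen L), sizes nu·N_anc, times T·2N_anc generations, with
μ = 1.91 × 10⁻⁹ per site per year and g = 1 year by default.

## Desk-scale experiment sizes

The test-suite experiments are sized to finish on one CPU while retaining
statistical power: self-consistency fits at n₁ = n₂ = 10; model recovery on
20 Poisson-resampled spectra of ~100k sites at n = 8; end-to-end split-time
recovery on ten 1.5 Mb simulations with 10 diploids per population
projected to 10 chromosomes (observed errors a few percent to ~15%);
load contrasts on twenty-five 6 Mb coding-only simulations with 20
diploids per population; sweep recovery on twenty-five 1.2 Mb simulations.
The bootstrap default is B = 100; tests use smaller B to bound runtime.

## Known limitations

* The moment-closure engine's jackknife is approximate near the spectrum
  boundaries; errors grow with migration rate and are largest in
  low-expectation corner cells (a few percent of cell mass at desk scale).
* Rescaling truncates the strongly deleterious DFE tail (s·Q capped near
  lethality), compressing purging dynamics.
* The PROVEAN-style score correlates with chemical radicality of the
  substitution, not with the simulator's true s, so hSNP recovery of true
  deleterious sites is reported, not asserted.
* Bootstrap intervals at B = 100 are percentile intervals without
  acceleration/bias correction; coverage is approximate.
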