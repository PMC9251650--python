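# Methods

## Scope and data model

powan reconstructs population histories from unlinked biallelic SNPs
(ddRAD-style: thousands of short loci, here 142 bp by default) plus short
mtDNA alignments.  Genotypes live in a samples × sites matrix of alt-allele
dosages with per-cell read depths and a sample → population map; spectra
live in a sparse multidimensional SFS (MSFS) keyed by per-deme allele
counts, folded to the globally minor allele, with an explicit
monomorphic-site entry.

## Filter cascade

Site filters run in a fixed order — presence across populations,
per-population completeness, observed heterozygosity, mean read depth,
missingness, minor-allele frequency, per-population exact HWE
(Wigginton–Cutler–Abecasis), one SNP per locus — and each removed site is
charged to the first rule that rejects it, so report counts sum to the
total removed.  Per-genotype depth bounds recode individual genotypes to
missing *before* any site rule runs: applying the recoding mid-cascade
would make a second pass of the cascade see different data, breaking
idempotence (`filters` tests assert `apply_filters ∘ apply_filters =
apply_filters`).  The site-level mean-depth bound keeps its place in the
rule order.  Presence and completeness split the Stacks `-p`/`-r` joint
criterion into two reported rules: at least `min_pops` populations with any
data, and at least `min_pops` populations genotyped at fraction ≥ `-r`.
The MAF rule is a single global pass over current genotypes.  HWE defaults
(α = 0.001, flag when over half the populations with data fail) follow the
conventions of the usual per-population filtering script.  "One SNP per
locus" keeps the first SNP by position within each locus id.

## Estimators

* H_O: heterozygote fraction among genotyped samples, averaged over SNPs.
* H_E: unbiased gene diversity (2n/(2n−1))(1 − Σp²) with per-site n; the
  small-sample correction is used throughout (the same quantity equals the
  mean pairwise difference over distinct gene copies, which is how the
  brute-force test oracle computes it).
* π and Dxy are per-bp: summed per-site mean pairwise differences divided
  by `n_loci × invariant_sites_per_locus + n_SNPs`.  The invariant length
  per locus defaults to the 142-bp locus span, a fragment-size-selection
  figure rather than a measured quantity, and is configurable.  Dxy of a
  population with itself uses the distinct-pair form and therefore equals
  that population's π.
* A_R: exact rarefaction, Σ_alleles [1 − C(N−N_a, g)/C(N, g)] per site with
  g = 2 × `min_diploids` (default 3 diploids, the smallest study sample).
* F_ST: Weir & Cockerham (1984) θ from per-site a/b/c variance components,
  multi-locus and windowed values as ratios of sums (negative window values
  reported as-is).  Missing data: pairwise deletion per site; a site enters
  when both populations have ≥ 1 genotyped diploid and ≥ 3 jointly.
  Significance: individuals permuted between the two populations, p = the
  plain fraction of permuted θ ≥ observed.
* Windowed scan: 0-based half-open 1-Mb windows per chromosome (VCF
  positions are 1-based), windows with < 5 SNPs dropped, outliers flagged
  at θ ≥ mean + 3 SD over retained windows.
* PCA: per-SNP mean imputation, centring by 2p and scaling by √(2p(1−p)),
  SVD, and |Pearson r| between every SNP column and each component's sample
  scores — the screen for whether an axis is driven by particular regions.

## Coalescent engine

One compiled (numba) walker simulates genealogies backward in time:
exponential within-deme coalescence via Gillespie sampling between
demographic events; splits move lineages to the ancestral deme; a pulse of
proportion α moves each lineage of the admixed deme to the donor with
probability α (the exact backward dual of an instantaneous admixture
event); size changes reset a deme's N_e.  Validation normalises the event
list by time, rejects events touching demes after they merged, and requires
exactly one un-merged root deme, which also rules out orphaned lineages.

The same walker serves three outputs: (i) branch lengths accumulated per
descendant configuration — the expected-SFS estimator; (ii) Poisson
infinite-sites mutations per configuration — simulated MSFS draws; (iii)
per-site leaf bitsets — genotype matrices and sequences.  Configurations
index mixed-radix over sampled demes (first deme most significant, so
numeric order = lexicographic order; folding ties keep the numerically
smaller side).  Randomness is a counter-based splitmix64 stream keyed by
(seed, locus index): results are bit-identical for a given seed and extend
without reshuffling when more loci are requested.  Dense configuration
arrays are capped at 2^26 cells; larger layouts must be down-sampled or
projected first.  Loci are unlinked and non-recombining, and multiple hits
are ignored (μL ≈ 1.4e-6 per locus per generation makes them negligible).
Continuous migration is not modelled: the admixture events of interest are
discrete pulses with times and proportions.

## Composite likelihood and optimisation

Expected entry probabilities are p_c = μ·Ê[ℓ_c] with Ê[ℓ_c] the mean
subtending branch length over `n_sims` simulated genealogies; p_mono = 1 −
Σ p_c.  This branch-length (Rao-Blackwellised) estimator has the same
estimand as counting mutations over simulated loci but strictly lower
variance.  Expected probabilities of zero for observed entries are floored
at 1/(10 · n_sims · locus_length).  All evaluations within one fit or
profile share a common random-number stream, making the objective a
deterministic function of parameters — cutting Monte-Carlo jitter out of
line searches and profiles.

Because log p̂ is concave in the Monte-Carlo estimate p̂, finite `n_sims`
biases CL downward more strongly for parameter values whose spectra spread
mass over many rare configurations; at small `n_sims` this visibly tilts
profiles.  Two choices keep the bias negligible at the scales used here:
observed and expected spectra are projected to 6 gene copies per deme
(7^6 configurations, densely covered), and evaluations use large `n_sims`
(400,000 genealogies in the full-scale script — cheap, as each 36-gene
genealogy takes microseconds).  Projection is exact hypergeometric
down-sampling, implemented as per-axis matrix products; simulating the
expected SFS directly at the projected sample size is equivalent by
coalescent sampling consistency.  Projection commutes with minor-allele
folding, so folded spectra are projected and re-folded exactly.

The optimiser replaces ECM-style conditional maximisation with cyclic
per-parameter golden-section search on log-scaled parameters (linear scale
for admixture proportions), from `n_starts` log-uniform starting points,
with the search bracket halving each cycle; `(n_starts, n_cycles, n_sims)`
therefore map one-to-one onto the conventional settings (100 starts, 40
cycles, 100,000 simulations).  Model comparison is by maximum CL with AIC
reported; hierarchical building fits every candidate attachment of each
newly added deme — all parameters free, backbone re-estimated — and carries
the winner forward.  Parametric bootstrap: simulate datasets of the
observed size at the point estimates, re-optimise each from jittered
(×exp(U(−0.25, 0.25))) starts, percentile 2.5/97.5 intervals; replicates
whose fits fail are excluded with a warning above 10%.

Profile grids skip parameter values that violate event ordering (e.g. a
root time below the next split): these are infeasible models, not low-
likelihood ones.

## Study template

The six-deme template fixes the event times and proportions listed in the
README.  Effective sizes are *free template configuration*, not estimates:
they were chosen once, before any end-to-end runs, from closed-form
two-lineage coalescent expectations — E[T_within] = 2N(1−q) + 2N_anc·q with
q = exp(−τ/2N) — so that each deme's per-bp diversity (2μ·E[T_within])
matches the observed study values (≈ 0.0012–0.0034) and the
Scotland–England lineage F_ST ≈ 1 − T_within/T_between lands near the
observed 0.569.  That yields ancestral demes of 110,000 and present demes
of 3,000–12,000 diploids.  The unprinted admixture proportions from the
Alpine and Wales/England-ancestor demes into the Baltic (0.20, 0.18) sit
inside the reported 0.15–0.46 range, at times inside the reported
4,433–6,663-generation window; the Welsh/English donor is the ancestral
deme because the daughter demes do not yet exist at those times.

The generator emulates: per-population sample sizes (3–11 diploids), ~20k
unlinked loci on 40 pseudo-chromosomes of 50 Mb with evenly spaced locus
starts (≈ 10 loci/Mb, so 1-Mb windows are populated), negative-binomial
read depth (mean 20, dispersion size 5), and per-population Bernoulli
missingness (default 5%).  It does not emulate: linkage within loci,
allele-balance or mapping artefacts, batch effects, or reference bias.
Note the depth model is dispersed enough that the per-genotype depth
bounds (5–30 reads) censor ≈ 17% of genotypes, so the 15% missingness rule
then removes most sites — an intended stress of the cascade; set
`depth_size=None` (uniform depth) for a clean-pass dataset.  mtDNA uses
the same demography at N_e/4 with haploid sampling, 975-bp sequences and a
5e-8 per-bp rate chosen to give a few mutational steps between demes.
Passing tests on these data show the estimators and inference loop are
correct under the generating model; they do not validate robustness to the
artefacts real ddRAD data add.

## Numerical and scale choices

Desk-scale defaults keep the full test suite at minutes on one CPU: profile
recovery tests use 6,000-locus observed spectra and 100,000-genealogy
evaluations; the full-scale script uses 20,000 loci and 400,000-genealogy
evaluations with ~40-point grids.  Bootstrap coverage is checked on a
two-deme toy (6 meta-replicates × 8 bootstrap replicates).  The exact HWE
test, rarefaction, and projection are exact; tolerances of 1e-9 apply only
where float summation order differs from the oracles'.

## Known limitations

Composite likelihood treats SNPs as independent, so CL differences
overstate evidence and AIC is heuristic here (the bootstrap, not CL
curvature, carries the uncertainty statements).  The optimiser's coordinate
search can stall on strongly correlated parameters (e.g. N_anc vs root
time); profiles over one parameter with others fixed avoid that but ignore
parameter covariance.  The median-joining implementation targets small
mtDNA haplotype sets (tens of haplotypes); its triple enumeration is
quadratic-cubic in nodes.  VCF support is biallelic SNPs with GT/DP only;
phasing, multi-allelic sites and structural variation are out of scope.
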