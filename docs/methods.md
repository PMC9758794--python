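# Methods

This note documents the models, estimators and numerical choices behind
`raddemog`, and what the synthetic-data experiments do and do not show.

## Data model

The pipeline operates on called diploid genotypes at biallelic SNPs
grouped into RAD loci of 125 bp (single-end reads). A
`GenotypeDataset` stores alternate-allele copy numbers (0/1/2, missing
allowed), the locus id and 1-based within-locus position of every SNP,
optionally a per-cell read-depth matrix and per-site coordinates.
Working on called genotypes is an explicit simplification of
genotype-likelihood pipelines used for low-coverage data: the same
estimators are computed, but uncertainty in individual genotypes is not
propagated. All synthetic experiments generate complete-information
genotypes, so tests validate the estimators, not robustness to calling
error.

## Filters

Five filters run in a fixed order: depth (cells with fewer than 3 reads
become missing; a site entirely masked is dropped), last-5-bp of locus,
heterozygote excess (SNPs heterozygous in ≥80% of non-missing
individuals; paralog signature), locus SNP count (loci with more than 5
surviving SNPs dropped entirely), and an optional minor-allele-frequency
floor (used only for FST, per the source pipeline's convention). Each
site counts toward the first filter that removes it, so the attrition
report sums exactly. Heterozygosity is computed over non-missing
individuals; the 80% rule is inclusive (≥).

## Site frequency spectra and diversity

Folded spectra count minor alleles: a site with alternate count *c* in
*n* haploids contributes to class min(*c*, *n−c*). Sites with any
missing genotype among the selected samples are excluded
(complete-case) and the exclusion count is reported. Joint 2D spectra
fold on the *global* minor allele: entry (i, j) with i+j > (n1+n2)/2 is
added to (n1−i, n2−j); exact ties stay where they fall (the convention
is stated because the source of a folded 2D-SFS file must match).

θπ (mean pairwise difference), θw (Watterson) and Tajima's D follow the
classical definitions, with θπ and θw reported per site (L includes
monomorphic sites) and D computed from the totals with the Tajima
(1989) normalizing constants. D is `None`, never silently NaN, when no
site segregates.

The significance of D is assessed against a constant-size coalescent
null matched to the data: L sites arranged as independent 125-bp loci,
population size θw/(4μ). By default the simulated SNP count is random
(Poisson, i.e. conditioning on θw); conditioning on the observed S is
available, since the choice is a genuine modelling fork — conditioning
on θw propagates the mutational variance of S into the null, which is
the more conservative reading. The p-value is the two-sided fraction of
replicates with |D| at least as extreme.

### Vectorized single-population sampler

The D null needs millions of constant-size genealogies, which is out of
reach through per-replicate tree-sequence simulation. A vectorized
Kingman sampler (numpy) draws branch-length AFS vectors for independent
genealogies under piecewise-constant diploid size: level waiting times
are piecewise-exponential (rate C(k,2)/(2N(t))), topology is simulated
by uniform pair merging across all replicates simultaneously, and
per-class branch lengths are accumulated by bincount. Cost is a few
microseconds per genealogy. The sampler is cross-validated against
msprime (constant and size-change histories) in the test suite, and is
used only for unstructured models; every structured demography (island,
stepping-stone, isolation/migration) runs through msprime.

## Reynolds-type FST

The differentiation estimator is a two-population coancestry moment
estimator in the Reynolds (1983) tradition, computed from sample allele
frequencies and haploid sample sizes c1, c2:

    h_i   = 2 p_i (1 - p_i) c_i / (c_i - 1)         (unbiased 2P(1-P))
    alpha = (p1 - p2)^2 - h1/(2 c1) - h2/(2 c2)      (unbiased (P1-P2)^2)
    denom = alpha + (h1 + h2) / 2

so that E[alpha]/E[denom] equals the coancestry θ under the standard
drift model. Multi-SNP FST is the ratio of sums (Σα / Σdenom), which
weights SNPs by information content. Being unbiased, the estimator is
centred on 0 — not clamped at 0 — for identical populations, and equals
1 exactly for fixed differences. Significance uses label permutations
preserving group sizes, with the +1 correction (p is never 0). The
Mantel IBD test correlates FST/(1−FST) with great-circle distance
(haversine; a user distance matrix is accepted since over-water
distances may be more faithful) and permutes site labels of the genetic
matrix.

## Spatial-structure ABC

Three single-site scenarios: NS (one population, instantaneous size
change N_mod→N_anc at T_s), FIM (100 demes exchanging Nm migrants per
generation uniformly, all colonized at T_col from an ancestor of size
N_anc), SS (same but migration restricted to the four nearest
neighbours of a non-periodic 10×10 grid; edge demes keep 2–3
neighbours, per-pair rate Nm/(4 N_deme)). Sampling one deme of a
structured metapopulation skews the SFS toward intermediate
frequencies (positive D), which is what the classifier exploits.

Default priors (log-uniform N ∈ [100, 1e5] diploids, T ∈ [100, 1e6]
years, Nm ∈ [0.05, 50]) bracket the fitting search bounds and are
deliberately wide; they are overridable, and tests use narrower priors
purely to keep simulation time down. Summaries are the folded SFS
normalized to proportions (comparable across θ), per-site θπ and θw,
and D; simulations with no SNP get uniform proportions and D = 0 so the
reference table has no holes. Two linear-discriminant projections
(fitted on the table, applied unchanged to the observation) can be
appended. Classification is a 500-tree random forest with out-of-bag
error checkpoints every 50 trees; the posterior probability of the
selected model regresses the OOB misclassification indicator on the
summaries with a second forest (vote share is the fallback). An
observation outside the reference table's feature ranges triggers a
prior-misfit warning.

## Isolation/migration fitting

Two populations (IP, AO) with modern sizes N_mod changing exponentially
back to ancestral sizes N_anc_IP / N_anc_AO over T_s years, merging at
T_div into an ancestor of size N_anc; migration is asymmetric and
either two-epoch (split at T_mig; `full` = both epochs, `anc` / `rec` =
one), constant (`bsc`) or absent (`div`); free-parameter counts are
13/11/11/10/8. Times are years (converted at 10 y/generation), sizes
diploid, and migration is reported as forward migrants per generation,
converted internally to backward per-generation fractions with the
receiving population's modern diploid size. Epochs are indexed backward
from the present. If a drawn T_s (or T_mig) exceeds T_div it is
truncated at T_div.

The expected folded 2D-SFS is the mean branch-length joint AFS over
`n_sims` independent genealogies (branch mode has the same expectation
as mutation placement with lower variance per genealogy), folded and
converted to per-site probabilities with μ. The monomorphic cell is a
likelihood class (p(0,0) = 1 − μ·E[total branch length]): this is what
identifies the absolute size/time scale, because the polymorphic-cell
proportions alone are exactly invariant under jointly rescaling every
size and time (with migrant numbers held fixed), so a relative-SFS fit
cannot return absolute divergence times or sizes. The two fixed/tie
cells of the folded spectrum are excluded (their folding is
convention-dependent); empty polymorphic cells are floored at
1/(10·n_sims) of the polymorphic mass before the log. The composite
likelihood pools observed entries below `min_entry` (default 10) into
one class and is Σ m_c ln p_c; natural log internally, with a log10
view for comparison with other software. AIC = 2k − 2 lnL uses the
natural log.

Maximization works in log10 parameter space (migration floored at 1e-3
in log space since its lower bound is 0) from Latin-hypercube random
restarts, each optionally searched with bounded Nelder–Mead for at
most `maxiter` outer cycles. Within a run the Monte-Carlo seed is
fixed (common random numbers), making the objective deterministic and
the search stable despite simulation noise. The surface has strong
local optima — a symmetric-migration configuration mimics the
asymmetric truth to within a few hundred log-likelihood units and is
conditionally optimal in every single coordinate — so random restarts
are complemented by data-driven structured starts: the size scale from
Watterson moments of the observed marginal spectra crossed with a
coarse grid of divergence-time multiples and migration regimes
(symmetric, strongly asymmetric either way, near-isolation). All
endpoints are scored with one shared seed and the best endpoint of
each migration regime (then the rest by score) is deepened with a
wide-simplex adaptive Nelder–Mead run, whose coordinated steps follow
the correlated valleys that defeat coordinate-wise search; the
incumbent then gets a short polish and, optionally, a low-noise
continuation at a larger `n_sims` — the Monte-Carlo error of the
expected SFS is what limits how finely the weakly-constrained small
migration rate can be resolved. The reported restart count is the
number of distinct random starting points.
Model choice compares AIC of the best run per model; the
distinguishability check re-estimates each fitted model's likelihood
distribution (independent Monte-Carlo draws at the ML parameters) and
declares models distinguishable when central 95% ranges are disjoint.
Confidence intervals are parametric-bootstrap 5th/95th percentiles from
refits of spectra re-simulated at the ML estimate.

## Skyline

The expected folded SFS under piecewise-constant N(t) is computed
exactly: the lineage-count death process (rates C(k,2)/(2N)) is
propagated through epochs with matrix exponentials, expected level
occupancy times combine with the classical subtending probability
C(n−i−1, k−2)/C(n−1, k−1), and folding gives expected class lengths.
Per-epoch sizes (log10, bounds 10–3×10^7) maximize a Poisson composite
likelihood of the folded class counts (λ_i = μ L E[ℓ_i]), which pins
the absolute size scale without a separate θ parameter. Epoch
boundaries sit on coalescent-time quantiles of the Watterson size
(geometric lineage levels); the epoch count is chosen by AIC among
{2, 4, 7, 9}. Bands are nonparametric site bootstraps (multinomial
over classes including the monomorphic class) at a configurable level,
75% by default. Singletons are included by default — they dominate the
signal about recent sizes but are also the most sensitive to calling
error in real data, the standard caveat. This is a simplified
stairway-style estimator, not a reimplementation of any specific tool.

## Synthetic data

Presets bundle demography, sample sizes and sequencing characteristics.
`paper_im_bsc` uses the published ML parameters of the inter-ocean
IM-bsc fit with 6+6 diploids and 60,000 loci (within the per-site locus
range of the study); `panmixia` is a single 10,000-diploid population.
Depth is negative-binomial with mean 12.65 and s.d. 6.36 (the study's
reported coverage moments; dispersion r = m²/(s²−m) ≈ 5.76), and
missingness arises only through the depth-3 filter, mirroring the
pipeline's logic. The generators do not emulate sequencing error,
paralog collapse, allele dropout or genotype-likelihood uncertainty, so
passing tests demonstrate correctness of the estimators under the
assumed model, not robustness to those artefacts.

## Problem sizes in tests and the acceptance script

Simulation-backed checks are scaled to desk size as the package's own
choice of experiment design: the IM-bsc recovery experiment fits a
70,000-locus spectrum (~47k polymorphic sites) with 20 random restarts
plus the structured starts, regime-diverse deepening, migration
profiling and two low-noise refinement restarts, every expectation
evaluated from at least 5000 coalescent simulations; FST reproduction
averages five 25,000-locus genotype replicates; calibration
experiments (type-I error of the FST permutation and D simulation
tests) use 300 trials each. Bootstrap-interval calibration is checked
where per-fit cost permits a meaningful trial count — the skyline
site-bootstrap band at nominal 90% over 25 constant-size replicates —
while the isolation/migration parametric bootstrap is exercised
structurally (interval ordering, non-convergence accounting, and both
the per-locus coalescent and the cheaper multinomial resampling modes,
which nearly coincide for short RAD loci carrying mostly 0-1 SNPs).
The corresponding full-scale settings (100 restarts, 300,000
simulations per expectation, 100 bootstraps) remain the library
defaults.
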