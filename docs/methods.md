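# Methods

This note documents the models, estimators and numerical choices behind
`cavepop`, and what the synthetic-data generator does and does not
emulate.

## The inference problem

Given diploid biallelic SNP data for individuals sampled from several
candidate populations (here: caves), the pipeline asks three questions:
do unsupervised views of the genotypes (distances, clustering, ordination,
mixture models, admixture) delineate the sampling sites as genetic
populations; how differentiated are the populations (F_ST, d_XY); and
what do diversity and differentiation imply about effective population
size and migration under an island model?

Two data tracks run in parallel, as is standard for RAD-seq data: hard
genotype calls (a dosage matrix with per-genotype depths) and genotype
likelihoods (three likelihoods per individual and site), the latter
propagating genotype uncertainty instead of fixing calls.

## Island-model simulator

Each site is an independent biallelic locus. Per generation and deme,
the allele frequency first mixes toward the mean of the other demes,
`p' = (1-m) p + m mean(others)`, then drifts by binomial resampling of
`2 Ne` allele copies. Sampling draws `n_i` diploids per deme under
Hardy-Weinberg at the final frequencies. Defaults follow the surveyed
study system's dimensions: 4 demes, 10 diploids sampled per deme,
5000 SNPs, ancestral frequencies Uniform(0.05, 0.95). `deme_size = 500`
and 2000 generations are the simulation-scale choices: 2000 generations
is at least three equilibration time constants (rate ≈ 2m + 1/(2Ne)) for
the slowest case studied (4Nem = 0.5), so the drift-migration balance is
effectively stationary.

Deliberate simplifications, hence limits on what passing tests show about
real data: no linkage (2bRAD tags are treated as unlinked, as in the
study design), no mutation during the run (variation enters through
ancestral frequencies; sites may fix and are retained for the filters to
handle), no demographic events, and deterministic frequency mixing rather
than individual migrants. The read layer is Poisson depth with a
symmetric per-base error rate and binomial read-count likelihoods — no
mapping error, allele dropout, PCR duplicates or base-quality structure.
Real 2bRAD data violate all of these mildly; the simulator is a
correctness harness, not an emulator of library-prep artefacts.

### Which F_ST formula the island model predicts

With `d` demes and the migrant pool excluding the home deme, mean
coalescence times give two distinct equilibrium parameters:

- between-deme θ (what Weir-Cockerham/Reynolds-type estimators target):
  `1 / (1 + 4 Ne m d/(d-1))`;
- pooled-total F_ST (what G_ST-style pooled-heterozygosity estimators
  target): `1 / (1 + 4 Ne m (d/(d-1))^2)`.

Both collapse to `1/(1 + 4 Ne m)` for large `d` — the form used for
migration inversion. The package exposes both estimator families
(`reynolds_fst`, `reynolds_fst_multi`, `global_fst` versus
`fst_pooled_total`), and the simulation checks compare each against its
own parameter; empirically both agree with theory to within ~6% at
4Nem ∈ {0.5, 1, 2}, the residual being the upward bias of conditioning
on non-fixed ancestry without mutation.

## Filters

Hard-call track, applied in a fixed order with removal charged to the
first failing rule (order cannot change the retained set, only the
report): per-genotype depth < 2 → missing; then biallelic-SNV,
call-rate ≥ 75%, singleton (minor-allele count exactly 1, the VCFtools
reading), and a one-sided exact Hardy-Weinberg test toward heterozygote
excess at p < 0.1 (lumped paralogs produce excess heterozygosity;
deficits are never filtered). The exact test conditions on the allele
counts and sums the tail `P(het ≥ observed)` with weights
`2^h n! / (n_AA! n_Aa! n_aa!)`; it matches brute-force enumeration over
all equally likely allele placements for every configuration up to 8
diploids (tested exhaustively).

GL track: sample representation ≥ 80%; a SNP likelihood-ratio test
(2·[ℓ(p̂) − max(ℓ(0), ℓ(1))] against χ²₁, keep p < 0.05, where ℓ is the
Hardy-Weinberg allele-frequency log-likelihood) so monomorphic sites are
dropped; a heterozygote-majority screen removing sites whose mean
posterior P(het) under a uniform genotype prior exceeds 50% (the exact
statistic of the original helper script is unpublished; the posterior
expectation is this package's documented stand-in); and a 1% MAF floor on
the MLE frequency, mirroring the -minMaf used for the IBS analysis.

## Structure

The IBS distance samples one allele uniformly per genotype (the
single-read sampling of the original analysis operates on reads; with
hard calls the allele draw has the same expectation) and counts mismatch
fractions over jointly observed sites; `M` per pair is recorded and pairs
with `M = 0` are flagged undefined rather than imputed. Clustering is
scipy agglomerative, average linkage by default (the linkage used in the
study is unstated; it is exposed as a flag). MDS is classical Torgerson
scaling — double-centred squared distances, eigendecomposition, axes
ordered by eigenvalue, non-positive eigenvalues dropped with zero-padding
and a truncation warning semantics. The number of mixture components is
chosen by BIC over Gaussian mixtures on the 3-axis MDS embedding with a
shared ('tied') covariance matrix, 10 restarts per K, K ≥ n excluded;
BIC is reported in the minimise convention (−2 log L + k log n).
scikit-learn offers a shared full covariance but not a shared diagonal
one; the shared-full family is used, which is immaterial for the
well-separated/single-cluster regimes the selection is validated on.

Admixture maximises the binomial likelihood `g_ij ~ Binom(2, Σ_k q_ik
f_kj)` by EM. From genotype likelihoods, the three genotypes are
posterior-weighted against the current Binomial prior each iteration (the
NGSadmix likelihood); the complete-data E-step allocates each allele copy
to ancestral components, which keeps the log-likelihood non-decreasing
(asserted in tests). Numerical choices: relative log-likelihood tolerance
1e-6, max 2000 iterations, 5 restarts by default (2 suffice for strongly
structured data and are used in the large replicate studies), Dirichlet(1)
random Q and Uniform(0.05, 0.95) F initialisation, frequencies clipped to
[1e-9, 1−1e-9]. K = 1 uses the closed form. Label switching is resolved
in evaluation only, by Hungarian assignment of components to demes on
mean ancestry.

## Differentiation

`weir_cockerham_fst` implements the 1984 two-population variance
components a, b, c from genotype counts, including the observed
heterozygosity term; per-site θ̂ = a/(a+b+c), the summary is the
unweighted mean over defined sites, and negative per-site values are
retained (matching common practice; the estimator is unbiased around
zero). Sites need ≥ 2 diploids per population. `reynolds_fst` is the
same moment algebra driven by sample frequencies only, with observed
heterozygosity replaced by its unbiased Hardy-Weinberg estimate
`2 p̂ q̂ · 2n/(2n−1)`; A is the between component and B the total, with
weighted = ΣA/ΣB and unweighted = mean(A/B) over B > 0. (The original
analysis obtained A and B as posterior expectations over genotype
likelihoods; that 2D-SFS machinery is out of scope, and the same algebra
is applied to hard-call or EM frequencies instead.) Both implementations
are checked against independent scalar transcriptions of the published
component formulas at 1e-10. d_XY is `x(1−y) + (1−x)y` from per-population
alt frequencies, averaged over SNPs, and is invariant to joint REF/ALT
relabelling.

Migration inversion: `M = 1/F_ST − 1`, `m = M/(4 Ne)`. F_ST ≤ 0 is
returned flagged undefined (unbounded migration). The Ne entering a
pair's m is the mean of the two populations' Ne by default ('min'/'max'
are exposed); with the survey's genotype-likelihood-based Ne values this
reproduces the published bound m < 1.5e-5, which the hard-call Ne values
would not — the choice consistent with the printed result.

## Diversity and Ne

Hard-call π sums `h = n/(n−1)(1 − p² − q²)` over segregating sites,
using each site's own non-missing sequence count n, and divides by a
caller-supplied `total_positions` (the interrogated-site denominator is
the main lever behind published discrepancies between pipelines, so it is
surfaced explicitly rather than defaulted; simulations pass all simulated
positions). The GL track computes, per site, the likelihood of every
total allele count 0..2N by convolving per-individual vectors
`GL(g)·C(2,g)` and dividing by `C(2N, j)` (exact marginalisation over
genotype configurations with hypergeometric composition weights; equal to
3^N enumeration at 1e-10), folds counts into minor-allele classes 0..N
(class N kept unhalved), estimates the folded SFS by EM over sites
(tolerance 1e-8 on proportions, max 1000 iterations, monotone
log-likelihood), and reports π as the SFS-prior posterior expectation of
`c(2N−c)/C(2N,2)` per site. Missing individuals enter the DP as flat
likelihoods, which is the exact marginal under the composition model. At
high depth the count posterior degenerates to the hard-call count and the
two tracks coincide algebraically (h = c(2N−c)/C(2N,2) when n = 2N),
which the depth-100 equivalence test exploits. A single global π is
computed (the study averaged over 30 pseudo-chromosome blocks; block
averaging changes variance, not the point estimate, and is omitted).

Ne = π/(4µ) with µ defaulting to 2.8e-9, a Drosophila estimate; the true
mutation rates for cave invertebrates are unknown, so Ne values are rough
rescalings of π and carry that caveat in their provenance fields.

## Regression

π against log10(cave length) by OLS (statsmodels), optional additive
species term; slope, intercept, R² and the slope t-test p-value are
reported. The published multiple regression that included both cave name
and cave length is rank-deficient as printed (name determines length), so
only the length + species model is implemented. On the published
diversity table the slope is positive (≈1.2e-3 per log10-metre,
R² ≈ 0.90), the longer-caves-more-diversity pattern.

## Validation scale

The replicate studies in the test suite and acceptance script use the
survey's own dimensions — 4 demes × 10 diploids × 5000 SNPs, 20
replicates per migration level — which keep the full suite within a few
minutes on one CPU while matching the sampling noise of the real design.
The published per-cave/per-pair tables ship in `cavepop.datasets` and
drive the arithmetic stages (Ne scaling, migration inversion, regression);
sequence-level reanalysis of the original survey is out of scope.
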