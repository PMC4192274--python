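# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Phenotype model and its assumptions

The unit of analysis is a de-regressed predicted transmitting ability (DRP)
with an accompanying reliability r² ∈ [0, 1]. DRPs are treated as given
inputs: the de-regression itself (removal of ancestral shrinkage from a
national evaluation) is upstream of this package. The only property the
models rely on is that a DRP behaves like a noisy observation of the
animal's transmitting ability with error variance that shrinks as r² → 1.

## Single SNP regression

The animal mixed model y = 1μ + x_j b_j + u + e with u ~ N(0, A σ²_a)
accounts for genetic covariance among relatives through the pedigree
relationship matrix A, built by the tabular recursion over a topologically
sorted pedigree (inbreeding is handled implicitly; dense storage, intended
for up to a few thousand animals).

Variance components are estimated once, on the null model without any SNP,
by REML: A is eigendecomposed, the restricted likelihood is profiled over
the ratio σ²_a/σ²_e on a log scale (bounded scalar optimization,
`xatol = 1e-8`, explicit comparison against the zero-heritability
boundary), and the components are then held fixed for the scan. This is
the standard EMMAX/GRAMMAR approximation; refitting variance components
per SNP (as a REML package would) changes p-values negligibly away from
very strong signals while costing orders of magnitude more. The adequacy
of the approximation is covered by the type-I-error calibration test
(fraction of p < 0.05 under a pure-polygenic trait within 0.05 ± 0.02).

Within the scan each SNP is fit by generalized least squares with the
fixed covariance structure; the residual *scale* is re-estimated per SNP
from the weighted residual sum of squares divided by n − 2, so that when
A = I and σ²_a = 0 the scan reduces exactly to ordinary least squares.
The Wald statistic is referred to a standard normal (not t): the intended
sample sizes are in the hundreds, where the difference is negligible.
Missing genotypes are mean-imputed per SNP, consistent with treating the
allele count as a continuous covariate. A SNP with zero variance after
imputation is flagged degenerate and reported with b = 0, p = 1.
Residuals are unweighted by reliability (whether the original analyses
weighted them is unknowable from the outside; unweighted is the neutral
choice and the reliability filter bounds the heteroscedasticity).

## q-values

π₀ is estimated on the grid λ = 0, 0.05, …, 0.90 from
\#{p > λ}/(m(1−λ)), smoothed by a cubic least-squares fit and read off at
λ = 0.90, clamped to [1/m, 1]; with fewer than 100 p-values the smoother
is unreliable and π₀ = 1 is returned. q-values follow the step-up
recursion q_(i) = min(π₀ m p_(i)/i, q_(i+1)), which with π₀ = 1 is
exactly Benjamini–Hochberg (verified against an independent
implementation in the tests). "Adjacent" SNPs for QTL merging means
consecutive rows of the position-sorted map on the same chromosome with
no base-pair cap — no distance cap is defensible absent LD estimates, and
the merge is conservative in QTL counts.

## BayesB sampler

Per sweep and per locus, the inclusion indicator and locus variance
(δ_j, σ²_j) are updated jointly by Metropolis–Hastings with the effect
a_j integrated out of the likelihood; the exclusion state δ = 0 has prior
mass π and no conjugate update, which is why the MH construction is
needed. The proposal equals the prior (δ = 0 with probability π,
otherwise σ²_j fresh from scaled-inv-χ²(ν, S)), so the acceptance ratio
is the marginal likelihood ratio

  Δll(v) = −½ [ log(1 + v·x'x/σ²_e) − v (x'w)² / (σ²_e (σ²_e + v·x'x)) ]

with w the residual excluding locus j. Ten proposals per locus per sweep
(`mh_inner`, configurable) give the locus a realistic chance to switch
states each sweep. Included effects, the intercept, and σ²_e are then
Gibbs-updated from their full conditionals; σ²_e uses a flat scale prior,
giving σ²_e | · = SSE/χ²_n. The recorded "summed absolute log-likelihood"
is Σ_i |log N(y_i; fitted_i, σ²_e)|, the literal per-observation absolute
Gaussian log-density sum.

The prior ν = 4.234, S = 0.0429 is the scaled inverse chi-squared
parameterization conventional in genomic prediction (mean νS/(ν−2) ≈
0.081); a scale-only reading was rejected as it has no finite mean at
these values and no precedent in this literature.

Randomness is counter-based: every locus update at every sweep draws from
a splitmix64 stream keyed by (chain seed, a stable 64-bit hash of the SNP
id, sweep index), and loci are visited in the canonical order of those
keys. Chains are therefore bit-reproducible and exactly invariant to the
column order of the genotype matrix. Normal draws use Box–Muller; gamma
draws (for the χ² variates, including non-integer degrees of freedom) use
Marsaglia–Tsang. The kernel is numba-compiled; a divergent (non-finite)
residual variance aborts the run with a diagnostic.

Chains are stored thinned-only (default: every 500th sweep) in an HDF5
container with the configuration embedded.

## Posterior probabilities, windows and the ensemble

Per-SNP PP is the post-burn-in inclusion fraction. Window PPs cover 5
map-adjacent SNPs, slide one SNP at a time, never cross a chromosome
boundary (a chromosome shorter than the window contributes one
whole-chromosome window), and count records in which *at least one*
member is included — hence a window PP always dominates its members'
PPs. The window width addresses LD spreading one QTL's inclusion mass
over neighbours.

The 11-prior grid: the printed endpoints 0.05 and 6.25×10⁻⁵ are fixed;
the six intermediate values are log-uniform between them (the exact
intermediate values used originally are not printed anywhere recoverable,
and log-uniform is the natural spacing for a probability scanned over
three decades; the list is overridable). The three data-derived priors
apply half/identity/double to the associated proportion 1 − pSSR and cap
at 0.5 so π remains a probability; the inline arithmetic in the source
description parses several ways and this is the only reading that keeps
all eleven values valid probabilities. Collisions between the derived and
fixed values are perturbed by half a (log) grid step with a warning so
the ensemble always has exactly 11 distinct analyses.

QTL identity across analyses is member-SNP set intersection with
transitive closure (union-find); an occurrence rate is the number of
analyses contributing to the cluster. The selected analysis maximizes the
average occurrence rate of its QTL; exact ties go to the larger 1 − π
(the more conservative direction is not derivable from the method
description, so the tie rule is explicit and warned about).

## Convergence diagnostics

Three traces per chain: the summed absolute log-likelihood; the count of
SNPs whose *cumulative* PP exceeds 0.5 at each record (a plateau suggests
all high-PP QTL have been found); and the Euclidean distance between the
cumulative posterior-mean BayesB effects and the SSR estimates over the
current high-PP set (threshold 0.5, chosen to match the definition of a
high-PP QTL; the BayesB point effect includes zero draws). Burn-in, done
by eye in interactive practice, is automated here: the reference band is
mean ± 4 SD of the final half of the log-likelihood trace and burn-in is
the first record from which the trace stays inside the band; if none
qualifies the chain is flagged unconverged. All three traces are pure
functions of the stored chain and SSR table, and are also written as SVG
plots for manual review.

## Pathway enrichment

With no gene-length bias correction the over-representation model reduces
to the classical hypergeometric: p = P(X ≥ overlap) with population
|background|, successes |pathway ∩ background| and draws |hits|. Pathway
membership is restricted to the background before testing. Flanks are
measured from member SNP positions (not QTL span ends). Raw p < 0.05 is
reported with no multiplicity correction, mirroring standard reporting of
this analysis; a Benjamini–Hochberg column is available behind a flag.

## The synthetic-data generator

What it emulates, per stage:

* **Pedigree** — discrete generations; each generation forms
  `n_founders // 2` matings of a distinct sire and dam drawn from the
  previous generation, each with `offspring_per_mating` offspring.
* **Genotypes** — founder haplotypes per chromosome with per-SNP allele
  frequencies uniform on [maf_low, maf_high] (defaults 0.05–0.5, a
  post-QC chip spectrum) and first-order Markov dependence with adjacent
  allelic correlation `ld_rho` (default 0.6, moderate chip-scale local
  LD). Descendants receive gametes by gene dropping with one expected
  crossover per chromosome, distributed proportionally to base-pair
  intervals (a one-Morgan chromosome is a standard cattle-scale
  approximation). Genotyping error randomizes a call uniformly in
  {0,1,2}; missingness blanks it.
* **QTL effects** — indices uniform without replacement; per-locus
  variances from scaled-inv-χ²(4.234, 0.0429), matching the analysis
  prior, effects zero-mean normal given the variance.
* **Phenotypes** — g = Xa + u with u ~ MVN(0, A σ²_poly), σ²_poly set so
  the polygenic share of genetic variance is `h2_polygenic`; when no QTL
  are planted the polygenic variance defaults to `h2_polygenic` on a unit
  scale. Observed y = g + ε with Var(ε) = σ²_g(1−r²)/r², the standard
  de-regressed-proof weighting, and r² ~ U(0.70, 0.99), the adjusted
  reliability range typical of progeny-tested sires. The realized g is
  stored only for test oracles.
* **Annotations** — non-overlapping gene intervals (one per equal-width
  slot per chromosome), 0/1/2 human orthologs per gene (default
  proportions 0.2/0.6/0.2 to exercise one-to-many mapping), random
  pathways of 10–200 genes, and one "spiked" pathway drawing 90 % of its
  members from orthologs of genes within 500 kb of a true QTL.

What it does **not** emulate: realistic cattle demography or effective
population size, sequence-level mutation/recombination hotspots, the X
chromosome, genotype intensity clusters, selection, or genotype-derived
polygenic backgrounds (the polygenic term is drawn from the pedigree
covariance and is *not* attached to markers). Consequently, passing tests
demonstrate correctness of the algorithms and calibration under the
assumed covariance structure — not performance on real chip data, where
the polygenic background is itself marker-tagged and LD is more
heterogeneous. Note one interaction: because simulated reliabilities
emulate the *adjusted* range directly, re-running the adjusted-reliability
filter on simulated data (which looks parents up in the same table)
removes a substantial minority of mid-range animals; pipeline-level tests
size their pedigrees with this in mind.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study design:
2,000 SNPs over 5 chromosomes, 300–560 animals, chains of 10⁴–2×10⁵
sweeps. These sizes were chosen so the full suite exercises every code
path, including a full-length 200,000-sweep recovery study, while staying
convenient to run repeatedly during development. Planted-QTL recovery
studies space QTL ≥ 25 Mb apart within a chromosome so that
"distinct locus recovered" is well-defined against LD smearing, and draw
the polygenic term residualized against the planted loci so the stipulated
variance decomposition holds exactly in the realized sample.

Other numerics: A-matrix validation tolerates 1e-12 asymmetry; REML adds
no jitter (eigenvalues are clipped at zero); Cholesky factorizations of
A-derived covariances add 1e-10 relative jitter; p-values are clipped away
from exact zero; the burn-in band uses 4 SD; degenerate inputs (constant
phenotype, empty p-vector, empty background, all-empty ensemble) raise
informative errors rather than returning silently.
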