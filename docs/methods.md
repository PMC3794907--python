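# Methods

## Model

`pathrates` infers evolutionary histories of gene-expression regulation
for *pathways* — a priori gene sets of common function — from expression
measured in a small number of species related by a fixed, time-calibrated
ultrametric phylogeny.

Let X_i be the vector of log expression levels of gene i at the n tips
of the tree. Under a Gaussian diffusion model, X_i ~ N(mu_i, sigma_i^2 V)
where sigma_i^2 is the gene's evolutionary rate and V depends only on the
tree and the model family:

* **Brownian motion (BM):** V_jk is the time shared from the root to the
  MRCA of tips j and k. A *lineage-specific rate shift* multiplies the
  rate on a designated subtree (its stem branch and every branch inside
  it) by a constant r > 0, equivalent to stretching those branch lengths
  by r.
* **Ornstein-Uhlenbeck (OU):** a phylogeny-wide restoring force of
  strength theta (units 1/time) pulls expression toward an optimum. With
  the root fixed at the optimum,
  V_jk = exp(-2 theta (T - t_jk)) (1 - exp(-2 theta t_jk)) / (2 theta),
  with T the tree height and t_jk the shared time (t_jj = T). As
  theta -> 0 this converges elementwise to the BM covariance, so the BM
  model is nested in the OU family; OU is only ever fit phylogeny-wide,
  never combined with subtree shifts.

Two normalizations remove nuisance structure:

1. **Contrasts.** The unknown ancestral mean mu_i is eliminated by
   subtracting a reference species: Y_ij = X_ij - X_i,ref. The contrast
   covariance is V'_jk = V_jk - V_j,ref - V_k,ref + V_ref,ref. Changing
   the reference is a unimodular linear transform of Y, so likelihoods
   and fits are reference-invariant (this is asserted in the tests to
   1e-6).
2. **Mean-centering** (default on). Each contrast column is recentered
   to mean zero across the pathway's genes, absorbing coherent drift
   shared by co-regulated genes. Centering contrasts equals contrasting
   centered expression (the operations act on different axes and
   commute); we center after contrasting. Centering removes one degree
   of freedom per column; no correction is applied for this, and genes
   are treated as independent afterwards — a composite-likelihood stance
   under which model choice and estimates remain correct on average.

Rather than fitting one rate per gene (hopeless for small species sets),
the rates of a pathway's genes are modeled as independent draws from an
inverse-gamma distribution with shape alpha and scale beta. The
inverse gamma has mean beta/(alpha-1) (alpha > 1), variance
beta^2/((alpha-1)^2 (alpha-2)) (alpha > 2), no mass at zero, and is the
conjugate prior to a Gaussian variance, so the rate integrates out in
closed form. Per gene with m = n - 1 contrasts and quadratic form
q = y' V'^-1 y:

    log f(y) = log Gamma(alpha + m/2) - log Gamma(alpha)
             + alpha log beta - (m/2) log(2 pi) - (1/2) log |V'|
             - (alpha + m/2) log(beta + q/2)

a multivariate-t-like heavy-tailed density. The pathway log-likelihood
is the sum over genes. The closed form is verified in the tests against
one-dimensional adaptive quadrature of the mixture integral to 1e-8 in
log space. As alpha -> infinity with beta = alpha s, the density
converges to the fixed-rate Gaussian with rate s, recovering the
one-rate-for-all-genes model as a limit.

## Candidate models and comparison

For each pathway the candidate set is: one equal-rates BM model (k = 2
parameters: alpha, beta); one shifted-BM model per candidate subtree
(k = 3: alpha, beta, r); and one phylogeny-wide OU model (k = 3: alpha,
beta, theta). Candidate subtrees are every proper clade of the tree,
except that one member of each complement-equivalent pair is dropped: a
shift (c, r) on a clade attached at the root and a shift (complement,
1/r) differ only by a global rescaling of V, which the free scale beta
absorbs, so their maximized likelihoods are identical (asserted in tests
to 1e-6). The smaller member of each pair is retained. On the packaged
four-taxon pectinate tree this yields five shift models (four single
species plus the two sister species), hence seven candidates in total.

Models are compared by AIC = 2k - 2 loglik and Akaike weights
w_i = exp(-(AIC_i - AIC_min)/2), normalized to sum to one. AIC (not
AICc) is used; nested likelihood-ratio testing is deliberately avoided
because no a priori null model exists among the candidates. Exact ties
for the best model are broken by smaller k, then declaration order.

## Optimization

The log-likelihood is maximized over log-transformed parameters inside
fixed boxes: alpha in [1e-2, 1e3], beta in [1e-4, 1e4], r in [1e-3,
1e3], theta in [1e-4, 1e3]. The objective is first evaluated on a
deterministic 3x3(x3) log-grid (geometric quartiles of each box), and a
bounded L-BFGS-B search (objective tolerance 1e-12, gradient tolerance
1e-8) is polished from the best four grid points; the best polished
optimum is reported, so the achieved log-likelihood is >= the value at
every grid point. Screening the grid rather than polishing all 27
points costs nothing in the cases we have examined (the surface is
unimodal away from the alpha-theta ridge) and makes the full candidate
sweep roughly seven times cheaper, which the replicate experiments rely
on.

Gradients are analytic: the derivatives in alpha and beta are digamma
expressions; for the shift model V'(r) is linear in r (the affected
branches' contribution enters additively), and for OU dV'/dtheta is the
elementwise derivative of the closed form pushed through the (linear)
contrast transform. The analytic gradient is checked against finite
differences in the tests.

Fitting requires at least two genes (centering and a rate-distribution
fit are undefined for one), and a contrast column that is identically
zero is rejected as degenerate.

## Synthetic data

The simulator generates per-gene log-expression tip values by walking
the tree in preorder, the terminal value on a branch seeding its
daughters, with the root at 0. Families:

* **BM** — increments N(0, rate x branch length); a subtree shift
  multiplies the rate on affected branches.
* **OU** — exact branch transitions
  child ~ N(parent e^(-theta dt), rate (1 - e^(-2 theta dt))/(2 theta));
  exact conditionals for a linear SDE avoid any step-size choice.
* **correlated-BM** — equal-regime BM whose per-branch increments are
  correlated across genes with coefficient rho, realized as
  sqrt(rate dt) (sqrt(rho) z0 + sqrt(1-rho) z_i) with z0 shared. Each
  gene still draws its own inverse-gamma rate; "equal regime" means no
  branch-specific shift, not identical rates across genes.
* **heterogeneous-BM** — the first floor(f G) genes evolve without the
  shift, the rest with it; membership is recorded.

Default generating conditions are those of the validation study:
alpha = 3, beta = 2 (mean rate 1, variance 1), shift factor 5,
constraint theta = 10, pathway sizes 2-100, 100 replicates per
condition. Replicate streams derive from a root seed as
`default_rng([seed, replicate])`, so each replicate is independently
reproducible and the whole experiment is bit-identical under a fixed
seed.

The fixture tree is a pectinate four-taxon ultrametric tree with the
*Saccharomyces sensu stricto* topology (cer, par, mik, bay) and height
0.5 in substitution-like time units, as for a calibrated yeast genome
tree. BM-based inferences are exactly invariant in law to the overall
time scale (a global rescaling of V is absorbed by beta), so the height
only matters for OU: theta has units 1/time, and on a much taller tree
2 theta T saturates the covariance and pushes theta = 10 onto the flat
alpha-theta ridge where only beta/theta is identified. At height 0.5,
theta = 10 is identified with an accurate median and a heavy right tail
in the sampling distribution — the known behavior of this estimator.

What the generator does *not* emulate: measurement/sampling error in
expression estimates, read-count noise, missing data patterns, ortholog
misassignment, and any non-Gaussian (jump) component of regulatory
evolution. Passing tests therefore demonstrate correctness and power of
the inference under the model's own assumptions, not robustness to
those real-data features.

## Pathway scanning

`scan_pathways` resolves each term's genes against the expression
matrix, drops genes with any missing species first, then requires at
least 10 complete genes (the stricter of the two possible filter
orders), fits all candidates, and reports per term: N, the best model,
its weight, the fitted constraint (theta) or shift (r) parameter —
empty for equal rates — and every candidate's weight. Output floats use
9 significant digits. Gene identifiers match exactly and
case-sensitively; ortholog mapping is upstream of this package.

`normalized_divergence` reproduces the visualization-oriented
transform: per species, log fold-change against the reference divided
by the patristic distance to the reference. Note this divides by the
branch length, not its square root, so even under equal-rates BM the
normalized widths are not equal across species (Var(Y_j)/d^2 =
E[sigma^2]/d); the transform is implemented exactly as described and
this caveat is documented rather than resolved. Its qualitative use is
unaffected: under phylogeny-wide constraint the most divergent species
yields the narrowest normalized distribution, which the tests assert.

## Known limitations

* At 100 genes with only three contrasts per gene, the joint MLE of
  (alpha, beta) is biased upward along the alpha-beta ridge (the mean
  rate beta/(alpha-1) is recovered); the bias vanishes by ~1000 genes.
  The shift multiplier r, the quantity of scientific interest, is
  unbiased to within a few percent at 100 genes.
* The mean-centering defense suppresses spurious shift calls only up to
  the per-gene rate dispersion: the residual shared-drift term scales
  with (sigma_i - mean sigma), a rank-one distortion that mimics a
  shift on whichever lineage drifted most. With inverse-gamma rate
  heterogeneity across genes, the centered spurious-call rate is at
  baseline (~0.07) through rho ~ 0.6 but rises steeply above rho ~
  0.75 (~0.67 at rho = 0.9). Centering is never worse than not
  centering at any rho. Very tightly co-regulated pathways therefore
  remain a false-positive risk.
* Under equal-rates generation the equal-rates model is the modal
  winner by a wide margin, but its absolute winning fraction is only
  slightly above one half: the AIC penalty of 2 per extra parameter
  leaves a ~50% chance that at least one of the six 3-parameter
  candidates improves the log-likelihood by more than 1 by chance.
  Individual spurious winners rarely carry high weight (the mean
  equal-rates weight stays the largest).
* OU constraint estimates have a heavy right tail (occasional very
  large theta with compensating beta); medians are reported for this
  estimator.
* No within-species replicate/sampling-error model; trees with more
  than ~10 tips are not a performance target (candidate enumeration is
  linear in clades but each fit is refit per candidate).
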