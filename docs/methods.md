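# Methods

## The neutral sampling model

The package models per-host community counts with the Dirichlet-multinomial
(DMN). For host *i* with species counts x_i and total N_i:

    p_i ~ Dirichlet(gamma),     x_i | p_i ~ Multinomial(N_i, p_i),
    gamma_j = pi_j (1 - theta) / theta,   sum_j gamma_j = (1 - theta)/theta.

* **pi** (simplex vector) — expected relative abundance of each species; in
  the colonization interpretation, each species' effective migration rate
  into the host from an even metacommunity.
* **theta** in (0, 1) — overdispersion: between-host compositional variance
  beyond multinomial counting noise. The marginal moment identity
  Var(x_j/N) = pi_j(1-pi_j)(theta + (1-theta)/N) shows theta -> 0 recovering
  the multinomial; theta is also 1/(1+gamma_+).

The model is *neutral* in the community-ecology sense: species differ in
colonization probability but not in within-host competitive ability, so any
dependence between species counts arises solely from (a) shared totals
("common species are common together" when N varies between hosts) and
(b) finite-sampling noise.

### Likelihood convention

`dm_log_likelihood` includes the multinomial coefficient and uses natural
logs; all Gamma-function ratios are evaluated through `gammaln` differences,
which is stable for totals of order 1e5. Log-likelihoods reported by other
conventions (e.g. coefficient-free) differ by a data-only additive constant;
any likelihood *comparison on fixed data* (fit quality, monotone-ascent
checks) is unaffected.

### Fitting

`fit_dmn` maximizes the likelihood in the unconstrained coordinates
eta = log(gamma), which removes the simplex and positivity constraints;
pi = gamma/gamma_+ and theta = 1/(1+gamma_+) are recovered at the optimum.

* **Initialization** — method of moments: pi0 from mean per-host
  proportions, theta0 by inverting the moment identity above averaged over
  species (clipped to [1e-3, 0.95]).
* **Ascent** — quasi-Newton (L-BFGS-B) with the exact analytic gradient,
  relative function tolerance ~1e-11, at most 500 iterations. Tests assert
  the fitted likelihood dominates both the moment start and a coarse random
  grid, and agrees with `scipy.stats.dirichlet_multinomial` on every point
  evaluation.
* **All-zero species** — excluded before fitting and reported in
  `dropped_species`: their MLE lies on the boundary pi_j = 0, which the
  Dirichlet parameterization cannot represent. (With a rare species at
  pi ~ 0.0015 and ~100 hosts this happens regularly in simulation.)
* **Determinism** — species are canonicalized to name-sorted order inside
  the optimizer, so the fit is exactly invariant to input column order.
* **Uncertainty** — `theta_standard_error` inverts the observed information
  in eta (finite differences of the exact gradient) and applies the delta
  method with d theta/d eta_j = -gamma_j/(1+gamma_+)^2.

## The structure-matched correlation-quantile test

`neutral_correlation_test` asks whether empirical interspecies Spearman
correlations exceed what neutral sampling alone produces *in data of
identical structure*:

1. Fit the DMN to the table.
2. Simulate B data sets (default 10,000) with the same hosts and the same
   per-host totals, taken verbatim from the data.
3. In each — and in the empirical table — compute all pairwise Spearman
   correlations **on raw counts** (average ranks at ties; pairs involving a
   constant species are undefined and excluded; the count of usable pairs is
   recorded per data set).
4. Compare chosen quantiles (default 20th and 80th, linear-interpolation
   convention) of the empirical correlation set with the null distribution
   of the same quantiles:
   p_lower = #{sim q20 < empirical q20}/B,
   p_upper = #{sim q80 > empirical q80}/B.

Counts, not relative abundances, are deliberate: the null distribution
itself carries the positive compositional coupling induced by variable
totals, so the test does not mistake that artifact for facilitation.
Strict inequalities follow the "percentage of simulated data sets with a
lower/higher quantile" definition; an `inclusive` tie rule
((#{<=}+1)/(B+1)) is available for sensitivity analysis. The whole
procedure is reproducible from one integer seed and exactly invariant to
species column order (the Dirichlet/multinomial draws are made in a
canonical component order and mapped back; otherwise the RNG stream would
depend on column layout).

Quantiles are computed over the unweighted upper triangle of the correlation
matrix. Empirical data are expected to be low-count-filtered first (see
data handling below).

## Shannon diversity and the lineage LRT

`shannon` is H = -sum p_j ln p_j (natural log; zero proportions contribute
0), with ceiling ln k — ln 8 ≈ 2.08 for the eight-species system.
`diversity_size_fit` regresses H on log10(total CFU) by OLS; slope,
intercept, adjusted R², slope p-value and the Gaussian ML log-likelihood
(-n/2 (ln(2π SSE/n) + 1)) are returned.

`diversity_size_lrt` compares H0 (one line, one residual variance, pooled
hosts) against H1 (separate line per lineage). By default each lineage also
keeps its own residual variance, so the parameter-count difference is
df = 3 (slope, intercept, variance); `common_variance=True` shares one
variance (df = 2). The default was chosen because per-lineage fits are
reported with per-lineage SSE in this style of analysis; both conventions
calibrate correctly under the null in the package's tests (KS-uniform
p-values at 500 repetitions), and the statistic equals the SSE form
n0 ln(SSE0/n0) - sum_g n_g ln(SSE_g/n_g) algebraically.

## Ordination statistics

* `log_standardize` — ln(count+1), then per-species z-scoring (mean 0,
  sd 1 with n-1 denominator). The pseudo-count is forced by zeros; the log
  base affects only scale. Alternatives (`total`, `hellinger`, `none`) are
  exposed because "standardization" is a genuinely open choice.
* `pca` — SVD of the column-centered matrix; each component's sign is fixed
  so its largest-magnitude loading is positive; explained-variance
  fractions sum to 1 over all components.
* `bray_curtis` — d(u,v) = sum|u-v| / sum(u+v), applied to the ln(count+1)
  values (z-scored values can be negative and are invalid here). An
  all-zero host pair gets distance 0 with a warning.
* `anosim` — R = (mean rank of between-group distances - mean rank of
  within-group distances)/(M/2) over the M = n(n-1)/2 pairs.
* `permanova` — one-factor pseudo-F from the squared-distance
  decomposition SS_total = sum d²/n, SS_within = per-group sums.

Both permutation tests default to the add-one Monte-Carlo p,
(#{stat_perm >= stat_obs} + 1)/(n_perm + 1) — the standard unbiased
convention whose floor at 999 permutations is 0.001 — with defaults of
9,999 permutations for ANOSIM and 999 for PERMANOVA. `exact=True`
enumerates all label permutations (n <= 9) and returns the plain fraction
at least as extreme, identity included; tests verify Monte-Carlo/exhaustive
agreement and cross-check statistics against scikit-bio.

## Data handling

Count tables are hosts x species integer matrices with a lineage label per
host (CSV/TSV/XLSX; header row of species names). Low-count hosts are
removed *before any analysis* — defaults: total < 100 CFU for the
derepressed-immunity (*daf-2*) lineage, < 1,000 CFU otherwise, reflecting
plate-count reliability at each lineage's typical community size. Host
filtering precedes species dropping, because the low-count judgment applies
to the full community total; a test pins this order. Zero-total hosts are
legal inputs and only removed by the filter.

## The synthetic-data generator

`synthetic` emulates the study conditions the analysis assumes:

* **Neutral preset** (`n2_neutral_spec`) — 8 species named MYb120…MYb71,
  pi = (0.0096, 0.0015, 0.0384, 0.0866, 0.0290, 0.0828, 0.0903, 0.6619)
  renormalized (the 4-decimal values sum to 1.0001), theta = 0.1698 — the
  wild-type maximum-likelihood fit — and per-host totals from a log-normal
  (meanlog = ln 13,000, sdlog = 0.8) truncated to [1,680, 67,200], matching
  the observed envelope (median ~1.3e4, ~two orders of magnitude span).
* **Interacting alternative** (`generate_interacting`) — logistic-normal-
  multinomial: z ~ N(mu, sigma) per host, composition softmax(z), counts
  multinomial. Chosen as the alternative because it nests compositional
  coupling and arbitrary correlation sign structure with few parameters;
  it is a modeling choice of this package, not a mechanistic colonization
  model.
* **Competition preset** (`n2_interacting_spec`) — sigma = L² b bᵀ with
  loadings L = 1.5 and b splitting the species into two anticorrelated
  blocks (a single competitive trade-off axis). A lone anticorrelated pair
  is a poor alternative for the quantile test: the softmax coupling it
  induces among the remaining species turns most pairs strongly positive
  and leaves the 20th quantile untouched; one factor with mixed signs
  drives 16 of 28 pairs negative at once. Loading 1.5 is the frozen
  "strong" effect size used in the power checks.

### What passing tests do and do not show

The generator reproduces the *statistical* structure the analysis assumes:
DMN compositions, realistic totals, and an interacting alternative. It does
not emulate plate-count measurement error, colony-morphology
misclassification, day/replicate batch effects, temporal succession, or
host-to-host covariates — so calibration and power results here demonstrate
correctness of the inference machinery under the stated model, not
robustness of the scientific conclusions to those real-data complications.

## Problem sizes and numerical choices

The self-test suite runs the expensive procedures at reduced but still
informative scale, chosen so each check has real statistical power: type-I
calibration at 200 neutral data sets of 100 hosts with B = 500 simulations;
power at 100 interacting data sets of 150 hosts; LRT calibration at 500
repetitions of 100+100 hosts; parameter recovery at 2,000 hosts of 10,000
CFU. `scripts/acceptance.py` re-runs the same computations from a single
seed. Production analyses should use the B = 10,000 default.

Tolerances: pmf normalization to 1e-10 (enumeration at k <= 3, N <= 6);
optimizer relative tolerance ~1e-11; simplex validation at 1e-8;
LRT statistics clipped at -1e-8 for numerical noise. Ties in ranks use
average ranks; quantiles interpolate linearly between order statistics.

## Known limitations

* The DMN cannot represent boundary abundances (pi_j = 0); all-zero species
  are dropped rather than fitted.
* The neutral test conditions on the *fitted* (pi, theta) rather than
  propagating their uncertainty (a parametric bootstrap, not a Bayesian
  posterior); calibration tests show the effect is negligible at the study
  sample sizes, but at very small n the p-values can be mildly
  non-uniform.
* ANOSIM/PERMANOVA treat hosts as exchangeable under the null: replicate
  or batch structure, if present, must be handled upstream.
* No partial-correlation or compositionality-corrected network inference is
  attempted; the claim structure is exactly the quantile test.
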