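# Methods

## The model

`ncdmap` estimates relative mortality risk jointly for several disease
groups over areas (countries) and years. Let `Y_itd` be observed deaths in
country `i`, year `t`, disease group `d`, and let

    E_itd = P_it * R_itd / 100000

be the expected deaths implied by the population `P_it` and the
age-standardized mortality rate `R_itd` (per 100,000). The observation
model is Poisson with multiplicative relative risk `theta`:

    Y_itd ~ Poisson(E_itd * theta_itd)
    log(theta_itd) = alpha_d + x_it' beta + lambda_i + u_id
                     + phi_t + v_td + psi_itd

with seven latent pieces:

| component | structure | role |
|---|---|---|
| `alpha_d` | iid Gaussian, precision `tau_alpha` | disease-specific level |
| `beta` | Gaussian, fixed precision 0.001 | covariate effects (z-scored scale) |
| `lambda_i` | BYM2(`tau_lambda`, `rho_lambda`) | spatial risk shared by all diseases |
| `u_id` | BYM2(`tau_u`, `rho_u`) per disease | disease-specific spatial residual |
| `phi_t` | RW1(`tau_phi`) | temporal trend shared by all diseases |
| `v_td` | RW1(`tau_v`) per disease | disease-specific temporal residual |
| `psi_itd` | iid Gaussian grouped by disease, `tau_psi` | space-time interaction |

Shared components enter every disease with unit loading; the model contains
no estimated cross-disease loadings. Covariates vary by `(i, t)` only and
are z-scored (sample sd, denominator n−1) over the unique country-year
cells before fitting, so `beta` is interpreted per one-sd increase. A
single `beta` is common to all diseases. The disease intercepts `alpha_d`
are iid (not sum-to-zero constrained) and absorb the overall level; no
separate global intercept is estimated.

### Spatial and temporal structures

The structured spatial half is an intrinsic CAR on the country adjacency
graph (`Q = D − W`, rank `I − c` with `c` connected components). The
default study graph is the seven EAC member states joined by land borders
(queen contiguity); the lake-separated COD–TZA pair is excluded by default
and can be toggled, since contiguity across Lake Tanganyika is a genuine
modeling choice. Temporal structures are first-order random walks
(first-difference penalty, rank `T − 1`).

Both intrinsic structures are *variance-scaled*: `Q* = s·Q` where `s` is
the geometric mean of the marginal variances under the sum-to-zero
constraint (diagonal of the constrained generalized inverse). After
scaling, a precision parameter means the same thing for every component,
which is what makes a common penalized-complexity prior sensible. The RW1
components are scaled exactly like the BYM2 structured parts for the same
reason.

The BYM2 field is `b = (sqrt(rho) u* + sqrt(1−rho) v)/sqrt(tau)` with `u*`
the scaled ICAR half and `v` iid; internally the pair `(b, u*)` is kept
with its joint precision, which is sparse-structured and positive definite
on the constrained subspace for `rho` strictly inside (0, 1).

### Identifiability constraints

Sum-to-zero constraints are imposed on: the combined shared spatial effect
and its structured half; both halves of each disease-specific spatial
field; the shared temporal trend; and each disease-specific trend.
Constraints are implemented by reparameterizing each block onto an
orthonormal basis of the constraint null space (`z = B w`), on which every
restricted prior precision is positive definite. For centered Gaussians
this is algebraically identical to conditioning by kriging, which the test
suite uses as the independent oracle.

### Hyperpriors

Every precision gets a PC prior: exponential on the sd scale, calibrated by
`P(sigma > U) = alpha` with defaults `U = 1, alpha = 0.01`. The BYM2
mixing parameters get the eigenvalue-based PC prior built from the
Kullback–Leibler distance to the iid base model, calibrated by
`P(rho < 0.5) = 2/3`. Because the distance is monotone in `rho`, the CDF
(and hence the calibration) has a closed form given the rate; only the
eigenvalues of the scaled structure are needed. All calibrations are
configurable per component.

## Inference

Inference follows the classical two-level scheme for latent Gaussian
models. For fixed hyperparameters the latent field (fixed effects included)
has a strictly log-concave posterior, optimized by Newton iterations with
step halving (monotone by construction; convergence at gradient norm 1e-8
or step norm 1e-10, with a relative floating-point floor for extreme
precisions). The iid interaction block — one cell per observation — is
eliminated by a Schur complement, so each Newton step costs one dense
factorization of the small structured block (~170 dimensions at the default
design) plus diagonal work, a few milliseconds at study scale.

The Laplace approximation at the mode yields the marginal likelihood of the
hyperparameters, explored by adaptive random-walk Metropolis on
`(log tau, logit rho)` (Robbins–Monro scale adaptation toward 0.35
acceptance plus empirical proposal covariance, both frozen after burn-in).
At each retained hyperparameter draw, latent draws come from the Gaussian
conditional; an optional independence-Metropolis refresh targets the exact
conditional (used where exactness matters, e.g. the one-cell validation
model, where the refresh acceptance rate is ~0.96). Defaults are 5,000
iterations with 1,000 burn-in; the test suite and acceptance script use
shortened chains (roughly 400–1,100 iterations) chosen as the package's
test-scale settings — posterior means and intervals at study scale are
stable well before the default lengths.

Posterior summaries report mean, sd, 2.5/50/97.5% quantiles and a kernel
density mode (Gaussian KDE, Silverman bandwidth). The sampler is
bit-reproducible under a fixed seed.

## Diagnostics

- **DIC**: `p_D` = mean deviance − deviance at the posterior mean of the
  linear predictor.
- **WAIC**: log-sum-exp `lppd` and the per-row posterior variance of the
  log-likelihood; computed from the retained per-row log-likelihood matrix,
  which is stored so brute-force recomputation is possible (and tested).
- **CPO / LCPO**: the harmonic-mean estimator per row, with failure
  detection by importance-weight concentration (largest normalized weight
  above 0.95) or non-finiteness. LCPO is reported both as the sum and the
  mean of log CPO since conventions differ.
- **Leave-one-out PIT and coverage**: the harmonic-mean route degrades
  badly for this model class: with an iid per-cell interaction and large
  counts, the in-sample posterior of a cell's predictor sits many prior sds
  from its leave-one-out version, and no feasible number of draws bridges
  that gap with importance weights. The package therefore computes LOO
  predictive checks by *Gaussian likelihood subtraction*: for each retained
  hyperparameter draw the sampler stores each row's conditional Gaussian
  marginal `N(m_i, v_i)` and likelihood curvature `W_i`; removing the row's
  own linearized likelihood gives the LOO Gaussian (precision
  `1/v_i − W_i`, positive by construction at fixed hyperparameters),
  against which the Poisson mid-CDF and pmf are integrated by
  Gauss–Hermite quadrature and averaged over draws. PIT is the discrete
  mid-PIT (`P(Y_rep < y) + 0.5 P(Y_rep = y)`), deterministic rather than
  randomized. The 95% predictive-coverage statistic is the fraction of LOO
  PIT values in [0.025, 0.975]. A plain in-sample posterior-predictive PIT
  is also available, but with per-cell effects it concentrates near 0.5 by
  construction and is not a calibration check.
- **Observed vs fitted**: per-row posterior mean of `E*theta` with 95%
  posterior-predictive intervals from sampled replicate counts.

On data simulated from the model at the default conditions, the LOO PIT
passes a Kolmogorov–Smirnov uniformity check at the 1% level and the LOO
coverage is consistent with 95% — both verified by the test suite, which
also checks that the PIT of the *generating* truth has the same KS
magnitude (i.e. the fit is at the data-noise floor).

## The synthetic-data generator

The generator is first-class, tested code that defines the study
conditions: a balanced panel over the EAC graph, 4 disease groups and 20
years (2000–2019; 560 rows). Its defaults, fixed once:

- **Populations**: log-uniform in 1e6–1e8 persons per country, growing
  1.5%/year — national scales typical of the region.
- **Baseline age-standardized rates** per 100,000: cardiovascular 250,
  neoplasms 120, respiratory 80, diabetes 40, each perturbed per country by
  a lognormal factor (sd 0.15); constant over years (trends enter through
  the latent temporal components, not the offset).
- **Covariates**: eight named series (NDVI, temperature, precipitation,
  GDP per capita, health expenditure, urbanization, population density,
  PM2.5), each a stationary AR(1) in time (coefficient 0.7, stationary sd
  0.5) around a country mean smoothed one step along the graph (weight
  0.5), affine-mapped to realistic unstandardized scales.
- **Generating effects**: `beta` on the standardized scale between −0.12
  and +0.12 with epidemiologically sensible signs (PM2.5 and urbanization
  positive; GDP and health expenditure negative); latent sds 0.1–0.4 on the
  log-risk scale (`rho_lambda = 0.6`, `rho_u = 0.5`) — moderate effects
  typical of national-level disease mapping.

Latent effects are drawn from the *same constrained, scaled priors the
model fits*, so recovery and calibration tests are exact self-consistency
checks. The generator does not emulate real EAC mortality levels, reporting
artifacts (e.g. rounding or missingness), or within-country heterogeneity;
passing tests demonstrate that the machinery is correct and calibrated
under the model's own assumptions, not that the model is adequate for any
particular real dataset.

## Numerical choices and edge cases

- Linear-predictor overflow guard at |eta| > 35: the likelihood reports
  −inf rather than overflowing, and the Newton line search backs off.
- Graphs with no edges are permitted but warned about (ICAR degenerates to
  zero); variance scaling of an all-zero structure is an error; isolated
  nodes are excluded from the scaling geometric mean with a warning.
- `rho` exactly 0 or 1 is valid for combining draws but not for the joint
  BYM2 precision; the sampler works on the logit scale and never touches
  the boundary.
- Constraint violations in user-supplied states raise rather than being
  silently projected.
- Newton failures during hyperparameter proposals reject the proposal and
  are counted in the sampler metadata; a post-adaptation acceptance rate
  outside [0.05, 0.95] is recorded as a warning.
- Perfectly collinear covariates yield infinite, flagged VIFs rather than
  an exception.

## Design choices on genuinely open points

- The adjacency rule for the study region is not standardized anywhere;
  land-border queen contiguity with an explicit lake-border toggle
  documents the ambiguity instead of hiding it.
- VIF is computed on standardized covariates over unique country-year
  cells (with the regression's own intercept); computing on raw covariates
  is available by argument.
- One common interaction precision `tau_psi` is the default; per-disease
  interaction precisions are exposed via `psi_by_disease`.
- The "exactly permuted under relabeling" exchangeability property holds
  for the deterministic Laplace mode and is tested there; sampled draws are
  equivariant in distribution only, because constraint-basis factors are
  not permutation-equivariant.

## Known limitations

- The hyperparameter posterior is explored by a single adaptive chain; no
  cross-chain convergence statistics are computed.
- The Laplace approximation is a mode/curvature approximation per
  hyperparameter value; no higher-order (skewness) corrections are applied.
  At the count magnitudes of national NCD panels the approximation error is
  far below posterior uncertainty (verified against quadrature in 1-D and
  against IRLS in the GLM limit).
- Spatial precisions estimated from 7 areas are weakly identified and
  prior-shrunk; simulation recovery is within a factor of two for most but
  not every replicate, dominated by the disease-replicated and temporal
  components.
- No support for higher-order random walks, Leroux priors, structured
  space-time interactions, estimated shared-component loadings, or
  non-Poisson likelihoods (the Gaussian likelihood exists for validation
  only).
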