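# Methods

## The survival model

We model a population mixing susceptible and non-susceptible subjects through
a bounded-cumulative-hazard (promotion-time) law. Mechanistically, subject
`i` with binary group `w` carries `N ~ Poisson(theta(w))` latent competent
clones; each clone activates at an i.i.d. time with proper distribution
`F(t|w) = 1 - exp(-H0(t) e^{beta w})`; the event is the first activation, and
subjects with `N = 0` never fail. Marginally

    S(t|w) = exp{-theta(w) (1 - e^{-H0(t) e^{beta w}})},  theta(w) = theta0 e^{alpha w}.

The cumulative hazard is bounded by `theta(w)`; the tail defect
`exp(-theta(w))` is the non-susceptible fraction. A form sometimes written
with `S = exp{-theta(w)[1 - H(t|w)]}` and `H` increasing to infinity is not a
distribution; the bounded form above is the one consistent with the two-group
hazard ratio

    lambda(t,1)/lambda(t,0) = e^alpha e^beta exp(-H0(t)(e^beta - 1)),

which equals `e^{alpha+beta}` at `t = 0`, is constant only when `beta = 0`,
and otherwise crosses 1 in finite time. That crossing is the key statistical
feature: a dynamics-only (`beta`) effect produces early excess events balanced
by a late deficit, which a plain logrank statistic integrates away.

Parameters and defaults: `theta0 > 0` (baseline mean clone count; cure
fraction `e^{-theta0}`), `alpha`, `beta` (log effects), `H0` a Weibull-type
baseline `(t/scale)^shape` with shape 1, scale 1 by default (exponential clone
times). Simulation requires an invertible (parametric) `H0`; event times are
drawn in closed form as `H0^{-1}(E / (N e^{beta w}))` with `E ~ Exp(1)`.
Censoring is administrative at a fixed horizon (mirroring a fixed monitoring
window), optionally combined with independent uniform dropout; the censoring
distribution of the motivating study is not identifiable from its report, so
administrative censoring is the default and all studies here state their
horizon.

## The splitting statistic

At a node, for a candidate binary split, we use the score of the model at the
null `alpha = beta = 0` with the baseline profiled by plug-ins: the
Nelson-Aalen estimate `Lambda_hat` of the node's pooled cumulative hazard,
`theta0_hat = Lambda_hat(largest event time)`, and
`H0_hat(t) = -log(1 - min(Lambda_hat(t)/theta0_hat, 1 - eps))` with
`eps = 1e-6`. In counting-process form over the node's distinct event times,

    U_alpha = sum_j (d_1j - Y_1j d_j/Y_j)
    U_beta  = sum_j (1 - H0_hat(t_j)) (d_1j - Y_1j d_j/Y_j)
    V_kl    = sum_j w_k(t_j) w_l(t_j) v_j,
    v_j     = d_j (Y_1j/Y_j)(1 - Y_1j/Y_j)(Y_j - d_j)/(Y_j - 1)

with `w_alpha = 1`, `w_beta(t) = 1 - H0_hat(t)` evaluated right-continuously,
and the statistic `U' V^- U` via a generalised inverse (rank decided at
relative tolerance 1e-10 on the 2x2 eigenvalues; the degrees of freedom equal
the rank). `U_alpha` is exactly the logrank numerator. The derivation is
guarded by an oracle used in the tests: `(U_alpha, U_beta)` equals, to within
numerical differentiation error, the gradient of the discrete
counting-process log-likelihood in which group-1 hazard increments are the
baseline Nelson-Aalen increments multiplied by the model's hazard ratio
`r(t; alpha, beta)`.

A within-node label-permutation covariance (default 500 permutations) is
available as an alternative to the hypergeometric `V`; the score vector is
identical under both.

**Known limitation — finite-sample conservativeness.** Because `theta0_hat`
is the terminal Nelson-Aalen value, `Lambda_hat/theta0_hat = 1` exactly at the
largest event time, so the clamp always binds there and the beta weight at
that point is `1 + ln(eps) ≈ -12.8`. When many subjects remain at risk beyond
the last event (the typical administrative-censoring cure setting), the beta
component is then dominated by a single bounded, discrete hypergeometric
term, and the chi-square reference is conservative: across our simulations the
type-I error at the nominal 0.05 level is about 0.034 (95% CI ±0.003 over
10,000 replicates at n = 200). The clamp value trades this conservativeness
against keeping the terminal weight finite; a larger `eps` (e.g. 1e-2)
restores nominal calibration but changes the statistic's definition, so the
default is left at 1e-6 and the behaviour is documented here. Conservativeness
costs some power but does not bias the split search, which only ranks
candidates within a node. For splitting, no p-value is used: the criterion
value is maximised over candidates, with deterministic tie-breaking (lowest
variable index, then lowest threshold).

## Candidate enumeration

Variable kinds drive the candidate set: binary variables contribute their
single partition; 0/1/2 genotypes the dominant (`{0} vs {1,2}`) and recessive
(`{0,1} vs {2}`) partitions; 3-level ordered scores both thresholds plus
optional one-vs-rest dummies; unordered categoricals one-vs-rest per level
(not all subsets — this matches the motivating analysis and bounds cost);
continuous variables every midpoint between consecutive distinct observed
values, or the three quartile cuts in `quartile_mode`. Candidates leaving a
child with fewer than `min_node_size` *distinct* subjects are inadmissible
(bootstrap duplicates never inflate a node).

## Trees and forests

Trees are grown without a depth limit and stop when a node has fewer than
`2 * min_node_size` (default 15) unique cases, has no events, is homogeneous
(identical outcomes and identical feature values across its subspace), or has
no admissible candidate. Leaves store the Nelson-Aalen cumulative hazard of
their in-bag sample on the forest-wide grid of distinct training event times,
so trees average pointwise; Nelson-Aalen is preferred over Kaplan-Meier for
its stability in small leaves.

Forest modes share bootstrap resampling (n draws with replacement per tree):

- **subspace** (default): `ceil(fraction * m)` variables drawn once per tree
  without replacement, all searched at every node; default fraction 0.75 (the
  configuration used for dense-genotype cohorts).
- **classical**: every node independently draws `ceil(sqrt(m))` candidates.
- **bagging**: all variables everywhere; implemented as subspace with the
  fraction pinned to 1.0, which makes the fraction-1.0/bagging equivalence
  exact by construction.

Per-tree seeds are spawned deterministically from the forest seed before any
tree is built, so results are independent of build order and bit-reproducible.
Out-of-bag prediction averages, per subject, exactly the trees whose bootstrap
multiset excludes that subject; subjects in-bag everywhere (probability
~`0.632^B`) are reported missing and excluded from the OOB error with a
logged count. The scalar risk for the concordance index is the ensemble
mortality — the predicted cumulative hazard summed over the grid — which
preserves pointwise ordering of hazard curves; the concordance convention is
Harrell's (pairs tied on time with both events impermissible; tied risks
credited 1/2), and the error rate is `1 - C`.

## Synthetic data

The generators define the study conditions rather than imitating any real
dataset:

- **Noise genotypes**: per column a minor allele frequency `q ~ U(0.25, 0.4)`,
  genotypes i.i.d. `((1-q)^2, 2q(1-q), q^2)` — Hardy-Weinberg equilibrium with
  intermediate MAF, matching the MAF > 25% filtering convention for real SNPs.
- **Cure cohorts**: covariates enter the log-linear predictors centred, so
  `theta0` stays the cohort-average baseline. Null-calibration and power
  studies use one balanced binary covariate, `theta0 = 0.7` (cure fraction
  ~0.50), exponential baseline, horizon 3.0 (events ~47%), n = 200; the power
  study plants `beta = 1, alpha = 0` — the crossing-hazards regime the 2-df
  statistic is designed for.
- **Benchmark fixture**: n = 312 subjects, 17 covariates (9 quartile-coded,
  8 binary) with heterogeneous effects — five strong (bilirubin-, edema-,
  albumin-, prothrombin-, ascites-like), four moderate, eight null — chosen to
  mirror the effect structure of the classic liver-cirrhosis trial data;
  `theta0 = 0.55`, Weibull(1.2, 1.5) baseline, horizon 3.0, 10% uniform
  dropout, giving ~60% censoring. The real trial data are not bundled;
  `load_pbc_file` accepts a user-supplied copy. The benchmark claim is the
  *qualitative ordering* (wide subspaces beat per-node sqrt(m) sampling by a
  wide margin when noise dominates), not any particular error value; at the
  scale run here (5,000 noise variables, 100 trees) the subspace forest at
  fraction 0.25 typically lands around 31-33% OOB error versus 45-48% for the
  classical forest.

What passing these simulations does *not* show: the generators draw
covariates independently, plant log-linear effects without interactions, and
use a smooth parametric baseline, so they say nothing about performance under
correlated predictors (linkage disequilibrium), non-multiplicative effects, or
informative censoring in real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at 5,000 noise
variables and 100 trees over three seeds, calibration/power at 2,000
replicates, and simulator checks at 1e5 subjects — sizes chosen so the whole
suite completes in a few minutes while every Monte-Carlo band stays several
standard errors wide of its threshold. Tolerances: clamp `eps = 1e-6`;
generalised-inverse rank tolerance 1e-10; exact identities are asserted to
1e-8 or tighter; Monte-Carlo quantities at 2-3 standard errors. Degenerate
inputs: nodes with no events are leaves with flat zero hazard; all-censored
cohorts are rejected at fit time; an all-tied candidate set resolves by the
deterministic tie-break.
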