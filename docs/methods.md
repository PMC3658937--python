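# Methods

## The problem

Paired designs are common in sequencing studies: tumour and matched
normal tissue from the same patient, pre- and post-infection samples
from the same individual. For each genomic object (gene, tag, miRNA,
methylation locus — a *tuple*) we observe a pair of counts per sample
pair, `D_c = {(u_1c, ..., u_nc), (u'_1c, ..., u'_nc)}`. Two questions
arise: does the ratio of expression within a pair deviate consistently
from one-to-one (within-pair differential expression, DE), and does
that ratio differ between experimental conditions (between-group DE)?
Working with the counts directly — rather than a log-linear
transformation — keeps precision at low expression where discreteness
dominates.

## Model

If both members of a pair are Poisson, the first count conditional on
the pair total `N = u + u'` is binomial with success probability `p`,
the expected fraction of reads in the first library. Biological
variation makes that fraction itself random; placing a beta
distribution on it yields the beta-binomial

    P(u, u' | Pi, phi, L, L') = C(N, u) B(u + alpha, u' + beta) / B(alpha, beta),

with `alpha = p(1-phi)/phi`, `beta = (1-p)(1-phi)/phi`. `Pi` is the
expected proportion before normalisation; unequal library scaling
factors enter only through `p = Pi L / (Pi L + (1-Pi) L')`. The
dispersion `phi` lies in `[0, 1)`; `phi = 0` recovers the binomial
exactly, and the variance `N p (1-p) (1 + (N-1) phi)` grows linearly in
`phi` at fixed `N` and `p`.

A *model* `M` is a partition `{E_q}` of the sample pairs; pairs within
one set share parameters `zeta_q = (Pi_q, phi)`, either with `Pi_q`
fixed (e.g. 0.5, the no-DE null) or free. The standard trio is: one
fixed-0.5 set (no DE); one free set (consistent within-pair DE); one
free set per condition (between-group DE).

### Empirical parameter distributions

The distribution `Theta_q` of `zeta_q` is estimated from the data
itself. For each of a random sample of tuples, the replicate-structure
likelihood

    P(D_c | {F_r}) = prod_r prod_{i in F_r} P({u, u'} | Pi_rc, phi_c)

is maximised jointly over one proportion per replicate group and a
shared dispersion. Estimating dispersion *under the replicate
structure* is what prevents genuine between-group DE from inflating
`phi`. Given `phi_c`, the set-specific proportion `Pi_qc` is a
one-dimensional profile maximum over the pairs in `E_q`. The collection
`Theta_q = {(Pi_qc, phi_c)}` over sampled tuples then acts as a
discrete prior: the marginal likelihood factorises over sets and is
approximated by the sample mean

    P(D_c | M) ~= prod_q |Theta_q|^-1 sum_{zeta in Theta_q}
                      prod_{i in E_q} P((u_ic, u'_ic) | zeta).

This "borrows" information across tuples: every tuple's evidence is
evaluated against parameter values realised elsewhere in the dataset.

### Priors, posteriors, FDR

Model priors are the proportions of tuples assigned to each model by
BIC, `BIC_M = -2 log P(D_c|M) + k_M log n`, with `k_M` the number of
free proportion sets (the dispersion is shared by construction and does
not differ between models) and `n` the number of sample pairs.
Posteriors follow from Bayes' theorem with the evidence summed over the
finite model set. Among the top `m` tuples ranked by posterior for a
model, the FDR is estimated as the mean of `1 - posterior` — each term
is the probability that the model is not the true one for that tuple.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `theta sample size` | min(5000, eligible) | tuples sampled into each `Theta_q`; balances the O(tuples x \|Theta\|) cost of the marginal likelihood against prior resolution |
| `per_group_dispersion` | off | estimate `phi` per model set from the restricted fit; only advisable with many replicates |
| prior floor | 1e-3 | no model prior reaches zero, which would zero every posterior |
| proportion clamp | 1e-6 | boundary maximisers are clamped so the implied beta shapes stay finite |
| scaling factors | design / total | column totals by default; user tables or simulator truth accepted |
| FDR threshold | 0.05 | the conventional reporting level |

## Estimation details

The Eq.-4 surface can be multi-modal at small `n`. The single-tuple
fitter uses six quasi-Newton starts on logit-transformed parameters
(method-of-moments and 0.5 proportions crossed with low/moderate/high
dispersion) and always evaluates the exact `phi = 0` boundary, keeping
the best. The batch fitter used for `Theta` construction localises
every tuple's optimum at once with a vectorised profile-likelihood grid
(40 dispersion x 81 proportion points per replicate group) — a stronger
multimodality guard than any finite start set — then polishes each
tuple with one quasi-Newton step, again comparing against the exact
boundary. The two routes agree to 1e-5 in log-likelihood in tests, and
the optimum matches a 1000 x 1000 exhaustive grid to 1e-6.

Numerical choices worth knowing:

* all likelihoods are computed in log space through log-gamma
  functions; pair totals of 1e5 are routine at the simulated depths;
* dispersions below 1e-9 are evaluated with the binomial branch: the
  two pmfs differ by O(N^2 phi) there, while the log-gamma arithmetic
  at the implied beta shapes (`alpha + beta ~ 1/phi`) would lose far
  more to cancellation;
* `phi` is clamped to `1 - 1e-6` from above before shapes are formed;
* BIC ties break toward the model with fewer free sets, then model
  order; FDR ranking ties break by tuple id — both for bit
  reproducibility;
* all-zero tuples have likelihood 1 under every model: they are
  retained but flagged, never sampled into `Theta`, excluded from BIC
  assignment counts, and reported with equal posteriors.

## The simulator

Counts are Poisson draws with means `lambda_c L_i Q_ic M_ic` and
`lambda_c L'_i Q_ic (1 - M_ic)`:

* `lambda_c` — baseline expression rate, drawn from a pool. The default
  pool is synthetic: `log10 lambda ~ N(-3.3, 0.8)` truncated to
  `[-6, -1]`, chosen so that with the library sizes below the per-pair
  totals span roughly 1–1e3, the regime where count discreteness
  matters. Real analyses should substitute an empirically estimated
  pool; none is bundled.
* `L_i, L'_i ~ U(30000, 90000)` — library scaling factors.
* `Q_ic = 2^nu`, `nu ~ U(-2, 2)` — individual effects, up to
  sixteen-fold between sample pairs.
* `phi_c ~ Beta(1, 10)` — biological dispersion (floored at 1e-5; below
  that the noise is indistinguishable from `phi = 0` at these depths
  and the minimax moment match leaves double-precision range).
* `M_ic ~ Beta(a_ic, b_ic)` with `a_ic = mu_ic/(mu_ic + mu'_ic) *
  (1-phi_c)/phi_c` and symmetric `b_ic`. Within-pair DE sets
  `mu = 2^{f_c}`, `mu' = 2^{-f_c}`, `f_c ~ U(-b, b)`; between-group DE
  multiplies one condition (chosen by a per-tuple indicator) by
  `2^{g_c}`, `g_c ~ U(-d, d)`.

Draws follow a fixed order (lambda, L, phi, f/g/indicator, nu, M,
Poisson) from one seeded generator, so datasets are bit-reproducible.

For robustness studies `M` can instead follow the minimax
(Kumaraswamy) distribution `f(x) = a b x^{a-1} (1 - x^a)^{b-1}`, whose
parameters are solved numerically so mean and variance match the beta
case exactly (moments `E X^r = b B(1 + r/a, b)` have no closed-form
inverse). The solve works in log-parameter space with two analytic
starts — the moment-matched beta and the concentration limit, where `b`
grows like `exp(a |log mean|)` — and series-expanded log-gamma
differences to avoid cancellation at extreme shapes. Sampling uses the
exact inverse CDF in `expm1`/`log1p` form.

What the simulator does *not* emulate: correlated expression between
tuples, positional/GC biases, zero inflation beyond what the Poisson
mixture produces, and empirical `lambda` distributions. Passing tests
therefore demonstrate correctness of the method under its own
generative assumptions (and, via the minimax family, mild robustness to
the noise law) — not performance guarantees on any particular real
dataset.

## Evaluation protocol

Tuples are ranked by the posterior of the relevant model (within-pair
DE: the consistent-ratio model; between-group DE: the group-difference
model; "any DE": the summed posteriors of all non-null models) and
ROC curves swept over the unique scores. In the two-task design,
tuples simulated with between-group DE are excluded from both rates of
the within-pair task: the set-based models correctly give them low
consistent-ratio posteriors, so counting them as either positives or
negatives would distort the comparison. Curves from repeated
simulations are averaged vertically at fixed FPR with step-function
interpolation.

The bundled studies use 1000 tuples with 100 DE per class and
`Theta` = 200 over 10 seeds (FDR calibration: 10000 tuples, 1000 DE,
5 seeds) — sizes at which the AUC orderings in the effect bound are
well resolved on a single core.

## Known limitations

* The FDR estimator inherits any miscalibration of the posteriors
  (finite `Theta` sample, BIC-estimated priors); it is approximately
  conservative in the bundled calibration study but is an estimate, not
  a guarantee.
* Minimax targets with variance above ~0.95 mean(1-mean) (dispersion
  ratio near 1) are unreachable within double precision — the required
  parameters sit in the a, b -> 0 corner the family approaches only
  logarithmically. The solver raises explicitly; such dispersions have
  probability ~1e-10 under the Beta(1, 10) draw.
* No shrinkage ("squeezing") of the empirical parameter distributions
  is applied; with many outliers the sampled `Theta` can be noisy.
* Prior estimation is a single BIC pass, not an iterative re-estimation.
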