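"""Simulation of paired count datasets with known truth labels.

Counts are Poisson draws whose means combine a per-tuple baseline rate
lambda_c, a per-library scaling factor L_i (uniform on [30000, 90000]),
an individual effect Q_ic = 2^nu_ic with nu uniform on [-2, 2] (up to
sixteen-fold variation between sample pairs), and a biological-noise
proportion M_ic:

    u_ic  ~ Poisson(lambda_c * L_i  * Q_ic * M_ic)
    u'_ic ~ Poisson(lambda_c * L'_i * Q_ic * (1 - M_ic))

M_ic is drawn from a beta distribution with shapes
a_ic = mu_ic/(mu_ic + mu'_ic) * (1 - phi_c)/phi_c and the symmetric
b_ic, where phi_c ~ Beta(1, 10) sets the dispersion.  Differential
expression enters through mu: within-pair DE sets mu_ic = 2^{f_c},
mu'_ic = 2^{-f_c} with f_c uniform on [-b, b]; between-group DE applies
an additional factor 2^{g_c} to one experimental condition (chosen by a
per-tuple indicator I_c), g_c uniform on [-d, d].

For robustness studies M_ic can instead be drawn from the minimax
(Kumaraswamy) distribution with density
f(x) = a b x^{a-1} (1 - x^a)^{b-1}, its parameters solved numerically so
that mean and variance match the beta case exactly — the two noise
families are then directly comparable at identical simulation settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, root
from scipy.special import gammaln, polygamma, psi
from scipy.stats import truncnorm

from .data_model import PairedCountMatrix, ScalingFactors

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "MinimaxParams",
    "simulate_dataset",
    "solve_minimax_parameters",
    "minimax_moments",
    "default_lambda_pool",
]

NULL, WITHIN_DE, BETWEEN_DE = "NULL", "WITHIN_DE", "BETWEEN_DE"

# default lambda pool: log10(lambda) ~ Normal(-3.3, 0.8) truncated to
# [-6, -1]; with L in [30000, 90000] this spans per-pair totals from ~1
# to ~1e3, the depth regime where count discreteness matters
_POOL_LOG10_MEAN = -3.3
_POOL_LOG10_SD = 0.8
_POOL_LOG10_RANGE = (-6.0, -1.0)


@dataclass
class SimulationConfig:
    """All generating parameters of one simulated dataset."""

    n_pairs_per_group: int = 4
    n_groups: int = 1
    n_tuples: int = 10000
    n_within_de: int = 1000
    n_between_de: int = 0
    b: float = 2.0                      # within-pair effect bound (log2)
    d: float = 0.0                      # between-group effect bound (log2)
    noise_family: str = "beta"          # "beta" or "minimax"
    lambda_pool: np.ndarray | None = None
    lambda_pool_size: int = 10000
    L_range: tuple = (30000.0, 90000.0)
    nu_range: tuple = (-2.0, 2.0)
    phi_shape: tuple = (1.0, 10.0)
    per_pair_indicator: bool = False    # draw I per (tuple, pair) instead of per tuple
    seed: int = 0

    def __post_init__(self):
        if self.n_groups not in (1, 2):
            raise ValueError("n_groups must be 1 or 2")
        if self.n_within_de + self.n_between_de > self.n_tuples:
            raise ValueError("more differentially expressed tuples than tuples")
        if self.n_between_de > 0 and self.n_groups != 2:
            raise ValueError("between-group differential expression needs two groups")
        if self.b < 0 or self.d < 0:
            raise ValueError("effect bounds b and d must be non-negative")
        if self.noise_family not in ("beta", "minimax"):
            raise ValueError("noise_family must be 'beta' or 'minimax'")
        if self.lambda_pool is not None:
            self.lambda_pool = np.asarray(self.lambda_pool, dtype=float)
            if self.lambda_pool.size == 0 or np.any(self.lambda_pool <= 0):
                raise ValueError("lambda pool must be non-empty and strictly positive")

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_per_group * self.n_groups

    @property
    def group_of_pair(self) -> np.ndarray:
        """Group index per sample pair: the first n pairs are condition A."""
        return np.repeat(np.arange(self.n_groups), self.n_pairs_per_group)


@dataclass
class SimulationTruth:
    """Every generating draw, recorded for downstream evaluation."""

    labels: np.ndarray           # (C,) in {NULL, WITHIN_DE, BETWEEN_DE}
    lam: np.ndarray              # (C,)
    phi: np.ndarray              # (C,)
    f: np.ndarray                # (C,) log2 within-pair effect
    g: np.ndarray                # (C,) log2 between-group effect
    indicator: np.ndarray        # (C,) or (C, n) condition receiving the effect
    L: np.ndarray                # (n,)
    L_prime: np.ndarray          # (n,)
    nu: np.ndarray               # (C, n) individual effects
    mu: np.ndarray               # (C, n)
    mu_prime: np.ndarray         # (C, n)
    M: np.ndarray                # (C, n) realised noise proportions
    group_of_pair: np.ndarray    # (n,)
    tuple_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "lambda": self.lam, "phi": self.phi,
             "f": self.f, "g": self.g},
            index=pd.Index(self.tuple_ids, name="tuple_id"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def ids_with_label(self, label: str) -> set:
        return {tid for tid, lab in zip(self.tuple_ids, self.labels) if lab == label}


def default_lambda_pool(size: int, seed: int) -> np.ndarray:
    """Reproducible heavy-tailed pool of baseline expression rates.

    The pool is generated through per-element inverse-CDF draws, so the
    first k values are identical for any requested size at the same seed.
    """
    if size < 1:
        raise ValueError("pool size must be at least 1")
    lo, hi = _POOL_LOG10_RANGE
    a = (lo - _POOL_LOG10_MEAN) / _POOL_LOG10_SD
    b = (hi - _POOL_LOG10_MEAN) / _POOL_LOG10_SD
    u = np.random.default_rng(seed).random(size)
    log10_lam = truncnorm.ppf(u, a, b, loc=_POOL_LOG10_MEAN, scale=_POOL_LOG10_SD)
    return 10.0 ** log10_lam


# --------------------------------------------------------------------------
# minimax (Kumaraswamy) moment matching


@dataclass
class MinimaxParams:
    alpha_hat: float
    beta_hat: float

    def __post_init__(self):
        if self.alpha_hat <= 0 or self.beta_hat <= 0:
            raise ValueError("minimax parameters must be positive")


_LOG_A_MAX = 50.0
_LOG_B_MAX = 700.0   # beta_hat beyond exp(700) overflows double precision


def _log_moment(r: float, log_a: float, log_b: float) -> float:
    # log E(X^r) = log(b) + log B(1 + e, b)
    #            = gammaln(1 + e) - [gammaln(b + 1 + e) - gammaln(b + 1)],
    # e = r/a.  The bracketed difference cancels catastrophically for
    # small e at large b, so it is expanded in digamma derivatives there
    # (and in the log(b) asymptote once b itself overflows the expansion).
    eps = r * np.exp(-min(log_a, _LOG_A_MAX))
    if log_b > 300.0:
        diff = eps * log_b              # psi(b+1) ~ log b, psi' ~ 1/b -> 0
    else:
        b1 = np.exp(log_b) + 1.0
        if eps < 1e-3 * b1:
            diff = (eps * psi(b1)
                    + eps ** 2 / 2.0 * polygamma(1, b1)
                    + eps ** 3 / 6.0 * polygamma(2, b1)
                    + eps ** 4 / 24.0 * polygamma(3, b1))
        else:
            diff = gammaln(b1 + eps) - gammaln(b1)
    return float(gammaln(1.0 + eps) - diff)


def minimax_moments(alpha_hat: float, beta_hat: float, r: int = 1) -> float:
    """E(X^r) = beta_hat * B(1 + r/alpha_hat, beta_hat)."""
    return float(np.exp(_log_moment(r, np.log(alpha_hat), np.log(beta_hat))))


def _minimax_residual(log_params, mean, var):
    log_a = np.clip(log_params[0], -_LOG_A_MAX, _LOG_A_MAX)
    log_b = np.clip(log_params[1], -_LOG_B_MAX, _LOG_B_MAX)
    m1 = np.exp(_log_moment(1, log_a, log_b))
    m2 = np.exp(_log_moment(2, log_a, log_b))
    # relative residuals keep the solve well conditioned at tiny variances
    return [(m1 - mean) / mean, (m2 - m1 * m1 - var) / var]


def solve_minimax_parameters(target_mean: float,
                             target_variance: float) -> MinimaxParams:
    """Minimax parameters matching a required mean and variance.

    No closed form exists, so the two moment equations are solved
    numerically in log-parameter space.  The moment pair must be
    achievable by a distribution on (0, 1):
    0 < variance < mean (1 - mean).
    """
    if not 0.0 < target_mean < 1.0:
        raise ValueError("target mean must lie in (0, 1)")
    if not 0.0 < target_variance < target_mean * (1.0 - target_mean):
        raise ValueError(
            "infeasible moments: need 0 < variance < mean*(1-mean)")

    def abs_residual(x):
        log_a = np.clip(x[0], -_LOG_A_MAX, _LOG_A_MAX)
        log_b = np.clip(x[1], -_LOG_B_MAX, _LOG_B_MAX)
        m1 = np.exp(_log_moment(1, log_a, log_b))
        m2 = np.exp(_log_moment(2, log_a, log_b))
        return max(abs(m1 - target_mean),
                   abs(m2 - m1 * m1 - target_variance))

    # two analytic starting points: the beta distribution with the same
    # moments (good for diffuse targets), and the concentration limit
    # log X ~ (log W)/a, W ~ Beta(1, b), where sd(X) ~ 1.2825 * mean / a
    # and E(X) = mean forces log b = -a log(mean) - 0.5772 (good for
    # small-variance targets, where b grows exponentially in a)
    t = target_mean * (1.0 - target_mean) / target_variance - 1.0
    a_conc = 1.2825 * target_mean / np.sqrt(target_variance)
    starts = [
        (np.log(target_mean * t), np.log((1.0 - target_mean) * t)),
        (np.log(a_conc), -a_conc * np.log(target_mean) - 0.5772),
        (0.0, 0.0),
        (np.log(0.5), np.log(0.5)),
        (np.log(5.0), np.log(5.0)),
        # near-Bernoulli targets (variance close to its upper bound) sit
        # in the a, b -> 0 corner of the family
        (-8.0, -8.0),
        (-16.0, -16.0),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float),
                     [-_LOG_A_MAX, -_LOG_B_MAX], [_LOG_A_MAX, _LOG_B_MAX])
        sol = root(_minimax_residual, x0, args=(target_mean, target_variance),
                   method="hybr", options={"xtol": 1e-14})
        res = abs_residual(sol.x)
        if best is None or res < best[1]:
            best = (sol.x, res)
        if res <= 1e-12:
            break
    if best[1] > 1e-9:
        sol = least_squares(_minimax_residual, best[0],
                            args=(target_mean, target_variance),
                            xtol=1e-15, ftol=1e-15)
        res = abs_residual(sol.x)
        if res < best[1]:
            best = (sol.x, res)
    if best[1] > 1e-8:
        raise RuntimeError(
            f"minimax moment matching failed: residual {best[1]:.3e} for "
            f"mean={target_mean}, variance={target_variance}")
    a = np.exp(np.clip(best[0][0], -_LOG_A_MAX, _LOG_A_MAX))
    b = np.exp(np.clip(best[0][1], -_LOG_B_MAX, _LOG_B_MAX))
    return MinimaxParams(alpha_hat=float(a), beta_hat=float(b))


def _sample_minimax(rng, mean, var):
    """Moment-matched minimax draws, elementwise over (mean, var) arrays.

    The parameter solve is cached over unique (mean, var) combinations —
    within a tuple the target moments repeat across sample pairs — and
    sampling uses the exact inverse CDF x = (1 - (1 - v)^{1/b})^{1/a}.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    pairs = np.column_stack([mean.ravel(), var.ravel()])
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    a = np.empty(uniq.shape[0])
    b = np.empty(uniq.shape[0])
    for j, (m, v) in enumerate(uniq):
        params = solve_minimax_parameters(m, v)
        a[j], b[j] = params.alpha_hat, params.beta_hat
    v = rng.random(mean.size)
    # inverse CDF x = (1 - (1 - v)^{1/b})^{1/a}, in log space: the inner
    # power rounds to 1.0 in double precision once b is astronomically
    # large (concentrated targets), so form 1 - e^t via expm1
    t = np.log1p(-v) / b[inverse]
    x = np.exp(np.log(-np.expm1(t)) / a[inverse])
    return x.reshape(mean.shape)


# --------------------------------------------------------------------------
# dataset generation


def simulate_dataset(config: SimulationConfig):
    """Generate one paired dataset with full truth bookkeeping.

    The draw order is fixed (lambda -> L, L' -> phi -> f, g, I -> nu ->
    M -> Poisson counts), all from a single seeded generator, so runs are
    bit-reproducible.  Returns (counts, scaling, truth).
    """
    rng = np.random.default_rng(config.seed)
    C, n = config.n_tuples, config.n_pairs
    group = config.group_of_pair

    pool = config.lambda_pool
    if pool is None:
        pool_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0]
                        % (2 ** 31))
        pool = default_lambda_pool(config.lambda_pool_size, pool_seed)
    lam = rng.choice(pool, size=C)

    lo, hi = config.L_range
    L = rng.uniform(lo, hi, size=n)
    L_prime = rng.uniform(lo, hi, size=n)

    # numerical floor on the drawn dispersions: below 1e-5 the noise is
    # indistinguishable from phi = 0 at realistic depths, while the
    # moment-matched minimax parameters leave double-precision range
    phi = rng.beta(*config.phi_shape, size=C)
    phi = np.clip(phi, 1e-5, 1.0 - 1e-5)

    labels = np.array([NULL] * C, dtype="<U10")
    labels[: config.n_within_de] = WITHIN_DE
    labels[config.n_within_de: config.n_within_de + config.n_between_de] = BETWEEN_DE
    de = labels != NULL
    between = labels == BETWEEN_DE

    f = np.zeros(C)
    f[de] = rng.uniform(-config.b, config.b, size=int(de.sum()))
    g = np.zeros(C)
    g[between] = rng.uniform(-config.d, config.d, size=int(between.sum()))
    if config.per_pair_indicator:
        indicator = rng.integers(0, 2, size=(C, n))
    else:
        indicator = rng.integers(0, 2, size=C)

    nu_lo, nu_hi = config.nu_range
    nu = rng.uniform(nu_lo, nu_hi, size=(C, n))
    Q = 2.0 ** nu

    # within-pair effect for all DE tuples; between-group tuples get the
    # extra 2^g factor on whichever condition the indicator selects
    mu = np.tile(2.0 ** f[:, None], (1, n))
    mu_prime = np.tile(2.0 ** (-f[:, None]), (1, n))
    if np.any(between):
        ind = indicator if config.per_pair_indicator else indicator[:, None]
        # effect lands on condition A where I = 1, on condition B where I = 0
        exponent = np.where(group[None, :] == 0, ind, 1 - ind) * g[:, None]
        mu = np.where(between[:, None], mu * 2.0 ** exponent, mu)
        mu_prime = np.where(between[:, None], mu_prime * 2.0 ** (-exponent),
                            mu_prime)

    mean = mu / (mu + mu_prime)
    if config.noise_family == "beta":
        shape_a = mean * (1.0 - phi[:, None]) / phi[:, None]
        shape_b = (1.0 - mean) * (1.0 - phi[:, None]) / phi[:, None]
        M = rng.beta(shape_a, shape_b)
    else:
        # matched variance: for beta shapes summing to (1-phi)/phi the
        # variance is mean (1 - mean) phi
        var = mean * (1.0 - mean) * phi[:, None]
        M = _sample_minimax(rng, mean, var)
    M = np.clip(M, 1e-12, 1.0 - 1e-12)

    mean_u = lam[:, None] * L[None, :] * Q * M
    mean_up = lam[:, None] * L_prime[None, :] * Q * (1.0 - M)
    u = rng.poisson(mean_u)
    u_prime = rng.poisson(mean_up)

    width = len(str(C))
    tuple_ids = [f"t{i:0{width}d}" for i in range(C)]
    pair_labels = [f"{'AB'[group[i]]}{i % config.n_pairs_per_group + 1}"
                   for i in range(n)]
    counts = PairedCountMatrix(tuple_ids, u, u_prime, pair_labels)
    scaling = ScalingFactors(L, L_prime)
    truth = SimulationTruth(labels=labels, lam=lam, phi=phi, f=f, g=g,
                            indicator=indicator, L=L, L_prime=L_prime, nu=nu,
                            mu=mu, mu_prime=mu_prime, M=M,
                            group_of_pair=group, tuple_ids=tuple_ids)
    return counts, scaling, truth
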