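"""Per-tuple maximum-likelihood estimation and empirical parameter sampling.

For one tuple pair the likelihood under the replicate structure
{F_1, ..., F_s} is

    P(D_c | {F_r}) = prod_r prod_{i in F_r} P({u_ic, u'_ic} | Pi_rc, phi_c)

with one free proportion per replicate group and a single shared
dispersion.  Maximising this yields the tuple's dispersion estimate
phi_c without confounding genuine between-group differential expression
with overdispersion.  Given phi_c, a one-dimensional profile likelihood
yields the proportion Pi_qc for any set of sample pairs E_q.

Repeating either fit over many sampled tuples produces the empirical
parameter collections Theta_q = {(Pi_qc, phi_c)} that act as a discrete
prior in the marginal-likelihood approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .betabinom import log_pmf
from .data_model import (
    FREE,
    ModelSpec,
    PairedCountMatrix,
    ReplicateStructure,
    ScalingFactors,
)

__all__ = [
    "DispersionFit",
    "ThetaSample",
    "estimate_dispersion",
    "estimate_proportion",
    "fit_dispersion_many",
    "eligible_tuples",
    "build_theta",
    "build_theta_many",
]

logger = logging.getLogger(__name__)

#: Clamp for estimated proportions: keeps the implied beta shapes finite
#: when the likelihood is maximised at a boundary.
PI_CLAMP = 1e-6
_PHI_INTERIOR_MAX = 1.0 - 1e-6


@dataclass
class DispersionFit:
    """Joint maximiser of the replicate-structure likelihood for one tuple."""

    phi: float
    pi_by_group: np.ndarray
    log_likelihood: float
    converged: bool
    degenerate: bool = False


@dataclass
class ThetaSample:
    """Empirical (Pi, phi) sample for one model set E_q."""

    pi: np.ndarray
    phi: np.ndarray
    tuple_ids: list
    seed: int

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.pi.shape != self.phi.shape or self.pi.ndim != 1:
            raise ValueError("pi and phi must be 1-D arrays of equal length")
        if self.pi.size == 0:
            raise ValueError("empty Theta sample")
        if np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise ValueError("Theta proportions must lie in (0, 1)")
        if np.any(self.phi < 0) or np.any(self.phi >= 1):
            raise ValueError("Theta dispersions must lie in [0, 1)")

    def __len__(self) -> int:
        return self.pi.size


# --------------------------------------------------------------------------
# single-tuple likelihood machinery


def _group_loglik(u, up, L, Lp, idx, pi, phi) -> float:
    return float(np.sum(log_pmf(u[idx], up[idx], pi, phi, L[idx], Lp[idx])))


def _moment_start(u, up, L, Lp, idx) -> float:
    """Pooled method-of-moments proportion on the unscaled (Pi) scale."""
    num = np.sum(u[idx] / L[idx])
    den = num + np.sum(up[idx] / Lp[idx])
    if den == 0:
        return 0.5
    return float(np.clip(num / den, 1e-3, 1.0 - 1e-3))


def _binomial_boundary_fit(u, up, L, Lp, groups):
    """Exact phi = 0 profile: independent 1-D binomial fits per group."""
    pis = np.empty(len(groups))
    total = 0.0
    for r, idx in enumerate(groups):
        idx = np.asarray(idx)

        def nll(pi, idx=idx):
            return -_group_loglik(u, up, L, Lp, idx, pi, 0.0)

        res = minimize_scalar(nll, bounds=(PI_CLAMP, 1.0 - PI_CLAMP),
                              method="bounded", options={"xatol": 1e-12})
        best_pi, best_val = float(res.x), float(res.fun)
        for edge in (PI_CLAMP, 1.0 - PI_CLAMP):
            v = nll(edge)
            if v < best_val:
                best_pi, best_val = edge, v
        pis[r] = best_pi
        total -= best_val
    return pis, total


def _interior_fit(u, up, L, Lp, groups, pi0, phi0):
    """Quasi-Newton maximisation on logit-transformed (Pi_r, phi)."""
    s = len(groups)
    idx_arrays = [np.asarray(g) for g in groups]

    def nll(x):
        # |x| <= 35 keeps expit strictly inside (0, 1) in double precision
        x = np.clip(x, -35.0, 35.0)
        pis = expit(x[:s])
        phi = expit(x[s]) * _PHI_INTERIOR_MAX
        return -sum(
            _group_loglik(u, up, L, Lp, idx, pis[r], phi)
            for r, idx in enumerate(idx_arrays)
        )

    x0 = np.concatenate([logit(np.asarray(pi0, dtype=float)),
                         [logit(max(phi0, 1e-8) / _PHI_INTERIOR_MAX)]])
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8})
    x = np.clip(res.x, -35.0, 35.0)
    pis = np.clip(expit(x[:s]), PI_CLAMP, 1.0 - PI_CLAMP)
    phi = float(expit(x[s]) * _PHI_INTERIOR_MAX)
    return pis, phi, -float(res.fun), bool(res.success)


def _restricted_groups(groups, restrict_to):
    keep = set(int(i) for i in restrict_to)
    induced = [[i for i in g if i in keep] for g in groups]
    return [g for g in induced if g]


def estimate_dispersion(tuple_counts, reps: ReplicateStructure,
                        scaling: ScalingFactors, restrict_to=None) -> DispersionFit:
    """Maximise the replicate-structure likelihood for one tuple pair.

    Parameters
    ----------
    tuple_counts : (u, u_prime)
        The tuple's paired counts, two length-n integer arrays.
    restrict_to : index set, optional
        Restrict the data (and the induced replicate structure) to these
        sample pairs, e.g. when estimating dispersion per model set.

    Returns the shared dispersion, one proportion per retained replicate
    group, and the maximised log-likelihood.  The surface can be
    multi-modal at small n, so several starts are tried (method-of-moments
    and balanced proportions crossed with low/moderate/high dispersion)
    and the exact phi = 0 boundary is always evaluated.
    """
    u, up = (np.asarray(a) for a in tuple_counts)
    L, Lp = scaling.L, scaling.L_prime
    groups = reps.groups if restrict_to is None else _restricted_groups(
        reps.groups, restrict_to)
    if not groups:
        raise ValueError("restriction leaves no sample pairs")
    totals = np.array([np.sum(u[g] + up[g]) for g in groups])
    if np.all(totals == 0):
        return DispersionFit(0.0, np.full(len(groups), 0.5), 0.0,
                             converged=True, degenerate=True)

    mom = [_moment_start(u, up, L, Lp, np.asarray(g)) for g in groups]
    starts = [(pi0, phi0)
              for pi0 in (mom, [0.5] * len(groups))
              for phi0 in (1e-4, 0.05, 0.3)]

    best = None
    any_success = False
    for pi0, phi0 in starts:
        pis, phi, ll, ok = _interior_fit(u, up, L, Lp, groups, pi0, phi0)
        any_success = any_success or ok
        if best is None or ll > best[2]:
            best = (pis, phi, ll)
    pis0, ll0 = _binomial_boundary_fit(u, up, L, Lp, groups)
    if ll0 >= best[2]:
        best = (pis0, 0.0, ll0)
    pis, phi, ll = best
    return DispersionFit(phi=float(phi), pi_by_group=np.asarray(pis),
                         log_likelihood=float(ll), converged=any_success)


def estimate_proportion(tuple_counts, phi: float, scaling: ScalingFactors,
                        indices=None) -> float:
    """Profile maximum-likelihood proportion at a fixed dispersion.

    Maximises prod_{i in E_q} P({u, u'} | Pi, phi) over Pi for the sample
    pairs in ``indices`` (all pairs if None); the result is clamped to
    [PI_CLAMP, 1 - PI_CLAMP] so downstream beta shapes stay finite.
    """
    u, up = (np.asarray(a) for a in tuple_counts)
    idx = np.arange(u.size) if indices is None else np.asarray(sorted(indices))
    if idx.size == 0:
        raise ValueError("empty sample-pair set")
    L, Lp = scaling.L, scaling.L_prime

    def nll(pi):
        return -_group_loglik(u, up, L, Lp, idx, pi, phi)

    res = minimize_scalar(nll, bounds=(PI_CLAMP, 1.0 - PI_CLAMP),
                          method="bounded", options={"xatol": 1e-12})
    best_pi, best_val = float(res.x), float(res.fun)
    for edge in (PI_CLAMP, 1.0 - PI_CLAMP):
        v = nll(edge)
        if v < best_val:
            best_pi, best_val = edge, v
    return best_pi


# --------------------------------------------------------------------------
# vectorised many-tuple fitting (grid localisation + per-tuple polish)

_PHI_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 0.95, 39)])
_PI_GRID = expit(np.linspace(-9.0, 9.0, 81))


def fit_dispersion_many(first: np.ndarray, second: np.ndarray, groups,
                        scaling: ScalingFactors, polish: bool = True):
    """Fit (phi_c, {Pi_rc}) for a batch of tuples.

    A vectorised profile-likelihood scan over a (phi x Pi) grid localises
    the optimum for every tuple at once — the grid doubles as a guard
    against multi-modality — and each tuple is then polished with a
    quasi-Newton step from its grid optimum, keeping the exact phi = 0
    boundary in the comparison.

    Returns (phi, pi_by_group, loglik): arrays of shape (T,), (T, s), (T,).
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    T = first.shape[0]
    s = len(groups)
    L, Lp = scaling.L, scaling.L_prime

    prof_pi = np.empty((T, _PHI_GRID.size, s))
    total = np.zeros((T, _PHI_GRID.size))
    for r, g in enumerate(groups):
        ll = np.zeros((T, _PHI_GRID.size, _PI_GRID.size))
        for i in g:
            ll += log_pmf(first[:, i, None, None], second[:, i, None, None],
                          _PI_GRID[None, None, :], _PHI_GRID[None, :, None],
                          L[i], Lp[i])
        prof_pi[:, :, r] = _PI_GRID[np.argmax(ll, axis=2)]
        total += ll.max(axis=2)
    best_phi_idx = np.argmax(total, axis=1)

    phi_out = np.empty(T)
    pi_out = np.empty((T, s))
    ll_out = np.empty(T)
    used = sorted({i for g in groups for i in g})
    for t in range(T):
        u, up = first[t], second[t]
        if np.sum(u[used] + up[used]) == 0:
            phi_out[t], pi_out[t], ll_out[t] = 0.0, 0.5, 0.0
            continue
        j = best_phi_idx[t]
        pi0 = np.clip(prof_pi[t, j], 1e-3, 1.0 - 1e-3)
        phi0 = max(_PHI_GRID[j], 1e-6)
        if polish:
            pis, phi, ll, _ = _interior_fit(u, up, L, Lp, groups, pi0, phi0)
        else:
            pis, phi = pi0, _PHI_GRID[j]
            ll = total[t, j]
        pis0, ll0 = _binomial_boundary_fit(u, up, L, Lp, groups)
        if ll0 >= ll:
            pis, phi, ll = pis0, 0.0, ll0
        phi_out[t], pi_out[t], ll_out[t] = phi, pis, ll
    return phi_out, pi_out, ll_out


# --------------------------------------------------------------------------
# Theta construction


def eligible_tuples(counts: PairedCountMatrix, reps: ReplicateStructure) -> np.ndarray:
    """Tuples informative for the replicate-structure fit.

    A tuple is eligible iff every replicate group contains at least one
    sample pair with a positive pair total; in particular all-zero tuples
    are never sampled.
    """
    totals = counts.pair_totals
    mask = np.ones(counts.n_tuples, dtype=bool)
    for g in reps.groups:
        mask &= totals[:, g].sum(axis=1) > 0
    return np.flatnonzero(mask)


def _sample_indices(eligible: np.ndarray, sample_size, seed: int) -> np.ndarray:
    if sample_size is None:
        sample_size = min(5000, eligible.size)
    if sample_size > eligible.size:
        logger.info("requested Theta sample of %d exceeds %d eligible tuples; "
                    "using all eligible tuples", sample_size, eligible.size)
        sample_size = eligible.size
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=sample_size, replace=False)
    return np.sort(chosen)


def build_theta_many(counts: PairedCountMatrix, models, reps: ReplicateStructure,
                     scaling: ScalingFactors, sample_size=None, seed: int = 0,
                     per_group_dispersion: bool = False) -> dict:
    """Build Theta samples for several models from one shared tuple sample.

    The same sampled tuples — and, unless ``per_group_dispersion`` is set,
    the same dispersion fits — are reused across all models, which is both
    cheaper and what makes posterior comparisons between models coherent.
    Sampling is uniform without replacement among eligible tuples and
    reproducible under ``seed``.

    Returns ``{model.name: [ThetaSample per set]}``.
    """
    eligible = eligible_tuples(counts, reps)
    if eligible.size == 0:
        raise ValueError("no eligible tuples for Theta sampling")
    chosen = _sample_indices(eligible, sample_size, seed)
    logger.info("Theta construction: %d of %d tuples eligible, sampling %d",
                eligible.size, counts.n_tuples, chosen.size)
    ids = [counts.tuple_ids[i] for i in chosen]
    first = counts.counts_first[chosen]
    second = counts.counts_second[chosen]

    shared_phi = None
    if not per_group_dispersion:
        shared_phi, _, _ = fit_dispersion_many(first, second, reps.groups, scaling)

    out = {}
    for model in models:
        thetas = []
        for q, (idx_set, mode) in enumerate(zip(model.sets, model.proportions)):
            if per_group_dispersion:
                sub = _restricted_groups(reps.groups, idx_set)
                phi_q, _, _ = fit_dispersion_many(first, second, sub, scaling)
            else:
                phi_q = shared_phi
            if mode is FREE:
                pi_q = np.array([
                    estimate_proportion((first[t], second[t]), phi_q[t],
                                        scaling, indices=idx_set)
                    for t in range(len(chosen))
                ])
            else:
                pi_q = np.full(len(chosen), float(mode))
            thetas.append(ThetaSample(pi=pi_q, phi=phi_q, tuple_ids=ids, seed=seed))
        out[model.name] = thetas
    return out


def build_theta(counts: PairedCountMatrix, model: ModelSpec, reps: ReplicateStructure,
                scaling: ScalingFactors, sample_size=None, seed: int = 0,
                per_group_dispersion: bool = False):
    """Theta samples for a single model; see :func:`build_theta_many`."""
    return build_theta_many(counts, [model], reps, scaling, sample_size, seed,
                            per_group_dispersion)[model.name]
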