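"""Beta-binomial likelihood for a paired count conditional on its pair total.

If the two counts of a sample pair are Poisson distributed, then
conditional on their sum ``N = u + u'`` the first count is binomial with
success probability ``p``, the expected proportion of reads in the first
library.  Biological variation makes this proportion itself random, which
we model with a beta distribution, giving the beta-binomial:

    P(u, u' | Pi, phi, L, L') = C(N, u) * B(u + alpha, u' + beta) / B(alpha, beta)

with ``alpha = p (1 - phi) / phi``, ``beta = (1 - p)(1 - phi) / phi``.
``Pi`` is the expected proportion before library-size correction; unequal
library scaling factors ``L, L'`` enter only through

    p = Pi L / (Pi L + (1 - Pi) L').

``phi`` in [0, 1) measures overdispersion; ``phi = 0`` recovers the plain
binomial.  All computation is in log space via log-gamma functions since
pair totals can reach 1e5 at realistic sequencing depths.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln, xlogy

__all__ = ["effective_proportion", "log_pmf", "pair_variance"]

# phi is clamped just below 1 before forming alpha, beta: both shapes
# vanish as phi -> 1 and the beta function ratio degenerates numerically.
_PHI_MAX = 1.0 - 1e-6
# dispersions below this are evaluated with the binomial branch: the two
# pmfs differ by O(N^2 phi) < 1e-4 at any realistic pair total, whereas
# the log-gamma arithmetic at the implied beta shapes (alpha + beta of
# order 1/phi) loses far more than that to cancellation
_PHI_MIN = 1e-9


def effective_proportion(pi, L=1.0, L_prime=1.0):
    """Library-size-corrected success probability p.

    Parameters
    ----------
    pi : float or array
        Expected proportion of reads in the first member of the pair,
        before scaling correction; strictly inside (0, 1).
    L, L_prime : float or array
        Library scaling factors of the first and second member.

    Returns
    -------
    p with ``p = pi`` whenever ``L == L_prime``.
    """
    pi = np.asarray(pi, dtype=float)
    L = np.asarray(L, dtype=float)
    L_prime = np.asarray(L_prime, dtype=float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("Pi must lie strictly inside (0, 1)")
    if np.any(L <= 0.0) or np.any(L_prime <= 0.0):
        raise ValueError("scaling factors must be strictly positive")
    p = pi * L / (pi * L + (1.0 - pi) * L_prime)
    return p if p.ndim else float(p)


def log_pmf(u, u_prime, pi, phi, L=1.0, L_prime=1.0):
    """Log probability of the paired count (u, u') given its total.

    phi = 0 routes to the exact binomial branch; phi > 0 uses the
    beta-binomial parameterisation above.  Broadcasts over all arguments.
    """
    u = np.asarray(u)
    u_prime = np.asarray(u_prime)
    for arr, name in ((u, "u"), (u_prime, "u_prime")):
        if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
            raise ValueError(f"{name} must be a non-negative integer")
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0.0) or np.any(phi_arr >= 1.0):
        raise ValueError("phi must lie in [0, 1)")

    p = effective_proportion(pi, L, L_prime)
    u, up, p, phi_b = np.broadcast_arrays(
        u.astype(float), u_prime.astype(float), np.asarray(p, dtype=float), phi_arr
    )
    n_total = u + up
    log_comb = gammaln(n_total + 1.0) - gammaln(u + 1.0) - gammaln(up + 1.0)

    out = np.empty(u.shape, dtype=float)
    binom = phi_b < _PHI_MIN
    if np.any(binom):
        out[binom] = (log_comb + xlogy(u, p) + xlogy(up, 1.0 - p))[binom]
    if np.any(~binom):
        phi_c = np.minimum(phi_b, _PHI_MAX)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = (1.0 - phi_c) / np.where(binom, 1.0, phi_c)
        alpha = p * scale
        beta = (1.0 - p) * scale
        bb = log_comb + betaln(u + alpha, up + beta) - betaln(alpha, beta)
        out[~binom] = bb[~binom]
    return out if out.ndim else float(out)


def pair_variance(N, p, phi):
    """Variance of u under the beta-binomial: N p (1-p) (1 + (N-1) phi).

    Equals the binomial variance N p (1-p) at phi = 0; the extra variance
    scales linearly with phi at fixed N and p.  phi = 1 (total dispersion)
    is admitted here even though the likelihood itself requires phi < 1.
    """
    N = np.asarray(N, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(N < 0):
        raise ValueError("pair total must be non-negative")
    if np.any(phi < 0.0) or np.any(phi > 1.0):
        raise ValueError("phi must lie in [0, 1]")
    v = N * p * (1.0 - p) * (1.0 + (N - 1.0) * phi)
    return v if v.ndim else float(v)
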