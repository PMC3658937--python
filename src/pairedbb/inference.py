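"""Posterior model probabilities for each tuple pair.

Each model M partitions the sample pairs into sets {E_q} whose data share
parameters zeta_q = (Pi_q, phi) drawn from an unknown distribution
Theta_q.  With an empirical sample Theta_q in hand, the marginal
likelihood factorises over sets and is approximated by the sample mean

    P(D_c | M) ~= prod_q (1/|Theta_q|) sum_{zeta in Theta_q}
                      prod_{i in E_q} P((u_ic, u'_ic) | zeta)

Priors P(M) are estimated by assigning every tuple to its best model
under the Bayesian Information Criterion and taking assignment
proportions; posteriors follow from Bayes' theorem with the evidence
obtained by summing over the (finite) model set.  False discovery rates
come directly from the posteriors: among the top m tuples for a model,
the expected proportion of wrong calls is the mean of (1 - posterior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .betabinom import log_pmf
from .data_model import ModelSpec, PairedCountMatrix, ScalingFactors

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorTable",
    "FdrResult",
    "marginal_log_likelihood",
    "marginal_log_likelihood_matrix",
    "estimate_priors_bic",
    "posterior_probabilities",
    "estimate_fdr",
    "select_at_fdr",
    "compute_posteriors",
]

#: No model's prior is allowed to vanish entirely: a zero prior would
#: force a zero posterior for every tuple, however strong the data.
PRIOR_FLOOR = 1e-3

_THETA_CHUNK = 512


def marginal_log_likelihood_matrix(counts: PairedCountMatrix, model: ModelSpec,
                                   theta, scaling: ScalingFactors) -> np.ndarray:
    """log P(D_c | M) for every tuple, vectorised over the Theta sample.

    ``theta`` is the list of :class:`ThetaSample`, one per model set.  The
    mean over Theta entries is computed with log-sum-exp; the result is
    deterministic given Theta.
    """
    if len(theta) != model.n_sets:
        raise ValueError("one ThetaSample per model set required")
    out = np.zeros(counts.n_tuples)
    L, Lp = scaling.L, scaling.L_prime
    for idx_set, th in zip(model.sets, theta):
        if len(th) == 0:
            raise ValueError("empty Theta sample")
        acc = np.full(counts.n_tuples, -np.inf)
        # streamed log-sum-exp over Theta chunks keeps memory at
        # n_tuples x chunk regardless of |Theta|
        for lo in range(0, len(th), _THETA_CHUNK):
            pi = th.pi[lo:lo + _THETA_CHUNK]
            phi = th.phi[lo:lo + _THETA_CHUNK]
            ll = np.zeros((counts.n_tuples, pi.size))
            for i in idx_set:
                ll += log_pmf(counts.counts_first[:, i, None],
                              counts.counts_second[:, i, None],
                              pi[None, :], phi[None, :], L[i], Lp[i])
            acc = np.logaddexp(acc, logsumexp(ll, axis=1))
        out += acc - np.log(len(th))
    return out


def marginal_log_likelihood(tuple_counts, model: ModelSpec, theta,
                            scaling: ScalingFactors) -> float:
    """log P(D_c | M) for a single tuple pair."""
    u, up = (np.asarray(a).reshape(1, -1) for a in tuple_counts)
    counts = PairedCountMatrix(["c"], u, up,
                               [f"p{i}" for i in range(u.shape[1])])
    return float(marginal_log_likelihood_matrix(counts, model, theta, scaling)[0])


def estimate_priors_bic(loglik: np.ndarray, models, n_pairs: int,
                        exclude=None, floor: float = PRIOR_FLOOR) -> np.ndarray:
    """Model priors from per-tuple BIC assignment proportions.

    For each tuple, BIC_M = -2 log P(D_c|M) + k_M log(n) where k_M counts
    the freely estimated proportions of M (the dispersion is estimated
    once under the replicate structure and shared by all models, so it
    does not differ between them) and n is the number of sample pairs.
    Each tuple is assigned to its minimum-BIC model, ties resolved toward
    the model with fewer free sets; priors are the assignment proportions,
    floored at ``floor`` and renormalised.

    ``exclude`` masks tuples (e.g. all-zero ones) out of the assignment
    counts.
    """
    loglik = np.atleast_2d(np.asarray(loglik, dtype=float))
    n_tuples, n_models = loglik.shape
    if n_models != len(models):
        raise ValueError("one log-likelihood column per model required")
    k = np.array([m.n_free_sets for m in models], dtype=float)
    bic = -2.0 * loglik + k[None, :] * np.log(n_pairs)
    # tie-break toward parsimony, then model order, via a lexicographic nudge
    order = np.lexsort((np.arange(n_models), k))
    ranked = bic[:, order]
    assigned = order[np.argmin(ranked, axis=1)]
    if exclude is not None:
        assigned = assigned[~np.asarray(exclude, dtype=bool)]
    if assigned.size == 0:
        counts = np.ones(n_models)
    else:
        counts = np.bincount(assigned, minlength=n_models).astype(float)
    priors = counts / counts.sum()
    priors = np.maximum(priors, floor)
    return priors / priors.sum()


def posterior_probabilities(loglik, priors) -> np.ndarray:
    """P(M | D_c) per model via Bayes' theorem in log space.

    Accepts a single row or a (tuples x models) matrix; the evidence
    P(D_c) is the log-sum-exp of log P(D_c|M) + log P(M) over models.
    """
    loglik = np.asarray(loglik, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if not np.isclose(priors.sum(), 1.0, atol=1e-8):
        raise ValueError("priors must sum to 1")
    row = loglik.ndim == 1
    ll = np.atleast_2d(loglik)
    if np.any(np.all(np.isinf(ll) & (ll < 0), axis=1)):
        raise ValueError("all model likelihoods are zero for some tuple")
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(priors)[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    return post[0] if row else post


@dataclass
class FdrResult:
    """Per-tuple FDR for one model, aligned to the input tuple order."""

    rank: np.ndarray      # 1-based position in the ranked list
    fdr: np.ndarray       # FDR of the prefix ending at this tuple
    order: np.ndarray     # indices sorting tuples by descending posterior


def estimate_fdr(posteriors, tuple_ids=None) -> FdrResult:
    """FDR at each prefix of the posterior-ranked list.

    Tuples are ranked by descending posterior (ties broken by tuple id
    for reproducibility); the FDR at rank m is the mean of
    (1 - posterior) over the top m tuples, which is non-decreasing in m.
    """
    post = np.asarray(posteriors, dtype=float)
    if np.any(post < 0) or np.any(post > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    ids = np.arange(post.size) if tuple_ids is None else np.asarray(tuple_ids)
    order = np.lexsort((ids, -post))
    cum_fdr = np.cumsum(1.0 - post[order]) / np.arange(1, post.size + 1)
    rank = np.empty(post.size, dtype=int)
    fdr = np.empty(post.size)
    rank[order] = np.arange(1, post.size + 1)
    fdr[order] = cum_fdr
    return FdrResult(rank=rank, fdr=fdr, order=order)


def select_at_fdr(fdr_result: FdrResult, threshold: float) -> np.ndarray:
    """Indices of the largest ranked prefix with FDR <= threshold."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    ranked_fdr = fdr_result.fdr[fdr_result.order]
    ok = np.flatnonzero(ranked_fdr <= threshold)
    if ok.size == 0:
        return np.array([], dtype=int)
    return fdr_result.order[: ok.max() + 1]


@dataclass
class PosteriorTable:
    """Full inference output: likelihoods, priors, posteriors, FDR ranks."""

    tuple_ids: list
    model_names: list
    log_likelihood: np.ndarray   # (tuples, models)
    priors: np.ndarray           # (models,)
    posteriors: np.ndarray       # (tuples, models)
    fdr: np.ndarray              # (tuples, models)
    rank: np.ndarray             # (tuples, models), 1-based

    def fdr_for(self, model_name: str) -> FdrResult:
        j = self.model_names.index(model_name)
        order = np.lexsort((np.asarray(self.tuple_ids), -self.posteriors[:, j]))
        return FdrResult(rank=self.rank[:, j], fdr=self.fdr[:, j], order=order)

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, name in enumerate(self.model_names):
            data[f"{name}_loglik"] = self.log_likelihood[:, j]
            data[f"{name}_posterior"] = self.posteriors[:, j]
            data[f"{name}_fdr"] = self.fdr[:, j]
            data[f"{name}_rank"] = self.rank[:, j]
        return pd.DataFrame(data, index=pd.Index(self.tuple_ids, name="tuple_id"))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def compute_posteriors(counts: PairedCountMatrix, models, theta_by_model: dict,
                       scaling: ScalingFactors, priors=None) -> PosteriorTable:
    """End-to-end posterior computation for a validated design.

    ``theta_by_model`` maps model name to its per-set Theta samples (from
    :func:`pairedbb.estimation.build_theta_many`).  When ``priors`` is
    None they are estimated by BIC assignment.  All-zero tuples carry no
    information (their likelihood is 1 under every model): they are
    excluded from the BIC assignment counts and reported with equal
    posteriors across models.
    """
    n_pairs = counts.n_pairs
    loglik = np.column_stack([
        marginal_log_likelihood_matrix(counts, m, theta_by_model[m.name], scaling)
        for m in models
    ])
    zero_mask = counts.all_zero_mask
    if priors is None:
        priors = estimate_priors_bic(loglik, models, n_pairs, exclude=zero_mask)
        logger.info("BIC-estimated priors: %s",
                    {m.name: round(float(p), 4)
                     for m, p in zip(models, priors)})
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
    post = posterior_probabilities(loglik, priors)
    post = np.atleast_2d(post)
    post[zero_mask] = 1.0 / len(models)

    fdr = np.empty_like(post)
    rank = np.empty(post.shape, dtype=int)
    ids = np.asarray(counts.tuple_ids)
    for j in range(len(models)):
        res = estimate_fdr(post[:, j], tuple_ids=ids)
        fdr[:, j] = res.fdr
        rank[:, j] = res.rank
    return PosteriorTable(
        tuple_ids=list(counts.tuple_ids),
        model_names=[m.name for m in models],
        log_likelihood=loglik,
        priors=priors,
        posteriors=post,
        fdr=fdr,
        rank=rank,
    )
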