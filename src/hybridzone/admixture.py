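"""Bayesian admixture clustering of multilocus genotypes.

A Gibbs sampler over the classic admixture model: each allele copy carries
a latent cluster of origin z, each individual a membership vector q with a
symmetric Dirichlet(alpha) prior, and each cluster per-locus allele
frequencies with a flat Dirichlet(1) prior (independent frequencies across
clusters).  The per-individual membership estimate is the posterior mean
of q after burn-in; the model log-probability for a given K is the
harmonic-style estimate mean(trace) - var(trace)/2 computed from the
post-burn-in data log-likelihood trace, which feeds the second-order
rate-of-change (ΔK) criterion for choosing K.

Missing allele copies contribute nothing to the likelihood and are
excluded from all count updates.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .data import GenotypeTable

__all__ = ["AdmixtureModel", "fit_admixture", "align_runs", "delta_k"]

_ALPHA_MAX = 10.0
_ALPHA_PROPOSAL_SD = 0.3


def _update_alpha(alpha: float, q: np.ndarray, rng) -> float:
    """Metropolis step for the symmetric Dirichlet concentration.

    Uniform prior on (0, _ALPHA_MAX]; log-normal random-walk proposal
    (the alpha'/alpha factor is the proposal's Jacobian correction).
    """
    n, K = q.shape
    sum_log_q = float(np.log(np.maximum(q, 1e-300)).sum())

    def log_lik(a: float) -> float:
        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * sum_log_q

    a_new = alpha * np.exp(rng.normal(0.0, _ALPHA_PROPOSAL_SD))
    if a_new > _ALPHA_MAX:
        return alpha
    log_accept = log_lik(a_new) - log_lik(alpha) + np.log(a_new / alpha)
    if np.log(rng.random()) < log_accept:
        return a_new
    return alpha


class AdmixtureModel(BaseEstimator):
    """Gibbs-sampled admixture model (STRUCTURE-style, no-admixture-of-frequencies prior).

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    sweeps : int
        Total Gibbs sweeps; must exceed ``burn_in``.
    burn_in : int
        Sweeps discarded before averaging.
    alpha : float
        Initial symmetric Dirichlet concentration of the membership prior.
    infer_alpha : bool
        Sample alpha by Metropolis-Hastings (uniform prior on (0, 10],
        log-normal proposal), as the original admixture samplers do; set
        False to keep alpha fixed.
    random_state : int or None
        Seed for the sampler.

    Attributes
    ----------
    q_ : ndarray of shape (n_individuals, n_clusters)
        Posterior-mean membership coefficients (rows sum to 1).
    cluster_freqs_ : ndarray of shape (n_clusters, total_alleles)
        Posterior-mean allele frequencies on the global allele coding.
    log_prob_trace_ : ndarray of shape (sweeps,)
        Data log-likelihood per sweep (full trace, no thinning).
    model_log_prob_ : float
        mean - var/2 estimate of the model log-probability from the
        post-burn-in trace.
    """

    def __init__(self, n_clusters: int = 2, sweeps: int = 2000,
                 burn_in: int = 500, alpha: float = 1.0,
                 infer_alpha: bool = True,
                 random_state: int | None = None,
                 track_coassignment: bool = False):
        self.n_clusters = n_clusters
        self.sweeps = sweeps
        self.burn_in = burn_in
        self.alpha = alpha
        self.infer_alpha = infer_alpha
        self.random_state = random_state
        # label-invariant E[q_i . q_j] accumulator; O(n^2) per sweep, so
        # opt-in (used by exactness checks, not routine runs)
        self.track_coassignment = track_coassignment

    def fit(self, gt: GenotypeTable, y=None) -> "AdmixtureModel":
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.sweeps <= self.burn_in:
            raise ValueError("sweeps must exceed burn_in")
        rng = np.random.default_rng(self.random_state)
        enc = gt.encode()
        n, L = gt.n_individuals, gt.n_loci
        K = self.n_clusters
        total = enc.n_alleles_total
        codes = enc.codes.reshape(n, 2 * L)
        obs = codes >= 0
        codes_safe = np.where(obs, codes, 0)
        offsets = enc.locus_offsets[:-1]
        seg_id = np.repeat(np.arange(L), np.diff(enc.locus_offsets))
        row_idx = np.broadcast_to(np.arange(n)[:, None], codes.shape)

        n_distinct = len({tuple(r) for r in codes})
        if K > n_distinct:
            warnings.warn(
                f"K={K} exceeds the number of distinct multilocus genotypes "
                f"({n_distinct}); extra clusters will starve"
            )

        z = rng.integers(0, K, size=codes.shape)
        alpha = float(self.alpha)
        alpha_sum = 0.0
        q_sum = np.zeros((n, K))
        p_sum = np.zeros((K, total))
        co_sum = np.zeros((n, n)) if self.track_coassignment else None
        trace = np.empty(self.sweeps)
        kept = 0
        for sweep in range(self.sweeps):
            # cluster allele frequencies | z
            counts = np.zeros((K, total))
            np.add.at(counts, (z[obs], codes[obs]), 1.0)
            p = rng.gamma(1.0 + counts)
            seg_tot = np.add.reduceat(p, offsets, axis=1)
            p /= seg_tot[:, seg_id]
            # memberships | z
            m = np.zeros((n, K))
            np.add.at(m, (row_idx[obs], z[obs]), 1.0)
            q = rng.gamma(alpha + m)
            q /= q.sum(axis=1, keepdims=True)
            if self.infer_alpha and K > 1:
                alpha = _update_alpha(alpha, q, rng)
            # origins | q, p  (and the mixture likelihood as a by-product)
            w = q[:, None, :] * p.T[codes_safe]  # (n, 2L, K)
            tot = w.sum(axis=2)
            trace[sweep] = float(np.log(tot[obs]).sum())
            cum = np.cumsum(w, axis=2)
            u = rng.random(codes.shape)[:, :, None] * tot[:, :, None]
            z = (u > cum).sum(axis=2)
            if sweep >= self.burn_in:
                q_sum += q
                p_sum += p
                alpha_sum += alpha
                if co_sum is not None:
                    co_sum += q @ q.T
                kept += 1
        self.q_ = q_sum / kept
        self.alpha_posterior_mean_ = alpha_sum / kept
        if co_sum is not None:
            self.coassignment_ = co_sum / kept
        self.cluster_freqs_ = p_sum / kept
        self.locus_offsets_ = enc.locus_offsets
        self.log_prob_trace_ = trace
        post = trace[self.burn_in:]
        self.model_log_prob_ = float(post.mean() - post.var() / 2.0)
        self.ids_ = list(gt.ids)
        return self

    def q_frame(self) -> pd.DataFrame:
        """Membership coefficients as a DataFrame (q_1..q_K, indexed by id)."""
        cols = [f"q_{k + 1}" for k in range(self.q_.shape[1])]
        return pd.DataFrame(self.q_, index=self.ids_, columns=cols)


def fit_admixture(gt: GenotypeTable, K: int, sweeps: int = 2000,
                  burn_in: int = 500, seed: int | None = None,
                  alpha: float = 1.0) -> AdmixtureModel:
    """Functional wrapper over :class:`AdmixtureModel`."""
    return AdmixtureModel(
        n_clusters=K, sweeps=sweeps, burn_in=burn_in, alpha=alpha,
        random_state=seed,
    ).fit(gt)


def align_runs(q_runs: list[np.ndarray]) -> np.ndarray:
    """Align cluster labels across runs and average the q matrices.

    The first run anchors the labelling; every other run's columns are
    permuted to minimise the summed squared difference to the anchor
    (exhaustive over permutations, K <= 6), then the aligned matrices are
    averaged.
    """
    q_runs = [np.asarray(q, dtype=float) for q in q_runs]
    ref = q_runs[0]
    if any(q.shape != ref.shape for q in q_runs):
        raise ValueError("runs have mismatched shapes")
    K = ref.shape[1]
    if K > 6:
        raise ValueError("exhaustive alignment supported for K <= 6")
    acc = ref.copy()
    for q in q_runs[1:]:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(K)):
            cost = ((q[:, perm] - ref) ** 2).sum()
            if cost < best_cost:
                best, best_cost = perm, cost
        acc += q[:, best]
    return acc / len(q_runs)


def delta_k(model_log_probs: dict[int, list[float]]):
    """Evanno-style second-order model-selection table.

    Parameters
    ----------
    model_log_probs : dict
        Maps K to the list of model log-probabilities across runs
        (>= 2 runs per K, >= 3 consecutive K values).

    Returns
    -------
    table : DataFrame with columns K, mean_log_prob, sd_log_prob, delta_k
        (ΔK = |L(K+1) - 2 L(K) + L(K-1)| / SD(K), interior K only).
    best_k : int
        K maximising ΔK.
    """
    ks = sorted(model_log_probs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need at least 3 consecutive K values")
    if any(len(model_log_probs[k]) < 2 for k in ks):
        raise ValueError("need at least 2 runs per K")
    means = {k: float(np.mean(model_log_probs[k])) for k in ks}
    sds = {k: float(np.std(model_log_probs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            num = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            if sds[k] == 0.0:
                warnings.warn(f"zero run-to-run SD at K={k}; ΔK reported as inf")
                dk = np.inf
            else:
                dk = num / sds[k]
        rows.append({"K": k, "mean_log_prob": means[k],
                     "sd_log_prob": sds[k], "delta_k": dk})
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    best_k = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return table, best_k
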