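"""Admixture-proportion (Q) estimation for haploid genotypes.

The model is the standard admixture likelihood specialised to haploid
calls: sample i carries ancestry fractions q_i (summing to 1 over K
clusters), cluster k has alt-allele frequency f_kj at locus j, and each
observed allele is Bernoulli with success probability
pi_ij = sum_k q_ik f_kj. The log-likelihood over non-missing calls is

    l = sum_ij [ x_ij ln pi_ij + (1 - x_ij) ln(1 - pi_ij) ].

``fit_admixture`` maximises this with plain EM (monotone ascent,
responsibilities over cluster-of-origin per allele), multiple random
restarts, and a log-likelihood increase below ``tol`` (default 1e-4) as
the stopping rule. ``estimate_q_supervised`` solves the K = 2 problem in
one dimension when cluster frequencies are known from labelled pure
training samples. Bootstrap standard errors resample loci with
replacement. Cluster labels are arbitrary up to permutation; reporting is
oriented so the "C" cluster is the one with higher mean Q among labelled
C-lineage reference samples, and individuals are classified pure-M
(C-ancestry < 0.05), pure-C (> 0.95) or hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._rng import substream
from .core_io import HaploidDataset, MISSING

__all__ = [
    "AdmixtureFit",
    "fit_admixture",
    "estimate_q_supervised",
    "bootstrap_se",
    "orient_and_classify",
]

_F_EPS = 1e-6


@dataclass
class AdmixtureFit:
    """Result of an admixture EM fit."""

    Q: np.ndarray  # (n_samples, K), rows sum to 1
    F: np.ndarray  # (K, n_loci), clamped to [eps, 1-eps]
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    kept_loci: np.ndarray | None = None  # columns used (all-missing loci dropped)
    bootstrap_se_: np.ndarray | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def K(self) -> int:
        return self.Q.shape[1]


def _loglik(X: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    pi = Q @ F
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    ll = np.where(X == 1, np.log(pi), np.log1p(-pi))
    return float(ll[obs].sum())


def _em(
    X: np.ndarray,
    obs: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """Plain EM on the haploid admixture likelihood. Monotone in l.

    The E-step responsibilities never need materialising as an
    n x L x K array: summing them over loci (for Q) or samples (for F)
    reduces to matrix products of the n x L "observation weight" matrices
    A = 1[x=1]/pi and B = 1[x=0]/(1-pi) with F and Q.
    """
    n, L = X.shape
    K = Q.shape[1]
    x_alt = ((X == 1) & obs).astype(float)
    x_ref = ((X == 0) & obs).astype(float)
    n_obs = obs.sum(axis=1).astype(float)  # per sample
    trace = [_loglik(X, obs, Q, F)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = np.clip(Q @ F, 1e-300, None)          # n x L
        qi = np.clip(1.0 - Q @ F, 1e-300, None)
        A = x_alt / pi
        B = x_ref / qi
        # Q update: q_ik <- q_ik * [(A F^T) + (B (1-F)^T)]_ik / n_obs_i
        Q_new = Q * (A @ F.T + B @ (1.0 - F).T)
        Q_new /= np.maximum(n_obs, 1.0)[:, None]
        Q_new[n_obs == 0] = 1.0 / K  # a fully missing sample stays uninformative
        # F update: alt responsibility mass over total mass at each locus
        alt_mass = (A.T @ Q) * F.T                 # L x K
        tot_mass = alt_mass + (B.T @ Q) * (1.0 - F).T
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (alt_mass / np.clip(tot_mass, 1e-300, None)).T
        F = np.clip(F, _F_EPS, 1.0 - _F_EPS)
        Q = np.clip(Q_new, 0.0, 1.0)
        Q /= Q.sum(axis=1, keepdims=True)
        trace.append(_loglik(X, obs, Q, F))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    return Q, F, trace, converged, it


def fit_admixture(
    ds: HaploidDataset,
    K: int = 2,
    tol: float = 1e-4,
    max_iter: int = 2_000,
    n_restarts: int = 5,
    seed: int = 0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> AdmixtureFit:
    """Unsupervised admixture fit on a haploid dataset.

    Runs ``n_restarts`` EM chains from random starts (Q from a flat
    Dirichlet, F from observed frequencies with jitter) and keeps the best
    final log-likelihood. ``init`` bypasses the random restarts with a
    single run from the given (Q, F) — used by the bootstrap. Loci with no
    observed calls are dropped with a warning recorded in ``kept_loci``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if ds.n_samples == 0 or ds.n_loci == 0:
        raise ValueError("dataset is empty")
    if K > ds.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({ds.n_samples})")
    X = ds.calls.astype(np.int8)
    obs = X != MISSING
    kept = np.nonzero(obs.any(axis=0))[0]
    X = X[:, kept]
    obs = obs[:, kept]
    n, L = X.shape
    if L == 0:
        raise ValueError("all loci are entirely missing")

    with np.errstate(invalid="ignore"):
        p_obs = np.where(obs, X == 1, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)

    if K == 1:
        F = np.clip(p_obs[None, :], _F_EPS, 1 - _F_EPS)
        Q = np.ones((n, 1))
        return AdmixtureFit(Q=Q, F=F, loglik_trace=[_loglik(X, obs, Q, F)],
                            converged=True, n_iter=0, seed=seed,
                            sample_ids=ds.sample_ids, kept_loci=kept)

    best: AdmixtureFit | None = None
    if init is not None:
        Q0, F0 = init
        starts = [(np.array(Q0, dtype=float), np.array(F0, dtype=float)[:, kept]
                   if F0.shape[1] != L else np.array(F0, dtype=float))]
    else:
        starts = []
        for r in range(n_restarts):
            rng = substream(seed, "admixture_init", r)
            Q0 = rng.dirichlet(np.ones(K), size=n)
            jitter = rng.uniform(-0.1, 0.1, size=(K, L))
            F0 = np.clip(p_obs[None, :] + jitter, _F_EPS, 1 - _F_EPS)
            starts.append((Q0, F0))
    for Q0, F0 in starts:
        Q, F, trace, converged, it = _em(X, obs, Q0, F0, tol, max_iter)
        fit = AdmixtureFit(Q=Q, F=F, loglik_trace=trace, converged=converged,
                           n_iter=it, seed=seed, sample_ids=ds.sample_ids,
                           kept_loci=kept)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def estimate_q_supervised(
    genotype_row: np.ndarray, F_ref: np.ndarray, tol: float = 1e-8
) -> tuple[float, float]:
    """Closed-form-style supervised K=2 estimate for one haploid sample.

    Maximises the haploid likelihood over the single parameter
    q = fraction of cluster 1 ancestry, given fixed reference frequencies
    ``F_ref`` (2 x n_loci, rows = clusters). Missing calls are skipped.
    Returns (q_hat, log-likelihood). Raises if every locus is missing.
    """
    x = np.asarray(genotype_row)
    F_ref = np.asarray(F_ref, dtype=float)
    if F_ref.ndim != 2 or F_ref.shape[0] != 2:
        raise ValueError("F_ref must be 2 x n_loci")
    if x.shape[0] != F_ref.shape[1]:
        raise ValueError(
            f"locus mismatch: genotype has {x.shape[0]} loci, "
            f"F_ref has {F_ref.shape[1]}"
        )
    obs = x != MISSING
    if not obs.any():
        raise ValueError("no information: all calls missing for this sample")
    xo = x[obs].astype(float)
    f1 = np.clip(F_ref[0, obs], _F_EPS, 1 - _F_EPS)
    f2 = np.clip(F_ref[1, obs], _F_EPS, 1 - _F_EPS)

    def neg_ll(q: float) -> float:
        pi = q * f1 + (1 - q) * f2
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        return -float(np.sum(xo * np.log(pi) + (1 - xo) * np.log1p(-pi)))

    res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    return float(res.x), -float(res.fun)


def _align_to(F_ref: np.ndarray, F_boot: np.ndarray) -> np.ndarray:
    """Return the column permutation of a K=2 bootstrap fit matching F_ref."""
    K = F_ref.shape[0]
    if K != 2:
        return np.arange(K)
    direct = np.abs(F_ref - F_boot).mean()
    swapped = np.abs(F_ref - F_boot[::-1]).mean()
    return np.array([0, 1]) if direct <= swapped else np.array([1, 0])


def bootstrap_se(
    fit: AdmixtureFit,
    ds: HaploidDataset,
    n_boot: int = 200,
    seed: int = 0,
    max_iter: int = 200,
) -> np.ndarray:
    """Per-sample bootstrap SE of Q by resampling loci with replacement.

    Each replicate refits with (Q, F) initialised at the point estimate and
    aligns cluster labels to the point estimate before accumulating, so
    label switching does not inflate the SEs. Stores and returns the
    per-sample SE of the first cluster's Q.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    kept = fit.kept_loci if fit.kept_loci is not None else np.arange(ds.n_loci)
    X = ds.calls[:, kept]
    L = X.shape[1]
    qs = np.empty((n_boot, fit.Q.shape[0]))
    for b in range(n_boot):
        rng = substream(seed, "bootstrap", b)
        cols = rng.integers(0, L, size=L)
        sub = HaploidDataset(
            samples=ds.samples,
            loci=[ds.loci[kept[j]] for j in cols],
            calls=X[:, cols],
        )
        # loci are no longer sorted after resampling; EM does not care
        boot = fit_admixture(sub, K=fit.K, tol=1e-4, max_iter=max_iter,
                             seed=seed, init=(fit.Q, fit.F[:, cols]))
        perm = _align_to(fit.F[:, cols], boot.F)
        qs[b] = boot.Q[:, perm][:, 0]
    se = qs.std(axis=0, ddof=1)
    fit.bootstrap_se_ = se
    return se


def orient_and_classify(
    fit: AdmixtureFit,
    reference_c_indices: Sequence[int],
    q_hi: float = 0.95,
    q_lo: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Orient a K=2 fit so the reported value is C-lineage ancestry.

    ``reference_c_indices`` are row indices of labelled C-lineage samples;
    the cluster with the higher mean Q among them is named C. Samples are
    classified pure-M when C-ancestry < ``q_lo``, pure-C when
    > ``q_hi`` (strict inequalities), otherwise hybrid. Returns the
    oriented C-ancestry vector and the purity labels.
    """
    refs = np.asarray(list(reference_c_indices), dtype=int)
    if refs.size == 0:
        raise ValueError("need at least one labelled C-lineage reference sample")
    if fit.K != 2:
        raise ValueError("orientation is defined for K=2 fits")
    means = fit.Q[refs].mean(axis=0)
    c_cluster = int(np.argmax(means))
    c_ancestry = fit.Q[:, c_cluster].copy()
    labels = [
        "pure_M" if q < q_lo else ("pure_C" if q > q_hi else "hybrid")
        for q in c_ancestry
    ]
    return c_ancestry, labels
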