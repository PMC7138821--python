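"""Maximum-likelihood admixture model fitted by expectation-maximization.

Model: sample i carries ancestry proportions q_i over K populations with
population allele frequencies f_kj at SNP j; the dosage g_ij is
Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj.  The EM updates are the
classic ones for this model: allele-origin responsibilities in the E step,
row-normalized expected ancestry counts and frequency ratios in the M step.
Missing dosages contribute nothing to the likelihood (complete case per
cell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, GenotypeMatrix, QMatrix, ValidationError

EPS = 1e-6  # frequency clamp keeping the log-likelihood finite


@dataclass
class AdmixtureFit:
    Q: QMatrix
    F: np.ndarray            # K x n_snps allele frequencies
    loglik_trace: list[float]
    seed: int
    iterations: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _masked(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    g = G.dosages.astype(float)
    obs = G.dosages != MISSING
    g[~obs] = 0.0
    return g, obs


def loglikelihood(G: GenotypeMatrix, Q: np.ndarray | QMatrix, F: np.ndarray) -> float:
    """Binomial log-likelihood of the dosage matrix under (Q, F)."""
    q = Q.proportions if isinstance(Q, QMatrix) else np.asarray(Q)
    F = np.asarray(F)
    if q.shape[0] != G.n_samples or F.shape != (q.shape[1], G.n_snps):
        raise ValidationError("dimension mismatch between G, Q and F")
    g, obs = _masked(G)
    p = q @ F
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("mixture probabilities escaped [0, 1]")
    p = np.clip(p, EPS, 1 - EPS)
    ll = g * np.log(p) + (2.0 - g) * np.log1p(-p)
    return float(ll[obs].sum())


def em_fit(G: GenotypeMatrix, K: int, seed: int, tol: float = 1e-4,
           max_iter: int = 2000) -> AdmixtureFit:
    """Fit ancestry proportions and allele frequencies by EM.

    Initialization is seeded: Q rows from a flat Dirichlet, F from the
    per-SNP sample frequency jittered by +-0.05.  The log-likelihood trace
    is non-decreasing; non-convergence returns a fit flagged
    ``converged=False`` with a warning rather than raising.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if G.n_samples < K:
        raise ValidationError(f"need at least K={K} samples, have {G.n_samples}")
    rng = np.random.default_rng(seed)
    n, m = G.n_samples, G.n_snps
    g, obs = _masked(G)
    n_obs_alleles = 2.0 * obs.sum(axis=1)  # per-sample allele count
    if (n_obs_alleles == 0).any():
        raise ValidationError("a sample has no observed genotypes")

    if K == 1:
        # analytic optimum: Q = 1, F = mean dosage / 2 over observed calls
        f = g.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
        F = np.clip(f, EPS, 1 - EPS)[None, :]
        Qm = QMatrix(list(G.sample_ids), np.ones((n, 1)))
        ll = loglikelihood(G, np.ones((n, 1)), F)
        return AdmixtureFit(Qm, F, [ll], seed, 0, True)

    base_f = g.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
    F = np.clip(base_f[None, :] + rng.uniform(-0.05, 0.05, size=(K, m)), EPS, 1 - EPS)
    Q = rng.dirichlet(np.ones(K), size=n)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(Q @ F, EPS, 1 - EPS)
        # responsibilities: expected allele counts attributed to population k
        #   a_ijk ~ reference ("1") alleles, b_ijk ~ alternate ("0") alleles
        ga = np.where(obs, g / p, 0.0)          # n x m
        gb = np.where(obs, (2.0 - g) / (1 - p), 0.0)
        # per-k sums computed without materializing an n x m x K tensor
        q_new = np.empty_like(Q)
        a_colsum = np.zeros((K, m))
        ab_colsum = np.zeros((K, m))
        for k in range(K):
            a_k = ga * (Q[:, k:k + 1] * F[k][None, :])     # n x m
            b_k = gb * (Q[:, k:k + 1] * (1 - F[k])[None, :])
            q_new[:, k] = a_k.sum(axis=1) + b_k.sum(axis=1)
            a_colsum[k] = a_k.sum(axis=0)
            ab_colsum[k] = a_colsum[k] + b_k.sum(axis=0)
        Q = q_new / n_obs_alleles[:, None]
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        F = np.clip(a_colsum / np.maximum(ab_colsum, 1e-300), EPS, 1 - EPS)
        ll = loglikelihood(G, Q, F)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", RuntimeWarning)
    return AdmixtureFit(QMatrix(list(G.sample_ids), Q), F, trace, seed, it, converged)


def multi_start(G: GenotypeMatrix, K: int, seeds: list[int], tol: float = 1e-4,
                max_iter: int = 2000) -> list[AdmixtureFit]:
    """Independent EM fits from the given seeds, sorted by final log-likelihood."""
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds passed to multi_start", RuntimeWarning)
    fits = [em_fit(G, K, s, tol=tol, max_iter=max_iter) for s in seeds]
    return sorted(fits, key=lambda f: -f.loglik)
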