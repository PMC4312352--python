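"""Maximum-likelihood ancestry-component estimation (binomial admixture model).

The model: individual i's dosage at marker l is Binomial(2, p_il) with
p_il = sum_k q_ik f_kl, where Q holds per-individual ancestry proportions
(rows on the K-simplex) and F per-component allele frequencies. Missing
genotypes contribute nothing to the likelihood.

Optimisation is plain EM. In supervised mode F is fixed at user-supplied
reference frequencies and only Q is updated — each row is then a concave
1-D/simplex problem, so the result is deterministic given the inputs. In
unsupervised mode both Q and F are updated from a seeded random start and
component labels are canonicalised by sorting on mean allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

#: Frequency clamp keeping the likelihood finite.
EPS = 1e-6


@dataclass
class AncestryEstimate:
    """EM output: Q (n x K), F (K x L), log-likelihood trace, convergence."""

    Q: np.ndarray
    F: np.ndarray
    loglik_trace: list[float]
    converged: bool
    K: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _clamp(F: np.ndarray) -> np.ndarray:
    return np.clip(F, EPS, 1.0 - EPS)


def loglikelihood(G: GenotypeMatrix | np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    """Total binomial log-likelihood of the genotype matrix under (Q, F).

    Includes the binomial coefficient log C(2, g); missing entries
    contribute 0.
    """
    geno = G.genotypes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    Q = np.asarray(Q, float)
    F = _clamp(np.asarray(F, float))
    if Q.shape[0] != geno.shape[0] or Q.shape[1] != F.shape[0] or F.shape[1] != geno.shape[1]:
        raise ValueError("inconsistent shapes among G, Q, F")
    P = np.clip(Q @ F, EPS, 1.0 - EPS)
    g = geno.astype(float)
    obs = geno != MISSING
    g = np.where(obs, g, 0.0)
    ll = g * np.log(P) + (2.0 - g) * np.log1p(-P)
    ll += gammaln(3.0) - gammaln(g + 1.0) - gammaln(3.0 - g)
    return float(np.sum(ll[obs]))


def _em_iterate(
    g: np.ndarray,
    g2: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    update_F: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One EM step; returns the updated (Q, F) and the log-likelihood of the
    *incoming* parameters (binomial-coefficient constant excluded).

    ``g`` holds dosages with missing entries zeroed; ``g2`` holds
    ``2 - dosage`` with missing entries zeroed, so both sums skip missing
    data without re-masking.
    """
    F = _clamp(F)
    P = np.clip(Q @ F, EPS, 1.0 - EPS)
    ll = float(np.sum(g * np.log(P)) + np.sum(g2 * np.log1p(-P)))
    # responsibilities: expected allele-copy counts attributed to component k
    #   a_ik_l = g * q_ik f_kl / p_il ; b_ik_l = (2-g) * q_ik (1-f_kl) / (1-p_il)
    GA = g / P             # (n, L)
    GB = g2 / (1.0 - P)
    A = Q * (GA @ F.T)     # (n, K): sum_l a
    B = Q * (GB @ (1.0 - F).T)
    denom = (A + B).sum(axis=1, keepdims=True)
    denom = np.where(denom > 0, denom, 1.0)
    Q_new = (A + B) / denom
    if update_F:
        # per (k, l): sum_i a_ikl / sum_i (a_ikl + b_ikl)
        Anum = F * (Q.T @ GA)          # (K, L)
        Bnum = (1.0 - F) * (Q.T @ GB)
        with np.errstate(invalid="ignore", divide="ignore"):
            F_new = Anum / (Anum + Bnum)
        F_new = _clamp(np.where(np.isfinite(F_new), F_new, F))
    else:
        F_new = F
    return Q_new, F_new, ll


def admixture_em(
    G: GenotypeMatrix | np.ndarray,
    K: int,
    supervised_F: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int = 0,
    Q_init: np.ndarray | None = None,
) -> AncestryEstimate:
    """Fit the admixture model by EM.

    Parameters
    ----------
    G
        Genotype matrix (or raw dosage array with MISSING codes).
    K
        Number of ancestry components (>= 1).
    supervised_F
        If given, a (K, L) array of fixed component frequencies (supervised
        mode); otherwise F is estimated (unsupervised mode, random seeded
        initialisation, labels canonicalised by ascending mean frequency).
    tol
        Stop when the log-likelihood increase falls below this.
    """
    geno = G.genotypes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    n, L = geno.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n and supervised_F is None:
        import warnings

        warnings.warn(f"K={K} exceeds the number of individuals ({n})")

    obs = geno != MISSING
    keep = obs.any(axis=0)
    if not keep.all():
        import logging

        logging.getLogger(__name__).info(
            "dropping %d all-missing markers", int((~keep).sum())
        )
        geno = geno[:, keep]
        obs = obs[:, keep]
    g = np.where(obs, geno.astype(float), 0.0)

    if K == 1:
        # closed form: F = observed allele frequencies, Q = 1
        with np.errstate(invalid="ignore"):
            F = (g.sum(0) / (2.0 * obs.sum(0)))[None, :]
        Q = np.ones((n, 1))
        ll = loglikelihood(geno, Q, F)
        return AncestryEstimate(Q=Q, F=_clamp(F), loglik_trace=[ll], converged=True, K=1)

    rng = np.random.default_rng(seed)
    if supervised_F is not None:
        F = _clamp(np.asarray(supervised_F, float)[:, keep].copy())
        if F.shape != (K, geno.shape[1]):
            raise ValueError("supervised_F must be (K, n_markers)")
        update_F = False
    else:
        F = _clamp(rng.uniform(0.1, 0.9, size=(K, geno.shape[1])))
        update_F = True
    if Q_init is not None:
        Q = np.asarray(Q_init, float).copy()
    elif update_F:
        Q = rng.dirichlet(np.ones(K), size=n)
    else:
        Q = np.full((n, K), 1.0 / K)  # supervised: deterministic interior start
    Q = np.clip(Q, 1e-12, None)
    Q /= Q.sum(1, keepdims=True)

    g2 = np.where(obs, 2.0 - geno.astype(float), 0.0)
    const = float(
        np.sum((gammaln(3.0) - gammaln(g[obs] + 1.0) - gammaln(3.0 - g[obs])))
    )
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        Q_new, F_new, ll = _em_iterate(g, g2, Q, F, update_F)
        trace.append(ll + const)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            Q, F = Q_new, F_new
            break
        Q, F = Q_new, F_new
    trace.append(loglikelihood(geno, Q, F))

    if update_F:  # canonical label order: ascending mean component frequency
        order = np.argsort(F.mean(axis=1))
        F = F[order]
        Q = Q[:, order]
    return AncestryEstimate(Q=Q, F=F, loglik_trace=trace, converged=converged, K=K)


def estimate_admixture_fraction(
    samples: GenotypeMatrix | np.ndarray,
    source_freqs: np.ndarray,
    background_freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> np.ndarray:
    """Per-individual source-ancestry fraction by supervised EM (K=2).

    ``source_freqs`` is component 0; the returned vector is the source column
    of Q. The supervised problem is concave per individual, so the result is
    deterministic given the inputs.
    """
    F = np.stack([np.asarray(source_freqs, float), np.asarray(background_freqs, float)])
    geno = samples.genotypes if isinstance(samples, GenotypeMatrix) else np.asarray(samples)
    n = geno.shape[0]
    Q0 = np.full((n, 2), 0.5)
    est = admixture_em(
        geno, K=2, supervised_F=F, tol=tol, max_iter=max_iter, Q_init=Q0
    )
    return est.Q[:, 0].copy()
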