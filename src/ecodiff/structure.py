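"""Population structure: genotype PCA and frequentist admixture EM.

PCA uses the standard genotype scaling: missing dosages are
mean-imputed per site, each site is centred and divided by
``sqrt(p(1-p))`` where ``p`` is the site's allele frequency, and the
samples' principal components are taken from the SVD of the resulting
matrix.  Zero-variance sites are dropped.

Admixture is estimated by maximum likelihood under the binomial mixture
model: individual ``i`` carries ancestry fractions ``q_i`` (summing to
1 over K source populations) and source ``k`` has allele frequency
``f_kj`` at site ``j``; each of the two allele copies is drawn from the
mixture ``sum_k q_ik f_kj``.  The EM algorithm ascends

    L = sum_ij [ g_ij log(sum_k q_ik f_kj) + (2 - g_ij) log(sum_k q_ik (1 - f_kj)) ]

with missing genotypes skipped; the log-likelihood is non-decreasing at
every iteration.  Multiple random restarts guard against local optima;
the best final likelihood is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecodiff.genotyping import MISSING, GenotypeMatrix

DEFAULT_MAX_ITER = 10_000
DEFAULT_TOL = 1e-6
_F_EPS = 1e-9


@dataclass
class PcaResult:
    coords: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    samples: list[str]


@dataclass
class AdmixtureFit:
    q: np.ndarray  # (n_samples, K) ancestry fractions
    f: np.ndarray  # (K, n_sites) allele frequencies
    loglik_trace: np.ndarray
    iterations: int
    converged: bool
    samples: list[str]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Genotype PCA with allele-frequency scaling."""
    g = matrix.dosage.astype(float).T  # (samples, sites)
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    p = mean / 2.0
    scale = np.sqrt(p * (1 - p))
    keep = scale > 0
    g = np.where(np.isnan(g), mean[None, :], g)[:, keep]
    x = (g - mean[None, keep]) / scale[None, keep]
    n_components = min(n_components, min(x.shape) - 1)
    u, s, _ = np.linalg.svd(x - x.mean(axis=0, keepdims=True), full_matrices=False)
    var = s**2
    return PcaResult(
        coords=u[:, :n_components] * s[:n_components],
        explained_variance_ratio=var[:n_components] / var.sum(),
        samples=list(matrix.samples),
    )


def _admixture_loglik(g, called, q, f) -> float:
    p = np.clip(q @ f, 1e-12, 1 - 1e-12)
    terms = np.where(called, g * np.log(p) + (2 - g) * np.log1p(-p), 0.0)
    return float(terms.sum())


def _em_run(g, called, k, rng, max_iter, tol):
    n, j = g.shape
    q = rng.dirichlet(np.ones(k), size=n)
    f = rng.uniform(0.05, 0.95, size=(k, j))
    trace = [_admixture_loglik(g, called, q, f)]
    converged = False
    g0 = np.where(called, g, 0.0)
    g2 = np.where(called, 2 - g, 0.0)
    sites_per_sample = called.sum(axis=1)
    for it in range(max_iter):
        p = np.clip(q @ f, 1e-12, 1 - 1e-12)
        inv_p = g0 / p
        inv_m = g2 / (1 - p)
        # expected allele-copy counts attributed to each source k
        a = q[:, :, None] * f[None, :, :]  # (n, k, j) contribution to "ref" copies
        b = q[:, :, None] * (1 - f[None, :, :])
        num_ref = a * inv_p[:, None, :]
        num_alt = b * inv_m[:, None, :]
        nk = (num_ref + num_alt).sum(axis=2)  # (n, k)
        q = nk / (2 * sites_per_sample)[:, None]
        q = q / q.sum(axis=1, keepdims=True)
        ref_k = num_ref.sum(axis=0)  # (k, j)
        tot_k = ref_k + num_alt.sum(axis=0)
        f = np.clip(ref_k / np.clip(tot_k, 1e-300, None), _F_EPS, 1 - _F_EPS)
        ll = _admixture_loglik(g, called, q, f)
        trace.append(ll)
        if abs(ll - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
    return q, f, np.array(trace), converged


def admixture_em(
    matrix: GenotypeMatrix,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_restarts: int = 5,
    seed: int = 0,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit by EM.

    Runs ``n_restarts`` random initialisations (seeds derived from
    ``seed``) and keeps the best final log-likelihood.  ``K=1`` has the
    closed-form optimum (q all ones, f = per-site mean dosage / 2),
    which EM reaches in one step.  Raises when ``k`` exceeds the sample
    count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_samples:
        raise ValueError(f"k={k} exceeds {matrix.n_samples} samples")
    g = matrix.dosage.astype(float).T  # (samples, sites)
    called = g != MISSING
    if not called.any(axis=1).all():
        raise ValueError("every sample needs at least one called genotype")
    g = np.where(called, g, 0.0)

    best = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        q, f, trace, converged = _em_run(g, called, k, rng, max_iter, tol)
        if best is None or trace[-1] > best[2][-1]:
            best = (q, f, trace, converged)
    q, f, trace, converged = best
    return AdmixtureFit(
        q=q, f=f, loglik_trace=trace, iterations=len(trace) - 1,
        converged=converged, samples=list(matrix.samples),
    )


def align_ancestry(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Resolve label switching: greedily match estimated to true columns."""
    k = q_true.shape[1]
    cost = np.array(
        [[np.mean(np.abs(q_est[:, a] - q_true[:, b])) for b in range(k)] for a in range(k)]
    )
    perm = np.full(k, -1)
    used = set()
    for a in np.argsort(cost.min(axis=1)):
        b = min((b for b in range(k) if b not in used), key=lambda b: cost[a, b])
        perm[a] = b
        used.add(b)
    out = np.empty_like(q_est)
    for a in range(k):
        out[:, perm[a]] = q_est[:, a]
    return out
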