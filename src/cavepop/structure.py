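"""Population delineation from genotype data.

Implements the structure toolkit used to delineate isolated populations:
an identity-by-state (IBS) distance with single-allele sampling per site,
agglomerative clustering of that distance, classical (Torgerson)
multidimensional scaling, BIC selection of the number of Gaussian mixture
components on the MDS embedding, and an ADMIXTURE/NGSadmix-style EM for
ancestry proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

from .containers import MISSING, DistanceMatrix, GenotypeLikelihoodTensor, GenotypeMatrix
from .io import linkage_to_newick

__all__ = [
    "AdmixtureResult",
    "KSelectionTable",
    "ibs_distance_matrix",
    "hierarchical_cluster",
    "classical_mds",
    "select_k_bic",
    "admixture_em",
]

_EPS = 1e-9


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray  # (n_samples, K) ancestry proportions
    F: np.ndarray  # (K, n_sites) ancestral allele frequencies
    log_likelihood: float
    n_iterations: int
    converged: bool
    seed: int
    samples: list[str]
    ll_trace: list[float] | None = None

    def __post_init__(self) -> None:
        if np.abs(self.Q.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("Q rows must sum to 1")
        if (self.F < 0).any() or (self.F > 1).any():
            raise ValueError("F must lie in [0, 1]")

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q, index=self.samples, columns=[f"K{k}" for k in range(self.K)]
        )


@dataclass
class KSelectionTable:
    """BIC per candidate K; the selected K minimises the criterion."""

    table: pd.DataFrame  # columns: k, bic
    selected_k: int

    def __post_init__(self) -> None:
        best = int(self.table.loc[self.table["bic"].idxmin(), "k"])
        if best != self.selected_k:
            raise ValueError("selected_k must minimise BIC")


def ibs_distance_matrix(
    matrix: GenotypeMatrix, min_maf: float = 0.01, seed: int = 0
) -> DistanceMatrix:
    """Pairwise IBS mismatch distance with one sampled allele per genotype.

    Sites are first screened at ``min_maf`` on the full-sample allele
    frequency.  For each sample x site one allele is drawn uniformly from
    the genotype (the analogue of single-read sampling); ``d_ij`` is the
    fraction of sites, among the ``M`` jointly non-missing ones, where the
    sampled bases differ.  Pairs with M = 0 get NaN.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    freq = matrix.allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    use = np.nan_to_num(maf, nan=-1.0) >= min_maf
    sub = matrix.take_sites(use)

    rng = np.random.default_rng(seed)
    d = sub.dosage
    obs = d != MISSING
    coin = rng.random(d.shape) < 0.5
    allele = np.where(d == 1, coin, d == 2)  # sampled allele is alt?

    n = sub.n_samples
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = obs[i] & obs[i + 1 :]
        mism = (allele[i] != allele[i + 1 :]) & both
        m = both.sum(axis=1)
        shared[i, i + 1 :] = shared[i + 1 :, i] = m
        with np.errstate(invalid="ignore"):
            row = mism.sum(axis=1) / np.where(m == 0, np.nan, m)
        dist[i, i + 1 :] = dist[i + 1 :, i] = row
    shared[np.diag_indices(n)] = obs.sum(axis=1)
    return DistanceMatrix(samples=matrix.samples, d=dist, n_shared_sites=shared)


def hierarchical_cluster(
    dm: DistanceMatrix, method: str = "average"
) -> tuple[np.ndarray, str]:
    """Agglomerative clustering of an IBS distance matrix.

    Returns the scipy linkage matrix and a Newick rendering with the
    samples as leaves.  Undefined (NaN) distances are refused: they mean a
    pair shares no sites, which stricter filtering should fix first.
    """
    if dm.has_undefined:
        raise ValueError(
            "distance matrix has undefined entries (pairs with no shared sites); "
            "filter sites or samples more strictly before clustering"
        )
    z = linkage(squareform(dm.d, checks=False), method=method)
    return z, linkage_to_newick(z, dm.samples)


def cut_clusters(linkage_matrix: np.ndarray, n_clusters: int) -> np.ndarray:
    """Cluster labels from cutting the dendrogram into ``n_clusters`` groups."""
    return fcluster(linkage_matrix, t=n_clusters, criterion="maxclust")


def classical_mds(dm: DistanceMatrix, n_axes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centres the squared distances and eigendecomposes the Gram
    matrix; axes are ordered by decreasing eigenvalue and axes with
    non-positive eigenvalues are dropped (with fewer axes returned).
    Returns ``(coordinates, eigenvalues)``.
    """
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("classical MDS needs a symmetric matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12).sum())
    k = min(n_axes, n_pos)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    if k < n_axes:
        coords = np.hstack([coords, np.zeros((n, n_axes - k))])
    return coords, evals


def select_k_bic(
    coords: np.ndarray,
    k_range: range | list[int] = range(1, 9),
    seed: int = 0,
    n_init: int = 10,
) -> KSelectionTable:
    """Choose the number of mixture components on an MDS embedding by BIC.

    Fits a Gaussian mixture with a shared ('tied') covariance matrix for
    each candidate K and reports BIC = -2 log L + n_params log(n), so the
    selected K minimises the criterion.  Candidates with K >= n_samples are
    skipped as degenerate.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    rows = []
    for k in k_range:
        if k >= n:
            continue
        gm = GaussianMixture(
            n_components=k, covariance_type="tied", n_init=n_init, random_state=seed
        ).fit(coords)
        rows.append((k, float(gm.bic(coords))))
    if not rows:
        raise ValueError("no admissible K candidates (all >= n_samples)")
    table = pd.DataFrame(rows, columns=["k", "bic"])
    return KSelectionTable(table=table, selected_k=int(table.loc[table["bic"].idxmin(), "k"]))


def _binom2_logpmf(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    coef = np.where(g == 1, np.log(2.0), 0.0)
    return coef + g * np.log(p) + (2.0 - g) * np.log1p(-p)


def _admixture_em_once(
    g_obs: np.ndarray | None,
    gl_lin: np.ndarray | None,
    obs_mask: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """One EM run.  ``g_obs`` is (n, m) float dosage with 0 at missing, or
    None when GLs drive the run; ``gl_lin`` is (n, m, 3) linear likelihoods."""
    n, m = obs_mask.shape
    q = rng.dirichlet(np.ones(K), size=n)
    f = rng.uniform(0.05, 0.95, size=(K, m))
    n_obs = np.maximum(obs_mask.sum(axis=1, keepdims=True), 1)
    g_levels = np.array([0.0, 1.0, 2.0])
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(q @ f, _EPS, 1.0 - _EPS)
        if gl_lin is None:
            g_eff = g_obs
            site_ll = _binom2_logpmf(g_obs, p)
            ll = float(site_ll[obs_mask].sum())
        else:
            prior = np.stack(
                [_binom2_logpmf(gg, p) for gg in g_levels], axis=-1
            )  # (n, m, 3) log P(g|p)
            joint = gl_lin * np.exp(prior - prior.max(axis=-1, keepdims=True))
            tot = joint.sum(axis=-1)
            w = joint / np.maximum(tot, 1e-300)[..., None]
            g_eff = w @ g_levels
            ll = float(
                (np.log(np.maximum(tot, 1e-300)) + prior.max(axis=-1))[obs_mask].sum()
            )
        alt_over_p = np.where(obs_mask, g_eff / p, 0.0)
        ref_over_q = np.where(obs_mask, (2.0 - g_eff) / (1.0 - p), 0.0)
        alt_k = q * (alt_over_p @ f.T)  # (n, K) expected alt copies from k
        ref_k = q * (ref_over_q @ (1.0 - f).T)
        q = (alt_k + ref_k) / (2.0 * n_obs)
        q = np.clip(q, _EPS, None)
        q /= q.sum(axis=1, keepdims=True)
        alt_kj = f * (q.T @ alt_over_p)  # (K, m)
        ref_kj = (1.0 - f) * (q.T @ ref_over_q)
        f = alt_kj / np.maximum(alt_kj + ref_kj, 1e-300)
        f = np.clip(f, _EPS, 1.0 - _EPS)
        trace.append(ll)
        if ll - ll_prev < tol * max(abs(ll), 1.0) and it > 1:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return q, f, ll_prev, it, converged, trace


def admixture_em(
    data: GenotypeMatrix | GenotypeLikelihoodTensor,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> AdmixtureResult:
    """Maximum-likelihood admixture proportions via EM.

    Models individual i's alt dosage at site j as Binomial(2, sum_k q_ik
    f_kj); with genotype likelihoods the three genotypes are posterior-
    weighted each iteration (the NGSadmix likelihood).  The best of
    ``n_restarts`` random starts (Dirichlet(1) Q, uniform F) by final
    log-likelihood is returned.  K = 1 has the closed form Q = 1, F =
    overall sample frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(data, GenotypeMatrix):
        obs_mask = data.dosage != MISSING
        g_obs = np.where(obs_mask, data.dosage, 0).astype(float)
        gl_lin = None
    else:
        obs_mask = ~data.missing
        g_obs = None
        gl_lin = np.exp(data.loglik - data.loglik.max(axis=-1, keepdims=True))
        gl_lin[data.missing] = 1.0

    n, m = obs_mask.shape
    if K == 1:
        if g_obs is not None:
            f = np.where(obs_mask, g_obs, 0).sum(axis=0) / np.maximum(
                2.0 * obs_mask.sum(axis=0), 1
            )
            p = np.clip(np.broadcast_to(f, (n, m)), _EPS, 1 - _EPS)
            ll = float(_binom2_logpmf(g_obs, p)[obs_mask].sum())
        else:
            # one EM pass per site is overkill for K=1; reuse the general EM
            q1, f, ll, _, _, _ = _admixture_em_once(
                g_obs, gl_lin, obs_mask, 1, np.random.default_rng(seed), tol, max_iter
            )
            f = f[0]
        return AdmixtureResult(
            K=1,
            Q=np.ones((n, 1)),
            F=f.reshape(1, m),
            log_likelihood=ll,
            n_iterations=0,
            converged=True,
            seed=seed,
            samples=list(data.samples),
            ll_trace=[ll],
        )

    best = None
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        q, f, ll, it, conv, trace = _admixture_em_once(
            g_obs, gl_lin, obs_mask, K, rng, tol, max_iter
        )
        if best is None or ll > best[2]:
            best = (q, f, ll, it, conv, trace)
    q, f, ll, it, conv, trace = best
    return AdmixtureResult(
        K=K,
        Q=q / q.sum(axis=1, keepdims=True),
        F=f,
        log_likelihood=ll,
        n_iterations=it,
        converged=conv,
        seed=seed,
        samples=list(data.samples),
        ll_trace=trace,
    )
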