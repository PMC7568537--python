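"""Nucleotide diversity and effective population size.

Two tracks mirror common RAD-seq practice:

* hard-call track — per-site expected heterozygosity
  ``h = n/(n-1) * (1 - sum p_i**2)`` summed over segregating sites and
  divided by the number of interrogated positions;
* genotype-likelihood track — per-site allele-frequency likelihoods, a
  dynamic program for the likelihood of every sample allele count, an EM
  estimate of the folded site-frequency spectrum, and pi from the
  SFS-prior posterior over counts.

Effective population size follows the neutral equilibrium ``Ne = pi/(4*mu)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import MISSING, GenotypeLikelihoodTensor, GenotypeMatrix, PopulationMap

__all__ = [
    "DiversityEstimate",
    "FoldedSFS",
    "expected_het",
    "pi_hard",
    "ne_from_pi",
    "gl_allele_frequency",
    "allele_count_likelihoods",
    "folded_sfs_em",
    "pi_from_sfs",
    "pi_gl",
]

#: default per-site per-generation mutation rate (a Drosophila estimate;
#: the true rate for most invertebrates is unknown, so downstream Ne values
#: are rough scalings of pi, not absolute census statements)
DEFAULT_MU = 2.8e-9


@dataclass
class DiversityEstimate:
    population: str
    pi_per_site: float
    S: int
    total_positions: int
    method: str  # "hard-call" or "GL-SFS"
    mu: float | None = None
    ne: float | None = None

    def __post_init__(self) -> None:
        if self.pi_per_site < 0:
            raise ValueError("pi must be non-negative")
        if self.S > self.total_positions:
            raise ValueError("segregating sites cannot exceed interrogated positions")


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum over minor-allele count classes 0..N."""

    population: str
    proportions: np.ndarray
    n_chromosomes: int  # 2N
    log_likelihood: float
    n_iterations: int
    converged: bool
    ll_trace: list[float] | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise ValueError("SFS proportions must sum to 1")


def expected_het(allele_counts: Sequence[float]) -> float:
    """Unbiased expected heterozygosity ``h = n/(n-1) * (1 - sum p_i^2)``.

    ``allele_counts`` are the observed counts of each allele at the site
    (n = their sum is the number of sequences).
    """
    counts = np.asarray(allele_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("allele counts must be non-negative")
    n = counts.sum()
    if n < 2:
        raise ValueError("expected_het requires at least 2 sequences")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def pi_hard(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    total_positions: int,
    mu: float | None = DEFAULT_MU,
) -> DiversityEstimate:
    """Hard-call nucleotide diversity for one population.

    Sums per-site expected heterozygosity over segregating sites (each site
    using its own non-missing sample count) and divides by
    ``total_positions``, the number of interrogated positions including
    monomorphic ones.
    """
    members = popmap.samples_in(population)
    if not members:
        raise ValueError(f"population {population!r} has no samples in the map")
    sub = matrix.take_samples([s for s in members if s in matrix.samples])
    if sub.n_samples == 0:
        raise ValueError(f"population {population!r} has no samples in the matrix")

    d = sub.dosage
    obs = d != MISSING
    n_seq = 2 * obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_seq
    seg = (n_seq >= 2) & (alt > 0) & (alt < n_seq)
    h = np.zeros(sub.n_sites)
    ns = n_seq[seg].astype(float)
    ps = p[seg]
    h[seg] = ns / (ns - 1.0) * (1.0 - ps**2 - (1.0 - ps) ** 2)

    S = int(seg.sum())
    if total_positions < S:
        raise ValueError("total_positions must be >= number of segregating sites")
    pi = float(h.sum() / total_positions)
    return DiversityEstimate(
        population=population,
        pi_per_site=pi,
        S=S,
        total_positions=total_positions,
        method="hard-call",
        mu=mu,
        ne=None if mu is None else ne_from_pi(pi, mu),
    )


def ne_from_pi(pi_per_site: float, mu: float = DEFAULT_MU) -> float:
    """Effective population size under neutral equilibrium, ``pi/(4 mu)``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi_per_site < 0:
        raise ValueError("pi must be non-negative")
    return pi_per_site / (4.0 * mu)


def _hwe_log_prior(p: float) -> np.ndarray:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return np.log(np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2]))


def gl_allele_frequency(
    site_loglik: np.ndarray,
    missing: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[float, Callable[[float], float], bool]:
    """Maximum-likelihood alt-allele frequency from one site's GL triples.

    Maximises ``sum_i log sum_g GL_i(g) P(g | p)`` with Hardy-Weinberg
    ``P(g|p)`` via EM.  Returns ``(p_hat, loglik_fn, flat)`` where
    ``loglik_fn(p)`` evaluates the profile log-likelihood (used by the SNP
    likelihood-ratio filter) and ``flat`` indicates an uninformative site.
    """
    ll = np.asarray(site_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[1] != 3:
        raise ValueError("site_loglik must have shape (n_samples, 3)")
    if missing is not None:
        ll = ll[~np.asarray(missing, bool)]
    if ll.shape[0] == 0:
        raise ValueError("no non-missing samples at site")
    ll = ll - ll.max(axis=1, keepdims=True)

    def loglik_fn(p: float) -> float:
        return float(logsumexp(ll + _hwe_log_prior(p), axis=1).sum())

    # flat if likelihoods carry no allele information
    flat = bool(np.ptp(ll, axis=1).max() < 1e-12)

    p = 0.2
    prev = loglik_fn(p)
    n_ind = ll.shape[0]
    g = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        w = ll + _hwe_log_prior(p)
        w = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        p_new = float((w @ g).sum() / (2.0 * n_ind))
        cur = loglik_fn(p_new)
        if abs(p_new - p) < tol:
            p = p_new
            break
        p, prev = p_new, cur
    return p, loglik_fn, flat


def allele_count_likelihoods(
    site_loglik: np.ndarray,
    missing: np.ndarray | None = None,
) -> np.ndarray:
    """Likelihood of each total minor/alt allele count 0..2N at one site.

    Dynamic program over individuals: convolving the per-individual vectors
    ``GL_i(g) * C(2, g)`` gives, for each total count j, the sum over
    genotype configurations weighted by their hypergeometric composition
    probability (after division by ``C(2N, j)``).  Missing individuals
    contribute a flat likelihood.  The returned vector is rescaled to a
    maximum of 1.
    """
    ll = np.asarray(site_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[1] != 3:
        raise ValueError("site_loglik must have shape (n_samples, 3)")
    if missing is not None:
        ll = np.where(np.asarray(missing, bool)[:, None], 0.0, ll)
    n = ll.shape[0]
    if n < 1:
        raise ValueError("need at least one diploid")
    lin = np.exp(ll - ll.max(axis=1, keepdims=True))
    z = np.array([1.0])
    weights = lin * np.array([1.0, 2.0, 1.0])  # C(2, g)
    for i in range(n):
        z = np.convolve(z, weights[i])
    j = np.arange(2 * n + 1)
    log_choose = gammaln(2 * n + 1) - gammaln(j + 1) - gammaln(2 * n - j + 1)
    out = z / np.exp(log_choose)
    m = out.max()
    if m <= 0:
        raise ValueError("degenerate allele-count likelihood (all zero)")
    return out / m


def _fold(sac: np.ndarray) -> np.ndarray:
    """Fold a 0..2N count-likelihood vector into minor-allele classes 0..N.

    The central class c = N is kept unhalved (it maps to itself).
    """
    two_n = sac.shape[-1] - 1
    n = two_n // 2
    if two_n % 2 != 0:
        raise ValueError("folding requires an even number of chromosomes")
    folded = sac[..., : n + 1].copy()
    folded[..., :n] += sac[..., :n:-1]
    return folded


def folded_sfs_em(
    site_likelihoods: Sequence[np.ndarray] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    population: str = "",
) -> FoldedSFS:
    """EM estimate of the folded SFS from per-site allele-count likelihoods.

    Treats the folded class proportions as mixture weights shared across
    sites; the log-likelihood is non-decreasing over iterations.
    """
    sacs = np.asarray(site_likelihoods, dtype=float)
    if sacs.ndim != 2:
        raise ValueError("site_likelihoods must be (n_sites, 2N+1)")
    if sacs.shape[0] < 1:
        raise ValueError("need at least one site")
    folded = _fold(sacs)  # (S, N+1)
    n_classes = folded.shape[1]
    eta = np.full(n_classes, 1.0 / n_classes)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        joint = folded * eta  # (S, N+1)
        site_tot = joint.sum(axis=1, keepdims=True)
        trace.append(float(np.log(site_tot).sum()))
        post = joint / site_tot
        eta_new = post.mean(axis=0)
        if np.abs(eta_new - eta).max() < tol:
            eta = eta_new
            converged = True
            break
        eta = eta_new
    final_ll = float(np.log((folded * eta).sum(axis=1)).sum())
    return FoldedSFS(
        population=population,
        proportions=eta / eta.sum(),
        n_chromosomes=sacs.shape[1] - 1,
        log_likelihood=final_ll,
        n_iterations=it,
        converged=converged,
        ll_trace=trace,
    )


def pi_from_sfs(
    site_likelihoods: Sequence[np.ndarray] | np.ndarray,
    sfs: FoldedSFS,
    total_positions: int,
    population: str = "",
    mu: float | None = DEFAULT_MU,
) -> DiversityEstimate:
    """Nucleotide diversity from per-site count posteriors under an SFS prior.

    Each site contributes ``sum_c P(c | site) * c (2N - c) / C(2N, 2)``; the
    heterozygosity weight is symmetric under c <-> 2N - c, so it is well
    defined on folded classes.
    """
    sacs = np.asarray(site_likelihoods, dtype=float)
    folded = _fold(sacs)
    two_n = sfs.n_chromosomes
    if folded.shape[1] != two_n // 2 + 1:
        raise ValueError("site likelihoods and SFS disagree on sample size")
    joint = folded * sfs.proportions
    post = joint / joint.sum(axis=1, keepdims=True)
    c = np.arange(two_n // 2 + 1, dtype=float)
    weight = c * (two_n - c) / (two_n * (two_n - 1) / 2.0)
    per_site = post @ weight
    if total_positions < sacs.shape[0]:
        raise ValueError("total_positions must cover all evaluated sites")
    pi = float(per_site.sum() / total_positions)
    # count sites whose posterior puts most mass off the monomorphic class
    S = int((post[:, 0] < 0.5).sum())
    return DiversityEstimate(
        population=population,
        pi_per_site=pi,
        S=S,
        total_positions=total_positions,
        method="GL-SFS",
        mu=mu,
        ne=None if mu is None else ne_from_pi(pi, mu),
    )


def pi_gl(
    tensor: GenotypeLikelihoodTensor,
    popmap: PopulationMap,
    population: str,
    total_positions: int,
    mu: float | None = DEFAULT_MU,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[DiversityEstimate, FoldedSFS]:
    """Full GL-track chain for one population: count DP -> SFS EM -> pi."""
    members = [s for s in popmap.samples_in(population) if s in tensor.samples]
    if not members:
        raise ValueError(f"population {population!r} has no samples in the tensor")
    sub = tensor.take_samples(members)
    sacs = np.stack(
        [
            allele_count_likelihoods(sub.loglik[:, j], sub.missing[:, j])
            for j in range(sub.n_sites)
        ]
    )
    sfs = folded_sfs_em(sacs, tol=tol, max_iter=max_iter, population=population)
    est = pi_from_sfs(sacs, sfs, total_positions, population=population, mu=mu)
    return est, sfs
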