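"""Pairwise population differentiation and island-model migration inversion.

Provides Weir & Cockerham's (1984) per-site theta from genotype counts, a
Reynolds-style A/B (between / total variance) decomposition from sample
allele frequencies with weighted (ratio of sums) and unweighted (mean of
ratios) averaging, absolute divergence d_XY, and the inversion of the
island-model expectation E[F_ST] = 1 / (1 + 4 Ne m) to a migration rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "FstComponents",
    "PairwiseStats",
    "MigrationEstimate",
    "genotype_counts",
    "weir_cockerham_fst",
    "reynolds_fst",
    "reynolds_fst_multi",
    "global_fst",
    "fst_pooled_total",
    "dxy",
    "dxy_from_matrix",
    "migration_from_fst",
    "pairwise_stats",
]


@dataclass
class FstComponents:
    """Per-site between-population (A) and total (B) variance components."""

    A: np.ndarray
    B: np.ndarray

    @property
    def weighted_fst(self) -> float:
        """Ratio of sums, sum(A)/sum(B)."""
        tot = float(np.nansum(self.B))
        if tot <= 0:
            raise ValueError("sum of total-variance components is not positive")
        return float(np.nansum(self.A) / tot)

    @property
    def unweighted_fst(self) -> float:
        """Mean of per-site ratios A/B over sites with B > 0."""
        ok = np.isfinite(self.B) & (self.B > 0)
        if not ok.any():
            raise ValueError("no sites with positive total variance")
        return float(np.mean(self.A[ok] / self.B[ok]))


@dataclass
class PairwiseStats:
    pop_a: str
    pop_b: str
    weighted_fst: float
    unweighted_fst: float
    wc_fst: float
    dxy: float
    n_sites: int


@dataclass
class MigrationEstimate:
    """Scaled migrants per generation M = 4 Ne m inverted from F_ST."""

    pop_a: str
    pop_b: str
    fst: float
    M: float
    m: float | None
    ne_used: float | None
    defined: bool


def genotype_counts(
    matrix: GenotypeMatrix, popmap: PopulationMap, population: str
) -> np.ndarray:
    """Per-site (hom_ref, het, hom_alt) counts for one population, (3, n_sites)."""
    members = [s for s in popmap.samples_in(population) if s in matrix.samples]
    if not members:
        raise ValueError(f"population {population!r} has no samples in the matrix")
    sub = matrix.take_samples(members)
    return np.stack(
        [(sub.dosage == g).sum(axis=0) for g in (0, 1, 2)]
    ).astype(np.int64)


def _wc_components(
    ns: np.ndarray, ps: np.ndarray, hs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) a, b, c for r populations, vectorised.

    ``ns``, ``ps`` and ``hs`` have shape (r, n_sites): diploid sample
    sizes, sample alt frequencies and heterozygote fractions.  Sites where
    any population has fewer than 2 individuals yield NaN components.
    """
    ns = np.asarray(ns, float)
    ps = np.asarray(ps, float)
    hs = np.asarray(hs, float)
    r = ns.shape[0]
    valid = (ns >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = ns.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (ns**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (ns * ps).sum(axis=0) / n_tot
        s2 = (ns * (ps - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (ns * hs).sum(axis=0) / n_tot
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def weir_cockerham_fst(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> tuple[np.ndarray, float]:
    """Per-site Weir-Cockerham theta-hat and its unweighted mean.

    Uses the two-population variance components from genotype counts,
    including the observed-heterozygosity term; the summary is the mean of
    per-site theta over sites where a + b + c is non-zero.  Negative
    per-site values are retained (the estimator is unbiased around zero for
    undifferentiated populations).
    """
    counts_a = genotype_counts(matrix, popmap, pop_a)
    counts_b = genotype_counts(matrix, popmap, pop_b)
    if counts_a.sum() == 0 or counts_b.sum() == 0:
        raise ValueError("a population has no genotype data at any site")
    n1 = counts_a.sum(axis=0)
    n2 = counts_b.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (counts_a[1] + 2 * counts_a[2]) / (2.0 * n1)
        p2 = (counts_b[1] + 2 * counts_b[2]) / (2.0 * n2)
        h1 = counts_a[1] / n1
        h2 = counts_b[1] / n2
    a, b, c = _wc_components(
        np.stack([n1, n2]), np.stack([p1, p2]), np.stack([h1, h2])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    ok = np.isfinite(theta)
    if not ok.any():
        raise ValueError("no informative sites for Weir-Cockerham F_ST")
    return theta, float(np.mean(theta[ok]))


def reynolds_fst(
    n1: np.ndarray,
    p1: np.ndarray,
    n2: np.ndarray,
    p2: np.ndarray,
) -> FstComponents:
    """Reynolds-style A/B components from sample sizes and frequencies only.

    Applies the same moment algebra as the coancestry estimator with the
    observed heterozygosity replaced by its unbiased within-population
    Hardy-Weinberg estimate ``2 p q * 2n/(2n - 1)``, so only per-population
    sample sizes (diploids) and allele frequencies are needed.  A is the
    between-population component, B the total (A + within).
    """
    return reynolds_fst_multi([n1, n2], [p1, p2])


def reynolds_fst_multi(
    ns: list[np.ndarray] | np.ndarray, ps: list[np.ndarray] | np.ndarray
) -> FstComponents:
    """A/B components over r >= 2 populations from sizes and frequencies.

    The all-populations ("global") version of :func:`reynolds_fst`; with d
    demes exchanging migrants at rate m its weighted ratio of sums tracks
    the finite-island expectation 1/(1 + 4 Ne m (d/(d-1))**2), whereas the
    two-population version tracks the pairwise 1/(1 + 4 Ne m d/(d-1)).
    """
    ns = np.asarray(ns, float)
    ps = np.asarray(ps, float)
    if ns.shape[0] < 2:
        raise ValueError("need at least two populations")
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = 2.0 * ps * (1.0 - ps) * (2.0 * ns) / (2.0 * ns - 1.0)
    a, b, c = _wc_components(ns, ps, hs)
    return FstComponents(A=a, B=a + b + c)


def global_fst(matrix: GenotypeMatrix, popmap: PopulationMap) -> FstComponents:
    """Reynolds-style A/B components over every population in the map."""
    ns, ps = [], []
    for pop in popmap.populations:
        counts = genotype_counts(matrix, popmap, pop)
        n = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (counts[1] + 2 * counts[2]) / (2.0 * n)
        ns.append(n)
        ps.append(p)
    return reynolds_fst_multi(ns, ps)


def fst_pooled_total(matrix: GenotypeMatrix, popmap: PopulationMap) -> FstComponents:
    """Pooled-total F_ST (G_ST form): A = H_T - H_S, B = H_T per site.

    Within-deme gene diversity H_S is the unbiased expected heterozygosity
    averaged over demes with equal weight; the pooled-total diversity H_T
    uses the equal-weight mean frequency with the Nei-Chesser small-sample
    correction.  With d demes exchanging migrants at rate m the weighted
    ratio of sums tracks 1/(1 + 4 Ne m (d/(d-1))**2) — the pooled-total
    finite-island expectation — whereas the between-deme theta estimators
    (:func:`weir_cockerham_fst`, :func:`reynolds_fst`) track
    1/(1 + 4 Ne m d/(d-1)).
    """
    ns, ps = [], []
    for pop in popmap.populations:
        counts = genotype_counts(matrix, popmap, pop)
        n = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (counts[1] + 2 * counts[2]) / (2.0 * n)
        ns.append(n)
        ps.append(p)
    ns = np.asarray(ns, float)
    ps = np.asarray(ps, float)
    d = ns.shape[0]
    valid = (ns >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = (2.0 * ps * (1.0 - ps) * (2.0 * ns) / (2.0 * ns - 1.0)).mean(axis=0)
        pbar = ps.mean(axis=0)
        n_harm = 1.0 / (1.0 / ns).mean(axis=0)
        ht = 2.0 * pbar * (1.0 - pbar) + hs / (2.0 * n_harm * d)
    a = np.where(valid, ht - hs, np.nan)
    b = np.where(valid, ht, np.nan)
    return FstComponents(A=a, B=b)


def dxy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Absolute divergence d_XY = x(1-y) + (1-x)y per site, and its mean.

    ``x`` and ``y`` are alt-allele frequencies in the two populations; the
    statistic is the probability that one allele drawn from each population
    differs, and is invariant to swapping REF/ALT labels in both
    populations jointly.
    """
    x = np.asarray(x, float); y = np.asarray(y, float)
    if ((x < 0) | (x > 1)).any() or ((y < 0) | (y > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    per_site = x * (1.0 - y) + (1.0 - x) * y
    return per_site, float(np.nanmean(per_site))


def dxy_from_matrix(
    matrix: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str
) -> tuple[np.ndarray, float]:
    """d_XY from hard-call allele frequencies at jointly observed sites."""
    ca = genotype_counts(matrix, popmap, pop_a)
    cb = genotype_counts(matrix, popmap, pop_b)
    na, nb = ca.sum(axis=0), cb.sum(axis=0)
    ok = (na > 0) & (nb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(ok, (ca[1] + 2 * ca[2]) / (2.0 * na), np.nan)
        y = np.where(ok, (cb[1] + 2 * cb[2]) / (2.0 * nb), np.nan)
    per_site = x * (1.0 - y) + (1.0 - x) * y
    return per_site, float(np.nanmean(per_site))


def migration_from_fst(
    fst: float, ne: float | None = None, pop_a: str = "", pop_b: str = ""
) -> MigrationEstimate:
    """Invert E[F_ST] = 1/(1 + 4 Ne m): M = 1/F_ST - 1, m = M/(4 Ne).

    F_ST <= 0 corresponds to effectively unbounded migration and is
    returned flagged undefined rather than as a number.
    """
    if fst > 1.0:
        raise ValueError("F_ST cannot exceed 1")
    if fst <= 0.0:
        return MigrationEstimate(pop_a, pop_b, fst, np.inf, None, ne, defined=False)
    M = 1.0 / fst - 1.0
    m = None
    if ne is not None:
        if ne <= 0:
            raise ValueError("Ne must be positive")
        m = M / (4.0 * ne)
    return MigrationEstimate(pop_a, pop_b, fst, M, m, ne, defined=True)


def pairwise_stats(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Differentiation summary for every population pair.

    Columns mirror the usual pairwise table: Reynolds-style weighted and
    unweighted F_ST, Weir-Cockerham theta (mean over sites), mean d_XY and
    the number of jointly informative sites.
    """
    popmap.validate_against(matrix.samples)
    pops = popmap.populations
    if pairs is None:
        pairs = list(combinations(pops, 2))
    rows = []
    for pop_a, pop_b in pairs:
        ca = genotype_counts(matrix, popmap, pop_a)
        cb = genotype_counts(matrix, popmap, pop_b)
        na, nb = ca.sum(axis=0), cb.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = (ca[1] + 2 * ca[2]) / (2.0 * na)
            pb = (cb[1] + 2 * cb[2]) / (2.0 * nb)
        comp = reynolds_fst(na, pa, nb, pb)
        _, wc = weir_cockerham_fst(matrix, popmap, pop_a, pop_b)
        _, dxy_mean = dxy_from_matrix(matrix, popmap, pop_a, pop_b)
        n_sites = int(np.isfinite(comp.B).sum())
        rows.append(
            PairwiseStats(
                pop_a, pop_b,
                comp.weighted_fst, comp.unweighted_fst, wc, dxy_mean, n_sites,
            )
        )
    return pd.DataFrame(
        [
            {
                "pop_a": r.pop_a,
                "pop_b": r.pop_b,
                "weighted_fst": r.weighted_fst,
                "unweighted_fst": r.unweighted_fst,
                "wc_fst": r.wc_fst,
                "dxy": r.dxy,
                "n_sites": r.n_sites,
            }
            for r in rows
        ]
    )
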