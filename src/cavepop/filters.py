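"""Site filtering for the two genotyping tracks.

Hard-call track (VCFtools-style): per-genotype depth floor, then ordered
site rules — biallelic SNV, call rate, singleton, heterozygote-excess exact
test (a paralog screen).  GL track (Angsd-style): sample representation,
SNP likelihood-ratio test, heterozygote-majority paralog screen, and a
minor-allele-frequency floor.  Each removed site is attributed to the first
rule it fails, so report counts always sum to the input site count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .containers import MISSING, GenotypeLikelihoodTensor, GenotypeMatrix
from .diversity import gl_allele_frequency

__all__ = [
    "HardFilterParams",
    "GLFilterParams",
    "FilterReport",
    "filter_hard_calls",
    "hwe_excess_het_p",
    "filter_gl_sites",
]


@dataclass(frozen=True)
class HardFilterParams:
    """Thresholds for the hard-call filter track."""

    min_genotype_depth: int = 2
    require_biallelic_snv: bool = True
    drop_singletons: bool = True
    min_call_rate: float = 0.75
    excess_het_p_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.min_genotype_depth < 0:
            raise ValueError("min_genotype_depth must be >= 0")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0.0 <= self.excess_het_p_threshold <= 1.0:
            raise ValueError("excess_het_p_threshold must be in [0, 1]")


@dataclass(frozen=True)
class GLFilterParams:
    """Thresholds for the genotype-likelihood filter track."""

    min_sample_fraction: float = 0.8
    snp_p_threshold: float = 0.05
    het_majority_threshold: float = 0.5
    min_maf_for_ibs: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_sample_fraction", "het_majority_threshold", "min_maf_for_ibs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.snp_p_threshold <= 1.0:
            raise ValueError("snp_p_threshold must be in [0, 1]")


@dataclass
class FilterReport:
    """Ordered per-rule removal counts; conserves the input site count."""

    n_input_sites: int
    removed: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input_sites != self.n_retained + sum(self.removed.values()):
            raise ValueError("filter report does not conserve site counts")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input_sites)]
        rows += [(f"removed_{rule}", n) for rule, n in self.removed.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["stage", "n_sites"])


def hwe_excess_het_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact Hardy-Weinberg test toward heterozygote excess.

    Conditions on the observed allele counts and returns the probability of
    observing at least as many heterozygotes under HWE (the exact-test tail
    used to screen lumped paralogs).  Monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_ref, n_alt)
    if n_minor == 0:
        return 1.0

    # P(h | n, n_minor) ∝ 2^h * n! / (n_AA! n_Aa! n_aa!), h same parity as n_minor
    def logw(h: int) -> float:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            h * math.log(2.0)
            + gammaln(n + 1)
            - gammaln(hom_major + 1)
            - gammaln(h + 1)
            - gammaln(hom_minor + 1)
        )

    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    logws = np.array([logw(int(h)) for h in hs])
    logz = logsumexp(logws)
    tail = logws[hs >= n_het]
    return float(min(1.0, math.exp(logsumexp(tail) - logz)))


def filter_hard_calls(
    matrix: GenotypeMatrix, params: HardFilterParams = HardFilterParams()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the hard-call filters; returns the filtered matrix and report.

    Genotypes below the depth floor are set missing before any site rule
    runs; site rules then apply in the fixed order biallelic-SNV ->
    call-rate -> singleton -> excess-het, with removal attributed to the
    first failing rule.
    """
    dosage = matrix.dosage.copy()
    depth = matrix.depth
    if params.min_genotype_depth > 0:
        if depth is None:
            raise ValueError(
                "min_genotype_depth is active but the matrix carries no depth; "
                "set min_genotype_depth=0 for depth-free input"
            )
        low = (depth == MISSING) | (depth < params.min_genotype_depth)
        dosage[low] = MISSING

    work = GenotypeMatrix(matrix.samples, matrix.sites, dosage, depth)
    obs = work.dosage != MISSING
    n_obs = obs.sum(axis=0)
    n_sites = work.n_sites

    keep = np.ones(n_sites, dtype=bool)
    removed: dict[str, int] = {}

    def apply_rule(name: str, fails: np.ndarray) -> None:
        newly = keep & fails
        removed[name] = int(newly.sum())
        keep[newly] = False

    if params.require_biallelic_snv:
        s = work.sites
        apply_rule(
            "biallelic_snv",
            (s["is_multiallelic"] | s["is_indel"] | s["is_bad_ploidy"]).to_numpy(),
        )
    else:
        removed["biallelic_snv"] = 0

    apply_rule("call_rate", n_obs < params.min_call_rate * work.n_samples)

    alt = np.where(obs, work.dosage, 0).sum(axis=0)
    n_seq = 2 * n_obs
    minor = np.minimum(alt, n_seq - alt)
    if params.drop_singletons:
        apply_rule("singleton", minor == 1)
    else:
        removed["singleton"] = 0

    het = (work.dosage == 1).sum(axis=0)
    hom_alt = (work.dosage == 2).sum(axis=0)
    hom_ref = n_obs - het - hom_alt
    excess = np.zeros(n_sites, dtype=bool)
    for j in np.flatnonzero(keep & (n_obs > 0) & (minor > 0)):
        p = hwe_excess_het_p(int(hom_ref[j]), int(het[j]), int(hom_alt[j]))
        excess[j] = p < params.excess_het_p_threshold
    apply_rule("excess_het", excess)

    out = work.take_sites(keep)
    report = FilterReport(n_input_sites=n_sites, removed=removed, n_retained=out.n_sites)
    return out, report


def filter_gl_sites(
    tensor: GenotypeLikelihoodTensor, params: GLFilterParams = GLFilterParams()
) -> tuple[GenotypeLikelihoodTensor, FilterReport]:
    """Apply the GL-track filters; returns the filtered tensor and report.

    Rule order: sample representation -> SNP likelihood-ratio test (null =
    monomorphic at the major allele, chi-square df 1) -> heterozygote
    majority (posterior-expected het fraction under a uniform genotype
    prior) -> minor-allele-frequency floor on the MLE frequency.
    """
    n_samples, n_sites = tensor.n_samples, tensor.n_sites
    keep = np.ones(n_sites, dtype=bool)
    removed: dict[str, int] = {}

    def apply_rule(name: str, fails: np.ndarray) -> None:
        newly = keep & fails
        removed[name] = int(newly.sum())
        keep[newly] = False

    frac = 1.0 - tensor.missing.mean(axis=0)
    apply_rule("representation", frac < params.min_sample_fraction)

    maf = np.zeros(n_sites)
    snp_fail = np.zeros(n_sites, dtype=bool)
    het_fail = np.zeros(n_sites, dtype=bool)
    for j in np.flatnonzero(keep):
        ll = tensor.loglik[:, j]
        miss = tensor.missing[:, j]
        p_hat, loglik_fn, flat = gl_allele_frequency(ll, miss)
        maf[j] = min(p_hat, 1.0 - p_hat)
        if flat:
            snp_fail[j] = True
            continue
        lrt = 2.0 * (loglik_fn(p_hat) - max(loglik_fn(0.0), loglik_fn(1.0)))
        p_val = stats.chi2.sf(max(lrt, 0.0), df=1)
        snp_fail[j] = p_val >= params.snp_p_threshold
        # posterior P(het) per sample, uniform genotype prior
        sub = ll[~miss]
        w = np.exp(sub - sub.max(axis=1, keepdims=True))
        het_fail[j] = float((w[:, 1] / w.sum(axis=1)).mean()) > params.het_majority_threshold
    apply_rule("snp_lrt", snp_fail)
    apply_rule("het_majority", het_fail)
    apply_rule("maf", maf < params.min_maf_for_ibs)

    out = tensor.take_sites(keep)
    report = FilterReport(n_input_sites=n_sites, removed=removed, n_retained=out.n_sites)
    return out, report
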