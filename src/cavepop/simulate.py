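"""Forward island-model simulator for RAD-seq style genotype data.

The generator emulates the product of a reduced-representation (2bRAD-like)
survey of several isolated demes: thousands of unlinked biallelic SNPs, a
handful of demes connected by symmetric migration, and an optional
read-observation layer that turns true genotypes into depths and genotype
likelihoods.

Model
-----
Each site evolves independently.  Per generation, deme ``i`` first mixes
its allele frequency toward the mean of the *other* demes,

    p_i' = (1 - m) * p_i + m * mean_{j != i}(p_j),

and then drifts by binomial resampling of ``2 * deme_size`` allele copies.
With ``d`` demes this equilibrates near the finite-island expectations

    pooled-total F_ST ~= 1 / (1 + 4 Ne m (d/(d-1))**2)
    between-deme theta ~= 1 / (1 + 4 Ne m d/(d-1))

(the first is what G_ST-style pooled-heterozygosity estimators measure,
the second what Weir-Cockerham/Reynolds-style estimators measure; both
collapse to 1/(1 + 4 Ne m) as d grows).

There is no mutation: polymorphism enters through the ancestral frequency
draw, and sites may fix during the run (they are retained; downstream
filters handle them).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats

from .containers import MISSING, GenotypeLikelihoodTensor, GenotypeMatrix, PopulationMap, make_site_table

__all__ = [
    "IslandModelConfig",
    "ReadObservationConfig",
    "SimulatedDataset",
    "simulate_island_model",
    "simulate_reads",
    "read_likelihoods",
]


@dataclass(frozen=True)
class IslandModelConfig:
    """Parameters of the forward island-model simulation.

    ``migration_rate`` is the per-generation probability that an allele copy
    is a migrant; ``deme_size`` is the diploid effective size Ne per deme, so
    the scaled migration rate of the classical formula is ``4 * deme_size *
    migration_rate``.
    """

    n_demes: int = 4
    deme_size: int = 500
    migration_rate: float = 5e-4
    n_sites: int = 5000
    n_generations: int = 2000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    sample_sizes: tuple[int, ...] | int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_demes < 2:
            raise ValueError(f"n_demes must be >= 2, got {self.n_demes}")
        if self.deme_size < 1:
            raise ValueError(f"deme_size must be >= 1, got {self.deme_size}")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError(f"migration_rate must be in [0, 1], got {self.migration_rate}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.n_generations < 0:
            raise ValueError(f"n_generations must be >= 0, got {self.n_generations}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"ancestral_freq_range must satisfy 0 <= lo <= hi <= 1, got {self.ancestral_freq_range}")
        for n in self.sample_sizes_tuple():
            if not 1 <= n <= self.deme_size:
                raise ValueError(
                    f"sample_sizes entries must be in [1, deme_size={self.deme_size}], got {n}"
                )

    def sample_sizes_tuple(self) -> tuple[int, ...]:
        if isinstance(self.sample_sizes, int):
            return (self.sample_sizes,) * self.n_demes
        if len(self.sample_sizes) != self.n_demes:
            raise ValueError("sample_sizes must have one entry per deme")
        return tuple(self.sample_sizes)

    @property
    def scaled_migration(self) -> float:
        """4*Ne*m, the scaled number of migrants per generation."""
        return 4.0 * self.deme_size * self.migration_rate


@dataclass(frozen=True)
class ReadObservationConfig:
    """Read-observation layer: Poisson depth and per-base error rate."""

    mean_depth: float = 8.0
    error_rate: float = 0.005
    missing_if_zero_depth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError(f"mean_depth must be >= 0, got {self.mean_depth}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")


@dataclass
class SimulatedDataset:
    """Simulation output: true deme frequencies plus sampled genotypes."""

    true_freqs: np.ndarray  # (n_demes, n_sites)
    genotypes: GenotypeMatrix
    population_map: PopulationMap
    config: IslandModelConfig

    def deme_names(self) -> list[str]:
        return self.population_map.populations


def _deme_names(n: int) -> list[str]:
    return [f"deme{i}" for i in range(n)]


def simulate_island_model(config: IslandModelConfig) -> SimulatedDataset:
    """Run Wright-Fisher drift with symmetric migration and sample genotypes.

    Returns the final per-deme allele frequencies together with Hardy-Weinberg
    genotype draws for ``sample_sizes`` individuals per deme.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    d, m_sites = config.n_demes, config.n_sites
    two_n = 2 * config.deme_size
    lo, hi = config.ancestral_freq_range
    p = np.broadcast_to(rng.uniform(lo, hi, m_sites), (d, m_sites)).copy()

    m = config.migration_rate
    for _ in range(config.n_generations):
        if m > 0.0 and d > 1:
            p_others = (p.sum(axis=0, keepdims=True) - p) / (d - 1)
            p = (1.0 - m) * p + m * p_others
        p = rng.binomial(two_n, p) / float(two_n)

    sizes = config.sample_sizes_tuple()
    dosage_blocks = []
    sample_names: list[str] = []
    mapping: dict[str, str] = {}
    for i, (name, n_i) in enumerate(zip(_deme_names(d), sizes)):
        dosage_blocks.append(rng.binomial(2, p[i], size=(n_i, m_sites)).astype(np.int8))
        for k in range(n_i):
            s = f"{name}_ind{k}"
            sample_names.append(s)
            mapping[s] = name

    sites = make_site_table(
        chrom=["sim1"] * m_sites,
        pos=np.arange(1, m_sites + 1),
        ref=["A"] * m_sites,
        alt=["C"] * m_sites,
    )
    genotypes = GenotypeMatrix(samples=sample_names, sites=sites, dosage=np.vstack(dosage_blocks))
    return SimulatedDataset(
        true_freqs=p,
        genotypes=genotypes,
        population_map=PopulationMap(mapping),
        config=config,
    )


def read_likelihoods(
    depth: np.ndarray | int, alt_reads: np.ndarray | int, error_rate: float
) -> np.ndarray:
    """Log-likelihood of each genotype given alt/total read counts.

    ``L(g) = Binom(alt_reads; depth, p_alt(g))`` with ``p_alt`` = e, 1/2,
    1 - e for g = 0, 1, 2.  The binomial coefficient is retained, so the
    triples are genuine read-count likelihoods (it cancels in ratios).
    Output shape is ``shape(depth) + (3,)``.
    """
    e = float(error_rate)
    p_alt = (e, 0.5, 1.0 - e)
    return np.stack(
        [stats.binom.logpmf(alt_reads, depth, p) for p in p_alt], axis=-1
    )


def simulate_reads(
    dataset: SimulatedDataset | GenotypeMatrix,
    config: ReadObservationConfig,
) -> tuple[GenotypeLikelihoodTensor, np.ndarray]:
    """Overlay Poisson read depths on true genotypes and compute likelihoods.

    For true dosage ``g`` the probability a read reports the alt base is
    ``e``, ``1/2`` and ``1 - e`` for g = 0, 1, 2.  The alt-read count is
    Binomial(depth, p_alt(g)), and the likelihood of each candidate genotype
    is the same binomial evaluated at its own p_alt.  Zero-depth entries are
    flagged missing.

    Returns the likelihood tensor (natural-log values) and the depth matrix.
    """
    matrix = dataset.genotypes if isinstance(dataset, SimulatedDataset) else dataset
    if matrix.missing_mask().any():
        raise ValueError("simulate_reads requires fully observed true genotypes")
    rng = np.random.default_rng(config.seed)
    g = matrix.dosage.astype(np.int64)
    depth = rng.poisson(config.mean_depth, size=g.shape)

    e = config.error_rate
    p_alt = np.array([e, 0.5, 1.0 - e])
    alt_reads = rng.binomial(depth, p_alt[g])
    loglik = read_likelihoods(depth, alt_reads, e)
    missing = depth == 0 if config.missing_if_zero_depth else np.zeros(g.shape, bool)
    loglik[missing] = 0.0
    return (
        GenotypeLikelihoodTensor(
            samples=matrix.samples, sites=matrix.sites, loglik=loglik, missing=missing
        ),
        depth.astype(np.int32),
    )
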