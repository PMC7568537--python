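"""Shared fixtures and tiny builders used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from cavepop import (
    GenotypeLikelihoodTensor,
    GenotypeMatrix,
    PopulationMap,
    make_site_table,
)
from cavepop.simulate import read_likelihoods


def build_matrix(dosage, depth=None, samples=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain nested list (use -1 for missing)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    sites = make_site_table(
        chrom=["chr1"] * m,
        pos=np.arange(1, m + 1),
        ref=["A"] * m,
        alt=["C"] * m,
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, depth=depth)


def confident_gl(dosage, depth: int = 60, error_rate: float = 0.001) -> GenotypeLikelihoodTensor:
    """Likelihood tensor whose triples point firmly at the given dosages.

    Builds the read counts a noiseless sequencer would produce for each
    genotype (0, depth/2, depth alt reads) and evaluates the binomial
    read-count likelihoods; -1 dosage entries become missing.
    """
    dosage = np.asarray(dosage, dtype=int)
    n, m = dosage.shape
    missing = dosage < 0
    g = np.where(missing, 0, dosage)
    alt = np.select([g == 0, g == 1, g == 2], [0, depth // 2, depth])
    ll = read_likelihoods(np.full((n, m), depth), alt, error_rate)
    ll[missing] = 0.0
    samples = [f"s{i}" for i in range(n)]
    sites = make_site_table(
        chrom=["chr1"] * m, pos=np.arange(1, m + 1), ref=["A"] * m, alt=["C"] * m
    )
    return GenotypeLikelihoodTensor(samples=samples, sites=sites, loglik=ll, missing=missing)


@pytest.fixture
def two_pop_matrix() -> tuple[GenotypeMatrix, PopulationMap]:
    """Ten diploids in two populations with a gradient of differentiation."""
    rng = np.random.default_rng(7)
    pa = rng.uniform(0.1, 0.9, 40)
    pb = np.clip(pa + rng.normal(0, 0.3, 40), 0.0, 1.0)
    dos = np.vstack(
        [rng.binomial(2, pa, size=(5, 40)), rng.binomial(2, pb, size=(5, 40))]
    ).astype(np.int8)
    matrix = build_matrix(dos)
    popmap = PopulationMap(
        {f"s{i}": ("popA" if i < 5 else "popB") for i in range(10)}
    )
    return matrix, popmap
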