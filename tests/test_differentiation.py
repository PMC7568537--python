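"""F_ST estimators against independent transcriptions of the published
component formulas, d_XY algebra, and migration-rate inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavepop import (
    PopulationMap,
    dxy,
    dxy_from_matrix,
    migration_from_fst,
    pairwise_stats,
    reynolds_fst,
    weir_cockerham_fst,
)
from cavepop.datasets import pairwise_fst_table

from conftest import build_matrix


def wc_theta_oracle(counts1, counts2):
    """Scalar transcription of the Weir & Cockerham (1984) two-population
    variance components (a, b, c) for one biallelic site, written
    independently of the vectorised implementation."""
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def reynolds_oracle(n1, p1, n2, p2):
    """Frequency-only A/B: the same components with the heterozygote term
    replaced by its unbiased Hardy-Weinberg estimate."""
    h1 = 2 * p1 * (1 - p1) * (2 * n1) / (2 * n1 - 1)
    h2 = 2 * p2 * (1 - p2) * (2 * n2) / (2 * n2 - 1)
    a, b, c = _abc_from_freqs(n1, p1, h1, n2, p2, h2)
    return a, a + b + c


def _abc_from_freqs(n1, p1, h1, n2, p2, h2):
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def _matrix_from_counts(counts1, counts2):
    dosages = []
    for counts in (counts1, counts2):
        dosages += [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
    dos = np.array(dosages, dtype=np.int8).reshape(-1, 1)
    matrix = build_matrix(dos)
    n1 = sum(counts1)
    popmap = PopulationMap(
        {s: ("A" if i < n1 else "B") for i, s in enumerate(matrix.samples)}
    )
    return matrix, popmap


def test_fixed_difference_gives_theta_one():
    matrix, popmap = _matrix_from_counts((4, 0, 0), (0, 0, 5))
    theta, mean = weir_cockerham_fst(matrix, popmap, "A", "B")
    assert mean == pytest.approx(1.0, abs=1e-12)


def test_identical_genotype_counts_give_nonpositive_theta():
    matrix, popmap = _matrix_from_counts((5, 3, 2), (5, 3, 2))
    _, mean = weir_cockerham_fst(matrix, popmap, "A", "B")
    assert mean <= 0.0


def test_theta_matches_component_oracle_on_worked_example():
    counts1, counts2 = (5, 3, 2), (1, 4, 5)
    matrix, popmap = _matrix_from_counts(counts1, counts2)
    _, mean = weir_cockerham_fst(matrix, popmap, "A", "B")
    a, b, c = wc_theta_oracle(counts1, counts2)
    assert mean == pytest.approx(a / (a + b + c), abs=1e-12)


def test_theta_matches_oracle_on_random_sites():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n1, n2 = rng.integers(2, 11, size=2)
        c1 = rng.multinomial(n1, rng.dirichlet(np.ones(3)))
        c2 = rng.multinomial(n2, rng.dirichlet(np.ones(3)))
        a, b, c = wc_theta_oracle(tuple(c1), tuple(c2))
        denom = a + b + c
        matrix, popmap = _matrix_from_counts(tuple(c1), tuple(c2))
        if denom == 0:
            # site uninformative for the ratio; the estimator refuses it
            with pytest.raises(ValueError):
                weir_cockerham_fst(matrix, popmap, "A", "B")
            continue
        theta, _ = weir_cockerham_fst(matrix, popmap, "A", "B")
        assert abs(theta[0] - a / denom) < 1e-10


def test_reynolds_trivial_limits():
    n = np.full(20, 8.0)
    fixed = reynolds_fst(n, np.ones(20), n, np.zeros(20))
    assert fixed.weighted_fst == pytest.approx(1.0, abs=1e-12)
    assert fixed.unweighted_fst == pytest.approx(1.0, abs=1e-12)

    p = np.linspace(0.2, 0.8, 20)
    same = reynolds_fst(n, p, n, p)
    assert same.weighted_fst < 0.02
    assert (same.A <= 1e-12).all()


def test_reynolds_sums_match_oracle_with_monomorphic_background():
    """10 divergent sites of varying strength over 990 monomorphic-in-both
    sites: monomorphic sites contribute zero to both component sums, and
    weighted/unweighted summaries equal the brute-force oracle sums."""
    rng = np.random.default_rng(3)
    n = np.full(1000, 10.0)
    p1 = np.zeros(1000)
    p2 = np.zeros(1000)
    p1[:10] = rng.uniform(0.0, 0.3, 10)
    p2[:10] = rng.uniform(0.6, 1.0, 10)
    comp = reynolds_fst(n, p1, n, p2)
    assert np.allclose(comp.A[10:], 0.0) and np.allclose(comp.B[10:], 0.0)
    a_sum = b_sum = 0.0
    ratios = []
    for j in range(1000):
        a, tot = reynolds_oracle(10.0, p1[j], 10.0, p2[j])
        a_sum += a
        b_sum += tot
        if tot > 0:
            ratios.append(a / tot)
    assert comp.weighted_fst == pytest.approx(a_sum / b_sum, abs=1e-12)
    assert comp.unweighted_fst == pytest.approx(np.mean(ratios), abs=1e-12)
    assert len(ratios) == 10  # unweighted mean runs over variable sites only


def test_dxy_closed_forms():
    per, mean = dxy([1.0, 0.5], [0.0, 0.5])
    assert per[0] == 1.0
    assert per[1] == 0.5
    assert mean == pytest.approx(0.75)


@settings(deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1))
def test_dxy_symmetry_and_relabel_invariance(x, y):
    per, _ = dxy([x], [y])
    swapped, _ = dxy([1 - x], [1 - y])
    assert per[0] == pytest.approx(swapped[0], abs=1e-12)
    same_freq, _ = dxy([x], [x])
    assert same_freq[0] == pytest.approx(2 * x * (1 - x), abs=1e-12)


def test_dxy_from_matrix_uses_population_frequencies():
    matrix, popmap = _matrix_from_counts((4, 0, 0), (0, 0, 5))
    per, mean = dxy_from_matrix(matrix, popmap, "A", "B")
    assert mean == pytest.approx(1.0)


def test_migration_inversion_arithmetic():
    assert migration_from_fst(0.5).M == pytest.approx(1.0)
    assert migration_from_fst(0.2).M == pytest.approx(4.0)
    est = migration_from_fst(0.5, ne=1e5)
    assert est.m == pytest.approx(2.5e-6)
    undefined = migration_from_fst(0.0)
    assert not undefined.defined


def test_migration_strictly_decreasing_in_fst():
    fsts = np.linspace(0.05, 1.0, 30)
    Ms = [migration_from_fst(f).M for f in fsts]
    assert np.all(np.diff(Ms) < 0)


def test_scaled_migration_means_match_published_summaries():
    table = pairwise_fst_table()
    for species, printed_mean in (("N. barri", 2.19), ("P. hatchi", 3.71)):
        weir = table.loc[table["species"] == species, "wc_fst"]
        mean_M = np.mean([migration_from_fst(f).M for f in weir])
        assert mean_M == pytest.approx(printed_mean, rel=0.01)


def test_pairwise_stats_table_schema(two_pop_matrix):
    matrix, popmap = two_pop_matrix
    df = pairwise_stats(matrix, popmap)
    assert list(df.columns) == [
        "pop_a", "pop_b", "weighted_fst", "unweighted_fst", "wc_fst", "dxy", "n_sites",
    ]
    assert len(df) == 1
    assert 0 <= df["dxy"].iloc[0] <= 1
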