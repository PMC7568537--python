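"""Nucleotide diversity: hard-call arithmetic, GL machinery against
exhaustive enumeration, folding invariances, and Ne scaling."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from cavepop import (
    PopulationMap,
    allele_count_likelihoods,
    expected_het,
    folded_sfs_em,
    gl_allele_frequency,
    ne_from_pi,
    pi_from_sfs,
    pi_gl,
    pi_hard,
)
from cavepop.datasets import diversity_table
from cavepop.simulate import (
    IslandModelConfig,
    ReadObservationConfig,
    simulate_island_model,
    simulate_reads,
)

from conftest import build_matrix, confident_gl


def test_expected_het_closed_forms():
    assert expected_het([6, 0]) == 0.0
    # n = 10 sequences at p = 0.5: (10/9) * 0.5
    assert expected_het([5, 5]) == pytest.approx(10 / 9 * 0.5, abs=1e-12)
    assert expected_het([3, 7]) == expected_het([7, 3])  # relabel invariance
    with pytest.raises(ValueError):
        expected_het([1, 0])


def test_pi_hard_arithmetic_example():
    # two segregating sites with h = 0.5 and 0.25 over 1000 positions
    # h = n/(n-1) (1 - p^2 - q^2): 4 diploids (n=8), crafted frequencies
    dos = np.array([
        [1, 1], [1, 0], [0, 0], [0, 0],
    ], dtype=np.int8)
    matrix = build_matrix(dos)
    popmap = PopulationMap({f"s{i}": "pop" for i in range(4)})
    est = pi_hard(matrix, popmap, "pop", total_positions=1000, mu=None)
    h0 = 8 / 7 * (1 - (2 / 8) ** 2 - (6 / 8) ** 2)
    h1 = 8 / 7 * (1 - (1 / 8) ** 2 - (7 / 8) ** 2)
    assert est.S == 2
    assert est.pi_per_site == pytest.approx((h0 + h1) / 1000, rel=1e-12)


def test_pi_hard_no_segregating_sites_is_zero():
    matrix = build_matrix(np.zeros((4, 5), dtype=np.int8))
    popmap = PopulationMap({f"s{i}": "pop" for i in range(4)})
    est = pi_hard(matrix, popmap, "pop", total_positions=100)
    assert est.pi_per_site == 0.0 and est.S == 0


def test_pi_hard_unbiased_for_true_heterozygosity():
    """Genotypes drawn at HWE from known frequencies: the n/(n-1)-corrected
    estimator is unbiased for sum(2 p q)/total, so the replicate mean must
    land close to the truth."""
    rng = np.random.default_rng(10)
    freqs = rng.uniform(0.05, 0.95, 400)
    truth = (2 * freqs * (1 - freqs)).sum() / 2000
    popmap = PopulationMap({f"s{i}": "pop" for i in range(8)})
    ests = []
    for _ in range(30):
        dos = rng.binomial(2, freqs, size=(8, 400)).astype(np.int8)
        est = pi_hard(build_matrix(dos), popmap, "pop", total_positions=2000, mu=None)
        ests.append(est.pi_per_site)
    assert np.mean(ests) == pytest.approx(truth, rel=0.03)


def test_ne_from_pi_reproduces_published_scaling():
    # published rows: pi = 3.3e-4 -> 2.9e4 and pi = 1.8e-3 -> 1.6e5
    assert ne_from_pi(3.3e-4, 2.8e-9) == pytest.approx(2.9e4, rel=0.02)
    assert ne_from_pi(1.8e-3, 2.8e-9) == pytest.approx(1.6e5, rel=0.02)
    assert ne_from_pi(0.0) == 0.0
    with pytest.raises(ValueError):
        ne_from_pi(1e-3, mu=0.0)


def test_gl_allele_frequency_limits():
    hom_ref = confident_gl(np.zeros((8, 1), dtype=int), depth=100)
    p, _, flat = gl_allele_frequency(hom_ref.loglik[:, 0])
    assert p < 1e-3 and not flat

    half = confident_gl(np.array([[0]] * 5 + [[2]] * 5), depth=100)
    p, _, _ = gl_allele_frequency(half.loglik[:, 0])
    assert p == pytest.approx(0.5, abs=1e-6)


def test_gl_allele_frequency_flat_likelihood_flagged():
    flat_ll = np.zeros((10, 3))
    p, loglik_fn, flat = gl_allele_frequency(flat_ll)
    assert flat
    grid = [loglik_fn(x) for x in np.linspace(0.01, 0.99, 9)]
    assert np.ptp(grid) < 1e-12


def brute_force_count_likelihood(site_loglik):
    """Exhaustive enumeration over all 3^N genotype configurations with
    hypergeometric composition weights."""
    lin = np.exp(site_loglik - site_loglik.max(axis=1, keepdims=True))
    n = lin.shape[0]
    out = np.zeros(2 * n + 1)
    for config in itertools.product((0, 1, 2), repeat=n):
        j = sum(config)
        w = np.prod([lin[i, g] * comb(2, g) for i, g in enumerate(config)])
        out[j] += w / comb(2 * n, j)
    return out / out.max()


def test_count_likelihood_concentrates_correctly():
    hom = confident_gl(np.zeros((3, 1), dtype=int), depth=100)
    sac = allele_count_likelihoods(hom.loglik[:, 0])
    assert sac.argmax() == 0 and sac[1:].max() < 1e-6

    one_het = confident_gl(np.array([[1], [0], [0]]), depth=100)
    sac = allele_count_likelihoods(one_het.loglik[:, 0])
    assert sac.argmax() == 1


@pytest.mark.parametrize("n_diploids", [1, 2, 3, 4])
def test_count_likelihood_dp_equals_enumeration(n_diploids):
    rng = np.random.default_rng(n_diploids)
    ll = np.log(rng.uniform(0.01, 1.0, size=(n_diploids, 3)))
    got = allele_count_likelihoods(ll)
    want = brute_force_count_likelihood(ll)
    assert np.abs(got - want).max() < 1e-10


def test_count_likelihood_missing_individual_is_flat():
    ll = np.log(np.random.default_rng(0).uniform(0.01, 1, size=(3, 3)))
    miss = np.array([False, True, False])
    got = allele_count_likelihoods(ll, miss)
    ll_flat = ll.copy()
    ll_flat[1] = 0.0
    assert np.allclose(got, allele_count_likelihoods(ll_flat))


def test_folded_sfs_em_monomorphic_and_monotone():
    hom = confident_gl(np.zeros((5, 40), dtype=int), depth=100)
    sacs = np.stack([
        allele_count_likelihoods(hom.loglik[:, j]) for j in range(40)
    ])
    sfs = folded_sfs_em(sacs)
    assert sfs.proportions[0] > 0.999
    assert np.all(np.diff(sfs.ll_trace) >= -1e-9)


def test_folded_sfs_matches_hard_histogram_at_high_depth():
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, 300), size=(5, 300))
    tensor = confident_gl(dos, depth=100)
    sacs = np.stack([
        allele_count_likelihoods(tensor.loglik[:, j]) for j in range(300)
    ])
    sfs = folded_sfs_em(sacs)
    counts = dos.sum(axis=0)
    folded_counts = np.minimum(counts, 10 - counts)
    hist = np.bincount(folded_counts, minlength=6) / 300
    assert np.abs(sfs.proportions - hist).max() < 1 / 300 + 1e-6


def test_pi_from_sfs_single_site_arithmetic():
    # posterior mass at c = 5 with 2N = 10: contribution 5*5/45
    sac = np.zeros((1, 11))
    sac[0, 5] = 1.0
    sfs = folded_sfs_em(sac)
    est = pi_from_sfs(sac, sfs, total_positions=1)
    assert est.pi_per_site == pytest.approx(25 / 45, rel=1e-9)


def test_pi_invariant_to_allele_relabeling():
    rng = np.random.default_rng(4)
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, 100), size=(6, 100))
    t1 = confident_gl(dos, depth=60)
    t2 = confident_gl(2 - dos, depth=60)  # swap REF/ALT everywhere
    pm = PopulationMap({f"s{i}": "pop" for i in range(6)})
    e1, _ = pi_gl(t1, pm, "pop", 500)
    e2, _ = pi_gl(t2, pm, "pop", 500)
    assert e1.pi_per_site == pytest.approx(e2.pi_per_site, rel=1e-9)

    m1 = pi_hard(build_matrix(dos), pm, "pop", 500, mu=None)
    m2 = pi_hard(build_matrix(2 - dos), pm, "pop", 500, mu=None)
    assert m1.pi_per_site == pytest.approx(m2.pi_per_site, rel=1e-12)


def test_gl_pi_matches_hard_pi_at_high_depth():
    ds = simulate_island_model(IslandModelConfig(
        n_demes=2, deme_size=100, migration_rate=0.01, n_sites=800,
        n_generations=200, sample_sizes=10, seed=21,
    ))
    tensor, _ = simulate_reads(ds, ReadObservationConfig(mean_depth=100, error_rate=0.001, seed=3))
    pm = ds.population_map
    hard = pi_hard(ds.genotypes, pm, "deme0", 4000, mu=None)
    gl, _ = pi_gl(tensor, pm, "deme0", 4000, mu=None)
    assert gl.pi_per_site == pytest.approx(hard.pi_per_site, rel=0.02)


def test_pi_hard_monotone_in_segregating_sites():
    pm = PopulationMap({f"s{i}": "pop" for i in range(6)})
    base = np.zeros((6, 50), dtype=np.int8)
    pis = []
    for n_seg in (5, 15, 30):
        dos = base.copy()
        dos[0, :n_seg] = 1
        dos[1, :n_seg] = 1
        est = pi_hard(build_matrix(dos), pm, "pop", 500, mu=None)
        pis.append(est.pi_per_site)
    assert pis[0] < pis[1] < pis[2]
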