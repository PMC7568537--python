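"""Filter tracks: rule semantics, exact HWE excess-het test, report accounting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavepop import (
    GLFilterParams,
    HardFilterParams,
    MISSING,
    filter_gl_sites,
    filter_hard_calls,
    hwe_excess_het_p,
)

from conftest import build_matrix, confident_gl


def enumeration_excess_het_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Independent oracle: enumerate allele placements into genotype slots.

    Conditional on the allele counts, every distinct placement of the minor
    alleles among the 2n ordered allele slots is equally likely under HWE;
    the heterozygote count of a placement is the number of diploid slots
    holding exactly one minor allele.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    hits = total = 0
    for positions in itertools.combinations(range(2 * n), n_minor):
        minor = np.zeros(2 * n, dtype=int)
        minor[list(positions)] = 1
        hets = int(np.sum(minor[0::2] != minor[1::2]))
        total += 1
        if hets >= n_het:
            hits += 1
    return hits / total


def test_monomorphic_site_has_p_one():
    assert hwe_excess_het_p(5, 0, 0) == 1.0
    assert hwe_excess_het_p(0, 0, 3) == 1.0


def test_two_diploid_example_matches_enumeration():
    # 2 hets among 2 diploids with 2 minor alleles: arrangements weight 2:4
    assert hwe_excess_het_p(0, 2, 0) == pytest.approx(2 / 3, abs=1e-12)
    assert hwe_excess_het_p(0, 2, 0) == pytest.approx(
        enumeration_excess_het_p(0, 2, 0), abs=1e-12
    )


def test_more_heterozygotes_gives_smaller_tail_probability():
    assert hwe_excess_het_p(2, 6, 2) < hwe_excess_het_p(4, 2, 4)


def test_exact_test_matches_enumeration_small_samples():
    for n in range(1, 6):
        for n_het in range(n + 1):
            for n_hom_alt in range(n - n_het + 1):
                n_hom_ref = n - n_het - n_hom_alt
                got = hwe_excess_het_p(n_hom_ref, n_het, n_hom_alt)
                want = enumeration_excess_het_p(n_hom_ref, n_het, n_hom_alt)
                assert got == pytest.approx(want, abs=1e-10), (
                    n_hom_ref, n_het, n_hom_alt,
                )


@settings(deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
)
def test_exact_test_returns_probability(a, h, b):
    if a + h + b == 0:
        return
    p = hwe_excess_het_p(a, h, b)
    assert 0.0 <= p <= 1.0


def test_singleton_site_removed():
    # minor allele observed exactly once across all non-missing genotypes
    matrix = build_matrix(
        [[0, 0], [0, 1], [0, 0], [1, 1]]  # site0: singleton; site1: count 3
    )
    out, report = filter_hard_calls(
        matrix, HardFilterParams(min_genotype_depth=0, min_call_rate=0.0,
                                 excess_het_p_threshold=0.0)
    )
    assert report.removed["singleton"] == 1
    assert out.n_sites == 1
    assert out.sites["pos"].iloc[0] == 2


def test_call_rate_rule_removes_seventy_percent_site():
    dos = np.zeros((10, 2), dtype=np.int8)
    dos[0, 1] = 1  # keep site 1 polymorphic, full call rate
    dos[7:, 0] = MISSING  # site 0: 7/10 genotyped
    matrix = build_matrix(dos)
    out, report = filter_hard_calls(
        matrix, HardFilterParams(min_genotype_depth=0, min_call_rate=0.75,
                                 drop_singletons=False, excess_het_p_threshold=0.0)
    )
    assert report.removed["call_rate"] == 1
    assert out.sites["pos"].tolist() == [2]


def test_all_het_site_removed_as_excess_heterozygosity():
    dos = np.ones((10, 1), dtype=np.int8)  # 10/10 heterozygotes
    matrix = build_matrix(dos)
    out, report = filter_hard_calls(
        matrix, HardFilterParams(min_genotype_depth=0, drop_singletons=False,
                                 min_call_rate=0.0, excess_het_p_threshold=0.1)
    )
    assert enumeration_excess_het_p(0, 10, 0) < 0.1
    assert report.removed["excess_het"] == 1
    assert out.n_sites == 0


def test_depth_floor_applied_before_site_rules():
    dos = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
    depth = np.array([[1, 9], [9, 9], [9, 9], [9, 9]], dtype=np.int32)
    matrix = build_matrix(dos, depth=depth)
    # site 0 loses s0's het to the depth floor -> minor count 1 -> singleton
    out, report = filter_hard_calls(
        matrix, HardFilterParams(min_genotype_depth=2, min_call_rate=0.0,
                                 excess_het_p_threshold=0.0)
    )
    assert report.removed["singleton"] == 1
    assert out.sites["pos"].tolist() == [2]
    # without the singleton rule the masked genotype persists as missing
    out2, _ = filter_hard_calls(
        matrix, HardFilterParams(min_genotype_depth=2, min_call_rate=0.0,
                                 drop_singletons=False, excess_het_p_threshold=0.0)
    )
    assert out2.dosage[0, 0] == MISSING


def test_depth_rule_without_depth_matrix_is_an_error():
    matrix = build_matrix([[0, 1], [1, 0]])
    with pytest.raises(ValueError, match="depth"):
        filter_hard_calls(matrix, HardFilterParams(min_genotype_depth=2))


def test_hard_filter_report_conserves_counts_and_is_idempotent():
    rng = np.random.default_rng(3)
    dos = rng.integers(0, 3, size=(12, 120)).astype(np.int8)
    dos[rng.random(dos.shape) < 0.3] = MISSING
    matrix = build_matrix(dos)
    params = HardFilterParams(min_genotype_depth=0)
    out, report = filter_hard_calls(matrix, params)
    assert report.n_input_sites == report.n_retained + sum(report.removed.values())
    again, report2 = filter_hard_calls(out, params)
    assert again.n_sites == out.n_sites
    assert sum(report2.removed.values()) == 0
    assert np.array_equal(again.dosage, out.dosage)


def test_gl_representation_rule():
    dos = np.zeros((10, 2), dtype=int)
    dos[0, 1] = 1
    dos[7:, 0] = -1  # site 0 observed in 70% of samples
    tensor = confident_gl(dos)
    out, report = filter_gl_sites(
        tensor, GLFilterParams(min_sample_fraction=0.8, snp_p_threshold=1.0,
                               het_majority_threshold=1.0, min_maf_for_ibs=0.0)
    )
    assert report.removed["representation"] == 1
    assert out.sites["pos"].tolist() == [2]


def test_gl_het_majority_rule_flags_paralog_signature():
    dos = np.ones((8, 1), dtype=int)  # every sample confidently het
    tensor = confident_gl(dos, depth=50)
    out, report = filter_gl_sites(
        tensor, GLFilterParams(min_sample_fraction=0.0, snp_p_threshold=1.0,
                               het_majority_threshold=0.5, min_maf_for_ibs=0.0)
    )
    assert report.removed["het_majority"] == 1
    assert out.n_sites == 0


def test_gl_monomorphic_site_fails_snp_likelihood_ratio_test():
    dos = np.zeros((10, 1), dtype=int)  # confidently hom-ref everywhere
    tensor = confident_gl(dos, depth=80)
    out, report = filter_gl_sites(
        tensor, GLFilterParams(min_sample_fraction=0.0, snp_p_threshold=0.05,
                               het_majority_threshold=1.0, min_maf_for_ibs=0.0)
    )
    assert report.removed["snp_lrt"] == 1
    assert out.n_sites == 0


def test_gl_polymorphic_site_passes_snp_test_and_maf_floor():
    dos = np.array([[0], [0], [1], [1], [2], [2], [0], [1]])
    tensor = confident_gl(dos, depth=80)
    out, report = filter_gl_sites(
        tensor, GLFilterParams(min_sample_fraction=0.5, snp_p_threshold=0.05,
                               het_majority_threshold=0.9, min_maf_for_ibs=0.01)
    )
    assert out.n_sites == 1
    assert sum(report.removed.values()) == 0


def test_gl_filter_report_conserves_and_idempotent():
    rng = np.random.default_rng(5)
    dos = rng.integers(0, 3, size=(10, 60))
    dos[rng.random(dos.shape) < 0.2] = -1
    tensor = confident_gl(dos, depth=30)
    params = GLFilterParams()
    out, report = filter_gl_sites(tensor, params)
    assert report.n_input_sites == report.n_retained + sum(report.removed.values())
    again, report2 = filter_gl_sites(out, params)
    assert sum(report2.removed.values()) == 0
    assert again.n_sites == out.n_sites
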