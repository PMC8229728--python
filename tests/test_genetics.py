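"""Compatibility combinatorics: predicate, enumeration, closed form, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from si_karyosim.genetics import (
    ENUMERATION_CAP,
    EnumerationCapError,
    GeneticsError,
    Locus,
    Mycelium,
    allele_profile,
    compatible_fraction_analytic,
    compatible_fraction_enumerate,
    compatible_fraction_mc,
    compatibility_matrix,
    enumerate_heterokaryons,
    is_compatible,
    percent,
    population_si_survey,
    sibling_cohort,
)

X2 = Locus.uniform("X", 2)
X3 = Locus.uniform("X", 3)


# -- strategies --------------------------------------------------------------

@st.composite
def random_locus(draw, max_k=5, locus_id="X"):
    k = draw(st.integers(1, max_k))
    raw = draw(
        st.lists(st.floats(0.01, 1.0, allow_nan=False), min_size=k, max_size=k)
    )
    total = sum(raw)
    freqs = [r / total for r in raw]
    freqs[-1] = 1.0 - math.fsum(freqs[:-1])
    return Locus(locus_id, tuple(f"A{i+1}" for i in range(k)), tuple(freqs))


@st.composite
def random_loci(draw, max_k=5, max_l=3):
    n = draw(st.integers(1, max_l))
    return [draw(random_locus(max_k=max_k, locus_id=f"L{i}")) for i in range(n)]


# -- validation --------------------------------------------------------------

@pytest.mark.parametrize(
    "alleles,freqs",
    [
        ((), ()),
        (("A1", "A1"), (0.5, 0.5)),
        (("A1", "A2"), (0.6, 0.6)),
        (("A1", "A2"), (-0.1, 1.1)),
        (("A1", "A2"), (1.0,)),
    ],
)
def test_locus_validation_rejects_bad_input(alleles, freqs):
    with pytest.raises(GeneticsError):
        Locus("X", alleles, freqs)


def test_mycelium_stage_is_pure_function_of_karyotype_length():
    assert Mycelium.from_alleles(X2, "A1").stage == "homokaryon"
    assert Mycelium.from_alleles(X2, "A1", "A2").stage == "heterokaryon"
    assert Mycelium.from_alleles(X2, "A1", "A1", "A2").stage == "trikaryon"
    with pytest.raises(GeneticsError):
        Mycelium(())


# -- allele profiles and the compatibility predicate -------------------------

def test_allele_profile_deduplicates():
    het = Mycelium.from_alleles(X2, "A1", "A2")
    hom = Mycelium.from_alleles(X2, "A1")
    tri = Mycelium.from_alleles(X2, "A1", "A1", "A2")
    assert allele_profile(het, X2) == {"A1", "A2"}
    assert allele_profile(hom, X2) == {"A1"}
    assert allele_profile(tri, X2) == {"A1", "A2"}


def test_allele_profile_unknown_locus_errors():
    m = Mycelium.from_alleles(X2, "A1")
    with pytest.raises(GeneticsError):
        allele_profile(m, Locus.uniform("Y", 2))


@pytest.mark.parametrize(
    "a1,a2,b1,b2,expected",
    [
        ("A1", "A2", "A2", "A1", True),   # nuclear order irrelevant
        ("A1", "A1", "A1", "A2", False),  # homozygote vs heterozygote
        ("A1", "A2", "A1", "A3", False),  # common nucleus A1 does not rescue
        ("A1", "A2", "A1", "A2", True),   # self
    ],
)
def test_is_compatible_is_allele_set_equality(a1, a2, b1, b2, expected):
    m1 = Mycelium.from_alleles(X3, a1, a2)
    m2 = Mycelium.from_alleles(X3, b1, b2)
    assert is_compatible(m1, m2, [X3]) is expected
    assert is_compatible(m2, m1, [X3]) is expected  # symmetry


@given(pairs=st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                      min_size=3, max_size=3))
def test_compatibility_is_an_equivalence_relation(pairs):
    ms = [Mycelium.from_alleles(X3, f"A{a+1}", f"A{b+1}") for a, b in pairs]
    for m in ms:
        assert is_compatible(m, m, [X3])
    for m1 in ms:
        for m2 in ms:
            assert is_compatible(m1, m2, [X3]) == is_compatible(m2, m1, [X3])
    a, b, c = ms
    if is_compatible(a, b, [X3]) and is_compatible(b, c, [X3]):
        assert is_compatible(a, c, [X3])


# -- enumeration -------------------------------------------------------------

@pytest.mark.parametrize("k,expected_n", [(1, 1), (2, 4), (3, 9)])
def test_enumeration_cardinality_and_uniform_probability(k, expected_n):
    genos = enumerate_heterokaryons([Locus.uniform("X", k)])
    assert len(genos) == expected_n
    for _, p in genos:
        assert p == pytest.approx(1.0 / expected_n)
    assert math.fsum(p for _, p in genos) == pytest.approx(1.0, abs=1e-12)


def test_enumeration_rejects_empty_locus_list():
    with pytest.raises(GeneticsError):
        enumerate_heterokaryons([])


def test_sibling_cohort_single_locus():
    parent = Mycelium.from_alleles(X2, "A1", "A2")
    cohort = sibling_cohort(parent, [X2])
    assert len(cohort.genotypes) == 4
    assert all(p == pytest.approx(0.25) for p in cohort.probabilities)
    # every sibling allele is parental
    for h1, h2 in cohort.genotypes:
        assert {h1.allele_of("X"), h2.allele_of("X")} <= {"A1", "A2"}


def test_sibling_cohort_homozygous_parent_is_monomorphic():
    parent = Mycelium.from_alleles(X2, "A1", "A1")
    cohort = sibling_cohort(parent, [X2])
    assert len(cohort.genotypes) == 1
    assert cohort.probabilities == [pytest.approx(1.0)]


def test_sibling_cohort_two_unlinked_loci_is_direct_product():
    loci = [Locus.uniform("L1", 2), Locus.uniform("L2", 2)]
    parent = Mycelium(
        (
            _hap(L1="A1", L2="A1"),
            _hap(L1="A2", L2="A2"),
        )
    )
    cohort = sibling_cohort(parent, loci)
    assert len(cohort.genotypes) == 16
    assert all(p == pytest.approx(1 / 16) for p in cohort.probabilities)


def _hap(**alleles):
    from si_karyosim.genetics import Haplotype

    return Haplotype.from_mapping(alleles)


def test_sibling_cohort_requires_heterokaryon_parent():
    with pytest.raises(GeneticsError):
        sibling_cohort(Mycelium.from_alleles(X2, "A1"), [X2])


# -- compatible fractions ----------------------------------------------------

def test_enumerated_fraction_canonical_values():
    assert compatible_fraction_enumerate([X2]).compatible_fraction == pytest.approx(
        0.375, abs=1e-15
    )
    assert compatible_fraction_enumerate([X3]).compatible_fraction == pytest.approx(
        15 / 81, abs=1e-15
    )


def test_enumerated_fraction_skewed_frequencies():
    # brute-force weighted enumeration over the 16 ordered pairs
    L = Locus("X", ("A1", "A2"), (0.9, 0.1))
    assert compatible_fraction_enumerate([L]).compatible_fraction == pytest.approx(
        0.6886, abs=1e-12
    )


@pytest.mark.parametrize("k", range(1, 7))
def test_uniform_closed_form(k):
    L = Locus.uniform("X", k)
    expected = (2 * k - 1) / k**3
    assert compatible_fraction_analytic([L]).compatible_fraction == pytest.approx(
        expected, abs=1e-14
    )
    if k**4 <= ENUMERATION_CAP:
        assert compatible_fraction_enumerate([L]).compatible_fraction == pytest.approx(
            expected, abs=1e-14
        )


@given(loci=random_loci())
def test_analytic_equals_enumeration(loci):
    a = compatible_fraction_analytic(loci).compatible_fraction
    # genotype spaces up to (5*5*5)^2 pairs: raise the pair cap for the oracle
    e = compatible_fraction_enumerate(loci, cap=10**9).compatible_fraction
    assert a == pytest.approx(e, abs=1e-12)


def test_multilocus_fraction_is_product_of_per_locus_fractions():
    loci = [Locus.uniform("L1", 3), Locus.uniform("L2", 3)]
    two = compatible_fraction_enumerate(loci).compatible_fraction
    one = compatible_fraction_enumerate([loci[0]]).compatible_fraction
    assert two == pytest.approx(one**2, abs=1e-12)
    assert 1 - two == pytest.approx(1 - (15 / 81) ** 2, abs=1e-12)


def test_fraction_weakly_decreasing_in_alleles_and_loci():
    fracs_k = [
        compatible_fraction_analytic([Locus.uniform("X", k)]).compatible_fraction
        for k in range(1, 7)
    ]
    assert all(a >= b for a, b in zip(fracs_k, fracs_k[1:]))
    fracs_l = [
        compatible_fraction_analytic(
            [Locus.uniform(f"L{i}", 3) for i in range(n)]
        ).compatible_fraction
        for n in range(1, 4)
    ]
    assert all(a >= b for a, b in zip(fracs_l, fracs_l[1:]))


def test_enumeration_cap_refuses_large_state_space():
    with pytest.raises(EnumerationCapError):
        compatible_fraction_enumerate([Locus.uniform("X", 40)])


# -- Monte Carlo -------------------------------------------------------------

def test_mc_within_four_se_over_many_seeds(biallelic):
    n = 10**5
    for seed in range(20):
        est = compatible_fraction_mc([biallelic], n, seed)
        assert abs(est.estimate - 0.375) <= 4 * est.standard_error


def test_mc_is_deterministic_for_fixed_seed(biallelic):
    a = compatible_fraction_mc([biallelic], 10**4, 42)
    b = compatible_fraction_mc([biallelic], 10**4, 42)
    assert a.estimate == b.estimate


def test_mc_monomorphic_is_exactly_one():
    L = Locus("X", ("A1",), (1.0,))
    assert compatible_fraction_mc([L], 1000, 0).estimate == 1.0


def test_mc_rejects_nonpositive_n():
    with pytest.raises(GeneticsError):
        compatible_fraction_mc([X2], 0, 0)


# -- matrices ----------------------------------------------------------------

def test_matrix_biallelic_pattern(biallelic):
    res = compatibility_matrix([biallelic])
    assert res.labels == ("A1/A1", "A1/A2", "A2/A1", "A2/A2")
    assert res.matrix.sum() == 6
    assert np.array_equal(res.matrix, res.matrix.T)
    assert res.matrix.diagonal().all()


def test_matrix_triallelic_pattern(triallelic):
    res = compatibility_matrix([triallelic])
    assert len(res.labels) == 9
    assert res.matrix.sum() == 15


def test_matrix_monomorphic():
    res = compatibility_matrix([Locus("X", ("A1",), (1.0,))])
    assert res.matrix.shape == (1, 1) and res.matrix[0, 0]


# -- population survey -------------------------------------------------------

def test_survey_false_clonemate_rate_tracks_analytic(triallelic):
    res = population_si_survey([triallelic], n_isolates=200, seed=7)
    se = math.sqrt(0.185 * 0.815 / res.n_nonclonal_pairs)
    # pairs share isolates so are weakly dependent; allow a generous band
    assert abs(res.false_clonemate_rate - 15 / 81) < max(0.05, 8 * se)


def test_survey_single_planted_clone_has_one_group(triallelic):
    res = population_si_survey([triallelic], n_isolates=10, clonal_groups=1, seed=0)
    assert res.n_groups == 1
    assert res.false_clonemate_rate is None
    assert res.matrix.all()


def test_survey_two_loci_rate_near_product(triallelic):
    loci = [Locus.uniform("L1", 3), Locus.uniform("L2", 3)]
    res = population_si_survey(loci, n_isolates=100, seed=3)
    assert abs(res.false_clonemate_rate - (15 / 81) ** 2) < 0.05


# -- percentage reporting ----------------------------------------------------

@pytest.mark.parametrize(
    "fraction,ndigits,expected",
    [
        (0.375, 1, 37.5),
        (15 / 81, 1, 18.5),
        (0.625, 1, 62.5),
        (1 - 0.375**2, 0, 86.0),
        (1 - (15 / 81) ** 2, 0, 97.0),
        (0.005, 0, 1.0),  # half away from zero
    ],
)
def test_percent_rounds_half_away_from_zero(fraction, ndigits, expected):
    assert percent(fraction, ndigits) == expected
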