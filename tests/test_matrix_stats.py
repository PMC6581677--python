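import itertools
import math

import numpy as np
import pytest

from herdnet.matrix_stats import (
    DifferenceMatrix,
    combine_pvalues,
    difference_matrix,
    mantel_test,
    perm_correlation,
    restrict_to_shared,
)
from herdnet.association import AssociationMatrix

from conftest import random_symmetric


# ---------------------------------------------------------------------------
# difference matrices
# ---------------------------------------------------------------------------

def test_identical_ages_give_zero_matrix():
    d = difference_matrix({"a": 4.0, "b": 4.0, "c": 4.0}, "abc", "age")
    assert np.all(d.values == 0)


def test_sex_difference_indicator():
    d = difference_matrix({"a": "F", "b": "F", "c": "M"}, "abc", "sex")
    assert np.array_equal(d.values,
                          [[0, 0, 1], [0, 0, 1], [1, 1, 0]])


def test_rank_differences_are_absolute():
    d = difference_matrix({"a": 1, "b": 2, "c": 4}, "abc", "rank")
    assert d.values[0, 1] == 1 and d.values[1, 2] == 2 and d.values[0, 2] == 3


def test_missing_attribute_errors():
    with pytest.raises(ValueError, match="missing"):
        difference_matrix({"a": 1}, "ab", "age")
    with pytest.raises(ValueError, match="kind"):
        difference_matrix({"a": 1, "b": 2}, "ab", "height")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _upper(m):
    n = m.shape[0]
    return np.array([m[i, j] for i in range(n) for j in range(i + 1, n)])


def brute_force_mantel(X, Y, sided):
    """Exhaustive enumeration oracle, independent of the implementation."""
    n = X.shape[0]
    x = _upper(X)

    def corr(perm):
        Yp = Y[np.ix_(perm, perm)]
        return np.corrcoef(x, _upper(Yp))[0, 1]

    obs = corr(tuple(range(n)))
    null = [corr(p) for p in itertools.permutations(range(n))]
    if sided == "two":
        count = sum(1 for r in null if abs(r) >= abs(obs) - 1e-12)
    elif sided == "one_pos":
        count = sum(1 for r in null if r >= obs - 1e-12)
    else:
        count = sum(1 for r in null if r <= obs + 1e-12)
    return obs, count / len(null)


def test_mantel_self_correlation(rng):
    X = random_symmetric(rng, 9)
    res = mantel_test(X, X, n_perm=199, sided="two", seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 200)


def test_mantel_perfect_anticorrelation(rng):
    X = random_symmetric(rng, 6)
    Y = 10.0 - X
    np.fill_diagonal(Y, 0)
    res = mantel_test(X, Y, sided="two")  # exhaustive at N=6
    assert res.r == pytest.approx(-1.0)


@pytest.mark.parametrize("sided", ["two", "one_pos", "one_neg"])
def test_mantel_exhaustive_matches_enumeration_oracle(rng, sided):
    X = random_symmetric(rng, 4, integer=True)
    Y = random_symmetric(rng, 4, integer=True)
    res = mantel_test(X, Y, sided=sided)
    obs, p = brute_force_mantel(X, Y, sided)
    assert res.exhaustive
    assert res.r == pytest.approx(obs, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)


def test_mantel_is_symmetric_in_its_arguments(rng):
    X = random_symmetric(rng, 5)
    Y = random_symmetric(rng, 5)
    a = mantel_test(X, Y, sided="two")
    b = mantel_test(Y, X, sided="two")
    assert a.r == pytest.approx(b.r, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)   # exhaustive: exact


def test_mantel_agrees_with_scikit_bio(rng):
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    X = random_symmetric(rng, 8)
    Y = random_symmetric(rng, 8)
    ours = mantel_test(X, Y, n_perm=999, sided="two", seed=1)
    r_ref, p_ref, _ = skbio_mantel(DistanceMatrix(X), DistanceMatrix(Y),
                                   permutations=999, alternative="two-sided")
    assert ours.r == pytest.approx(r_ref, abs=1e-12)
    assert ours.p == pytest.approx(p_ref, abs=0.05)  # both stochastic


def test_mantel_requires_explicit_sidedness_and_valid_input(rng):
    X = random_symmetric(rng, 4)
    with pytest.raises(TypeError):
        mantel_test(X, X, 99)          # sided is keyword-only
    with pytest.raises(ValueError, match="sided"):
        mantel_test(X, X, sided="left")
    with pytest.raises(ValueError, match="at least 3"):
        mantel_test(X[:2, :2], X[:2, :2], sided="two")
    with pytest.raises(ValueError, match="constant"):
        mantel_test(np.zeros((4, 4)), X, sided="two")
    with pytest.raises(ValueError, match="mismatch"):
        mantel_test(X, random_symmetric(rng, 5), sided="two")


def test_mantel_accepts_domain_objects(rng):
    members = tuple("abcd")
    A = AssociationMatrix(members, random_symmetric(rng, 4, integer=True))
    D = difference_matrix({"a": 1, "b": 2, "c": 3, "d": 5}, members, "age")
    res = mantel_test(A, D, sided="one_neg")
    assert -1 <= res.r <= 1 and 0 < res.p <= 1


# ---------------------------------------------------------------------------
# restriction
# ---------------------------------------------------------------------------

def test_restrict_identity_and_intersection(rng):
    A = AssociationMatrix(tuple("abcd"), random_symmetric(rng, 4, True))
    B = AssociationMatrix(tuple("bcde"), random_symmetric(rng, 4, True))
    ra, rb = restrict_to_shared(A, B)
    assert ra.members == rb.members == ("b", "c", "d")
    for i, x in enumerate(ra.members):
        for j, y in enumerate(ra.members):
            assert ra.counts[i, j] == A.counts[A.index(x), A.index(y)]
            assert rb.counts[i, j] == B.counts[B.index(x), B.index(y)]
    sa, sb = restrict_to_shared(A, A)
    assert np.array_equal(sa.counts, A.counts)


def test_restrict_commutes_with_reordering(rng):
    A = AssociationMatrix(tuple("abcd"), random_symmetric(rng, 4, True))
    B = AssociationMatrix(tuple("bcde"), random_symmetric(rng, 4, True))
    ra1, _ = restrict_to_shared(A, B)
    ra2, _ = restrict_to_shared(A.reorder(("d", "a", "c", "b")), B)
    assert ra1.members == ra2.members
    assert np.array_equal(ra1.counts, ra2.counts)


def test_restrict_requires_three_shared(rng):
    A = AssociationMatrix(tuple("abcd"), random_symmetric(rng, 4))
    B = AssociationMatrix(tuple("cdef"), random_symmetric(rng, 4))
    with pytest.raises(ValueError, match="shared"):
        restrict_to_shared(A, B)


# ---------------------------------------------------------------------------
# permutation correlation
# ---------------------------------------------------------------------------

def test_perm_correlation_trivial_signs():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    rho, _ = perm_correlation(x, x, sided="two")
    assert rho == pytest.approx(1.0)
    rho, _ = perm_correlation(x, [-v for v in x], sided="two")
    assert rho == pytest.approx(-1.0)


def test_perm_correlation_exhaustive_matches_enumeration():
    import scipy.stats

    x = [1.0, 2.0, 3.0, 4.0]
    y = [2.0, 1.0, 4.0, 3.0]
    rho, p = perm_correlation(x, y, method="spearman", sided="two")
    null = [scipy.stats.spearmanr(x, perm).statistic
            for perm in itertools.permutations(y)]
    expected = sum(1 for r in null if abs(r) >= abs(rho) - 1e-12) / 24
    assert p == pytest.approx(expected, abs=1e-12)


def test_perm_correlation_rejects_constant():
    with pytest.raises(ValueError, match="constant"):
        perm_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0],
                         sided="two")


# ---------------------------------------------------------------------------
# p-value combination
# ---------------------------------------------------------------------------

def test_combine_single_and_degenerate():
    assert combine_pvalues([0.37]) == 0.37
    assert combine_pvalues([1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_combine_fisher_matches_chi_square_tail_oracle():
    # closed form for df = 4: sf(x) = exp(-x/2) * (1 + x/2)
    p1 = p2 = 0.05
    x2 = -2 * (math.log(p1) + math.log(p2))
    assert x2 == pytest.approx(11.98, abs=0.01)
    oracle = math.exp(-x2 / 2) * (1 + x2 / 2)
    assert combine_pvalues([p1, p2]) == pytest.approx(oracle, abs=1e-12)


def test_combine_is_monotone(rng):
    base = [0.2, 0.5, 0.8]
    combined = combine_pvalues(base)
    for k in range(3):
        smaller = list(base)
        smaller[k] /= 2
        assert combine_pvalues(smaller) <= combined


def test_combine_rejects_out_of_range():
    for bad in ([0.0, 0.5], [0.5, 1.5], []):
        with pytest.raises(ValueError):
            combine_pvalues(bad)
    with pytest.raises(ValueError, match="method"):
        combine_pvalues([0.2, 0.3], method="tippett")


def test_stouffer_option_runs():
    p = combine_pvalues([0.05, 0.05], method="stouffer")
    assert 0 < p < 0.05


def test_difference_matrix_invariants():
    with pytest.raises(ValueError, match="symmetric"):
        DifferenceMatrix(("a", "b"), np.array([[0, 1], [2, 0]]), "age")
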