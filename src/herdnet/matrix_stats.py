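"""Matrix-level statistics: attribute-difference matrices, Mantel tests,
matrix restriction across compositions, permutation correlation tests, and
p-value combination.

Dyadic association weights are not independent observations, so homophily
("do similar individuals associate more?") is tested by correlating the
association matrix with an attribute-difference matrix using a Mantel
test: the correlation of the vectorised upper triangles, with a null built
by permuting rows and columns of one matrix simultaneously.  Permutation
p-values follow the +1/+1 rule, p = (#{extreme} + 1) / (n_perm + 1), so
p > 0 always; when N! is small enough the full permutation group is
enumerated instead and the p-value is exact.

Sidedness is always an explicit argument: ``one_neg`` asks whether the
observed correlation is more negative than chance (e.g. association vs.
age difference under homophily), ``one_pos`` the mirror, ``two`` either.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .association import AssociationMatrix

__all__ = [
    "DifferenceMatrix",
    "MantelResult",
    "difference_matrix",
    "mantel_test",
    "restrict_to_shared",
    "perm_correlation",
    "combine_pvalues",
]

#: exhaustive permutation enumeration is used when N! does not exceed this.
EXHAUSTIVE_LIMIT = 5000

SIDES = ("one_neg", "one_pos", "two")


@dataclass(frozen=True)
class DifferenceMatrix:
    """Pairwise attribute differences: |a_i - a_j| for ordinal/numeric
    attributes (age, rank), or the inequality indicator for sex."""

    members: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValueError("difference matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("difference matrix must have zero diagonal")
        if np.any(v < 0):
            raise ValueError("difference matrix must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "members", tuple(self.members))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    sided: str
    exhaustive: bool = False
    seed: int | None = None


def difference_matrix(attributes: dict, members, kind: str) -> DifferenceMatrix:
    """Build the pairwise difference matrix for one attribute.

    ``kind`` is ``"age"`` or ``"rank"`` (absolute numeric difference, e.g.
    0 = same age, 1 = about one year apart) or ``"sex"`` (0 = same sex,
    1 = different sex).
    """
    members = tuple(members)
    missing = [m for m in members if m not in attributes or attributes[m] is None]
    if missing:
        raise ValueError(f"attribute {kind!r} missing for {missing}")
    if kind == "sex":
        vals = [attributes[m] for m in members]
        mat = np.array(
            [[0.0 if a == b else 1.0 for b in vals] for a in vals]
        )
    elif kind in ("age", "rank"):
        vals = np.array([float(attributes[m]) for m in members])
        mat = np.abs(vals[:, None] - vals[None, :])
    else:
        raise ValueError(f"unknown difference kind {kind!r}")
    return DifferenceMatrix(members, mat, kind)


def _as_square(mat) -> np.ndarray:
    if isinstance(mat, AssociationMatrix):
        return mat.counts
    if isinstance(mat, DifferenceMatrix):
        return mat.values
    return np.asarray(mat, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("constant matrix: correlation undefined")
    return float(a @ b) / denom


def mantel_test(X, Y, n_perm: int = 1000, *, sided: str,
                seed: int | None = None,
                exhaustive: bool | None = None) -> MantelResult:
    """Mantel test of matrix correlation with row/column permutations.

    ``r`` is the Pearson correlation of the vectorised upper triangles.
    The null permutes rows and columns of ``Y`` simultaneously; when
    N! <= 5000 the full permutation group is enumerated and ``p`` is exact,
    otherwise ``n_perm`` random permutations are drawn (seeded) and the
    +1/+1 rule applies.  ``exhaustive`` forces one mode or the other
    (None = automatic).  ``sided`` must be given explicitly.
    """
    if sided not in SIDES:
        raise ValueError(f"sided must be one of {SIDES}, got {sided!r}")
    Xm, Ym = _as_square(X), _as_square(Y)
    if Xm.shape != Ym.shape or Xm.shape[0] != Xm.shape[1]:
        raise ValueError(f"matrix shape mismatch: {Xm.shape} vs {Ym.shape}")
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 individuals")
    if not (np.allclose(Xm, Xm.T) and np.allclose(Ym, Ym.T)):
        raise ValueError("Mantel test requires symmetric matrices")
    iu = np.triu_indices(n, k=1)
    x = Xm[iu]
    r_obs = _pearson(x, Ym[iu])

    def r_for(perm) -> float:
        Yp = Ym[np.ix_(perm, perm)]
        return _pearson(x, Yp[iu])

    if exhaustive is None:
        exhaustive = math.factorial(n) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        null = np.array([r_for(list(p)) for p in
                         itertools.permutations(range(n))])
        n_used = len(null)
        count = _count_extreme(null, r_obs, sided)
        p = count / n_used
    else:
        rng = np.random.default_rng(seed)
        null = np.array([r_for(rng.permutation(n)) for _ in range(n_perm)])
        n_used = n_perm
        p = (_count_extreme(null, r_obs, sided) + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_used, sided=sided,
                        exhaustive=exhaustive, seed=seed)


def _count_extreme(null: np.ndarray, obs: float, sided: str) -> int:
    tol = 1e-12  # permutation statistics equal to the observed one count
    if sided == "two":
        return int(np.sum(np.abs(null) >= abs(obs) - tol))
    if sided == "one_pos":
        return int(np.sum(null >= obs - tol))
    return int(np.sum(null <= obs + tol))


def restrict_to_shared(assoc_before: AssociationMatrix,
                       assoc_after: AssociationMatrix
                       ) -> tuple[AssociationMatrix, AssociationMatrix]:
    """Subset two association matrices to their shared members.

    Both are returned in the same (sorted) shared-member order so they can
    be correlated entry-for-entry.  Fewer than 3 shared members is an
    error (a Mantel test would be undefined).
    """
    shared = sorted(set(assoc_before.members) & set(assoc_after.members))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared members; need at least 3"
        )

    def sub(a: AssociationMatrix) -> AssociationMatrix:
        idx = [a.members.index(m) for m in shared]
        return AssociationMatrix(tuple(shared), a.counts[np.ix_(idx, idx)],
                                 a.n_scans_used)

    return sub(assoc_before), sub(assoc_after)


def perm_correlation(x, y, n_perm: int = 1000, method: str = "spearman",
                     *, sided: str = "two", seed: int | None = None,
                     exhaustive: bool | None = None) -> tuple[float, float]:
    """Correlation coefficient with a permutation p-value.

    Shuffles ``y`` to build the null; exhaustive over all n! orderings when
    feasible, else ``n_perm`` seeded draws with the +1/+1 rule.
    """
    if sided not in SIDES:
        raise ValueError(f"sided must be one of {SIDES}, got {sided!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")

    if method == "spearman":
        def coef(yv):
            return float(scipy.stats.spearmanr(x, yv).statistic)
    elif method == "pearson":
        def coef(yv):
            return _pearson(x, yv)
    else:
        raise ValueError(f"unknown method {method!r}")

    obs = coef(y)
    if exhaustive is None:
        exhaustive = math.factorial(n) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        null = np.array([coef(np.array(p)) for p in itertools.permutations(y)])
        p = _count_extreme(null, obs, sided) / len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.array([coef(rng.permutation(y)) for _ in range(n_perm)])
        p = (_count_extreme(null, obs, sided) + 1) / (n_perm + 1)
    return obs, float(p)


def combine_pvalues(p_list, method: str = "fisher") -> float:
    """Combine per-composition p-values into one global p.

    Fisher's method (default): X^2 = -2 * sum(ln p_k) referred to the
    chi-square upper tail with 2k degrees of freedom.  ``"stouffer"`` is
    the inverse-normal alternative.  Inputs must lie in (0, 1]; a p of 0
    (impossible under the +1/+1 rule upstream) is rejected.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return float(p[0])
    if method not in ("fisher", "stouffer"):
        raise ValueError(f"unknown combination method {method!r}")
    res = scipy.stats.combine_pvalues(p, method=method)
    return float(min(res.pvalue, 1.0))
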