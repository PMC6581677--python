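"""Modified David's Score (MDS) dominance ranking from win/loss matrices.

David's score summarises a win/loss matrix into one cardinal dominance
score per individual, combining an unweighted and a weighted sum of its
dyadic win proportions with the analogous loss sums.  The "modified"
variant replaces each raw dyadic win proportion P_ij = w_ij / n_ij with the
chance-corrected index

    D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1)

which shrinks sparse dyads toward 0.5 so that a 1-0 record does not count
as total dominance.  Scores:

    w_i  = sum_j D_ij           (unweighted win sum)
    w2_i = sum_j D_ij * w_j     (wins weighted by opponents' win sums)
    l_i  = sum_j D_ji           (unweighted loss sum)
    l2_i = sum_j D_ji * l_j     (losses weighted by opponents' loss sums)
    DS_i = w_i + w2_i - l_i - l2_i

Dyads that never interacted contribute 0 to every sum (no evidence adds no
score), which preserves the zero-sum property of DS across the group.
Individuals are ranked from highest to lowest DS, rank 1 = most dominant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .herd_data import AgonisticEvent

__all__ = [
    "AgonisticMatrix",
    "DominanceResult",
    "build_agonistic_matrix",
    "compute_mds",
    "rank_correlation_with_latent",
]


@dataclass(frozen=True)
class AgonisticMatrix:
    """Directed win counts: ``wins[i, j]`` = times member i beat member j."""

    members: tuple[str, ...]
    wins: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wins, dtype=float)
        n = len(self.members)
        if w.shape != (n, n):
            raise ValueError(f"wins shape {w.shape} != ({n}, {n})")
        if np.any(w < 0):
            raise ValueError("win counts must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("win matrix must have zero diagonal")
        object.__setattr__(self, "wins", w)
        object.__setattr__(self, "members", tuple(self.members))


def build_agonistic_matrix(events, composition) -> AgonisticMatrix:
    """Sum agonistic events of one composition into a directed win matrix.

    All three behaviour categories (supplant, avoidance, aggression) count
    equally as wins.
    """
    members = tuple(sorted(composition.members))
    pos = {m: i for i, m in enumerate(members)}
    wins = np.zeros((len(members), len(members)))
    for e in events:
        if e.composition_id != composition.id:
            continue
        wins[pos[e.winner], pos[e.loser]] += 1
    return AgonisticMatrix(members, wins)


@dataclass(frozen=True)
class DominanceResult:
    """Per-individual MDS components, scores and ranks.

    ``rank`` maps each member to its dominance rank (1 = highest DS); ties
    in DS are broken by lexicographic id order and listed in ``ties``.
    """

    members: tuple[str, ...]
    P: np.ndarray
    D: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray
    rank: dict[str, int]
    ties: tuple[tuple[str, ...], ...] = ()

    def ds_of(self, member: str) -> float:
        return float(self.ds[self.members.index(member)])


def compute_mds(agonistic: AgonisticMatrix, *, chance_corrected: bool = True
                ) -> DominanceResult:
    """Compute (Modified) David's Scores and dominance ranks.

    ``chance_corrected=False`` uses the plain dyadic proportions P_ij in
    place of D_ij (classic David's score).
    """
    n = len(agonistic.members)
    if n < 2:
        raise ValueError("David's score needs at least 2 individuals")
    wins = agonistic.wins
    n_dyad = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(n_dyad > 0, wins / np.where(n_dyad > 0, n_dyad, 1), 0.0)
    if chance_corrected:
        D = np.where(n_dyad > 0, P - (P - 0.5) / (n_dyad + 1), 0.0)
    else:
        D = P
    np.fill_diagonal(D, 0.0)
    w = D.sum(axis=1)
    l = D.sum(axis=0)
    w2 = D @ w
    l2 = D.T @ l
    ds = w + w2 - l - l2

    order = sorted(range(n), key=lambda i: (-ds[i], agonistic.members[i]))
    rank = {agonistic.members[i]: r + 1 for r, i in enumerate(order)}
    ties = []
    by_score: dict[float, list[str]] = {}
    for i in range(n):
        by_score.setdefault(round(float(ds[i]), 12), []).append(
            agonistic.members[i])
    for grp in by_score.values():
        if len(grp) > 1:
            ties.append(tuple(sorted(grp)))
    return DominanceResult(
        members=agonistic.members, P=P, D=D, w=w, w2=w2, l=l, l2=l2, ds=ds,
        rank=rank, ties=tuple(sorted(ties)),
    )


def rank_correlation_with_latent(result: DominanceResult, latent_order
                                 ) -> float:
    """Spearman correlation between MDS ranks and a supplied latent order.

    ``latent_order`` maps member id -> latent rank (1 = highest).  Used to
    validate hierarchy recovery on synthetic herds with a known ground
    truth.
    """
    if set(latent_order) != set(result.members):
        raise ValueError("latent order must cover exactly the same members")
    est = [result.rank[m] for m in result.members]
    lat = [latent_order[m] for m in result.members]
    rho = scipy.stats.spearmanr(est, lat).statistic
    return float(rho)


def write_dominance_csv(result: DominanceResult, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["id", "w", "w2", "l", "l2", "ds", "rank"])
        for i, m in enumerate(result.members):
            wtr.writerow(
                [m, f"{result.w[i]:.6f}", f"{result.w2[i]:.6f}",
                 f"{result.l[i]:.6f}", f"{result.l2[i]:.6f}",
                 f"{result.ds[i]:.6f}", result.rank[m]]
            )
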