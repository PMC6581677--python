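"""Synthetic herds with known social structure.

No field data ships with the package, so every pipeline stage is exercised
on generated herds whose ground truth is known by construction:

* a roster of individuals with sex, age and a staggered arrival history
  (which determines familiarity);
* a latent linear dominance hierarchy, score = gamma * age + noise, that
  drives agonistic outcomes through a logistic win curve;
* nearest-neighbour scan logs with homophily: the probability that focal i
  names j as nearest neighbour is proportional to

      exp(-beta_age |age_i - age_j| - beta_rank |rank_i - rank_j|
          + beta_sex 1[sex_i = sex_j] + beta_fam 1[i, j familiar])

  where rank is the rank of the latent score (ground truth, not the
  estimated dominance rank — generation and inference stay separable);
* a timeline of compositions in two groups linked by transfers, including
  one enclosure-only change, so transfer bookkeeping has all its cases.

The default scenario mirrors the scale of small managed herds: group
sizes 8-13, 100-900 scans and a few hundred agonistic interactions per
composition.  Scan emission starts after the post-change exclusion window
(scoring begins on day 8 after a transfer), mirroring how the field data
were scored.  All randomness flows from the scenario seed; a fixed seed
reproduces the logs byte for byte.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import scipy.special

from .herd_data import (
    AgonisticEvent,
    BEHAVIOUR_CATEGORIES,
    Composition,
    Individual,
    ScanObservation,
    compute_familiarity,
)

__all__ = [
    "HerdScenario",
    "SyntheticHerd",
    "neighbour_probabilities",
    "generate_timeline",
    "generate_scans",
    "generate_agonistic",
    "generate_herd",
]


@dataclass(frozen=True)
class HerdScenario:
    """Parameters of the data-generating model.

    Homophily coefficients are log-scale weights on neighbour choice
    (positive ``beta_age`` means same-aged animals associate more).  The
    latent dominance score of individual i is ``gamma * age_i + N(0,
    sigma_dominance)``; i beats j with probability
    ``logistic(win_steepness * (score_i - score_j))`` and each dyad
    interacts ``Poisson(interaction_rate * days)`` times per composition.
    """

    seed: int
    n_individuals: int = 20
    sex_proportions: tuple[tuple[str, float], ...] = (
        ("F", 0.7), ("M", 0.15), ("CM", 0.15))
    juvenile_fraction: float = 0.4
    juvenile_age_range: tuple[float, float] = (0.5, 3.0)
    adult_age_range: tuple[float, float] = (3.0, 12.0)
    gamma: float = 1.0
    sigma_dominance: float = 2.0
    beta_age: float = 0.8
    beta_rank: float = 0.15
    beta_sex: float = 0.5
    beta_fam: float = 0.5
    interaction_rate: float = 0.1
    win_steepness: float = 1.0
    scans_range: tuple[int, int] = (100, 900)
    scans_per_day: int = 72
    exclusion_days: int = 7
    composition_length_days: int = 40
    familiarity_threshold_days: float = 90.0
    start_date: dt.date = dt.date(2015, 4, 14)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        total = sum(p for _, p in self.sex_proportions)
        if not np.isclose(total, 1.0):
            raise ValueError("sex proportions must sum to 1")
        if self.n_individuals < 4:
            raise ValueError("need at least 4 individuals")


@dataclass(frozen=True)
class SyntheticHerd:
    """A generated dataset plus its ground truth."""

    scenario: HerdScenario
    individuals: dict[str, Individual]
    compositions: dict[str, Composition]
    scans: list[ScanObservation]
    events: list[AgonisticEvent]
    latent_scores: dict[str, float]
    #: per composition: member id -> latent dominance rank (1 = highest)
    latent_ranks: dict[str, dict[str, int]] = field(default_factory=dict)
    ages: dict[str, dict[str, float]] = field(default_factory=dict)
    familiarity: dict[str, dict[str, int]] = field(default_factory=dict)
    #: per composition: row-normalised neighbour-choice probability matrix
    #: over sorted members (zero diagonal)
    neighbour_probs: dict[str, np.ndarray] = field(default_factory=dict)


def neighbour_probabilities(ages, ranks, sexes, familiar, *, beta_age,
                            beta_rank, beta_sex, beta_fam) -> np.ndarray:
    """Row-normalised neighbour-choice probabilities for one composition.

    ``ages``/``ranks``/``sexes`` are length-N vectors; ``familiar`` is an
    N x N boolean matrix.  Row i holds P(focal i names j), zero diagonal.
    """
    ages = np.asarray(ages, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    sexes = np.asarray(sexes)
    fam = np.asarray(familiar, dtype=float)
    n = len(ages)
    if n < 2:
        raise ValueError("neighbour choice undefined for a singleton group")
    logw = (
        -beta_age * np.abs(ages[:, None] - ages[None, :])
        - beta_rank * np.abs(ranks[:, None] - ranks[None, :])
        + beta_sex * (sexes[:, None] == sexes[None, :])
        + beta_fam * fam
    )
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Timeline: roster, residences, compositions
#
# Default structure (days relative to the study start; L = composition
# length):
#   north: N1 [0, L)   N2 [L, 2L)  -2 animals   N3 [2L, 3L)  +1 animal
#          N4 [3L, 4L) enclosure change only
#   south: S1 [0, L)   S2 [L, 2L)  +2 animals   S3 [2L, 3L)  -1 animal
# ---------------------------------------------------------------------------

def _rng_for(scenario: HerdScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed % (2 ** 31), stream])


def generate_timeline(scenario: HerdScenario
                      ) -> tuple[dict[str, Individual], dict[str, Composition]]:
    """Roster with residence histories, and the composition manifest.

    Residences are written so that familiarity computed from interval
    overlap matches the generator's intent: arrival days are staggered
    between 300 and 10 days before the study starts, so animals arriving
    late are unfamiliar with everyone at the first composition.
    """
    rng = _rng_for(scenario, 0)
    n = scenario.n_individuals
    ids = [f"ind{i:02d}" for i in range(n)]

    sexes_pool = [s for s, _ in scenario.sex_proportions]
    probs = [p for _, p in scenario.sex_proportions]
    sexes = rng.choice(sexes_pool, size=n, p=probs)
    is_juv = rng.random(n) < scenario.juvenile_fraction
    lo_j, hi_j = scenario.juvenile_age_range
    lo_a, hi_a = scenario.adult_age_range
    ages0 = np.where(is_juv, rng.uniform(lo_j, hi_j, n),
                     rng.uniform(lo_a, hi_a, n))
    start = scenario.start_date
    birth_dates = [start - dt.timedelta(days=int(round(a * 365.25)))
                   for a in ages0]
    arrival_days = rng.integers(10, 301, size=n)  # days before study start
    arrivals = []
    for i in range(n):
        arr = start - dt.timedelta(days=int(arrival_days[i]))
        earliest = birth_dates[i] + dt.timedelta(days=1)
        arrivals.append(max(arr, earliest))

    L = scenario.composition_length_days
    n_north = (n + 1) // 2 + 2  # north starts larger, like a nursery group
    members_n1 = set(ids[:n_north])
    members_s1 = set(ids[n_north:])
    moved_out = set(rng.choice(sorted(members_n1), size=2, replace=False))
    members_n2 = members_n1 - moved_out
    members_s2 = members_s1 | moved_out
    moved_back = {str(rng.choice(sorted(members_s2 - members_n1)))}
    members_n3 = members_n2 | moved_back
    members_s3 = members_s2 - moved_back

    def comp(cid, group, members, day0, day1, enclosure_only=False):
        return Composition(
            id=cid, group=group, members=frozenset(members),
            start_date=start + dt.timedelta(days=day0),
            end_date=start + dt.timedelta(days=day1),
            enclosure_change_only=enclosure_only,
        )

    compositions = {
        "N1": comp("N1", "north", members_n1, 0, L),
        "N2": comp("N2", "north", members_n2, L, 2 * L),
        "N3": comp("N3", "north", members_n3, 2 * L, 3 * L),
        "N4": comp("N4", "north", members_n3, 3 * L, 4 * L,
                   enclosure_only=True),
        "S1": comp("S1", "south", members_s1, 0, L),
        "S2": comp("S2", "south", members_s2, L, 2 * L),
        "S3": comp("S3", "south", members_s3, 2 * L, 4 * L),
    }

    # residence histories: group location, switching on transfer days;
    # the whole north group changes enclosure at day 3L
    end_of_study = start + dt.timedelta(days=4 * L)
    individuals = {}
    for i, iid in enumerate(ids):
        segs: list[tuple[str, dt.date, dt.date | None]] = []
        day_l = start + dt.timedelta(days=L)
        day_2l = start + dt.timedelta(days=2 * L)
        day_3l = start + dt.timedelta(days=3 * L)
        if iid in members_n1:
            if iid in moved_out:
                segs = [("north", arrivals[i], day_l),
                        ("south", day_l, end_of_study)]
            else:
                segs = [("north", arrivals[i], day_3l),
                        ("north-b", day_3l, end_of_study)]
        else:
            if iid in moved_back:
                segs = [("south", arrivals[i], day_2l),
                        ("north", day_2l, day_3l),
                        ("north-b", day_3l, end_of_study)]
            else:
                segs = [("south", arrivals[i], end_of_study)]
        individuals[iid] = Individual(
            id=iid, sex=str(sexes[i]), birth_date=birth_dates[i],
            residences=tuple(segs),
        )
    return individuals, compositions


def _latent_scores(scenario: HerdScenario, individuals) -> dict[str, float]:
    rng = _rng_for(scenario, 1)
    scores = {}
    for iid in sorted(individuals):
        age = (scenario.start_date - individuals[iid].birth_date).days / 365.25
        scores[iid] = scenario.gamma * age + rng.normal(0.0,
                                                        scenario.sigma_dominance)
    return scores


def _composition_ground_truth(scenario, individuals, composition, scores):
    members = sorted(composition.members)
    ages = np.array(
        [(composition.start_date - individuals[m].birth_date).days / 365.25
         for m in members]
    )
    s = np.array([scores[m] for m in members])
    order = np.argsort(-s)
    ranks = np.empty(len(members), dtype=int)
    ranks[order] = np.arange(1, len(members) + 1)
    sexes = np.array([individuals[m].sex for m in members])
    fam_counts = compute_familiarity(
        composition, individuals, scenario.familiarity_threshold_days
    )
    fam = np.zeros((len(members), len(members)), dtype=bool)
    from .herd_data import coresidence_days

    for i, a in enumerate(members):
        for j in range(i + 1, len(members)):
            b = members[j]
            days = coresidence_days(individuals[a], individuals[b],
                                    composition.start_date)
            fam[i, j] = fam[j, i] = days > scenario.familiarity_threshold_days
    return members, ages, ranks, sexes, fam, fam_counts


def generate_scans(scenario: HerdScenario, herd_parts=None
                   ) -> list[ScanObservation]:
    """Nearest-neighbour scan log for every composition.

    Each focal independently names one neighbour per scan, drawn from the
    homophily kernel; designations within a scan share a scan index.  Scan
    indices start after the post-change exclusion window (index =
    day * scans_per_day + slot with day >= exclusion_days for compositions
    that follow a change), so the association builder's default window
    drops nothing that was never scored.
    """
    if herd_parts is None:
        individuals, compositions = generate_timeline(scenario)
        scores = _latent_scores(scenario, individuals)
    else:
        individuals, compositions, scores = herd_parts
    rng = _rng_for(scenario, 2)
    scans: list[ScanObservation] = []
    for cid in sorted(compositions):
        composition = compositions[cid]
        members, ages, ranks, sexes, fam, _ = _composition_ground_truth(
            scenario, individuals, composition, scores
        )
        if len(members) < 2:
            raise ValueError(f"composition {cid!r} is a singleton")
        P = neighbour_probabilities(
            ages, ranks, sexes, fam,
            beta_age=scenario.beta_age, beta_rank=scenario.beta_rank,
            beta_sex=scenario.beta_sex, beta_fam=scenario.beta_fam,
        )
        n_scans = int(rng.integers(scenario.scans_range[0],
                                   scenario.scans_range[1] + 1))
        follows_change = cid not in ("N1", "S1")
        day0 = scenario.exclusion_days if follows_change else 0
        base = day0 * scenario.scans_per_day
        cum = np.cumsum(P, axis=1)
        for i, focal in enumerate(members):
            draws = np.searchsorted(cum[i], rng.random(n_scans))
            for s_idx, j in enumerate(draws):
                scans.append(
                    ScanObservation(cid, base + s_idx, focal, members[int(j)])
                )
    return scans


def generate_agonistic(scenario: HerdScenario, herd_parts=None
                       ) -> list[AgonisticEvent]:
    """Agonistic event log driven by the latent hierarchy.

    Each dyad interacts Poisson(rate * days) times per composition and the
    higher-scoring animal wins each bout with logistic probability; event
    dates fall after the exclusion window.
    """
    if herd_parts is None:
        individuals, compositions = generate_timeline(scenario)
        scores = _latent_scores(scenario, individuals)
    else:
        individuals, compositions, scores = herd_parts
    rng = _rng_for(scenario, 3)
    events: list[AgonisticEvent] = []
    for cid in sorted(compositions):
        composition = compositions[cid]
        members = sorted(composition.members)
        follows_change = cid not in ("N1", "S1")
        first = composition.start_date + dt.timedelta(
            days=scenario.exclusion_days + 1 if follows_change else 0)
        days = (composition.end_date - first).days
        if days <= 0:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                n_int = int(rng.poisson(scenario.interaction_rate * days))
                if n_int == 0:
                    continue
                diff = scores[a] - scores[b]
                p_a = float(scipy.special.expit(scenario.win_steepness * diff))
                wins_a = int(rng.binomial(n_int, p_a))
                for k in range(n_int):
                    winner, loser = (a, b) if k < wins_a else (b, a)
                    date = first + dt.timedelta(days=int(rng.integers(0, days)))
                    behaviour = BEHAVIOUR_CATEGORIES[
                        int(rng.integers(0, len(BEHAVIOUR_CATEGORIES)))]
                    events.append(
                        AgonisticEvent(cid, date, winner, loser, behaviour)
                    )
    return events


def generate_herd(scenario: HerdScenario) -> SyntheticHerd:
    """Generate the full dataset plus ground truth in one pass."""
    individuals, compositions = generate_timeline(scenario)
    scores = _latent_scores(scenario, individuals)
    parts = (individuals, compositions, scores)
    scans = generate_scans(scenario, parts)
    events = generate_agonistic(scenario, parts)
    latent_ranks, ages_by_comp, fam_by_comp, probs = {}, {}, {}, {}
    for cid in sorted(compositions):
        members, ages, ranks, sexes, fam, fam_counts = \
            _composition_ground_truth(scenario, individuals,
                                      compositions[cid], scores)
        latent_ranks[cid] = dict(zip(members, map(int, ranks)))
        ages_by_comp[cid] = dict(zip(members, map(float, ages)))
        fam_by_comp[cid] = fam_counts
        probs[cid] = neighbour_probabilities(
            ages, ranks, sexes, fam,
            beta_age=scenario.beta_age, beta_rank=scenario.beta_rank,
            beta_sex=scenario.beta_sex, beta_fam=scenario.beta_fam,
        )
    return SyntheticHerd(
        scenario=scenario,
        individuals=individuals,
        compositions=compositions,
        scans=scans,
        events=events,
        latent_scores=scores,
        latent_ranks=latent_ranks,
        ages=ages_by_comp,
        familiarity=fam_by_comp,
        neighbour_probs=probs,
    )
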