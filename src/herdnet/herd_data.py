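"""Domain types, CSV readers/writers, and attribute derivation for herd data.

The raw material of the analysis is four tables: a roster of individuals
(with sex, birth date and residence history), a scan-sampling log of
nearest-neighbour observations, a log of agonistic interactions, and a
manifest of group compositions.  This module defines the in-memory types,
validates referential integrity on load, and derives the individual-level
attributes (age, familiarity) used as predictors downstream.

Conventions
-----------
* Dates are ISO-8601.  Residence intervals are closed on the start date and
  open on the end date.
* Birth dates may be given to year precision; a year-only birth date is
  imputed to July 1 of that year (configurable via ``compute_age``'s
  ``year_imputation_month``/``day`` arguments at parse time).
* Familiarity counts groupmates whose accumulated co-residence (same
  location, overlapping interval) before the composition start strictly
  exceeds the threshold (default 90 days, i.e. "more than 3 months").
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "Individual",
    "Composition",
    "ScanObservation",
    "AgonisticEvent",
    "HerdDataError",
    "ReferentialIntegrityError",
    "load_tables",
    "save_tables",
    "compute_age",
    "compute_familiarity",
    "coresidence_days",
    "parse_date",
]

SEX_CATEGORIES = ("F", "M", "CM")
BEHAVIOUR_CATEGORIES = ("supplant", "avoidance", "aggression")

#: month/day used to impute year-precision birth dates (mid-year).
YEAR_IMPUTATION = (7, 1)


class HerdDataError(ValueError):
    """Malformed or inconsistent herd data."""


class ReferentialIntegrityError(HerdDataError):
    """A row references an id that does not exist where it should."""


def parse_date(text: str, *, context: str = "") -> dt.date:
    """Parse an ISO date, or a bare year imputed to mid-year (July 1)."""
    text = text.strip()
    try:
        if len(text) == 4 and text.isdigit():
            return dt.date(int(text), *YEAR_IMPUTATION)
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise HerdDataError(f"cannot parse date {text!r}{context}") from exc


@dataclass(frozen=True)
class Individual:
    """One animal: id, sex category, birth date and residence history.

    ``residences`` is a chronologically ordered, non-overlapping list of
    ``(location, start, end)`` intervals, closed on start, open on end.
    An open-ended residence uses ``end = None``.
    """

    id: str
    sex: str
    birth_date: dt.date
    residences: tuple[tuple[str, dt.date, dt.date | None], ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEX_CATEGORIES:
            raise HerdDataError(
                f"individual {self.id!r}: sex {self.sex!r} not in {SEX_CATEGORIES}"
            )
        prev_end: dt.date | None = None
        for loc, start, end in self.residences:
            if end is not None and start >= end:
                raise HerdDataError(
                    f"individual {self.id!r}: empty residence interval at {loc}"
                )
            if self.birth_date > start:
                raise HerdDataError(
                    f"individual {self.id!r}: residence at {loc} starts before birth"
                )
            if prev_end is not None and start < prev_end:
                raise HerdDataError(
                    f"individual {self.id!r}: overlapping residence intervals"
                )
            prev_end = end if end is not None else dt.date.max

    def location_on(self, day: dt.date) -> str | None:
        for loc, start, end in self.residences:
            if start <= day and (end is None or day < end):
                return loc
        return None


@dataclass(frozen=True)
class Composition:
    """A stable group membership episode between two composition changes."""

    id: str
    group: str
    members: frozenset[str]
    start_date: dt.date
    end_date: dt.date
    enclosure_change_only: bool = False
    n_scans: int = 0
    n_agonistic: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise HerdDataError(f"composition {self.id!r}: empty member set")
        if self.start_date >= self.end_date:
            raise HerdDataError(f"composition {self.id!r}: start_date >= end_date")
        if self.n_scans < 0:
            raise HerdDataError(f"composition {self.id!r}: negative n_scans")


@dataclass(frozen=True)
class ScanObservation:
    """One nearest-neighbour designation: at scan ``scan_index``, ``focal``'s
    nearest neighbour (closest individual, whatever the distance) was
    ``neighbour``."""

    composition_id: str
    scan_index: int
    focal: str
    neighbour: str

    def __post_init__(self) -> None:
        if self.focal == self.neighbour:
            raise HerdDataError(
                f"scan {self.scan_index} in {self.composition_id!r}: "
                f"focal equals neighbour ({self.focal!r})"
            )


@dataclass(frozen=True)
class AgonisticEvent:
    """One decided agonistic interaction (supplant, avoidance or aggression)."""

    composition_id: str
    date: dt.date
    winner: str
    loser: str
    behaviour: str

    def __post_init__(self) -> None:
        if self.winner == self.loser:
            raise HerdDataError(
                f"agonistic event in {self.composition_id!r}: winner equals loser"
            )
        if self.behaviour not in BEHAVIOUR_CATEGORIES:
            raise HerdDataError(
                f"agonistic event in {self.composition_id!r}: "
                f"behaviour {self.behaviour!r} not in {BEHAVIOUR_CATEGORIES}"
            )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialects (comma-separated, UTF-8, mandatory header row):
#   roster.csv:    id,sex,birth_date,location,res_start,res_end
#                  (one row per residence interval; res_end empty if open)
#   scans.csv:     composition_id,scan_index,focal_id,neighbour_id
#   agonistic.csv: composition_id,date,winner_id,loser_id,behaviour
#   manifest.csv:  composition_id,group,start_date,end_date,
#                  enclosure_change_only,member_ids  (semicolon-joined)
# ---------------------------------------------------------------------------

ROSTER_HEADER = ["id", "sex", "birth_date", "location", "res_start", "res_end"]
SCANS_HEADER = ["composition_id", "scan_index", "focal_id", "neighbour_id"]
AGONISTIC_HEADER = ["composition_id", "date", "winner_id", "loser_id", "behaviour"]
MANIFEST_HEADER = [
    "composition_id",
    "group",
    "start_date",
    "end_date",
    "enclosure_change_only",
    "member_ids",
]


def _read_rows(path, expected_header):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise HerdDataError(f"{path}: empty file, expected header row") from None
        if header != expected_header:
            raise HerdDataError(
                f"{path}: bad header {header!r}, expected {expected_header!r}"
            )
        yield from ((lineno, row) for lineno, row in enumerate(reader, start=2))


def load_tables(roster_path, scans_path, agonistic_path, manifest_path):
    """Load and cross-validate the four input tables.

    Returns ``(individuals, compositions, scans, events)`` where
    ``individuals`` maps id -> :class:`Individual` and ``compositions`` maps
    id -> :class:`Composition` (insertion-ordered).  Every id referenced by a
    scan or agonistic row must exist in the roster and in the named
    composition's member set, else :class:`ReferentialIntegrityError` names
    the offending row.
    """
    # roster: accumulate residence rows per individual
    rows_by_id: dict[str, list] = {}
    attrs: dict[str, tuple[str, dt.date]] = {}
    for lineno, row in _read_rows(roster_path, ROSTER_HEADER):
        iid, sex, birth, loc, start, end = row
        ctx = f" (roster row {lineno})"
        birth_d = parse_date(birth, context=ctx)
        if iid in attrs and attrs[iid] != (sex, birth_d):
            raise HerdDataError(
                f"roster row {lineno}: conflicting sex/birth for {iid!r}"
            )
        attrs[iid] = (sex, birth_d)
        interval = (
            loc,
            parse_date(start, context=ctx),
            parse_date(end, context=ctx) if end.strip() else None,
        )
        rows_by_id.setdefault(iid, []).append(interval)
    individuals = {
        iid: Individual(
            id=iid,
            sex=attrs[iid][0],
            birth_date=attrs[iid][1],
            residences=tuple(sorted(res, key=lambda r: r[1])),
        )
        for iid, res in rows_by_id.items()
    }

    compositions: dict[str, Composition] = {}
    for lineno, row in _read_rows(manifest_path, MANIFEST_HEADER):
        cid, group, start, end, flag, member_ids = row
        if cid in compositions:
            raise HerdDataError(f"manifest row {lineno}: duplicate composition {cid!r}")
        members = frozenset(m for m in member_ids.split(";") if m)
        missing = members - individuals.keys()
        if missing:
            raise ReferentialIntegrityError(
                f"manifest row {lineno}: members {sorted(missing)} not in roster"
            )
        ctx = f" (manifest row {lineno})"
        compositions[cid] = Composition(
            id=cid,
            group=group,
            members=members,
            start_date=parse_date(start, context=ctx),
            end_date=parse_date(end, context=ctx),
            enclosure_change_only=flag.strip().lower() in ("1", "true", "yes"),
        )

    scans: list[ScanObservation] = []
    scan_keys: dict[str, set[int]] = {}
    for lineno, row in _read_rows(scans_path, SCANS_HEADER):
        cid, idx, focal, neighbour = row
        if cid not in compositions:
            raise ReferentialIntegrityError(
                f"scans row {lineno}: unknown composition {cid!r}"
            )
        comp = compositions[cid]
        for who in (focal, neighbour):
            if who not in comp.members:
                raise ReferentialIntegrityError(
                    f"scans row {lineno}: id {who!r} not a member of {cid!r}"
                )
        try:
            idx_i = int(idx)
        except ValueError:
            raise HerdDataError(f"scans row {lineno}: bad scan_index {idx!r}") from None
        scans.append(ScanObservation(cid, idx_i, focal, neighbour))
        scan_keys.setdefault(cid, set()).add(idx_i)

    events: list[AgonisticEvent] = []
    n_events: dict[str, int] = {}
    for lineno, row in _read_rows(agonistic_path, AGONISTIC_HEADER):
        cid, date, winner, loser, behaviour = row
        if cid not in compositions:
            raise ReferentialIntegrityError(
                f"agonistic row {lineno}: unknown composition {cid!r}"
            )
        comp = compositions[cid]
        for who in (winner, loser):
            if who not in comp.members:
                raise ReferentialIntegrityError(
                    f"agonistic row {lineno}: id {who!r} not a member of {cid!r}"
                )
        events.append(
            AgonisticEvent(
                cid,
                parse_date(date, context=f" (agonistic row {lineno})"),
                winner,
                loser,
                behaviour,
            )
        )
        n_events[cid] = n_events.get(cid, 0) + 1

    # recompute per-composition counts; warn on manifest mismatch
    out = {}
    for cid, comp in compositions.items():
        n_scans = len(scan_keys.get(cid, set()))
        n_ago = n_events.get(cid, 0)
        if comp.n_scans not in (0, n_scans):
            warnings.warn(
                f"composition {cid!r}: manifest n_scans {comp.n_scans} != "
                f"recomputed {n_scans}",
                stacklevel=2,
            )
        out[cid] = replace(comp, n_scans=n_scans, n_agonistic=n_ago)
    return individuals, out, scans, events


def _fmt_date(d: dt.date | None) -> str:
    return "" if d is None else d.isoformat()


def save_tables(individuals, compositions, scans, events,
                roster_path, scans_path, agonistic_path, manifest_path) -> None:
    """Write the four tables in canonical form (sorted, ISO dates).

    ``load_tables`` after ``save_tables`` is idempotent: saving the loaded
    objects again produces byte-identical files.
    """
    with open(roster_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ROSTER_HEADER)
        for iid in sorted(individuals):
            ind = individuals[iid]
            for loc, start, end in ind.residences:
                w.writerow(
                    [ind.id, ind.sex, _fmt_date(ind.birth_date), loc,
                     _fmt_date(start), _fmt_date(end)]
                )
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_HEADER)
        for cid in compositions:
            c = compositions[cid]
            w.writerow(
                [c.id, c.group, _fmt_date(c.start_date), _fmt_date(c.end_date),
                 int(c.enclosure_change_only), ";".join(sorted(c.members))]
            )
    with open(scans_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SCANS_HEADER)
        for s in sorted(scans, key=lambda s: (s.composition_id, s.scan_index, s.focal)):
            w.writerow([s.composition_id, s.scan_index, s.focal, s.neighbour])
    with open(agonistic_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(AGONISTIC_HEADER)
        for e in sorted(events, key=lambda e: (e.composition_id, e.date.isoformat(),
                                               e.winner, e.loser)):
            w.writerow([e.composition_id, _fmt_date(e.date), e.winner, e.loser,
                        e.behaviour])


# ---------------------------------------------------------------------------
# Attribute derivation
# ---------------------------------------------------------------------------

def compute_age(individual: Individual, reference_date: dt.date) -> float:
    """Age in years at ``reference_date`` (day count / 365.25).

    Monotone in the reference date; errors if the reference precedes birth.
    """
    if reference_date < individual.birth_date:
        raise HerdDataError(
            f"reference date {reference_date} precedes birth of {individual.id!r}"
        )
    return (reference_date - individual.birth_date).days / 365.25


def coresidence_days(a: Individual, b: Individual, until: dt.date) -> float:
    """Total days A and B spent at the same location before ``until``.

    Sums the overlap of every pair of residence intervals that share a
    location, truncated at ``until``.  Transfers reset accumulation only in
    the sense that intervals at different locations never overlap-count.
    """
    total = 0
    for loc_a, sa, ea in a.residences:
        ea_ = min(ea or dt.date.max, until)
        for loc_b, sb, eb in b.residences:
            if loc_a != loc_b:
                continue
            eb_ = min(eb or dt.date.max, until)
            lo, hi = max(sa, sb), min(ea_, eb_)
            if hi > lo:
                total += (hi - lo).days
    return float(total)


def compute_familiarity(composition: Composition, individuals,
                        threshold_days: float = 90.0) -> dict[str, int]:
    """Count, for each member, groupmates familiar at the composition start.

    A partner is familiar when accumulated co-residence strictly exceeds
    ``threshold_days`` ("more than 3 months").  Symmetric at the dyad level.
    """
    members = sorted(composition.members)
    for m in members:
        if m not in individuals:
            raise ReferentialIntegrityError(f"no roster entry for {m!r}")
        if not individuals[m].residences:
            raise HerdDataError(f"individual {m!r} has no residence history")
    counts = {m: 0 for m in members}
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            days = coresidence_days(
                individuals[a], individuals[b], composition.start_date
            )
            if days > threshold_days:
                counts[a] += 1
                counts[b] += 1
    return counts
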