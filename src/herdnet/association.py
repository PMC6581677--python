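"""Dyadic nearest-neighbour association matrices from scan-sampling logs.

Each scan records, for every focal, its single nearest neighbour.  Directed
designations are summed into one symmetric matrix: A being B's nearest
neighbour and B being A's both increment the (A, B) dyad, so a mutual
nearest-neighbour scan contributes 2 to that dyad (the ``directed_sum``
convention; ``once`` counts each unordered dyad at most once per scan).

The first days after a composition or enclosure change are excluded from
scoring because relationships are unstable immediately after a transfer:
with the default window, scoring starts on the eighth day.  Scan logs carry
scan indices rather than timestamps; the observation day of a scan is
derived as ``scan_index // scans_per_day`` (default 72 scans per full
observation day).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .herd_data import Composition, HerdDataError, ScanObservation

__all__ = [
    "AssociationMatrix",
    "build_association_matrix",
    "aggregate_daily",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_edge_list",
]

#: scans per full observation day, used to map scan_index -> day.
SCANS_PER_DAY = 72
#: days excluded after a composition/enclosure change (scoring starts day 8).
DEFAULT_EXCLUSION_DAYS = 7


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric non-negative dyadic association counts with zero diagonal."""

    members: tuple[str, ...]
    counts: np.ndarray
    n_scans_used: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        n = len(self.members)
        if c.shape != (n, n):
            raise ValueError(f"counts shape {c.shape} != ({n}, {n})")
        if not np.allclose(c, c.T):
            raise ValueError("association matrix must be symmetric")
        if np.any(c < 0):
            raise ValueError("association counts must be non-negative")
        if np.any(np.diag(c) != 0):
            raise ValueError("association matrix must have zero diagonal")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def n(self) -> int:
        return len(self.members)

    def index(self, member: str) -> int:
        return self.members.index(member)

    def reorder(self, members) -> "AssociationMatrix":
        """Return the same matrix with rows/columns in the given member order."""
        members = tuple(members)
        if set(members) != set(self.members):
            raise ValueError("reorder requires the same member set")
        idx = [self.members.index(m) for m in members]
        return AssociationMatrix(members, self.counts[np.ix_(idx, idx)],
                                 self.n_scans_used)


def build_association_matrix(
    scans,
    composition: Composition,
    exclusion_days: int = DEFAULT_EXCLUSION_DAYS,
    *,
    scans_per_day: int = SCANS_PER_DAY,
    follows_change: bool = True,
    convention: str = "directed_sum",
) -> AssociationMatrix:
    """Sum a composition's scan log into a symmetric association matrix.

    Parameters
    ----------
    scans
        Iterable of :class:`ScanObservation`; only those matching
        ``composition.id`` are used, and all of their ids must be members.
    exclusion_days
        Scans in observation days ``0..exclusion_days-1`` are dropped when
        ``follows_change`` is true (the post-transfer instability window).
    follows_change
        Whether this composition starts at a transfer or enclosure change;
        the first composition of a never-changed group should pass False.
    convention
        ``"directed_sum"`` (default): both directed nearest-neighbour
        designations of a scan increment the dyad.  ``"once"``: each
        unordered dyad counts at most once per scan.
    """
    if convention not in ("directed_sum", "once"):
        raise ValueError(f"unknown convention {convention!r}")
    members = tuple(sorted(composition.members))
    pos = {m: i for i, m in enumerate(members)}
    counts = np.zeros((len(members), len(members)))
    cutoff = exclusion_days * scans_per_day if follows_change else 0
    used: set[int] = set()
    seen_per_scan: dict[int, set[frozenset]] = {}
    n_total = 0
    for s in scans:
        if s.composition_id != composition.id:
            continue
        n_total += 1
        if s.focal not in pos or s.neighbour not in pos:
            raise HerdDataError(
                f"scan {s.scan_index}: {s.focal!r}/{s.neighbour!r} not members "
                f"of {composition.id!r}"
            )
        if s.scan_index < cutoff:
            continue
        used.add(s.scan_index)
        i, j = pos[s.focal], pos[s.neighbour]
        if convention == "once":
            dyads = seen_per_scan.setdefault(s.scan_index, set())
            key = frozenset((i, j))
            if key in dyads:
                continue
            dyads.add(key)
        counts[i, j] += 1
        counts[j, i] += 1
    if n_total and not used:
        warnings.warn(
            f"composition {composition.id!r}: no scans left after the "
            f"{exclusion_days}-day exclusion window; matrix is all zero",
            stacklevel=2,
        )
    return AssociationMatrix(members, counts, n_scans_used=len(used))


def aggregate_daily(matrices) -> AssociationMatrix:
    """Elementwise sum of per-day association matrices (identical members)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to aggregate")
    members = matrices[0].members
    total = np.zeros_like(matrices[0].counts)
    n_scans = 0
    for m in matrices:
        if m.members != members:
            raise ValueError(
                f"member mismatch: {m.members!r} != {members!r}"
            )
        total = total + m.counts
        n_scans += m.n_scans_used
    return AssociationMatrix(members, total, n_scans_used=n_scans)


# ---------------------------------------------------------------------------
# I/O: square CSV with id header row/column, and an edge list
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: AssociationMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["", *matrix.members])
        for i, m in enumerate(matrix.members):
            w.writerow([m, *(f"{v:g}" for v in matrix.counts[i])])


def read_matrix_csv(path) -> AssociationMatrix:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise HerdDataError(f"{path}: empty matrix file")
    members = tuple(rows[0][1:])
    counts = np.zeros((len(members), len(members)))
    for i, row in enumerate(rows[1:]):
        if row[0] != members[i]:
            raise HerdDataError(
                f"{path}: row label {row[0]!r} != column label {members[i]!r}"
            )
        counts[i] = [float(v) for v in row[1:]]
    return AssociationMatrix(members, counts)


def write_edge_list(matrix: AssociationMatrix, path, *, include_zero=False) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id1", "id2", "weight"])
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                v = matrix.counts[i, j]
                if include_zero or v != 0:
                    w.writerow([matrix.members[i], matrix.members[j], f"{v:g}"])
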