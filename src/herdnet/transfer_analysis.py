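"""Impact of composition and enclosure changes on the social network.

Adjacent compositions of the same group are compared on their shared
members: the two association matrices are restricted to the intersection
and correlated with a Mantel test (how stable are dyadic relationships
across the change?), and each shared individual's centrality metrics are
differenced (after minus before).  An enclosure change without any animal
added or removed counts as a transfer of 0 individuals, giving the
no-transfer baseline against which real transfers are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import AssociationMatrix
from .herd_data import Composition
from .matrix_stats import MantelResult, mantel_test, perm_correlation, \
    restrict_to_shared

__all__ = [
    "TransferRecord",
    "build_transfer_record",
    "stability_vs_transfers",
    "mean_stability",
    "records_to_frames",
]


@dataclass(frozen=True)
class TransferRecord:
    """One before/after comparison across a composition or enclosure change."""

    before: str
    after: str
    shared_members: tuple[str, ...]
    n_transferred: int
    enclosure_only: bool
    mantel: MantelResult
    #: per shared individual: dict with d_eigenvector, d_strength, d_rank
    #: (None when the rank is undefined on either side), familiarity_new.
    deltas: dict[str, dict]


def _metric_lookup(metrics: pd.DataFrame, cid: str) -> pd.DataFrame:
    sub = metrics[metrics["composition_id"] == cid]
    return sub.set_index("individual_id")


def build_transfer_record(
    comp_before: Composition,
    comp_after: Composition,
    assoc_before: AssociationMatrix,
    assoc_after: AssociationMatrix,
    metrics_before: pd.DataFrame,
    metrics_after: pd.DataFrame,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    use_corrected: bool = True,
) -> TransferRecord:
    """Compare two adjacent compositions of one group.

    Metric deltas are taken on the group-size-corrected columns by default
    (``use_corrected=False`` switches to raw metrics).  A rank delta is
    reported as missing when an individual has no dominance rank in either
    composition; it is never imputed.
    """
    if comp_before.group != comp_after.group:
        raise ValueError(
            f"compositions {comp_before.id!r} and {comp_after.id!r} belong to "
            "different groups"
        )
    if comp_before.end_date > comp_after.start_date:
        raise ValueError(
            f"compositions {comp_before.id!r} and {comp_after.id!r} are not "
            "adjacent in time"
        )
    removed = comp_before.members - comp_after.members
    added = comp_after.members - comp_before.members
    n_transferred = len(removed) + len(added)
    enclosure_only = comp_after.enclosure_change_only
    if enclosure_only and n_transferred != 0:
        raise ValueError(
            f"{comp_after.id!r} is flagged enclosure-only but membership "
            f"changed by {n_transferred}"
        )
    rb, ra = restrict_to_shared(assoc_before, assoc_after)
    mantel = mantel_test(rb.counts, ra.counts, n_perm=n_perm,
                         sided="one_pos", seed=seed)

    mb = _metric_lookup(metrics_before, comp_before.id)
    ma = _metric_lookup(metrics_after, comp_after.id)
    suffix = "_corrected" if use_corrected else ""
    deltas: dict[str, dict] = {}
    for m in rb.members:
        before_row, after_row = mb.loc[m], ma.loc[m]
        rank_b, rank_a = before_row["rank"], after_row["rank"]
        d_rank = (
            None if pd.isna(rank_b) or pd.isna(rank_a)
            else int(rank_a) - int(rank_b)
        )
        deltas[m] = {
            "d_eigenvector": float(after_row[f"eigenvector{suffix}"]
                                   - before_row[f"eigenvector{suffix}"]),
            "d_strength": float(after_row[f"strength{suffix}"]
                                - before_row[f"strength{suffix}"]),
            "d_rank": d_rank,
            "familiarity_new": after_row["familiarity"],
        }
    return TransferRecord(
        before=comp_before.id,
        after=comp_after.id,
        shared_members=rb.members,
        n_transferred=n_transferred,
        enclosure_only=enclosure_only,
        mantel=mantel,
        deltas=deltas,
    )


def stability_vs_transfers(records, *, n_perm: int = 1000,
                           seed: int | None = None) -> tuple[float, float]:
    """Does network stability depend on how many animals moved?

    Spearman-with-permutations of the per-change Mantel r against the
    number of individuals transferred.  A constant transfer count makes
    the correlation undefined and is surfaced as an error.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 transfer records")
    r_values = [rec.mantel.r for rec in records]
    n_values = [rec.n_transferred for rec in records]
    return perm_correlation(n_values, r_values, n_perm=n_perm,
                            method="spearman", sided="two", seed=seed)


def mean_stability(records) -> tuple[float, float, float]:
    """Mean, min and max of the per-change Mantel correlations."""
    records = list(records)
    if not records:
        raise ValueError("no transfer records")
    rs = [rec.mantel.r for rec in records]
    return (sum(rs) / len(rs), min(rs), max(rs))


def records_to_frames(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy frames: one row per change, and one row per shared individual."""
    t_rows, d_rows = [], []
    for rec in records:
        t_rows.append(
            {
                "before_id": rec.before,
                "after_id": rec.after,
                "n_transferred": rec.n_transferred,
                "enclosure_only": rec.enclosure_only,
                "mantel_r": rec.mantel.r,
                "mantel_p": rec.mantel.p,
                "n_shared": len(rec.shared_members),
            }
        )
        for m, d in rec.deltas.items():
            d_rows.append(
                {"individual_id": m, "before_id": rec.before,
                 "after_id": rec.after, **d}
            )
    return pd.DataFrame(t_rows), pd.DataFrame(d_rows)
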