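"""Individual centralities from association matrices, and the group-size
correction applied before regression.

Two node-level metrics are used: *strength* (the sum of an individual's
edge weights — its social activity) and *eigenvector centrality* (the
entry of the dominant eigenvector of the weighted adjacency matrix — high
when connected to well-connected partners).  Because both metrics scale
mechanically with the number of nodes, they are corrected for group size
before entering any regression.

Correction modes
----------------
``residual`` (default)
    Fit the pooled regression metric = a * group_size + b and remove the
    fitted size trend: y' = y - a * (x - mean(x)).  This removes the
    mathematical group-size effect while preserving the metric's mean.
``literal``
    y' = y * b, with b the fitted intercept.  A constant rescaling cannot
    remove a size effect; the mode exists so the multiplicative reading of
    the correction can be reproduced, and is not the default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse.csgraph

from .association import AssociationMatrix

__all__ = [
    "strength",
    "eigenvector_centrality",
    "correct_for_group_size",
    "build_metric_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "individual_id", "composition_id", "group_size",
    "strength", "eigenvector", "strength_corrected", "eigenvector_corrected",
    "age", "sex", "rank", "familiarity",
]


def strength(assoc: AssociationMatrix) -> np.ndarray:
    """Row sums of the association matrix: s_i = sum_j counts[i, j]."""
    return assoc.counts.sum(axis=1)


def eigenvector_centrality(
    assoc: AssociationMatrix,
    tol: float = 1e-10,
    max_iter: int = 1000,
    *,
    norm: str = "euclidean",
) -> np.ndarray:
    """Entrywise non-negative dominant eigenvector of the association matrix.

    Computed by exact symmetric eigendecomposition (refined by power
    iteration when the residual exceeds ``tol``).  ``norm`` is
    ``"euclidean"`` (unit 2-norm, default) or ``"max"`` (largest entry 1).

    Raises on an all-zero matrix (centrality undefined).  On a disconnected
    association graph the dominant eigenvector concentrates on the
    strongest component; a structural warning listing the components is
    emitted.
    """
    A = assoc.counts
    if not np.any(A > 0):
        raise ValueError("eigenvector centrality undefined for an all-zero matrix")
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(A), directed=False
    )
    if n_comp > 1:
        comps = [
            tuple(m for m, lab in zip(assoc.members, labels) if lab == c)
            for c in range(n_comp)
        ]
        warnings.warn(
            "association graph is disconnected; eigenvector centrality "
            f"concentrates on the strongest component (components: {comps})",
            stacklevel=2,
        )
    evals, evecs = np.linalg.eigh(A)
    v = evecs[:, -1]
    lam = evals[-1]
    # Perron-Frobenius: the dominant eigenvector of a non-negative symmetric
    # matrix can be taken entrywise non-negative; fix the sign.
    if v.sum() < 0:
        v = -v
    for _ in range(max_iter):
        if np.linalg.norm(A @ v - lam * v) <= tol * max(lam, 1.0):
            break
        v = A @ v
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("power iteration collapsed to zero")
        v = v / nv
        lam = float(v @ A @ v)
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations"
        )
    v = np.clip(v, 0.0, None)
    if norm == "euclidean":
        v = v / np.linalg.norm(v)
    elif norm == "max":
        v = v / v.max()
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return v


def correct_for_group_size(
    table: pd.DataFrame,
    mode: str = "residual",
    *,
    metrics: tuple[str, ...] = ("strength", "eigenvector"),
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Add ``<metric>_corrected`` columns controlling for group size.

    Fits metric = a * group_size + b pooled over all rows and applies the
    selected mode.  Returns the augmented table (a copy) and the fitted
    ``{metric: (a, b)}`` coefficients for the run log.  With fewer than two
    distinct group sizes the correction is the identity, with a warning.
    """
    if mode not in ("residual", "literal"):
        raise ValueError(f"unknown correction mode {mode!r}")
    out = table.copy()
    x = out["group_size"].to_numpy(dtype=float)
    coeffs: dict[str, tuple[float, float]] = {}
    degenerate = np.unique(x).size < 2
    if degenerate:
        warnings.warn(
            "fewer than 2 distinct group sizes: group-size correction is the "
            "identity",
            stacklevel=2,
        )
    for metric in metrics:
        y = out[metric].to_numpy(dtype=float)
        if degenerate:
            a, b = 0.0, float(np.mean(y))
            out[f"{metric}_corrected"] = y
        else:
            a, b = np.polyfit(x, y, 1)
            if mode == "residual":
                out[f"{metric}_corrected"] = y - a * (x - x.mean())
            else:
                out[f"{metric}_corrected"] = y * b
        coeffs[metric] = (float(a), float(b))
    return out, coeffs


def build_metric_table(per_composition: dict) -> pd.DataFrame:
    """Assemble the per-individual, per-composition metric table.

    ``per_composition`` maps composition id to a dict with keys ``assoc``
    (:class:`AssociationMatrix`), ``rank`` (id -> dominance rank), ``age``,
    ``sex``, ``familiarity`` (id -> value).  Returns one row per individual
    per composition with raw metrics; corrected columns are added by
    :func:`correct_for_group_size`.
    """
    rows = []
    for cid, parts in per_composition.items():
        assoc: AssociationMatrix = parts["assoc"]
        s = strength(assoc)
        ev = eigenvector_centrality(assoc)
        for i, m in enumerate(assoc.members):
            rows.append(
                {
                    "individual_id": m,
                    "composition_id": cid,
                    "group_size": assoc.n,
                    "strength": float(s[i]),
                    "eigenvector": float(ev[i]),
                    "age": parts["age"][m],
                    "sex": parts["sex"][m],
                    "rank": parts["rank"].get(m),
                    "familiarity": parts["familiarity"][m],
                }
            )
    return pd.DataFrame(rows)
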