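"""Mixed-effects inference on individual centralities.

The regression unit is one individual in one composition; because the same
animal appears in several compositions, a Gaussian linear mixed model with
a random intercept per individual is used.  Inference follows the
information-theoretic, permutation-based workflow standard in animal
social-network analysis:

* every subset of the candidate fixed effects is fitted (all-subsets /
  multi-model inference), models are ranked by AICc, and each predictor's
  relative variable importance (RVI) is the summed Akaike weight of the
  models containing it;
* significance comes from node-label permutations: the response is shuffled
  across individuals (within composition by default), the model refitted,
  and each coefficient's left/right permutation p-values computed against
  the empirical null of permuted estimates;
* multicollinearity is screened with variance inflation factors before
  any model set is fitted.

The random-intercept-only Gaussian LMM admits a closed-form profiled
maximum likelihood over the variance ratio theta = tau^2 / sigma^2 (the
marginal covariance is sigma^2 (I + theta Z Z'), block-diagonal by
individual), which this module exploits: each refit is a one-dimensional
optimisation with O(n p^2) likelihood evaluations, fast enough for
thousands of permutation refits.  ML (not REML) is used throughout so that
AICc comparisons across fixed-effect sets are valid.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "ModelSpec",
    "MixedFit",
    "InferenceResult",
    "fit_mixed",
    "all_subsets_inference",
    "node_label_permutation",
    "compute_vif",
    "build_design",
]

#: candidate fixed effects understood by the design builder.  ``sex``
#: expands to two dummies (SexF, SexM) against a castrated-male reference.
SEX_REFERENCE = "CM"
MAX_CANDIDATE_TERMS = 6


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank-deficient."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"singular design; aliased columns: {self.aliased}")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``response`` is a column of the metric (or delta) table; ``fixed_effects``
    a subset of the candidate predictors; the random intercept groups rows by
    ``random_intercept`` (individual id).  Delta responses (columns starting
    with ``d_``) must not include sex: too few transferred males make the
    term inestimable and aliased with age.
    """

    response: str
    fixed_effects: tuple[str, ...]
    random_intercept: str = "individual_id"
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError("only the gaussian family is supported")
        if self.response.startswith("d_") and "sex" in self.fixed_effects:
            raise ValueError("sex cannot enter a delta (d_*) model")
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))


def build_design(table: pd.DataFrame, terms, *, standardize: bool = False
                 ) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for the given terms.

    Numeric terms enter as-is (optionally z-scored); ``sex`` enters as
    SexF/SexM dummies against the castrated-male reference.
    """
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["(Intercept)"]
    for term in terms:
        if term == "sex":
            sex = table["sex"].astype(str)
            levels = sorted(sex.unique())
            # castrated male is the reference when present, else the first
            # observed level; only observed non-reference levels get dummies
            reference = SEX_REFERENCE if SEX_REFERENCE in levels else levels[0]
            for level in levels:
                if level == reference:
                    continue
                cols.append((sex == level).to_numpy(dtype=float))
                names.append(f"Sex{level}")
        else:
            v = table[term].to_numpy(dtype=float)
            if standardize:
                sd = v.std()
                v = (v - v.mean()) / (sd if sd > 0 else 1.0)
            cols.append(v)
            names.append(term)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns via pivoted QR
        import scipy.linalg as sla

        _, R, piv = sla.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(X.shape[1]) if diag[i] <= tol]
        raise SingularDesignError(aliased)


@dataclass(frozen=True)
class MixedFit:
    """One fitted Gaussian random-intercept model."""

    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    zvalues: dict[str, float]
    loglik: float
    aic: float
    aicc: float
    sigma2: float
    tau2: float
    n: int
    k: int
    residuals: np.ndarray = field(repr=False, default=None)


def _profile_stats(X, y, group_index, group_sizes, theta):
    """GLS pieces for V0 = I + theta Z Z' (block by group)."""
    c = theta / (1.0 + theta * group_sizes)  # per group
    # group sums of X columns and y
    Xs = np.zeros((len(group_sizes), X.shape[1]))
    ys = np.zeros(len(group_sizes))
    np.add.at(Xs, group_index, X)
    np.add.at(ys, group_index, y)
    XtVX = X.T @ X - (Xs * c[:, None]).T @ Xs
    XtVy = X.T @ y - (Xs * c[:, None]).T @ ys
    ytVy = float(y @ y - c @ (ys ** 2))
    return XtVX, XtVy, ytVy


def _ml_deviance(theta, X, y, group_index, group_sizes):
    n = len(y)
    XtVX, XtVy, ytVy = _profile_stats(X, y, group_index, group_sizes, theta)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(theta * group_sizes)))
    dev = n * math.log(2 * math.pi * sigma2) + logdet + n
    return dev, beta, sigma2, XtVX


def fit_mixed(model_spec: ModelSpec, table: pd.DataFrame,
              *, standardize: bool = False) -> MixedFit:
    """Maximum-likelihood fit of the Gaussian random-intercept model.

    Profiles the likelihood down to the variance ratio theta = tau^2 /
    sigma^2 and optimises it on a log grid plus local refinement.  When the
    random variance is unidentifiable (one observation per individual) the
    boundary estimate tau^2 = 0 is returned and the coefficients reduce to
    ordinary least squares.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 observations")
    X, names = build_design(table, model_spec.fixed_effects,
                            standardize=standardize)
    _check_rank(X, names)
    y = table[model_spec.response].to_numpy(dtype=float)
    groups, group_index = np.unique(
        table[model_spec.random_intercept].to_numpy(), return_inverse=True
    )
    group_sizes = np.bincount(group_index).astype(float)

    def dev_of(theta):
        return _ml_deviance(theta, X, y, group_index, group_sizes)[0]

    # coarse log-spaced scan, then bounded refinement around the best point
    grid = np.concatenate(([0.0], np.logspace(-4, 4, 25)))
    devs = [dev_of(t) for t in grid]
    i = int(np.argmin(devs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = scipy.optimize.minimize_scalar(
            dev_of, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(res.x) if res.fun <= devs[i] + 1e-12 else float(grid[i])
    else:
        theta = float(grid[i])
    # prefer the boundary when it is (numerically) as good: unidentifiable
    # random variance is reported as 0, not as an arbitrary interior point
    if dev_of(0.0) <= dev_of(theta) + 1e-8:
        theta = 0.0

    dev, beta, sigma2, XtVX = _ml_deviance(theta, X, y, group_index,
                                           group_sizes)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    loglik = -dev / 2.0
    k = X.shape[1] + 2  # betas + sigma^2 + tau^2
    n = len(y)
    aic = -2 * loglik + 2 * k
    aicc = aic + (2 * k * (k + 1)) / (n - k - 1) if n - k - 1 > 0 else math.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(beta) / se, 0.0)
    return MixedFit(
        terms=tuple(model_spec.fixed_effects),
        params=dict(zip(names, map(float, beta))),
        bse=dict(zip(names, map(float, se))),
        zvalues=dict(zip(names, map(float, z))),
        loglik=float(loglik),
        aic=float(aic),
        aicc=float(aicc),
        sigma2=float(sigma2),
        tau2=float(theta * sigma2),
        n=n,
        k=k,
        residuals=y - X @ beta,
    )


def compute_vif(table: pd.DataFrame, terms) -> dict[str, float]:
    """Variance inflation factor of each term regressed on the others.

    VIF_k = 1 / (1 - R^2_k); perfect collinearity is reported as ``inf``.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("VIF needs at least 2 terms")
    X, names = build_design(table, terms)
    cols = {name: X[:, i] for i, name in enumerate(names) if name != "(Intercept)"}
    out: dict[str, float] = {}
    ones = np.ones(len(table))
    for name, y in cols.items():
        others = np.column_stack(
            [ones] + [v for nm, v in cols.items() if nm != name]
        )
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0:
            raise ValueError(f"term {name!r} is constant")
        r2 = 1.0 - float((resid ** 2).sum()) / tss
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass(frozen=True)
class InferenceResult:
    """Multi-model inference summary.

    ``models`` has one row per fitted subset (model_id, terms, aicc,
    delta_aicc, weight); ``terms`` one row per design column averaged over
    the best set (delta AICc <= ``best_delta``) with RVI from the full set.
    """

    models: pd.DataFrame
    terms: pd.DataFrame
    rvi: dict[str, float]
    vif: dict[str, float]
    best_delta: float
    residual_normality: tuple[float, float]  # Shapiro-Wilk (W, p) of full model


def all_subsets_inference(model_spec: ModelSpec, table: pd.DataFrame,
                          *, best_delta: float = 2.0,
                          standardize: bool = False) -> InferenceResult:
    """Fit every fixed-effect subset; rank by AICc; RVI and model averages.

    The intercept and the random intercept are always included.  Akaike
    weights are w_m = exp(-delta_m / 2) normalised over the full set;
    RVI(term) sums the weights of models containing the term.  Estimates
    are averaged over the best set (delta AICc <= ``best_delta``) with
    zero substitution for absent terms, the convention that shrinks weakly
    supported effects toward zero.
    """
    cand = list(model_spec.fixed_effects)
    if len(cand) > MAX_CANDIDATE_TERMS:
        raise ValueError(
            f"{len(cand)} candidate terms exceed the {MAX_CANDIDATE_TERMS}-term"
            " combinatorial guard"
        )
    if len(cand) >= 2:
        vif = compute_vif(table, cand)
        bad = [t for t, v in vif.items() if math.isinf(v)]
        if bad:
            raise SingularDesignError(bad)
    else:
        vif = {}

    fits: list[tuple[tuple[str, ...], MixedFit]] = []
    for r in range(len(cand) + 1):
        for subset in itertools.combinations(cand, r):
            sub_spec = ModelSpec(
                response=model_spec.response,
                fixed_effects=subset,
                random_intercept=model_spec.random_intercept,
            )
            fits.append((subset, fit_mixed(sub_spec, table,
                                           standardize=standardize)))

    aiccs = np.array([f.aicc for _, f in fits])
    delta = aiccs - aiccs.min()
    weights = np.exp(-delta / 2.0)
    weights = weights / weights.sum()

    models = pd.DataFrame(
        {
            "model_id": range(len(fits)),
            "terms": ["+".join(s) if s else "(intercept)" for s, _ in fits],
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": weights,
        }
    )
    rvi = {
        t: float(sum(w for (s, _), w in zip(fits, weights) if t in s))
        for t in cand
    }

    best = [(s, f, w) for (s, f), w, d in zip(fits, weights, delta)
            if d <= best_delta]
    bw = np.array([w for _, _, w in best])
    bw = bw / bw.sum()
    all_names = sorted({nm for _, f, _ in best for nm in f.params},
                       key=lambda nm: (nm != "(Intercept)", nm))
    rows = []
    for nm in all_names:
        est = np.array([f.params.get(nm, 0.0) for _, f, _ in best])
        ses = np.array([f.bse.get(nm, 0.0) for _, f, _ in best])
        avg = float(bw @ est)
        # unconditional SE (variation between models included)
        se = float(bw @ np.sqrt(ses ** 2 + (est - avg) ** 2))
        rows.append(
            {"term": nm, "estimate": avg, "std_error": se,
             "z_value": abs(avg) / se if se > 0 else 0.0}
        )
    terms_df = pd.DataFrame(rows)

    full_fit = next(f for s, f in fits if len(s) == len(cand))
    if full_fit.n >= 3 and np.ptp(full_fit.residuals) > 0:
        shp = scipy.stats.shapiro(full_fit.residuals)
        normality = (float(shp.statistic), float(shp.pvalue))
    else:
        normality = (float("nan"), float("nan"))
    return InferenceResult(models=models, terms=terms_df, rvi=rvi, vif=vif,
                           best_delta=best_delta, residual_normality=normality)


def node_label_permutation(model_spec: ModelSpec, table: pd.DataFrame,
                           n_perm: int = 1000, seed: int | None = None,
                           *, unit: str = "composition",
                           max_retries: int = 10) -> dict[str, tuple[float, float]]:
    """Left/right permutation p-values for every coefficient.

    Shuffles the response across individuals — within each composition by
    default (``unit="composition"``), or over the whole table
    (``unit="table"``) — refits the model, and compares the observed
    estimate of each term with the null distribution of permuted estimates
    under the +1/+1 rule:

        p_right = (#{beta* >= beta_hat} + 1) / (n_perm + 1)
        p_left  = (#{beta* <= beta_hat} + 1) / (n_perm + 1)

    Refit failures are retried with a fresh permutation (and counted);
    they are never silently dropped.
    """
    if unit not in ("composition", "table"):
        raise ValueError(f"unknown permutation unit {unit!r}")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is low for permutation inference; "
            "p-value resolution will be coarse",
            stacklevel=2,
        )
    observed = fit_mixed(model_spec, table)
    names = list(observed.params)
    rng = np.random.default_rng(seed)
    y = table[model_spec.response].to_numpy(dtype=float)
    if unit == "composition":
        comp_groups = [
            np.flatnonzero(table["composition_id"].to_numpy() == c)
            for c in pd.unique(table["composition_id"])
        ]
    null = np.empty((n_perm, len(names)))
    perm_table = table.copy()
    failures = 0
    for it in range(n_perm):
        for attempt in range(max_retries + 1):
            y_perm = y.copy()
            if unit == "composition":
                for idx in comp_groups:
                    y_perm[idx] = y[rng.permutation(idx)]
            else:
                y_perm = y[rng.permutation(len(y))]
            perm_table[model_spec.response] = y_perm
            try:
                fit = fit_mixed(model_spec, perm_table)
            except (np.linalg.LinAlgError, ValueError):
                failures += 1
                continue
            null[it] = [fit.params[nm] for nm in names]
            break
        else:
            raise RuntimeError(
                f"permutation refit failed {max_retries + 1} times in a row"
            )
    if failures:
        warnings.warn(f"{failures} permutation refits failed and were "
                      "resampled", stacklevel=2)
    tol = 1e-12
    out: dict[str, tuple[float, float]] = {}
    for j, nm in enumerate(names):
        b = observed.params[nm]
        right = (int(np.sum(null[:, j] >= b - tol)) + 1) / (n_perm + 1)
        left = (int(np.sum(null[:, j] <= b + tol)) + 1) / (n_perm + 1)
        out[nm] = (left, right)
    return out
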