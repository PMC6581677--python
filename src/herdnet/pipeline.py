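"""End-to-end orchestration: raw tables -> report bundle.

Stage order follows the analysis's four questions: build association and
agonistic matrices per composition, score dominance, compute and correct
centralities, test homophily (association vs. attribute-difference
matrices, combined across compositions), model centralities and centrality
deltas with multi-model inference and node-label permutations, and
quantify transfer impact.

Every stochastic stage draws its seed from the run seed (recorded in the
manifest); with a fixed seed the whole report bundle is byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    DEFAULT_EXCLUSION_DAYS,
    SCANS_PER_DAY,
    build_association_matrix,
    write_matrix_csv,
)
from .dominance import build_agonistic_matrix, compute_mds, write_dominance_csv
from .herd_data import compute_familiarity, load_tables, save_tables
from .matrix_stats import combine_pvalues, difference_matrix, mantel_test
from .model_inference import (
    ModelSpec,
    all_subsets_inference,
    node_label_permutation,
)
from .network_metrics import build_metric_table, correct_for_group_size
from .synthetic_herd import HerdScenario, generate_herd
from .transfer_analysis import (
    build_transfer_record,
    mean_stability,
    records_to_frames,
    stability_vs_transfers,
)

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """One run: either an input directory of CSV tables or a synthetic
    scenario seed, plus all analysis knobs and permutation counts."""

    out_dir: str
    input_dir: str | None = None
    scenario_seed: int | None = None
    scenario_overrides: dict = field(default_factory=dict)
    seed: int = 0
    exclusion_days: int = DEFAULT_EXCLUSION_DAYS
    scans_per_day: int = SCANS_PER_DAY
    familiarity_threshold_days: float = 90.0
    n_perm_mantel: int = 1000
    n_perm_model: int = 1000
    n_perm_correlation: int = 1000
    correction_mode: str = "residual"
    combine_method: str = "fisher"
    permutation_unit: str = "composition"
    strict: bool = False

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.scenario_seed is None):
            raise ValueError(
                "exactly one of input_dir and scenario_seed must be given"
            )
        for name in ("n_perm_mantel", "n_perm_model", "n_perm_correlation"):
            n = getattr(self, name)
            if n < 100:
                msg = f"{name}={n} is below 100; permutation p-values are coarse"
                if self.strict:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# stage helpers (each usable on its own; run_pipeline strings them together)
# --------------------------------------------------------------------------

def load_or_generate(config: RunConfig):
    """Return (individuals, compositions, scans, events)."""
    if config.input_dir is not None:
        d = Path(config.input_dir)
        return load_tables(d / "roster.csv", d / "scans.csv",
                           d / "agonistic.csv", d / "manifest.csv")
    scenario = HerdScenario(seed=config.scenario_seed,
                            **config.scenario_overrides)
    herd = generate_herd(scenario)
    return herd.individuals, herd.compositions, herd.scans, herd.events


def _order_compositions(compositions) -> list[str]:
    return sorted(compositions,
                  key=lambda c: (compositions[c].group,
                                 compositions[c].start_date))


def _follows_change(compositions, cid: str) -> bool:
    """A composition follows a change unless it opens its group's timeline."""
    comp = compositions[cid]
    return any(
        o.group == comp.group and o.start_date < comp.start_date
        for o in compositions.values()
    )


def stage_associations(compositions, scans, config: RunConfig):
    return {
        cid: build_association_matrix(
            scans, compositions[cid],
            exclusion_days=config.exclusion_days,
            scans_per_day=config.scans_per_day,
            follows_change=_follows_change(compositions, cid),
        )
        for cid in _order_compositions(compositions)
    }


def stage_dominance(compositions, events, config: RunConfig):
    out = {}
    for cid in _order_compositions(compositions):
        comp = compositions[cid]
        if len(comp.members) < 2:
            continue
        out[cid] = compute_mds(build_agonistic_matrix(events, comp))
    return out


def stage_metrics(individuals, compositions, assoc, dominance,
                  config: RunConfig) -> tuple[pd.DataFrame, dict]:
    parts = {}
    for cid in _order_compositions(compositions):
        comp = compositions[cid]
        fam = compute_familiarity(comp, individuals,
                                  config.familiarity_threshold_days)
        ages = {
            m: (comp.start_date - individuals[m].birth_date).days / 365.25
            for m in comp.members
        }
        sexes = {m: individuals[m].sex for m in comp.members}
        ranks = dominance[cid].rank if cid in dominance else {}
        parts[cid] = {
            "assoc": assoc[cid], "age": ages, "sex": sexes,
            "rank": ranks, "familiarity": fam,
        }
    table = build_metric_table(parts)
    table, coeffs = correct_for_group_size(table, mode=config.correction_mode)
    return table, coeffs


def stage_homophily(individuals, compositions, assoc, dominance,
                    config: RunConfig, *, seeds) -> pd.DataFrame:
    """Association vs. attribute-difference Mantel tests, per composition,
    plus a combined row per factor.

    Sidedness: age and rank differences are tested one-sided for negative
    correlation (homophily: smaller difference, stronger association); sex
    is tested two-sided.  Compositions where a factor is constant (e.g. a
    single-sex group) are reported as NA.
    """
    factor_sides = (("age", "one_neg"), ("rank", "one_neg"), ("sex", "two"))
    rows = []
    per_factor_p: dict[str, list[float]] = {k: [] for k, _ in factor_sides}
    seed_iter = iter(seeds)
    for cid in _order_compositions(compositions):
        comp = compositions[cid]
        members = tuple(sorted(comp.members))
        A = assoc[cid].reorder(members)
        ages = {m: (comp.start_date - individuals[m].birth_date).days / 365.25
                for m in members}
        attrs = {
            "age": ages,
            "rank": dominance[cid].rank if cid in dominance else None,
            "sex": {m: individuals[m].sex for m in members},
        }
        for kind, sided in factor_sides:
            seed = next(seed_iter)
            if attrs[kind] is None:
                rows.append({"composition_id": cid, "matrix_pair":
                             f"assoc-{kind}", "r": math.nan, "p": math.nan,
                             "n_perm": 0, "sided": sided, "seed": seed,
                             "note": "no dominance data"})
                continue
            diff = difference_matrix(attrs[kind], members, kind)
            try:
                res = mantel_test(A, diff, n_perm=config.n_perm_mantel,
                                  sided=sided, seed=seed)
            except ValueError as exc:
                rows.append({"composition_id": cid,
                             "matrix_pair": f"assoc-{kind}", "r": math.nan,
                             "p": math.nan, "n_perm": 0, "sided": sided,
                             "seed": seed, "note": str(exc)})
                continue
            rows.append({"composition_id": cid,
                         "matrix_pair": f"assoc-{kind}", "r": res.r,
                         "p": res.p, "n_perm": res.n_perm, "sided": sided,
                         "seed": seed, "note": ""})
            per_factor_p[kind].append(res.p)
    for kind, sided in factor_sides:
        ps = per_factor_p[kind]
        combined = combine_pvalues(ps, config.combine_method) if ps else math.nan
        rows.append({"composition_id": "GLOBAL",
                     "matrix_pair": f"assoc-{kind}", "r": math.nan,
                     "p": combined, "n_perm": 0, "sided": sided,
                     "seed": -1, "note": f"{config.combine_method} over "
                     f"{len(ps)} compositions"})
    return pd.DataFrame(rows)


def _model_results(spec: ModelSpec, table: pd.DataFrame, config: RunConfig,
                   seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    inference = all_subsets_inference(spec, table)
    pperm = node_label_permutation(
        spec, table, n_perm=config.n_perm_model, seed=seed,
        unit=config.permutation_unit,
    )
    terms = inference.terms.copy()
    terms["pperm_left"] = [pperm.get(t, (math.nan, math.nan))[0]
                           for t in terms["term"]]
    terms["pperm_right"] = [pperm.get(t, (math.nan, math.nan))[1]
                            for t in terms["term"]]
    rvi_for = {}
    for cand, value in inference.rvi.items():
        if cand == "sex":
            rvi_for["SexF"] = rvi_for["SexM"] = value
        else:
            rvi_for[cand] = value
    terms["rvi"] = [rvi_for.get(t, math.nan) for t in terms["term"]]
    return terms, inference.models


def stage_models(metric_table: pd.DataFrame, delta_table: pd.DataFrame | None,
                 config: RunConfig, *, seeds) -> dict[str, dict]:
    """The four regressions: corrected eigenvector and strength on
    sociodemographics, and their deltas on transfer covariates."""
    out: dict[str, dict] = {}
    terms: tuple[str, ...] = ("age", "rank", "familiarity")
    # sex enters only when the data carry more than one sex category
    if metric_table["sex"].nunique() > 1:
        terms = ("age", "sex", "rank", "familiarity")
    specs = {
        "eigenvector": ModelSpec("eigenvector_corrected", terms),
        "strength": ModelSpec("strength_corrected", terms),
    }
    seed_iter = iter(seeds)
    for name, spec in specs.items():
        terms, models = _model_results(spec, metric_table, config,
                                       next(seed_iter))
        out[name] = {"terms": terms, "models": models}
    if delta_table is not None and len(delta_table) >= 8:
        for name, resp in (("d_eigenvector", "d_eigenvector"),
                           ("d_strength", "d_strength")):
            spec = ModelSpec(resp, ("age", "familiarity", "d_rank",
                                    "n_transferred"))
            sub = delta_table.dropna(subset=["d_rank"])
            terms, models = _model_results(spec, sub, config, next(seed_iter))
            out[name] = {"terms": terms, "models": models}
    return out


def stage_transfers(individuals, compositions, assoc, metric_table,
                    config: RunConfig, *, seeds):
    """Adjacent-composition records per group, ordered chronologically."""
    records = []
    order = _order_compositions(compositions)
    seed_iter = iter(seeds)
    for before_id, after_id in zip(order, order[1:]):
        b, a = compositions[before_id], compositions[after_id]
        if b.group != a.group:
            continue
        records.append(
            build_transfer_record(
                b, a, assoc[before_id], assoc[after_id],
                metric_table, metric_table,
                n_perm=config.n_perm_mantel, seed=next(seed_iter),
            )
        )
    return records


def _delta_table(records, individuals, compositions) -> pd.DataFrame:
    rows = []
    for rec in records:
        after = compositions[rec.after]
        for m, d in rec.deltas.items():
            rows.append(
                {
                    "individual_id": m,
                    "composition_id": rec.after,
                    "age": (after.start_date
                            - individuals[m].birth_date).days / 365.25,
                    "familiarity": d["familiarity_new"],
                    "d_rank": d["d_rank"],
                    "n_transferred": rec.n_transferred,
                    "d_eigenvector": d["d_eigenvector"],
                    "d_strength": d["d_strength"],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the full run
# --------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a summary dict (also serialised as ``manifest.json``) with the
    seeds used per stage and a checksum for every written file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        "homophily": [int(s) for s in rng.integers(2 ** 31, size=256)],
        "models": [int(s) for s in rng.integers(2 ** 31, size=8)],
        "transfers": [int(s) for s in rng.integers(2 ** 31, size=64)],
        "stability": int(rng.integers(2 ** 31)),
    }

    individuals, compositions, scans, events = load_or_generate(config)
    if config.input_dir is None:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        save_tables(individuals, compositions, scans, events,
                    inputs / "roster.csv", inputs / "scans.csv",
                    inputs / "agonistic.csv", inputs / "manifest.csv")

    assoc = stage_associations(compositions, scans, config)
    (out / "associations").mkdir(exist_ok=True)
    for cid, mat in assoc.items():
        write_matrix_csv(mat, out / "associations" / f"{cid}.csv")

    dominance = stage_dominance(compositions, events, config)
    (out / "dominance").mkdir(exist_ok=True)
    for cid, res in dominance.items():
        write_dominance_csv(res, out / "dominance" / f"{cid}.csv")

    metric_table, correction_coeffs = stage_metrics(
        individuals, compositions, assoc, dominance, config)
    _write_csv(metric_table, out / "metrics.csv")

    homophily = stage_homophily(individuals, compositions, assoc, dominance,
                                config, seeds=stage_seeds["homophily"])
    _write_csv(homophily, out / "homophily.csv")

    records = stage_transfers(individuals, compositions, assoc, metric_table,
                              config, seeds=stage_seeds["transfers"])
    transfers_df, deltas_df = records_to_frames(records)
    _write_csv(transfers_df, out / "transfers.csv")
    _write_csv(deltas_df, out / "deltas.csv")
    stability = {}
    if records:
        mean_r, min_r, max_r = mean_stability(records)
        stability = {"mean_r": mean_r, "min_r": min_r, "max_r": max_r}
        n_vals = {rec.n_transferred for rec in records}
        if len(records) >= 3 and len(n_vals) > 1:
            rho, p = stability_vs_transfers(
                records, n_perm=config.n_perm_correlation,
                seed=stage_seeds["stability"])
            stability.update({"rho_vs_n_transferred": rho, "p": p})

    delta_table = _delta_table(records, individuals, compositions)
    models = stage_models(metric_table, delta_table, config,
                          seeds=stage_seeds["models"])
    (out / "models").mkdir(exist_ok=True)
    for name, parts in models.items():
        _write_csv(parts["terms"], out / "models" / f"{name}_terms.csv")
        _write_csv(parts["models"], out / "models" / f"{name}_models.csv")

    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "models": stage_seeds["models"],
            "stability": stage_seeds["stability"],
        },
        "correction": {k: list(v) for k, v in correction_coeffs.items()},
        "stability": stability,
        "compositions": {
            cid: {
                "group": compositions[cid].group,
                "n": len(compositions[cid].members),
                "n_scans_used": assoc[cid].n_scans_used,
                "n_agonistic": compositions[cid].n_agonistic,
                "follows_change": _follows_change(compositions, cid),
            }
            for cid in _order_compositions(compositions)
        },
        "checksums": {str(p.relative_to(out)): _checksum(p) for p in files},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
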