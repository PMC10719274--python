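"""End-to-end orchestration: inputs -> fits -> topology -> associations.

A run consumes either real input files (choice CSV, BIS CSV, per-subject
tractography edge lists + node table, covariates CSV) or a synthetic cohort
spec, and produces per-subject discounting fits, an exclusion log, topology
reports, the assembled cohort table, the association battery, and a
provenance manifest.  All randomness flows from one top-level seed, split
deterministically per stage and per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import fit_cohort, load_bis_key, score_bis
from .metrics import global_metrics, nodal_metrics
from .network import WeightedNetwork, build_network, load_node_table, read_edge_list
from .stats import BatterySpec, run_association_battery
from .synthetic import CohortSpec, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "DEFAULT_BEHAVIORAL", "GLOBAL_METRIC_COLUMNS"]

log = logging.getLogger("impnet")

DEFAULT_BEHAVIORAL = ["log10_k", "bis_total", "bis_attentional", "bis_motor", "bis_nonplanning"]
GLOBAL_METRIC_COLUMNS = ["Cp", "Lp", "gamma", "lambda", "sigma", "Eglob", "Eloc"]
COVARIATE_COLUMNS = ["age", "sex", "education_years"]


@dataclass
class RunConfig:
    out_dir: str | Path = "impnet_run"
    seed: int = 0
    # exactly one of: simulate spec, or real input paths
    simulate: CohortSpec | None = None
    choices_path: str | None = None
    bis_path: str | None = None
    edges_dir: str | None = None
    nodes_path: str | None = None
    covariates_path: str | None = None
    n_nulls: int = 100
    rewires_per_edge: int = 10
    degree_mode: str = "strength"
    behavioral: list[str] = field(default_factory=lambda: list(DEFAULT_BEHAVIORAL))
    force: bool = False

    def __post_init__(self) -> None:
        real = [self.choices_path, self.bis_path, self.edges_dir, self.nodes_path, self.covariates_path]
        has_real = any(p is not None for p in real)
        if self.simulate is not None and has_real:
            raise ValueError("provide either a simulate spec or real input paths, not both")
        if self.simulate is None and not all(p is not None for p in real):
            raise ValueError("real-input runs need choices, bis, edges_dir, nodes and covariates paths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw.pop("simulate")
            from .synthetic import NetworkParams, PlantedEffect, TaskDesign

            for key, klass in [("task", TaskDesign), ("network", NetworkParams), ("planted_effect", PlantedEffect)]:
                if key in sim and isinstance(sim[key], dict):
                    sub = sim[key]
                    for f_ in ("delayed_amount_range", "delay_range", "rewiring_range"):
                        if f_ in sub:
                            sub[f_] = tuple(sub[f_])
                    sim[key] = klass(**sub)
            raw["simulate"] = CohortSpec(**sim)
        raw.update(overrides)
        return cls(**raw)


def _null_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), 7919 + index]).generate_state(1)[0] % (2**31))


def _load_real_inputs(config: RunConfig):
    choices = pd.read_csv(config.choices_path)
    bis = pd.read_csv(config.bis_path)
    covariates = pd.read_csv(config.covariates_path)
    node_table = load_node_table(config.nodes_path)
    networks: dict[str, WeightedNetwork] = {}
    for p in sorted(Path(config.edges_dir).glob("*_edges.tsv")):
        sid = p.name[: -len("_edges.tsv")]
        networks[sid] = build_network(read_edge_list(p), node_table)
    return choices, bis, covariates, networks, node_table


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts to ``config.out_dir``.

    Returns a dict of the in-memory artifacts (fits, exclusions, topology
    tables, cohort table, association table, manifest).  Subjects missing
    from any input file are dropped with a warning; degenerate responders
    are excluded and logged.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True / --force)")
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        spec = config.simulate
        cohort_data = simulate_cohort(spec)
        choices, bis, covariates = cohort_data.choices, cohort_data.bis, cohort_data.covariates
        networks = cohort_data.networks
        cohort_data.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        choices, bis, covariates, networks, _ = _load_real_inputs(config)

    # subject alignment across inputs
    ids_choices = set(map(str, choices["subject_id"].unique()))
    ids_bis = set(map(str, bis["subject_id"]))
    ids_cov = set(map(str, covariates["subject_id"]))
    ids_net = set(networks)
    common = sorted(ids_choices & ids_bis & ids_cov & ids_net)
    dropped = sorted((ids_choices | ids_bis | ids_cov | ids_net) - set(common))
    if dropped:
        log.warning("dropping %d subjects missing from some input: %s", len(dropped), dropped)
    if not common:
        raise ValueError("no subject is present in all inputs")

    # stage: discounting fits + exclusions
    fits, exclusions = fit_cohort(choices[choices["subject_id"].astype(str).isin(common)])
    kept = [s for s in common if s in set(fits["subject_id"])]
    log.info("fitted %d subjects, excluded %d degenerate responders", len(kept), len(exclusions))

    # stage: BIS scoring
    key = load_bis_key()
    item_cols = [f"item{j:02d}" for j in range(1, 31)]
    bis_rows = []
    for row in bis.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in kept:
            continue
        rec = score_bis([getattr(row, c) for c in item_cols], key, subject_id=sid)
        bis_rows.append(
            {
                "subject_id": sid,
                "bis_attentional": rec.attentional,
                "bis_motor": rec.motor,
                "bis_nonplanning": rec.non_planning,
                "bis_total": rec.total,
            }
        )
    bis_scores = pd.DataFrame(bis_rows)

    # stage: topology per subject
    glob_rows, nodal_rows = [], []
    labels = None
    for idx, sid in enumerate(kept):
        net = networks[sid]
        labels = net.node_table.labels
        gm = global_metrics(
            net,
            n_nulls=config.n_nulls,
            seed=_null_seed(config.seed, idx),
            rewires_per_edge=config.rewires_per_edge,
        )
        nm = nodal_metrics(net, degree_mode=config.degree_mode)
        glob_rows.append(
            {
                "subject_id": sid,
                "Cp": gm.Cp,
                "Lp": gm.Lp,
                "gamma": gm.gamma,
                "lambda": gm.lambda_,
                "sigma": gm.sigma,
                "Eglob": gm.E_glob,
                "Eloc": gm.E_loc,
                "n_unreachable_pairs": gm.n_unreachable_pairs,
            }
        )
        for i, lab in enumerate(labels):
            nodal_rows.append(
                {
                    "subject_id": sid,
                    "node_id": i,
                    "label": lab,
                    "degree": nm.degree[i],
                    "degree_norm": nm.degree_norm[i],
                    "betweenness": nm.betweenness[i],
                    "betweenness_norm": nm.betweenness_norm[i],
                    "is_hub_degree": i in nm.hubs_degree,
                    "is_hub_betweenness": i in nm.hubs_betweenness,
                }
            )
    topology_global = pd.DataFrame(glob_rows)
    topology_nodal = pd.DataFrame(nodal_rows)

    # stage: cohort assembly (wide nodal columns for the battery)
    nodal_wide = topology_nodal.pivot(index="subject_id", columns="label")
    deg = nodal_wide["degree_norm"].add_prefix("deg_")
    btw = nodal_wide["betweenness_norm"].add_prefix("btw_")
    cohort = (
        fits[["subject_id", "log10_k", "k", "beta"]]
        .merge(bis_scores, on="subject_id")
        .merge(covariates.assign(subject_id=covariates["subject_id"].astype(str)), on="subject_id")
        .merge(topology_global.drop(columns=["n_unreachable_pairs"]), on="subject_id")
        .merge(deg, on="subject_id")
        .merge(btw, on="subject_id")
        .sort_values("subject_id")
        .reset_index(drop=True)
    )
    n_missing = int(cohort[COVARIATE_COLUMNS].isna().any(axis=1).sum())
    if n_missing:
        log.warning("dropping %d subjects with missing covariates", n_missing)
        cohort = cohort.dropna(subset=COVARIATE_COLUMNS).reset_index(drop=True)

    # stage: association battery
    nodal_cols = [c for c in cohort.columns if c.startswith(("deg_", "btw_"))]
    spec_b = BatterySpec(
        behavioral=[b for b in config.behavioral if b in cohort.columns],
        global_metrics=GLOBAL_METRIC_COLUMNS,
        nodal_metrics=nodal_cols,
        covariates=COVARIATE_COLUMNS,
        n_nodes=len(labels) if labels else 90,
    )
    associations = run_association_battery(cohort, spec_b)

    manifest = {
        "impnet_version": __version__,
        "seed": int(config.seed),
        "n_subjects": len(kept),
        "n_excluded": len(exclusions),
        "n_nulls": int(config.n_nulls),
        "rewires_per_edge": int(config.rewires_per_edge),
        "degree_mode": config.degree_mode,
        "mode": "simulate" if config.simulate is not None else "real",
    }

    fits.to_csv(out / "fits.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    topology_global.to_csv(out / "topology_global.csv", index=False)
    topology_nodal.to_csv(out / "topology_nodal.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    associations.to_csv(out / "associations.csv", index=False)
    associations[associations["top_decile_nodal"]].to_csv(out / "top_decile_nodal.csv", index=False)
    with open(out / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)

    return {
        "fits": fits,
        "exclusions": exclusions,
        "topology_global": topology_global,
        "topology_nodal": topology_nodal,
        "cohort": cohort,
        "associations": associations,
        "manifest": manifest,
    }


def _check_numeric(df: pd.DataFrame, path: str, col: str, issues: list[str], valid=None) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    for i in bad:
        issues.append(f"{path}: line {i + 2}: non-numeric value in column {col!r}")
    if valid is not None:
        bad = df.index[vals.notna() & ~vals.isin(valid)]
        for i in bad:
            issues.append(f"{path}: line {i + 2}: column {col!r} value {df[col][i]!r} outside {sorted(valid)}")


def validate_inputs(
    choices_path: str | None = None,
    bis_path: str | None = None,
    edges_dir: str | None = None,
    nodes_path: str | None = None,
    covariates_path: str | None = None,
) -> list[str]:
    """Schema-check input files; returns a list of human-readable issues.

    Line numbers refer to the file (header = line 1).  Also reports subjects
    that are not present in every provided file.
    """
    issues: list[str] = []
    ids: dict[str, set[str]] = {}

    if choices_path:
        df = pd.read_csv(choices_path, dtype=str)
        need = ["subject_id", "immediate_amount", "delayed_amount", "delay_days", "choice"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            issues.append(f"{choices_path}: missing columns {missing}")
        else:
            for c in need[1:]:
                _check_numeric(df, str(choices_path), c, issues, valid={0, 1} if c == "choice" else None)
            ids["choices"] = set(df["subject_id"])
    if bis_path:
        df = pd.read_csv(bis_path, dtype=str)
        item_cols = [f"item{j:02d}" for j in range(1, 31)]
        missing = [c for c in ["subject_id"] + item_cols if c not in df.columns]
        if missing:
            issues.append(f"{bis_path}: missing columns {missing}")
        else:
            for c in item_cols:
                _check_numeric(df, str(bis_path), c, issues, valid={1, 2, 3, 4})
            ids["bis"] = set(df["subject_id"])
    if covariates_path:
        df = pd.read_csv(covariates_path, dtype=str)
        need = ["subject_id"] + COVARIATE_COLUMNS
        missing = [c for c in need if c not in df.columns]
        if missing:
            issues.append(f"{covariates_path}: missing columns {missing}")
        else:
            for c in COVARIATE_COLUMNS:
                _check_numeric(df, str(covariates_path), c, issues)
            ids["covariates"] = set(df["subject_id"])
    if nodes_path:
        try:
            load_node_table(nodes_path)
        except Exception as e:  # surface as an issue, not a crash
            issues.append(f"{nodes_path}: {e}")
    if edges_dir:
        paths = sorted(Path(edges_dir).glob("*_edges.tsv"))
        if not paths:
            issues.append(f"{edges_dir}: no *_edges.tsv files found")
        ids["networks"] = {p.name[: -len("_edges.tsv")] for p in paths}
        for p in paths:
            df = pd.read_csv(p, sep="\t", dtype=str)
            need = ["node_i", "node_j", "fiber_count", "mean_fa"]
            missing = [c for c in need if c not in df.columns]
            if missing:
                issues.append(f"{p}: missing columns {missing}")
            else:
                for c in need:
                    _check_numeric(df, str(p), c, issues)

    if len(ids) > 1:
        everyone = set.union(*ids.values())
        shared = set.intersection(*ids.values())
        for sid in sorted(everyone - shared):
            absent = [name for name, s in ids.items() if sid not in s]
            issues.append(f"subject {sid!r} missing from: {', '.join(absent)}")
    return issues
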