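"""End-to-end pipeline: simulate/load -> reliability -> landmarks -> shapes -> stats.

Every stage writes its artifacts under the run's output directory and the run
closes with a manifest (config hash, seed, library versions, counts and
output checksums).  Reruns with an identical configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import categorize_icp, fit_gee, rm_anova, roc_auc
from .curve_io import (
    aggregate_reliability,
    canonicalize,
    reliability_report,
    write_traces,
)
from .errors import ConfigurationError, PbmShapeError
from .landmarks import STRATEGIES, build_dataset, configs_to_frame, write_tps
from .morphometrics import pc1_scores
from .synthetic_data import (
    ANGLES,
    SynthParams,
    read_cohort_files,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)


class StageError(PbmShapeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    synth: SynthParams = field(default_factory=SynthParams)
    input_dir: str | None = None  # files mode
    strategies: tuple = ("user-16", "user-14", "distance-16", "distance-14")
    groupings: tuple = ("all", "per_angle")
    dichotomies: tuple = ("elevated_vs_rest", "rest_vs_normal")
    out_dir: str = "pbmshape_run"
    seed: int = 0
    center_rule: str = "scan_midpoint"
    eye_rule: str = "right"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"mode must be synthetic|files, got {self.mode!r}")
        if not self.strategies:
            raise ConfigurationError("at least one strategy is required")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ConfigurationError(f"unknown strategies {unknown}")
        if self.mode == "files" and not self.input_dir:
            raise ConfigurationError("files mode requires input_dir")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["baseline_shape"] = dataclasses.asdict(self.synth.baseline_shape)
        return d


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    synth = d.pop("synth", {})
    if isinstance(synth, dict):
        synth = dict(synth)
        from .synthetic_data import BaselineShape

        if "baseline_shape" in synth and isinstance(synth["baseline_shape"], dict):
            synth["baseline_shape"] = BaselineShape(**synth["baseline_shape"])
        if "deflection_gain" in synth:
            synth["deflection_gain"] = tuple(synth["deflection_gain"])
        if "icp_distribution" in synth:
            synth["icp_distribution"] = tuple(synth["icp_distribution"])
        synth = SynthParams(**synth)
    for key in ("strategies", "groupings", "dichotomies"):
        if key in d:
            d[key] = tuple(d[key])
    return RunConfig(synth=synth, **d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PbmShapeError as e:
                raise StageError(f"stage {name!r} failed: {e}") from e

        return wrapper

    return deco


@_stage("acquire")
def _acquire(config: RunConfig, out: Path):
    """Simulate or load the cohort; returns (scan list, icp by subject)."""
    if config.mode == "synthetic":
        params = replace(config.synth, seed=config.seed)
        cohort = simulate_cohort(params)
        write_cohort(cohort, out / "cohort")
        scans = [(s.meta, list(s.traces), s.icp) for s in cohort.scans]
    else:
        scans = read_cohort_files(config.input_dir)
    scans.sort(key=lambda rec: rec[0].scan_id)  # order-independent downstream
    icp = {}
    for meta, _, scan_icp in scans:
        if scan_icp is not None:
            icp[meta.subject_id] = scan_icp
    return scans, icp


@_stage("reliability")
def _reliability(scans, out: Path) -> dict:
    reports = [(meta, reliability_report(traces, meta)) for meta, traces, _ in scans]
    agg = aggregate_reliability(reports)
    per_scan = agg.pop("per_scan")
    per_scan.to_csv(out / "reliability_per_scan.csv", index=False)
    pd.DataFrame([{k: v for k, v in agg.items() if not isinstance(v, dict)}]).to_csv(
        out / "reliability_summary.csv", index=False
    )
    pd.Series(agg["per_angle_prop_flagged"], name="prop_flagged").rename_axis(
        "angle_deg"
    ).to_csv(out / "reliability_per_angle.csv")
    return agg


@_stage("landmarks")
def _landmarks(scans, config: RunConfig, out: Path):
    curves = [canonicalize(traces, meta) for meta, traces, _ in scans]
    lm_dir = out / "landmarks"
    lm_dir.mkdir(exist_ok=True)
    per_strategy = {}
    for name in config.strategies:
        configs, exclusions = build_dataset(curves, STRATEGIES[name], config.center_rule)
        write_tps(lm_dir / f"{name}.tps", configs)
        configs_to_frame(configs).to_csv(lm_dir / f"{name}.csv", index=False)
        exclusions.to_csv(lm_dir / f"{name}_exclusions.csv", index=False)
        per_strategy[name] = (configs, exclusions)
        logger.info("strategy %s: %d configurations, %d excluded",
                    name, len(configs), len(exclusions))
    return per_strategy


@_stage("shapes")
def _shapes(per_strategy, config: RunConfig, out: Path):
    spaces = {}
    tables = []
    for name, (configs, _) in per_strategy.items():
        for grouping in config.groupings:
            sp, table = pc1_scores(configs, grouping=grouping)
            spaces[(name, grouping)] = sp
            table = table.copy()
            table["strategy"] = name
            tables.append(table)
    scores = pd.concat(tables, ignore_index=True)
    scores.to_csv(out / "scores.csv", index=False)
    consensus = {
        f"{name}|{grouping}|{label}": {
            "consensus": sp2.consensus.tolist(),
            "pc1": sp2.components[0].tolist(),
            "eigenvalues": sp2.eigenvalues.tolist(),
        }
        for (name, grouping), sp in spaces.items()
        for label, sp2 in sp.items()
    }
    (out / "shape_spaces.json").write_text(json.dumps(consensus, sort_keys=True))
    return spaces, scores


@_stage("stats")
def _stats(scores: pd.DataFrame, icp: dict, config: RunConfig, out: Path):
    if not icp:
        raise ConfigurationError("no ICP values available; cannot run statistics")
    scores = scores.copy()
    scores["icp_cm_h2o"] = scores["subject_id"].map(icp)
    scores["category"] = scores["icp_cm_h2o"].map(categorize_icp)

    rows_rm, rows_gee, rows_roc, roc_points = [], [], [], []
    for name in config.strategies:
        sub_all = scores[(scores["strategy"] == name) & (scores["grouping"] == "all")]
        if not sub_all.empty:
            res = rm_anova(sub_all[["subject_id", "eye", "angle_deg", "score"]], icp)
            rows_rm.append(
                {
                    "strategy": name,
                    "angle_f": res.angle_f,
                    "angle_p": res.angle_p,
                    "eye_f": res.eye_f,
                    "eye_p": res.eye_p,
                    "icp_f": res.icp_f,
                    "icp_p": res.icp_p,
                    "n_subjects": res.n_subjects,
                    "n_dropped": res.n_dropped,
                }
            )
        for ang in ANGLES:
            sub = scores[
                (scores["strategy"] == name)
                & (scores["grouping"] == f"angle_{ang}")
            ]
            if sub.empty:
                continue
            fit = fit_gee(
                sub["score"].to_numpy(),
                sub["icp_cm_h2o"].to_numpy(),
                sub["subject_id"].to_numpy(),
            )
            rows_gee.append(
                {
                    "strategy": name,
                    "angle_deg": ang,
                    "slope": fit.slope,
                    "slope_se": fit.slope_se,
                    "wald_z": fit.wald_z,
                    "p_value": fit.p_value,
                    "n_clusters": fit.n_clusters,
                }
            )
            for dich in config.dichotomies:
                roc = roc_auc(sub, dichotomy=dich, eye_rule=config.eye_rule,
                              seed=config.seed)
                rows_roc.append(
                    {
                        "strategy": name,
                        "angle_deg": ang,
                        "dichotomy": dich,
                        "auc": roc.auc,
                        "ci_lower": roc.ci_lower,
                        "ci_upper": roc.ci_upper,
                        "n_positive": roc.n_positive,
                        "n_negative": roc.n_negative,
                    }
                )
                pts = roc.operating_points.copy()
                pts["strategy"], pts["angle_deg"], pts["dichotomy"] = name, ang, dich
                roc_points.append(pts)

    pd.DataFrame(rows_rm).to_csv(out / "rm_anova.csv", index=False)
    pd.DataFrame(rows_gee).to_csv(out / "gee.csv", index=False)
    roc_df = pd.DataFrame(rows_roc)
    roc_df.to_csv(out / "roc.csv", index=False)
    if roc_points:
        pd.concat(roc_points, ignore_index=True).to_csv(out / "roc_points.csv", index=False)
    # AUC [CI] grids, rows = scan angle, columns = strategy, one per dichotomy
    for dich in config.dichotomies:
        sub = roc_df[roc_df["dichotomy"] == dich]
        if sub.empty:
            continue
        cell = sub.assign(
            cell=[
                f"{r.auc:.3f} [{r.ci_lower:.3f}, {r.ci_upper:.3f}]"
                for r in sub.itertuples()
            ]
        ).pivot(index="angle_deg", columns="strategy", values="cell")
        cell.to_csv(out / f"auc_table_{dich}.csv")
    return {"rm_anova": rows_rm, "gee": rows_gee, "roc": rows_roc}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scans, icp = _acquire(config, out)
    reliability = _reliability(scans, out)
    per_strategy = _landmarks(scans, config, out)
    spaces, scores = _shapes(per_strategy, config, out)
    stats = _stats(scores, icp, config, out)

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "pbmshape": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "n_scans": len(scans),
            "n_subjects": len(icp),
            "configs_per_strategy": {
                name: len(cfgs) for name, (cfgs, _) in per_strategy.items()
            },
            "exclusions_per_strategy": {
                name: len(exc) for name, (_, exc) in per_strategy.items()
            },
            "shape_spaces": {
                f"{name}|{grouping}": len(sp) for (name, grouping), sp in spaces.items()
            },
        },
        "reliability": {
            k: v for k, v in reliability.items() if isinstance(v, (int, float, str))
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
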