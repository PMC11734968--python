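"""End-to-end orchestration: one configuration, one reproducible report bundle.

Stages run in a fixed order — preprocessing, network estimation, bootstrap
stability, nodewise predictability, community detection with threshold
optimisation, local-structure indices (plus optional subscale re-analysis),
and optionally a moderated model — each writing its machine-readable
artifact into the output directory.  All randomness derives from the single
configured seed, so re-running an identical configuration reproduces every
artifact byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import data_io
from .communities import (
    EntropyNull,
    SelectionResult,
    ThresholdGrid,
    permute_entropy_null,
    select_solution,
    threshold_grid,
)
from .data_io import ExclusionReport, FrameRule, MixedDataset
from .local_structure import LocalIndexTable, local_indices, subscale_network
from .mgm import (
    EstimatorConfig,
    ModeratedNetwork,
    PredictabilityReport,
    WeightedNetwork,
    estimate_mgm,
    fit_moderated,
    predictability,
)
from .stability import BootstrapSummary, bootstrap_stability
from . import synthetic

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "mgmnet_out",
    "data": {"synthetic": {"kind": "study_mimic", "n": 2000}},
    "preprocessing": {
        "mad": None,            # {"variable": ..., "threshold": 2.5}
        "flag_rules": [],       # [{"name": ..., "variable": ..., "remove_value": ...}]
        "merges": {},           # {var: {"mapping": {...}} | {"min_count": int}}
        "select_first": None,
    },
    "estimator": {
        "gamma": 0.25,
        "rule": "AND",
        "n_lambdas": 50,
        "lambda_min_ratio": 0.01,
    },
    "bootstrap": {"enabled": True, "B": 1000, "level": 0.95},
    "communities": {"k_values": [3, 4], "I_step": 0.005, "n_perm": 100},
    "local": {"display_threshold": 0.05, "subscale_map": {}},
    "moderation": {"moderator": None},
}


def _merge_defaults(user: Mapping[str, Any], defaults: Mapping[str, Any]) -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if (
            key in defaults
            and isinstance(defaults[key], Mapping)
            and isinstance(value, Mapping)
        ):
            out[key] = _merge_defaults(value, defaults[key])
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Validated full-pipeline configuration (defaults mirror the study run)."""

    raw: dict[str, Any]

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        merged = _merge_defaults(doc, DEFAULT_CONFIG)
        est = merged["estimator"]
        if est["gamma"] < 0:
            raise ValueError("gamma must be >= 0")
        if merged["bootstrap"]["B"] < 1:
            raise ValueError("bootstrap B must be >= 1")
        if merged["communities"]["n_perm"] < 1:
            raise ValueError("n_perm must be >= 1")
        data = merged["data"]
        if ("synthetic" in data) == ("data_path" in data):
            raise ValueError("configure exactly one of data.synthetic / data.data_path")
        return cls(raw=merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def estimator_config(self, moderator: str | None = None) -> EstimatorConfig:
        est = self.raw["estimator"]
        return EstimatorConfig(
            gamma=float(est["gamma"]),
            rule=str(est["rule"]),
            n_lambdas=int(est["n_lambdas"]),
            lambda_min_ratio=float(est["lambda_min_ratio"]),
            moderator=moderator,
        )

    def hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run plus the paths written."""

    output_dir: Path
    dataset: MixedDataset
    exclusion_report: ExclusionReport | None
    network: WeightedNetwork
    predictability: PredictabilityReport
    bootstrap: BootstrapSummary | None
    grid: ThresholdGrid
    null: EntropyNull
    selection: SelectionResult
    indices: LocalIndexTable
    subscale_networks: dict[str, WeightedNetwork] = field(default_factory=dict)
    moderated: ModeratedNetwork | None = None
    manifest: dict[str, Any] = field(default_factory=dict)


def _stage(name: str, manifest: dict):
    """Context manager logging a stage and re-raising failures with its name."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.1fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, dt)
            manifest["stages"].append(name)
            return False

    return _Ctx()


def _load_data(config: PipelineConfig, seed: int, out: Path, manifest: dict):
    data = config["data"]
    if "synthetic" in data:
        syn = dict(data["synthetic"])
        kind = syn.pop("kind", "study_mimic")
        if kind == "study_mimic":
            model, dataset = synthetic.study_mimic(seed=syn.pop("seed", seed), **syn)
            synthetic.write_planted_model(model, out / "planted_model.yaml")
            manifest["planted_model"] = "planted_model.yaml"
        else:
            raise ValueError(f"unknown synthetic kind {kind!r}")
        return dataset
    return data_io.read_mixed_table(data["data_path"], data["spec_path"])


def _preprocess(config: PipelineConfig, dataset: MixedDataset, out: Path, manifest):
    pre = config["preprocessing"]
    rules = []
    for spec in pre["flag_rules"]:
        var, bad = spec["variable"], spec["remove_value"]
        rules.append(
            (spec["name"], lambda row, v=var, b=bad: row[v] == b)
        )
    if pre["mad"]:
        var = pre["mad"]["variable"]
        thr = float(pre["mad"].get("threshold", data_io.DEFAULT_MAD_THRESHOLD))
        rules.append(
            (
                f"mad_outlier[{var}]",
                FrameRule(
                    lambda frame, v=var, t=thr: data_io.mad_outlier_flags(
                        frame[v].to_numpy(dtype=float), t
                    )
                ),
            )
        )
    report = None
    if rules or pre["select_first"] is not None:
        dataset, report = data_io.apply_exclusions(
            dataset, rules, select_first=pre["select_first"]
        )
        (out / "exclusion_report.txt").write_text(report.to_text())
        for rule, count in report.per_rule_removed:
            log.info("exclusion rule %s removed %d rows", rule, count)
    for var, how in pre["merges"].items():
        dataset = data_io.merge_sparse_categories(dataset, var, **how)
    drop = [s.name for s in dataset.specs if s.name in pre.get("drop", [])]
    if drop:
        keep_specs = tuple(s for s in dataset.specs if s.name not in drop)
        dataset = MixedDataset(
            values=dataset.values[[s.name for s in keep_specs]].copy(),
            specs=keep_specs,
        )
    data_io.write_mixed_table(dataset, out / "cleaned.csv", out / "cleaned_spec.yaml")
    return dataset, report


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every configured stage and write the report bundle."""
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    # independent, reproducible seed per random stage
    ss = np.random.SeedSequence(config.seed)
    seed_data, seed_boot, seed_perm = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    manifest: dict[str, Any] = {
        "config": config.raw,
        "config_hash": config.hash(),
        "seeds": {
            "root": config.seed,
            "data": seed_data,
            "bootstrap": seed_boot,
            "permutation": seed_perm,
        },
        "stages": [],
        "warnings": [],
    }
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        bundle = _run_stages(config, out, manifest, seed_data, seed_boot, seed_perm)
    manifest["warnings"] = sorted({str(w.message) for w in caught})
    import sklearn

    manifest["versions"] = {
        "mgmnet": _package_version(),
        "numpy": np.__version__,
        "scikit-learn": sklearn.__version__,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    bundle.manifest = manifest
    return bundle


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("mgmnet")
    except Exception:
        return "unknown"


def _run_stages(config, out, manifest, seed_data, seed_boot, seed_perm):
    with _stage("load", manifest):
        dataset = _load_data(config, seed_data, out, manifest)
    with _stage("preprocess", manifest):
        dataset, exclusion_report = _preprocess(config, dataset, out, manifest)

    est_config = config.estimator_config()
    with _stage("estimate", manifest):
        network, fits = estimate_mgm(dataset, est_config)
        network.edge_frame(include_zero=False).to_csv(
            out / "network_edges.csv", index=False, float_format=_FLOAT_FMT
        )
        network.to_graphml(out / "network.graphml")

    boot = None
    if config["bootstrap"]["enabled"]:
        with _stage("bootstrap", manifest):
            boot = bootstrap_stability(
                dataset,
                est_config,
                B=int(config["bootstrap"]["B"]),
                level=float(config["bootstrap"]["level"]),
                seed=seed_boot,
                full_network=network,
            )
            boot.to_frame().to_csv(
                out / "stability.csv", index=False, float_format=_FLOAT_FMT
            )

    with _stage("predictability", manifest):
        pred = predictability(dataset, fits)
        pred.to_frame().to_csv(
            out / "predictability.csv", index=False, float_format=_FLOAT_FMT
        )

    comm_cfg = config["communities"]
    with _stage("communities", manifest):
        grid = threshold_grid(
            network,
            k_values=tuple(comm_cfg["k_values"]),
            I_step=float(comm_cfg["I_step"]),
        )
        grid.frame.to_csv(
            out / "threshold_grid.csv", index=False, float_format=_FLOAT_FMT
        )
        null = permute_entropy_null(
            network,
            k_values=tuple(comm_cfg["k_values"]),
            I_step=float(comm_cfg["I_step"]),
            n_perm=int(comm_cfg["n_perm"]),
            seed=seed_perm,
        )
        null_frame = [
            {"k": k, "upper_95": null.upper[k]} for k in sorted(null.upper)
        ]
        import pandas as pd

        pd.DataFrame(null_frame).to_csv(
            out / "entropy_null.csv", index=False, float_format=_FLOAT_FMT
        )
        selection = select_solution(grid, null)
        (out / "community_solution.txt").write_text(selection.chosen.to_text())
        (out / "selection_rationale.txt").write_text(selection.rationale)

    with _stage("local_structure", manifest):
        indices = local_indices(network, selection.chosen)
        indices.frame.to_csv(
            out / "local_indices.csv", index=False, float_format=_FLOAT_FMT
        )
        subscales: dict[str, WeightedNetwork] = {}
        sub_map = config["local"]["subscale_map"]
        if sub_map:
            thr = float(config["local"]["display_threshold"])
            for cid, comm in enumerate(selection.chosen.communities):
                if not any(node in sub_map for node in comm):
                    continue
                full, displayed, _ = subscale_network(
                    dataset, set(comm), sub_map, display_threshold=thr,
                    config=est_config,
                )
                subscales[f"community_{cid}"] = full
                displayed.edge_frame().to_csv(
                    out / f"subscale_community_{cid}.csv",
                    index=False,
                    float_format=_FLOAT_FMT,
                )

    moderated = None
    moderator = config["moderation"]["moderator"]
    if moderator:
        with _stage("moderation", manifest):
            std, _ = data_io.standardize_continuous(dataset)
            moderated = fit_moderated(
                std,
                moderator,
                gamma=est_config.gamma,
                n_lambdas=est_config.n_lambdas,
                lambda_min_ratio=est_config.lambda_min_ratio,
                rule=est_config.rule,
            )
            moderated.moderation_frame().to_csv(
                out / "moderation.csv", index=False, float_format=_FLOAT_FMT
            )
    else:
        manifest["moderation"] = "disabled"

    return ReportBundle(
        output_dir=out,
        dataset=dataset,
        exclusion_report=exclusion_report,
        network=network,
        predictability=pred,
        bootstrap=boot,
        grid=grid,
        null=null,
        selection=selection,
        indices=indices,
        subscale_networks=subscales,
        moderated=moderated,
    )
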