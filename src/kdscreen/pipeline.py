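"""End-to-end pipeline: ingest/simulate -> CBU -> augment -> train -> evaluate.

Stages run in fixed order, each seeded deterministically from the single
top-level seed via :func:`kdscreen.seeds.derive_seed`, and each writing its
artifact (filtered cohort, balanced cohort, fidelity report, model bundle,
metrics tables) into the output directory together with a JSON manifest of
stage seeds, input hashes and row counts. Rerunning an identical config
reproduces byte-identical metrics tables.

An ablation runner re-executes the pipeline along one axis (undersampler,
clustering metric, generator backend, or target ratio) with everything else
fixed, averaging over several seeds, and emits a long-format comparison
table.
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

from . import augment as _augment
from . import cbu as _cbu
from .cohort import CohortTable, class_ratio, read_cohort, write_cohort
from .ensemble import StackingConfig, predict_scores, train_stacking
from .evaluate import DEFAULT_RECALL_TARGETS, evaluate_scores, sweep_frame
from .fidelity import fidelity_report
from .seeds import derive_seed
from .synth import make_fixture_suite

logger = logging.getLogger("kdscreen.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str | Path = "kdscreen_run"
    # input: either CSV paths (train/test[/external]) or the synthetic suite
    train_csv: str | None = None
    test_csv: str | None = None
    external_csv: str | None = None
    suite_sizes: tuple[int, int, int] = (6500, 4800, 1600)
    undersampler: str = "cbu"            # cbu | random | none
    # None -> conventional balanced undersampling (1:1); "match_cbu" -> use
    # the negative budget the cluster filter would have retained
    rus_target_ratio: float | str | None = None
    clustering: _cbu.ClusteringConfig = field(default_factory=_cbu.ClusteringConfig)
    filter_policy: _cbu.FilterPolicy = field(default_factory=_cbu.FilterPolicy)
    r_target: float = 24.0
    backend: _augment.GeneratorBackendConfig = field(
        default_factory=_augment.GeneratorBackendConfig
    )
    stacking: StackingConfig = field(default_factory=StackingConfig)
    recall_targets: tuple[float, ...] = DEFAULT_RECALL_TARGETS


def _hash_table(t: CohortTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(t.values).tobytes())
    h.update(np.ascontiguousarray(t.labels).tobytes())
    return h.hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    from .cohort import kd_schema

    if config.train_csv:
        schema = kd_schema()
        train = read_cohort(config.train_csv, schema)
        test = read_cohort(config.test_csv, schema) if config.test_csv else None
        external = (
            read_cohort(config.external_csv, schema) if config.external_csv else None
        )
        return train, test, external
    n_tr, n_te, n_ex = config.suite_sizes
    return make_fixture_suite(
        derive_seed(config.seed, "suite"), n_tr, n_te, n_ex
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}

    def stage(name: str, **info) -> None:
        entry = {"stage": name, **info}
        manifest["stages"].append(entry)
        logger.info("stage=%s %s", name, info)

    train, test, external = _load_inputs(config)
    stage("ingest", rows=train.n_rows, pos=train.n_pos,
          input_hash=_hash_table(train))

    # Step 1: undersampling
    if config.undersampler == "cbu":
        clus_cfg = replace(config.clustering, seed=derive_seed(config.seed, "cbu"))
        assignment = _cbu.assign_clusters(train, clus_cfg)
        filtered = _cbu.filter_clusters(train, assignment, config.filter_policy)
        summaries = _cbu.summarize_clusters(assignment, train.labels)
        cluster_report = [dataclasses.asdict(s) for s in summaries]
        (out / "clusters.json").write_text(
            json.dumps(cluster_report, indent=2, default=float)
        )
        manifest["artifacts"]["clusters"] = "clusters.json"
    elif config.undersampler == "random":
        ratio = config.rus_target_ratio
        if ratio == "match_cbu":
            clus_cfg = replace(config.clustering, seed=derive_seed(config.seed, "cbu"))
            assignment = _cbu.assign_clusters(train, clus_cfg)
            cbu_out = _cbu.filter_clusters(train, assignment, config.filter_policy)
            ratio = cbu_out.n_neg / max(cbu_out.n_pos, 1)
        elif ratio is None:
            ratio = 1.0
        filtered = _cbu.random_undersample(
            train, float(ratio), derive_seed(config.seed, "rus")
        )
    elif config.undersampler == "none":
        filtered = train
    else:
        raise ValueError(f"unknown undersampler {config.undersampler!r}")
    write_cohort(filtered, out / "filtered.csv")
    manifest["artifacts"]["filtered"] = "filtered.csv"
    stage("undersample", method=config.undersampler, rows=filtered.n_rows,
          pos=filtered.n_pos, neg=filtered.n_neg)

    # Step 2: augmentation
    backend_cfg = replace(config.backend, seed=derive_seed(config.seed, "augment"))
    balanced, plan = _augment.balance_cohort(
        filtered, config.r_target, backend_cfg
    )
    write_cohort(balanced, out / "balanced.csv")
    (out / "augmentation_plan.json").write_text(json.dumps(plan.to_dict(), indent=2))
    manifest["artifacts"]["balanced"] = "balanced.csv"
    manifest["artifacts"]["augmentation_plan"] = "augmentation_plan.json"
    stage("augment", backend=backend_cfg.backend, n_aug=plan.n_aug,
          rows=balanced.n_rows, pos=balanced.n_pos)

    report = fidelity_report(filtered, balanced, backend=backend_cfg.backend)
    report.to_json(out / "fidelity.json")
    manifest["artifacts"]["fidelity"] = "fidelity.json"
    stage("fidelity", mmd=report.mmd, pcd=report.pcd)

    # Step 3: stacking
    stack_cfg = replace(config.stacking, seed=derive_seed(config.seed, "stacking"))
    model = train_stacking(balanced, stack_cfg)
    model.save(out / "model.pkl")
    manifest["artifacts"]["model"] = "model.pkl"
    stage("train", n_folds=stack_cfg.n_folds,
          bases=[s.name for s in stack_cfg.base_specs])

    # Evaluation
    frames = []
    for name, cohort in (("test", test), ("external", external)):
        if cohort is None:
            continue
        scores = predict_scores(model, cohort)
        reports = evaluate_scores(scores, cohort.labels, config.recall_targets)
        frames.append(sweep_frame(reports, dataset=name))
    metrics = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    metrics.to_csv(out / "metrics.csv", index=False)
    manifest["artifacts"]["metrics"] = "metrics.csv"
    stage("evaluate", datasets=[f["dataset"].iloc[0] for f in frames])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


_AXES = {
    "undersampler": lambda cfg, v: replace(cfg, undersampler=v),
    "metric": lambda cfg, v: replace(cfg, clustering=replace(cfg.clustering, metric=v)),
    "backend": lambda cfg, v: replace(cfg, backend=replace(cfg.backend, backend=v)),
    "ratio": lambda cfg, v: replace(cfg, r_target=float(v)),
}


def run_ablation(
    config: PipelineConfig,
    axis: str,
    values: list,
    n_seeds: int = 5,
    recall_target: float = 0.90,
) -> pd.DataFrame:
    """One pipeline run per (value, seed) with all else fixed.

    Returns a long-format table (axis value x seed x metrics at the given
    recall target) plus per-value means; single runs on stochastic
    pipelines are noise-dominated, hence the seed averaging.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    rows = []
    base_out = Path(config.output_dir)
    for value in values:
        for s in range(n_seeds):
            seed = derive_seed(config.seed, f"ablate:{axis}:{value}:{s}")
            cfg = _AXES[axis](config, value)
            cfg = replace(
                cfg,
                seed=seed,
                output_dir=base_out / f"ablate_{axis}_{value}_{s}",
                recall_targets=(recall_target,),
            )
            manifest = run_pipeline(cfg)
            metrics = pd.read_csv(Path(cfg.output_dir) / "metrics.csv")
            test_row = metrics[metrics["dataset"] == "test"].iloc[0]
            rows.append(
                {
                    "axis": axis,
                    "value": value,
                    "seed_index": s,
                    "f1": test_row["f1"],
                    "precision": test_row["precision"],
                    "specificity": test_row["specificity"],
                    "actual_recall": test_row["actual_recall"],
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(base_out / f"ablation_{axis}.csv", index=False)
    return table
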