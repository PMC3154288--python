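"""End-to-end orchestration: featurize -> clean -> normalize -> weight/select
-> clustering grid / trees / cross-validated networks, with the tabular
reports (attribute vote tally; weighting-method x clusterer grid).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import CleaningConfig, CleaningReport, clean, normalize
from .features import featurize
from .neural import NetTopology, TrainingConfig, cross_validate, mlp_factory
from .records import ProteinRecord
from .table import FeatureTable
from .trees import CRITERIA, TreeConfig, TreeModel, induce_tree
from .unsupervised import CLUSTERERS, ClusterConfig, ConfusionTable, evaluate_clusters
from .weighting import METHODS, SelectionResult, WeightingConfig, weighting_suite


@dataclass
class PipelineConfig:
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    weighting: WeightingConfig = field(default_factory=WeightingConfig)
    weighting_methods: tuple[str, ...] = METHODS
    selection_threshold: float = 0.5
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    clusterers: tuple[str, ...] = tuple(CLUSTERERS)
    tree_criteria: tuple[str, ...] = CRITERIA
    tree: TreeConfig = field(default_factory=TreeConfig)
    nn_topology: NetTopology = field(default_factory=lambda: NetTopology([10, 5]))
    nn_training: TrainingConfig = field(default_factory=TrainingConfig)
    cv_folds: int = 10
    run_neural: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    cleaning_report: CleaningReport
    weights: dict
    selections: dict[str, SelectionResult]
    weighting_failures: dict[str, str]
    votes: pd.Series
    grid: pd.DataFrame
    grid_cells: dict[tuple[str, str], ConfusionTable]
    tree_models: dict[str, TreeModel]
    cv_report: object | None
    manifest: dict


def votes_tally(selections: dict[str, SelectionResult], schema=None) -> pd.Series:
    """Attribute -> number of methods selecting it, sorted descending
    (ties by schema order when a schema is given)."""
    counts: dict[str, int] = {}
    for sel in selections.values():
        for attr in sel.selected:
            counts[attr] = counts.get(attr, 0) + 1
    if not counts:
        return pd.Series(dtype=int)
    order_key = schema.sort_key if schema is not None else (lambda a: a)
    names = sorted(counts, key=lambda a: (-counts[a], order_key(a)))
    return pd.Series([counts[a] for a in names], index=names, name="votes")


def build_grid(
    datasets: dict[str, FeatureTable],
    labels,
    clusterers: tuple[str, ...],
    config: ClusterConfig,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ConfusionTable], dict[tuple[str, str], str]]:
    """Cluster every dataset with every algorithm and evaluate against T/F.

    Returns the tabular grid (rows = clusterers; per dataset the mapped T
    and F counts and accuracy), the raw ConfusionTables, and any failures.
    """
    cells: dict[tuple[str, str], ConfusionTable] = {}
    failures: dict[tuple[str, str], str] = {}
    for ds_name, ds in datasets.items():
        for algo in clusterers:
            try:
                assignment = CLUSTERERS[algo](ds, config)
                cells[(algo, ds_name)] = evaluate_clusters(assignment, labels)
            except Exception as exc:  # noqa: BLE001 - grid isolates failures
                failures[(algo, ds_name)] = str(exc)
    columns = pd.MultiIndex.from_product(
        [list(datasets), ["T", "F", "accuracy"]], names=["dataset", "cell"]
    )
    grid = pd.DataFrame(index=list(clusterers), columns=columns, dtype=float)
    for (algo, ds_name), ct in cells.items():
        grid.loc[algo, (ds_name, "T")] = ct.n_pred_T
        grid.loc[algo, (ds_name, "F")] = ct.n_pred_F
        grid.loc[algo, (ds_name, "accuracy")] = ct.accuracy
    return grid, cells, failures


def run_full(
    records: list[ProteinRecord],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole pipeline on labelled records.

    The clustering grid covers the full cleaned dataset ("FCdb") plus one
    reduced dataset per weighting method; independent stage failures are
    recorded in the manifest without aborting the run.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    stages: list[dict] = []

    def log(stage: str, **info) -> None:
        stages.append({"stage": stage, "elapsed_s": round(time.time() - t0, 3), **info})

    table = featurize(records)
    log("featurize", n_records=table.n_records, n_attributes=table.n_attributes)

    cleaned, cleaning_report = clean(table, config.cleaning)
    normalized, minmax = normalize(cleaned)
    log("clean", n_records=normalized.n_records, n_attributes=normalized.n_attributes)

    vectors, selections, failures = weighting_suite(
        normalized,
        config.weighting,
        config.selection_threshold,
        config.weighting_methods,
    )
    votes = votes_tally(selections, normalized.schema)
    log("weighting", methods_ok=len(vectors), methods_failed=len(failures))

    datasets: dict[str, FeatureTable] = {"FCdb": normalized}
    for method, sel in selections.items():
        if sel.selected:
            datasets[method] = normalized.select(sel.selected)
    cluster_config = ClusterConfig(
        k=config.cluster.k,
        seed=config.seed,
        max_iter=config.cluster.max_iter,
        tol=config.cluster.tol,
        em_covariance=config.cluster.em_covariance,
        svc_q=config.cluster.svc_q,
        svc_C=config.cluster.svc_C,
        svc_segment_samples=config.cluster.svc_segment_samples,
        svc_max_n=config.cluster.svc_max_n,
    )
    grid, cells, grid_failures = build_grid(
        datasets, normalized.labels, config.clusterers, cluster_config
    )
    log("clustering_grid", n_datasets=len(datasets), n_failures=len(grid_failures))

    tree_models: dict[str, TreeModel] = {}
    for criterion in config.tree_criteria:
        tree_models[criterion] = induce_tree(
            normalized,
            TreeConfig(
                criterion=criterion,
                max_depth=config.tree.max_depth,
                min_leaf=config.tree.min_leaf,
                min_gain=config.tree.min_gain,
            ),
        )
    log("trees", criteria=list(config.tree_criteria))

    cv_report = None
    if config.run_neural:
        nn_cfg = TrainingConfig(
            learning_rate=config.nn_training.learning_rate,
            epochs=config.nn_training.epochs,
            seed=config.seed,
            batch_size=config.nn_training.batch_size,
            val_fraction=config.nn_training.val_fraction,
            patience=config.nn_training.patience,
            elman_context_steps=config.nn_training.elman_context_steps,
        )
        cv_report = cross_validate(
            normalized,
            mlp_factory(config.nn_topology, nn_cfg),
            k=config.cv_folds,
            seed=config.seed,
        )
        log("neural_cv", k=config.cv_folds)

    manifest = {
        "seed": config.seed,
        "stages": stages,
        "weighting_failures": failures,
        "grid_failures": {f"{a}/{d}": msg for (a, d), msg in grid_failures.items()},
        "datasets": {name: ds.n_attributes for name, ds in datasets.items()},
        "cleaning": cleaning_report.to_dict(),
    }
    result = PipelineResult(
        cleaning_report=cleaning_report,
        weights=vectors,
        selections=selections,
        weighting_failures=failures,
        votes=votes,
        grid=grid,
        grid_cells=cells,
        tree_models=tree_models,
        cv_report=cv_report,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_artifacts(result, normalized, minmax, Path(out_dir))
    return result


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(result: PipelineResult, table, minmax, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "weights").mkdir(exist_ok=True)
    (out_dir / "trees").mkdir(exist_ok=True)
    with open(out_dir / "cleaning.json", "w") as fh:
        json.dump(result.cleaning_report.to_dict(), fh, indent=1)
    with open(out_dir / "minmax.json", "w") as fh:
        json.dump(minmax.to_dict(), fh, indent=1)
    for method, wv in result.weights.items():
        pd.DataFrame({"raw": wv.raw, "normalized": wv.weights}).to_csv(
            out_dir / "weights" / f"{method}.tsv", sep="\t", index_label="attribute"
        )
    result.votes.to_csv(out_dir / "votes.tsv", sep="\t", index_label="attribute")
    result.grid.to_csv(out_dir / "grid.tsv", sep="\t")
    for criterion, model in result.tree_models.items():
        model.save(out_dir / "trees" / f"{criterion}.json")
    if result.cv_report is not None:
        with open(out_dir / "cv.json", "w") as fh:
            json.dump(result.cv_report.to_dict(), fh, indent=1)
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    result.manifest["artifact_hashes"] = {
        str(p.relative_to(out_dir)): _hash_file(p) for p in files
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)
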