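"""Benchmark orchestration: run integration strategies over hyperparameter
grids and score them on trajectory inference and classification.

The output is a long-format ScoreTable (one row per method, parameter
setting, task, metric, and replicate) that feeds
:func:`modalfuse.class_eval.aggregate_scores` for cross-dataset ranking.
Given identical seeds and inputs the table is bit-reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .bundle import BundleError, ModalityBundle
from .class_eval import ClassificationTask, label_propagation
from .integrate import run_method
from .preprocess import normalize
from .traj_eval import (
    predict_trajectory,
    reference_from_bundle,
    reference_feature_scores,
    score_trajectory,
)
from .velocity import add_velocity

log = logging.getLogger("modalfuse")

TASKS = ("classification", "trajectory")


@dataclass
class BenchmarkConfig:
    methods: List[str] = field(default_factory=lambda: ["unintegrated", "concat", "sum"])
    method_params: Dict[str, Dict[str, list]] = field(default_factory=dict)
    tasks: List[str] = field(default_factory=lambda: ["classification"])
    seeds: List[int] = field(default_factory=lambda: [0])
    dataset_name: str = "simulated"
    k: int = 10
    n_pcs: int = 50
    train_frac: float = 0.5
    n_replicates: int = 10
    n_roots: int = 10
    connectivity_threshold: float = 0.05
    n_trees: int = 100
    max_fcorr_genes: Optional[int] = 30

    def __post_init__(self) -> None:
        for task in self.tasks:
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}; choose from {TASKS}")
        if not all(isinstance(s, (int, np.integer)) for s in self.seeds):
            raise ValueError("seeds must be integers")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        for name, grid in self.method_params.items():
            for param, values in grid.items():
                vals = values if isinstance(values, (list, tuple)) else [values]
                for v in vals:
                    _check_param_range(name, param, v)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _check_param_range(method: str, param: str, value) -> None:
    checks = {
        ("cellrank", "lam"): lambda v: 0 <= v <= 1,
        ("snf", "mu"): lambda v: 0 < v,
        ("snf", "K_eigs"): lambda v: v >= 2,
        ("grassmann", "K_eigs"): lambda v: v >= 2,
        ("grassmann", "alpha"): lambda v: v >= 0,
        ("grassmann", "t"): lambda v: v is None or v > 0,
        ("intdiff", "n_clusters"): lambda v: v >= 2,
        ("precise", "n_pv"): lambda v: v >= 1,
        ("factor", "K"): lambda v: v >= 1,
    }
    fn = checks.get((method, param))
    if fn is not None and not fn(value):
        raise ValueError(f"{method}.{param}={value!r} outside its legal range")


def _expand_grid(grid: Dict[str, list]) -> List[Dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    values = [grid[k] if isinstance(grid[k], (list, tuple)) else [grid[k]] for k in keys]
    return [dict(zip(keys, combo)) for combo in itertools.product(*values)]


def _params_tag(params: Dict) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(params.items())) or "default"


def prepare_inputs(bundle: ModalityBundle, k: int = 10, n_pcs: int = 50) -> Dict[str, np.ndarray]:
    """Normalized inputs for the integration strategies.

    Most strategies consume the normalized log spliced/unspliced layers;
    the velocity-aware strategy consumes spliced moments plus the
    steady-state velocity layer computed on the normalized counts.
    """
    norm, _ = normalize(bundle, method="library_size")
    with_v = add_velocity(norm, k=k, n_pcs=n_pcs)
    return {
        "log_spliced": np.log1p(norm.layers["spliced"]),
        "log_unspliced": np.log1p(norm.layers["unspliced"]),
        "moments_spliced": with_v.layers["moments_spliced"],
        "velocity": with_v.layers["velocity"],
    }


def integrate_for_benchmark(
    name: str,
    inputs: Dict[str, np.ndarray],
    params: Dict,
    k: int,
    n_pcs: int,
    seed: int,
):
    params = dict(params)
    if name == "cellrank":
        params.setdefault("lam", 0.5)
        return run_method(
            "cellrank", inputs["moments_spliced"], inputs["velocity"],
            k=k, n_pcs=n_pcs, seed=seed, **params,
        )
    if name == "unintegrated":
        return run_method("unintegrated", inputs["log_spliced"], k=k, n_pcs=n_pcs, seed=seed, **params)
    kwargs = dict(seed=seed, **params)
    if name in ("concat", "sum", "wnn"):
        kwargs.update(k=k, n_pcs=n_pcs)
    else:
        kwargs.setdefault("k_out", k)
    return run_method(name, inputs["log_spliced"], inputs["log_unspliced"], **kwargs)


def run_benchmark(config: BenchmarkConfig, bundle: ModalityBundle) -> pd.DataFrame:
    """Score every (method, parameter setting, task, seed) combination.

    Returns the long-format ScoreTable with columns ``method, params,
    dataset, task, metric, replicate, seed, value``.
    """
    if "classification" in config.tasks:
        bundle.require_columns("condition_label")
    if "trajectory" in config.tasks:
        bundle.require_columns("cluster_label")
        if "topology" not in bundle.uns:
            raise BundleError("trajectory task needs a reference topology in bundle.uns")

    inputs = prepare_inputs(bundle, k=config.k, n_pcs=config.n_pcs)

    ref = ref_scores = expr = None
    if "trajectory" in config.tasks:
        ref = reference_from_bundle(bundle)
        expr = np.log1p(bundle.layers["spliced"])
        if config.max_fcorr_genes and expr.shape[1] > config.max_fcorr_genes:
            var = expr.var(axis=0)
            keep = np.sort(np.argsort(-var, kind="stable")[: config.max_fcorr_genes])
            expr = expr[:, keep]
        ref_scores = reference_feature_scores(ref, expr, n_trees=config.n_trees, seed=config.seeds[0])
        root_cluster = str(
            bundle.uns["topology"].root
            if "topology" in bundle.uns
            else bundle.cell_meta.loc[bundle.cell_meta["is_root_cluster"], "cluster_label"].iloc[0]
        )

    rows = []
    for name in config.methods:
        for params in _expand_grid(config.method_params.get(name, {})):
            tag = _params_tag(params)
            for seed in config.seeds:
                log.info("integrate method=%s params=%s seed=%d", name, tag, seed)
                result = integrate_for_benchmark(name, inputs, params, config.k, config.n_pcs, seed)
                graph = result.graph

                if "classification" in config.tasks:
                    task = ClassificationTask(
                        graph=graph,
                        y=bundle.cell_meta["condition_label"].to_numpy(),
                        train_frac=config.train_frac,
                        n_inits=config.n_replicates,
                    )
                    report = label_propagation(task, seed=seed)
                    for _, rec in report.metrics.iterrows():
                        for metric in ("F1", "acc_b", "AUC"):
                            rows.append(
                                dict(
                                    method=name, params=tag, dataset=config.dataset_name,
                                    task="classification", metric=metric,
                                    replicate=int(rec["replicate"]), seed=seed,
                                    value=float(rec[metric]),
                                )
                            )

                if "trajectory" in config.tasks:
                    preds = predict_trajectory(
                        graph,
                        bundle.cell_meta["cluster_label"].to_numpy(),
                        root_cluster=root_cluster,
                        n_roots=config.n_roots,
                        connectivity_threshold=config.connectivity_threshold,
                        seed=seed,
                    )
                    for r_i, pred in enumerate(preds):
                        score = score_trajectory(
                            ref, pred, expr, n_trees=config.n_trees,
                            seed=config.seeds[0], ref_scores=ref_scores,
                        )
                        for metric, value in (
                            ("C_corr", score.C_corr),
                            ("F_corr", score.F_corr),
                            ("TI_corr", score.TI_corr),
                        ):
                            rows.append(
                                dict(
                                    method=name, params=tag, dataset=config.dataset_name,
                                    task="trajectory", metric=metric,
                                    replicate=r_i, seed=seed, value=float(value),
                                )
                            )
    return pd.DataFrame(rows)
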