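"""The full classification workflow: encoder → Mapper partition → per-node
model pipelines → convex node weighting → decision threshold; plus grid
search over the Mapper parameters driven by cross-validated AUC."""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from mapperflow.core import ContractError, NotFittedError
from mapperflow.mapper import (
    Cover,
    MapperGraph,
    MapperParams,
    assign_new_points,
    build_mapper_graph,
)
from mapperflow.morphisms import (
    ClassifierModel,
    ConstantPriorModel,
    EncoderMap,
    StandardizeParams,
    ThresholdParams,
    apply_standardize,
    encode,
    fit_encoder,
    fit_pca,
    fit_standardize,
    rose_sample,
    smote_balance,
    threshold_fit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NodePipelineSpec",
    "NodePipeline",
    "NodeModel",
    "EnsembleWorkflow",
    "fit_node_models",
    "compute_weights",
    "ensemble_predict_proba",
    "fit_workflow",
    "predict",
]

_WEIGHT_SCHEMES = ("closest", "equal", "inverse_distance", "auc_proportional")


@dataclass(frozen=True)
class NodePipelineSpec:
    """Per-node model pipeline: optional PCA (with internal standardization),
    optional resampler applied to training folds only, and a classifier."""

    use_pca: bool = False
    pca_dims: int = 2
    sampler: str = "none"  # 'none' | 'smote' | 'rose'
    classifier: str = "logistic"
    hyper_grid: dict | None = None

    def __post_init__(self) -> None:
        if self.sampler not in ("none", "smote", "rose"):
            raise ContractError(f"unknown sampler {self.sampler!r}")


class NodePipeline:
    """Fit/predict wrapper implementing one NodePipelineSpec."""

    def __init__(self, spec: NodePipelineSpec, cv_folds: int = 10, seed: int = 0):
        self.spec = spec
        self.cv_folds = cv_folds
        self.seed = seed
        self.standardize_: StandardizeParams | None = None
        self.loadings_: np.ndarray | None = None
        self.clf_: ClassifierModel | None = None

    def _resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.spec.sampler == "none" or len(np.unique(y)) < 2:
            return X, y
        if self.spec.sampler == "smote":
            return smote_balance(X, y, seed=self.seed)
        return rose_sample(X, y, n_out=len(y), seed=self.seed)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if not self.spec.use_pca:
            return X
        Z = apply_standardize(X, self.standardize_)
        return Z @ self.loadings_.T

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NodePipeline":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).astype(int).ravel()
        Xs, ys = self._resample(X, y)
        if self.spec.use_pca:
            dims = min(self.spec.pca_dims, Xs.shape[1])
            self.standardize_ = fit_standardize(Xs)
            self.loadings_ = fit_pca(Xs, dims)
            Xs = self._transform(Xs)
        self.clf_ = ClassifierModel(
            self.spec.classifier, self.spec.hyper_grid, self.cv_folds, self.seed
        ).fit(Xs, ys)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.clf_ is None:
            raise NotFittedError("pipeline not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.clf_.predict_proba(self._transform(X))[:, 1]


@dataclass
class NodeModel:
    """A node's fitted pipeline with its cross-validated hold-out AUC and the
    pooled hold-out (score, label) pairs used for threshold tuning."""

    node_id: int
    spec: NodePipelineSpec
    pipeline: NodePipeline
    cv_auc: float
    holdout_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    holdout_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _cv_node(
    X: np.ndarray,
    y: np.ndarray,
    spec: NodePipelineSpec,
    cv_folds: int,
    seed: int,
) -> tuple[NodePipeline, float, np.ndarray, np.ndarray]:
    """Cross-validate one node: samplers touch training folds only, hold-out
    scores come from the untouched validation folds.  Returns the pipeline
    refitted on all node data plus (cv_auc, holdout scores, holdout labels)."""
    from mapperflow.evaluation import roc_auc

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        if len(classes) < 2:
            warnings.warn("single-class node; constant-prior fallback")
        pipe = NodePipeline(spec, cv_folds, seed)
        if len(classes) < 2:
            pipe.clf_ = ConstantPriorModel(float(classes[0]))
        else:
            pipe.fit(X, y)
        return pipe, 0.5, np.empty(0), np.empty(0, dtype=int)

    n_splits = min(cv_folds, int(counts.min()))
    if n_splits < cv_folds:
        logger.info("node CV folds reduced to %d", n_splits)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs, hs, hl = [], [], []
    for tr, va in cv.split(X, y):
        pipe = NodePipeline(spec, cv_folds, seed).fit(X[tr], y[tr])
        p = pipe.predict_proba(X[va])
        hs.append(p)
        hl.append(y[va])
        if len(np.unique(y[va])) == 2:
            aucs.append(roc_auc(y[va], p))
    cv_auc = float(np.mean(aucs)) if aucs else 0.5
    final = NodePipeline(spec, cv_folds, seed).fit(X, y)
    return final, cv_auc, np.concatenate(hs), np.concatenate(hl)


def fit_node_models(
    graph: MapperGraph,
    X_encoded: np.ndarray,
    y: np.ndarray,
    pipeline_spec: NodePipelineSpec,
    cv_folds: int = 10,
    seed: int = 0,
) -> list[NodeModel]:
    """Train one model pipeline per retained Mapper node on that node's
    member samples only."""
    if not graph.nodes:
        raise ContractError("graph has no retained nodes")
    X_encoded = np.atleast_2d(np.asarray(X_encoded, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    models = []
    for node in graph.nodes:
        pipe, auc, hs, hl = _cv_node(
            X_encoded[node.members], y[node.members], pipeline_spec, cv_folds, seed
        )
        models.append(
            NodeModel(
                node_id=node.id,
                spec=pipeline_spec,
                pipeline=pipe,
                cv_auc=auc,
                holdout_scores=hs,
                holdout_labels=hl,
            )
        )
    return models


def compute_weights(
    assignments: list[tuple[int, float]],
    scheme: str,
    node_models: Mapping[int, NodeModel] | None = None,
) -> np.ndarray:
    """Convex weights over the assigned nodes.

    ``closest`` puts all mass on the nearest node; ``equal`` splits mass
    evenly; ``inverse_distance`` weights by 1/(d+ε); ``auc_proportional``
    weights by each node's cross-validated AUC relative to the pair total.
    The result is always nonnegative and sums to one.
    """
    if not assignments:
        raise ContractError("empty assignment")
    if scheme not in _WEIGHT_SCHEMES:
        if scheme == "trained":
            raise NotImplementedError(
                "training weights within cross validation is not implemented"
            )
        raise ContractError(f"unknown weight scheme {scheme!r}")
    m = len(assignments)
    if scheme == "closest" or m == 1:
        w = np.zeros(m)
        w[int(np.argmin([d for _, d in assignments]))] = 1.0
        return w
    if scheme == "equal":
        return np.full(m, 1.0 / m)
    if scheme == "inverse_distance":
        inv = np.array([1.0 / (d + 1e-9) for _, d in assignments])
        return inv / inv.sum()
    # auc_proportional
    if node_models is None:
        raise ContractError("auc_proportional needs node models")
    aucs = np.array([node_models[i].cv_auc for i, _ in assignments])
    if aucs.sum() <= 0:
        return np.full(m, 1.0 / m)
    return aucs / aucs.sum()


@dataclass
class EnsembleWorkflow:
    """Fitted end-to-end pipeline.

    When ``graph`` is None the workflow degenerates to the single global
    pipeline stored in ``global_model``.
    """

    encoder: EncoderMap
    column_spec: list[dict]
    graph: MapperGraph | None
    filtration: Any
    cover: Cover | None
    mapper_params: MapperParams | None
    node_models: dict[int, NodeModel]
    weight_scheme: str
    max_nodes: int
    threshold: ThresholdParams
    global_model: NodeModel | None = None
    selection_score: float = float("nan")
    grid_scores: list[dict] = field(default_factory=list)


def ensemble_predict_proba(
    workflow: EnsembleWorkflow,
    X_table: pd.DataFrame,
    return_details: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[dict]]:
    """Convex blend of node-model probabilities for each input point."""
    Xe = encode(workflow.encoder, X_table)
    if workflow.graph is None:
        p = workflow.global_model.pipeline.predict_proba(Xe)
        if return_details:
            details = [
                {"assignments": [(-1, 0.0)], "weights": np.array([1.0]),
                 "node_probs": np.array([pi])}
                for pi in p
            ]
            return p, details
        return p

    assignments = assign_new_points(
        workflow.graph, workflow.filtration, workflow.cover,
        X_table, Xe, workflow.max_nodes,
    )
    # batch the per-node probability calls
    need: dict[int, list[int]] = {}
    for r, picks in enumerate(assignments):
        for node_id, _ in picks:
            need.setdefault(node_id, []).append(r)
    probs: dict[int, dict[int, float]] = {}
    for node_id, rows in need.items():
        p = workflow.node_models[node_id].pipeline.predict_proba(Xe[rows])
        probs[node_id] = dict(zip(rows, p))

    out = np.empty(len(X_table))
    details = []
    for r, picks in enumerate(assignments):
        w = compute_weights(picks, workflow.weight_scheme, workflow.node_models)
        node_p = np.array([probs[node_id][r] for node_id, _ in picks])
        out[r] = float(w @ node_p)
        if return_details:
            details.append({"assignments": picks, "weights": w, "node_probs": node_p})
    if return_details:
        return out, details
    return out


def predict(workflow: EnsembleWorkflow, X_table: pd.DataFrame) -> np.ndarray:
    """Hard labels: boundary-inclusive threshold on ensemble probabilities."""
    from mapperflow.morphisms import threshold_apply

    return threshold_apply(ensemble_predict_proba(workflow, X_table),
                           workflow.threshold)


# --------------------------------------------------------------- fit_workflow
_DEFAULT_CONFIG: dict = {
    "mapper": {
        "enabled": True,
        "grid": {"k": [5, 10, 15, 20], "o": [0.2, 0.4, 0.6], "b": [5, 15, 30]},
        "min_node_size": 40,
        "distance": "gower",
        "filtration": "pc1",
    },
    "pipeline": {},
    "weights": {"scheme": "equal", "max_nodes": 2},
    "threshold": {"criterion": "youden"},
    "cv_folds": 10,
}


def _merge(default: Mapping, user: Mapping) -> dict:
    out = dict(default)
    for k, v in user.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _selection_auc(models: list[NodeModel], graph: MapperGraph) -> float:
    """Member-count-weighted mean of node hold-out AUCs."""
    sizes = np.array([len(graph.node(m.node_id).members) for m in models], dtype=float)
    aucs = np.array([m.cv_auc for m in models])
    return float((sizes * aucs).sum() / sizes.sum())


def fit_workflow(
    X_table: pd.DataFrame,
    y: np.ndarray,
    config: Mapping | None = None,
    seed: int = 0,
) -> EnsembleWorkflow:
    """Fit the complete workflow, grid-searching the Mapper parameters.

    For each (k, o, b) grid point (row-major order, first maximum wins) the
    graph is built, node models are cross-validated, and the configuration
    maximising the size-weighted mean CV hold-out AUC is kept.  The decision
    threshold is then tuned on the pooled CV hold-out scores.  With
    ``mapper.enabled=False`` the workflow is a single global pipeline.
    """
    cfg = _merge(_DEFAULT_CONFIG, config or {})
    y = np.asarray(y).astype(int).ravel()
    if len(np.unique(y)) != 2:
        raise ContractError("binary outcome required")

    column_spec = cfg.get("column_spec")
    encoder = fit_encoder(X_table, column_spec)
    if column_spec is None:
        from mapperflow.morphisms import infer_column_spec

        column_spec = infer_column_spec(X_table)
    Xe = encode(encoder, X_table)

    pipeline_spec = NodePipelineSpec(**cfg["pipeline"])
    cv_folds = int(cfg["cv_folds"])
    wcfg = cfg["weights"]
    tcfg = cfg["threshold"]
    mcfg = cfg["mapper"]

    if not mcfg.get("enabled", True):
        pipe, auc, hs, hl = _cv_node(Xe, y, pipeline_spec, cv_folds, seed)
        thr = (
            threshold_fit(hs, hl, tcfg.get("criterion", "youden"))
            if len(hs)
            else ThresholdParams(0.5)
        )
        gm = NodeModel(node_id=-1, spec=pipeline_spec, pipeline=pipe, cv_auc=auc,
                       holdout_scores=hs, holdout_labels=hl)
        return EnsembleWorkflow(
            encoder=encoder, column_spec=column_spec, graph=None, filtration=None,
            cover=None, mapper_params=None, node_models={}, weight_scheme="closest",
            max_nodes=1, threshold=thr, global_model=gm, selection_score=auc,
        )

    if "fixed" in mcfg:
        f = mcfg["fixed"]
        grid_points = [(int(f["k"]), float(f["o"]), int(f["b"]))]
    else:
        g = mcfg["grid"]
        grid_points = [
            (int(k), float(o), int(b))
            for k, o, b in itertools.product(g["k"], g["o"], g["b"])
        ]
    if not grid_points:
        raise ContractError("empty Mapper grid")

    best = None
    grid_scores = []
    for k, o, b in grid_points:
        params = MapperParams(
            k=k, o=o, b=b,
            min_node_size=int(mcfg.get("min_node_size", 40)),
            filtration=mcfg.get("filtration", "pc1"),
            distance=mcfg.get("distance", "gower"),
        )
        try:
            graph, filtration = build_mapper_graph(X_table, Xe, params, column_spec)
        except ContractError as exc:
            logger.info("grid point (k=%d, o=%.2f, b=%d) skipped: %s", k, o, b, exc)
            grid_scores.append({"k": k, "o": o, "b": b, "cv_auc": float("nan")})
            continue
        models = fit_node_models(graph, Xe, y, pipeline_spec, cv_folds, seed)
        score = _selection_auc(models, graph)
        grid_scores.append({"k": k, "o": o, "b": b, "cv_auc": score})
        if best is None or score > best[0]:
            best = (score, params, graph, filtration, models)

    if best is None:
        raise ContractError("no Mapper grid point produced a graph; "
                            "lower min_node_size")
    score, params, graph, filtration, models = best
    hs = np.concatenate([m.holdout_scores for m in models]) if models else np.empty(0)
    hl = np.concatenate([m.holdout_labels for m in models]) if models else np.empty(0)
    if len(hs) and len(np.unique(hl)) == 2:
        thr = threshold_fit(hs, hl, tcfg.get("criterion", "youden"))
    else:
        thr = ThresholdParams(0.5)

    return EnsembleWorkflow(
        encoder=encoder,
        column_spec=column_spec,
        graph=graph,
        filtration=filtration,
        cover=graph.cover,
        mapper_params=params,
        node_models={m.node_id: m for m in models},
        weight_scheme=wcfg.get("scheme", "equal"),
        max_nodes=int(wcfg.get("max_nodes", 2)),
        threshold=thr,
        selection_score=score,
        grid_scores=grid_scores,
    )
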