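"""Metrics, repeated-holdout protocol, and workflow comparison tables."""

from __future__ import annotations

import warnings
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from mapperflow.core import ContractError
from mapperflow.morphisms import threshold_apply

__all__ = [
    "roc_auc",
    "binary_metrics",
    "metric_by_name",
    "split_sizes",
    "cohort_summary",
    "repeated_holdout",
    "compare_workflows",
]

METRIC_NAMES = ("roc_auc", "sensitivity", "specificity", "accuracy")


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank (Mann–Whitney) statistic with midranks for ties."""
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ContractError("roc_auc undefined: y_true has a single class")
    r = rankdata(s)  # average (mid) ranks for ties
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def binary_metrics(
    y_true: np.ndarray, scores: np.ndarray, T: float = 0.5
) -> dict[str, float]:
    """AUC plus sensitivity/specificity/accuracy at threshold ``T``
    (boundary-inclusive: score ≥ T predicts 1)."""
    y = np.asarray(y_true).astype(int).ravel()
    pred = threshold_apply(scores, T)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    if tp + fn == 0 or tn + fp == 0:
        raise ContractError("binary_metrics undefined: y_true has a single class")
    return {
        "roc_auc": roc_auc(y, scores),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
    }


def metric_by_name(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    """Registered performance measures operating on (y_true, scores)."""
    if name == "roc_auc":
        return roc_auc
    if name in ("sensitivity", "specificity", "accuracy"):
        return lambda y, s: binary_metrics(y, s)[name]
    raise ContractError(f"unknown metric {name!r}")


def split_sizes(n: int, train_frac: float = 0.8) -> tuple[int, int]:
    """(n_train, n_test) with the test size rounded down."""
    n_test = int(np.floor((1.0 - train_frac) * n))
    return n - n_test, n_test


def cohort_summary(y: np.ndarray) -> dict[str, float]:
    """Counts and minority prevalence (percent, one decimal) of a label vector."""
    y = np.asarray(y).astype(int).ravel()
    n = len(y)
    n_pos = int(np.sum(y == 1))
    return {
        "n": n,
        "n_positive": n_pos,
        "prevalence_pct": round(100.0 * n_pos / n, 1),
    }


def _fit_and_score(
    X_table: pd.DataFrame,
    y: np.ndarray,
    config: Mapping,
    seed: int,
    train_frac: float,
) -> dict[str, float]:
    from mapperflow.ensemble import ensemble_predict_proba, fit_workflow

    n_train, n_test = split_sizes(len(y), train_frac)
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed, shuffle=True
    )
    wf = fit_workflow(X_table.iloc[tr].reset_index(drop=True), y[tr], config, seed=seed)
    scores = ensemble_predict_proba(wf, X_table.iloc[te].reset_index(drop=True))
    return binary_metrics(y[te], scores, T=wf.threshold.T)


def repeated_holdout(
    X_table: pd.DataFrame,
    y: np.ndarray,
    workflow_config: Mapping,
    n_runs: int = 10,
    train_frac: float = 0.8,
    base_seed: int = 0,
) -> dict[str, float]:
    """Stratified repeated 80/20 holdout: fit on train, score on test, report
    mean and sample (n−1) std of each metric across ``n_runs`` splits."""
    y = np.asarray(y).astype(int).ravel()
    rows = [
        _fit_and_score(X_table, y, workflow_config, base_seed + i, train_frac)
        for i in range(n_runs)
    ]
    out: dict[str, float] = {}
    for m in METRIC_NAMES:
        vals = np.array([r[m] for r in rows])
        out[f"{m}_mean"] = float(vals.mean())
        if n_runs == 1:
            warnings.warn("n_runs=1: std reported as 0")
            out[f"{m}_std"] = 0.0
        else:
            out[f"{m}_std"] = float(vals.std(ddof=1))
    return out


def compare_workflows(
    configs: Mapping[str, Mapping],
    X_table: pd.DataFrame,
    y: np.ndarray,
    n_runs: int = 10,
    base_seed: int = 0,
    train_frac: float = 0.8,
) -> pd.DataFrame:
    """One row of mean/std metrics per named config, with the same split
    seeds shared across configs (paired comparison).  ``configs`` is a
    mapping or a sequence of (name, config) pairs."""
    pairs = list(configs.items()) if isinstance(configs, Mapping) else list(configs)
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ContractError("duplicate workflow names")
    rows = {
        name: repeated_holdout(X_table, y, cfg, n_runs, train_frac, base_seed)
        for name, cfg in pairs
    }
    return pd.DataFrame.from_dict(rows, orient="index")
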