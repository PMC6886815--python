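"""Seeded generators for cohorts with the structure the workflow targets:
mixed continuous/categorical features, a rare binary outcome, and latent
groups along the dominant variance direction whose feature–outcome effects
may flip sign between groups."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from mapperflow.core import ContractError

__all__ = [
    "CohortSpec",
    "generate_mixed_imbalanced",
    "column_spec_for",
    "generate_noisy_circle",
    "generate_orthogonal_design",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for :func:`generate_mixed_imbalanced`.

    ``effect_flip`` multiplies the base logistic coefficients per latent
    group; a mix of +1/−1 plants the group-dependent sign reversal that a
    single global model cannot represent.  ``group_sep`` controls the gap
    between group centers along the first numeric axis, which dominates the
    covariance and therefore the first principal component.
    """

    n: int = 776
    n_numeric: int = 4
    n_categorical: int = 2
    levels: int = 3
    minority_frac: float = 0.173
    n_groups: int = 2
    effect_flip: tuple[float, ...] | None = None
    base_coefs: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    group_sep: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.minority_frac < 1.0):
            raise ContractError("minority_frac must lie in (0, 1)")
        if self.n_groups < 1:
            raise ContractError("n_groups must be >= 1")
        if self.effect_flip is not None and len(self.effect_flip) != self.n_groups:
            raise ContractError("effect_flip length must equal n_groups")
        if self.base_coefs is not None and len(self.base_coefs) != self.n_numeric:
            raise ContractError("base_coefs length must equal n_numeric")


def _default_coefs(n_numeric: int) -> np.ndarray:
    base = np.array([1.5, -1.0, 0.75, -0.5])
    reps = int(np.ceil(n_numeric / len(base)))
    return np.tile(base, reps)[:n_numeric]


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection for the shift t with mean(sigmoid(t + eta)) = target."""
    lo, hi = -30.0, 30.0
    if expit(lo + eta).mean() > target or expit(hi + eta).mean() < target:
        raise ContractError("target prevalence unreachable for these coefficients")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = expit(mid + eta).mean()
        if abs(p - target) < tol:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_mixed_imbalanced(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate ``(X_table, y, group_labels)``.

    Numeric features are group-shifted Gaussians (groups separated along the
    first axis); categorical level probabilities depend on the group; the
    outcome follows a logistic model on the *group-centered* numeric features
    with group-specific coefficient signs, and a shared intercept shift is
    calibrated by bisection so overall prevalence hits ``minority_frac``.
    """
    rng = np.random.default_rng(spec.seed)
    n, G = spec.n, spec.n_groups
    groups = rng.integers(0, G, size=n)

    # spread the group offset over every numeric column so the group
    # direction still dominates after per-column standardization
    direction = np.ones(spec.n_numeric) / np.sqrt(spec.n_numeric)
    offsets = (np.arange(G) - (G - 1) / 2.0) * spec.group_sep
    centers = offsets[:, None] * direction[None, :]
    X_num = rng.standard_normal((n, spec.n_numeric)) * spec.noise_sd
    X_num += centers[groups]

    data: dict[str, np.ndarray] = {}
    for j in range(spec.n_numeric):
        data[f"num{j}"] = X_num[:, j]

    L = spec.levels
    level_names = [f"l{v}" for v in range(L)]
    base_probs = 0.25 ** np.arange(L, dtype=float)  # sharply peaked per group
    base_probs /= base_probs.sum()
    for c in range(spec.n_categorical):
        vals = np.empty(n, dtype=object)
        for g in range(G):
            mask = groups == g
            probs = np.roll(base_probs, g + c)
            vals[mask] = rng.choice(level_names, size=int(mask.sum()), p=probs)
        data[f"cat{c}"] = vals

    coefs = (
        np.asarray(spec.base_coefs, dtype=float)
        if spec.base_coefs is not None
        else _default_coefs(spec.n_numeric)
    )
    flips = (
        np.asarray(spec.effect_flip, dtype=float)
        if spec.effect_flip is not None
        else np.ones(G)
    )
    centered = X_num - centers[groups]
    eta = flips[groups] * (centered @ coefs)
    t = _calibrate_intercept(eta, spec.minority_frac)
    y = rng.binomial(1, expit(t + eta)).astype(int)

    X_table = pd.DataFrame(data)
    return X_table, y, groups


def column_spec_for(spec: CohortSpec) -> list[dict]:
    """Column-type sidecar matching :func:`generate_mixed_imbalanced` output."""
    cols = [{"name": f"num{j}", "kind": "continuous"} for j in range(spec.n_numeric)]
    cols += [
        {"name": f"cat{c}", "kind": "categorical"} for c in range(spec.n_categorical)
    ]
    return cols


def generate_noisy_circle(
    n: int, radius: float = 1.0, noise_sd: float = 0.05, seed: int = 0
) -> np.ndarray:
    """2-D points at ``radius + N(0, noise_sd)`` around a circle."""
    if n < 50:
        raise ContractError("n must be >= 50")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = radius + rng.standard_normal(n) * noise_sd
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_orthogonal_design(
    n: int,
    m: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    p_true: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design with exactly orthogonal columns plus a linear response.

    Columns come from the QR factorization of a seeded Gaussian matrix, so
    ``XᵀX`` is the identity (off-diagonals < 1e−10 numerically).  Returns
    ``(X, Y, p_true)`` with ``Y = X·p_true + noise``.
    """
    if n < m:
        raise ContractError("need n >= m")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
    if p_true is None:
        p_true = rng.standard_normal(m) * 2.0
    p_true = np.asarray(p_true, dtype=float)
    Y = Q @ p_true
    if noise_sd > 0:
        Y = Y + rng.standard_normal(n) * noise_sd
    return Q, Y, p_true
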