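"""Risk-minimizing morphisms: fit, apply, composition, direct sums, collections.

A :class:`Morphism` bundles a parametric map ``F(x; p)`` with an empirical
risk function and a parameter prior.  Fitting a morphism means minimising the
risk over training realizations; unsupervised morphisms are fitted with an
empty outcome vector.  Morphisms compose sequentially or jointly, and two
morphisms whose risks add may be fitted independently (direct sum).
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ContractError",
    "NotFittedError",
    "SpaceDescriptor",
    "Prior",
    "Morphism",
    "Collection",
    "compose",
    "direct_sum",
    "evaluate_collection",
    "select_best",
    "register_kind",
    "morphism_from_json",
]


class ContractError(ValueError):
    """An input violates a morphism's declared contract."""


class NotFittedError(RuntimeError):
    """The morphism was applied before being fitted."""


_COLUMN_KINDS = frozenset({"continuous", "categorical", "probability", "label"})


@dataclass(frozen=True)
class SpaceDescriptor:
    """Shape and per-column kind of a data space.

    ``dim`` is ``None`` for abstract spaces (e.g. raw mixed-type tables)
    where no numeric dimension applies.
    """

    dim: int | None = None
    kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for k in self.kinds:
            if k not in _COLUMN_KINDS:
                raise ContractError(f"unknown column kind {k!r}")
        if self.kinds and self.dim is not None and len(self.kinds) != self.dim:
            raise ContractError("kinds length must match dim")

    @classmethod
    def continuous(cls, dim: int) -> "SpaceDescriptor":
        return cls(dim=dim, kinds=("continuous",) * dim)

    @classmethod
    def probability(cls) -> "SpaceDescriptor":
        return cls(dim=1, kinds=("probability",))

    @classmethod
    def label(cls) -> "SpaceDescriptor":
        return cls(dim=1, kinds=("label",))

    @classmethod
    def abstract(cls) -> "SpaceDescriptor":
        return cls(dim=None)

    def to_dict(self) -> dict:
        return {"dim": self.dim, "kinds": list(self.kinds)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpaceDescriptor":
        return cls(dim=d["dim"], kinds=tuple(d["kinds"]))


_PRIOR_KINDS = frozenset({"improper-uniform", "uniform-box", "point-mass", "gaussian"})


@dataclass(frozen=True)
class Prior:
    """Parameter-prior descriptor consumed by solvers that support one.

    * ``improper-uniform`` — the default flat prior; imposes no constraint.
    * ``uniform-box`` — ``low``/``high`` arrays bounding a grid search.
    * ``point-mass`` — fixes the parameter at ``value``.
    * ``gaussian`` — ``mean``/``sd`` metadata for solvers that regularise.
    """

    kind: str = "improper-uniform"
    low: Any = None
    high: Any = None
    value: Any = None
    mean: Any = None
    sd: Any = None

    def __post_init__(self) -> None:
        if self.kind not in _PRIOR_KINDS:
            raise ContractError(f"unknown prior kind {self.kind!r}")

    def grid(self, num: int = 21) -> np.ndarray:
        """Candidate parameter grid for a uniform-box prior."""
        if self.kind == "point-mass":
            return np.asarray([self.value], dtype=float)
        if self.kind != "uniform-box":
            raise ContractError("grid requires a uniform-box or point-mass prior")
        low = np.atleast_1d(np.asarray(self.low, dtype=float))
        high = np.atleast_1d(np.asarray(self.high, dtype=float))
        axes = [np.linspace(lo, hi, num) for lo, hi in zip(low, high)]
        if len(axes) == 1:
            return axes[0][:, None]
        return np.array(list(itertools.product(*axes)))


def _as_2d(x: Any) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


class Morphism:
    """A parametric map fitted by minimising an empirical risk.

    Parameters
    ----------
    kind:
        Short identifier used for serialization and repr.
    morphism:
        ``F(X, params) -> outputs``; receives a 2-D array (or whatever the
        abstract input space carries) and the fitted parameters.
    risk:
        ``risk(params, X, Y) -> float``.  Optional for morphisms whose solver
        is closed-form, but required for grid solvers and joint composition.
    solver:
        ``solver(X, Y, prior) -> params``.  When omitted, fitting performs a
        grid search over ``prior.grid()`` minimising ``risk``.
    supervised:
        Whether ``fit`` requires a non-empty outcome vector.
    """

    def __init__(
        self,
        kind: str,
        input_space: SpaceDescriptor,
        output_space: SpaceDescriptor,
        morphism: Callable[[Any, Any], Any],
        risk: Callable[[Any, Any, Any], float] | None = None,
        solver: Callable[[Any, Any, Prior], Any] | None = None,
        prior: Prior | None = None,
        supervised: bool = True,
        validate_input: Callable[[Any], None] | None = None,
    ) -> None:
        self.kind = kind
        self.input_space = input_space
        self.output_space = output_space
        self.morphism = morphism
        self.risk = risk
        self.solver = solver
        self.prior = prior if prior is not None else Prior()
        self.supervised = supervised
        self.validate_input = validate_input
        self.params: Any = None
        self.fitted: bool = False

    # ------------------------------------------------------------------ fit
    def _check_X(self, X: Any) -> None:
        if X is None:
            raise ContractError("X must be nonempty")
        if self.validate_input is not None:
            self.validate_input(X)
            return
        if self.input_space.dim is not None:
            arr, _ = _as_2d(X)
            if arr.shape[1] != self.input_space.dim:
                raise ContractError(
                    f"{self.kind}: expected {self.input_space.dim} columns, "
                    f"got {arr.shape[1]}"
                )

    def fit(self, X: Any, Y: Any = None) -> "Morphism":
        """Set ``params`` to the risk minimizer on the training realizations."""
        self._check_X(X)
        n = len(X)
        if n == 0:
            raise ContractError("X must be nonempty")
        if self.supervised:
            if Y is None or len(np.atleast_1d(Y)) == 0:
                raise ContractError(f"{self.kind}: supervised morphism needs Y")
            if len(np.atleast_1d(Y)) != n:
                raise ContractError(f"{self.kind}: Y length {len(Y)} != X rows {n}")
        if self.solver is not None:
            self.params = self.solver(X, Y, self.prior)
        else:
            self.params = self._grid_solve(X, Y)
        self.fitted = True
        return self

    def _grid_solve(self, X: Any, Y: Any) -> Any:
        if self.risk is None:
            raise ContractError(f"{self.kind}: no solver and no risk to minimise")
        grid = self.prior.grid()
        values = [self.risk(p, X, Y) for p in grid]
        return grid[int(np.argmin(values))]

    # ---------------------------------------------------------------- apply
    def apply(self, x: Any) -> Any:
        """Evaluate ``F(x; params)``, vectorizing row-wise over matrices."""
        if not self.fitted:
            raise NotFittedError(f"{self.kind}: apply before fit")
        if self.validate_input is not None:
            self.validate_input(x)
            return self.morphism(x, self.params)
        if self.input_space.dim is not None:
            arr, was_1d = _as_2d(x)
            if arr.shape[1] != self.input_space.dim:
                raise ContractError(
                    f"{self.kind}: expected {self.input_space.dim} columns, "
                    f"got {arr.shape[1]}"
                )
            out = self.morphism(arr, self.params)
            if was_1d:
                out = np.asarray(out)[0]
            return out
        return self.morphism(x, self.params)

    def __call__(self, x: Any) -> Any:
        return self.apply(x)

    def risk_at(self, params: Any, X: Any, Y: Any = None) -> float:
        if self.risk is None:
            raise ContractError(f"{self.kind}: no risk declared")
        return float(self.risk(params, X, Y))

    def clone(self) -> "Morphism":
        """Unfitted deep copy."""
        c = copy.deepcopy(self)
        c.params = None
        c.fitted = False
        return c

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "fitted" if self.fitted else "unfitted"
        return f"<Morphism {self.kind} ({state})>"

    # -------------------------------------------------------- serialization
    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "input_space": self.input_space.to_dict(),
            "output_space": self.output_space.to_dict(),
            "fitted": self.fitted,
            "params": _params_to_jsonable(self.params),
        }
        return json.dumps(payload)


def _params_to_jsonable(params: Any) -> Any:
    if params is None:
        return None
    if isinstance(params, np.ndarray):
        return {"__ndarray__": params.tolist()}
    if isinstance(params, (list, tuple)):
        return [_params_to_jsonable(p) for p in params]
    if isinstance(params, dict):
        return {k: _params_to_jsonable(v) for k, v in params.items()}
    if isinstance(params, (int, float, str, bool)):
        return params
    if hasattr(params, "to_jsonable"):
        return params.to_jsonable()
    raise TypeError(f"cannot serialize params of type {type(params)}")


def _params_from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict) and "__ndarray__" in obj:
        return np.asarray(obj["__ndarray__"], dtype=float)
    if isinstance(obj, list):
        return tuple(_params_from_jsonable(o) for o in obj)
    if isinstance(obj, dict):
        return {k: _params_from_jsonable(v) for k, v in obj.items()}
    return obj


_KIND_REGISTRY: dict[str, Callable[..., Morphism]] = {}


def register_kind(kind: str, factory: Callable[..., Morphism]) -> None:
    """Register a zero-argument factory used by :func:`morphism_from_json`."""
    _KIND_REGISTRY[kind] = factory


def morphism_from_json(payload: str) -> Morphism:
    d = json.loads(payload)
    kind = d["kind"]
    if kind not in _KIND_REGISTRY:
        raise ContractError(f"no registered factory for kind {kind!r}")
    m = _KIND_REGISTRY[kind]()
    m.params = _params_from_jsonable(d["params"])
    m.fitted = bool(d["fitted"])
    return m


# ------------------------------------------------------------- composition
class ComposedMorphism(Morphism):
    """``outer ∘ inner``; fit/apply delegate to the two fitted factors so
    cloning keeps the pair self-contained."""

    def __init__(self, outer: Morphism, inner: Morphism, mode: str) -> None:
        super().__init__(
            kind=f"{outer.kind}*{inner.kind}",
            input_space=inner.input_space,
            output_space=outer.output_space,
            morphism=lambda x, p: None,  # unused; apply is overridden
            supervised=outer.supervised,
            validate_input=inner.validate_input,
        )
        self.inner = inner.clone()
        self.outer = outer.clone()
        self.mode = mode

    def fit(self, X: Any, Y: Any = None) -> "ComposedMorphism":
        self._check_X(X)
        if self.mode == "sequential":
            self.inner.fit(X, Y if self.inner.supervised else None)
            Z = self.inner.apply(X)
            self.outer.fit(Z, Y)
        else:  # joint grid search over the product parameter space
            if self.outer.risk is None:
                raise ContractError("joint composition requires an outer risk")
            g1 = self.inner.prior.grid()
            g2 = self.outer.prior.grid()
            best, best_val = None, np.inf
            for p1 in g1:
                self.inner.params, self.inner.fitted = p1, True
                Z = self.inner.apply(X)
                for p2 in g2:
                    val = self.outer.risk(p2, Z, Y)
                    if val < best_val:
                        best_val, best = val, (np.array(p1), np.array(p2))
            self.inner.params, self.inner.fitted = best[0], True
            self.outer.params, self.outer.fitted = best[1], True
        self.params = (self.inner.params, self.outer.params)
        self.fitted = True
        return self

    def apply(self, x: Any) -> Any:
        if not self.fitted:
            raise NotFittedError(f"{self.kind}: apply before fit")
        return self.outer.apply(self.inner.apply(x))


def compose(outer: Morphism, inner: Morphism, mode: str = "sequential") -> Morphism:
    """Compose two morphisms: result maps ``x`` to ``outer(inner(x))``.

    ``sequential`` fits the inner morphism first, transforms the training
    data and then fits the outer morphism on the transformed realizations.
    ``joint`` minimises the outer risk over the product of both parameter
    grids (uniform-box or point-mass priors required on both factors).
    """
    if mode not in ("sequential", "joint"):
        raise ContractError(f"unknown composition mode {mode!r}")
    a, b = inner.output_space, outer.input_space
    # abstract spaces (dim None) are compatible with anything
    if a.dim is not None and b.dim is not None and a != b:
        raise ContractError(
            f"space mismatch: inner output {a} != outer input {b}"
        )
    return ComposedMorphism(outer, inner, mode)


class DirectSumMorphism(Morphism):
    """Two morphisms on concatenated inputs combined by a closed operation;
    the summed risk makes independent fitting optimal."""

    def __init__(
        self, ml1: Morphism, ml2: Morphism, op: Callable, a: float, b: float
    ) -> None:
        d1 = ml1.input_space.dim
        super().__init__(
            kind=f"{ml1.kind}+{ml2.kind}",
            input_space=SpaceDescriptor(
                dim=d1 + ml2.input_space.dim,
                kinds=ml1.input_space.kinds + ml2.input_space.kinds,
            ),
            output_space=ml1.output_space,
            morphism=lambda x, p: None,
            supervised=ml1.supervised or ml2.supervised,
        )
        self.m1 = ml1.clone()
        self.m2 = ml2.clone()
        self.op = op
        self.a = a
        self.b = b
        self._d1 = d1
        if ml1.risk is not None and ml2.risk is not None:
            self.risk = self._sum_risk

    def _split(self, X: Any) -> tuple[np.ndarray, np.ndarray]:
        arr, _ = _as_2d(X)
        return arr[:, : self._d1], arr[:, self._d1 :]

    def _sum_risk(self, params: Any, X: Any, Y: Any) -> float:
        p1, p2 = params
        X1, X2 = self._split(X)
        return self.a * self.m1.risk(p1, X1, Y) + self.b * self.m2.risk(p2, X2, Y)

    def fit(self, X: Any, Y: Any = None) -> "DirectSumMorphism":
        self._check_X(X)
        X1, X2 = self._split(X)
        self.m1.fit(X1, Y if self.m1.supervised else None)
        self.m2.fit(X2, Y if self.m2.supervised else None)
        self.params = (self.m1.params, self.m2.params)
        self.fitted = True
        return self

    def apply(self, x: Any) -> Any:
        if not self.fitted:
            raise NotFittedError(f"{self.kind}: apply before fit")
        arr, was_1d = _as_2d(x)
        X1, X2 = arr[:, : self._d1], arr[:, self._d1 :]
        out = self.op(self.m1.apply(X1), self.m2.apply(X2))
        if was_1d:
            out = np.asarray(out).ravel()[0]
        return out


def direct_sum(
    ml1: Morphism,
    ml2: Morphism,
    op: Callable[[Any, Any], Any],
    a: float = 1.0,
    b: float = 1.0,
) -> Morphism:
    """Combine two morphisms on concatenated inputs with a closed operation.

    The result's risk is ``a*R1 + b*R2``, so fitting it is equivalent to
    fitting the two members independently; ``fit`` does exactly that.
    """
    if a <= 0 or b <= 0:
        raise ContractError("weights a, b must be positive")
    if ml1.output_space != ml2.output_space:
        raise ContractError("direct_sum requires a shared output space")
    if ml1.input_space.dim is None or ml2.input_space.dim is None:
        raise ContractError("direct_sum requires numeric input spaces")
    return DirectSumMorphism(ml1, ml2, op, a, b)


# -------------------------------------------------------------- collections
@dataclass
class Collection:
    """Ordered list of fitted morphisms sharing an output space."""

    members: list[Morphism] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.members:
            out = self.members[0].output_space
            for m in self.members[1:]:
                if m.output_space != out:
                    raise ContractError("collection members must share output space")

    @property
    def dimension(self) -> int:
        return len(self.members)


def _resolve_metric(metric: str | Callable) -> Callable:
    if callable(metric):
        return metric
    from mapperflow import evaluation

    return evaluation.metric_by_name(metric)


def evaluate_collection(
    coll: Collection, metric: str | Callable, X: Any, Y: Any
) -> np.ndarray:
    """Score every member on (X, Y) in declaration order."""
    if coll.dimension == 0:
        raise ContractError("empty collection")
    fn = _resolve_metric(metric)
    scores = []
    for m in coll.members:
        if not m.fitted:
            raise NotFittedError("collection member not fitted")
        scores.append(float(fn(np.asarray(Y), np.asarray(m.apply(X)))))
    return np.asarray(scores)


def select_best(
    coll: Collection, metric: str | Callable, X: Any, Y: Any
) -> tuple[int, Morphism]:
    """Pick the member maximising ``metric``; ties go to the lowest index."""
    scores = evaluate_collection(coll, metric, X, Y)
    idx = int(np.argmax(scores))  # argmax returns the first maximum
    return idx, coll.members[idx]
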