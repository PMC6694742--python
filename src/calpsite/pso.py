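"""Particle swarm optimization for hyperparameter search.

Standard global-best PSO: each particle carries a position x and velocity v
in a bounded real box; per iteration

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- clip(x + v, bounds)

with r1, r2 fresh uniform draws per particle and dimension.  Positions that
hit a bound are clipped and the violating velocity component zeroed.  The
defaults (w = 0.729, c1 = c2 = 1.49445) are the constriction-equivalent
constants common in the PSO literature.  Hyperparameter search minimizes
1 - mean inner-CV AUC of the decoded configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .nn import Hyperparameters
from .sequence_io import LabeledDataset


@dataclass
class SwarmConfig:
    """Swarm size, update constants, per-dimension box bounds, and the seed."""

    bounds: Sequence[tuple[float, float]]
    n_particles: int = 20
    n_iterations: int = 30
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bound ({lo}, {hi}) must have lower < upper")
        if self.n_particles < 1 or self.n_iterations < 0:
            raise ValueError("need n_particles >= 1 and n_iterations >= 0")
        if self.inertia <= 0 or self.cognitive < 0 or self.social < 0:
            raise ValueError("inertia must be > 0; cognitive/social weights >= 0")


@dataclass
class SearchResult:
    """Best position/value found and the per-iteration best-so-far trace."""

    best_position: np.ndarray
    best_value: float
    trace: list[float] = field(default_factory=list)


def optimize(objective: Callable[[np.ndarray], float], config: SwarmConfig) -> SearchResult:
    """Minimize ``objective`` over the bounded box by global-best PSO.

    The trace records the global best after initialization and after each
    iteration; it is non-increasing by construction.  Raises if the objective
    returns a non-finite value.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    dim = len(config.bounds)
    n = config.n_particles

    # velocity clamp: initial speeds at a tenth of the box width per dimension
    x = rng.uniform(lo, hi, size=(n, dim))
    v = rng.uniform(-(hi - lo) / 10.0, (hi - lo) / 10.0, size=(n, dim))

    def _eval(pos: np.ndarray) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite objective value at position {pos}")
        return val

    pbest = x.copy()
    pbest_val = np.array([_eval(x[i]) for i in range(n)])
    g = int(np.argmin(pbest_val))
    gbest = pbest[g].copy()
    gbest_val = float(pbest_val[g])
    trace = [gbest_val]

    for _ in range(config.n_iterations):
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest - x)
            + config.social * r2 * (gbest - x)
        )
        x = x + v
        low_hit = x < lo
        high_hit = x > hi
        x = np.clip(x, lo, hi)
        v[low_hit | high_hit] = 0.0
        for i in range(n):
            val = _eval(x[i])
            if val < pbest_val[i]:
                pbest_val[i] = val
                pbest[i] = x[i].copy()
                if val < gbest_val:
                    gbest_val = val
                    gbest = x[i].copy()
        trace.append(gbest_val)

    return SearchResult(best_position=gbest, best_value=gbest_val, trace=trace)


#: Default search space for the classifier: one shared hidden width per
#: branch, the merged width, the dropout rate, and log10 learning rate.
DEFAULT_SEARCH_SPACE = [
    {"name": "branch_width", "low": 4, "high": 64, "type": "int"},
    {"name": "merged_width", "low": 4, "high": 64, "type": "int"},
    {"name": "dropout_rate", "low": 0.0, "high": 0.5, "type": "float"},
    {"name": "log10_learning_rate", "low": -4.0, "high": -2.0, "type": "float"},
]


def decode_position(position: np.ndarray, space: Sequence[dict]) -> dict:
    """Map a real PSO position to named hyperparameter values.

    Float dimensions pass through; int dimensions round half-up.  The decode
    is idempotent on already-integral positions.
    """
    if len(position) != len(space):
        raise ValueError("position length does not match search space")
    out = {}
    for xi, dim in zip(position, space):
        if not dim["low"] <= xi <= dim["high"]:
            raise ValueError(
                f"position component {xi} outside bounds for {dim['name']}"
            )
        if dim["type"] == "int":
            out[dim["name"]] = int(np.floor(xi + 0.5))
        elif dim["type"] == "float":
            out[dim["name"]] = float(xi)
        else:
            raise ValueError(f"unknown dimension type {dim['type']!r}")
    return out


def hyperparameters_from_params(
    params: dict, template: Hyperparameters | None = None
) -> Hyperparameters:
    """Fill a :class:`Hyperparameters` from decoded search-space values."""
    base = template.to_dict() if template is not None else Hyperparameters().to_dict()
    if "branch_width" in params:
        base["branch_layers"] = [[params["branch_width"]]] * 4
    if "merged_width" in params:
        base["merged_layers"] = [params["merged_width"]]
    if "dropout_rate" in params:
        base["dropout_rate"] = params["dropout_rate"]
    if "log10_learning_rate" in params:
        base["learning_rate"] = 10.0 ** params["log10_learning_rate"]
    for key in ("batch_size", "epochs"):
        if key in params:
            base[key] = params[key]
    return Hyperparameters.from_dict(base)


def tune_model(
    dataset: LabeledDataset,
    swarm_config: SwarmConfig | None = None,
    space: Sequence[dict] = DEFAULT_SEARCH_SPACE,
    inner_folds: int = 3,
    seed: int = 0,
    search_epochs: int = 8,
    kmax: int = 3,
    template: Hyperparameters | None = None,
) -> tuple[Hyperparameters, SearchResult]:
    """PSO search over hyperparameters, scoring 1 - mean inner-CV AUC.

    Candidates train with a reduced epoch budget (``search_epochs``) to keep
    the search cheap; the returned configuration carries the template's full
    epoch budget for the final retraining.
    """
    from .evaluation import kfold_cv  # deferred: evaluation imports nn

    if swarm_config is None:
        swarm_config = SwarmConfig(
            bounds=[(d["low"], d["high"]) for d in space], seed=seed
        )

    def objective(position: np.ndarray) -> float:
        params = decode_position(position, space)
        hyper = hyperparameters_from_params(params, template)
        hyper = Hyperparameters.from_dict({**hyper.to_dict(), "epochs": search_epochs})
        cv = kfold_cv(dataset, k=inner_folds, hyper=hyper, seed=seed, kmax=kmax)
        return 1.0 - float(np.mean([f.auc for f in cv.folds]))

    result = optimize(objective, swarm_config)
    best = hyperparameters_from_params(decode_position(result.best_position, space), template)
    return best, result
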