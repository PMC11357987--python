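"""Stochastic-gradient hyperparameter search over hypercubic meshes.

Each iteration proposes candidates around the current hyperparameter vector
(the full ``3^N`` hypercubic mesh, or ``2N + 1`` coordinate directions),
evaluates every candidate on a fresh independent random minibatch, moves
integer parameters to the best candidate and takes a bounded gradient-ascent
step for real parameters. The incumbent (best-seen state) is tracked
alongside the full trajectory.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["HyperparamDef", "TuneTrajectory", "propose_mesh",
           "propose_coordinate", "sgd_tune"]


@dataclass
class HyperparamDef:
    """One tunable parameter: integers probe +/-1, reals +/-1e-6."""

    name: str
    kind: str                    # 'integer' | 'real'
    initial: float
    bounds: tuple[float, float]
    step: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "real"):
            raise InvalidParameterError(f"unknown kind {self.kind!r}")
        if self.step is None:
            self.step = 1.0 if self.kind == "integer" else 1e-6
        if not self.step > 0:
            raise InvalidParameterError("step must be positive")
        lo, hi = self.bounds
        if not (lo <= self.initial <= hi):
            raise InvalidParameterError(
                f"initial value {self.initial} outside bounds {self.bounds}")

    def clip(self, value: float) -> float:
        value = float(np.clip(value, *self.bounds))
        return float(round(value)) if self.kind == "integer" else value

    @property
    def scale(self) -> float:
        return self.bounds[1] - self.bounds[0]


@dataclass
class TuneTrajectory:
    states: list[tuple[float, ...]] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    minibatches: list[list] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    best_state: tuple[float, ...] | None = None
    best_objective: float = -np.inf

    def incumbent_curve(self) -> np.ndarray:
        """Best-seen objective after each iteration (non-decreasing)."""
        return np.maximum.accumulate(np.asarray(self.objectives))

    def to_dict(self) -> dict:
        return {"states": [list(s) for s in self.states],
                "objectives": self.objectives,
                "minibatches": self.minibatches,
                "accepted": self.accepted,
                "best_state": list(self.best_state) if self.best_state else None,
                "best_objective": self.best_objective}


def propose_mesh(state: list[float], defs: list[HyperparamDef]
                 ) -> list[tuple[float, ...]]:
    """All 3^N combinations of {-step, 0, +step}, clipped and deduplicated."""
    if not defs:
        raise InvalidParameterError("need >= 1 hyperparameter")
    axes = [[d.clip(x - d.step), d.clip(x), d.clip(x + d.step)]
            for x, d in zip(state, defs)]
    seen: dict[tuple[float, ...], None] = {}
    for combo in itertools.product(*axes):
        seen.setdefault(tuple(combo))
    return list(seen)


def propose_coordinate(state: list[float], defs: list[HyperparamDef]
                       ) -> list[tuple[float, ...]]:
    """Current point plus +/-step along each coordinate (2N+1 before clip)."""
    if not defs:
        raise InvalidParameterError("need >= 1 hyperparameter")
    current = tuple(d.clip(x) for x, d in zip(state, defs))
    seen: dict[tuple[float, ...], None] = {current: None}
    for k, d in enumerate(defs):
        for sign in (-1.0, 1.0):
            cand = list(current)
            cand[k] = d.clip(state[k] + sign * d.step)
            seen.setdefault(tuple(cand))
    return list(seen)


def sgd_tune(objective, defs: list[HyperparamDef], n_iter: int = 50,
             minibatch_size: int | None = None, n_data: int | None = None,
             seed: int = 0, mode: str = "mesh", learning_rate: float = 0.1,
             plateau: int = 10) -> TuneTrajectory:
    """Maximize ``objective(state, minibatch) -> float`` by stochastic search.

    A fresh independent minibatch (ids sampled from ``range(n_data)``) is
    drawn per candidate per iteration; with ``n_data=None`` the objective
    receives ``minibatch=None`` (full data). Integer parameters jump to the
    argmax candidate; real parameters take a bounded step
    ``learning_rate * scale * sign(slope)`` along the central-difference
    slope. Equal-objective ties keep the current state. Stops at ``n_iter``
    or when the state has not changed for ``plateau`` iterations.
    """
    if mode not in ("mesh", "coordinate"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    propose = propose_mesh if mode == "mesh" else propose_coordinate
    state = tuple(d.clip(d.initial) for d in defs)
    traj = TuneTrajectory()
    stale = 0

    def draw_batch():
        if n_data is None:
            return None
        size = min(minibatch_size or n_data, n_data)
        return [int(i) for i in rng.choice(n_data, size=size, replace=False)]

    for _it in range(n_iter):
        candidates = propose(list(state), defs)
        values: dict[tuple[float, ...], float] = {}
        batches: dict[tuple[float, ...], list | None] = {}
        for cand in candidates:
            batch = draw_batch()
            val = float(objective(list(cand), batch))
            if not np.isfinite(val):
                warnings.warn(f"objective non-finite at {cand}; candidate "
                              "discarded", stacklevel=2)
                continue
            values[cand] = val
            batches[cand] = batch
        if not values:
            break
        best_cand = max(values, key=values.get)
        cur_val = values.get(state, -np.inf)
        if cur_val >= values[best_cand]:
            best_cand = state  # tie-break: keep the current state

        new_state = list(best_cand)
        for k, d in enumerate(defs):
            if d.kind != "real":
                continue
            plus = tuple(state[:k] + (d.clip(state[k] + d.step),) + state[k + 1:])
            minus = tuple(state[:k] + (d.clip(state[k] - d.step),) + state[k + 1:])
            if plus in values and minus in values:
                slope = values[plus] - values[minus]
            elif plus in values:
                slope = values[plus] - values.get(state, cur_val)
            else:
                slope = 0.0
            if slope != 0.0:
                new_state[k] = d.clip(state[k] + learning_rate * d.scale
                                      * np.sign(slope))
            else:
                new_state[k] = state[k]
        new_state = tuple(new_state)

        accepted = new_state != state
        traj.states.append(new_state)
        traj.objectives.append(values[best_cand])
        traj.minibatches.append(batches[best_cand])
        traj.accepted.append(accepted)
        if values[best_cand] > traj.best_objective:
            traj.best_objective = values[best_cand]
            traj.best_state = best_cand
        stale = 0 if accepted else stale + 1
        state = new_state
        if stale >= plateau:
            break
    if traj.best_state is None:
        traj.best_state = state
    return traj
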